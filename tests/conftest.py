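import numpy as np
import pytest

from cropsae import SimConfig, TrainConfig, assemble_dataset, simulate_cropseq


@pytest.fixture(scope="session")
def small_sim():
    """A small planted screen: 60+60 cells, 40 genes, 4 signature genes."""
    cfg = SimConfig(n_control=60, n_targeted=60, n_genes=40, n_signature=4,
                    signature_lfc=(2.0, -2.0, 2.0, -2.0), frac_perturbed=0.7,
                    seed=3)
    counts, annotations, truth = simulate_cropseq(cfg)
    dataset = assemble_dataset(counts, annotations, cfg.target_gene,
                               cfg.condition)
    return cfg, counts, annotations, truth, dataset


@pytest.fixture(scope="session")
def fast_config():
    """A cheap training configuration for unit tests."""
    return TrainConfig(eta=8.0, hidden_dim=16, epochs_phase1=40,
                       epochs_phase2=40, n_folds=4, n_seeds=2, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
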