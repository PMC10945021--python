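"""Attribution, rank aggregation, fold changes and signature assembly."""

import numpy as np
import pandas as pd
import pytest

from cropsae.model import SSAEWeights, forward
from cropsae.signature import (aggregate_ranks, attribute_cells,
                               attribute_features, build_signature,
                               compute_log2fc, log2fc_from_means, rank_genes)
from cropsae.io import LabeledDataset


def _positive_region_weights(rng, d=6, h=4):
    """Weights whose ReLU units stay active on nonnegative inputs: positive
    first-layer weights and large positive biases make the network linear
    over the whole evaluation region."""
    return SSAEWeights(
        W1=np.abs(rng.normal(size=(d, h))), b1=np.full(h, 10.0),
        W2=rng.normal(size=(h, 2)), b2=np.zeros(2),
        W3=rng.normal(size=(2, h)), b3=np.full(h, 100.0),
        W4=rng.normal(size=(h, d)), b4=np.zeros(d),
    )


def test_linear_network_attribution_closed_form(rng):
    w = _positive_region_weights(rng)
    coef = w.W1 @ w.W2[:, 1]            # end-to-end linear coefficient
    x = rng.uniform(1, 5, size=6)
    b = rng.uniform(1, 5, size=6)
    attr = attribute_cells(w, x[None, :], b[None, :], n_baseline_samples=1)
    np.testing.assert_allclose(attr[0], (x - b) * coef, rtol=1e-9)


def test_attribution_completeness_fixed_region(rng):
    """Per-cell attributions sum to logit(x) minus the mean baseline logit."""
    w = _positive_region_weights(rng, d=8, h=5)
    X = rng.uniform(1, 6, size=(3, 8))
    pool = rng.uniform(1, 6, size=(7, 8))
    attr = attribute_cells(w, X, pool, n_baseline_samples=4, seed=1)
    picks = np.random.default_rng(1).choice(7, size=4, replace=False)
    logit = lambda M: forward(w, np.atleast_2d(M)).Z[:, 1]
    base_mean = logit(pool[picks]).mean()
    np.testing.assert_allclose(attr.sum(axis=1), logit(X) - base_mean,
                               rtol=0.05)


def test_dead_gene_gets_zero_attribution(rng):
    w = _positive_region_weights(rng)
    w.W1[2, :] = 0.0
    X = rng.uniform(1, 5, size=(4, 6))
    pool = rng.uniform(1, 5, size=(5, 6))
    attr = attribute_features(w, X, pool, n_baseline_samples=3)
    assert attr[2] == 0.0
    assert np.all(attr[[0, 1, 3, 4, 5]] > 0)


def test_attribution_requires_baselines(rng):
    w = _positive_region_weights(rng)
    with pytest.raises(ValueError, match="empty"):
        attribute_features(w, np.ones((1, 6)), np.empty((0, 6)))


def test_rank_genes_orders_by_attribution():
    attr = np.array([0.0, 3.0, 1.0, 0.0, 2.0])
    ranks = rank_genes(attr)
    assert ranks.tolist() == [5, 1, 3, 5, 2]


def test_rank_genes_tie_break_deterministic():
    ranks = rank_genes(np.array([1.0, 1.0, 2.0]))
    assert ranks.tolist() == [2, 3, 1]


@pytest.mark.parametrize("ranks,mean,sd", [
    ((1.0, 1.0, 1.0), 1.0, 0.0),
    ((1.0, 500.0, 1000.0), 500.3333, 499.5001),
])
def test_aggregate_ranks_formulas(ranks, mean, sd):
    runs = [np.array([r]) for r in ranks]   # one gene, one run per element
    m, s = aggregate_ranks(runs)
    assert m[0] == pytest.approx(mean, abs=1e-3)
    assert s[0] == pytest.approx(sd, abs=1e-3)


def test_aggregate_ranks_needs_two_runs():
    with pytest.raises(ValueError, match="two rankings"):
        aggregate_ranks([np.array([1.0, 2.0])])


def test_aggregate_ranks_permutation_equivariant(rng):
    runs = [rng.permutation(10).astype(float) + 1 for _ in range(3)]
    perm = rng.permutation(10)
    m1, s1 = aggregate_ranks(runs)
    m2, s2 = aggregate_ranks([r[perm] for r in runs])
    np.testing.assert_allclose(m2, m1[perm])
    np.testing.assert_allclose(s2, s1[perm])


@pytest.mark.parametrize("mp,mc,eps,expected", [
    (8.0, 2.0, 0.0, 2.0),
    (3.0, 3.0, 1.0, 0.0),
    (0.0, 4.0, 1.0, np.log2(1 / 5)),
])
def test_log2fc_from_means(mp, mc, eps, expected):
    assert log2fc_from_means(np.array([mp]), np.array([mc]),
                             eps)[0] == pytest.approx(expected, abs=1e-6)


def test_compute_log2fc_identical_groups_is_zero():
    rng = np.random.default_rng(0)
    block = rng.poisson(4.0, size=(5, 6)).astype(float)
    ds = LabeledDataset(X=np.vstack([block, block]),
                        Y=np.array([0] * 5 + [1] * 5),
                        gene_ids=[f"g{i}" for i in range(6)], target_gene="t",
                        condition="c", barcodes=[f"b{i}" for i in range(10)])
    lfc = compute_log2fc(ds, ds.targeted_indices)
    np.testing.assert_allclose(lfc, 0.0, atol=1e-12)


def _toy_signature_inputs():
    d = 6
    gene_ids = [f"g{i}" for i in range(d)]
    # gene 0 always rank 1; gene 1 wildly unstable; others middling
    rankings = [np.array([1, 2, 3, 4, 5, 6], dtype=float),
                np.array([1, 6, 2, 3, 4, 5], dtype=float),
                np.array([1, 5, 3, 2, 6, 4], dtype=float)]
    attributions = [np.array([5.0, 1.0, 0.8, 0.7, 0.5, 0.4])] * 3
    log2fc = np.array([1.2, -0.3, 0.5, -0.5, 0.1, -0.1])
    return attributions, rankings, log2fc, gene_ids


def test_build_signature_ordering_direction_stability():
    attributions, rankings, log2fc, gene_ids = _toy_signature_inputs()
    sig = build_signature(attributions, rankings, log2fc, gene_ids,
                          top_n=6, sd_threshold=1.5)
    assert sig.iloc[0]["gene"] == "g0"
    assert sig.iloc[0]["direction"] == "up"
    assert bool(sig.iloc[0]["stable"]) is True
    g1 = sig[sig.gene == "g1"].iloc[0]
    assert bool(g1["stable"]) is False          # sd of (2,6,5) > 1.5
    assert g1["direction"] == "down"


def test_build_signature_warns_when_few_selected():
    attributions = [np.array([1.0, 0.5, 0.0, 0.0])] * 2
    rankings = [np.array([1.0, 2.0, 4.0, 4.0])] * 2
    log2fc = np.zeros(4)
    with pytest.warns(UserWarning, match="ever selected"):
        sig = build_signature(attributions, rankings, log2fc,
                              ["a", "b", "c", "d"], top_n=20)
    assert len(sig) == 2


def test_build_signature_table_is_sorted_by_mean_rank():
    attributions, rankings, log2fc, gene_ids = _toy_signature_inputs()
    sig = build_signature(attributions, rankings, log2fc, gene_ids, top_n=6)
    assert sig["mean_rank"].is_monotonic_increasing
    assert isinstance(sig, pd.DataFrame)
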