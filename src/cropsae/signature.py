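"""Feature attribution and perturbation-signature construction.

Gene importance is computed by Shapley-style path integration: for an
evaluation cell x (perturbed class) and a baseline b sampled from the
control pool, the attribution of gene g is ``(x_g - b_g)`` times the path
integral of the gradient of the class-1 logit along the straight line from
b to x (integrated gradients).  Averaging over sampled baselines
approximates a Shapley value under the baseline distribution; the per-gene
importance is the mean absolute attribution over evaluation cells.  Because
the logit depends on the input only through the sparse first layer, genes
outside the selected support receive exactly zero.

Attributions from repeated runs (seeds x control subsamples) are turned
into per-run gene rankings; their mean and standard deviation across runs
quantify the signature and its stability.  Direction comes from the log2
fold change of library-size-normalized counts, perturbed versus control
cells.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import LabeledDataset, SIGNATURE_COLUMNS
from .model import SSAEWeights, class1_logit_input_gradient, forward

__all__ = [
    "integrated_gradients", "attribute_cells", "attribute_features",
    "rank_genes", "aggregate_ranks", "compute_log2fc", "log2fc_from_means",
    "build_signature",
]


def integrated_gradients(weights: SSAEWeights, x: np.ndarray,
                         baseline: np.ndarray, n_steps: int = 50) -> np.ndarray:
    """Signed per-gene attribution of the class-1 logit for one cell and one
    baseline, midpoint-rule path integration with ``n_steps`` points."""
    x = np.asarray(x, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    alphas = (np.arange(n_steps) + 0.5) / n_steps
    points = baseline + alphas[:, None] * (x - baseline)
    grads = class1_logit_input_gradient(weights, points)
    return (x - baseline) * grads.mean(axis=0)


def attribute_cells(weights: SSAEWeights, X_eval: np.ndarray,
                    baseline_pool: np.ndarray, n_baseline_samples: int = 10,
                    seed: int = 0, n_steps: int = 50) -> np.ndarray:
    """Signed attributions (n_eval, d): mean integrated gradients over
    baselines sampled from the control pool (seeded, without replacement
    when the pool allows)."""
    X_eval = np.atleast_2d(np.asarray(X_eval, dtype=float))
    baseline_pool = np.atleast_2d(np.asarray(baseline_pool, dtype=float))
    if baseline_pool.shape[0] == 0:
        raise ValueError("baseline pool is empty")
    rng = np.random.default_rng(seed)
    k = min(n_baseline_samples, baseline_pool.shape[0])
    picks = rng.choice(baseline_pool.shape[0], size=k, replace=False)
    total = np.zeros_like(X_eval)
    for b_idx in picks:
        b = baseline_pool[b_idx]
        for i, x in enumerate(X_eval):
            total[i] += integrated_gradients(weights, x, b, n_steps=n_steps)
    return total / k


def attribute_features(weights: SSAEWeights, X_eval: np.ndarray,
                       baseline_pool: np.ndarray, n_baseline_samples: int = 10,
                       seed: int = 0, n_steps: int = 50,
                       max_eval_cells: int | None = 64) -> np.ndarray:
    """Per-gene importance: mean |attribution| over evaluation cells.

    ``X_eval`` should hold perturbed-class cells and ``baseline_pool``
    control cells.  Evaluation cells beyond ``max_eval_cells`` are
    subsampled (seeded) to bound runtime.
    """
    X_eval = np.atleast_2d(np.asarray(X_eval, dtype=float))
    rng = np.random.default_rng(seed)
    if max_eval_cells is not None and X_eval.shape[0] > max_eval_cells:
        keep = rng.choice(X_eval.shape[0], size=max_eval_cells, replace=False)
        X_eval = X_eval[keep]
    attr = attribute_cells(weights, X_eval, baseline_pool,
                           n_baseline_samples=n_baseline_samples,
                           seed=seed, n_steps=n_steps)
    return np.abs(attr).mean(axis=0)


def rank_genes(attribution: np.ndarray) -> np.ndarray:
    """Rank genes by descending attribution: 1 = most important.

    Genes with zero attribution (outside the selected support) all receive
    the worst rank d.  Ties among nonzero attributions break by gene index
    (deterministic).
    """
    attribution = np.asarray(attribution, dtype=float)
    d = attribution.size
    ranks = np.full(d, d, dtype=float)
    sel = np.flatnonzero(attribution > 0)
    if sel.size:
        order = sel[np.lexsort((sel, -attribution[sel]))]
        ranks[order] = np.arange(1, sel.size + 1)
    return ranks


def aggregate_ranks(rankings: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Mean and sample standard deviation of per-gene ranks across runs."""
    if len(rankings) < 2:
        raise ValueError("at least two rankings are required to compute a"
                         " rank standard deviation")
    R = np.asarray(rankings, dtype=float)
    if R.ndim != 2:
        raise ValueError("rankings must share one gene universe")
    return R.mean(axis=0), R.std(axis=0, ddof=1)


def log2fc_from_means(mean_perturbed: np.ndarray, mean_control: np.ndarray,
                      pseudocount: float = 1.0) -> np.ndarray:
    return np.log2((np.asarray(mean_perturbed, dtype=float) + pseudocount)
                   / (np.asarray(mean_control, dtype=float) + pseudocount))


def compute_log2fc(dataset: LabeledDataset, perturbed_indices,
                   pseudocount: float = 1.0) -> np.ndarray:
    """Per-gene log2 fold change, perturbed versus control cells.

    Counts are library-size normalized (scaled to the median library) before
    group means are taken; a pseudocount guards against zero means.
    Positive values mean upregulation in perturbed cells.
    """
    perturbed_indices = np.asarray(perturbed_indices, dtype=int)
    controls = dataset.control_indices
    if perturbed_indices.size == 0 or controls.size == 0:
        raise ValueError("both the perturbed and control groups must be non-empty")
    X = dataset.X
    lib = X.sum(axis=1)
    lib[lib == 0] = 1.0
    Xn = X / lib[:, None] * np.median(lib)
    return log2fc_from_means(Xn[perturbed_indices].mean(axis=0),
                             Xn[controls].mean(axis=0), pseudocount)


def build_signature(attributions: list[np.ndarray], rankings: list[np.ndarray],
                    log2fc: np.ndarray, gene_ids: list[str],
                    top_n: int = 20, sd_threshold: float | None = None
                    ) -> pd.DataFrame:
    """Assemble the ranked, direction-annotated signature table.

    Takes per-run attribution vectors and rank vectors, aggregates ranks
    (mean, sd) across runs, keeps the ``top_n`` ever-selected genes by mean
    rank (ties broken by higher mean attribution, then gene id), annotates
    direction from the log2FC sign, and flags genes whose rank sd is at most
    ``sd_threshold`` (default d/20) as stable.
    """
    d = len(gene_ids)
    mean_rank, sd_rank = aggregate_ranks(rankings)
    A = np.asarray(attributions, dtype=float)
    mean_attr = A.mean(axis=0)
    if sd_threshold is None:
        sd_threshold = d / 20.0
    ever_selected = np.flatnonzero((A > 0).any(axis=0))
    if ever_selected.size == 0:
        raise ValueError("no gene was ever selected; cannot build a signature")
    if ever_selected.size < top_n:
        warnings.warn(
            f"only {ever_selected.size} genes were ever selected; returning "
            f"all of them instead of top {top_n}")
    table = pd.DataFrame({
        "gene": [gene_ids[i] for i in ever_selected],
        "attribution": mean_attr[ever_selected],
        "mean_rank": mean_rank[ever_selected],
        "sd_rank": sd_rank[ever_selected],
        "log2fc": np.asarray(log2fc, dtype=float)[ever_selected],
    })
    table["direction"] = np.where(table["log2fc"] > 0, "up", "down")
    table["stable"] = table["sd_rank"] <= sd_threshold
    table = table.sort_values(
        ["mean_rank", "attribution", "gene"],
        ascending=[True, False, True], kind="mergesort",
    ).head(top_n).reset_index(drop=True)
    return table[SIGNATURE_COLUMNS]
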