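"""Two-round selection of actually-perturbed cells.

Round 1 trains the SSAE on all control versus all gRNA-targeted cells; each
cell's out-of-fold softmax class-1 probability, averaged over seeds, is its
perturbation score.  Targeted cells scoring strictly above 0.5 are called
"perturbed"; the rest "non-perturbed" (a score exactly at the threshold is
conservatively non-perturbed).  Round 2 re-trains on the perturbed cells
against an equal number of freshly sampled control cells (class-balanced),
once per seed with an independent control subsample, and the perturbation
signature is aggregated over those runs.  When too few cells are selected
for cross-validation, round 2 is skipped with an explicit reason and the
round-1 report stands.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import LabeledDataset
from .signature import (attribute_features, build_signature, compute_log2fc,
                        rank_genes)
from .train import FitReport, FoldRecord, TrainConfig, crossvalidate

__all__ = [
    "PerturbationScores", "TwoStepResult",
    "score_cells", "scores_from_report", "select_perturbed",
    "build_second_round", "run_two_step",
]


@dataclass
class PerturbationScores:
    """Per-cell class-1 probabilities: one row per seed, plus the mean."""

    per_seed: np.ndarray   # (n_seeds, n_cells)
    mean: np.ndarray       # (n_cells,)

    def __post_init__(self):
        if np.nanmin(self.mean) < 0 or np.nanmax(self.mean) > 1:
            raise ValueError("scores must lie in [0, 1]")


def scores_from_report(report: FitReport) -> PerturbationScores:
    """Perturbation scores from a cross-validation report's out-of-fold
    probabilities, averaged over seeds."""
    return PerturbationScores(per_seed=report.oof_scores,
                              mean=report.oof_scores.mean(axis=0))


def score_cells(dataset: LabeledDataset, config: TrainConfig) -> PerturbationScores:
    """Out-of-fold perturbation score for every cell (controls included)."""
    return scores_from_report(crossvalidate(dataset, config))


def select_perturbed(scores: PerturbationScores, dataset: LabeledDataset,
                     threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Partition the *targeted* cells by the strict score threshold.

    Returns ``(perturbed_indices, non_perturbed_indices)`` as dataset cell
    indices.  Only Y = 1 cells are partitioned; controls never enter the
    perturbed set regardless of score.
    """
    targeted = dataset.targeted_indices
    above = scores.mean[targeted] > threshold
    return targeted[above], targeted[~above]


def build_second_round(dataset: LabeledDataset, perturbed_indices,
                       seed: int) -> LabeledDataset:
    """Balanced round-2 dataset: all perturbed cells plus an equal number of
    controls sampled without replacement (seeded).

    If fewer controls exist than perturbed cells, all controls are used and
    a warning is emitted (classes then stay slightly unbalanced).
    """
    perturbed_indices = np.asarray(perturbed_indices, dtype=int)
    if perturbed_indices.size == 0:
        raise ValueError("no perturbed cells to build a second round from")
    controls = dataset.control_indices
    rng = np.random.default_rng(seed)
    if controls.size < perturbed_indices.size:
        warnings.warn(
            f"only {controls.size} controls available for "
            f"{perturbed_indices.size} perturbed cells; using all controls")
        picked = controls
    else:
        picked = rng.choice(controls, size=perturbed_indices.size, replace=False)
    picked = np.sort(picked)
    order = np.concatenate([picked, perturbed_indices])
    return LabeledDataset(
        X=dataset.X[order],
        Y=np.concatenate([np.zeros(picked.size, dtype=int),
                          np.ones(perturbed_indices.size, dtype=int)]),
        gene_ids=dataset.gene_ids, target_gene=dataset.target_gene,
        condition=dataset.condition,
        barcodes=[dataset.barcodes[i] for i in order])


@dataclass
class TwoStepResult:
    """Everything the two-round procedure produces for one (target,
    condition) pair."""

    first_report: FitReport
    scores: PerturbationScores
    perturbed_indices: np.ndarray
    pct_perturbed: float
    skipped_second_round: bool
    skip_reason: str | None = None
    second_report: FitReport | None = None
    signature: pd.DataFrame | None = field(default=None, repr=False)

    def summary(self) -> dict:
        out = {
            "target_gene": None,
            "n_perturbed": int(np.asarray(self.perturbed_indices).size),
            "pct_perturbed": self.pct_perturbed,
            "round1": self.first_report.to_dict(),
            "skipped_second_round": self.skipped_second_round,
            "skip_reason": self.skip_reason,
            "round2": self.second_report.to_dict() if self.second_report else None,
        }
        return out

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))


def _second_round_signature(dataset: LabeledDataset, perturbed: np.ndarray,
                            config: TrainConfig, top_n: int,
                            sd_threshold: float | None,
                            seeds: list[int]) -> tuple[FitReport, pd.DataFrame]:
    """One balanced CV per seed (independent control subsample each time);
    attribution per run = mean over fold models evaluated on their held-out
    perturbed cells, baselines drawn from the run's control cells."""
    records: list[FoldRecord] = []
    attributions, rankings = [], []
    for seed_idx, run_seed in enumerate(seeds):
        ds2 = build_second_round(dataset, perturbed, seed=run_seed)
        cfg2 = replace(config, n_seeds=1, seed=run_seed)
        rep = crossvalidate(ds2, cfg2, keep_models=True)
        for r in rep.records:
            records.append(replace(r, seed=seed_idx))
        fold_attrs = []
        ctrl = ds2.X[ds2.Y == 0]
        for m in rep.fold_models:
            test_idx = m["test_idx"]
            eval_cells = ds2.X[test_idx][ds2.Y[test_idx] == 1]
            if eval_cells.shape[0] == 0:
                continue
            fold_attrs.append(attribute_features(
                m["weights"], eval_cells, ctrl, seed=run_seed))
        attr_run = np.mean(fold_attrs, axis=0)
        attributions.append(attr_run)
        rankings.append(rank_genes(attr_run))
    second_report = FitReport(records=records,
                              oof_scores=np.zeros((0, 0)),
                              n_folds=config.n_folds, n_seeds=len(seeds))
    log2fc = compute_log2fc(dataset, perturbed)
    sig = build_signature(attributions, rankings, log2fc, dataset.gene_ids,
                          top_n=top_n, sd_threshold=sd_threshold)
    return second_report, sig


def run_two_step(dataset: LabeledDataset, config: TrainConfig,
                 min_cells_per_class: int = 40, top_n: int = 20,
                 sd_threshold: float | None = None) -> TwoStepResult:
    """The full two-round procedure for one (target, condition) dataset.

    Round 1: cross-validated SSAE on controls versus targeted cells; scores
    from out-of-fold probabilities; strict >0.5 selection of perturbed
    cells.  If fewer than ``min_cells_per_class`` cells are selected, the
    second round cannot be cross-validated and is skipped with a reason.
    Otherwise round 2 runs one balanced CV per seed and the signature is
    aggregated across those runs.
    """
    first_report = crossvalidate(dataset, config)
    scores = scores_from_report(first_report)
    perturbed, _ = select_perturbed(scores, dataset)
    n_targeted = dataset.targeted_indices.size
    pct = float(perturbed.size / n_targeted) if n_targeted else 0.0

    if perturbed.size < min_cells_per_class:
        return TwoStepResult(
            first_report=first_report, scores=scores,
            perturbed_indices=perturbed, pct_perturbed=pct,
            skipped_second_round=True,
            skip_reason=(
                f"only {perturbed.size} perturbed cells selected "
                f"(< {min_cells_per_class}); too few for "
                f"{config.n_folds}-fold cross-validation"))

    seeds = [int(s) % (2 ** 31)
             for s in np.random.SeedSequence(config.seed).generate_state(
                 config.n_seeds, dtype=np.uint64)]
    second_report, sig = _second_round_signature(
        dataset, perturbed, config, top_n, sd_threshold, seeds)
    return TwoStepResult(
        first_report=first_report, scores=scores,
        perturbed_indices=perturbed, pct_perturbed=pct,
        skipped_second_round=False, second_report=second_report,
        signature=sig)
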