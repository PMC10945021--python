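"""Projected double-descent training, cross-validated evaluation, eta tuning.

Training follows the pruning-style double descent recipe: train with Adam
while projecting the first encoder layer onto the l1,1 ball after every
step (projected gradient); record which gene rows survived (the support);
rewind all weights to their initial values with the dead rows frozen at
zero; retrain under the same projection.  The surviving rows are the
selected genes.

Evaluation is stratified k-fold cross-validation repeated over several
initialization seeds; out-of-fold class-1 probabilities double as the
per-cell perturbation scores consumed by the cell-selection stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .io import LabeledDataset
from .model import (Adam, SSAEWeights, accuracy_f1, forward, init_weights,
                    loss_and_grads)
from .projection import project_l11_bilevel, selected_feature_fraction

__all__ = [
    "TrainConfig", "FoldRecord", "FitReport", "TrainResult",
    "InsufficientCellsError", "TrainingDivergedError",
    "train_double_descent", "crossvalidate", "tune_eta",
]


class InsufficientCellsError(ValueError):
    """A class has too few cells for stratified cross-validation."""


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during optimization."""


@dataclass
class TrainConfig:
    """Hyperparameters of one SSAE run.

    ``lam`` weighs the Huber reconstruction term against the cross-entropy;
    ``eta`` is the l1,1 radius of the first encoder layer (smaller eta,
    fewer genes kept).  Defaults are desk-scale choices: Adam at 1e-3,
    full-batch gradients (``batch_size=None``), 120 + 120 epochs for the
    two descent phases, 4-fold CV averaged over 3 seeds.

    Full-batch projected gradients are the default deliberately: with
    minibatches, Adam's per-coordinate step normalization amplifies the
    gradient noise of uninformative genes enough to keep their rows alive
    through the projection, crowding weakly informative genes (notably
    down-regulated, lowly expressed ones) out of the selected support.
    Averaging the gradient over all cells cancels that noise and markedly
    improves recovery of weak signature genes.
    """

    lam: float = 1.0
    eta: float = 25.0
    hidden_dim: int = 100
    lr: float = 1e-3
    epochs_phase1: int = 120
    epochs_phase2: int = 120
    batch_size: int | None = None
    n_folds: int = 4
    n_seeds: int = 3
    huber_delta: float = 1.0
    class_weighting: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if min(self.epochs_phase1, self.epochs_phase2) < 1:
            raise ValueError("epoch counts must be at least 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainResult:
    weights: SSAEWeights
    support: np.ndarray          # boolean per gene: survived phase 1 & 2
    history: list[dict]          # per (phase, epoch) loss components


@dataclass(frozen=True)
class FoldRecord:
    fold: int
    seed: int
    accuracy: float
    f1: float
    selected_fraction: float


@dataclass
class FitReport:
    """Cross-validation summary: n_folds x n_seeds records plus the
    out-of-fold score matrix (n_seeds, n_cells) of class-1 probabilities."""

    records: list[FoldRecord]
    oof_scores: np.ndarray
    n_folds: int
    n_seeds: int
    fold_models: list[dict] | None = field(default=None, repr=False)

    def _vals(self, attr):
        return np.array([getattr(r, attr) for r in self.records])

    @property
    def accuracy_mean(self) -> float:
        return float(self._vals("accuracy").mean())

    @property
    def accuracy_sd(self) -> float:
        return float(self._vals("accuracy").std(ddof=1))

    @property
    def f1_mean(self) -> float:
        return float(self._vals("f1").mean())

    @property
    def f1_sd(self) -> float:
        return float(self._vals("f1").std(ddof=1))

    @property
    def selected_fraction_mean(self) -> float:
        return float(self._vals("selected_fraction").mean())

    def to_dict(self) -> dict:
        return {
            "accuracy_mean": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
            "f1_mean": self.f1_mean,
            "f1_sd": self.f1_sd,
            "selected_fraction_mean": self.selected_fraction_mean,
            "records": [asdict(r) for r in self.records],
        }


def _class_weights(Y: np.ndarray, enabled: bool) -> np.ndarray | None:
    if not enabled:
        return None
    counts = np.bincount(Y, minlength=2).astype(float)
    if np.any(counts == 0):
        return None
    return counts.sum() / (2.0 * counts)


def _run_phase(weights: SSAEWeights, X, Y, config: TrainConfig, epochs: int,
               rng: np.random.Generator, support: np.ndarray | None,
               history: list[dict], phase: int) -> None:
    """Minibatch Adam with per-step projection of the first layer.

    When ``support`` is given (phase 2), gradients of dead gene rows are
    masked so they stay exactly zero.
    """
    n = X.shape[0]
    bs = config.batch_size or n
    cw = _class_weights(Y, config.class_weighting)
    opt = Adam(weights, lr=config.lr)
    dead = None if support is None else ~support
    for epoch in range(epochs):
        order = rng.permutation(n) if bs < n else np.arange(n)
        tot = ce = rec = 0.0
        n_batches = 0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            loss, ce_b, rec_b, grads = loss_and_grads(
                weights, X[idx], Y[idx], lam=config.lam,
                delta=config.huber_delta, class_weights=cw)
            if not math.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at phase {phase}, epoch {epoch}")
            if dead is not None:
                grads["W1"][dead] = 0.0
            opt.step(grads)
            if dead is not None:
                weights.W1[dead] = 0.0
            weights.W1[...] = project_l11_bilevel(weights.W1, config.eta)
            tot += loss
            ce += ce_b
            rec += rec_b
            n_batches += 1
        history.append({
            "phase": phase, "epoch": epoch,
            "total": tot / n_batches, "ce": ce / n_batches,
            "reconstruction": rec / n_batches,
            "selected_fraction": selected_feature_fraction(weights.W1),
        })


def train_double_descent(dataset: LabeledDataset, config: TrainConfig,
                         seed: int) -> TrainResult:
    """Two-phase projected training with weight rewinding.

    Phase 1 trains from a seeded initialization with per-step l1,1
    projection; the support is the set of gene rows still nonzero at its
    end.  All weights are then rewound to their initial values, dead rows
    frozen at zero, and phase 2 retrains under the same constraint.  The
    final support is a subset of the phase-1 support.
    """
    X, Y = dataset.X, dataset.Y
    if len(np.unique(Y)) < 2:
        raise InsufficientCellsError("training data contains a single class")
    ss = np.random.SeedSequence(seed)
    init_rng, rng1, rng2 = (np.random.default_rng(s) for s in ss.spawn(3))
    init = init_weights(dataset.n_genes, config.hidden_dim, init_rng)

    history: list[dict] = []
    weights = init.copy()
    _run_phase(weights, X, Y, config, config.epochs_phase1, rng1,
               support=None, history=history, phase=1)
    support = np.abs(weights.W1).sum(axis=1) > 1e-12

    # rewind to initial configuration, dead rows frozen at zero
    weights = init.copy()
    weights.W1[~support] = 0.0
    _run_phase(weights, X, Y, config, config.epochs_phase2, rng2,
               support=support, history=history, phase=2)
    final_support = np.abs(weights.W1).sum(axis=1) > 1e-12
    return TrainResult(weights=weights, support=final_support, history=history)


def _check_cv_feasible(Y: np.ndarray, n_folds: int) -> None:
    counts = np.bincount(Y, minlength=2)
    if counts.min() < n_folds:
        raise InsufficientCellsError(
            f"insufficient cells for {n_folds}-fold cross-validation: "
            f"class sizes {counts.tolist()}")


def crossvalidate(dataset: LabeledDataset, config: TrainConfig,
                  keep_models: bool = False) -> FitReport:
    """Stratified k-fold CV repeated over ``n_seeds`` initialization seeds.

    Every (fold, seed) pair trains :func:`train_double_descent` on the
    remaining folds and evaluates accuracy/F1 on the held-out fold.  The
    out-of-fold class-1 probabilities are collected per seed; they are the
    perturbation scores of the two-step procedure.
    """
    X, Y = dataset.X, dataset.Y
    _check_cv_feasible(Y, config.n_folds)
    n = dataset.n_cells
    records: list[FoldRecord] = []
    oof = np.full((config.n_seeds, n), np.nan)
    models: list[dict] = []
    master = np.random.SeedSequence(config.seed)
    for seed_idx, child in enumerate(master.spawn(config.n_seeds)):
        states = child.generate_state(config.n_folds + 1)
        fold_state = int(states[0])
        skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                              random_state=fold_state % (2 ** 31))
        for fold_idx, (train_idx, test_idx) in enumerate(skf.split(X, Y)):
            sub = LabeledDataset(
                X=X[train_idx], Y=Y[train_idx], gene_ids=dataset.gene_ids,
                target_gene=dataset.target_gene, condition=dataset.condition,
                barcodes=[dataset.barcodes[i] for i in train_idx])
            result = train_double_descent(
                sub, config, seed=int(states[1 + fold_idx]) % (2 ** 31))
            out = forward(result.weights, X[test_idx])
            acc, f1 = accuracy_f1(out.scores, Y[test_idx])
            oof[seed_idx, test_idx] = out.scores[:, 1]
            records.append(FoldRecord(
                fold=fold_idx, seed=seed_idx, accuracy=acc, f1=f1,
                selected_fraction=selected_feature_fraction(result.weights.W1)))
            if keep_models:
                models.append({
                    "seed": seed_idx, "fold": fold_idx,
                    "weights": result.weights, "support": result.support,
                    "test_idx": test_idx,
                })
    return FitReport(records=records, oof_scores=oof,
                     n_folds=config.n_folds, n_seeds=config.n_seeds,
                     fold_models=models if keep_models else None)


_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


def tune_eta(dataset: LabeledDataset | None, config: TrainConfig,
             eta_low: float, eta_high: float, max_iters: int = 20,
             objective=None) -> tuple[float, list[tuple[float, float]]]:
    """Golden-section maximization of CV accuracy as a function of eta.

    The accuracy-versus-eta curve is concave in practice, so golden-section
    search over ``[eta_low, eta_high]`` locates the optimum with one CV run
    per iteration.  ``objective`` may override the default (cross-validated
    mean accuracy) — used for testing and for custom criteria.

    Returns the best eta and the evaluated ``(eta, objective)`` trace.
    """
    if not eta_low < eta_high:
        raise ValueError("eta_low must be smaller than eta_high")
    if objective is None:
        if dataset is None:
            raise ValueError("dataset required when no objective is given")

        def objective(eta: float) -> float:
            return crossvalidate(dataset, replace(config, eta=eta)).accuracy_mean

    trace: list[tuple[float, float]] = []

    def evaluate(eta: float) -> float:
        val = float(objective(eta))
        if not math.isfinite(val):
            raise ValueError(f"objective is non-finite at eta={eta}")
        trace.append((eta, val))
        return val

    a, b = float(eta_low), float(eta_high)
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = evaluate(c), evaluate(d)
    for _ in range(max_iters - 2):
        if fc >= fd:   # maximum lies in [a, d]
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = evaluate(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = evaluate(d)
    best_eta, _ = max(trace, key=lambda t: t[1])
    return best_eta, trace
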