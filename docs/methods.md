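# Methods

## Model

The classifier–reconstructor is a symmetric fully connected autoencoder.
The encoder maps a cell's raw UMI count vector `x ∈ ℝᵈ` through one hidden
layer of width `h` with ReLU activation to a latent vector `z ∈ ℝ²`; the
decoder mirrors the encoder (independent weights, mirrored shapes, ReLU on
its hidden layer) back to a reconstruction `x̂`. "Symmetric" is read as
architectural symmetry, not weight tying. The two latent coordinates act
directly as class logits: the softmax over `z` gives the class
probabilities, and the class-1 probability is the cell's perturbation
score. There is no extra classification layer — with two classes a
2-dimensional latent is the classification head.

The training objective is

    L(W) = CE(softmax(Z), Y) + λ · Huber(X̂ − X)   s.t.  ‖W₁‖₁,₁ ≤ η

with the Huber (smooth-ℓ1) loss in the convention `0.5 r²/δ` for `|r| ≤ δ`
and `|r| − 0.5 δ` beyond, mean-reduced over all matrix entries. Cross-
entropy uses inverse-class-frequency weights by default (disable with
`class_weighting=False`): first-round datasets are often unbalanced and
unweighted CE can collapse to the majority class. The unweighted mode
reproduces that collapse, which is itself informative — it is how weakly
perturbed targets end up with single-digit perturbed-cell percentages.

Inputs are raw counts by default. `assemble_dataset(..., normalize=True)`
offers per-cell library-size scaling + log1p for robustness experiments,
but nothing downstream assumes it.

## Sparsity: the bilevel ℓ1,1 projection

A gene's presence in the model is its fan-out row in the first encoder
layer `W₁` (d × h). After every optimizer step `W₁` is projected:

1. compute per-gene row norms `t_i = ‖W₁,ᵢ‖₁`;
2. project `t` onto the ℓ1 ball of radius η (exact sort-based algorithm),
   giving per-row budgets `t*`;
3. project each row onto the ℓ1 ball of radius `t*_i`; rows with zero
   budget become exactly zero.

This operator is idempotent, keeps `Σᵢ‖W₁,ᵢ‖₁ ≤ η`, and zeroes whole rows —
structured feature selection. It is **not** in every case the exact
Euclidean projection onto `{‖W‖₁,₁ ≤ η}`: the exact projection
soft-thresholds individual entries by a single level and therefore rarely
deselects whole rows (e.g. for `W = [[2,2],[2,0]]`, η = 4 the exact
projection is `[[4/3,4/3],[4/3,0]]` while the bilevel operator returns
`[[1.5,1.5],[1,0]]`). The bilevel form is used deliberately for its
feature-selection semantics; the test suite compares both against an
independent oracle and records the divergences rather than assuming
equality. One consequence worth stating plainly: because the bilevel
operator is not a projection onto a convex set, it is not strictly
non-expansive — nearby inputs can map to outputs up to ~2% farther apart
(a concrete counterexample is kept as a unit test). The exact Euclidean
projection is non-expansive; the bilevel operator is close to it in
practice, and the expansion bound is verified empirically.
Both the vector projection and the row-wise batch version carry a
floating-point guard (rescale into the ball) so the constraint holds even
at radii near machine precision.

## Training schedule

Double descent in the pruning sense: phase 1 trains from a seeded Glorot
initialization with the projection applied after every Adam step; the
support is the set of gene rows still nonzero at its end. All weights are
then rewound to their initial values, dead rows frozen at zero (their
gradients masked), and phase 2 retrains under the same projection. The
final support is a subset of the phase-1 support.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| hidden width `h` | 100 | enough capacity at desk scale; configurable |
| latent `k` | 2 | one coordinate per class |
| λ | 1.0 | CE and Huber are of comparable magnitude on counts |
| Huber δ | 1.0 | standard smooth-ℓ1 convention |
| η | 25 | keeps ~10% of 1000 genes on the reference simulation; tune per dataset with `tune_eta` |
| optimizer | Adam, lr 1e-3 | stable across the tested range |
| batch | full batch | see below |
| epochs | 120 + 120 | convergence of the full-batch schedule |
| CV | 4 folds × 3 seeds | stratified; fold splits re-randomized per seed |

**Full-batch gradients are a deliberate choice.** With minibatches, Adam's
per-coordinate step normalization amplifies the gradient *noise* of
uninformative genes enough that their rows keep pace with weakly
informative ones and survive the projection, crowding weak signature genes
(particularly down-regulated, lowly expressed ones) out of the support.
Averaging the gradient over all cells cancels that noise; in the planted
benchmark this raised recovery of the 10 planted genes in the top-15 from
4–6 to 7–8 at identical η. `batch_size` remains configurable for larger
datasets.

η is tuned, when desired, by golden-section search on cross-validated mean
accuracy over a bracket — the accuracy-vs-η curve is concave in practice
(too small starves the model, too large admits noise). Tuning per dataset
is supported in the CLI; the reference analyses use the fixed default.

## Two-round cell selection

Round 1 cross-validates the SSAE on all controls vs all targeted cells.
Each cell's score is its **out-of-fold** class-1 probability (models that
never saw the cell), averaged over seeds — refit-on-all-data scores would
select cells with an overfit classifier. Targeted cells with score
strictly > 0.5 are "perturbed"; a score exactly at 0.5 is conservatively
non-perturbed; control cells never enter the perturbed set.

If fewer than `min_cells_per_class` (default 40) cells are selected, the
second round is skipped with an explicit reason and the round-1 report
stands — 4-fold CV on a balanced set needs a sensible number of positives
per fold. Otherwise, for each of `n_seeds` runs an independent balanced
dataset is built (all perturbed cells + an equal number of controls
sampled without replacement; if controls are short, all of them with a
warning) and a 4-fold CV is run with that seed. Attributions from each
run's fold models (evaluated on their held-out perturbed cells, baselines
drawn from the run's controls) are averaged into one ranking per run.

## Attribution and the signature

Gene importance is Shapley-style path integration of the class-1 logit:
for evaluation cell `x` and baseline `b` sampled from controls, the
attribution of gene `g` is `(x_g − b_g)` times the mean gradient of the
logit along the straight path from `b` to `x` (midpoint rule, 50 steps, 10
baselines, evaluation cells capped at 64 per call — all seeded). The logit
depends on the input only through `W₁`, so deselected genes get exactly 0.
On a fixed ReLU region the per-cell attributions sum to
`logit(x) − mean logit(baselines)` (completeness), which the tests verify.

Per run, genes are ranked by descending attribution (ties broken by gene
index); genes outside the run's support get the worst rank `d` — a gene
absent from a run is maximally non-discriminant for that run. Ranks are
aggregated across runs into mean and sample sd. The signature table keeps
the `top_n` (default 20, as in the usual top-20 figures) ever-selected
genes by mean rank, annotates direction from the sign of the log2 fold
change of library-size-normalized counts (perturbed vs control cells,
pseudocount 1), and flags genes with rank sd ≤ `sd_threshold` (default
`d/20`) as stable. The sd threshold is a reporting convention, not an
inference procedure; rank sds should be read qualitatively, and the flag
is only meaningful relative to replicate or null behaviour.

## Synthetic screens

`simulate_cropseq` emulates the generative structure the method targets:

* gene baseline means log-normal (default meanlog 0, sdlog 1 — median
  1 UMI, heavy right tail, a realistic shallow 10x profile);
* counts negative-binomial via Gamma–Poisson with Var = μ + μ²/θ,
  θ = 2 by default (strongly overdispersed);
* the target gene (default mean 20 UMI — CRISPRi targets are expressed
  genes; a knockdown of a 0.5-UMI gene would be unobservable) is
  multiplied in **every** targeted cell by a per-cell efficiency drawn
  from a truncated normal centred at `knockdown_factor` (default 0.1,
  i.e. 90% knockdown, sd 0.1, truncated to (0,1)) — the guide is present
  in all targeted cells but acts with variable efficiency;
* only a Bernoulli(`frac_perturbed`, default 0.7) subset of targeted
  cells — the truly perturbed ones — additionally express the planted
  signature: `n_signature` genes (default 10, drawn from the expressed
  half of the transcriptome) with means multiplied by `2^lfc`
  (default |log2FC| = 1.5, alternating signs);
* control cells are untouched; `simulate_null` makes targeted and control
  cells exchangeable (no knockdown, no signature).

Because the knockdown is universal but the signature is not, the target
gene is always the top discriminant feature even when no downstream
signature exists — matching the behaviour seen in real screens — and
perturbed-cell selection is a genuine task: non-perturbed targeted cells
carry the knockdown but look like controls elsewhere.

What the simulator does **not** model: doublets, ambient RNA, batch/HTO
effects, gene–gene correlation beyond the planted signature, and
count-depth variation between cells. Passing the benchmark therefore shows
the machinery works under the stated generative assumptions, not that it
is robust to every artifact of real data.

## Benchmark scales and numerical choices

The reference benchmark uses 1000 genes, 300 control + 300 targeted cells
and 3 seeds; the replicate null-specificity experiment uses 10 independent
null screens at 300 genes and 150 + 150 cells. These sizes were chosen so
the whole analysis runs comfortably on a single CPU while keeping all
class sizes comfortably above the 4-fold stratification limit.

Degenerate inputs are handled explicitly: single-class datasets and
classes smaller than the fold count raise `InsufficientCellsError`
(mirrored by the round-2 skip rule); non-finite losses abort with a
diagnostic; a score exactly at threshold is non-perturbed; empty
signatures (all genes deselected) raise rather than returning an empty
table. All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` spawning, so every reported metric is exactly
reproducible; the implementation is pure numpy, which makes repeat runs
bit-identical on a given platform.

## Known limitations

* **Round-2 accuracy carries selection bias.** Selecting the cells a
  round-1 classifier scored > 0.5 and re-fitting on them inflates round-2
  accuracy even when no signal exists: on independent null screens the
  second round reaches ~0.62–0.71 accuracy (round 1 stays at chance).
  Round-2 accuracy should therefore be read against this null baseline,
  not against 0.5; the genuine signal shows in the margin above it and in
  the signature's stability.
* Scores are calibrated only through the CE loss; the 0.5 threshold is a
  convention, not a posterior probability statement (no mixture model as
  in probabilistic assignment methods).
* With a fixed dataset, the three signature runs share the same selected
  cells, so rank sd understates sampling variability; distinguishing real
  but weak signatures from data artifacts requires replicate experiments
  (the null replicate test shows what chance consistency looks like).
* The ℓ1,∞ variant of the projection and k > 2 (multi-class) screens are
  out of scope.
* Raw-count inputs make attribution magnitudes expression-dependent;
  comparisons of attribution values across genes of very different
  expression should lean on ranks, not raw attribution.
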