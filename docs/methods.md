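# Methods

## Model

The classifier is a supervised autoencoder. The encoder is a linear fully
connected network `d → 96 (ReLU) → k`; the latent dimension equals the number
of classes, so the latent code is used directly as the logit vector of a
softmax classifier and, for k = 2, as plottable 2-D coordinates. The decoder
mirrors the encoder (`k → 96 (ReLU) → d`, linear output) and reconstructs the
input in *standardized* space. All layers carry bias terms; only the `d × 96`
first-layer weight matrix is subject to the sparsity constraint, because its
rows index input features.

The training criterion is

    loss = cross_entropy(softmax(Z), y) + λ · ψ(X̂ − X),   s.t. ‖W₁‖₁,₁ ≤ η

with ψ either the Huber loss (default, `delta = 1.0` in standardized units:
quadratic below delta, linear above — a single extreme sample perturbs the
criterion linearly rather than quadratically) or half squared error for
comparison. The cross-entropy is averaged over the batch, the reconstruction
loss over all batch entries. λ defaults to 1.0; λ = 0 with the constraint
disabled reduces the model *exactly* to the plain neural-network baseline (the
implementation guarantees bit-identical encoder trajectories, which is also a
regression test).

## The ℓ1,1 projection

The constraint set is `{W : Σᵢ ‖rowᵢ(W)‖₁ ≤ η}`. It is enforced by a two-stage
operator: (1) project the vector of row ℓ1 norms onto the ℓ1 ball of radius η,
yielding per-row budgets `tᵢ` (rows with small norms get `tᵢ = 0`); (2) project
each row onto the ℓ1 ball of its budget. Rows with zero budget become exactly
zero — whole-feature elimination. This is deliberately *not* the Euclidean
projection onto the set (which would be a global soft-threshold and would
scatter zeros across all rows); the row-structured allocation is the point.
Single-vector projections use the exact sort-based algorithm (O(n log n)); the
test suite checks it against an independent Lagrangian-bisection oracle to
1e-9. The support-size search uses a `≥` comparison so that a radius too small
to register in floating point still yields a well-defined (empty-support)
projection. The two-stage operator is idempotent, fixes feasible points
exactly, and its row-sparsity is monotone in η.

## Training loop

Projected minibatch ADAM (learning rate 1e-3, batch size 8, β = (0.9, 0.999)),
in float32, with the projection applied to `W₁` once per epoch after the
optimiser steps (per-minibatch projection is available via
`project_every_batch`). Projection radii are always recomputed from the
current post-step weights. Training runs a **double-descent** schedule: phase 1
trains everything for `epochs` epochs under the projection; at the phase
boundary the rows of `W₁` that are exactly zero are frozen (their gradients
are zeroed and the optimiser state is reset, so a frozen row can never be
revived); phase 2 retrains the survivors for another `epochs` epochs with the
projection still active. Weight initialisation is the standard uniform fan-in
scheme. Initialisation and batch shuffling draw from independent streams
spawned deterministically from the seed, so runs are bit-reproducible and the
encoder stream is shared between the SAE and the NN baseline.

Constraint checks on float32 training output use absolute tolerance 1e-5;
float64 operator-level checks use 1e-9.

Preprocessing is per-feature standardization (centre/scale) fitted on the
training portion only and stored in the model; intensities span decades, and
without a common scale η would not be comparable across features. An optional
log1p transform is off by default. The reconstruction loss is computed in this
standardized space, which also gives `huber_delta = 1` a natural meaning (one
standard deviation).

## η selection and the benchmark protocol

η is chosen by maximising mean stratified-CV accuracy over a grid (default
1, 5, 10, 25, 50, 100), ties broken toward the smallest (sparsest) value.
`select_eta` is an explicit step run on training data. The benchmark harness
(`cross_validate_all`) evaluates all methods with a *fixed* configuration on
identical splits: 4 stratified folds × 3 seeds = 12 train/test splits, every
data-dependent step (standardization, SAE training, the SVM's inner C search)
fitted inside the training fold. Nesting the full η grid search inside each of
the 12 splits is supported by composing `select_eta` with the harness but is
not the default: it multiplies cost by the grid size and, on the synthetic
conditions used here, accuracy is flat across a wide η range.

Folds are stratified by class (small cohorts make unstratified 4-fold splits
risky; an unstratified fallback with a warning covers classes smaller than the
fold count). Metrics are accuracy, ROC AUC (one-vs-rest macro for k > 2) and
the support-weighted F1, the conventional choice for unbalanced cohorts; all
three come from scikit-learn and are cross-checked in the tests against a
brute-force confusion-matrix/ROC-pair enumeration. Baselines: PLS-DA
(4 components on one-hot labels, arg-max decision, |loading|-based feature
ranking), Random Forest (400 trees, depth ≤ 3, Gini importance), linear SVM
(C grid 1e-3..1e3 by decades, inner CV), and the plain NN described above.

## Feature ranking and interpretation

The primary feature score is the ℓ1 norm of each feature's row of the trained
`W₁` — the direct product of the constraint; the selected set is exactly the
set of nonzero rows. A gradient × input attribution of the predicted-class
probability (computed in standardized space, averaged as |·| over samples) is
provided as an independent secondary ranking. The held-out simulation
withholds one random patient per class, retrains, and reports each withheld
patient's predicted class, softmax confidence (bounded in [1/k, 1]) and latent
position among the training cohort, plus per-class Gaussian KDEs (Scott's
rule) of the latent cloud projected on the class-discriminant axis (difference
of class means for k = 2). Correlation analysis of selected features uses
plain Pearson correlation across all samples.

## Synthetic data

The generator emulates what matters statistically about LC-MS feature tables,
on the log scale: per-feature Gaussian variation (`log_sigma = 0.25`) around
baselines drawn uniformly over log-intensities 2–9 (so raw intensities span
~e²…e⁹, several decades); balanced classes (an imbalance option exists);
`n_informative` features shifted between classes by `effect_size` standard
deviations (default 1.5 — a strong but realistic univariate biomarker);
adduct/isotope blocks sharing a common factor so that within-block Pearson
correlation equals the configured value (default 0.8; with `log_sigma = 0.25`
the correlation survives exponentiation to within ~0.01); and a 5% fraction of
outlier samples with additive Student-t(3) noise, the contamination that
motivates the Huber loss. Default shape 200 × 500 with 10 planted features;
presets reproduce the shapes of three published clinical cohorts (1005 × 2944,
271 × 161, 88 × 7022) and a 60 × 40 `tiny` preset for fast tests.

What the generator does **not** emulate: batch effects and drift, missingness
/ censoring at the detection limit, retention-time structure, non-Gaussian
within-class multimodality, and m/z-level adduct chemistry (names like
"MZ 264.12" are cosmetic). Passing tests therefore demonstrate that the
optimisation, selection and protocol machinery behave as designed under a
realistic correlation/noise structure — not that any particular clinical
performance level will be reached on real cohorts.

## Numerical and degenerate-input choices

- Ties among equal row norms at the projection threshold are handled
  continuously by soft-thresholding (equal inputs → equal budgets).
- η = 0 zeroes the first layer; the classifier can still move through biases
  and predictions collapse toward class priors.
- `batch_size` is clipped to the number of samples; `d < hidden_width` is
  allowed.
- Zero-variance features get unit scale in standardization and are flagged at
  load time; zero-variance features are excluded from correlation matrices.
- Labels in files are mapped to 0..k−1 lexicographically; the mapping is
  recorded in the run manifest.
- Missing values are rejected by default, with optional half-minimum
  imputation (a standard metabolomics convention for sub-detection values).

## Problem sizes in the test suite

The suite and the acceptance script run everything at the generator's default
or tiny shapes (200 × 500 for recovery, 60 × 40 for protocol and robustness
checks, 200 × 96 matrices for the projection contrast), which exercise every
code path in well under a minute each on a single CPU core.

## Known limitations

- The network is intentionally small (one hidden layer); multi-layer encoders
  and GPU execution are out of scope.
- PLS-DA decides by arg-max of the regressed one-hot scores; score
  thresholding variants are not implemented.
- AUC for k > 2 is one-vs-rest macro; the shipped presets are all binary.
- ℓ2,1 (group-lasso) and ℓ∞ projections are not implemented.
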