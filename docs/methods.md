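# Methods

## Signal model and half-life extraction

Each well's chemiluminescence trace is modelled as a one-phase decay,
I(t) = A·exp(−k·t) + c, with amplitude A > 0, rate k > 0 per minute, and a
sign-unconstrained plateau c (instrument baselines can dip below zero).
The half-lifetime T1/2 = ln 2 / k is the only feature propagated
downstream; the assay's other observables (peak intensity, plateau level)
are deliberately not used, and bi-exponential kinetics are out of scope —
one half-life per curve is the unit of analysis.

Fitting is unweighted nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective with bounds A > 0, k > 0). Weighted schemes (e.g.
1/Y²) would be defensible but are not implemented; unweighted is the
documented choice. Initialization is derivative-free and robust: plateau
from the trace minimum, amplitude from the span, and rate from the
log-linear slope of the first half of the background-subtracted trace.
Convergence tolerance is 1e−10 on the relative SSE change with at most
10,000 function evaluations; both are recorded in every `DecayFit`.
Degenerate inputs are split into two behaviors: inputs that can never be
fitted (fewer than 4 points, non-finite values, flat traces with zero
intensity variance) raise typed errors, while optimizer breakdown on a
legal input is reported as `converged=False` so a plate-level fit never
aborts on one bad well. On noiseless model-generated traces with k in
[1e−3, 1] per minute on the default 5–180 min grid, parameters are
recovered to relative error below 1e−6 (property-tested), and on noisy
traces the optimum coincides with an independent grid search over k with
the two linear parameters profiled exactly.

Replicate wells are fitted independently and their half-lives averaged at
the screening stage (not their curves); this preserves per-replicate
diagnostics and makes replicate dropout harmless.

## Plate data model

Plate files are tidy long-format CSV — one row per (well, replicate, time
point) — because the format is unambiguous under ragged time grids.
Comma-separated with dot decimals only; other dialects are rejected rather
than guessed. Vehicle wells carry the fixed sentinel compound id
`BASELINE`. Intensities are opaque instrument counts; no unit conversion is
attempted. Reading uses round-trip float parsing so write→read is the
identity to full precision.

## Flag screening

Normalized ratio: half-life with compound divided by the same sample's
mean vehicle-well half-life (the per-sample baseline). Flag calling
centers on the mean ratio across the library and thresholds at 3 × the
sample (n−1) SD across compounds — one point per compound, so replicate
variation enters only through the upstream averaging. The mean was chosen
as the center as the simplest reading of a "3 × SD" rule; robust centers
(median/MAD) would change which marginal compounds are called and are not
offered. An all-identical input has SD exactly 0 and flags nothing.

Disease screening scores each compound as mean normalized ratio over AD
samples divided by the same over HC samples. Panels are ranked by
|log score| descending, because informative compounds sit on both sides of
ratio 1 and a 2-fold increase should rank with a 2-fold decrease; ties
break lexicographically on compound id so the ranking is deterministic.
The ranking statistic is a design choice of this package, not an inferred
property of any particular dataset.

## Batch-baseline correction

Model: x_ij = μ_i + Δ_g + ε_ij, with additive per-batch baseline μ_i,
group effect Δ_g under the identifiability convention Δ_HC + Δ_AD = 0, and
zero-mean noise. Averaging x over a batch's HC members and separately over
its AD members and halving the sum cancels Δ exactly and ε in expectation,
giving μ̂_i = ½(mean_HC + mean_AD) per compound (each compound is treated
as an independent feature). The estimator is exact — for arbitrary
baselines — when ε ≡ 0 and the convention holds, which the generator can
realise and the tests verify; with noise, its error shrinks as per-batch
group sizes grow. The expectation argument assumes batch compositions are
balanced enough for the group-wise noise means to vanish; under strong
imbalance the estimate inherits the imbalance and no correction for that
is attempted.

A batch lacking either anchor group is rejected by name (the estimator is
undefined there). Samples from non-anchor groups (MS, DB, RA, AD-MCI) are
corrected with the baselines estimated from their batch's HC/AD members.
Estimation and application are split so a model fitted on training samples
can be applied to held-out ones; the default pipeline corrects the full
matrix before cross-validation (matching the preprocessing-then-CV order),
and leakage-averse users can instead call `estimate_batch_baselines` /
`correct_batches` per fold with the same API.

## Diagnostic evaluation

Standardization scales each feature to mean 0 and unit sample (ddof = 1)
SD, dropping zero-variance features with a warning; the scaling parameters
are retained for held-out application. PCA reduces to nPC components.
Seven classifier families are compared — logistic regression, LDA, QDA,
RBF-kernel SVM, KNN (k = 5, capped at the training-fold size), decision
tree and random forest (100 trees) — all with fixed, recorded sklearn
defaults and a shared seed; none of the hyperparameters are tuned.

Cross-validation is stratified 3-fold with seeded shuffling; "the average
over 3 iterations" is read as the mean over the 3 folds of a single CV
split. By default standardization and PCA are fitted inside the training
folds and applied to the test fold; `transform_within_folds=False` exposes
the simpler whole-matrix order to make the leakage difference explicit.
The positive class for precision/recall/F1 is the disease group (AD),
the clinically natural choice. AUC uses predicted probabilities where the
model has them and decision-function values otherwise (SVM), avoiding a
calibration step; thresholded metrics always use the model's native
predicted labels. AUC itself is the rank statistic (ties averaged),
verified in tests against brute-force positive–negative pair counting.
`sweep_models` selects, per family, the nPC maximizing mean AUC (ties to
the smaller nPC) and ranks families by that AUC.

Multi-group comparisons use 2-D projections rather than classifier
metrics, because the comparison cohorts are small: LDA projects onto the
top-2 discriminant axes (second coordinate zero when only one axis
exists); QDA coordinates are the first two class log-posterior contrasts,
and a group too small for a full-rank class covariance is rejected with a
pointer to LDA. Group differences on single features use the classical
pooled-variance unpaired two-tailed t test, annotated at P ≤ 0.05.

## Synthetic-data generator

The generator emulates the study conditions the analysis targets: 31 AD
and 37 HC samples (the larger of the two stated cohort sizes is used for
HC), a 96-compound library by default (up to 1,024), control half-life
13.15 min — the healthy-serum reference value — with AD samples shifted
shorter by a multiplicative factor (0.9 by default), four batches with
additive offsets of ±0.5 and ±1.0 min, log-normal biological noise
(σ = 0.05 on log half-life), and traces on a 5–180 min grid. The 5-min
acquisition step is a generator choice; only the imaging window is fixed
by the assay. Trace-level noise is multiplicative Gaussian on intensity
(SD 2 % of amplitude), a detector-like model.

True half-life of sample s (group g, batch i) against compound c:
T = T_base(g) · effect(c, g) · exp(ε), plus the additive batch offset μ_i.
Group and flag effects are multiplicative on half-life (additive in log),
while batch offsets are additive on the feature — matching the additive
decomposition the correction step assumes; in the ε = 0, balanced-Δ limit
the generator realises the correction model exactly, which is what lets
the exactness properties serve as end-to-end tests. Configurations that
would produce a non-positive half-life are rejected before any file is
written. Both simulation paths (trace-level and the feature-level
shortcut) consume one random stream in a fixed draw order, so with zero
trace noise the fitted features of the trace path equal the shortcut's
matrix to optimizer precision; all randomness derives from a single seed
and output files are byte-reproducible.

What the generator does not emulate: compound-specific chemistry (effect
sizes are free parameters, not estimates of any real library),
heavy-tailed or correlated noise across compounds, plate-position effects,
replicate-level structure beyond independent wells, and any
concentration-, pH- or viscosity-dependence of the probe. Passing tests
therefore demonstrate that the pipeline recovers the parameters of its own
assumed data-generating process at realistic sizes and noise — not that
real serum data meet those assumptions.

## Problem sizes in the test and acceptance runs

The suite runs the statistical checks at the cohort sizes above: the
AUC-calibration checks use 30 seeded replicates of the 68-sample,
12-compound design (null band [0.35, 0.65]; 2-fold planted effect must
exceed AUC 0.9), and panel recovery uses 50 seeded replicates of a
6-sample, 96-compound trace-level experiment requiring full recovery of 6
planted compounds in at least 45. The whole suite completes in under two
minutes on one CPU.

## Known limitations

- The half-life is the only feature; intensity- or plateau-based features
  would need a parallel feature matrix and are not implemented.
- The batch estimator requires both anchor groups in every batch; designs
  where a batch holds only comparison-disease samples cannot be corrected.
- QDA projections need per-group sample counts exceeding the feature
  dimension; use LDA or reduce dimensionality first.
- Classifier hyperparameters are fixed defaults; the sweep optimizes only
  nPC, so reported metrics are conservative for tunable families (SVM, RF).
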