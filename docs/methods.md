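# Methods

## Covariance descriptors on the SPD manifold

The feature of every 2 s segment `X ∈ ℝ^{n×T}` is its spatial covariance
`C = XXᵀ/(T−1)` (band-passed data are zero-mean, so no mean subtraction).
Covariances are compared with the affine-invariant Riemannian metric
`d(S₁,S₂) = sqrt(Σ log² λᵢ(S₁⁻¹S₂))`, which is invariant to any invertible
channel recombination and to joint inversion.  Linearization at a reference
point `C` uses the log map `T = log(C^{-1/2} S C^{-1/2})`; tangent vectors
are half-vectorized with off-diagonal weight √2, which makes the Euclidean
norm of the feature equal the Frobenius norm of the tangent matrix — the
property that lets Euclidean machinery (PCA, RBF kernels) act on manifold
data, and the reason √2 (not 2) is the correct off-diagonal weight.

The Karcher (Fréchet) mean is computed by the standard fixed-point
iteration: initialize at the arithmetic mean, repeatedly average tangent
vectors at the current estimate, exp-map the average back; stop when the
mean tangent norm (or its change) falls below `tol = 1e-6`, cap at 50
iterations and raise a diagnostic error with the last residual otherwise.
At the fixed point the mean tangent vector vanishes, which characterizes
the Fréchet mean; the test suite cross-checks against a brute-force
Nelder–Mead minimization of the Fréchet functional over a Cholesky
parametrization.

Numerical choices: eigendecomposition always operates on `(S + Sᵀ)/2`;
eigenvalues are floored at 1e-12 (with a warning) before logarithms; the
covariance of a rank-deficient segment raises a degenerate-segment error
unless a shrinkage toward the scaled identity `(tr C / n) I` is requested —
pipeline callers pass `shrinkage = 1e-4` on low-channel-count data.

## Preprocessing and segmentation

Recordings follow the protocol this method targets: 1000 Hz acquisition
downsampled to 256 Hz (polyphase 32/125, line-extension padding), 5th-order
Butterworth band-pass 8–70 Hz, 60 Hz IIR notch.  Filters run zero-phase
(forward–backward) for offline analysis and causal for online replay —
which the original experiment used is not recorded, so both are exposed.
Trials are 10 s; sliding 2 s windows advancing 0.25 s yield 33 segments per
trial, 1320 per 40-trial run, 330 per class.  Ocular-artifact removal is a
pass-through hook accepting any `(samples, rate) -> samples` callable; EDF
and BrainVision readers (via `mne`) cut labeled trials at annotation
markers and exclude EOG-prefixed channels from the analysis montage.

## Multi-class CSP

The spatial filter whitens with the pooled (balanced) class-mean
covariance, approximately jointly diagonalizes the class means with Jacobi
rotations (for commuting inputs this is an exact common eigenbasis), and
ranks components by the mutual information between per-segment log-variance
and the class label.  MI is computed in closed form under a
Gaussian-per-class model of the log-variance — stable at a few hundred
segments per class, where histogram estimators are noisy; it is a ranking
score and may exceed the 1-bit entropy bound of a binary label.  Ties break
to the lower component index.  Default `d = 12` components.

## Sparse multinomial-probit RVM

Class scores are kernel expansions `y_c(x) = Σ_m w_{mc} K(x, x_m)` with an
RBF kernel on tangent features; the bandwidth defaults to the median
pairwise training distance and is recorded in the model.  Class membership
follows the multinomial probit: the predicted probability
`P(c|x) = E_u[Π_{j≠c} Φ(u + y_c − y_j)]` is evaluated by 48-node
Gauss–Hermite quadrature, so training and prediction are deterministic.
Training is EM on the truncated latent scores with automatic relevance
determination: each training sample has one precision shared across the
class weights (samples are kept or pruned jointly), updated MacKay-style;
five precision/weight updates run per latent refresh because the precision
fixed point converges much faster than the latents move.  Samples whose
precision exceeds 1e6 are pruned; convergence is declared when the largest
log-precision change drops below 1e-4, with a 500-iteration cap.  A kernel
Gramian jitter of 1e-8 guards the Cholesky factorizations.  A model whose
basis prunes away entirely (label-shuffled data) predicts the uniform
distribution.

One honest caveat: a MAP sparse-Bayes model is not exactly idempotent under
training-set duplication — doubling the data doubles the likelihood against
a fixed prior — so duplicated training sets reproduce the decision function
(identical argmax) but probabilities can move by up to a few percent.

## Representative-sample selection and adaptation

Algorithm, per run: (pre-filter) drop segments whose true-class probability
under the previous mixture is ≤ ε_f = 0.1 — deliberately below the 0.25
chance level so the selection stays nearly independent of old models; a
trial that would lose everything keeps its single best segment, with a
warning.  (select) Apply the current `W` (run 0: fitted on all segments;
later: the previous run's filter), compute per-trial covariances, keep the
`k` nearest neighbours of each trial's Karcher mean (ties to the lower
segment index), then refit the CSP on the selected segments only.  The pass
runs once by default (a config-gated fixed-point iteration count exists).
Sub-model training then recomputes covariances of the selected segments
under the refitted filter, takes their Karcher mean `μ` as tangent
reference, and trains the RVM.

After run `r` completes, the candidate family `{R_{r-1}^k, k = 8..12}` is
cross-validated on the new data `D_r` by QCM (ties to smaller k); the
winner replaces the run-(r−1) sub-model, and the run-r sub-model is
appended using the same inferred `k*` (no `D_{r+1}` exists yet to validate
against; the very first mixture uses the `k = 9` heuristic).  Every
sub-model's prior is re-evaluated on each new run — `a_i = p(Q_i on D_r)`,
suppressed to 0 below ε = 0.25 — and the newest model receives the maximum
of the others' qualities (floored to 1 if the whole history is degenerate,
so prediction never divides by zero).  All non-suppressed sub-models are
retained; an optional cap evicts oldest-first.

Online weights: `b_i = a_i / max(d̄_i, 1e-6)`, normalized over active
sub-models.  `d̄_i` is the running arithmetic mean, within the current
trial, of the distances between the incoming filtered covariances and
`μ_i`; it resets at each trial onset (first segment's distance initializes
it).  The within-trial reset keeps weights responsive to the user's current
state yet stable inside a trial; exponential-decay and run-level variants
are config-selectable.  Argmax ties break to the lowest class index.

The replay driver applies the experiment's feedback schedule: run 0 sham
(displayed motion is correct with probability 0.8, random otherwise —
purely seed-driven), runs 1–4 constrained (motion advances only on correct
predictions), later runs full (raw argmax drives the display).

## Evaluation metrics

* **QCM** `min(q)/mean(q)` over the row-normalized confusion matrix's
  diagonal; counts are also exposed.  An all-zero diagonal scores 0; QCM is
  invariant to joint relabeling.  Note QCM measures *balance*: a balanced
  random predictor at chance accuracy scores near 1, only degenerate
  (single-class) predictors score near 0.
* **Separability** `d(μ_A, μ_B)/(σ_A σ_B)` with Karcher means and sample
  standard deviations (ddof 1) of members' distances to their own mean;
  two CSP conventions are supported (previous-run filter vs own-run filter,
  the latter preferred for classifier-independent evaluation).
* **Instability**: PCA on the class's tangent vectors at its Karcher mean;
  the count of components reaching ≥ 0.95 cumulative explained variance
  (inclusive); a zero-variance class scores 0 by convention.
* **Exact Wilcoxon signed-rank, left tail** (H1: before < after): zero
  differences dropped, mid-ranks for ties, and the exact tail probability
  of the positive-rank sum over all 2^n sign assignments, computed by
  subset-sum dynamic programming on doubled (integer) mid-ranks; supported
  for n ≤ 25.  p-values print as the result tables do: three decimals below
  0.01, two otherwise, half-up.
* **Run regression**: OLS of QCM on run index 1..4.

## Synthetic sessions

The generator emulates the study protocol (60 channels, 256 Hz, 7 runs of
40 ten-second trials, 10 per class) with all class structure in the spatial
covariance — exactly the surface the descriptor can see.  Base covariance:
AR(1) channel correlation `0.5^|i−j|`, so CSP has realistic structure.
Class prototypes sit at `Exp_{C0}(δ·diag(u_c))` with orthonormal diagonal
direction vectors in the whitened frame; within this commuting family the
geometry is flat, so pairwise prototype distances are exactly `δ√2`.
Trial means sit at geodesic distance `τ` from their prototype; segments are
zero-mean Gaussian series with the trial covariance.  Run-to-run
non-stationarity: prototypes drift `ρ` per run along fixed per-class
directions drawn orthogonal to the class directions (so separation is
stable), and exploitation shrinks the dispersion, `τ_{r+1} = γ τ_r`.

Exploitation additionally *concentrates* exploration: trial tangent
directions mix a fresh random direction with a preferred axis, with
alignment `1 − γ^(c·r)` (concentration exponent `c = 8` by default).  This
is deliberate: the instability metric counts explained-variance components
and is therefore scale-invariant, so shrinking τ alone cannot lower it —
what falls is the *rank* of exploration.  The preferred axis is shared by
all classes (a settling mental strategy, not class content), so a
zero-separation session remains uninformative about labels.  The
concentration scale was chosen so the mechanism expresses itself above the
segment-covariance sampling-noise floor; with it, the run-1→4 instability
change is negative under exploitation and ~0 without, consistently across
seeds.  Note that per-class *drift* directions are class information: a
chance control must set both `δ = 0` and `ρ = 0`.

Outlier spans model distraction: whole 2 s spans resampled from a far-off
covariance (geodesic magnitude 3 by default), implanted in the time series
so overlapping segmentation smears them naturally.  Spans are capped to a
strict minority of a trial, keeping the trial's central pattern dominant —
the premise of representative-sample selection (uncapped, ~1 in 6 trials at
`p_out = 0.3` would be majority-outlier, inverting the farthest-from-mean
ranking).  A small feedback-responsive user model closes the loop for
co-adaptation tests: majority-correct feedback in a trial multiplies τ by
γ, majority-incorrect by 1/γ, and a feedback-regime change steps each
prototype exactly `drift_step` along a fixed unit tangent direction.

What the generator does *not* model: evoked temporal structure, 1/f
spectra, volume conduction from a biophysical head model, artifacts, or
real imagery physiology.  Passing tests therefore demonstrate correct
recovery of covariance-borne class structure and correct adaptive
machinery — not performance on physiological EEG.

## Problem sizes used by tests and the acceptance script

The suites scale channel counts down (8–16 channels, 3–5 runs, 5–10
trials/class) while keeping the protocol's temporal structure (10 s trials,
2 s / 0.25 s segmentation, `k ∈ 8..12`, sham → constrained replay schedule)
so every code path of the full pipeline runs.  The acceptance script's
end-to-end sessions use 16 channels: a high-separation session (δ = 1.0,
τ = 0.2, 4 runs; held-out accuracy expected above 80%) and a
zero-separation control (5 runs, two held-out runs ≈ 80 trials, keeping the
standard error of the chance-level estimate under 5 points — predictions
are correlated within trials, so trials, not segments, are the effective
sample size).  Statistics derived from the packaged study tables are exact
recomputations at full size.

## Known limitations

* Karcher-mean iteration assumes moderately dispersed inputs (guaranteed
  convergent for data within a geodesic ball; the protocol's data qualify).
* The RVM's duplication caveat above; probabilities are MAP, not fully
  Bayesian.
* The exact signed-rank test enumerates up to n = 25 pairs; larger samples
  need an asymptotic variant that is out of scope here.
* A handful of published derived statistics do not reproduce exactly from
  the *printed* (rounded) score tables; the recomputation matches wherever
  the printed precision permits, and the discrepant cells are flagged in
  the test suite.
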