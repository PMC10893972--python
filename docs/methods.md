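# Methods

This note documents the models implemented in `orientwm`, the defaults and
why they were chosen, what the simulator does and does not emulate, and the
numerical decisions that were genuinely open.

## Orientation space

Gratings are 180°-periodic, so all orientations live in [0°, 180°) and
signed differences in [−90°, 90°) (`circ_diff_180`). Wherever a circular
distribution is needed, the half-circle is mapped to the full circle by
doubling: a difference d in degrees corresponds to the radian angle
d·π/90.

## Simulator (`simdata`)

**Trial design.** Each run presents 40 targets at 1.125° + k·4.5°
(k = 0…39) and 40 distractors at those values + 2.25°, each exactly once in
independently shuffled order; the retro-cue is uniform over {1, 2} and the
probe's start orientation uniform over [0°, 180°). The 1.125° shift keeps
every stimulus off the cardinal axes; targets and distractors never
coincide. Eight runs give the standard 320 trials.

**Voxel tuning.** Voxel i's tuning curve is a zero-mean Gaussian-process
draw zᵢ ~ 𝒩(0, Kᵢ) on a grid of p equally spaced orientation-phase values
in [0, 2π), with the periodic kernel
K(x_m, x_n, σᵢ) = exp(−2 sin²(½(x_m − x_n)) / σᵢ²) and per-voxel
smoothness σᵢ ~ Γ(shape 2, scale 2) (mean 4; the shape/scale convention is
a deliberate choice where shape/rate would also have been possible, and
both parameters are exposed). K(x, x) = 1, so tuning values have unit
marginal variance. A 10⁻⁶ diagonal jitter precedes the Cholesky factor;
sampling is per voxel since every voxel has its own σᵢ.

**Signal.** Trial j of voxel i measures yᵢⱼ = zᵢ(θⱼ)·s + εᵢⱼ with
εᵢⱼ ~ 𝒩(0, 1) i.i.d. across trials, voxels and runs, and s ∈ [0, 1] the
SNR factor. Orientation θ ∈ [0°, 180°) maps to phase 2πθ/180 and is looked
up at the nearest grid point; the default grid size p = 180 keeps the
lookup error at or below half a degree. (The grid size is a package
default, not a claim about any particular dataset; orientations may be the
40-level design set or arbitrary continuous values.)

**Timecourse expansion.** The trialwise simulation can be expanded to a
TR-resolved layout for testing the time-resolved decoder: each trial
occupies a fixed number of TRs, the trial's pattern is present in an
"active window" of TRs, and every TR receives fresh unit-variance noise,
so out-of-window TRs are pure noise. This is plumbing for the decoder
tests, not a hemodynamic model.

**Behavior.** Reports follow the detection/swap/guess mixture (below) with
response = center + μ + von Mises error (center = target for detections,
distractor for swaps), guesses uniform. For κ > 10⁵ the sampler switches to
the 𝒩(0, 1/κ) limit, which is indistinguishable at that concentration and
numerically safe.

**What the simulator does not emulate:** hemodynamic convolution and lag,
temporal autocorrelation, physiological noise, spatial voxel correlations,
drift (unless added for the detrending tests), or attentional/strategic
effects. Passing tests therefore show that the *analysis chain* is
correct and calibrated, not that real data will reach any particular
accuracy.

**Seeding.** Every public sampler takes a seed or Generator; dataset- and
experiment-level drivers derive per-stage substreams from one master
`numpy.random.SeedSequence`, so each stage is independently reproducible
and whole runs are bit-identical under a fixed seed.

## Von Mises mixture model (`vmmm`)

Trialwise report density (with respect to the doubled-angle radian
measure):

P(θr | θt, θd) = r₁·VM((θr−θt)ᶜ − μ; κ₁) + r₂·VM((θr−θd)ᶜ − μ; κ₂) + r₃/(2π)

with VM(d; κ) = exp(κ cos(d·π/90)) / (2π I₀(κ)), mixture weights on the
simplex, and a bias μ (degrees) shared by the detection and swap
components. μ is defined as the mean signed report error (θr − θt), so a
negative μ means reports rotated anticlockwise of the target; since the
cosine is even, this convention only fixes the sign of μ̂ and leaves the
likelihood otherwise unchanged. Densities use the exponentially scaled
Bessel function, so they are finite up to the precision cap κ_max = 700.

**Estimation.** Maximum likelihood by multistart L-BFGS-B (default 10
starts: one detection-dominant, the rest random) on a transformed
parameterization — softmax for the weights, log for the precisions, μ
boxed to [−90°, 90°). Two bounds matter:

- κ ≤ 700 avoids Bessel overflow; fits at the cap are flagged
  (`at_kappa_bound`), which is the expected outcome for degenerate data
  such as responses exactly equal to targets.
- κ ≥ 0.5 (`KAPPA_FIT_FLOOR`) is an identifiability floor: a von Mises
  flatter than this is practically the uniform distribution, so without
  the floor a guess-dominated dataset can be fitted equally well by a
  flat "swap" component with arbitrary weight splits. The floor attributes
  that mass to the guess component. Density evaluation still accepts
  κ = 0.

The model/results split follows statsmodels: `VonMisesMixture` holds the
data and likelihood, `fit()` returns a `VonMisesMixtureResults` with the
estimates, log-likelihood, convergence and boundary flags, and a
`summary()` table.

## Preprocessing (`preprocess`)

**Spline detrending.** Per run and voxel, the series is split into
`n_trials/2` equal segments (20 nodes for a 40-trial run), one node per
segment at the segment center, and a cubic spline through the nodes is
subtracted. Node *values* are solved from a small linear system so that
the fitted drift's per-segment means equal the data's per-segment means;
for constant or linear drifts this coincides with plain segment
averaging, and it makes the detrender a projection — applying it twice
changes nothing. The half-trial node resolution deliberately cannot absorb
within-trial structure. An odd trial count has no defined node rule and
requires an explicit `n_nodes`.

**Temporal smoothing.** Centered moving average, default width 3 TR;
edges shrink the window to the available neighbors (no padding values are
invented, length is preserved).

**Feature-space smoothing.** Each trial's voxel vector is replaced by a
weighted average over trials with nearby labels, with Gaussian weights in
circular orientation distance, σ = FWHM / √(8 ln 2), rows normalized to
sum 1. FWHM 0 is exactly the identity. The default scope is within-run:
pooling across runs would let leave-one-run-out folds share smoothed
information; the cross-run variant is available behind
`SmoothingSpec(scope="all")` so the leakage is measurable rather than
silent. The smoothing label is the trial's own target orientation.

**Voxel selection** takes precomputed per-voxel activation scores (the
pipeline does not estimate a GLM) and keeps the n largest, ties resolved
to the lowest index so selections are deterministic.

## Decoder (`psvr`)

Labels encode as x = sin(2θ·π/180), y = cos(2θ·π/180) (the cosine is the
45°-shifted sinusoid of the pair; any consistent convention satisfies the
round-trip identity). Two independent SVRs (RBF kernel, epsilon-
insensitive loss) predict x̂ and ŷ; the angle is θ̂ = atan2(x̂, ŷ)·90/π
reduced into [0°, 180°). Predicted pairs are *not* renormalized to the
unit circle before atan2 — atan2 is invariant to a common positive scale
but not to componentwise changes, and raw predictions are used as they
come.

Hyperparameters are deliberately library-conventional, since nothing in
the problem pins them: cost 1.0, epsilon tube 0.1, and
γ = 1/(n_features · Var(training features)) computed per training fold.
Across-scaling (per-feature min-max to [0, 1], constant features to 0) is
fitted inside each training fold only; test values may leave [0, 1].
Cross-validation is leave-one-run-out; every trial is predicted exactly
once. The time-resolved driver repeats extract → smooth → decode at every
TR offset of the trial window for any of the four label kinds (target,
distractor, probe start, report).

## Accuracy metrics (`metrics`)

FCA(θ, θ̂) = (90 − |θ − θ̂|ᶜ₉₀)/90 · 100. BFCA sorts trials by true label,
averages FCA within duplicate labels (zero-width trapezoids would
otherwise be order-dependent), closes the integral circularly by appending
the first point at its label + 180°, and divides the trapezoid integral
by 180. The circular closure makes a constant FCA integrate exactly to
itself and respects periodicity; on the balanced 40-level design BFCA is
within half a point of the plain FCA mean, while clustered labels are
down-weighted as intended. Window summaries (`mean_window_accuracy`)
average per-TR BFCA over an inclusive TR range — the canonical delay
window TRs 6–15 contains exactly 10 values.

## Inference (`inference`)

**Cluster permutation.** Per TR, a one-sample t of (accuracy − chance);
TRs above the one-tailed t threshold at α = .05 (above-chance direction
only) form contiguous clusters scored by summed t (t-mass). The null is
built by randomly sign-flipping each subject's chance-centered timecourse
(the exchangeability argument for a one-sample design) and taking the
maximum cluster mass per permutation; cluster p-values use the
(1 + k)/(1 + N) correction, so p ≥ 1/(N+1). Zero-variance TRs are excluded
with a warning. 10,000 permutations by default, configurable downward for
tests.

**Grid optimization.** The FWHM × voxel-count grid accuracy (subject ×
fwhm × count × TR) is averaged over the delay window and over all subjects
*except* the one being assigned; the argmax cell is assigned, exact ties
resolving to the smaller FWHM, then the smaller voxel count. The
assignment provably never reads the assigned subject's own slice (tested
by sentinel poisoning).

**Group statistics** are pooled-variance two-tailed two-sample t-tests and
Pearson correlations (scipy implementations behind the package surface).
Bayesian follow-up tests are out of scope; the pipeline writes the per-
subject inputs an external tool would need.

## End-to-end experiment (`pipeline`)

`run_experiment` simulates two groups with identical signal-generating
distributions (per-subject SNR uniform over a configurable range), fits
the behavioral model per subject, decodes the search grid on the
trialwise samples, assigns parameters leave-one-subject-out, reconstructs
the TR-resolved timecourse at the assigned parameters, and runs the group
inference. When `couple_behavior_to_snr` is on (default), the generating
behavioral precision is κ₁ = 2 + 8·snr, so decodable signal and
behavioral precision covary across subjects — the positive control for
the brain–behavior correlation. Voxel activation scores are emulated as
the tuning-curve amplitude plus noise, an orientation-unspecific quantity
analogous to an activation contrast, so selection cannot leak label
information.

Default problem sizes are intentionally small — 5 subjects per group, 4
runs, 100 voxels, a 3 × 2 parameter grid, 6 TRs per trial, 200
permutations — chosen so a full experiment runs in seconds while
exercising every stage; the full-study scale (20 per group, 8 runs,
10 × 10 grid, 30 TRs, 10⁴ permutations) is reachable purely through
configuration. The same holds for `run_smoothing_simulation`, whose
default grid is a small slice of the full 11 SNR × 37 FWHM × 1000-rep
surface.

## Known limitations

- No hemodynamic model: timecourse results concern decoder behavior, not
  BOLD dynamics.
- The κ floor (0.5) mildly biases fits of genuinely near-flat von Mises
  components; such data are better described by the guess component
  anyway.
- SVR hyperparameters are conventional defaults; absolute accuracy values
  on simulated data depend on them and should be read qualitatively.
- The nearest-grid-point orientation lookup quantizes tuning at the grid
  resolution (≤ 0.5° at the default p = 180).
- Real-data ingestion is limited to the documented TSV + flat-binary
  containers; a neuroimaging-volume adapter is a documented extension
  point, not implemented.
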