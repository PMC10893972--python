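# orientwm

Orientation working-memory decoding on simulated fMRI data.

`orientwm` is a tested, reusable implementation of a delayed-estimation
decoding pipeline for 180°-periodic orientation stimuli, built for
researchers who want every stage of such an analysis to be verifiable on
synthetic data — no scanner data required. It covers:

- **Simulation** (`orientwm.simdata`) — counterbalanced trial designs (40
  equally spaced orientations per run, shifted 1.125° off the cardinal
  axes, distractors offset by 2.25°), voxel populations with smooth
  periodic tuning curves *z*ᵢ ~ 𝒩(0, *K*ᵢ) drawn from the periodic kernel
  *K*(x_m, x_n, σ) = exp(−2 sin²(½(x_m−x_n))/σ²) with per-voxel smoothness
  σᵢ ~ Γ(2, 2), trialwise signals *y*ᵢⱼ = *z*ᵢ(θⱼ)·s + εᵢⱼ with SNR factor
  s ∈ [0, 1], and behavioral reports from a detection/swap/guess mixture.
- **Behavioral modeling** (`orientwm.vmmm`) — a von Mises mixture model of
  report errors in statsmodels style: `VonMisesMixture(...).fit()` returns
  a results object with mixture coefficients (r₁, r₂, r₃), precisions
  (κ₁, κ₂), bias μ, and a `summary()` table. κ₁ is the behavioral-precision
  readout.
- **Preprocessing** (`orientwm.preprocess`) — cubic-spline detrending with
  half-a-node-per-trial resolution, a 3-TR moving average, trial-sample
  extraction, Gaussian *feature-space smoothing* over circular orientation
  distance (the SNR-raising step for feature-continuous designs), and
  score-based voxel selection.
- **Decoding** (`orientwm.psvr`) — periodic support vector regression:
  labels are projected onto two sinusoids of the doubled angle
  (x = sin 2θ, y = cos 2θ), each predicted by an RBF-kernel
  epsilon-insensitive SVR, and recombined as θ̂ = atan2(x̂, ŷ); min-max
  "across-scaling" is fitted on the training folds only; cross-validation
  leaves one run out; the decoder runs per TR for time-resolved
  reconstruction.
- **Metrics** (`orientwm.metrics`) — feature-continuous accuracy
  FCA = (90 − |θ − θ̂|₉₀)/90 · 100 (100% perfect, 50% chance, 0%
  orthogonal) and its label-balance-corrected integral
  BFCA = (1/180)∫ FCA dθ via trapezoid integration over sorted labels.
- **Inference** (`orientwm.inference`) — cluster-based t-mass permutation
  over accuracy timecourses (sign-flip null, max-cluster statistic),
  pooled two-sample t-tests, Pearson correlations, and leave-one-subject-
  out optimization of the FWHM × voxel-count search grid.
- **Orchestration** (`orientwm.pipeline`, CLI `orientwm`) — a seeded,
  manifest-writing end-to-end experiment (two simulated groups → decode →
  optimize → cluster tests → group comparison → brain–behavior
  correlation) at configurable scale.

## Worked example

```python
import orientwm as ow
from orientwm.vmmm import VMMMParams

design = ow.generate_design(8, seed=1)                  # 8 runs x 40 trials
truth = VMMMParams(0.947, 0.028, 0.025, 5.673, 5.673, -0.889)
behavior = ow.simulate_behavior(design, truth, seed=2)
print(ow.fit_vmmm(behavior, seed=3).summary())

profiles = ow.sample_tuning_profiles(250, seed=4)       # 250 tuned voxels
voxels = ow.simulate_voxel_responses(profiles, design, snr=0.5, seed=5)
samples = ow.extract_trial_samples(voxels, design)
plain = ow.bfca(samples.labels, ow.loro_cv(samples))
smoothed = ow.feature_space_smooth(samples, ow.SmoothingSpec(60.0))
acc = ow.bfca(smoothed.labels, ow.loro_cv(smoothed))
print(f"BFCA without smoothing: {plain:.1f}%")
print(f"BFCA with 60 deg feature-space smoothing: {acc:.1f}% (chance 50%)")
```

prints

```
Von Mises Mixture Model Results
==============================================
No. trials:               320
Log-likelihood:      -260.554
Converged:               True
Restarts:                  10
----------------------------------------------
r1 (detection)         0.9363
r2 (swap)              0.0347
r3 (guess)             0.0290
kappa1                 5.3999
kappa2                 4.9899
mu (deg)              -0.8391
==============================================
BFCA without smoothing: 87.9%
BFCA with 60 deg feature-space smoothing: 94.8% (chance 50%)
```

The mixture fit recovers the generating behavior (95% detections at
precision κ₁ ≈ 5.4 with a small anticlockwise bias), and the decoder
reconstructs the remembered orientation far above the 50% chance level at
a moderate SNR, with feature-space smoothing adding roughly 7 accuracy
points.

The same stages are available from the shell:

```bash
orientwm simulate --n-runs 8 --snr 0.5 --seed 1 --out data/
orientwm fit-behavior --responses data/behavior.tsv --out fit.json
orientwm decode --voxels data/voxels --design data/behavior.tsv \
    --fwhm 60 --out preds.tsv
orientwm evaluate --predictions preds.tsv --out bfca.tsv
orientwm run-all --seed 7 --out experiment/
orientwm smoothing-sim --reps 20 --out surface.tsv
```

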