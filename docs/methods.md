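# Methods

This note documents the models, defaults, and numerical conventions
behind `wmdecode`, and what its synthetic-data tests do and do not show
about real data.

## Task and design model

The simulator reproduces the structure of a memory-guided saccade task
with interleaved distraction. Each 10-trial run mixes 7 distractor-
present and 3 distractor-absent trials in random order (a 70/30 mix);
targets are i.i.d. uniform on the polar-angle circle at 12° eccentricity.
On present trials the distractor appears at one of seven counterbalanced
angular offsets from the target — each offset bin exactly once per run —
jittered uniformly by ±12°. The seven bin centers are not printed
numerically in the source task description (they appear only in a figure
inset), so the default takes the seven absolute separations
{0°, 30°, 60°, 90°, 120°, 150°, 180°} with random sign, giving seven
24°-wide bins that tile the circle and keep one bin inside the ±12°
"near-distractor" window used by the coupling analyses. Bin centers are
configurable.

Timing sits on the 750 ms TR grid, in seconds relative to delay onset:
pre-cue −2.25, target −0.75 (500 ms), delay 0–12, distractor 4.5–5.5,
response cue 12. The training (model-estimation) design has no
distractors: 16 targets per run spaced 22.5° apart, with odd runs offset
by 11.25°, so two consecutive runs tile 32 unique positions.

## Voxel population and BOLD model

Each voxel gets ground-truth pRF-like parameters: preferred polar angle
(uniform), eccentricity (uniform 2–15°, the band the univariate analysis
selects), pRF size growing linearly with eccentricity, simulated variance
explained (uniform 0.1–0.8), an angular tuning width (uniform 25–45°, a
circular-Gaussian SD), and lognormal response gains. Fitting pRFs is out
of scope — these parameters *are* the ground truth the analyses consume.

The noiseless signal of trial t, voxel v is

* a sustained delay response `gain_delay_v · tune_v(θ_target + bias_t − φ_v)`
  over 0–12 s, where `bias_t` is an optional per-trial neural bias
  (degrees) that rotates the represented angle;
* on present trials, a transient `distractor_gain · gain_dist_v ·
  tune_v(θ_dist − φ_v)` during the 1 s distractor window;
* on present trials, a fractional attenuation (`target_suppression`,
  default 0.5 in the study configuration) of the sustained response over
  4.5–7.0 s — the distractor stimulus plus its discrimination-response
  period. This is the simulator's stand-in for the interference observed
  when target and distractor are jointly encoded; its magnitude and
  window are modeling choices, not measured quantities. Under the
  default kernel the suppression's hemodynamic echo extends into the
  late-delay epoch, so simulated fidelity dips do not fully recover by
  the POST window as they partially do in real early-visual data.

`tune` is a circular Gaussian (`exp(−Δ²/2w²)` on wrapped differences).
Everything is convolved with a canonical double-gamma HRF (peak ~5 s,
unit integral; configurable), sampled at TR onsets from −3.0 to 14.25 s,
given i.i.d. Gaussian noise per (trial, TR, voxel) (`noise_sd`, default
1.0 — roughly signal amplitude, which puts single-trial decoding SD near
20°), and finally z-scored per voxel across each run's volumes. Trials
are simulated independently; there is no inter-trial hemodynamic
carryover, scanner drift, or physiological noise.

### What z-scoring does to single-trial decoding

Per-run z-scoring subtracts, from every trial, the run's mean voxel
pattern — a mixture of that run's ten tuning bumps. This adds a
run-specific, angle-dependent component to every reconstruction and
biases single-trial circular-mean decoding by several degrees even in
noiseless data; across runs the bias is zero-mean. Consequently the
pipeline-exactness test (noiseless decoding to within the 1° grid
resolution on every trial) runs on the un-z-scored signal path with the
distractor response disabled, which isolates the IEM chain itself.
Signed bias-recovery and all statistical analyses run under the full
default (z-scored, noisy) conditions.

## Encoding model

Eight channels, raised-cosine-to-the-8th basis with size constant 180°.
The basis formula admits two exponent-precedence readings; the
default raises the cosine alone to the power (`power_on_cosine`), which
leaves each channel a 0.5 baseline over most of its support;
`power_on_sum` (exponent applied to the whole half-raised cosine) is
available, and all structural invariants hold in both modes. Training
activation is the mean over TR onsets in [5.25, 12) s — exactly 9 TRs;
all epoch windows are half-open `[start, end)` on TR onsets (PRE
[3.75, 5.25), DIST [8.25, 9.75), POST [10.5, 12)), a convention forced
by the 9-TR training window. Weight estimation refuses matrices whose
reciprocal condition number falls below 1e-10. Estimated models are
frozen (immutable weights) so every timepoint and condition is read out
through one fixed model. Reconstructions use a 360-point (1°) grid;
alignment snaps references to the nearest grid point and circularly
rolls the activation, preserving total mass exactly.

Fidelity and circular-mean decoding keep negative activations as-is. A
decoded angle is "undefined" (NaN, or an exception in the scalar API)
when the resultant length falls below 1e-9 × mean |r| × grid size — flat
and antipodally symmetric reconstructions have no circular mean, and
silently returning 0° would corrupt downstream correlations; undefined
trials are dropped with a logged count.

## Statistics

All permutation tests shuffle only within participant. One-tailed p is
the proportion of null statistics ≥ observed (ties toward the null),
floored at 1/n_perm; two-tailed p doubles the smaller tail, capped at 1.
Doubling the smaller tail (rather than doubling the upper tail
unconditionally) keeps the test calibrated regardless of effect
direction. The repeated-measures ANOVA uses the standard fully-within
decomposition (each effect's error term is its interaction with
subjects; verified against `statsmodels.AnovaRM` to machine precision);
its permutation scheme shuffles the flattened cell labels freely within
each participant — the exchangeability assumption adopted where a finer
scheme (which factor labels shuffle jointly) is not dictated by the
design.
Correlations are clipped to |r| ≤ 1 − 1e-10 before the Fisher z
transform. FDR is Benjamini–Hochberg step-up. Type-I calibration of
every test is itself under test (500-replicate null simulations checked
against the binomial CI of α = 0.05).

The run-wise paired permutation test aggregates fidelity per run and
condition (7 present / 3 absent trials per run) before testing, because
present-trial fidelity cannot be compared trial-by-trial across the
seven relative distractor positions.

## Behavior, staircase, gaze

Saccade endpoint errors follow `ρ·bias_t + attract·sign(toward
distractor) + N(0, motor_sd)`, wrapped; defaults ρ = 0.5, attract = 1°,
motor_sd = 5°, with `bias_t` the same per-trial neural bias driving the
BOLD simulator (SD 10°) — so the neural-behavioral coupling analyses
have known ground truth. The 3-down/1-up staircase steps difficulty
down after three consecutive correct responses and up after any error;
its accuracy fixed point solves P³ = 0.5 (P ≈ 0.794), and the simulator
discards the first 25% of trials as burn-in before reporting converged
accuracy.

Gaze traces (500 Hz) fixate centrally, then execute a raised-cosine
saccade to the behavioral endpoint with amplitude-scaled duration
(~21 ms + 2.2 ms/°); onsets snap to the sampling grid so ground truth is
exact. Preprocessing: unit conversion, blink/extreme invalidation,
Gaussian smoothing (5 ms SD), per-trial drift correction by the
fixation-epoch mean, then run-wise cubic-polynomial recalibration of x
and y against known target positions. Saccades are runs of speed
strictly > 30°/s (central differences on the smoothed trace) lasting
≥ 7.5 ms — ceil to 4 samples — with net displacement ≥ 0.25°. A trial's
report is the endpoint of the last saccade landing before the target
reappears; RT runs from response cue to first-saccade onset. Exclusions
(conjunctive): initial saccade duration ≥ 150 ms (valid initial saccades
must complete in under 150 ms), amplitude < 5°, endpoint > 5°
(Euclidean) from
the target, fixation excursion ≥ 2.5° during the delay, or no saccade in
the response window. Precision is the ordinary sample SD of wrapped
endpoint polar-angle errors — appropriate in this small-error regime —
not a circular SD.

## Problem sizes

Group-level analyses simulate 7 participants × 30 runs (mid-range of
the study's 25–36 runs per participant) × 120–160 voxels, with 1000
permutations for reported tests and 99–199 for calibration sweeps.
Boundary conventions adopted where the source is silent: "within 12°"
and the 15°/165° RF windows are inclusive; the antipode wraps to +180°.

## Known limitations

The simulator's fidelity to real fMRI stops at i.i.d. Gaussian noise,
independent trials, and a shared canonical HRF: temporal autocorrelation,
voxel-wise HRF variability, eccentricity-dimension structure, and
realistic pRF size/eccentricity covariation are absent. Passing tests
demonstrate the *analysis chain* is correct and calibrated under the
stated generative model; they do not certify effect sizes or power for
real data. The 2-D (eccentricity) component of spatial representations
is unmodeled throughout, and no Bayesian or maximum-likelihood decoder
variants are provided.
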