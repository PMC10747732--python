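# Methods

`runload` studies whether peak tissue loads in running — the patella
ligament force and the Achilles tendon force, both mass-normalized — can
be predicted from a handful of body-worn accelerometers plus simple
anthropometrics. Because the motion-capture / musculoskeletal-simulation
data that originally motivated this question are not publicly deposited,
the package pairs the full prediction-and-evaluation machinery with a
synthetic study generator whose structure mirrors the real protocol: a
heterogeneous cohort, treadmill trials over 6–20 km/h, periodic segment
kinematics, five virtual accelerometers, Fourier-domain feature
compression, and a repeated random-split evaluation of elastic-net and
gradient-boosted predictors over seven sensor configurations.

## Synthetic cohort and trials

The default cohort is 78 runners (30 female, 48 male) with per-sex
Gaussian anthropometrics:

| parameter | female | male | unit |
|---|---|---|---|
| mass | 62 ± 7 | 78 ± 9 | kg |
| stature | 1.67 ± 0.06 | 1.80 ± 0.07 | m |
| age | 38 ± 10 | 40 ± 11 | yr |

Thigh, shank and foot lengths are fixed stature fractions (0.245, 0.246,
0.152) with 2% multiplicative jitter; BMI is derived. 285 trials are
assigned to runners uniformly at random with speeds uniform on
6–20 km/h. Cadence follows an affine law, step frequency
`f = 2.40 + 0.04·v` Hz (v in km/h) plus a runner-specific offset
(SD 0.08 Hz), giving stride periods around 0.6–0.8 s. The duty factor
(ground-contact fraction of a step) decreases affinely with speed,
`0.486 − 0.011·v`, clipped to (0.20, 0.45). Each runner carries a
habitual strike style, forefoot with probability 0.30. All of these
constants live in `CohortConfig` and are recorded in run manifests.

## Kinematics model

Per trial, every kinematic channel is a truncated Fourier series of the
stride frequency: a DC term plus five sine and five cosine coefficients.
The cycle origin (phase 0) is right heel strike; the left leg strikes
half a stride later. Channel templates encode the qualitative structure
of running: limb channels (hip, knee, ankle, shoulder) are dominated by
the first stride harmonic, while torso channels (vertical pelvis
excursion, trunk lean) repeat once per *step* and are therefore dominated
by the second harmonic. Amplitudes grow affinely with normalized speed
and receive per-trial multiplicative jitter (SD 0.05) drawn from
channel-specific child seeds, so channels untouched by a configuration
change (e.g. strike style) are bit-identical across it. Ankle
dorsiflexion templates differ between heel and forefoot styles — this is
the deliberate nonlinearity that a tree model can exploit and a linear
model cannot fully capture. Right-side channels are the left channels
delayed by half a stride (mirror symmetry); an asymmetry factor in the
config can scale the right side down for robustness experiments.

## Ground-truth force model

True tissue loads come from a declared quasi-static model rather than a
full musculoskeletal simulation; the aim is a transparent, monotone,
smoothly speed-dependent target with a style-dependent discontinuity,
not anatomical fidelity:

* Stance vertical ground reaction per unit mass:
  `F(τ) = g·A·sin(π τ/t_c)` on the contact interval `t_c = duty·step
  period`, with `A = π/(2·duty)` fixed by impulse balance (the mean
  vertical force over a step equals body weight).
* Knee moment: `F(τ)·d_knee(τ)` with `d_knee = 0.18 m/rad ×` the
  instantaneous knee-flexion angle over that leg's stance window.
* Ankle moment: `F(τ)·d_ankle(τ)` where the centre-of-pressure lever is
  a strike-style ramp scaled by foot length — heel:
  `(−0.30 + 0.90·τ/t_c)·L_foot`, forefoot: `(0.55 + 0.05·τ/t_c)·L_foot`.
* Peak patella ligament force = max knee moment / `(0.12·L_shank)`;
  peak Achilles force = max ankle moment / `(0.25·L_foot)`; both per
  unit mass (mass cancels exactly).

Defaults produce peaks of roughly 35–90 N/kg (patella) and 40–110 N/kg
(Achilles), the right order of magnitude for running, with forefoot
trials loading the Achilles roughly twice as much as heel trials. Forces
increase strictly with speed for a fixed runner and style.

## Virtual accelerometers

The body is a planar sagittal chain — pelvis root, trunk, two
single-segment arms, thigh–shank–foot legs — driven by the kinematic
channels, with mediolateral pelvis sway as the out-of-plane component.
Five sensors (two wrists, two ankles, sternum) are fixed to segments
with the convention x anterior, y along the segment long axis, z
lateral. A sensor reads proper acceleration: the second time derivative
of its attachment-point trajectory minus gravity, rotated into the
sensor frame, so a static sensor reads +1 g. Differentiation is spectral
(FFT) on one uniformly sampled stride (default 300 Hz, endpoint
excluded), which is exact for band-limited trajectories. Note that the
chain's trigonometric nonlinearity means joint-driven accelerations
contain energy above the fifth stride harmonic even though every joint
channel is band-limited; only root-translation-driven motion is exactly
band-limited, and the band-limit test asserts that case. Gyroscopes,
soft-tissue artefacts, mounting error and terrain are not modeled; the
default accelerations are noise-free, with an optional additive Gaussian
noise flag.

## Features

Each sensor channel (three axes plus magnitude) over one stride is
compressed to 11 Fourier coefficients under the reconstruction
convention `s(t) = dc + Σ cos_k·cos(kωt) + sin_k·sin(kωt)`, giving 44
columns per sensor. The FFT runs on the native per-stride sample count;
no power-of-two resampling is performed since `rfft` is exact under the
same convention at any length. Seven sensor configurations (subsets of
left wrist, right wrist, sternum, left ankle; the right ankle is dropped
as mirror-redundant) plus ten scalar predictors — step frequency, sex
(female 0 / male 1), age, thigh/shank/foot length, mass, stature, BMI,
speed — give 54 or 98 predictors for single- and double-sensor
configurations. A schema-accounting helper reproduces the full study
table arithmetic (88 kinematic DOFs × 11 = 968 columns, 5 × 44 = 220
acceleration columns, 4 force + 35 anthropometric + 2 scalar columns,
1229 total); only the acceleration block and the ten scalars feed the
models.

## Models

*Elastic net* — glmnet-style objective on standardized predictors,
mixing parameter α ∈ {0, 0.5, 1} in replication mode. The penalty λ is
chosen by 10-fold cross-validation over a log-spaced path from λ_max
(the smallest all-zero-slope penalty) down four decades, 100 points;
ties resolve to the largest λ. Fold assignment is a seeded permutation,
no stratification. α = 0 is solved in closed form via SVD for the whole
path at once; α > 0 uses coordinate descent with a precomputed Gram
matrix. The CV path tolerance is 1e-3 (max 2000 iterations) — loose
enough for repeated-refit throughput, tight enough that the CV argmin is
stable; single fixed-λ fits use 1e-7. Coefficients are reported on the
original scale; standardized coefficients are kept for effect-size
ranking. A constant training target yields a flagged intercept-only
model.

*Gradient-boosted trees* (XGBoost) — squared-error boosting with depth
∈ {3, 6} and learning rate ∈ {0.1, 0.3}; the tree count is chosen by
5-fold `xgb.cv` (smallest count on ties), capped at 80 rounds with
early stopping after 8 stagnant rounds; base score at the target mean;
`hist` trees with 32 bins; all other booster parameters at library
defaults. The cap and histogram settings are desk-scale defaults
recorded here and in the results metadata.

## Evaluation protocol

Models are scored over independent random 90/10 training/test splits;
identical partitions may recur across repetitions (the splits, not the
rows, are resampled). The model, including its CV-chosen tuning
parameter, is refit inside every training set — the statistically
defensible reading of the protocol; tuning once on the full data would
leak test information. Reported per cell: mean Pearson correlation over
splits where it is defined (a constant predictor makes it undefined;
such splits are excluded and counted) and mean nRMSE (RMSE divided by
the full-data target mean). nRMSE identifies the best model; ties break
toward fewer sensors, then the elastic net (fewer tuned parameters).
Calibration is the least-squares line of observed on predicted over a
250-point random subsample of pooled test predictions, with (0, 1) as
the no-bias reference. Elastic-net importance reports per-predictor
inclusion frequency and the average rank of |standardized coefficient|
(zeroed predictors share the worst tied rank, giving scale-free ranks);
boosted-tree importance reports average total gain and average gain
rank, with unused features at gain 0.

### Problem sizes

Repeated-split evaluation with per-split CV retuning is the dominant
cost: the full grid (7 configurations × 7 model cells × 2 targets) costs
roughly 25 s per split on one CPU. The package therefore uses a tiered
profile, chosen as its own desk-scale defaults: the full grid runs at a
reduced split count (8 in `scripts/acceptance.py`, 250 in
`RunConfig.n_splits` for single-grid pipeline runs), and the winning
cell per tissue is re-evaluated at 250 splits for the reported numbers.
A ridge cell evaluates at ~9 ms/split, so split-count stability (2500
vs 250) is verified on that family.

## What the generator does and does not show

The synthetic study preserves the statistical *shape* of the problem —
n ≪ p regime within configurations, strongly collinear Fourier
predictors, smooth speed-driven common variation, a style-driven
nonlinearity in one target — so protocol-level conclusions (e.g. that
ankle sensors predict patella load best, that undefined correlations
must be handled, that single sensors can beat pairs) are meaningful.
It does not emulate measurement noise, soft-tissue artefact, sensor
misplacement, inter-subject style diversity beyond the configured
jitters, or the anatomical detail of a full musculoskeletal model, so
absolute performance numbers on synthetic data say nothing quantitative
about real runners. The generator's sagittal-chain accelerations are
strongly collinear across coefficients; only the lateral-axis
coefficients carry close-to-independent variation, which is why the
support-recovery benchmark plants its signal there — support recovery is
only identifiable for predictors that are not linear combinations of the
rest.

## Numerical choices and degenerate inputs

Seeds: every stochastic stage derives a child seed (< 2^31) from the
master seed and a stage label via BLAKE2; identical configs reproduce
byte-identical artifacts. Degenerate cases are defined, not fatal:
empty cohorts and zero-split evaluations return empty results; constant
targets yield flagged intercept-only models; constant predictions carry
an undefined-correlation flag; degenerate calibration variance flags the
result. Sub-Nyquist sample rates (fewer than 11 samples per stride),
non-uniform time grids, unknown sites, empty-cohort trial requests and
out-of-range duty factors raise errors.

## Known limitations

* The planar chain cannot reproduce true 3-D axial rotations; lateral
  channels derive from pelvis sway only.
* The quasi-static force model ignores swing-phase loads, muscle
  co-contraction and elastic energy storage; it is a declared stand-in,
  not a validated biomechanical model.
* Left-side forces are the prediction targets (matching the retained
  left-ankle sensor); which side the original protocol predicted is
  unresolved, and the generator is symmetric by default so the choice is
  immaterial there.
* With 285 trials and up to 98 collinear predictors, elastic-net support
  sets are unstable across splits for sagittal coefficients; inclusion
  frequencies below 1 should be read as collinearity, not irrelevance.
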