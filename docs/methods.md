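# Methods

## The experiment being simulated

A two-group real-time fMRI neurofeedback study. Each subject completes
four runs of a block design: eight 15-volume neutral blocks interleaved
with four 22-volume tenderness/affection and four 22-volume pride blocks
(TR = 2 s, 296 volumes, ≈10 min per run). Run 1 trains a two-class
linear SVM on the multivoxel patterns of the two emotional conditions;
in runs 2–4 the decoder classifies each incoming volume and the subject
sees a ring whose distortion level encodes the classifier's confidence.
Neurofeedback (NFB) subjects see rings contingent on their decoded brain
state; control (CTR) subjects see uniformly random rings. Before each
classification session the decoder is retrained on the immediately
preceding run. The first emotional block's baseline is the run-initial
neutral block, which the design guarantees; the order of emotional
conditions within a run is strict alternation, with the starting
condition counterbalanced across subjects.

## Generative model of a run

Voxel signal in a run is

```
y(v, t) = B + Σ_c a_c · p_c(v) · (h ⊛ box_c)(t) + m·t + ε(v, t)
```

with baseline `B = 100` (arbitrary scanner units), condition amplitudes
`a_c`, spatial patterns `p_c` (uniform magnitudes in [0.5, 1] inside two
disjoint ellipsoids, zero elsewhere), the canonical double-gamma HRF `h`
(response peak 6 s, undershoot peak 16 s, undershoot ratio 1/6, 32 s
support, unit peak), condition boxcars `box_c`, linear drift of slope
`m` per volume, and stationary AR(1) noise `ε` with marginal SD σ and
lag-1 autocorrelation φ, independent across voxels. Neutral blocks
carry baseline + drift + noise only.

Default grid: 24×24×12 voxels of 3 mm — a desk-scale stand-in for a
64×64×22 EPI matrix that keeps a 96-run cohort simulation under a
minute. The feature mask is a large central ellipsoid (≈2300 voxels);
the small-volume-correction ROI is a sub-ellipsoid overlapping the
tenderness pattern, standing in for an a-priori anatomical mask of a
few dozen voxels.

### Learning rule

Learning acts on signal amplitude, not pattern shape: the observable
group effect is an increased frequency of tenderness-characteristic
patterns, which amplitude gain produces most simply. After each
classification run the mean displayed ring level over usable
tenderness volumes, `L̄ ∈ [1, 20]`, updates

```
a_tenderness ← max(0, a_tenderness + η · (L̄ − 10.5) / 9.5)
```

for contingent (NFB) subjects only; 10.5 is the scale midpoint, which is
also the expectation of the CTR group's uniform random levels, so
random feedback is neutral in expectation. CTR states never update.
Feedback is aggregated per run rather than per volume to stabilize the
toy dynamics.

### Parameter defaults and calibration

| parameter | default | units | role |
|---|---|---|---|
| `amp_tenderness`, `amp_pride` | 0.7 | signal units | initial pattern amplitudes |
| `noise_sd` (σ) | 10.0 | signal units | marginal voxel noise SD |
| `ar_coeff` (φ) | 0.3 | — | lag-1 noise autocorrelation |
| `drift_slope` | 0.01 | units/volume | linear scanner drift |
| `learning_rate` (η, NFB) | 3.0 | signal units per unit feedback | closed-loop gain |
| display saturation `DISPLAY_D_MAX` | 0.3 | decision-value units | ring level 20 threshold in the simulator loop |

σ and η are calibrated jointly so that the default cohort starts near
60–70% single-volume accuracy and the NFB group improves by roughly
+20 percentage points over three sessions while CTR stays flat — the
qualitative group × session dissociation the pipeline must reproduce.

The display saturation deserves explanation. The generic feedback
default maps level 20 to decision values at the support-vector margin
(`d_max = 1`). Out-of-sample decision values, however, shrink far below
the training margin when features (~2300 masked voxels) vastly
outnumber training volumes (160): empirically |d| is typically ≤ 0.5 on
unseen volumes. With `d_max = 1` the rings would occupy only the lowest
third of the scale, the mean displayed level would sit below the
midpoint at *any* accuracy, and the learning rule above could only
shrink amplitudes. A working display must span the decision-value range
the decoder actually emits, so the simulator's loop saturates at 0.3.
`FeedbackConfig` keeps 1.0 as its general default.

### What the generator does and does not emulate

Emulated: block-locked HRF-shaped responses, spatially structured
condition patterns inside a restricted feature mask, slow drift,
temporally autocorrelated noise, per-session decoder retraining, and a
feedback-contingent learning effect confined to the NFB group. Not
emulated: spatially correlated physiological noise, head motion (an
optional translation-realignment stage exists but synthetic runs are
motion-free), susceptibility dropout, between-subject anatomical
variability, and any saturation or forgetting in learning. Passing
tests therefore demonstrate that the *analysis* behaves correctly under
its own assumptions, not that real subjects learn by amplitude gain.

## Real-time preprocessing

Per-volume, causal pipeline in acquisition order: optional
translation-only realignment to the first volume (FFT cross-correlation
peak, quadratic sub-voxel interpolation, linear resampling), Gaussian
smoothing (FWHM 6 mm, σ = FWHM/(2√(2 ln 2)) per axis in voxel units,
reflective boundaries so constant fields are preserved, kernel truncated
at 6σ), then subtraction of the voxelwise mean of the most recent
*completed* neutral block, and masked feature extraction in fixed
row-major (x, y, z) voxel order. Smoothing precedes baseline
subtraction, matching the stated online order; full 6-degree-of-freedom
rigid realignment is out of scope at desk scale.

## Decoder

`sklearn.svm.SVC(kernel="linear")` behind a thin surface; C defaults to
1.0 and no standardization is applied beyond the neutral-baseline
subtraction, the protocol's only stated normalization. Decision value
`d = xᵀw + b`; class tenderness iff `d > 0`, with an exact zero resolved
to pride so tenderness-classification claims stay conservative.
Discriminant maps rank voxels by |w|; the flagged count is
round-half-away-from-zero of fraction × n with ties broken by voxel
order. Session k's decoder is trained on run k−1 only. Tests verify the
hard-margin limit against an enumerated brute-force max-margin search
on small 2D instances.

## Feedback quantizer

Toward-target signed distance `s` (= d for tenderness targets, −d for
pride). `s ≤ 0` → level 1 (most distorted; misclassification).
Otherwise level = 1 + min(19, ⌈min(s, d_max)/d_max · 19⌉): a monotone
step function with exactly 20 attainable values, saturating at `d_max`.
Near-zero correct distances map to level 2, keeping level 1 an
unambiguous error signal. No feedback exists for neutral volumes or the
first two volumes of a block — they are never classified.

## Outcome statistics

Accuracy is computed over usable volumes (not blocks): the binomial
reliability criterion — accuracy above 60% with exact one-sided
p < .05 at chance 0.5 — is only meaningful at n ≈ 80 volumes per
session. One-sample t tests are two-sided against 0 (session changes)
or 50% (last-session accuracy); the between-group test is
pooled-variance Student t with df = n₁ + n₂ − 2. Per-subject
reliability uses the last classification session only. p-values come
from `scipy.stats`; the statistics are computed from their defining
formulas and verified against a numerical-integration oracle of the t
density.

## Offline GLM

First level: tenderness and pride boxcars over whole blocks convolved
with the canonical HRF; neutral is the implicit baseline — the three
condition boxcars sum to one at every volume, so a modeled neutral
regressor would be collinear with the intercept up to HRF edge effects,
and dropping it leaves the tenderness − pride contrast unchanged while
keeping the design well conditioned. Drift regressors: the SPM-style
DCT set with K = ⌊2·T·TR/cutoff⌋ columns (cutoff 448 s → K = 2 for a
296-volume run) plus a centered linear trend, because the generator's
drift is exactly linear and the two lowest DCT harmonics alone leave a
ramp residual that would leak into condition betas. Estimation is
voxelwise OLS (unbiased under the acceptance surface of parameter
recovery; AR(1) prewhitening is not implemented).

Second level: per-voxel simple regression of the subject contrast maps
on the behavioral covariate (session-3 minus session-1 tenderness
classification change), slope t with df = n − 2. Family-wise error
inside an a-priori ROI is controlled by max-statistic permutation: the
covariate is permuted (seeded), the null is the ROI-maximum |t|, and
`fwe_p = (1 + #{null ≥ observed peak})/(n_perm + 1)`. This replaces
random-field-theory small-volume correction: permutation gives exact
finite-sample control at desk scale without smoothness estimation.
Cluster extent is counted at a one-sided uncorrected forming threshold
of p < .005. Tests verify null calibration (rejection rate at α = .05
within [0.02, 0.08] over 200 null simulations) and monotonicity of
`fwe_p` in planted effect size.

## Numerical and design choices

- Voxel indices are 0-based; masks and series share one grid; no
  world-space resampling.
- Feature ordering is row-major over (x, y, z) and stored with the
  decoder so train/decode orderings always agree.
- `simulate_run` accepts the per-volume feedback stream for validation
  and logging, but the within-run signal does not depend on it:
  learning acts between runs.
- Degenerate inputs raise typed errors (empty mask, single-class
  training, zero-variance t test, constant covariate, no preceding
  neutral block) rather than returning NaN.
- Problem sizes: the default cohort (24 subjects × 4 runs × 296 volumes
  at 24×24×12) simulates in well under a minute; unit tests use a
  16×16×8 grid and shortened designs where the full protocol adds
  nothing.

## Known limitations

- The learning model is a one-parameter amplitude gain with no noise in
  the update; real neurofeedback learning is slower, noisier, and
  partly strategic.
- Session-to-session decoder variability dominates single-subject
  trajectories at the default noise level, exactly as the large
  per-subject SDs of the emulated study suggest; group-level contrasts
  are the reliable read-out.
- OLS ignores the AR(1) noise in first-level inference; only contrast
  *estimates* (which remain unbiased), not their single-subject
  standard errors, are consumed downstream.
- Translation-only realignment cannot correct rotations; it exists to
  exercise the streaming interface, not to model real head motion.
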