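# Methods

`facekin` measures how a performer reshapes their face while speaking,
using 3D motion-capture marker trajectories, and relates those facial
changes to the voice. This note documents the models, the synthetic
cohort the tests run on, the numerical choices, and the limits of what
the test suite can show.

## The measurement model

**Segments.** A facial segment is the straight line between two
markers; its per-frame Euclidean length
`d = sqrt((x2-x1)^2 + (y2-y1)^2 + (z2-z1)^2)` (millimetres) indexes
expansion or contraction of that part of the face. The default set is

| segment | markers | orientation | region |
|---|---|---|---|
| brow | mid_brow – nose_bridge | vertical | upper |
| eyebrow | l_eyebrow – r_eyebrow | horizontal | upper |
| lips | l_lip – r_lip | horizontal | lower |
| jaw | nose_bridge – jaw | vertical | lower |

plus four supplementary vertical segments (nose bridge to each inner
eyebrow and each lip corner). The exact pairings are a convention of
this package, configurable per study; they are not claimed as the
ground-truth wiring of any particular marker-placement protocol.

**Trial mean.** The trial feature is the mean segment length `Md` over
the trial. Reconstruction gaps are never interpolated: a frame missing
either marker of a pair is dropped, and the mean divides by the number
of *valid* frames, not by `sample_rate x duration`. On a gap-free trial
the two denominators coincide; with gaps, dividing by total frames
would drag the mean toward zero, which is exactly the bias the
no-interpolation policy exists to avoid. A segment mean is reported
only when at least 50% of frames are valid (configurable).

**Percent change.** Expressive scores are confounded by speech
articulation and by head size. Both are removed within subject:

```
%change = 100 * (Md_performance - Md_neutral) / Md_neutral
```

where the baseline is the same subject reciting the same script with
neutral emotion. The neutral trial maps to exactly 0 and is excluded
from the univariate analyses; multiplying all of a subject's
coordinates by any c > 0 leaves every %change unchanged. Outlier
screening is report-only (robust z from median/MAD, default threshold
|z| > 4): the screen is printed, nothing is edited or removed.

## The design

Characters live on a 3x3 grid of cooperativeness x assertiveness
(low/medium/high each); the shipped name-to-cell placement (bully,
hero, king / loner, self, lover / recluse, librarian, caregiver) is a
documented convention and a **required** input in pipeline config
files. Eight emotions are grouped 2x2 by valence and arousal:
happy/proud/surprised (+,high), angry/fearful/disgusted (−,high),
calm (+,low), sad (−,low); neutral is the baseline only. The character
design is balanced (each cell once per subject); the emotion design is
unbalanced by construction (cells of 3/3/1/1 emotions), which is why
all factor codings are sum-to-zero — type III tests are otherwise not
well-defined in the unbalanced case.

## The mixed model

Each segment's %change is modelled as

```
y_ij = x_ij' beta + u_i + e_ij,   u_i ~ N(0, tau^2),  e_ij ~ N(0, sigma^2)
```

with a random intercept per subject and the two design factors (plus
interaction) as fixed effects, estimated by maximum likelihood
(REML available as an option). Type III F tests use Satterthwaite
denominator degrees of freedom: the contrast covariance `L C(theta) L'`
is eigendecomposed, each one-degree component gets
`nu_m = 2 f_m^2 / Var(f_m)` by the delta method through the observed
information of the profile likelihood, and the components are pooled
into one denominator df. `SumSq = F * NumDF * sigma^2`, the convention
of mixed-model type III tables. Effect sizes are the variance-
decomposition R²: marginal (fixed effects over total variance) and
conditional (fixed plus random over total).

The model is implemented directly on the closed-form profile likelihood
of the two variance components (each subject block has covariance
`sigma^2 I + tau^2 J`, invertible by Sherman–Morrison), because the
Satterthwaite machinery needs the curvature of that likelihood and no
installed Python library exposes it. The optimizer is Nelder–Mead on
log-variances at tight tolerance (`xatol 1e-12`); the fit is verified
in the tests against statsmodels `MixedLM` (log-likelihood and variance
components) and against `lme4`/`lmerTest` via Rscript (full type III
Satterthwaite tables under both ML and REML).

Two df facts worth knowing. On a balanced design the REML fit
reproduces the classical pooled-error repeated-measures ANOVA exactly
(F equal to the closed form at 1e-6 relative; denominator df
`(s-1)(c-1)` pooled across effects). Under ML the Satterthwaite
denominator is instead `n_obs - n_subjects` (192 for 24 subjects x 9
characters) because the ML residual variance is profiled over the full
within-subject space; ML F values are mildly anti-conservative at this
scale (ratio 192/184 on the character design). The calibration test
therefore checks exactness under REML; ML remains the default because
it is the conventional estimation choice for these type III tables and
its DenDF bookkeeping matches common practice.

Bonferroni correction is alpha/n over the family of segments tested
(.05/4 = .0125 for the default set). Estimated marginal means per
factor level (equal cell weights, so sum-coded terms drop out) are
exported to back effect plots.

## Face–voice coupling and the self contrast

Pearson correlations (two-tailed, Fisher-z 95% CIs, df = n−2) pair each
trial's segment scores with its vocal parameters; character and emotion
trial sets are correlated separately, with Bonferroni flags across the
segment family. Which trials enter each set is explicit configuration:
default all 9 characters (including the performed self) and the 8
non-neutral emotions. Missing vocal rows are dropped pairwise here —
imputation is reserved for the multivariate analysis. The performed-
vs control-self contrast is a paired t test per segment with Cohen's
d_z.

## Multimodal PCA

The 4 facial + 12 vocal parameters over all 9 characters + 9 emotions
(n = subjects x 18; the neutral row enters as the all-zero %change
reference) are z-scored within subject (sample SD, ddof = 1), missing
cells are filled by *similar-case imputation* — the mean of the same
condition across the other subjects, computed after z-scoring, with
every imputed cell flagged in the output — and principal components are
extracted from the correlation matrix. Retention heuristics (Kaiser
count of eigenvalues > 1, scree data) are reported; the retained k is
configuration, default 2. The first k loading columns are rotated by
varimax with Kaiser row normalization; a k = 2 rotation is verified
against a brute-force 0.001-rad scan of the criterion. Orthogonal
rotation preserves communalities and total retained variance (checked
at 1e-9). Sign convention: each rotated component is flipped so that
its largest-|loading| parameter loads positively. Component scores are
the standardized PC scores rotated by the same orthogonal map;
per-condition means across subjects place each character and emotion in
the rotated plane. Loading magnitudes are banded for interpretation:
< .35 below, .35–.49 moderately low, .50–.59 moderate, .60–.79 strong,
>= .80 very strong.

## The synthetic cohort

No public corpus of facial motion capture for character portrayal
exists, so the generator creates one with known structure: 24 subjects
by default, each performing 9 characters, 9 emotions (including
neutral) and a control-self trial; 7 facial markers at 120 Hz.

- **Geometry.** A fixed 7-marker rest face, scaled per subject by
  `1 + N(0, 0.1)` — faces differ in size, nothing else.
- **Condition targets.** Each trial's designed %change per segment is
  the sum of the factor effects for its design cell, a per-subject
  expressiveness offset (SD 2%), a latent shared within the
  upper-face "quality" block (brow/eyebrow/lips, SD 3%) or the
  "intensity" block (jaw, SD 3%), and independent trial noise
  (SD 1.5%). Default designed effects: cooperativeness slopes of
  +/−2, 1.5, 2.5% on brow/eyebrow/lips; assertiveness +/−2.5% on jaw;
  valence effects on all four segments; arousal +/−2% on jaw; the
  control-self contracted by 4–5% on eyebrow/lips/jaw (a moderate
  paired effect size, d_z ≈ 0.6, at these noise levels). Neutral is
  exactly zero — it is the reference.
- **Trajectories.** Offsets scale rest lengths multiplicatively, so the
  designed %change is recovered *analytically* by the pipeline when
  noise is off. Articulation is an additive zero-mean sinusoid on lips
  and jaw (2 and 5 mm, 4 Hz, per-subject phase), identical across a
  subject's conditions — the assumption the baseline correction rests
  on; a config switch (`articulation_varies_by_condition`) breaks it
  for robustness studies. Rigid head sway (translation plus small yaw)
  is added, then Gaussian marker jitter, then the face-scale factor,
  then Bernoulli dropout of marker-frames. Because jitter and
  articulation are applied at unit scale before the size factor,
  scaling a face is an exact similarity transform and %change is
  scale-invariant to machine precision.
- **Voice.** Each of 12 vocal parameters is a linear function of the
  trial's realized jaw expansion (intensity driver) and the mean
  realized upper-face expansion (quality driver) plus noise:
  pitch and loudness load on intensity (r ≈ 0.6 with the jaw at
  default settings, between the correlations reported for character
  and emotion sets in comparable acted-speech data); pause duration
  and shimmer load weakly negatively on intensity; duration and two
  timbre parameters load negatively on quality; the rest are noise.

All randomness flows from one seed through keyed `SeedSequence`
children: identical configs reproduce identical files byte-for-byte.

**What the generator does not emulate:** real articulatory kinematics
(speech is a sinusoid, not phoneme-driven), non-rigid head/skin motion,
marker swaps and reflective artefacts, autocorrelated dropout runs,
between-condition differences in articulation (unless switched on), or
actors' idiosyncratic strategies. Passing tests therefore demonstrate
that the pipeline recovers known structure under the stated noise
model — not that any particular real cohort would show these effects.

## Problem sizes and determinism choices

Tests run 2-s trials on 6-subject cohorts for I/O-bound paths and
feature-level simulation (skipping trajectory synthesis, which the
multiplicative construction makes exactly equivalent in expectation)
for the statistical studies: type-I calibration uses 500 replicates of
the 24-subject character design, power uses 200, all seeded. The
acceptance script simulates the full default cohort (456 trials, 10-s
trajectories at 120 Hz) and runs every stage on disk. Full-length
(120-s) trials are a config flag away and change only runtime.

Numerical details: trajectory files store 6 decimal places
(sub-micrometre); eigendecompositions order eigenvalues descending with
deterministic sign fixes; the varimax iteration stops at relative
criterion change 1e-12; variance-parameter Hessians use central
differences with steps of 1e-5 relative; a rank-deficient design or a
zero-variance response is an explicit error, never a silent drop.

## Known limitations

- Random-intercept structure only; no random slopes or Kenward–Roger
  df. Where true subject-by-factor heterogeneity exists the pooled
  residual is optimistic.
- Satterthwaite df for the unbalanced emotion design are approximate
  (as everywhere); agreement with lmerTest is verified to ~1%.
- "Similar-case imputation" is implemented as the same-condition
  cross-subject mean after z-scoring — the closest defensible reading
  of that phrase; imputed cells are always flagged so any alternative
  can be substituted.
- The 2D-to-3D reconstruction of raw camera data is out of scope; the
  pipeline starts at labeled 3D trajectories.
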