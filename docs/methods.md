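# Methods

## Thickness profiles from traced contours

Input is a pair of open polylines per subject — the manually traced upper
(dorsal) and lower (ventral) callosal boundaries in the midsagittal plane,
in millimetres. The package-wide coordinate convention is x increasing
anterior → posterior and y increasing inferior → superior, so anterior-first
orientation is decided by comparing endpoint x coordinates (ties leave the
polyline unchanged).

Each boundary is resampled to `n_points` (default 100) points equidistant
along its own cumulative arc length, by linear interpolation between
vertices. Linear (not spline) interpolation is deliberate: manual traces
are polylines, and a spline would invent curvature the rater never drew.
The first and last resampled points are pinned to the traced endpoints.

Correspondence between the two boundaries is index-wise after independent
resampling — point *i* of the upper boundary is paired with point *i* of
the lower — with no closest-point matching. The midline is the spatial
average of corresponding points (`pointwise_average`, the default). With
this midline, the distance from upper point *i* to midline point *i*
equals the distance from lower point *i* to the same midline point (up to
one rounding ulp), so a single callosal distance value (CDV) per position
describes local thickness on both outlines, and thickness = 2 × CDV. An
alternative `resampled_average` mode re-resamples the averaged midline to
equidistant points along its own arc length before measuring; the upper
and lower distances then differ slightly and the CDV is defined as their
mean. The alternative mode exists for sensitivity analyses; all defaults
and all validation use the pointwise mode.

Numerical notes:

- CDVs are invariant to rigid motions of the traced pair and scale
  linearly with uniform scaling (tested to 1e-9 and 1e-12 relative).
- Arc-length resampling is idempotent to 1e-9 only on polylines whose own
  segments already have equal length (the fixed point of the operation);
  on generic curves each additional pass moves points by a strictly
  smaller amount, on the order of 1e-3 of the curve length for smooth
  shapes. The profile itself is computed with a single pass, so this
  matters only if resampled outputs are fed back in as inputs.
- CDV at the first and last positions can approach zero when the
  boundaries meet at the tips; the endpoints are retained in the profile.

## Pointwise group model

At each position independently, ordinary least squares of CDV on an
intercept, reference-coded diagnosis indicators (healthy controls, HC, as
reference when present), and the configured covariates (defaults: age,
education, total intracranial volume, illness duration,
chlorpromazine-equivalent dose). Sex is never entered: the design it
serves is fully sex-matched and sex is collinear with head size. The
omnibus statistic is the extra-sum-of-squares F for dropping all diagnosis
columns (df₁ = k−1, df₂ = n − p); pairwise contrasts refit on two groups
(df₁ = 1; the reported F is the squared t). The implementation solves all
positions in one vectorized least-squares call; it is checked in the test
suite against statsmodels and against a hand-rolled normal-equations
solver.

Clinical covariates exist only for patients. Entering them raw in a model
that includes HC would make them proxies for patient status; the centering
scheme therefore maps HC to 0 and each patient's value to the deviation
from their own diagnostic group's mean. Per-group means of the centered
values are 0 (to 1e-12), so the group contrasts keep their meaning while
within-group dose/duration variability is still adjusted for. The rule is
applied automatically: centering on for the omnibus model and any contrast
involving HC, off (raw values) for patient-vs-patient contrasts. Missing
patient values are imputed at their own group mean (centered 0, or the raw
group mean when centering is off), preserving the matched design rather
than dropping subjects.

Each comparison's `n_points` raw p-values form one multiple-testing
family, corrected with the Benjamini–Hochberg step-up procedure at
q = 0.05 (adjusted p-values are reported; a Benjamini–Yekutieli option
exists but is off by default, since neighbouring positions are positively
dependent and BH remains valid under that dependence). Post-hoc contrasts
are gated on the omnibus family containing at least one FDR-significant
position; the gate is configurable.

Covariate-adjusted group means are least-squares means: model predictions
per group with every covariate column fixed at its sample mean (centered
clinical covariates at 0). Power for the omnibus test uses the noncentral
F distribution with noncentrality λ = f²·N (Cohen's f convention) and
error df reduced by the covariate count; f = 0 returns exactly α.

One-way ANOVA from per-group summary statistics (means, SDs, group sizes)
is provided for checking published demographic tables; it pools the
printed SDs into the within-group mean square and reproduces the raw-data
omnibus F exactly when no covariates are modelled.

## Synthetic cohorts

The generator's role is to exercise every pipeline stage with known ground
truth, not to be anatomically faithful. The centerline is a circular arc
(span 70 mm, apex height 16 mm) — deliberately low, uniform curvature —
and the boundaries are normal offsets by the half-thickness

  h(t) = scale(t) · effect(t) · template(t),

where `template` is a smooth baseline (base 2.3 mm plus Gaussian genu and
splenium bulges, a body dip, and tapered tips; overall amplitude scales
the profile linearly) and `effect` is a per-group multiplicative thinning
map. Boundaries are emitted as 120-vertex polylines with isotropic
Gaussian tracing noise (SD 0.10 mm per coordinate) added to every vertex;
draws that produce degenerate polylines are retried a bounded number of
times.

Template and arch parameters were calibrated once, at design time, so that
the measurement pipeline run on noise-free output recovers the injected
half-thickness within 2% of the template mean at interior positions. The
residual error comes from differential arc-length warping: offsetting by a
position-dependent thickness makes the two boundaries locally longer where
|dh/ds| or thickness×curvature is large, which shifts the equidistant
index correspondence. Keeping bump slopes gentle and curvature low bounds
the effect. A corollary worth knowing: *focal* injected thinning shortens
a boundary and slightly shifts correspondences everywhere downstream, so
very small systematic group differences can appear at positions outside
the injected window (e.g. in the spared middle body of the global-thinning
preset). This mirrors a genuine property of relative-arc-length
correspondence, not a bug in the statistics.

Inter-subject variability has two components, chosen to make the
mass-univariate family behave realistically:

- a global size factor exp(0.08 · z_TIV) coupled to the subject's
  simulated intracranial volume — the head-size effect that the TIV
  covariate is designed to absorb;
- a smooth regional modulation of log-thickness: 4 random-phase cosine
  modes along the midline with pointwise SD 0.10. Regional (rather than
  global) subject variation keeps distant positions only weakly
  correlated; a single global multiplier would make all 100 position
  tests rise and fall together, turning null significance maps into
  all-or-nothing events.

Cohort structure mimics a matched case-control design: one age vector
(normal, mean 40.5, SD 11, truncated to 18–65) shared across groups
subject-for-subject (exact matching), sex alternating M/F within group
(15/15 at n = 30), group-specific education/illness-duration/CPZ
distributions loosely matching a typical adult psychiatric cohort, and
absent clinical covariates for HC. Covariates carry no structural effect
on thickness except the TIV size coupling, so covariate adjustment is
exercised without introducing confounds. The global seed expands into
independent per-subject substreams, making cohorts reproducible and
byte-stable under serialization.

Effect presets (1-based position windows, configurable): `null` (no
effects), `ocd_global` (factor 0.8 everywhere except positions 40–60),
`sz_focal` (0.8 at rostrum 1–8 and isthmus 70–80), `paper_like` (both
combined; BD/MDD at 1.0). The 0.8 factor and the window bounds are
generator choices for test power; no published effect sizes exist for
these maps.

What passing tests do *not* show about real data: real tracings have
rater-specific, spatially correlated error rather than iid vertex noise;
real anatomy varies in shape (arch geometry, relative bulge positions) and
not only in thickness; and real covariates correlate with diagnosis and
with anatomy in ways the generator deliberately omits. Recovery rates on
synthetic cohorts are therefore an upper bound on what identical settings
would achieve on clinical data.

## Problem sizes used in validation

The shipped validation suite runs five-group cohorts of 30 subjects per
group (150 contour pairs, 100 positions); injected-effect recovery
averages 10 simulation seeds; the type-I calibration pools 2,500
position-tests of iid-normal null data on a realistic design; Monte-Carlo
power verification uses 200,000 one-way ANOVA replicates. These sizes make
every Monte-Carlo band used in testing (3 binomial SEs, ±0.01 for power)
comfortably tight while keeping the whole suite in well under a minute of
compute for the statistical parts.

## Known limitations

- The single-CDV-per-position convention ties thickness to the pointwise
  midline; profiles are not comparable across the two midline modes.
- Anterior-first orientation relies on the coordinate convention; traces
  in other conventions must be converted on import.
- The generator does not model tracing-error correlation, medication
  effects on anatomy, or missing clinical covariates (the analysis
  handles missingness; the simulator simply does not produce it).
- `anova_from_summary` assumes the printed SDs are per-group sample SDs
  (ddof = 1); tables printing SEs or pooled SDs will not reproduce.
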