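# Methods

This note documents the measurement model, the numerical choices, and what
the synthetic ground-truth material does and does not establish.

## Densitometry model

A cuticle cross-section in a TEM micrograph is described by three traced
polylines in image coordinates (x right, y down, origin at the top-left
pixel center, sub-pixel positions allowed): the inner primary-wall
boundary, the primary-wall/cuticle interface, and the cuticle outer edge,
plus an extracellular background polygon on the same image. All physical
lengths are nanometres; the single nm/pixel calibration is supplied by the
user (TEM rasters do not carry it) and is converted exactly once, at load.

The measured quantity is optical density,

    OD(t) = log10( I_bg / I(t) ),

a dimensionless proxy for local electron density: the darker the stained
material relative to the extracellular background `I_bg` of the *same*
image, the higher the OD. Because OD is a ratio, it is exactly invariant to
any global linear gain of the detector — multiplying an image and its
background region by any c > 0 leaves every profile unchanged (this is a
tested property).

Pipeline stages and their parameters:

| stage | parameter | default | rationale |
|---|---|---|---|
| blur | Gaussian sigma | 1.5 px | standard pre-measurement noise suppression at this magnification; "radius" is read as sigma, the common imaging-software convention |
| line placement | interface arc spacing | 200 nm | systematic coverage of the wall without operator choice of regions |
| extraction | sampling step | 1 px | after a 1.5 px blur the image contains no information above the pixel rate |
| OD | intensity floor | 1 unit | bounds OD at zero-valued pixels; negligible after blurring |
| resampling | spline | cubic, not-a-knot | reproduces the original MATLAB `spline` semantics; interpolating, so positions 0/100 anchor the raw endpoint values exactly |
| averaging | SEM | sd(n−1)/√n | standard definition |

Line geometry: the interface is resampled at 0.5 px arc steps; tangents are
central differences on the resampled polyline; normals are the tangents
rotated 90° toward the side named by the trace's orientation flag, with the
rotation sign fixed globally from the mean normal so that a curved
interface keeps a continuous normal field. Each line ends at its first
crossing of the outer-edge polyline. Lines that miss the outer edge,
re-cross the interface, or exceed 3× the median line length are skipped and
counted in the per-image report — broken geometry is excluded rather than
truncated, mirroring manual curation. Profiles with fewer than 4 raw
samples fall back to linear interpolation (a cubic spline is not defined on
2–3 points).

## Statistics

Two cohorts are compared position by position on the normalized 0–100
coordinate: at each position, the per-line OD values of each cohort form a
sample, and the two-sample Kolmogorov–Smirnov statistic
`D = sup_x |ECDF_A − ECDF_B|` is computed by a direct sweep over all pooled
sample points. The p-value uses the asymptotic Kolmogorov distribution at
`λ = (√n_e + 0.12 + 0.11/√n_e)·D`, `n_e = n_A n_B/(n_A+n_B)` — the
classical finite-sample argument correction used by the common KS-test
implementations; an exact small-sample method is selected automatically
when either side has ≤ 10 observations. Raw p-values are reported against a
fixed threshold (default 10⁻²) with no multiplicity correction, matching
how per-position profile comparisons are conventionally plotted; a
Benjamini–Hochberg option (`correction="bh"`) is provided for analyses that
need a multiplicity-controlled detection set. Note the interpretation: the
per-position samples are the individual line profiles, since a
distributional test is undefined on two already-averaged values.

Group-mean comparisons use Student's t-test (pooled variance; Welch
optional). Normality of each group is checked first by a one-sample KS test
against a normal with the group's estimated mean and sd; failure raises a
warning but does not gate the t-test, since no decision rule on failure is
part of the protocol being reproduced.

Width morphometry measures, per micrograph, the perpendicular
interface→outer-edge and interface→inner-wall distances at two interior
arc fractions (default 1/3 and 2/3 — symmetric positions that avoid end
effects) and averages them; relative thickness is computed per image and
then averaged (mean of ratios, not ratio of means). Cell areas use the
shoelace formula on continuous polygon coordinates, scaled by
(nm/px / 1000)²; stain scoring is mean blue dominance
`(B − (R+G)/2) / intensity_max` over the embryo mask — raw blue is high in
white pixels and therefore not monotone in staining, blue dominance is.

## Synthetic scenes

The generator renders, from outside in: extracellular background at a known
intensity; a cuticle band of known width whose intensity at normalized
depth s is `I_bg·10^(−od(s))` for a known template `od`; a primary-wall
band; a cell interior. Band boundaries are anti-aliased over one pixel.
Noise is additive Gaussian on intensity, clipped to the bit-depth range —
the simplest model that exercises the log-ratio transform. Traces are
placed exactly on the true boundaries, so geometric and densitometric
errors can be attributed unambiguously.

Defaults are the wild-type-like study conditions: 315 nm cuticle, primary
wall sized for a 34% width ratio, 8-bit intensities with background 200,
noise sd 10 (5% of background), 5 nm/px. Cohorts jitter the band geometry
by ±5% per image but share the OD template, so a cohort has a single
well-defined profile ground truth; the 0–100 normalization makes per-line
OD samples invariant to the width jitter, which keeps per-position samples
i.i.d. given noise — the property the KS type-I calibration checks assume.

Two deliberate continuity choices protect the band edges from blur
artifacts. The primary-wall intensity equals the cuticle intensity at the
interface (`I_bg·10^(−od(0))`), and the default template has od(100) = 0
with zero slope at both ends (quintic-smoothstep base plus a sin² bump,
peak OD 0.6 mid-cuticle, OD 0.3 at the interface). A template that steps or
kinks at a band edge is smeared by the 1.5 px pre-blur into the outermost
~15 positions of the normalized profile (an 0.01–0.2 OD artifact depending
on the step size); with C¹-continuous scenes the pipeline recovers the
template to ≤ 0.01 OD everywhere, which is the tested fidelity bound. Real
cuticle edges are likewise diffuse at this scale. Flat (discontinuous)
templates remain available for closed-form checks; their recovery guarantee
holds only away from the edges.

Defect modes:

* `cavernous` — Poisson-count axis-aligned elliptical inclusions inside the
  band, intensity pulled a fixed fraction toward background; strictly
  lowers mean cuticle OD.
* `near_interface_shift` — OD mass moved toward position 0: a Gaussian
  bump (+0.15 OD, scale 12 positions) at the interface and a small broad
  decrease (5·10⁻⁴ OD, ramped over positions 60–100) toward the outer
  edge. The decrease magnitude is a design point: it keeps the noise-free
  mean-OD ordering (higher near 0, lower on 70–100) while sitting below
  the n = 200 per-position KS detection threshold (~3·10⁻³ OD at default
  noise), so the detectable signature of the defect is confined to the
  wall-proximal band — the qualitative phenotype being emulated.

Cell fields place random star polygons (evenly spaced, jittered vertex
angles) on a jittered grid — non-overlap by construction — rescaled to
exactly known target areas; bright circular "vacuole" blobs cover a
requested fraction of each cell. Stain images mix a noisy gray embryo body
with pure blue so the expected blue-dominance score equals the requested
level.

What the synthetic material does *not* model: TEM image formation (no
point-spread function, no section-thickness or staining-gradient effects),
curvature of real cell walls beyond a single circular-arc mode, correlated
detector noise, or operator tracing error. Passing the recovery tests
therefore demonstrates the correctness of the measurement code under known
conditions, not the biological accuracy of any particular template.

## Problem sizes and determinism

The shipped checks use cohorts of 20–39 images (260–520 lines) for
recovery tests and 200 profiles per side for the statistical tests, with
50 replicate pairs for the type-I calibration — sizes at which the
quantities under test are stable while a full run stays within a couple of
minutes on one CPU. All randomness flows through explicit integer seeds
(cohorts derive per-image seeds from a base seed via `SeedSequence`), and
identical parameters plus seed give bit-identical images across runs.

## Known limitations

* The orientation flag is a single global side declaration; traces that
  wrap more than ~180° would need to be split.
* Sampling lines are independent; no regularisation couples neighbouring
  lines, so extremely noisy traces can produce crossing lines (these are
  skipped, not repaired).
* The exact KS method is only engaged for very small samples; for moderate
  n the corrected asymptotic p is slightly conservative, which the type-I
  calibration test quantifies (observed per-position rejection ≈ 0.008 at
  α = 0.01, n = 200).
* Stain scoring presumes white-balanced RGB input; it is invariant to
  pixels outside the mask but not to colour casts inside it.
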