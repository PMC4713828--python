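# Methods

## Measurement model

A B-scan is a grayscale grid (rows = axial depth, columns = lateral
position) with anisotropic physical scales, `lateral_scale` and
`axial_scale` in µm/px, supplied as metadata. Layer boundaries arrive as
sparse polylines (the natural export of manual segmentation tools) and are
linearly interpolated to one sub-pixel row per column; columns outside a
polyline's x-extent are undefined. Coordinates are 0-based with row 0 at
the vitreous side; intervals are half-open.

The subfoveal choroidal ROI is the set of pixels in a window of
`round(width_um / lateral_scale)` columns centred at the fovea (floor(w/2)
columns to the left, the remainder right — deterministic, centre bias
≤ 1 px) whose rows satisfy `RPE_outer(c) < r ≤ CSJ(c)`. The boundary-pixel
ownership rule (a boundary row belongs to the layer beneath it) is a
convention; it makes the retina/RPE/choroid bands tile the ILM→CSJ column
exactly, which the tests assert. The fovea is the column of minimal
ILM→inner-RPE thickness (lowest index on ties), unless the boundary file
pins `fovea_x` explicitly.

Areas use the anisotropic pixel area `lateral_scale × axial_scale`:
B-scan pixels are not square, and an isotropic (lateral-only) conversion
would bias areas by the aspect ratio. CVI and LA/SA are computed from raw
pixel counts, so they are exactly invariant to the scale factors.

## Binarization

The chain is: 8-bit conversion (16-bit input min–max rescaled, rounded
half-up; 8-bit passed through), optional signed brightness offset clamped
to [0, 255] (default 0 — the magnitude used in manual protocols is
unreported, so it is exposed rather than guessed), auto local threshold,
strict-less partition (pixel < T → luminal; equality → stromal, so
constant regions are conservatively stromal).

Thresholds:

* **Niblack** (default): `T = μ_w + k·σ_w` over a `(2·radius+1)²` window,
  radius 15 px, k = 0.2 — the de-facto defaults of the ImageJ Auto Local
  Threshold plugin whose lineage this follows. Window statistics are
  computed from int64 integral images over a symmetric (reflection) pad.
  Because sums of 8-bit values and squares are exact in int64, the
  computed thresholds are bit-identical to a brute-force per-window loop;
  the test suite and the acceptance script both verify exact equality.
  The in-package implementation exists because common library variants use
  the opposite sign convention (`μ − k·σ`) and floating-point filters,
  which would break both the polarity and the exactness guarantee.
* **Phansalkar**: `T = μ·(1 + p·e^{−q·μ/255} + k·(σ/R − 1))`, p = 2,
  q = 10, R = 0.5·255 — the standard parameterization transplanted to the
  8-bit scale.
* **Otsu**, global (over ROI pixels) or local (rank filter). Otsu on
  integer data returns the maximum of the dark class; 0.5 is added so the
  threshold sits strictly between the classes and the strict-less rule
  assigns the dark class to lumen. On a noiseless two-level phantom this
  makes global-Otsu recovery of the ground-truth lumen mask exact.

Edge handling is reflection padding, avoiding threshold bias at borders.
No despeckling is applied before thresholding; denoising is out of scope.

## Layer metrics

Per-layer thickness is `(bottom − top) × axial_scale` per column; volume
integrates per-scan cross-sectional areas (`Σ thickness × lateral_scale`)
across the raster with the trapezoidal rule at the user-supplied
inter-scan spacing (the reading-centre software this emulates does not
publish its interpolation rule; trapezoidal is the parsimonious choice).
The degree-to-µm conversion of a 20°×15° raster depends on axial length,
so spacing is required input; the test fixtures use 625 µm for 7 scans as
an arbitrary documented value. Intensity is the band's mean 8-bit value
divided by 255, landing on a 0–1 reflectivity scale; the reference
software's exact intensity definition is unpublished, so intensities are
comparable only qualitatively.

## Phantoms

A phantom stacks vitreous (level 15), retina (90) under an ILM with a
Gaussian foveal pit, RPE (220), a choroidal band of stroma (180) with dark
elliptical lumens (40), and sclera (120), at Spectralis-like scales
(11.6 × 3.87 µm/px, band ≈ 264 µm — mid normal range). Ellipses with
semi-axes uniform in 2–5 px are placed with centres uniform over the band,
overlap allowed, until the union lumen fraction reaches the target
`f_true` (generator contract: within 0.02; typical overshoot < 0.005).
Speckle is multiplicative unit-mean gamma noise (variance 0.05 by
default) — the standard first-order surrogate for coherent-imaging
speckle, with no claim about device physics: no point-spread function,
depth attenuation or vessel shadowing. Passing recovery tests on phantoms
therefore shows the geometry/threshold/bookkeeping chain is correct under
controlled two-compartment contrast, not that Niblack parameters are
optimal on clinical scans.

Under speckle, Niblack slightly overestimates the luminal fraction
(≈ +1–4 points, larger at low `f_true`); the acceptance run quantifies the
mean absolute error (≤ 0.05 at f ∈ {0.55, 0.65, 0.75}).

Paired cohorts draw per-eye baseline fractions N(f_baseline, 0.047) — the
between-eye spread reported for uveitic eyes — and a per-eye longitudinal
change N(f_baseline − f_followup, 0.028), matching a relative change of
about 6 ± 4 % of baseline; control cohorts use 0.015 / 0.0074. Each eye
keeps its geometry (choroidal thickness drawn once, sd 8 px) across
visits; only lumen fill and speckle are redrawn, emulating re-scanning the
same eye. All randomness flows from one seed through `numpy`'s Generator;
identical seeds give bit-identical cohorts.

Problem sizes: phantoms are 320 × 240 px, recovery runs use 30 phantoms
per fraction, and the power analysis 100 replicates of 19 paired eyes —
sizes chosen so a full validation sweep completes in minutes on a laptop
while keeping Monte-Carlo error well below the tolerances tested.

## Statistics

The signed-rank test uses the drop-zeros convention (the Stata lineage):
zero differences discarded, average ranks on ties, statistic
W = min(W⁺, W⁻). For n ≤ 25 the null distribution of W⁺ is exact — a
dynamic-programming convolution over sign assignments on doubled ranks
(integers even with .5 average ranks) — and the two-sided p is
`min(1, 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w)))`; tests verify bit-level agreement
with full 2ⁿ enumeration and with an established exact implementation on
tie-free data. Above n = 25 a normal approximation with continuity
correction and the tie term `Σ(t³ − t)/48` is used.

Two-sample comparisons default to Welch's t (the equal-variance variant is
not assumed); ANOVA reports R² = SS_between/SS_total alongside F and p.
All p-values are two-sided and uncorrected for multiplicity — a deliberate
mirror of common practice in small ophthalmic cohorts, and a documented
caveat: with ~20 comparisons per battery, isolated p ≈ 0.03 results should
be read accordingly.

Degenerate inputs: all-zero differences → p = 1 with a warning; identical
samples → t = 0, p = 1; all-identical ANOVA input → F undefined, R² = 0;
zero baselines make percent change undefined (NaN) rather than infinite.

## Known limitations

* Boundaries are inputs; no automatic segmentation is provided.
* The binarization parameters used by manual ImageJ protocols
  (brightness reduction, window radius) are unreported in the literature
  this follows, so patient-level pixel-exact reproduction of published
  tables is not expected — phantom ground truth is the verification
  instrument instead.
* Sattler/Haller sublayer separation, vessel connectivity, ETDRS
  sectorization and device raw-format parsing are out of scope.
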