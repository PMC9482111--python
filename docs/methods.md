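# Methods

`fibroquant` quantifies how cultured scleral fibroblasts respond to cyclic
tensile strain: it converts intraocular pressure (IOP) into the strain a
stretch device must deliver, measures cell and nuclear morphology, scores
cytoskeletal fibre alignment and chromatin condensation from fluorescence
micrographs, and compares loading groups with assumption-gated statistics.
A seeded synthetic-micrograph generator with known ground truth exercises
the whole chain.

## Pressure-to-strain mechanics

The eye globe is idealised as a pressurised thin-walled sphere, giving the
Young-Laplace hoop stress

    sigma = p * r / (2 t)

with IOP `p`, globe radius `r` and wall thickness `t`.  Dividing by the
tissue Young's modulus yields tensile strain.  Because sclera
strain-stiffens, a modulus *range* (default 1–7 MPa for bovine sclera) maps
one pressure to a strain *band*: the stiff endpoint bounds strain from
below, the compliant endpoint from above.  Defaults follow the bovine
globe: r = 16.2 mm, t = 1.6 mm; pressures convert at 133.322 Pa/mmHg.  With
a healthy bovine IOP of 27 mmHg (3.6 kPa) the band is 0.26–1.8 %; with a
glaucomatous 60 mmHg (8 kPa) it is 0.6–4 % (reported at the conventional
one-to-two significant figures).  The 1 Hz loading frequency — the ocular
pulse rate — is carried as metadata only; no time-domain waveform is
simulated, and the well-known shortcomings of the thin-shell idealisation
(no regional thickness variation, no viscoelasticity) are accepted, not
remedied.

## Morphometry

Confocal Z-stacks are collapsed by maximum-intensity projection before any
2D measurement.  Region area is the true-pixel count of the curated mask,
reported both raw and calibrated (default 0.1 µm/px).  **Shape is reported
as the width/length ratio** of the mask's moment-equivalent ellipse
(minor/major axis from second central moments): 1 for a circle, towards 0
for an elongated cell.  This deliberately differs from the textbook ellipse
eccentricity `sqrt(1 - b²/a²)` — the ratio convention is the one whose
direction ("closer to 0 = more elongated") matches how elongation is
discussed in this field's loading experiments.  Moments were chosen over
bounding-box or Feret measures because they are rotation-invariant and
standard.  Synthetic images carry their generator ground-truth masks; for
real images an Otsu-threshold + largest-component + hole-fill fallback is
provided and explicitly flagged as heuristic.

## Fibre anisotropy

Within a region of interest, each pixel's local fibril direction is taken
perpendicular to the intensity gradient (central differences, reflective
borders, optional Gaussian pre-smoothing off by default).  The outer
products of these directions, weighted by squared gradient magnitude, are
averaged into a 2×2 nematic tensor and normalised to unit trace; the
anisotropy score is the eigenvalue gap λ₁ − λ₂ ∈ [0, 1] (0 = randomly
aligned fibres, 1 = perfectly parallel), with the leading eigenvector's
axial angle as the mean orientation.  This is the tensor score popularised
by the FibrilTool protocol for cytoskeletal images; with the λ₁ + λ₂ = 1
normalisation the alternative (λ₁−λ₂)/(λ₁+λ₂) is the same number.

Numerical choices:

* pixels whose gradient magnitude falls below 1e−6 of the in-region
  intensity range carry no orientation information and are skipped; a
  region with no usable gradient (uniform intensity) returns a flagged
  undefined-direction result scored 0;
* a 2-px band just inside the mask boundary is excluded by default
  (`exclude_rim`): the intensity step at the region outline otherwise
  contributes outline-tangent orientations that measure the region's shape
  rather than its texture — on isotropic phantoms this artefact alone
  produced anisotropy ≈ 0.17.  Passing `exclude_rim=0` restores pooling
  over every masked pixel.

The implementation is checked against a naive double-loop accumulation to
1e−10, and for rotation equivariance (value stable to ±0.02 under image
rotation; the tolerance is interpolation error) and affine intensity
invariance.

## Chromatin condensation parameter (CCP)

Condensed chromatin appears as punctate bright foci in a DNA stain, so the
amount of intensity edge inside the nucleus tracks condensation.  CCP is
the count of Sobel edge pixels divided by the nucleus pixel area.  The
implementation uses the standard 3×3 Sobel pair with reflective borders; a
pixel is an edge pixel when its gradient magnitude reaches a **relative**
threshold — default 0.15 of the maximum in-nucleus magnitude, exposed as
`--ccp-threshold` — and the 1-px rim inside the nucleus outline is excluded
so the outline itself never counts (counting it would make the ratio
size-dependent, defeating the purpose of dividing by area).  Relative
thresholding makes CCP invariant to affine intensity rescaling.  The exact
threshold used in prior per-study scripts is not public, so absolute CCP
values are comparable only within a fixed threshold; all group contrasts
here hold the threshold fixed.

Degenerate input note: on a nucleus with *no* structure but nonzero noise,
the relative threshold keys on the noise maximum and CCP becomes a noise
statistic; CCP is exactly 0 only for constant in-mask intensity.  The
tiling-invariance property (same texture tiled into a larger nucleus gives
the same CCP within ~5 %) holds up to the rim fraction, which shrinks with
nucleus size.

## Synthetic micrographs

The generator emulates single-cell fluorescence fields with known ground
truth; it is the package's test bed, not a PSF-accurate optics simulation.

* **Cell phantoms**: an elliptical cell (default semi-axes 170 × 85 px on a
  512² canvas, long axis along the imposed mean orientation) filled with
  200 anti-aliased straight fibre segments of width 2 px.  Orientations are
  axial (period π), sampled by the doubled-angle trick
  θ = vonMises(2µ, κ)/2 mod π; κ = 0 is uniform, κ = ∞ a point mass.
  Fibre lengths vary uniformly over 0.3–0.9 of the long axis and strokes
  accumulate additively (amplitude 0.35, clipped at 1): full-length chords
  composited with a per-pixel maximum were tried first and rejected because
  they saturate the cell into a structureless blob whose residual gaps bias
  the measured anisotropy.  A κ = 0 phantom measures ≈ 0.05–0.15 (the
  finite-sample floor of 200 orientations plus chord-clipping bias), κ = ∞
  ≈ 0.96.
* **Nucleus phantoms**: an ellipse (60 × 45 px) at background intensity 0.4
  carrying n bright discs of radius 3 px at twice the background
  (contrast 1.0), placed uniformly inside the ellipse shrunk by the disc
  radius.
* **Noise**: additive Gaussian (default sd 0.02 on the unit scale), clipped
  to [0, 1] and quantised to 8-bit (16-bit selectable).  Poisson shot noise
  was deliberately not modelled — Gaussian noise is sufficient for testing
  estimator behaviour and keeps the ground truth simple.
* **Z-stack mode**: an optional n-slice stack multiplies the plane by a
  Gaussian focal envelope and adds independent per-slice noise, so the
  maximum-intensity projection recovers (a dimmed copy of) the focal plane;
  it exists to exercise the projection step.

What the phantoms do **not** capture: optical blur and anisotropic PSFs,
curved or branching filaments, multi-cell crowding, intensity
inhomogeneity, or chromatin texture beyond discrete foci.  Passing tests on
phantoms therefore validate the estimators' mathematics and orderings, not
their absolute accuracy on real confocal data.

### Study-level generation

`generate_study` builds a 3-group × 3-timepoint design — unloaded /
physiological / pathological at 1 h, 6 h, 24 h, default 10 cell+nucleus
pairs per combination split round-robin over 3 wells and 3 plates — with
group effects entering through two templates:

| group × time | κ (fibres) | foci (nucleus) |
|---|---|---|
| unloaded, all | 0.5 | 15 |
| physiological 1 h / 6 h / 24 h | 4.0 / 2.5 / 0.6 | 25 / 16 / 15 |
| pathological 1 h / 6 h / 24 h | 0.5 / 0.7 / 3.5 | 60 / 58 / 22 |

i.e. a transient physiological alignment response that decays by 24 h, a
delayed pathological alignment response appearing only at 24 h, and
chromatin condensation strongly elevated early after pathological load,
relaxing towards baseline by 24 h.  Per-image parameters jitter around the
template means (log-normal σ = 0.2 on κ; rounded Gaussian, 10 % relative,
on the focus count; ±10 % on the phantom size).  The template magnitudes
are a design choice — chosen so the group orderings are unambiguous at
n = 10 per cell of the design — not a calibration to any real data set.
Everything is deterministic given (config, seed): per-image sub-seeds are
drawn from one root generator.

## Group statistics

Each (metric, timepoint) family is tested independently — mirroring
per-panel comparisons; no cross-timepoint correction is applied.  The gate:
every group must pass the Anderson-Darling normality test and the k-sample
Bartlett homogeneity test, all at α = 0.05, for the parametric branch
(one-way ANOVA, Tukey HSD pairwise).  Otherwise Kruskal-Wallis with Dunn's
rank-based pairwise z-tests (tie-corrected, Bonferroni-adjusted over the
three pairs) — Dunn is an explicit choice for the post-hoc of the
rank-based branch, since an omnibus test alone cannot localise the
difference.  Stars: * p < 0.05, ** p < 0.01, *** p < 0.001.  Note the
joint gate's composition: with four screens each at α = 0.05 the parametric
branch is taken ≈ 81–86 % of the time even for perfectly normal,
homoscedastic data; the full gated pipeline still holds the omnibus type-I
error at ≈ 5 % because both branches are level-α tests.

Degenerate inputs: groups with n < 3 or zero variance force the
nonparametric branch with a warning; an all-identical table short-circuits
to p = 1 with no significant pairs.

Box-whisker summaries use linear-interpolation (type-7) quantiles —
documented because Q1/Q3 conventions differ across software — with
whiskers at the most extreme observations inside the 1.5 IQR Tukey fences
and points beyond listed as outliers; means and SDs accompany the order
statistics so either median ± SD or box conventions can be rendered.

## Pipeline

Stages (simulate → project → measure → compare) communicate via tidy CSVs
on disk; a JSON manifest records the configuration hash, package version,
seed, per-stage row counts, per-image warnings (missing files are skipped
and counted, never silently fatal) and a SHA-256 checksum of every output.
Re-running with the same configuration and seed reproduces byte-identical
outputs.

## Problem sizes used in the test suite

Unit tests run on ≤ 256² images and ≤ 2 images per design cell.  The
oracle-equivalence checks use ≤ 32² arrays (where double loops are exact
and fast).  The type-I-error simulation uses 1000 replicates of three
n = 30 normal samples; the significance-pattern recovery study runs the
full default design (n = 10 per group per timepoint, 180 images per run)
over 50 seeds.  These sizes give Monte-Carlo error comfortably inside the
asserted tolerances while keeping the suite practical to run routinely.

## Known limitations

* Absolute areas, anisotropy values and CCPs on real confocal data depend
  on acquisition calibration, ROI practice and threshold choices that no
  synthetic study can pin down; the phantom tests validate orderings and
  invariances, not real-data absolute values.
* The thin-sphere strain model ignores regional wall-thickness variation
  and viscoelasticity.
* Wells and plates are carried as metadata but pooled in the statistics
  (no mixed-effects modelling of the nesting).
* The Otsu fallback segmentation is a convenience, not a validated
  segmentation method.
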