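# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic generator does and does not
emulate, and the known limitations.

## Gray-level ↔ calcium calibration

qBEI gray values are proportional to the mean atomic number of the imaged
volume and, over the physiological range of bone mineral, to the calcium
weight fraction. The map is affine, `ca = slope·gl + intercept`, fitted
exactly (not least-squares) through two anchors. The instrument convention
this package follows pins the bone/void segmentation threshold at gray
level 55 ↔ 5.2 wt% Ca; the second default anchor places the organic
(osteoid) phase at gray level 25 ↔ 0.0 wt% Ca, consistent with common
qBEI practice of setting the organic-phase signal near gray level 25.
Both anchors are configurable, and the calibration is serialized with its
anchors into every output. A quadratic term is deliberately not modeled:
the backscattered signal is linear in this range and two standards
(carbon, aluminum) determine exactly two parameters.

The raw affine value may be negative below the organic anchor; the
`clip_negative` option floors reported Ca at zero while the raw map keeps
the exact inverse property `ca_to_gl(gl_to_ca(x)) = x` on [0, 255].
Gray levels are treated as integer bin centers; images are converted
per-pixel with no smoothing.

## BMDD

Bone pixels are those with gl ≥ 55 (inclusive on the bone side); pores,
marrow and osteoid fall below. The Ca histogram uses uniform bins anchored
at 0 wt% (default width 0.17 wt% Ca ≈ one gray level under the default
calibration) and is normalized to percent of contributing pixels, so mass
partitions exactly: CaLow + CaHigh + (between) = 100.

* **CaMean** — frequency-weighted mean of the raw bin centers. It agrees
  with the direct masked pixel mean to within half a bin by construction.
* **CaPeak / CaWidth** — evaluated on a boxcar-smoothed histogram
  (default window 3 bins, recorded in the result metadata) to stabilize
  the mode on noisy data. CaWidth is the full width at half maximum with
  linear interpolation between bin centers at half-peak height; the
  distribution is treated as zero outside the histogram support, so with
  smoothing disabled a single occupied bin has width exactly one bin.
  Equal smoothed maxima tie-break to the lowest Ca and set a flag.
* **CaLow / CaHigh** — strict comparisons of bin centers against the cuts
  17.68 and 25.30 wt% Ca (5th/95th percentile of the adult trabecular
  reference distribution; overridable for other reference populations).
  Note that 17.68 lies exactly on the default bin grid, so the bin-center
  rule makes CaLow the cumulative mass up to the cut; in 8-bit images the
  effective boundary shifts to the gray-level quantization midpoint, a
  sub-bin effect the test oracles model explicitly.

Compartment comparisons report `100·(cortical − trabecular)/trabecular`
per parameter to one decimal; a zero trabecular value yields NaN rather
than an exception. Z-scores are reported to two decimals. Both use
half-away-from-zero rounding (the convention of clinical tables), with
binary-float noise absorbed nine digits below the reported precision.
Z-scores are computed for the trabecular compartment only: the bundled
reference is a trabecular reference and no cortical normative
distribution is bundled. Whether a dilated border zone around pores should
be excluded before histogramming is not settled; none is applied, and the
choice is visible in the output metadata.

## OLS morphometry

Pores are connected components of pixels with gl < 55 (strict), so the
bone/pore partition is exhaustive against the BMDD bone definition.
Default connectivity is 8 for pores (avoiding fragmentation of thin
lacunae); 4 is available. Geometry comes from scikit-image region
properties: area as pixel count × pixel area, perimeter from the contour
approximation, and ellipse-equivalent major/minor axes from second-order
central moments, making the aspect ratio rotation-invariant (a bounding
box would not be). Degenerate regions are handled explicitly: a single
pixel has aspect ratio 1, a one-pixel-wide line is infinitely elongated.

Filtering: regions with area > 200 μm² (cutoff inclusive on the lacuna
side) are vascular canals, Haversian channels or cracks and are excluded;
border-touching regions have censored geometry and are excluded by
default but counted separately. A region that is both over-size and
border-touching counts as over-size. No minimum-area cutoff is applied by
default (a config option exists for noise suppression).

Bone area — the denominator of lacunar density and porosity — is the
mineralized area plus the retained lacuna pixels: lacunae are part of the
bone, larger pores are not. Porosity is lacunar area per bone area (not
per total tissue area), and is labeled as such in outputs. No normative
lacunar reference is bundled, so OLS results are reported as absolute
statistics without Z-scores.

## Histomorphometry

Inputs are a class raster (void/marrow, mineralized, osteoid; indexed
8-bit values) with physical pixel size, and a surface annotation: bone
surface polylines partitioned into QUIESCENT / OSTEOID / OSTEOBLAST /
ERODED / OSTEOCLAST states, plus tetracycline label traces (double, with
a mean inter-label distance, or single). Osteoid surface includes the
osteoblast-covered surface and eroded surface includes the
osteoclast-covered surface, the standard ASBMR readings of an exhaustive
state partition. Annotation polylines more than 2 px from the bone
boundary raise an alignment error (checked against a distance transform
of the boundary).

Derived parameters follow the ASBMR definitions given in the README. The
conventions that needed a decision:

* **Label interval** defaults to 15 days — midpoint-to-midpoint of the
  standard two 3-day tetracycline courses separated by a 12-day gap. It
  is configurable and recorded in outputs.
* **O.Th** is the directly measured seam width when the annotation
  carries width measurements, and OV/OS otherwise. No π/4
  section-obliquity correction is applied, which keeps the identity
  `Mlt = O.Th / Aj.Ar` exact in the reported numbers.
* **Tb.Th** uses the plate model, `2·BV/BS`, and `Tb.N =
  (BV/TV)/Tb.Th`. Laboratories that measure trabecular thickness
  directly will not reproduce the plate-model value; it is a model
  estimate, not a measurement.
* **Ct.Po** is void area within the cortical compartment over cortical
  compartment area; **Ct.Wi** is the mean per-column cortical extent.
* Parameters are stored unrounded; rounding to the table precision
  happens only in the report layer.

Zero denominators set flags (`undefined: …`) instead of raising, with one
exception: a nonzero mineralizing surface with zero osteoid surface is
physically contradictory and raises.

Z-scoring matches reference rows by parameter name, sex and age band
(`age_lo ≤ age ≤ age_hi`); an absent band raises an error listing the
available bands, while individual parameters the reference table leaves
blank (e.g. cortical porosity) are carried through unscored. |z| > 2 is
flagged, threshold configurable.

## Synthetic scenes

The generator's purpose is measurement validation, not biological or
physical realism. It emulates the *structure* the analyses assume — gray
levels linear in Ca, compartmentalized mineralization, elliptical lacuna
sections, seams/labels along straight surfaces — and records every
generating parameter.

qBEI fields: a solid cortical band (left fraction of columns, default
0.25) and trabecular struts obtained by thresholding Gaussian-smoothed
white noise (correlation length 12 px) at the quantile matching the
target bone-volume fraction (0.25). Enclosed marrow pockets are filled so
every sub-threshold pore in the emitted raster is a planted lacuna. Ca is
drawn i.i.d. per bone pixel from a per-compartment mixture of normals —
defaults: trabecular N(21.0, 2.12²) (CaWidth ≈ 5.0), cortical
N(22.4, 1.84²), reproducing the disease-range condition of a poorly
mineralized, heterogeneous matrix with a more mineralized cortex. Lacunae
are stamped as rotated ellipses with lognormal areas (mean 45 μm²,
log-SD 0.4), clamped-normal aspect ratios (mean 2.0, SD 0.5, ≥ 1.05) and
uniform orientation, placed by rejection sampling at 220/mm² of bone with
a one-pixel mineralized rim (so they never merge with the marrow
component) and ≥ 2 px separation; infeasible densities raise a packing
error. The sensor model is additive Gaussian gray-level noise (SD 2) and
8-bit quantization. Four independent random sub-streams (geometry,
mineralization, lacunae, noise) derive from the scene seed, so toggling
noise does not reshuffle geometry, and identical seeds give byte-identical
rasters.

Histomorphometry scenes: horizontal struts (140 μm thick, 560 μm pitch)
with osteoid seams (4.1 μm wide over 50% of the surface, 15% of that
osteoblast-covered), an eroded fraction of 8% plus 0.5%
osteoclast-covered, and double labels over 3.8% of the surface with a
10.5 μm inter-label distance (MAR 0.7 μm/day at the 15-day interval) —
the disease-range dynamic condition. The recorded ground-truth
primitives are computed from the same rasterized geometry the scene
emits, so measurement recovery is exact up to rasterization of the seam
columns.

What the generator does **not** emulate — and hence what passing recovery
tests do not show about real data: spatially correlated mineralization
(osteons, lamellae, gradients around lacunae), realistic trabecular
architecture, partial-volume effects at pore boundaries, detector drift
or shading, label blurring in woven bone, and stain-dependent class
errors in section rasters. Recovery tolerances (CaMean 2%, CaWidth 8%,
lacunar density and mean area 5%, mean aspect ratio 0.05 absolute,
checked over ten seeds at 1024² px) reflect quantization and sampling
effects only.

Scene sizes in the test suite (256²–1024² px) were chosen as the smallest
fields at which estimator noise is comfortably inside those tolerances
— e.g. ≈ 80 lacunae per 1024² field at 0.88 μm/px, enough for a stable
mean aspect ratio.

## Known limitations

* The calibration's second anchor (GL 25 ↔ 0.0 wt%) is a documented
  convention, not an instrument-specific fact; laboratories should fit
  their own anchors.
* The plate-model Tb.Th/Tb.N route differs from direct thickness
  measurement; do not compare across routes.
* 2D OLS statistics are section statistics; no stereological correction
  to 3D lacunar volume or number is attempted.
* The bundled normative tables are transcriptions of published reference
  columns for two age bands of adult males; analyses outside those bands
  need user-supplied references.
* The exact divisor behind a published MAR value is generally not
  recoverable from a table; the 15-day default is the schedule midpoint
  and configurable.
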