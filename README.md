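# bonematrix

Quantitative analysis of bone tissue at the material level: calibrated
backscattered-electron imaging (qBEI), osteocyte lacuna morphometry, and
ASBMR bone histomorphometry, with Z-score standardization against normative
reference tables. The package is aimed at bone researchers who work with
transiliac biopsy sections — e.g. in rare skeletal disorders and metabolic
bone disease — and at method developers who need every measurement stage
testable against exact ground truth.

## What it computes

**Calibration.** qBEI gray levels scale linearly with local calcium
content. A two-point affine map (default: gray level 25 ↔ 0.0 wt% Ca for
the organic phase, 55 ↔ 5.2 wt% Ca) converts 8-bit rasters to calcium
weight-percent; gray level 55 doubles as the bone/pore threshold.

**BMDD.** The bone mineralization density distribution is the
area-frequency histogram of Ca over mineralized pixels, summarized by
CaMean (weighted mean), CaPeak (mode), CaWidth (full width at half
maximum), and the tail fractions CaLow (< 17.68 wt% Ca) and CaHigh
(> 25.30 wt% Ca) — the 5th/95th percentiles of the adult trabecular
reference distribution. Cortical and trabecular compartments are compared
as percent differences, and trabecular parameters as Z-scores
`z = (measured − reference mean) / reference SD` against the bundled
normative table.

**Osteocyte lacunae sections (OLS).** Connected components of
sub-threshold pixels in high-resolution scans (0.88 μm/px) are measured by
second-order moments (ellipse-equivalent axes, rotation-invariant aspect
ratio). Regions over 200 μm² are vascular/Haversian space and excluded;
the rest yield lacunar density (/mm² bone), mean area/perimeter/aspect
ratio, and lacunar porosity.

**Histomorphometry.** From a class-coded section raster
(void/mineralized/osteoid) plus a surface annotation (remodeling-state
polylines and tetracycline label traces), the module measures the raw
primitives and derives the standard parameters, including the dynamic
chain

    MS/BS = (dL.Pm + sL.Pm/2) / BS          MAR  = Ir.L.Wi / label interval
    Aj.Ar = MAR · (MS/BS)/(OS/BS)           Mlt  = O.Th / Aj.Ar
    BFR/BS = MAR · (MS/BS/100) · 365

with the identities `Mlt · Aj.Ar = O.Th` and the BFR relation holding
exactly before rounding. Parameters are standardized against an age- and
sex-banded normative table; |z| > 2 is flagged.

**Synthetic scenes.** A seeded generator emits qBEI-like rasters (cortical
band + trabecular struts, per-compartment Ca mixtures, stamped elliptical
lacunae, Gaussian sensor noise, 8-bit quantization) and histomorphometry
scenes (struts, osteoid seams, surface states, label traces) together with
their exact generating parameters, so recovery of every quantity is
testable without patient data.

## Worked example

```python
import bonematrix as bm
from bonematrix.bmdd import analyze_image as bmdd_analyze, bmdd_zscores, compare_compartments
from bonematrix.ols import analyze_image as ols_analyze
from bonematrix.datasets import load_bmdd_reference

scene = bm.generate_qbei(bm.SyntheticSpec(seed=7, shape=(1024, 1024)))
cal = bm.default_map()

hist, trab = bmdd_analyze(scene.image, cal, scene.compartments == 2)
_, cort = bmdd_analyze(scene.image, cal, scene.compartments == 1)
print({k: round(v, 2) for k, v in trab.as_dict().items()})
print(compare_compartments(cort, trab))
print({r.parameter: r.z2 for r in bmdd_zscores(trab, load_bmdd_reference())})

summary, lacunae, excluded = ols_analyze(scene.image)
print(summary.n_lacunae, round(summary.ols_density_per_mm2, 1),
      round(summary.mean_area_um2, 1), round(summary.mean_aspect_ratio, 2))
```

prints

```
{'CaMean': 21.02, 'CaPeak': 20.83, 'CaWidth': 4.96, 'CaLow': 5.67, 'CaHigh': 2.06}
{'CaMean': 6.6, 'CaPeak': 6.5, 'CaWidth': -12.1, 'CaLow': -91.0, 'CaHigh': 165.1}
{'CaMean': -2.63, 'CaPeak': -5.42, 'CaWidth': 4.73, 'CaLow': 0.47, 'CaHigh': -1.05}
80 220.7 46.2 2.06
```

The trabecular field was generated with CaMean 21.0 wt%, CaWidth 4.99 wt%
and 80 planted lacunae at 220.7/mm² — the pipeline recovers CaMean to
0.1%, CaWidth to 1%, and the lacunar census exactly. The percent
differences show the cortical compartment more mineralized than the
trabecular one (CaMean +6.6%), and the Z-scores place this synthetic
"patient" well below the healthy trabecular reference (CaMean −2.63 SD)
with markedly increased heterogeneity (CaWidth +4.73 SD).

The same analyses are available from the shell:

```sh
bonematrix calibrate --anchor 25:0.0 --anchor 55:5.2 -o calib.json
bonematrix simulate --seed 7 -o scene/
bonematrix bmdd scene/qbei.tif --calib calib.json -o out/
bonematrix ols scene/qbei.tif --pixel-size 0.88 -o out/
bonematrix histo --primitives prim.csv --sex M --age 61 -o out/
```

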