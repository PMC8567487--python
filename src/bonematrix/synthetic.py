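"""Synthetic qBEI rasters and histomorphometry scenes with known ground truth.

Patient biopsy images are not distributable, so every pipeline stage is
validated against simulated data whose generating parameters are recorded
exactly. The generator emulates the *measurement geometry* of the real
modalities, not their physics:

* **qBEI fields** — a cortical band plus trabecular struts (Gaussian-smoothed
  white noise thresholded at the quantile matching the target bone-volume
  fraction), per-compartment Ca values drawn from a mixture of normals,
  mapped to gray levels through the calibration, degraded by additive
  Gaussian sensor noise and 8-bit quantization. Osteocyte lacunae are
  stamped as non-overlapping ellipses (rejection sampling, 2 px minimum
  separation) filled at a sub-threshold gray level.
* **Histomorphometry scenes** — horizontal trabecular struts with osteoid
  seams over a set fraction of the surface, a surface-state partition, and
  tetracycline label traces with a planted inter-label distance.

Default parameters reproduce the disease-range conditions the package is
meant to analyze: trabecular CaMean ≈ 21 wt%, CaWidth ≈ 5 wt% (broad,
poorly mineralized matrix), a more mineralized cortex, lacunar density
≈ 220/mm² with mean section area ≈ 45 μm², osteoid on half the surface
with ~4 μm seams, and sparse double labels giving MAR 0.7 μm/day at a
15-day label interval.

One pseudo-random stream per layer (geometry, mineralization, lacunae,
noise) is derived from the scene seed, so toggling sensor noise does not
reshuffle geometry. The same seed always yields byte-identical rasters.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import yaml
from scipy import ndimage

from .calibration import BONE_GL_THRESHOLD, CalibrationMap, default_map
from .errors import GeometryError, PackingError
from .histomorphometry import (
    DEFAULT_LABEL_INTERVAL,
    ClassRaster,
    HistoPrimitives,
    LabelTrace,
    SurfaceAnnotation,
    SurfaceSegment,
    SurfaceState,
    TissueClass,
)

GAUSSIAN_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


@dataclass
class MixtureModel:
    """Mixture of normals describing a compartment's Ca distribution (wt% Ca)."""

    weights: tuple[float, ...] = (1.0,)
    means: tuple[float, ...] = (21.0,)
    sds: tuple[float, ...] = (2.12,)

    def __post_init__(self) -> None:
        if not (len(self.weights) == len(self.means) == len(self.sds)):
            raise ValueError("weights, means, sds must have equal length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if any(s < 0 for s in self.sds):
            raise ValueError("mixture SDs must be non-negative")

    @property
    def true_mean(self) -> float:
        return float(np.dot(self.weights, self.means))

    @property
    def true_width(self) -> float:
        """FWHM of the mixture density (closed form for one component)."""
        if len(self.weights) == 1:
            return GAUSSIAN_FWHM_FACTOR * self.sds[0]
        x = np.linspace(min(self.means) - 6 * max(self.sds),
                        max(self.means) + 6 * max(self.sds), 20001)
        pdf = np.zeros_like(x)
        for w, m, s in zip(self.weights, self.means, self.sds):
            pdf += w * np.exp(-0.5 * ((x - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
        half = pdf.max() / 2.0
        above = np.flatnonzero(pdf >= half)
        return float(x[above[-1]] - x[above[0]])

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n, p=np.asarray(self.weights))
        return rng.normal(np.take(self.means, comp), np.take(self.sds, comp))


@dataclass
class LacunaModel:
    """Planted osteocyte-lacuna population."""

    density_per_mm2: float = 220.0
    mean_area_um2: float = 45.0  # arithmetic mean of the lognormal area law
    log_sigma: float = 0.4
    ar_mean: float = 2.0
    ar_sd: float = 0.5
    ar_min: float = 1.05
    fill_gl: int = 10
    min_separation_px: int = 2
    max_retries: int = 500


@dataclass
class OsteoidModel:
    """Osteoid seams on the planted bone surface."""

    surface_fraction: float = 0.5  # fraction of bone surface carrying a seam
    osteoblast_fraction: float = 0.15  # fraction of the seam surface with osteoblasts
    width_um: float = 4.1


@dataclass
class LabelModel:
    """Tetracycline labels on the planted surface."""

    double_fraction: float = 0.038  # of bone surface
    single_fraction: float = 0.0
    inter_label_um: float = 10.5  # -> MAR 0.7 μm/day at a 15-day interval
    interval_days: float = DEFAULT_LABEL_INTERVAL
    eroded_fraction: float = 0.08
    osteoclast_fraction: float = 0.005


@dataclass
class SyntheticSpec:
    """Everything a scene needs; same seed ⇒ bit-identical output."""

    seed: int = 0
    shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.88
    cortical_fraction: float = 0.25  # left-band width as a fraction of columns
    trab_bvtv: float = 0.25
    trab_corr_px: float = 12.0  # smoothing length of the strut noise field
    cortical_mix: MixtureModel = field(
        default_factory=lambda: MixtureModel(means=(22.4,), sds=(1.84,))
    )
    trab_mix: MixtureModel = field(default_factory=MixtureModel)
    lacunae: Optional[LacunaModel] = field(default_factory=LacunaModel)
    osteoid: OsteoidModel = field(default_factory=OsteoidModel)
    labels: Optional[LabelModel] = field(default_factory=LabelModel)
    calibration: CalibrationMap = field(default_factory=default_map)
    noise_gl_sd: float = 2.0
    background_gl: int = 5
    # histomorphometry-scene geometry
    histo_pixel_size_um: float = 2.0
    strut_thickness_um: float = 140.0
    strut_pitch_um: float = 560.0  # thickness + marrow gap -> BV/TV = 0.25

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["calibration"] = self.calibration.to_dict()
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "SyntheticSpec":
        if isinstance(source, str) and "\n" in source:
            d = yaml.safe_load(source)
        else:
            with open(source) as fh:
                d = yaml.safe_load(fh)
        for key, sub in (
            ("cortical_mix", MixtureModel),
            ("trab_mix", MixtureModel),
            ("lacunae", LacunaModel),
            ("osteoid", OsteoidModel),
            ("labels", LabelModel),
        ):
            if d.get(key) is not None:
                val = d[key]
                for tup in ("weights", "means", "sds"):
                    if tup in val:
                        val[tup] = tuple(val[tup])
                d[key] = sub(**val)
        if d.get("calibration") is not None:
            d["calibration"] = CalibrationMap.from_dict(d["calibration"])
        d["shape"] = tuple(d["shape"])
        return cls(**d)


@dataclass
class PlantedLacuna:
    """Nominal (sampled) and realized (rasterized) geometry of one lacuna."""

    center_px: tuple[float, float]  # (row, col)
    area_um2: float  # nominal
    aspect_ratio: float  # nominal
    theta: float  # orientation, radians
    n_pixels: int  # realized
    realized_area_um2: float
    compartment: str  # 'cortical' | 'trabecular'


@dataclass
class GroundTruth:
    """Exact planted values recorded alongside each emitted raster."""

    ca_mean: dict[str, float] = field(default_factory=dict)  # per compartment
    ca_width: dict[str, float] = field(default_factory=dict)
    lacunae: list[PlantedLacuna] = field(default_factory=list)
    n_lacunae: int = 0
    bone_area_mm2: float = 0.0
    lacuna_density_per_mm2: float = 0.0
    primitives: Optional[HistoPrimitives] = None

    @property
    def mean_lacuna_area_um2(self) -> float:
        return float(np.mean([l.area_um2 for l in self.lacunae])) if self.lacunae else float("nan")

    @property
    def mean_lacuna_ar(self) -> float:
        return float(np.mean([l.aspect_ratio for l in self.lacunae])) if self.lacunae else float("nan")


@dataclass
class QBEIScene:
    """A generated qBEI field: raster, compartment mask, ground truth."""

    image: np.ndarray  # uint8
    compartments: np.ndarray  # uint8: 0 none, 1 cortical, 2 trabecular
    bone_mask: np.ndarray  # bool, pre-lacuna bone pixels
    ground_truth: GroundTruth


def _trabecular_struts(
    rng: np.random.Generator, shape: tuple[int, int], corr_px: float, bvtv: float
) -> np.ndarray:
    """Thresholded smoothed white noise: a seedable strut-like bone phase."""
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=corr_px)
    cut = np.quantile(smooth, 1.0 - bvtv)
    return smooth >= cut


def _ellipse_pixels(
    center: tuple[float, float], a_px: float, b_px: float, theta: float, shape: tuple[int, int]
):
    """Row/col indices of pixel centers inside a rotated ellipse."""
    r0, c0 = center
    half = int(np.ceil(max(a_px, b_px))) + 1
    rlo, rhi = int(np.floor(r0)) - half, int(np.floor(r0)) + half + 1
    clo, chi = int(np.floor(c0)) - half, int(np.floor(c0)) + half + 1
    if rlo < 0 or clo < 0 or rhi > shape[0] or chi > shape[1]:
        return None  # would cross the image border
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    dr, dc = rr - r0, cc - c0
    u = dc * np.cos(theta) + dr * np.sin(theta)
    v = -dc * np.sin(theta) + dr * np.cos(theta)
    inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    return rr[inside], cc[inside]


def _place_lacunae(
    rng: np.random.Generator,
    model: LacunaModel,
    bone: np.ndarray,
    compartments: np.ndarray,
    pixel_size: float,
) -> tuple[np.ndarray, list[PlantedLacuna]]:
    bone_area_mm2 = bone.sum() * (pixel_size / 1000.0) ** 2
    n_target = int(round(model.density_per_mm2 * bone_area_mm2))
    occupied = np.zeros_like(bone)
    sep = ndimage.generate_binary_structure(2, 2)
    rows, cols = np.nonzero(bone)
    planted: list[PlantedLacuna] = []
    mu = np.log(model.mean_area_um2) - model.log_sigma**2 / 2.0
    for _ in range(n_target):
        for attempt in range(model.max_retries):
            area = float(rng.lognormal(mu, model.log_sigma))
            # clamped normal; the sub-1 tail is physically meaningless and rare
            ar = max(float(rng.normal(model.ar_mean, model.ar_sd)), model.ar_min)
            theta = float(rng.uniform(0, np.pi))
            a_px = np.sqrt(area * ar / np.pi) / pixel_size
            b_px = np.sqrt(area / (ar * np.pi)) / pixel_size
            k = rng.integers(len(rows))
            center = (float(rows[k]), float(cols[k]))
            px = _ellipse_pixels(center, a_px, b_px, theta, bone.shape)
            if px is None:
                continue
            rr, cc = px
            if rr.size == 0 or not bone[rr, cc].all():
                continue
            patch = np.zeros_like(bone)
            patch[rr, cc] = True
            # demand a mineralized rim: a lacuna diagonal-adjacent to marrow
            # would merge with the vascular/marrow component on segmentation
            rim = ndimage.binary_dilation(patch, sep)
            if (rim & ~bone).any():
                continue
            # keep components disjoint: dilate the candidate by the minimum
            # separation and test against already-placed lacunae
            grown = ndimage.binary_dilation(rim, sep, iterations=model.min_separation_px - 1) if model.min_separation_px > 1 else rim
            if (grown & occupied).any():
                continue
            occupied |= patch
            comp = "cortical" if compartments[int(center[0]), int(center[1])] == 1 else "trabecular"
            planted.append(
                PlantedLacuna(
                    center_px=center,
                    area_um2=area,
                    aspect_ratio=ar,
                    theta=theta,
                    n_pixels=int(rr.size),
                    realized_area_um2=rr.size * pixel_size**2,
                    compartment=comp,
                )
            )
            break
        else:
            raise PackingError(
                f"could not place lacuna {len(planted) + 1}/{n_target} after "
                f"{model.max_retries} retries; lower the density or separation"
            )
    return occupied, planted


def generate_qbei(spec: SyntheticSpec) -> QBEIScene:
    """Generate a qBEI-like raster with compartment mask and ground truth."""
    h, w = spec.shape
    ss = np.random.SeedSequence(spec.seed)
    geom_rng, min_rng, lac_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(4))

    compartments = np.zeros((h, w), dtype=np.uint8)
    n_cort = int(round(spec.cortical_fraction * w))
    compartments[:, :n_cort] = 1
    compartments[:, n_cort:] = 2

    bone = np.zeros((h, w), dtype=bool)
    bone[:, :n_cort] = True  # cortex: solid bone
    if n_cort < w:
        trab = _trabecular_struts(
            geom_rng, (h, w - n_cort), spec.trab_corr_px, spec.trab_bvtv
        )
        bone[:, n_cort:] = trab
    # fill enclosed marrow pockets (incl. those sealed against the cortex):
    # every sub-threshold pore in the emitted raster should be a planted lacuna
    bone = ndimage.binary_fill_holes(bone)

    gl = np.full((h, w), float(spec.background_gl))
    truth = GroundTruth()
    for code, name, mix in ((1, "cortical", spec.cortical_mix), (2, "trabecular", spec.trab_mix)):
        sel = bone & (compartments == code)
        n = int(sel.sum())
        if n:
            ca = mix.sample(min_rng, n)
            gl[sel] = spec.calibration.ca_to_gl(ca, clip=True)
        truth.ca_mean[name] = mix.true_mean
        truth.ca_width[name] = mix.true_width

    if spec.lacunae is not None:
        occupied, planted = _place_lacunae(
            lac_rng, spec.lacunae, bone, compartments, spec.pixel_size_um
        )
        gl[occupied] = float(spec.lacunae.fill_gl)
        truth.lacunae = planted
        truth.n_lacunae = len(planted)
    truth.bone_area_mm2 = bone.sum() * (spec.pixel_size_um / 1000.0) ** 2
    if truth.bone_area_mm2 > 0:
        truth.lacuna_density_per_mm2 = truth.n_lacunae / truth.bone_area_mm2

    if spec.noise_gl_sd > 0:
        gl = gl + noise_rng.normal(0.0, spec.noise_gl_sd, size=gl.shape)
    image = np.clip(np.rint(gl), 0, 255).astype(np.uint8)
    return QBEIScene(image=image, compartments=compartments, bone_mask=bone, ground_truth=truth)


def _surface_partition(x0: float, length: float, y: float, spec: SyntheticSpec):
    """Split one straight surface line into state spans (exact μm extents)."""
    os_frac = spec.osteoid.surface_fraction
    ob_frac = os_frac * spec.osteoid.osteoblast_fraction
    er_frac = spec.labels.eroded_fraction if spec.labels else 0.0
    oc_frac = spec.labels.osteoclast_fraction if spec.labels else 0.0
    if os_frac + er_frac + oc_frac > 1.0 + 1e-9:
        raise GeometryError("surface-state fractions exceed the available surface")
    spans = [
        (SurfaceState.OSTEOID, (os_frac - ob_frac) * length),
        (SurfaceState.OSTEOBLAST, ob_frac * length),
        (SurfaceState.ERODED, er_frac * length),
        (SurfaceState.OSTEOCLAST, oc_frac * length),
        (SurfaceState.QUIESCENT, (1.0 - os_frac - er_frac - oc_frac) * length),
    ]
    segments = []
    x = x0
    for state, ext in spans:
        if ext > 1e-12:
            segments.append(SurfaceSegment(state, [[x, y], [x + ext, y]]))
            x += ext
    return segments


def generate_histo_scene(
    spec: SyntheticSpec,
) -> tuple[ClassRaster, SurfaceAnnotation, GroundTruth]:
    """Generate a class-coded section with surface annotation and exact primitives.

    Horizontal mineralized struts span the full width; osteoid seams replace
    the outermost strut rows over the planted surface fraction; tetracycline
    label traces run parallel to the surface with the planted inter-label
    distance. The recorded ground-truth primitives are computed from the
    same rasterized geometry the scene emits.
    """
    h, w = spec.shape
    ps = spec.histo_pixel_size_um
    t_px = int(round(spec.strut_thickness_um / ps))
    pitch_px = int(round(spec.strut_pitch_um / ps))
    if t_px < 2 or pitch_px <= t_px:
        raise GeometryError("strut pitch must exceed strut thickness (>= 2 px)")
    seam_px = int(round(spec.osteoid.width_um / ps))
    if seam_px >= t_px:
        raise GeometryError(
            f"osteoid seam ({seam_px} px) as wide as the strut ({t_px} px)"
        )

    classes = np.zeros((h, w), dtype=np.uint8)
    gap = (pitch_px - t_px) // 2
    strut_rows = []
    y0 = gap
    while y0 + t_px + gap <= h:
        strut_rows.append(y0)
        classes[y0 : y0 + t_px, :] = TissueClass.MINERALIZED
        y0 += pitch_px
    if not strut_rows:
        raise GeometryError("canvas too small for a single strut")

    length_um = w * ps
    os_cols = int(round(spec.osteoid.surface_fraction * w))
    segments: list[SurfaceSegment] = []
    labels: list[LabelTrace] = []
    lm = spec.labels
    for y0 in strut_rows:
        for surface_y, seam_slice, label_row in (
            (y0, slice(y0, y0 + seam_px), y0 + seam_px + 2),  # top surface
            (y0 + t_px, slice(y0 + t_px - seam_px, y0 + t_px), y0 + t_px - seam_px - 3),  # bottom
        ):
            if seam_px > 0 and os_cols > 0:
                classes[seam_slice, :os_cols] = TissueClass.OSTEOID
            segments.extend(
                _surface_partition(0.0, length_um, surface_y * ps, spec)
            )
            if lm is not None:
                x = spec.osteoid.surface_fraction * length_um  # label the front edge
                for kind, frac in (("double", lm.double_fraction), ("single", lm.single_fraction)):
                    ext = frac * length_um
                    if ext > 1e-12:
                        labels.append(
                            LabelTrace(
                                kind,
                                [[x - ext, label_row * ps], [x, label_row * ps]],
                                inter_label_distance_um=(
                                    lm.inter_label_um if kind == "double" else None
                                ),
                            )
                        )

    ann = SurfaceAnnotation(
        segments=segments,
        labels=labels,
        label_interval_days=lm.interval_days if lm else DEFAULT_LABEL_INTERVAL,
    )

    raster = ClassRaster(classes=classes, pixel_size_um=ps)
    pa = raster.pixel_area_mm2
    n_surf = 2 * len(strut_rows)
    bs_mm = n_surf * length_um / 1000.0
    os_mm = spec.osteoid.surface_fraction * bs_mm
    ov_mm2 = float(np.sum(classes == TissueClass.OSTEOID)) * pa
    truth = GroundTruth(
        primitives=HistoPrimitives(
            tv_mm2=classes.size * pa,
            bv_mm2=float(np.sum(classes == TissueClass.MINERALIZED)) * pa,
            bs_mm=bs_mm,
            ov_mm2=ov_mm2,
            os_mm=os_mm,
            o_th_um=seam_px * ps,
            ob_s_mm=spec.osteoid.surface_fraction * spec.osteoid.osteoblast_fraction * bs_mm,
            es_mm=(lm.eroded_fraction + lm.osteoclast_fraction) * bs_mm if lm else 0.0,
            oc_s_mm=lm.osteoclast_fraction * bs_mm if lm else 0.0,
            dl_pm_mm=lm.double_fraction * bs_mm if lm else 0.0,
            sl_pm_mm=lm.single_fraction * bs_mm if lm else 0.0,
            ir_l_wi_um=lm.inter_label_um if lm and lm.double_fraction > 0 else 0.0,
            label_interval_days=lm.interval_days if lm else DEFAULT_LABEL_INTERVAL,
        )
    )
    return raster, ann, truth
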