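"""Osteocyte lacuna section (OLS) segmentation and morphometry.

In high-resolution qBEI rasters (0.88 μm/px) osteocyte lacunae appear as
dark pores inside the mineralized matrix. A pore pixel is one with a gray
level strictly below the bone threshold (default 55, i.e. 5.2 wt% Ca under
the default calibration), so the bone/pore partition is exhaustive with the
BMDD module's bone definition (gl >= 55). Connected pore components are
measured (area, perimeter, ellipse-equivalent axes from second-order
moments) and partitioned into osteocyte lacunae (area <= 200 μm², the
conventional cutoff separating lacunae from vascular channels, Haversian
canals and cracks) versus larger pores. Border-touching regions have
censored geometry and are excluded by default.

Summary statistics: OLS density (lacunae per mm² bone area, where bone area
counts mineralized pixels plus the retained lacuna pixels), arithmetic mean
area / perimeter / aspect ratio, and lacunar porosity (percent of bone area
occupied by lacunae).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage import measure

from .calibration import BONE_GL_THRESHOLD
from .errors import EmptyRegionError, ShapeMismatchError

#: Area cutoff (μm², inclusive) separating osteocyte lacunae from larger pores.
MAX_LACUNA_AREA: float = 200.0

#: Default pixel size of the high-resolution qBEI scans used for OLS work.
OLS_PIXEL_SIZE: float = 0.88


@dataclass(frozen=True)
class PoreRegion:
    """One connected pore component with ellipse-equivalent geometry."""

    label: int
    n_pixels: int
    area_um2: float
    perimeter_um: float
    centroid_um: tuple[float, float]  # (y, x)
    major_um: float
    minor_um: float
    aspect_ratio: float
    touches_border: bool


@dataclass
class OLSummary:
    """Lacunar morphometry over all retained lacunae in one field."""

    n_lacunae: int
    n_excluded_large: int
    n_excluded_border: int
    bone_area_mm2: float
    ols_density_per_mm2: float
    mean_area_um2: float
    mean_perimeter_um: float
    mean_aspect_ratio: float
    lacunar_porosity_pct: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _aspect_ratio(major: float, minor: float) -> float:
    if minor > 0:
        return major / minor
    # degenerate regions: a single pixel has zero axes (treated as round),
    # a 1-px-wide line has zero minor axis (infinitely elongated)
    return 1.0 if major == 0 else float("inf")


def segment_pores(
    image,
    gl_threshold: int = BONE_GL_THRESHOLD,
    pixel_size: float = OLS_PIXEL_SIZE,
    connectivity: int = 8,
    mask=None,
) -> list[PoreRegion]:
    """Segment connected components of pore pixels (gl < threshold).

    8-connectivity (default) avoids fragmenting thin lacunae; pass 4 for the
    stricter convention. Geometry comes from second-order moments
    (rotation-invariant ellipse-equivalent axes), perimeter from the
    standard contour approximation.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    image = np.asarray(image)
    if image.size == 0:
        raise EmptyRegionError("empty image")
    pores = image < gl_threshold
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != image.shape:
            raise ShapeMismatchError(
                f"mask shape {mask.shape} != image shape {image.shape}"
            )
        if not mask.any():
            raise EmptyRegionError("mask selects no pixels")
        pores &= mask

    labels = measure.label(pores, connectivity=2 if connectivity == 8 else 1)
    h, w = labels.shape
    regions: list[PoreRegion] = []
    for rp in measure.regionprops(labels):
        minr, minc, maxr, maxc = rp.bbox
        touches = minr == 0 or minc == 0 or maxr == h or maxc == w
        major = rp.axis_major_length * pixel_size
        minor = rp.axis_minor_length * pixel_size
        cy, cx = rp.centroid
        regions.append(
            PoreRegion(
                label=int(rp.label),
                n_pixels=int(rp.num_pixels),
                area_um2=float(rp.num_pixels) * pixel_size**2,
                perimeter_um=float(rp.perimeter) * pixel_size,
                centroid_um=(cy * pixel_size, cx * pixel_size),
                major_um=float(major),
                minor_um=float(minor),
                aspect_ratio=_aspect_ratio(major, minor),
                touches_border=bool(touches),
            )
        )
    return regions


def filter_lacunae(
    regions: Sequence[PoreRegion],
    max_area: float = MAX_LACUNA_AREA,
    exclude_border: bool = True,
    min_area: float = 0.0,
) -> tuple[list[PoreRegion], dict[str, list[PoreRegion]]]:
    """Partition pore regions into lacunae and excluded regions by reason.

    The area cutoff is inclusive (a region of exactly ``max_area`` is a
    lacuna). Over-size regions are classed 'large' even when they also touch
    the border (large pores are vascular/Haversian regardless of position);
    'small' collects regions below ``min_area`` (default 0: none).
    """
    lacunae: list[PoreRegion] = []
    excluded: dict[str, list[PoreRegion]] = {"large": [], "border": [], "small": []}
    for region in regions:
        if region.area_um2 > max_area:
            excluded["large"].append(region)
        elif exclude_border and region.touches_border:
            excluded["border"].append(region)
        elif region.area_um2 < min_area:
            excluded["small"].append(region)
        else:
            lacunae.append(region)
    return lacunae, excluded


def ols_summary(
    lacunae: Sequence[PoreRegion],
    bone_area_mm2: float,
    n_excluded_large: int = 0,
    n_excluded_border: int = 0,
) -> OLSummary:
    """Aggregate lacunar statistics over one field.

    An empty lacuna list yields n=0 with NaN means and zero density/porosity
    (flagged by NaN, not an exception).
    """
    if not bone_area_mm2 > 0:
        raise ValueError("bone_area_mm2 must be positive")
    n = len(lacunae)
    if n == 0:
        return OLSummary(
            n_lacunae=0,
            n_excluded_large=n_excluded_large,
            n_excluded_border=n_excluded_border,
            bone_area_mm2=bone_area_mm2,
            ols_density_per_mm2=0.0,
            mean_area_um2=float("nan"),
            mean_perimeter_um=float("nan"),
            mean_aspect_ratio=float("nan"),
            lacunar_porosity_pct=0.0,
        )
    areas = np.array([r.area_um2 for r in lacunae])
    total_area_mm2 = areas.sum() / 1e6
    return OLSummary(
        n_lacunae=n,
        n_excluded_large=n_excluded_large,
        n_excluded_border=n_excluded_border,
        bone_area_mm2=bone_area_mm2,
        ols_density_per_mm2=n / bone_area_mm2,
        mean_area_um2=float(areas.mean()),
        mean_perimeter_um=float(np.mean([r.perimeter_um for r in lacunae])),
        mean_aspect_ratio=float(np.mean([r.aspect_ratio for r in lacunae])),
        lacunar_porosity_pct=100.0 * total_area_mm2 / bone_area_mm2,
    )


def analyze_image(
    image,
    gl_threshold: int = BONE_GL_THRESHOLD,
    pixel_size: float = OLS_PIXEL_SIZE,
    connectivity: int = 8,
    mask=None,
    max_area: float = MAX_LACUNA_AREA,
    exclude_border: bool = True,
    min_area: float = 0.0,
) -> tuple[OLSummary, list[PoreRegion], dict[str, list[PoreRegion]]]:
    """Full OLS pipeline: segment, filter, summarize.

    Bone area is the masked mineralized area (gl >= threshold) plus the
    retained lacuna pixels — lacunae are part of the bone, larger pores
    (vascular space) are not.
    """
    image = np.asarray(image)
    regions = segment_pores(image, gl_threshold, pixel_size, connectivity, mask)
    lacunae, excluded = filter_lacunae(regions, max_area, exclude_border, min_area)
    bone = image >= gl_threshold
    if mask is not None:
        bone &= np.asarray(mask).astype(bool)
    n_bone_px = int(bone.sum()) + sum(r.n_pixels for r in lacunae)
    if n_bone_px == 0:
        raise EmptyRegionError("no bone pixels in field")
    bone_area = n_bone_px * (pixel_size / 1000.0) ** 2
    summary = ols_summary(
        lacunae,
        bone_area,
        n_excluded_large=len(excluded["large"]),
        n_excluded_border=len(excluded["border"]),
    )
    return summary, lacunae, excluded


def lacunae_to_records(
    lacunae: Sequence[PoreRegion], excluded: dict[str, Sequence[PoreRegion]] | None = None
) -> list[dict]:
    """Flatten regions into per-lacuna records for CSV export."""
    records = []
    groups = [("", lacunae)]
    if excluded:
        groups += [(reason, regs) for reason, regs in excluded.items()]
    for reason, regs in groups:
        for r in regs:
            records.append(
                {
                    "id": r.label,
                    "area_um2": r.area_um2,
                    "perimeter_um": r.perimeter_um,
                    "major_um": r.major_um,
                    "minor_um": r.minor_um,
                    "aspect_ratio": r.aspect_ratio,
                    "x_um": r.centroid_um[1],
                    "y_um": r.centroid_um[0],
                    "excluded_reason": reason,
                }
            )
    return records
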