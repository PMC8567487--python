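"""Gray-level <-> calcium weight-percent calibration for qBEI rasters.

In quantitative backscattered electron imaging (qBEI) the backscattered
signal of a polished, carbon-coated bone block increases linearly with the
local mean atomic number and hence, over the physiological range, with the
calcium weight fraction of the mineralized matrix. After calibrating the
detector against carbon and aluminum standards, every 8-bit gray level maps
to a Ca concentration through a single affine transform. That transform is
the anchor of every downstream quantity in this package: mineralization
histograms, the bone/pore threshold, and the synthetic-image sensor model.

The default anchors place the organic (osteoid) phase at gray level 25
(0.0 wt% Ca) and pin gray level 55 to 5.2 wt% Ca — the conventional
bone/void threshold for osteocyte-lacuna segmentation. Both anchors are
overridable; the map itself is exact (solved, not least-squares).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import CalibrationError, CalibrationRangeWarning, DomainError

#: Default anchor pairs (gray level, wt% Ca): organic matrix and the
#: lacuna-segmentation threshold.
DEFAULT_ANCHORS: tuple[tuple[float, float], tuple[float, float]] = (
    (25.0, 0.0),
    (55.0, 5.2),
)

#: Gray level at and above which a pixel counts as mineralized bone;
#: below it lies void, marrow or osteoid. Shared by the bmdd and ols modules
#: so the bone/pore partition is exhaustive.
BONE_GL_THRESHOLD: int = 55


@dataclass(frozen=True)
class CalibrationMap:
    """Affine map ``ca = slope * gl + intercept`` between gray level and wt% Ca.

    Parameters
    ----------
    slope
        wt% Ca per gray level; must be positive (brighter = more mineralized).
    intercept
        wt% Ca at gray level 0 (typically negative: the organic phase sits
        above gray level 0).
    anchors
        The two (gl, ca) pairs the map was fitted through, kept for
        provenance and serialization.
    """

    slope: float
    intercept: float
    anchors: tuple[tuple[float, float], tuple[float, float]] = field(
        default=DEFAULT_ANCHORS
    )

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise CalibrationError(
                f"calibration slope must be positive, got {self.slope!r}"
            )

    def gl_to_ca(self, gl, *, clip_negative: bool = False):
        """Convert gray level(s) in [0, 255] to wt% Ca.

        With ``clip_negative=True`` sub-organic values are floored at 0 for
        reporting; the default keeps the raw affine value so that
        ``ca_to_gl(gl_to_ca(x)) == x`` holds exactly.
        """
        arr = np.asarray(gl, dtype=float)
        if np.any(arr < 0) or np.any(arr > 255):
            raise DomainError("gray level outside [0, 255]")
        ca = self.slope * arr + self.intercept
        if clip_negative:
            ca = np.maximum(ca, 0.0)
        return float(ca) if np.isscalar(gl) or arr.ndim == 0 else ca

    def ca_to_gl(self, ca, *, clip: bool = True):
        """Invert the map: wt% Ca to real-valued gray level.

        Quantization to 8-bit is the caller's responsibility. Values mapping
        outside [0, 255] raise :class:`CalibrationRangeWarning`; with
        ``clip=True`` (default) the result is clipped to the valid range,
        otherwise returned raw.
        """
        arr = np.asarray(ca, dtype=float)
        gl = (arr - self.intercept) / self.slope
        if np.any(gl < 0) or np.any(gl > 255):
            warnings.warn(
                "Ca value maps outside the 8-bit gray-level range"
                + ("; clipping" if clip else ""),
                CalibrationRangeWarning,
                stacklevel=2,
            )
            if clip:
                gl = np.clip(gl, 0.0, 255.0)
        return float(gl) if np.isscalar(ca) or arr.ndim == 0 else gl

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "anchors": [list(a) for a in self.anchors],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationMap":
        anchors = tuple(tuple(map(float, a)) for a in d.get("anchors", DEFAULT_ANCHORS))
        return cls(slope=float(d["slope"]), intercept=float(d["intercept"]), anchors=anchors)

    @classmethod
    def from_json(cls, source) -> "CalibrationMap":
        """Load from a JSON string or a path to a JSON file."""
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            return cls.from_dict(json.loads(source))
        with open(source) as fh:
            return cls.from_dict(json.load(fh))


def fit_two_point(gl_a: float, ca_a: float, gl_b: float, ca_b: float) -> CalibrationMap:
    """Fit the affine gray-level -> Ca map exactly through two anchor points.

    Raises
    ------
    CalibrationError
        If both anchors share the same gray level (degenerate system).
    DomainError
        If an anchor Ca is negative or a gray level falls outside [0, 255].
    """
    for gl in (gl_a, gl_b):
        if not 0 <= gl <= 255:
            raise DomainError(f"anchor gray level {gl} outside [0, 255]")
    for ca in (ca_a, ca_b):
        if ca < 0:
            raise DomainError(f"anchor Ca {ca} is negative")
    if gl_a == gl_b:
        raise CalibrationError(
            f"anchors share gray level {gl_a}: calibration is degenerate"
        )
    slope = (ca_b - ca_a) / (gl_b - gl_a)
    intercept = ca_a - slope * gl_a
    return CalibrationMap(
        slope=slope,
        intercept=intercept,
        anchors=((float(gl_a), float(ca_a)), (float(gl_b), float(ca_b))),
    )


def fit_anchors(anchors: Sequence[Sequence[float]]) -> CalibrationMap:
    """Fit from a sequence of exactly two (gl, ca) pairs."""
    if len(anchors) != 2:
        raise CalibrationError(f"expected exactly 2 anchors, got {len(anchors)}")
    (gl_a, ca_a), (gl_b, ca_b) = anchors
    return fit_two_point(gl_a, ca_a, gl_b, ca_b)


def default_map() -> CalibrationMap:
    """The package-default calibration (organic phase at GL 25, 5.2 wt% at GL 55)."""
    return fit_anchors(DEFAULT_ANCHORS)


# Module-level functional aliases mirroring the object API.
def gl_to_ca(cal: CalibrationMap, gl, *, clip_negative: bool = False):
    return cal.gl_to_ca(gl, clip_negative=clip_negative)


def ca_to_gl(cal: CalibrationMap, ca, *, clip: bool = True):
    return cal.ca_to_gl(ca, clip=clip)
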