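"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: input/usage problems (shape mismatches,
missing reference rows, unreadable files) exit with 2; degenerate data
(empty bone regions, degenerate calibrations, infeasible packing) with 3.
"""


class BoneMatrixError(Exception):
    """Base class for all package errors."""


class InputError(BoneMatrixError):
    """Malformed or inconsistent input (CLI exit code 2)."""


class DegenerateDataError(BoneMatrixError):
    """Data that is formally valid but cannot be analyzed (CLI exit code 3)."""


class CalibrationError(DegenerateDataError):
    """Degenerate calibration, e.g. two anchors at the same gray level."""


class DomainError(InputError):
    """Value outside the physically meaningful domain (gl not in [0, 255], Ca < 0)."""


class EmptyRegionError(DegenerateDataError):
    """No pixels satisfy the bone/pore definition inside the mask."""


class ShapeMismatchError(InputError):
    """Image and mask (or class raster and annotation) are not congruent."""


class MissingReferenceError(InputError):
    """No normative reference row for the requested parameter / sex / age band."""


class AlignmentError(InputError):
    """Surface annotation polyline strays from the bone boundary."""


class GeometryError(InputError):
    """Infeasible synthetic geometry, e.g. osteoid seam wider than the strut."""


class PackingError(DegenerateDataError):
    """Requested lacuna density cannot be placed without overlap."""


class InconsistencyError(DegenerateDataError):
    """Mutually contradictory measurements, e.g. mineralizing surface without osteoid."""


class CalibrationRangeWarning(UserWarning):
    """Ca value maps to a gray level outside the 8-bit range; result clipped."""
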