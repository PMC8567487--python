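"""Raster reading/writing for 8-bit grayscale images and masks.

TIFF via tifffile, PNG (and anything else Pillow handles) via PIL. Round
trips are bit-exact for uint8 data, which the synthetic generator's tests
rely on.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .errors import InputError


def read_raster(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:  # collapse accidental RGB of a grayscale export
        if not (arr[..., 0] == arr[..., 1]).all():
            raise InputError(f"{path} is not a grayscale raster")
        arr = arr[..., 0]
    return arr


def write_raster(path, array: np.ndarray) -> None:
    path = Path(path)
    array = np.asarray(array)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, array)
    else:
        Image.fromarray(array).save(path)
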