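"""Grayscale image container used throughout the package.

All structure statistics operate on 8-bit luminance grids.  Images supplied
as floating point in [0, 1] are quantized to 256 levels on construction so
that histogram-based measures (entropy, skew) are always computed on the
same discrete scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image as _PILImage


@dataclass(frozen=True)
class GrayImage:
    """A 2-D luminance grid stored as 8-bit levels 0-255.

    Parameters
    ----------
    levels
        2-D uint8 array; rows are y (downward), columns are x (rightward).
    """

    levels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.levels)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("GrayImage requires a non-empty 2-D array")
        if arr.dtype != np.uint8:
            if not np.all(np.isfinite(arr)):
                raise ValueError("GrayImage levels must be finite")
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("GrayImage levels must lie in [0, 255]")
            arr = np.round(arr).astype(np.uint8)
        object.__setattr__(self, "levels", arr)

    @property
    def height(self) -> int:
        return self.levels.shape[0]

    @property
    def width(self) -> int:
        return self.levels.shape[1]

    @property
    def normalized(self) -> np.ndarray:
        """Luminance as float64 in [0, 1]."""
        return self.levels.astype(np.float64) / 255.0

    @classmethod
    def from_normalized(cls, arr: np.ndarray) -> "GrayImage":
        """Quantize a [0, 1] float array to 8-bit levels."""
        arr = np.asarray(arr, dtype=np.float64)
        if not np.all(np.isfinite(arr)):
            raise ValueError("input must be finite")
        arr = np.clip(arr, 0.0, 1.0)
        return cls(np.round(arr * 255.0).astype(np.uint8))

    @classmethod
    def open(cls, path: str | Path) -> "GrayImage":
        """Read a PNG/TIFF grayscale file; 16-bit inputs are rescaled to 8-bit."""
        img = _PILImage.open(path)
        if img.mode in ("I;16", "I;16B", "I"):
            arr = np.asarray(img, dtype=np.float64)
            arr = arr / 65535.0 if arr.max() > 255 else arr / 255.0
            return cls.from_normalized(arr)
        return cls(np.asarray(img.convert("L")))

    def save(self, path: str | Path) -> None:
        _PILImage.fromarray(self.levels, mode="L").save(path)
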