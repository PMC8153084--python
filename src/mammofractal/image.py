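"""Core raster containers: grayscale images and breast-region masks.

Intensities are stored as float64 internally; ``bit_depth`` records the
acquisition range (8-bit, 12-bit, or native float) so that values can be
written back losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Physical pixel pitch of screening mammograms handled by default, in microns.
DEFAULT_PIXEL_SIZE_UM = 50.0

_VALID_BIT_DEPTHS = (8, 12, "float")


@dataclass
class GrayImage:
    """A 2D scalar intensity field ``f(x, y)``.

    Parameters
    ----------
    values
        2D array of intensities, stored as float64.
    pixel_size_um
        Physical size of one pixel in microns (50 um for the mammograms
        this package targets).
    bit_depth
        8, 12, or ``"float"``. Integer depths assert the value range
        ``[0, 2**depth - 1]``.
    """

    values: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    bit_depth: int | str = "float"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("GrayImage requires a 2D array")
        if min(self.values.shape) < 32:
            raise ValueError("GrayImage dimensions must both be >= 32")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("GrayImage values must be finite")
        if self.bit_depth not in _VALID_BIT_DEPTHS:
            raise ValueError(f"bit_depth must be one of {_VALID_BIT_DEPTHS}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def max_intensity(self) -> float:
        """Full-scale value for the declared bit depth."""
        if self.bit_depth == "float":
            return float(self.values.max())
        return float(2 ** int(self.bit_depth) - 1)


@dataclass
class BreastRegionMask:
    """Boolean mask of the breast interior, aligned with a :class:`GrayImage`.

    ``provenance`` records whether the mask was supplied by the caller or
    produced by the automatic segmentation fallback.
    """

    mask: np.ndarray
    provenance: str = "provided"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if self.provenance not in ("provided", "auto"):
            raise ValueError("provenance must be 'provided' or 'auto'")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @classmethod
    def full(cls, shape: tuple[int, int]) -> "BreastRegionMask":
        return cls(np.ones(shape, dtype=bool), provenance="provided")


def quantize(values: np.ndarray, bit_depth: int | str) -> np.ndarray:
    """Rescale a float field onto the integer range of ``bit_depth``.

    The field is mapped affinely so that its minimum hits 0 and its maximum
    hits full scale, then rounded. ``bit_depth == "float"`` returns the
    input unchanged.
    """
    if bit_depth == "float":
        return np.asarray(values, dtype=np.float64)
    lo, hi = float(values.min()), float(values.max())
    full = 2 ** int(bit_depth) - 1
    if hi == lo:
        return np.zeros_like(values)
    scaled = (values - lo) / (hi - lo) * full
    return np.round(scaled)
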