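"""Sliding-window Hurst mapping of a mammogram.

The mammogram is scanned with overlapping 360 x 360-px windows advanced in
32-px steps (top-left to bottom-right); the wavelet transform sees the full
window but maxima statistics are restricted to the central 256 x 256 core.
Each analyzed window yields a Hurst exponent that is binned into a tissue
class:

* ``H <= 0.45``  — anti-correlated fluctuations, fatty tissue (blue);
* ``0.45 < H < 0.55`` — uncorrelated fluctuations, disrupted tissue (yellow);
* ``H >= 0.55`` — long-range correlated fluctuations, dense tissue (red).

Windows where no monofractal scaling can be established are rejected and
shown gray, mirroring the screening step of the underlying method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .image import BreastRegionMask, GrayImage
from .wtmm import HurstEstimate, ScaleFamily, estimate_hurst

# class codes; identical to mammofractal.synthetic
CLASS_FATTY = 0
CLASS_DISRUPTED = 1
CLASS_DENSE = 2
CLASS_REJECTED = 3

CLASS_NAMES = {
    CLASS_FATTY: "fatty",
    CLASS_DISRUPTED: "disrupted",
    CLASS_DENSE: "dense",
    CLASS_REJECTED: "rejected",
}

#: render colors following the blue/yellow/red/gray convention
CLASS_COLORS = {
    CLASS_FATTY: (43, 98, 222),
    CLASS_DISRUPTED: (240, 210, 50),
    CLASS_DENSE: (213, 45, 38),
    CLASS_REJECTED: (128, 128, 128),
}

FATTY_MAX = 0.45  # H <= 0.45 -> fatty (boundary included)
DENSE_MIN = 0.55  # H >= 0.55 -> dense (boundary included)


@dataclass(frozen=True)
class WindowGeometry:
    """Sliding-window layout: 360-px window, 256-px core, 32-px stride."""

    window_side: int = 360
    core_side: int = 256
    stride: int = 32
    min_mask_coverage: float = 0.5

    def __post_init__(self) -> None:
        if self.core_side > self.window_side:
            raise ValueError("core must fit inside the window")
        if (self.window_side - self.core_side) % 2 != 0:
            raise ValueError("core must be centerable in the window")
        if self.stride <= 0:
            raise ValueError("stride must be positive")
        if not 0.0 <= self.min_mask_coverage <= 1.0:
            raise ValueError("min_mask_coverage must lie in [0, 1]")

    @property
    def core_margin(self) -> int:
        return (self.window_side - self.core_side) // 2

    def grid_shape(self, image_shape: tuple[int, int]) -> tuple[int, int]:
        """Window-grid dimensions: floor((image - window) / stride) + 1."""
        n_r = (image_shape[0] - self.window_side) // self.stride + 1
        n_c = (image_shape[1] - self.window_side) // self.stride + 1
        return max(n_r, 0), max(n_c, 0)


@dataclass
class WindowRef:
    """One grid position: indices and the window's top-left pixel (0-based)."""

    row: int
    col: int
    origin_r: int
    origin_c: int


@dataclass
class WindowResult:
    """Outcome for one window: H and class, or a rejection reason."""

    row: int
    col: int
    origin_r: int
    origin_c: int
    hurst: float | None
    tissue_class: int
    reason: str | None = None

    def __post_init__(self) -> None:
        rejected = self.tissue_class == CLASS_REJECTED
        if rejected != (self.hurst is None):
            raise ValueError("class is 'rejected' iff H is undefined")


@dataclass
class TissueClassMap:
    """Grid of tissue classes aligned with the window grid."""

    classes: np.ndarray  # int8 grid, CLASS_* codes; -1 where no window ran
    geometry: WindowGeometry
    config_hash: str = ""

    def counts(self) -> dict[str, int]:
        flat = self.classes[self.classes >= 0]
        return {name: int(np.sum(flat == code)) for code, name in CLASS_NAMES.items()}

    def render(self) -> np.ndarray:
        """RGB image (uint8) of the class map, gray for rejected windows.

        Cells where no window was analyzed (outside the breast) render black.
        """
        out = np.zeros(self.classes.shape + (3,), dtype=np.uint8)
        for code, color in CLASS_COLORS.items():
            out[self.classes == code] = color
        return out


def classify_hurst(hurst: float) -> int:
    """Map a Hurst exponent to its tissue class.

    Boundaries are closed on the outer classes: ``H <= 0.45`` is fatty and
    ``H >= 0.55`` is dense; strictly between lies the disrupted class.
    """
    h = float(hurst)
    if not np.isfinite(h):
        raise ValueError("H must be finite")
    if h <= FATTY_MAX:
        return CLASS_FATTY
    if h < DENSE_MIN:
        return CLASS_DISRUPTED
    return CLASS_DENSE


def tile_image(
    image: GrayImage | np.ndarray,
    mask: BreastRegionMask | np.ndarray | None,
    geometry: WindowGeometry,
) -> list[WindowRef]:
    """All window positions fully inside the image with enough breast in core.

    Windows are returned in raster order (top-left to bottom-right). A
    window qualifies when the breast mask covers at least
    ``geometry.min_mask_coverage`` of its central core. An image smaller
    than one window yields an empty list with a warning.
    """
    shape = image.shape if isinstance(image, (GrayImage, np.ndarray)) else None
    if isinstance(image, GrayImage):
        shape = image.values.shape
    n_r, n_c = geometry.grid_shape(shape)
    if n_r == 0 or n_c == 0:
        warnings.warn("image smaller than one window; nothing to analyze", stacklevel=2)
        return []
    if mask is None:
        mask_arr = None
    else:
        mask_arr = mask.mask if isinstance(mask, BreastRegionMask) else np.asarray(mask, bool)
    cm = geometry.core_margin
    core_area = geometry.core_side**2
    refs = []
    for i in range(n_r):
        for j in range(n_c):
            r0, c0 = i * geometry.stride, j * geometry.stride
            if mask_arr is not None:
                core = mask_arr[
                    r0 + cm : r0 + cm + geometry.core_side,
                    c0 + cm : c0 + cm + geometry.core_side,
                ]
                if core.sum() / core_area < geometry.min_mask_coverage:
                    continue
            refs.append(WindowRef(row=i, col=j, origin_r=r0, origin_c=c0))
    return refs


def analyze_window(
    image: GrayImage | np.ndarray,
    ref: WindowRef,
    geometry: WindowGeometry,
    *,
    scales: ScaleFamily | None = None,
    **wtmm_kwargs,
) -> WindowResult:
    """Run the WTMM pipeline on one window and classify its H.

    The transform is computed over the full window; maxima statistics come
    from the central core. Failure to establish monofractal scaling is a
    value (class ``rejected`` with a reason), not an error.
    """
    values = image.values if isinstance(image, GrayImage) else np.asarray(image, float)
    win = values[
        ref.origin_r : ref.origin_r + geometry.window_side,
        ref.origin_c : ref.origin_c + geometry.window_side,
    ]
    cm = geometry.core_margin
    core = (slice(cm, cm + geometry.core_side), slice(cm, cm + geometry.core_side))
    if scales is None:
        scales = ScaleFamily.default_for(geometry.core_side)
    est: HurstEstimate = estimate_hurst(win, scales=scales, core=core, **wtmm_kwargs)
    if est.status != "ok":
        return WindowResult(
            row=ref.row,
            col=ref.col,
            origin_r=ref.origin_r,
            origin_c=ref.origin_c,
            hurst=None,
            tissue_class=CLASS_REJECTED,
            reason=est.reason,
        )
    return WindowResult(
        row=ref.row,
        col=ref.col,
        origin_r=ref.origin_r,
        origin_c=ref.origin_c,
        hurst=est.hurst,
        tissue_class=classify_hurst(est.hurst),
    )


def analyze_mammogram(
    image: GrayImage | np.ndarray,
    mask: BreastRegionMask | np.ndarray | None = None,
    geometry: WindowGeometry | None = None,
    *,
    scales: ScaleFamily | None = None,
    config_hash: str = "",
    **wtmm_kwargs,
) -> tuple[TissueClassMap, list[WindowResult]]:
    """Full sliding-window protocol over one mammogram.

    Deterministic given image, mask, and configuration. Returns the tissue
    class map (grid cells without an analyzed window carry -1) and the
    per-window results in raster order.
    """
    geometry = geometry or WindowGeometry()
    values = image.values if isinstance(image, GrayImage) else np.asarray(image, float)
    refs = tile_image(values, mask, geometry)
    grid = np.full(geometry.grid_shape(values.shape), -1, dtype=np.int8)
    results = []
    for ref in refs:
        res = analyze_window(values, ref, geometry, scales=scales, **wtmm_kwargs)
        grid[res.row, res.col] = res.tissue_class
        results.append(res)
    return TissueClassMap(classes=grid, geometry=geometry, config_hash=config_hash), results
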