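"""Image I/O, breast segmentation fallback, run configuration, and
patient-level composition.

Mammograms are read losslessly from PNG/TIFF/PGM/BMP (8- or 12-bit stored
in 8- or 16-bit containers); lossy formats are refused outright. Every
run writes a manifest carrying the configuration hash and seed so that any
output can be regenerated byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image as PILImage
from skimage import filters, measure, morphology

from .image import DEFAULT_PIXEL_SIZE_UM, BreastRegionMask, GrayImage
from .metrics import (
    MammogramMetrics,
    PatientRecord,
    UndefinedMetricError,
    compute_metrics,
    yb_factor,
)
from .windows import TissueClassMap, WindowGeometry, WindowResult, analyze_mammogram
from .wtmm import ScaleFamily

logger = logging.getLogger("mammofractal")

LOSSLESS_SUFFIXES = {".png", ".tif", ".tiff", ".pgm", ".bmp"}


@dataclass
class RunConfig:
    """Serializable configuration of an end-to-end run.

    The hash of the canonical JSON form is embedded in every output file,
    making re-runs verifiable.
    """

    window_side: int = 360
    core_side: int = 256
    stride: int = 32
    min_mask_coverage: float = 0.5
    scale_min: float = 2.0
    scale_max: float = 24.0
    n_scales: int = 40
    q_min: float = -2.0
    q_max: float = 3.0
    q_step: float = 0.25
    fatty_max: float = 0.45
    dense_min: float = 0.55
    min_span_octaves: float = 1.5
    min_r2: float = 0.98
    curvature_tol: float = 0.05
    include_rejected_in_denominator: bool = False
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    seed: int = 0

    def geometry(self) -> WindowGeometry:
        return WindowGeometry(
            window_side=self.window_side,
            core_side=self.core_side,
            stride=self.stride,
            min_mask_coverage=self.min_mask_coverage,
        )

    def scale_family(self) -> ScaleFamily:
        return ScaleFamily.log_spaced(self.scale_min, self.scale_max, self.n_scales)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def read_mammogram(
    path: str | Path,
    *,
    bit_depth_hint: int | str | None = None,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> GrayImage:
    """Read a grayscale mammogram losslessly.

    Integer pixel values are preserved exactly; 12-bit data stored in a
    16-bit container keeps its native range (no rescaling to 8 bits).
    Lossy-compressed inputs (JPEG) are refused because block artifacts
    corrupt the fine-scale fluctuation statistics this package measures.
    """
    path = Path(path)
    if path.suffix.lower() in {".jpg", ".jpeg"}:
        raise ValueError(
            f"{path.name}: lossy JPEG input is refused; supply PNG/TIFF/PGM/BMP"
        )
    if path.suffix.lower() not in LOSSLESS_SUFFIXES:
        raise ValueError(f"{path.name}: unsupported format {path.suffix!r}")
    with PILImage.open(path) as img:
        if img.mode not in ("L", "I", "I;16", "I;16B", "F", "P"):
            img = img.convert("L")
        arr = np.asarray(img)
    if arr.ndim == 3:
        arr = arr[..., 0]
    arr = arr.astype(np.float64)
    if bit_depth_hint is None:
        bit_depth_hint = 8 if arr.max() <= 255 else 12
    return GrayImage(arr, pixel_size_um=pixel_size_um, bit_depth=bit_depth_hint)


def write_image_png(values: np.ndarray, path: str | Path) -> None:
    """Write an integer field as 16-bit grayscale PNG (lossless)."""
    arr = np.asarray(values)
    out = np.round(arr).astype(np.uint16)
    PILImage.fromarray(out).save(Path(path), format="PNG")


def segment_breast(
    image: GrayImage | np.ndarray, *, closing_radius: int = 5
) -> BreastRegionMask:
    """Fallback breast segmentation: Otsu threshold, largest component,
    morphological closing.

    Intended for images without a supplied mask; when a mask is provided
    this function is never consulted. An all-dark image yields an all-false
    mask with a warning.
    """
    values = image.values if isinstance(image, GrayImage) else np.asarray(image, float)
    if np.ptp(values) == 0:
        logger.warning("segment_breast: flat image, empty mask returned")
        return BreastRegionMask(np.zeros(values.shape, dtype=bool), provenance="auto")
    thresh = filters.threshold_otsu(values)
    fg = values > thresh
    if not fg.any():
        logger.warning("segment_breast: empty foreground, empty mask returned")
        return BreastRegionMask(np.zeros(values.shape, dtype=bool), provenance="auto")
    labels = measure.label(fg)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest
    mask = morphology.closing(mask, morphology.disk(closing_radius)).astype(bool)
    return BreastRegionMask(mask, provenance="auto")


# ---------------------------------------------------------------------------
# Result serialization (deterministic: sorted keys, repr floats, no clocks)


def window_results_to_csv(results: list[WindowResult], path: str | Path, config_hash: str) -> None:
    lines = [f"# config_hash={config_hash}", "row,col,origin_r,origin_c,H,class,reason"]
    from .windows import CLASS_NAMES

    for r in results:
        h = "" if r.hurst is None else repr(round(r.hurst, 10))
        lines.append(
            f"{r.row},{r.col},{r.origin_r},{r.origin_c},{h},{CLASS_NAMES[r.tissue_class]},{r.reason or ''}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def patient_record_to_json(rec: PatientRecord, config_hash: str, seed: int) -> str:
    def _metrics(m: MammogramMetrics | None):
        if m is None:
            return None
        return {
            "pct_blue": round(m.pct_blue, 10),
            "pct_yellow": round(m.pct_yellow, 10),
            "pct_red": round(m.pct_red, 10),
            "yb_ratio": None if m.yb_ratio is None else round(m.yb_ratio, 10),
            "n_accepted": m.n_accepted,
            "n_rejected": m.n_rejected,
        }

    payload = {
        "patient_id": rec.patient_id,
        "group": rec.group,
        "tumor_side": rec.tumor_side,
        "tumor": _metrics(rec.tumor_metrics),
        "opposite": _metrics(rec.opposite_metrics),
        "yb_factor": None if rec.yb_factor is None else round(rec.yb_factor, 10),
        "config_hash": config_hash,
        "seed": seed,
    }
    return json.dumps(payload, sort_keys=True, indent=2)


def patch_result_to_json(fit, est) -> str:
    """Serialize one patch's scaling fit and Hurst verdict.

    Contains the tau(q) table with standard errors and fit quality, the
    selected scaling range, and the monofractality outcome.
    """
    payload = {
        "status": est.status,
        "monofractal": est.monofractal,
        "hurst": None if est.hurst is None else round(est.hurst, 10),
        "stderr": None if est.stderr is None else round(est.stderr, 10),
        "reason": est.reason,
        "scaling_range_px": fit.scaling_range,
        "tau": None
        if fit.status != "ok"
        else [
            {
                "q": float(q),
                "tau": round(float(t), 10),
                "stderr": round(float(se), 10),
                "r2": round(float(r2), 10),
            }
            for q, t, se, r2 in zip(fit.q_grid, fit.tau, fit.stderr, fit.r2)
        ],
    }
    return json.dumps(payload, sort_keys=True, indent=2)


def patch_result_to_csv(fit, path: str | Path) -> None:
    """tau(q) table as CSV (q, tau, stderr, r2)."""
    lines = ["q,tau,stderr,r2"]
    if fit.status == "ok":
        for q, t, se, r2 in zip(fit.q_grid, fit.tau, fit.stderr, fit.r2):
            lines.append(f"{q},{t!r},{se!r},{r2!r}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Composition


def analyze_breast(
    image: GrayImage,
    mask: BreastRegionMask | None,
    config: RunConfig,
) -> tuple[TissueClassMap, list[WindowResult], MammogramMetrics]:
    """Window analysis plus metrics for one breast."""
    if mask is None:
        mask = segment_breast(image)
    cmap, results = analyze_mammogram(
        image,
        mask,
        config.geometry(),
        scales=config.scale_family(),
        config_hash=config.hash,
        min_span_octaves=config.min_span_octaves,
        min_r2=config.min_r2,
        curvature_tol=config.curvature_tol,
    )
    counts = cmap.counts()
    logger.info(
        "breast analyzed: %d accepted, %d rejected",
        counts["fatty"] + counts["disrupted"] + counts["dense"],
        counts["rejected"],
    )
    metrics = compute_metrics(
        cmap, include_rejected_in_denominator=config.include_rejected_in_denominator
    )
    return cmap, results, metrics


def run_patient(
    patient_id: str,
    group: str,
    tumor_side: str,
    tumor_image: GrayImage,
    opposite_image: GrayImage | None,
    config: RunConfig,
    *,
    tumor_mask: BreastRegionMask | None = None,
    opposite_mask: BreastRegionMask | None = None,
) -> PatientRecord:
    """Analyze both breasts of a patient and compute the YB Factor.

    A missing opposite image yields a partial record (tumor metrics only,
    no factor). An undefined ratio on either side is logged and leaves the
    factor None rather than failing the run.
    """
    _, _, m_tumor = analyze_breast(tumor_image, tumor_mask, config)
    if opposite_image is None:
        return PatientRecord(patient_id, group, tumor_side, m_tumor, None, None)
    _, _, m_opp = analyze_breast(opposite_image, opposite_mask, config)
    try:
        factor = yb_factor(m_tumor, m_opp)
    except UndefinedMetricError as exc:
        logger.warning("patient %s: YB Factor undefined (%s)", patient_id, exc)
        factor = None
    return PatientRecord(patient_id, group, tumor_side, m_tumor, m_opp, factor)
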