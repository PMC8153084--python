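"""Per-mammogram tissue-composition metrics and the per-patient YB Factor.

For each mammogram the analyzed (non-rejected) windows are summarized as
percentages per class: %B (blue, fatty), %Y (yellow, disrupted), %R (red,
dense), plus the combination score %Y/%B. The YB Factor compares the two
breasts of one patient:

    YB Factor = (%Y_tumor / %B_tumor) / (%Y_opposite / %B_opposite)

A value near 1 means the two breasts carry similar proportions of disrupted
relative to fatty tissue; values above 1 quantify excess disruption on the
tumor side.
"""

from __future__ import annotations

from dataclasses import dataclass

from .windows import CLASS_DENSE, CLASS_DISRUPTED, CLASS_FATTY, CLASS_REJECTED, TissueClassMap


class UndefinedMetricError(ValueError):
    """Raised when a metric has an empty or zero denominator."""


@dataclass
class MammogramMetrics:
    """Class percentages over one mammogram's analyzed windows."""

    pct_blue: float
    pct_yellow: float
    pct_red: float
    n_accepted: int
    n_rejected: int

    @property
    def yb_ratio(self) -> float | None:
        """%Y / %B; None (flagged undefined) when no blue windows exist."""
        if self.pct_blue == 0.0:
            return None
        return self.pct_yellow / self.pct_blue


@dataclass
class PatientRecord:
    """Paired-breast metrics for one patient plus the YB Factor."""

    patient_id: str
    group: str
    tumor_side: str
    tumor_metrics: MammogramMetrics | None
    opposite_metrics: MammogramMetrics | None
    yb_factor: float | None

    def __post_init__(self) -> None:
        if self.yb_factor is not None and self.yb_factor <= 0:
            raise ValueError("YB Factor must be positive when defined")


def metrics_from_counts(
    n_blue: int,
    n_yellow: int,
    n_red: int,
    n_rejected: int = 0,
    *,
    include_rejected_in_denominator: bool = False,
) -> MammogramMetrics:
    """Percentages from window-class counts.

    The denominator is the accepted windows only (the gray, rejected
    windows carry no tissue information); setting
    ``include_rejected_in_denominator`` switches to all windows, in which
    case the three percentages no longer sum to 100.
    """
    accepted = n_blue + n_yellow + n_red
    if accepted == 0:
        raise UndefinedMetricError("no accepted windows; metrics undefined")
    denom = accepted + n_rejected if include_rejected_in_denominator else accepted
    return MammogramMetrics(
        pct_blue=100.0 * n_blue / denom,
        pct_yellow=100.0 * n_yellow / denom,
        pct_red=100.0 * n_red / denom,
        n_accepted=accepted,
        n_rejected=n_rejected,
    )


def compute_metrics(
    class_map: TissueClassMap, *, include_rejected_in_denominator: bool = False
) -> MammogramMetrics:
    """Summarize a tissue-class map as %B / %Y / %R percentages."""
    c = class_map.classes
    return metrics_from_counts(
        int((c == CLASS_FATTY).sum()),
        int((c == CLASS_DISRUPTED).sum()),
        int((c == CLASS_DENSE).sum()),
        int((c == CLASS_REJECTED).sum()),
        include_rejected_in_denominator=include_rejected_in_denominator,
    )


def yb_factor(tumor: MammogramMetrics, opposite: MammogramMetrics) -> float:
    """Ratio of the tumor breast's %Y/%B to the contralateral breast's.

    Equals 1 exactly when both breasts have the same ratio; swapping the
    breasts gives the reciprocal. Undefined (raises) when either breast has
    no blue windows or the opposite breast has no yellow windows.
    """
    rt = tumor.yb_ratio
    ro = opposite.yb_ratio
    if rt is None:
        raise UndefinedMetricError("tumor breast %Y/%B undefined (%B = 0)")
    if ro is None:
        raise UndefinedMetricError("opposite breast %Y/%B undefined (%B = 0)")
    if ro == 0.0:
        raise UndefinedMetricError("opposite breast %Y/%B is zero; factor undefined")
    return rt / ro
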