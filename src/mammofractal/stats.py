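"""Cohort statistics: normality screening, rank-sum contrasts, box plots.

The comparisons mirror a two-arm observational design: breast-level metrics
(%B, %Y, %R, %Y/%B of the tumorous breast) compared between diagnosis
groups, and the patient-level YB Factor compared between cancer and benign
patients. Tests are non-parametric (Wilcoxon rank-sum / Mann-Whitney) and
p-values are reported unadjusted; a Benjamini-Hochberg column is provided
for reference but plays no role in any decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

from .metrics import PatientRecord
from .synthetic import BENIGN_GROUPS, CANCER_GROUPS

METRIC_NAMES = ("%B", "%Y", "%R", "%Y/%B", "YB Factor")


@dataclass
class GroupComparison:
    """One two-group contrast of one metric."""

    metric: str
    group_a: str
    group_b: str
    values_a: np.ndarray
    values_b: np.ndarray
    statistic: float
    p_value: float
    mode: str = "auto"

    def __post_init__(self) -> None:
        self.values_a = np.asarray(self.values_a, float)
        self.values_b = np.asarray(self.values_b, float)
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    @property
    def n_a(self) -> int:
        return self.values_a.size

    @property
    def n_b(self) -> int:
        return self.values_b.size


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p for a sample of 3 to 5000 values."""
    x = np.asarray(values, float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk is calibrated for n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("sample is constant; normality test undefined")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def rank_sum_test(x, y, mode: str = "auto") -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    ``mode``:
      * ``"exact"`` — exact null distribution of U (no ties required);
      * ``"normal-approx"`` — normal approximation with tie and continuity
        corrections;
      * ``"auto"`` — exact when n_x + n_y <= 20 and the data carry no ties,
        otherwise the approximation.

    Two identical samples (all values tied across both groups) give p = 1
    with a warning rather than an error.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        import warnings

        warnings.warn("all values tied across both groups; p = 1", stacklevel=2)
        return GroupComparison("", "x", "y", x, y, statistic=float(x.size * y.size / 2), p_value=1.0, mode=mode)
    if mode == "auto":
        use_exact = (x.size + y.size <= 20) and not has_ties
    elif mode == "exact":
        use_exact = True
    elif mode == "normal-approx":
        use_exact = False
    else:
        raise ValueError("mode must be 'auto', 'exact', or 'normal-approx'")
    method = "exact" if use_exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GroupComparison(
        "", "x", "y", x, y, statistic=float(res.statistic), p_value=float(res.pvalue), mode=method
    )


def rank_sum_exact_bruteforce(x, y) -> float:
    """Exact two-sided rank-sum p by full enumeration of group assignments.

    Reference oracle for small samples (n_x + n_y <= ~12): enumerates all
    C(n_x + n_y, n_x) ways the pooled ranks could split between groups and
    counts splits whose rank sum is at least as extreme as observed.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n, nx = pooled.size, x.size
    observed = ranks[:nx].sum()
    mu = nx * (n + 1) / 2.0
    count = 0
    total = comb(n, nx)
    for idx in combinations(range(n), nx):
        s = ranks[list(idx)].sum()
        if abs(s - mu) >= abs(observed - mu) - 1e-9:
            count += 1
    return count / total


@dataclass
class BoxplotSummary:
    """Tukey five-number summary plus outliers beyond 1.5 IQR."""

    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    outliers: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if not (self.minimum <= self.q1 <= self.median <= self.q3 <= self.maximum):
            raise ValueError("five-number summary out of order")


def boxplot_summary(values) -> BoxplotSummary:
    """Five-number summary with linear-interpolation quartiles.

    Outliers are points beyond 1.5 IQR from the quartile fences.
    """
    x = np.asarray(values, float)
    if x.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    out = x[(x < lo) | (x > hi)]
    return BoxplotSummary(
        minimum=float(x.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        maximum=float(x.max()),
        outliers=np.sort(out),
    )


# ---------------------------------------------------------------------------
# Cohort-level contrasts


def _metric_value(rec: PatientRecord, metric: str, breast: str = "tumor") -> float | None:
    if metric == "YB Factor":
        return rec.yb_factor
    m = rec.tumor_metrics if breast == "tumor" else rec.opposite_metrics
    if m is None:
        return None
    if metric == "%B":
        return m.pct_blue
    if metric == "%Y":
        return m.pct_yellow
    if metric == "%R":
        return m.pct_red
    if metric == "%Y/%B":
        return m.yb_ratio
    raise ValueError(f"unknown metric {metric!r}")


def _group_selector(label: str):
    """Map a contrast label to a patient-group predicate.

    ``Cancer`` = ILC + IDC grades; ``Benign`` = fibroadenoma + fibrocystic
    mastopathy; ``IDC`` = the three IDC grades combined; any single group
    label selects exactly that group.
    """
    if label == "Cancer":
        return lambda g: g in CANCER_GROUPS
    if label == "Benign":
        return lambda g: g in BENIGN_GROUPS
    if label == "IDC":
        return lambda g: g.startswith("IDC")
    return lambda g: g == label


DEFAULT_PLAN = [
    ("%B", "Cancer", "Benign"),
    ("%Y", "Cancer", "Benign"),
    ("%R", "Cancer", "Benign"),
    ("%Y/%B", "Cancer", "Benign"),
    ("%B", "IDC", "ILC"),
    ("%Y", "IDC", "ILC"),
    ("%R", "IDC", "ILC"),
    ("%Y/%B", "IDC", "ILC"),
    ("%B", "fib_a", "fib_m"),
    ("%Y", "fib_a", "fib_m"),
    ("%R", "fib_a", "fib_m"),
    ("%Y/%B", "fib_a", "fib_m"),
    ("YB Factor", "Cancer", "Benign"),
    ("YB Factor", "IDC", "Benign"),
    ("YB Factor", "ILC", "Benign"),
    ("YB Factor", "IDC", "ILC"),
]


def compare_groups(
    cohort: list[PatientRecord],
    plan: list[tuple[str, str, str]] | None = None,
    *,
    breast: str = "tumor",
    mode: str = "auto",
) -> list[GroupComparison]:
    """Run every (metric, group A, group B) contrast of the plan.

    Breast-level metrics are taken from the tumorous breast by default
    (``breast="opposite"`` switches); the YB Factor is patient-level by
    construction. Patients whose metric is undefined are dropped from that
    contrast; an empty group skips the contrast with a warning.
    """
    import warnings

    plan = DEFAULT_PLAN if plan is None else plan
    out = []
    for metric, label_a, label_b in plan:
        sel_a, sel_b = _group_selector(label_a), _group_selector(label_b)
        va = [v for r in cohort if sel_a(r.group) and (v := _metric_value(r, metric, breast)) is not None]
        vb = [v for r in cohort if sel_b(r.group) and (v := _metric_value(r, metric, breast)) is not None]
        if not va or not vb:
            warnings.warn(f"empty group in contrast {metric} {label_a} vs {label_b}; skipped", stacklevel=2)
            continue
        gc = rank_sum_test(va, vb, mode=mode)
        gc.metric = metric
        gc.group_a = label_a
        gc.group_b = label_b
        out.append(gc)
    return out


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (reported alongside, never used for decisions)."""
    p = np.asarray(p_values, float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj
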