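"""Clinical method-comparison statistics for stroke-volume estimates.

Error metrics against the pulmonary-artery-catheter reference (signed and
absolute, in mL and percent), Bland-Altman agreement (bias, 1.96-SD limits
of agreement with large-sample confidence intervals), Spearman rank
correlation, 4-quadrant trending concordance with a 10% central exclusion
zone, and a paired t-test comparing per-sample absolute errors of two
methods on identical samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

__all__ = [
    "PairedSeries",
    "MetricsReport",
    "BlandAltmanResult",
    "ConcordanceResult",
    "error_metrics",
    "bland_altman",
    "pct_changes",
    "four_quadrant",
    "spearman_rho",
    "paired_compare",
]


@dataclass
class PairedSeries:
    """One case's paired predicted / reference stroke volumes over time."""

    case_id: str
    times: np.ndarray
    pred: np.ndarray
    ref: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.pred = np.asarray(self.pred, float)
        self.ref = np.asarray(self.ref, float)
        if not (len(self.times) == len(self.pred) == len(self.ref)):
            raise ValueError("times, pred and ref must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class MetricsReport:
    """Mean (SD) of the four per-sample error terms."""

    error_mean: float
    error_sd: float
    abs_error_mean: float
    abs_error_sd: float
    pct_error_mean: float
    pct_error_sd: float
    abs_pct_error_mean: float
    abs_pct_error_sd: float
    n: int
    n_excluded_zero_ref: int = 0


@dataclass
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_low: tuple[float, float]  # 95% CI of the lower limit
    ci_high: tuple[float, float]  # 95% CI of the upper limit
    n: int


@dataclass
class ConcordanceResult:
    rate: float  # %; NaN when undefined
    n_pairs_total: int
    n_excluded: int
    exclusion_zone: float = 10.0

    @property
    def n_retained(self) -> int:
        return self.n_pairs_total - self.n_excluded

    @property
    def defined(self) -> bool:
        return self.n_retained > 0


def _pool(p) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(p, PairedSeries):
        return p.pred, p.ref
    if isinstance(p, (list, tuple)) and p and isinstance(p[0], PairedSeries):
        return (
            np.concatenate([q.pred for q in p]),
            np.concatenate([q.ref for q in p]),
        )
    pred, ref = p
    return np.asarray(pred, float), np.asarray(ref, float)


def error_metrics(p) -> MetricsReport:
    """Signed/absolute error (mL) and percentage error (%), mean and SD.

    ``p`` is a :class:`PairedSeries`, a list of them (pooled), or a
    ``(pred, ref)`` pair of arrays. Points with a zero reference are
    excluded from the percentage metrics and counted.
    """
    pred, ref = _pool(p)
    if len(pred) < 1:
        raise ValueError("need at least one pair")
    err = pred - ref
    nz = ref != 0
    pct = 100.0 * err[nz] / ref[nz]

    def mean_sd(x):
        if len(x) == 0:
            return float("nan"), float("nan")
        return float(np.mean(x)), float(np.std(x, ddof=1)) if len(x) > 1 else 0.0

    e_m, e_s = mean_sd(err)
    a_m, a_s = mean_sd(np.abs(err))
    p_m, p_s = mean_sd(pct)
    ap_m, ap_s = mean_sd(np.abs(pct))
    return MetricsReport(
        error_mean=e_m, error_sd=e_s,
        abs_error_mean=a_m, abs_error_sd=a_s,
        pct_error_mean=p_m, pct_error_sd=p_s,
        abs_pct_error_mean=ap_m, abs_pct_error_sd=ap_s,
        n=len(pred), n_excluded_zero_ref=int(np.sum(~nz)),
    )


def bland_altman(p) -> BlandAltmanResult:
    """Agreement analysis of pooled pairs: bias and 1.96-SD limits.

    Confidence intervals of each limit use the classic large-sample
    standard error 1.96 * sd * sqrt(3/n).
    """
    pred, ref = _pool(p)
    n = len(pred)
    if n < 3:
        raise ValueError("Bland-Altman needs at least 3 pairs")
    diffs = pred - ref
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    loa_low = bias - 1.96 * sd
    loa_high = bias + 1.96 * sd
    half = 1.96 * sd * np.sqrt(3.0 / n)
    return BlandAltmanResult(
        bias=bias, sd_diff=sd,
        loa_low=loa_low, loa_high=loa_high,
        ci_low=(loa_low - half, loa_low + half),
        ci_high=(loa_high - half, loa_high + half),
        n=n,
    )


def pct_changes(values: np.ndarray, stride: int = 1) -> np.ndarray:
    """Percentage changes over consecutive retained points of one case.

    change_i = 100 * (v_{i+stride} - v_i) / v_i; pairs with a zero
    denominator are skipped. Never call this across case boundaries.
    """
    v = np.asarray(values, float)
    if len(v) < stride + 1:
        return np.array([])
    a, b = v[:-stride], v[stride:]
    ok = a != 0
    return 100.0 * (b[ok] - a[ok]) / a[ok]


def four_quadrant(
    pred_changes: np.ndarray,
    ref_changes: np.ndarray,
    zone: float = 10.0,
    both_axes: bool = True,
) -> ConcordanceResult:
    """Concordance rate of paired percentage changes.

    Pairs inside the central exclusion zone (|change| < ``zone`` on both
    axes by default, reference axis only with ``both_axes=False``) are
    excluded; the rate is the percentage of retained pairs whose changes
    share a sign. With every pair excluded the rate is undefined (NaN).
    """
    pc = np.asarray(pred_changes, float)
    rc = np.asarray(ref_changes, float)
    if len(pc) != len(rc):
        raise ValueError("change vectors must have equal length")
    if both_axes:
        keep = (np.abs(rc) >= zone) & (np.abs(pc) >= zone)
    else:
        keep = np.abs(rc) >= zone
    n_total = len(pc)
    n_excl = int(np.sum(~keep))
    if n_excl == n_total:
        return ConcordanceResult(float("nan"), n_total, n_excl, zone)
    concordant = np.sign(pc[keep]) == np.sign(rc[keep])
    rate = 100.0 * float(np.mean(concordant))
    return ConcordanceResult(rate, n_total, n_excl, zone)


def spearman_rho(p) -> float:
    """Spearman rank correlation (average ranks for ties) of pooled pairs."""
    pred, ref = _pool(p)
    if len(pred) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(pred) == 0 or np.ptp(ref) == 0:
        return float("nan")
    rho, _ = scipy.stats.spearmanr(pred, ref)
    return float(rho)


def paired_compare(
    abs_err_a: np.ndarray, abs_err_b: np.ndarray
) -> tuple[float, float, float]:
    """Paired t-test of per-sample absolute errors from two methods.

    Returns (mean_a, mean_b, two-sided p). Identical inputs give p = 1;
    a constant nonzero difference gives p at the floating-point floor.
    """
    a = np.asarray(abs_err_a, float)
    b = np.asarray(abs_err_b, float)
    if len(a) != len(b):
        raise ValueError("error vectors must be paired (equal length)")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.all(d == d[0]):
        p = 1.0 if d[0] == 0 else float(np.finfo(float).tiny)
        return float(np.mean(a)), float(np.mean(b)), p
    t = scipy.stats.ttest_rel(a, b)
    return float(np.mean(a)), float(np.mean(b)), float(t.pvalue)
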