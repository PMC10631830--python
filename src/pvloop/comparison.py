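"""Method-agreement statistics and the EDP sensitivity sweep.

Agreement between non-invasively modelled and invasively measured loop
metrics is quantified the way method-comparison studies conventionally do:
ordinary least-squares regression (R^2, slope, intercept, slope F-test p),
Bland-Altman bias with 1.96*SD limits of agreement on percent differences,
a paired t-test, and the intraclass correlation coefficient ICC(2,1)
(two-way random effects, absolute agreement, single measures).

The Bland-Altman percent difference uses the pairwise mean as denominator
(``100 * (a - b) / ((a + b)/2)``, the standard convention); pass
``denominator="reference"`` to divide by the reference value instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .elastance import ElastanceCurve
from .errors import DegenerateRegressorError, PressureOrderingError, UndefinedICCError
from .metrics import METRIC_NAMES, PVMetrics, compute_all_metrics
from .noninvasive import BrachialBP, compute_noninvasive_loop, lvp_systole
from .volumes import VolumeCurve

__all__ = [
    "PairedMetrics",
    "AgreementResult",
    "linear_regression_r2",
    "bland_altman_percent",
    "paired_t_test",
    "icc_absolute_agreement",
    "edp_sensitivity_sweep",
    "compare_methods",
    "EDP_GRID",
]

#: End-diastolic pressure grid of the sensitivity sweep (mmHg).
EDP_GRID = (3.0, 7.5, 10.0, 16.0, 25.0, 40.0)


@dataclass(frozen=True)
class PairedMetrics:
    """Matched per-dataset metric sets for two methods (a vs reference b)."""

    labels: tuple
    method_a: tuple  # PVMetrics, non-invasive
    method_b: tuple  # PVMetrics, invasive reference

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "method_a", tuple(self.method_a))
        object.__setattr__(self, "method_b", tuple(self.method_b))
        if not (len(self.labels) == len(self.method_a) == len(self.method_b)):
            raise ValueError("labels and both metric sequences must match in length")
        if len(self.labels) < 3:
            raise ValueError("need at least 3 paired datasets")

    def values(self, metric_name: str) -> tuple[np.ndarray, np.ndarray]:
        if metric_name not in METRIC_NAMES:
            raise KeyError(f"unknown metric {metric_name!r}; one of {METRIC_NAMES}")
        a = np.array([getattr(m, metric_name) for m in self.method_a], dtype=float)
        b = np.array([getattr(m, metric_name) for m in self.method_b], dtype=float)
        return a, b


@dataclass(frozen=True)
class AgreementResult:
    """Agreement statistics for one metric across paired datasets."""

    metric: str
    r2: float
    slope: float
    intercept: float
    p_regression: float
    bias_pct: float
    loa_low_pct: float
    loa_high_pct: float
    t_paired_p: float
    icc: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def linear_regression_r2(x, y) -> dict:
    """Ordinary least squares of y on x.

    Returns r2 (squared Pearson correlation), slope, intercept, and the
    two-sided p-value of the slope (equivalent to the F-test for simple
    regression).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched sequences of length >= 3")
    if np.ptp(x) == 0:
        raise DegenerateRegressorError("regression on a constant predictor")
    res = stats.linregress(x, y)
    return {
        "r2": res.rvalue**2,
        "slope": res.slope,
        "intercept": res.intercept,
        "p": res.pvalue,
    }


def bland_altman_percent(a, b, denominator: str = "mean") -> dict:
    """Bland-Altman agreement on percent differences.

    Per-pair percent difference ``100 * (a - b) / d`` with ``d`` the
    pairwise mean (default) or the reference value ``b``. Bias is the mean
    percent difference; the limits of agreement are ``bias +/- 1.96 * SD``
    (sample SD). All denominators must be positive.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need matched sequences of length >= 2")
    if denominator == "mean":
        d = (a + b) / 2.0
    elif denominator == "reference":
        d = b
    else:
        raise ValueError("denominator must be 'mean' or 'reference'")
    if np.any(d <= 0):
        raise ValueError("pairwise denominators must be positive")
    diff = 100.0 * (a - b) / d
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return {
        "bias_pct": bias,
        "loa_low_pct": bias - 1.96 * sd,
        "loa_high_pct": bias + 1.96 * sd,
    }


def paired_t_test(a, b) -> dict:
    """Two-sided paired t-test; identical arrays return t = 0, p = 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired sequences must match in length")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.std(d, ddof=1) == 0.0:
        # degenerate difference distribution: identical arrays are "no
        # difference" (p = 1); a constant nonzero shift is detected with
        # certainty in the limit
        if np.all(d == 0.0):
            return {"t": 0.0, "p": 1.0}
        return {"t": float(np.sign(d[0]) * np.inf), "p": 0.0}
    res = stats.ttest_rel(a, b)
    return {"t": float(res.statistic), "p": float(res.pvalue)}


def icc_absolute_agreement(a, b) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    From the two-way ANOVA mean squares with n subjects and k = 2 raters:

        ICC = (MSR - MSE) / (MSR + (k-1)*MSE + k*(MSC - MSE)/n)

    where MSR is the between-subject, MSC the between-rater, and MSE the
    residual mean square.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need matched sequences of length >= 3")
    data = np.column_stack([a, b])
    n, k = data.shape
    grand = data.mean()
    if np.allclose(data, grand):
        raise UndefinedICCError("no variance in the data; ICC undefined")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum(
        (data - row_means[:, None] - col_means[None, :] + grand) ** 2
    )
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise UndefinedICCError("degenerate ANOVA decomposition; ICC undefined")
    return float((msr - mse) / denom)


def edp_sensitivity_sweep(
    vol: VolumeCurve,
    bp: BrachialBP,
    edp_grid=EDP_GRID,
    elastance: ElastanceCurve | None = None,
) -> dict[float, PVMetrics]:
    """Recompute the non-invasive metric set across an EDP grid.

    One full pipeline run per grid value; with the default grid the
    7.5 mmHg row equals the default pipeline bit-for-bit. Every grid value
    must lie below the estimated peak systolic pressure.
    """
    lvp = lvp_systole(bp)
    for edp in edp_grid:
        if edp >= lvp:
            raise PressureOrderingError(
                f"EDP grid value {edp} mmHg is not below LVPsystole ({lvp:.1f})"
            )
    out: dict[float, PVMetrics] = {}
    for edp in edp_grid:
        loop = compute_noninvasive_loop(vol, bp, edp=edp, elastance=elastance)
        out[float(edp)] = compute_all_metrics(loop, vol.heart_rate)
    return out


def compare_methods(pairs: PairedMetrics, metric_name: str) -> AgreementResult:
    """Full agreement panel for one metric across the paired datasets.

    Regression is of the non-invasive values on the reference values; bias
    is non-invasive minus reference.
    """
    a, b = pairs.values(metric_name)
    reg = linear_regression_r2(b, a)
    ba = bland_altman_percent(a, b)
    tt = paired_t_test(a, b)
    icc = icc_absolute_agreement(a, b)
    return AgreementResult(
        metric=metric_name,
        r2=reg["r2"],
        slope=reg["slope"],
        intercept=reg["intercept"],
        p_regression=reg["p"],
        bias_pct=ba["bias_pct"],
        loa_low_pct=ba["loa_low_pct"],
        loa_high_pct=ba["loa_high_pct"],
        t_paired_p=tt["p"],
        icc=icc,
    )
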