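"""Agreement statistics for estimated vs. true nutrient/volume values.

Median absolute error with 25th/75th percentiles (linear-interpolation
convention), mean absolute relative error (MARE), Pearson correlation,
Bland-Altman limits of agreement, and a one-sided Welch two-sample t-test
for comparing two methods' absolute errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class BlandAltman:
    mean_difference: float
    loa_low: float    # mean difference - 1.96 sd
    loa_high: float   # mean difference + 1.96 sd
    sd_difference: float


@dataclass(frozen=True)
class QuantityEvaluation:
    """Agreement of one estimated quantity with its ground truth."""

    n: int
    median_abs_error: float
    p25_abs_error: float
    p75_abs_error: float
    mare: float
    pearson_r: float
    bland_altman: BlandAltman

    def __post_init__(self) -> None:
        if not (self.p25_abs_error <= self.median_abs_error <= self.p75_abs_error):
            raise ValueError("error percentiles out of order")
        if self.mare < 0:
            raise ValueError("MARE must be >= 0")


@dataclass
class EvaluationReport:
    """Per-quantity agreement statistics (e.g. CHO / PRO / fat / kcal)."""

    quantities: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {name: asdict(q) for name, q in self.quantities.items()}


def mare(estimates: np.ndarray, truths: np.ndarray) -> float:
    """Mean absolute relative error; zero-truth items are excluded with a
    warning."""
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    ok = tru > 0
    if not ok.all():
        warnings.warn(
            f"MARE: excluded {int((~ok).sum())} item(s) with zero/negative truth",
            stacklevel=2,
        )
    if not ok.any():
        raise ValueError("MARE undefined: no positive truth values")
    return float(np.abs(est[ok] - tru[ok]).__truediv__(tru[ok]).mean())


def bland_altman(a: np.ndarray, b: np.ndarray) -> BlandAltman:
    """Limits of agreement between two paired measurement series."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    m = float(d.mean())
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    return BlandAltman(
        mean_difference=m,
        loa_low=m - 1.96 * sd,
        loa_high=m + 1.96 * sd,
        sd_difference=sd,
    )


def evaluate_quantity(estimates, truths) -> QuantityEvaluation:
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if len(est) != len(tru) or len(est) < 3:
        raise ValueError("need paired samples of equal length >= 3")
    abs_err = np.abs(est - tru)
    p25, p50, p75 = np.percentile(abs_err, [25, 50, 75])  # linear interpolation
    if np.std(est) == 0 or np.std(tru) == 0:
        r = 1.0 if np.allclose(est, tru) else 0.0
    else:
        r = float(stats.pearsonr(est, tru).statistic)
    return QuantityEvaluation(
        n=len(est),
        median_abs_error=float(p50),
        p25_abs_error=float(p25),
        p75_abs_error=float(p75),
        mare=mare(est, tru),
        pearson_r=r,
        bland_altman=bland_altman(est, tru),
    )


def evaluate_against_truth(estimates, truths) -> EvaluationReport:
    """Full agreement report.

    ``estimates``/``truths`` are either flat arrays (reported under the
    quantity name "value") or dicts mapping quantity names (e.g. "cho_g")
    to arrays.
    """
    if not isinstance(estimates, dict):
        estimates = {"value": estimates}
        truths = {"value": truths}
    if set(estimates) != set(truths):
        raise ValueError("estimates and truths must cover the same quantities")
    report = EvaluationReport()
    for name in estimates:
        report.quantities[name] = evaluate_quantity(estimates[name], truths[name])
    return report


def compare_methods(errors_a, errors_b, significance: float = 0.05) -> dict:
    """One-sided Welch t-test of 'method A's absolute errors exceed B's'.

    Degenerate zero-variance samples take an exact-equality fast path.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 absolute errors per method")
    if np.std(a) == 0 and np.std(b) == 0:
        if a.mean() == b.mean():
            p = 0.5
        else:
            p = 0.0 if a.mean() > b.mean() else 1.0
        t = np.inf if a.mean() > b.mean() else (-np.inf if a.mean() < b.mean() else 0.0)
    else:
        res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
        t, p = float(res.statistic), float(res.pvalue)
    return {
        "t_statistic": t,
        "p_value": float(p),
        "significant": bool(p < significance),
        "significance_level": significance,
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
    }


def bland_altman_plot(a, b, path, label_a="method A", label_b="method B", title=None):
    """Write a Bland-Altman figure (difference vs. mean) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ba = bland_altman(a, b)
    mean = (a + b) / 2.0
    diff = a - b
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, diff, s=18, alpha=0.7)
    ax.axhline(ba.mean_difference, color="k", lw=1)
    for y in (ba.loa_low, ba.loa_high):
        ax.axhline(y, color="tab:blue", ls="--", lw=1)
    ax.set_xlabel(f"mean of {label_a} and {label_b}")
    ax.set_ylabel(f"{label_a} - {label_b}")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return ba
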