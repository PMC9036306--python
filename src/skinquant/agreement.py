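"""The statistical layer: simple linear regression with r², Bland–Altman
method agreement, and the paired Student t-test.

Conventions: Bland–Altman differences are (method A − method B) in the
metric's native units, with A the classifier-style pipeline and B the
threshold-style pipeline when produced by :func:`agreement_report`; limits of
agreement default to bias ± 1.96·SD with the SD using the n−1 denominator.
No multiple-testing correction is applied anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .density import DensityReport
from .errors import AgreementError

__all__ = [
    "RegressionResult",
    "BlandAltmanResult",
    "PairedTestResult",
    "linear_fit",
    "bland_altman",
    "paired_t_test",
    "agreement_report",
    "AGREEMENT_STRATA",
    "plot_bland_altman",
    "plot_regression",
]

# the six method-agreement strata: each compartment's stained cell area under
# each normalization
AGREEMENT_STRATA = tuple(
    (compartment, metric)
    for compartment in ("epidermis", "dermis", "total")
    for metric in ("area_per_area", "area_per_length")
)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class BlandAltmanResult:
    differences: np.ndarray
    means: np.ndarray
    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    n: int
    multiplier: float = 1.96


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    zero_variance: bool = False


def linear_fit(x, y) -> RegressionResult:
    """Ordinary least squares with intercept; r² = 1 − SS_res/SS_tot (the
    squared Pearson correlation). Constant y yields r² = 0 with a warning;
    constant x is an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AgreementError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise AgreementError(f"need at least 3 points for a regression, got {n}")
    if np.ptp(x) == 0:
        raise AgreementError("constant x: regression slope undefined")
    if np.ptp(y) == 0:
        warnings.warn("constant y: r_squared reported as 0", stacklevel=2)
        return RegressionResult(slope=0.0, intercept=float(y[0]), r_squared=0.0, n=n)
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=n,
    )


def bland_altman(a, b, loa_multiplier: float = 1.96) -> BlandAltmanResult:
    """Agreement between two measurement series on the same samples.

    d = a − b; bias = mean(d); SD uses the n−1 denominator; limits of
    agreement are bias ± multiplier·SD. Per-pair means (a+b)/2 are returned
    for the difference-vs-mean plot.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise AgreementError("a and b must be 1-D vectors of equal length")
    n = a.size
    if n < 2:
        raise AgreementError(f"need at least 2 pairs, got {n}")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        differences=d,
        means=(a + b) / 2.0,
        bias=bias,
        sd=sd,
        loa_lower=bias - loa_multiplier * sd,
        loa_upper=bias + loa_multiplier * sd,
        n=n,
        multiplier=loa_multiplier,
    )


def paired_t_test(a, b) -> PairedTestResult:
    """Two-sided paired Student t-test: t = mean(d)/(SD(d)/sqrt(n)), df = n−1.

    Zero-variance nonzero differences give an infinite t and p = 0, flagged
    via ``zero_variance``; identical vectors give t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise AgreementError("a and b must be 1-D vectors of equal length")
    n = a.size
    if n < 2:
        raise AgreementError(f"need at least 2 pairs, got {n}")
    d = a - b
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        if d.mean() == 0:
            return PairedTestResult(t=0.0, df=df, p=1.0, zero_variance=True)
        t = np.inf if d.mean() > 0 else -np.inf
        return PairedTestResult(t=float(t), df=df, p=0.0, zero_variance=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return PairedTestResult(t=float(t), df=df, p=float(p))


def agreement_report(
    reports_a: list[DensityReport],
    reports_b: list[DensityReport],
    label_a: str = "classifier",
    label_b: str = "threshold",
    loa_multiplier: float = 1.96,
) -> tuple[pd.DataFrame, dict[tuple[str, str], BlandAltmanResult]]:
    """Bland–Altman analyses of stained cell area for the six strata
    (epidermis/dermis/total × per-area/per-length) between two pipelines run
    on identical inputs. Differences are (label_a − label_b). Returns a tidy
    table and the per-stratum results."""
    if len(reports_a) != len(reports_b) or len(reports_a) < 2:
        raise AgreementError("need matched report lists with at least 2 samples")
    ids_a = [r.sample_id for r in reports_a]
    ids_b = [r.sample_id for r in reports_b]
    if ids_a != ids_b:
        raise AgreementError(f"unmatched sample sets: {ids_a} vs {ids_b}")
    rows = []
    results: dict[tuple[str, str], BlandAltmanResult] = {}
    for compartment, metric in AGREEMENT_STRATA:
        va = [r.metric(metric, compartment) for r in reports_a]
        vb = [r.metric(metric, compartment) for r in reports_b]
        res = bland_altman(va, vb, loa_multiplier=loa_multiplier)
        results[(compartment, metric)] = res
        rows.append(
            {
                "compartment": compartment,
                "metric": metric,
                "difference": f"{label_a} - {label_b}",
                "bias": res.bias,
                "sd": res.sd,
                "loa_lower": res.loa_lower,
                "loa_upper": res.loa_upper,
                "mean_of_methods": float(np.mean(res.means)),
                "n": res.n,
            }
        )
    return pd.DataFrame(rows), results


def plot_bland_altman(result: BlandAltmanResult, path, title: str = "") -> None:
    """Difference-vs-mean plot with bias and limit-of-agreement lines."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter(result.means, result.differences, s=18, color="k")
    ax.axhline(result.bias, color="tab:blue", label=f"bias = {result.bias:.3g}")
    for loa in (result.loa_lower, result.loa_upper):
        ax.axhline(loa, color="tab:red", linestyle="--")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_regression(x, y, result: RegressionResult, path, title: str = "") -> None:
    """Scatter with the fitted line and the identity line."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter(x, y, s=18, color="k")
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, result.slope * xs + result.intercept, color="tab:blue",
            label=f"fit (r² = {result.r_squared:.3f})")
    lo, hi = min(x.min(), y.min()), max(x.max(), y.max())
    ax.plot([lo, hi], [lo, hi], color="gray", linestyle=":", label="identity")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
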