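"""Method-vs-reference agreement statistics.

Implements the agreement protocol used to benchmark volume estimators
against reference volumes:

* **Lin's concordance correlation coefficient (CCC)** — agreement with the
  identity line, penalizing both location and scale shifts:

      CCC = 2 s_xy / (s_x² + s_y² + (μ_x − μ_y)²)

  with population (1/n) moments; 95% CI via Lin's Fisher-z asymptotics.

* **Intraclass correlation ICC(A,1)** — two-way random-effects,
  absolute-agreement, single-measure ICC from the two-way ANOVA mean
  squares, with the McGraw–Wong F-based 95% CI.  A consistency variant
  ICC(C,1) is available as an option.

* **Bland–Altman** — bias (mean of method − reference) and 95% limits of
  agreement bias ± 1.96·SD of the differences (sample SD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, UndefinedStatisticError

__all__ = [
    "EstimateCI",
    "BlandAltman",
    "AgreementReport",
    "ccc",
    "icc",
    "bland_altman",
    "compare_methods",
    "MethodComparison",
]


@dataclass(frozen=True)
class EstimateCI:
    value: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n: int


@dataclass(frozen=True)
class AgreementReport:
    """Agreement of one method with the reference."""

    method: str
    n: int
    icc: EstimateCI
    ccc: EstimateCI
    bias: float
    loa_low: float
    loa_high: float


def _as_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise AlignmentError(f"series lengths differ: {len(x)} vs {len(y)}")
    return x, y


def ccc(x, y, confidence: float = 0.95) -> EstimateCI:
    """Lin's concordance correlation coefficient with a Fisher-z CI."""
    x, y = _as_pair(x, y)
    n = len(x)
    if n < 3:
        raise UndefinedStatisticError("CCC needs n >= 3")
    sx2 = float(np.var(x))  # population moments
    sy2 = float(np.var(y))
    if sx2 == 0 or sy2 == 0:
        raise UndefinedStatisticError("CCC undefined for a constant series")
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    dmu = float(x.mean() - y.mean())
    value = 2.0 * sxy / (sx2 + sy2 + dmu**2)
    r = sxy / np.sqrt(sx2 * sy2)
    # Lin (1989; corrected 2000) variance of the z-transformed CCC
    if abs(value) >= 1.0 - 1e-12 or abs(r) < 1e-12:
        return EstimateCI(value, value, value)
    u = dmu / (sx2 * sy2) ** 0.25
    c2 = value**2
    se_z2 = (
        (1 - r**2) * c2 / ((1 - c2) * r**2)
        + 4 * value**3 * (1 - value) * u**2 / (r * (1 - c2) ** 2)
        - 2 * value**4 * u**4 / (r**2 * (1 - c2) ** 2)
    ) / (n - 2)
    se_z = float(np.sqrt(max(se_z2, 0.0)))
    zcrit = stats.norm.ppf(0.5 + confidence / 2.0)
    z = np.arctanh(value)
    return EstimateCI(value, float(np.tanh(z - zcrit * se_z)),
                      float(np.tanh(z + zcrit * se_z)))


def _two_way_mean_squares(x: np.ndarray, y: np.ndarray):
    """Two-way ANOVA mean squares for an n×2 (subject × rater) layout."""
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * float(np.sum((row_means - grand) ** 2)) / (n - 1)
    msc = n * float(np.sum((col_means - grand) ** 2)) / (k - 1)
    resid = data - row_means[:, None] - col_means[None, :] + grand
    mse = float(np.sum(resid**2)) / ((n - 1) * (k - 1))
    return n, k, msr, msc, mse


def icc(x, y, variant: str = "a1", confidence: float = 0.95) -> EstimateCI:
    """Single-measure intraclass correlation between two measurement series.

    ``variant="a1"`` (default) is the two-way random-effects
    absolute-agreement ICC(A,1); ``variant="c1"`` is the consistency form
    ICC(C,1).
    """
    x, y = _as_pair(x, y)
    if len(x) < 3:
        raise UndefinedStatisticError("ICC needs n >= 3")
    if np.var(x) == 0 and np.var(y) == 0:
        raise UndefinedStatisticError("ICC undefined for constant series")
    n, k, msr, msc, mse = _two_way_mean_squares(x, y)
    alpha = 1.0 - confidence
    if variant == "c1":
        value = (msr - mse) / (msr + (k - 1) * mse)
        f = msr / mse if mse > 0 else np.inf
        fl = f / stats.f.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
        fu = f * stats.f.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
        return EstimateCI(value, (fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
    if variant != "a1":
        raise UndefinedStatisticError(f"unknown ICC variant {variant!r}")
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise UndefinedStatisticError("ICC denominator is zero")
    value = (msr - mse) / denom
    # McGraw & Wong F-based CI for ICC(A,1)
    a = k * value / (n * (1 - value)) if value < 1 else np.inf
    b = 1 + k * value * (n - 1) / (n * (1 - value)) if value < 1 else np.inf
    if not np.isfinite(a):
        return EstimateCI(value, value, value)
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return EstimateCI(value, float(lower), float(upper))


def bland_altman(x, y) -> BlandAltman:
    """Bland–Altman bias and 95% limits of agreement for x − y."""
    x, y = _as_pair(x, y)
    n = len(x)
    if n < 2:
        raise UndefinedStatisticError("Bland-Altman needs n >= 2")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias, bias - 1.96 * sd, bias + 1.96 * sd, sd, n)


@dataclass
class MethodComparison:
    """Agreement of several methods with one reference series."""

    reports: dict[str, AgreementReport]
    table: pd.DataFrame
    panel: pd.DataFrame  # tidy Bland-Altman data: method, mean, difference


def compare_methods(estimates: dict[str, "pd.Series | np.ndarray"],
                    reference) -> MethodComparison:
    """Agreement statistics of every method against the reference.

    Series given as :class:`pandas.Series` are aligned on their index
    (frame ids); plain arrays must match the reference length.  The panel
    frame carries (mean, difference) pairs per method for Bland–Altman
    plotting.
    """
    if not estimates:
        raise AlignmentError("no method series supplied")
    ref = reference
    reports: dict[str, AgreementReport] = {}
    panel_rows = []
    rows = []
    for method, est in estimates.items():
        if isinstance(est, pd.Series) and isinstance(ref, pd.Series):
            missing = ref.index.difference(est.index)
            if len(missing):
                raise AlignmentError(
                    f"method {method!r} missing frames: {list(missing[:10])}"
                )
            x = est.loc[ref.index].to_numpy(dtype=float)
            y = ref.to_numpy(dtype=float)
        else:
            x, y = _as_pair(est, ref)
        c = ccc(x, y)
        i = icc(x, y)
        ba = bland_altman(x, y)
        reports[method] = AgreementReport(
            method=method, n=len(x), icc=i, ccc=c,
            bias=ba.bias, loa_low=ba.loa_low, loa_high=ba.loa_high,
        )
        rows.append({
            "method": method, "n": len(x),
            "icc": i.value, "icc_ci_low": i.ci_low, "icc_ci_high": i.ci_high,
            "ccc": c.value, "ccc_ci_low": c.ci_low, "ccc_ci_high": c.ci_high,
            "bias": ba.bias, "loa_low": ba.loa_low, "loa_high": ba.loa_high,
        })
        panel_rows.append(pd.DataFrame({
            "method": method, "mean": (x + y) / 2.0, "difference": x - y,
        }))
    return MethodComparison(
        reports=reports,
        table=pd.DataFrame(rows).set_index("method"),
        panel=pd.concat(panel_rows, ignore_index=True),
    )
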