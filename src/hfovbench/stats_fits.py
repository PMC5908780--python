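"""Statistical layer: curve-fit families and one-way ANOVA with Tukey's HSD.

Power and exponential fits are linearized least squares (log transforms), so
their correlations are signed Pearson coefficients in the linearized space —
this is what allows a decaying exponential to report a negative R.  P-values
for correlations use the t-transform of r with n-2 degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "FitResult",
    "TukeyPair",
    "AnovaResult",
    "fit_linear",
    "fit_power",
    "fit_exponential",
    "fit_quadratic",
    "one_way_anova_tukey",
    "significance_band",
]


@dataclass(frozen=True)
class FitResult:
    family: str  # linear | power | exponential | quadratic
    coefficients: dict[str, float]
    correlation: float  # signed R in the (linearized) fitting space
    p_value: float
    n: int

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        c = self.coefficients
        if self.family == "linear":
            return c["slope"] * x + c["intercept"]
        if self.family == "power":
            return c["amplitude"] * x ** c["exponent"]
        if self.family == "exponential":
            return c["y_intercept"] * np.exp(-c["rate"] * x)
        if self.family == "quadratic":
            return c["a2"] * x**2 + c["a1"] * x + c["a0"]
        raise ValueError(f"unknown family {self.family!r}")


@dataclass(frozen=True)
class TukeyPair:
    group_a: str
    group_b: str
    mean_diff: float
    p_adj: float
    band: str  # ns | <0.05 | <0.01 | <0.001


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    group_labels: tuple[str, ...]
    tukey_pairs: tuple[TukeyPair, ...]
    df_between: int
    df_within: int
    degenerate: bool = False


def significance_band(p: float) -> str:
    if p < 0.001:
        return "<0.001"
    if p < 0.01:
        return "<0.01"
    if p < 0.05:
        return "<0.05"
    return "ns"


def _as_xy(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} points, got {x.size}")
    return x, y


def _corr_pvalue(r: float, n: int) -> float:
    """Two-sided p for Pearson r via the t-transform with n-2 df."""
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(t, n - 2))


def _linearized_fit(u: np.ndarray, v: np.ndarray) -> tuple[float, float, float, float]:
    """OLS of v on u; returns (slope, intercept, r, p)."""
    if np.ptp(u) == 0:
        raise ValueError("degenerate predictor: zero variance in x")
    res = sps.linregress(u, v)
    n = u.size
    if np.ptp(v) == 0:
        # constant response: perfect flat fit, correlation undefined -> 0
        return 0.0, float(v[0]), 0.0, 1.0
    return float(res.slope), float(res.intercept), float(res.rvalue), _corr_pvalue(float(res.rvalue), n)


def fit_linear(x, y) -> FitResult:
    """Ordinary least squares y = slope*x + intercept; R is Pearson r of (x, y)."""
    x, y = _as_xy(x, y, 3)
    slope, intercept, r, p = _linearized_fit(x, y)
    return FitResult(
        family="linear",
        coefficients={"slope": slope, "intercept": intercept},
        correlation=r,
        p_value=p,
        n=x.size,
    )


def fit_power(x, y) -> FitResult:
    """Power-law fit y = a*x**b by least squares on (ln x, ln y)."""
    x, y = _as_xy(x, y, 3)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power fit requires strictly positive x and y")
    slope, intercept, r, p = _linearized_fit(np.log(x), np.log(y))
    return FitResult(
        family="power",
        coefficients={"amplitude": math.exp(intercept), "exponent": slope},
        correlation=r,
        p_value=p,
        n=x.size,
    )


def fit_exponential(x, y) -> FitResult:
    """Exponential fit y = Y0*exp(-k*x) by least squares on (x, ln y).

    R is the signed Pearson r of (x, ln y): negative for decaying data.
    """
    x, y = _as_xy(x, y, 3)
    if np.any(y <= 0):
        raise ValueError("exponential fit requires strictly positive y")
    slope, intercept, r, p = _linearized_fit(x, np.log(y))
    return FitResult(
        family="exponential",
        coefficients={"y_intercept": math.exp(intercept), "rate": -slope},
        correlation=r,
        p_value=p,
        n=x.size,
    )


def fit_quadratic(x, y) -> FitResult:
    """Degree-2 polynomial least squares; R is Pearson r of fitted vs observed y."""
    x, y = _as_xy(x, y, 4)
    if np.unique(x).size < 3:
        raise ValueError("degenerate design: need >= 3 distinct x values")
    a2, a1, a0 = np.polyfit(x, y, 2)
    fitted = a2 * x**2 + a1 * x + a0
    if np.ptp(y) == 0 or np.ptp(fitted) < 1e-300:
        r, p = 0.0, 1.0
    else:
        r = float(np.corrcoef(fitted, y)[0, 1])
        p = _corr_pvalue(r, x.size)
    return FitResult(
        family="quadratic",
        coefficients={"a2": float(a2), "a1": float(a1), "a0": float(a0)},
        correlation=r,
        p_value=p,
        n=x.size,
    )


def one_way_anova_tukey(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA with Tukey HSD pairwise comparisons.

    The F statistic is computed from between/within sums of squares; Tukey
    adjusted p-values use the studentized-range distribution with the
    Tukey-Kramer standard error for (possibly) unequal group sizes.
    """
    labels = tuple(groups.keys())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    data = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in data.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs at least 2 observations")
    k = len(labels)
    ns = {g: v.size for g, v in data.items()}
    n_total = sum(ns.values())
    grand = sum(v.sum() for v in data.values()) / n_total
    means = {g: float(v.mean()) for g, v in data.items()}
    ss_between = sum(ns[g] * (means[g] - grand) ** 2 for g in labels)
    ss_within = sum(float(((v - means[g]) ** 2).sum()) for g, v in data.items())
    df_between = k - 1
    df_within = n_total - k

    degenerate = False
    if ss_within == 0.0:
        if ss_between == 0.0:
            # all observations identical: no variance anywhere
            f_stat, p_value, degenerate = 0.0, 1.0, True
        else:
            f_stat, p_value = math.inf, 0.0
    else:
        ms_between = ss_between / df_between
        ms_within = ss_within / df_within
        f_stat = ms_between / ms_within
        p_value = float(sps.f.sf(f_stat, df_between, df_within))

    ms_within = ss_within / df_within if df_within > 0 else 0.0
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = labels[i], labels[j]
            diff = means[a] - means[b]
            if ms_within == 0.0:
                p_adj = 1.0 if diff == 0.0 else 0.0
            else:
                se = math.sqrt(ms_within / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
                q = abs(diff) / se
                p_adj = float(sps.studentized_range.sf(q, k, df_within))
                p_adj = min(1.0, max(0.0, p_adj))
            pairs.append(
                TukeyPair(
                    group_a=a,
                    group_b=b,
                    mean_diff=diff,
                    p_adj=p_adj,
                    band=significance_band(p_adj),
                )
            )
    return AnovaResult(
        f_statistic=f_stat,
        p_value=p_value,
        group_labels=labels,
        tukey_pairs=tuple(pairs),
        df_between=df_between,
        df_within=df_within,
        degenerate=degenerate,
    )
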