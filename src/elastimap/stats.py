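"""Regression and effect-size statistics for elasticity summaries.

Covers the quantitative post-processing applied to per-map medians:

* **linear-vs-constant model comparison** — ordinary least squares of
  ``K = a x + b`` against the constant model ``K = c`` (the mean), decided
  by the extra-sum-of-squares F-test with (1, n-2) degrees of freedom;
* **relative slope** — the fitted slope normalised to the predicted K at a
  reference temperature (38 degC, physiological rat body temperature),
  in %/degC, which makes compartments of different absolute stiffness
  comparable;
* **nominal strain** ``epsilon = delta / h`` and **strain rate**
  ``epsilon_dot = 1 / (2 t_delta)`` (one indentation treated as half an
  oscillation period), used to place indentation protocols on a common
  axis with other rheological methods;
* **K-k correlation** — Pearson correlation between the model-derived
  modulus K and the model-free stiffness k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "RelativeSlope",
    "StrainEstimate",
    "StrainRateEstimate",
    "fit_linear_vs_constant",
    "relative_slope",
    "nominal_strain",
    "strain_rate",
    "correlate_K_k",
    "regression_report",
    "DEFAULT_ALPHA",
    "DEFAULT_T_REF",
]

DEFAULT_ALPHA = 0.05
DEFAULT_T_REF = 38.0


@dataclass
class RegressionResult:
    """Linear-vs-constant comparison for one response series.

    ``preferred`` is ``"linear"`` when the extra-sum-of-squares F-test
    rejects the constant model at level ``alpha``, else ``"horizontal"``.
    """

    slope: float
    intercept: float
    constant: float
    rss_null: float
    rss_alt: float
    F: float
    p: float
    adjusted_r2: float
    n: int
    alpha: float = DEFAULT_ALPHA

    @property
    def preferred(self) -> str:
        return "linear" if self.p < self.alpha else "horizontal"

    def slope_confidence_interval(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided t confidence interval for the slope."""
        se = self.slope_se
        tcrit = sps.t.ppf(0.5 + level / 2, self.n - 2)
        return self.slope - tcrit * se, self.slope + tcrit * se

    @property
    def slope_se(self) -> float:
        return self._slope_se

    _slope_se: float = math.nan


@dataclass(frozen=True)
class RelativeSlope:
    """Slope normalised to the predicted response at a reference x."""

    reference_temperature: float
    predicted_K_at_ref: float
    relative_slope: float  # %/degC


@dataclass(frozen=True)
class StrainEstimate:
    """Nominal strain epsilon = delta / h (dimensionless; percent = 100*value)."""

    delta: float
    sample_height: float
    strain: float

    @property
    def percent(self) -> float:
        return 100.0 * self.strain


@dataclass(frozen=True)
class StrainRateEstimate:
    """Strain rate 1/(2 t_delta) in Hz for an indentation of duration t_delta."""

    t_delta: float
    rate_hz: float


def fit_linear_vs_constant(
    x: Sequence[float],
    y: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
) -> RegressionResult:
    """OLS line against a horizontal line, judged by the F-test.

    ``F = ((RSS_null - RSS_alt) / 1) / (RSS_alt / (n - 2))`` with p from the
    F(1, n-2) distribution; adjusted r-squared uses the one-predictor
    residual degrees of freedom, ``1 - (1 - r2)(n - 1)/(n - 2)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError(f"need n >= 3 points, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("degenerate design: x values are all equal")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    rss_alt = float(resid @ resid)
    rss_null = float(np.sum((y - y.mean()) ** 2))
    df = n - 2
    sigma2 = rss_alt / df
    if rss_alt == 0:
        F, p = math.inf, 0.0
    else:
        F = (rss_null - rss_alt) / sigma2
        p = float(sps.f.sf(F, 1, df))
    r2 = 1.0 - rss_alt / rss_null if rss_null > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / df
    result = RegressionResult(
        slope=slope, intercept=intercept, constant=float(y.mean()),
        rss_null=rss_null, rss_alt=rss_alt, F=float(F), p=p,
        adjusted_r2=float(adj), n=n, alpha=alpha,
    )
    result._slope_se = math.sqrt(sigma2 / sxx) if sxx > 0 else math.nan
    return result


def relative_slope(
    result: Union[RegressionResult, tuple[float, float]],
    T_ref: float = DEFAULT_T_REF,
) -> RelativeSlope:
    """Slope as a percentage of the predicted response at ``T_ref``.

    ``predicted = a * T_ref + b`` and ``relative = 100 a / predicted``
    (%/degC). Accepts a fitted :class:`RegressionResult` or a bare
    ``(slope, intercept)`` pair.
    """
    if isinstance(result, RegressionResult):
        a, b = result.slope, result.intercept
    else:
        a, b = result
    predicted = a * T_ref + b
    if predicted <= 0:
        raise ValueError(
            f"predicted response at {T_ref} degC is {predicted:.4g} <= 0; "
            "relative slope undefined"
        )
    return RelativeSlope(
        reference_temperature=T_ref,
        predicted_K_at_ref=predicted,
        relative_slope=100.0 * a / predicted,
    )


def nominal_strain(delta: float, sample_height: float) -> StrainEstimate:
    """Nominal strain of an indentation: depth over sample height."""
    if sample_height <= 0:
        raise ValueError("sample height must be positive")
    if delta < 0:
        raise ValueError("indentation depth must be non-negative")
    return StrainEstimate(delta=delta, sample_height=sample_height,
                          strain=delta / sample_height)


def strain_rate(t_delta: float) -> StrainRateEstimate:
    """Strain rate of one indentation of duration ``t_delta`` (s): 1/(2 t)."""
    if t_delta <= 0:
        raise ValueError("indentation duration must be positive")
    return StrainRateEstimate(t_delta=t_delta, rate_hz=1.0 / (2.0 * t_delta))


def correlate_K_k(K: Sequence[float], k: Sequence[float]) -> tuple[float, tuple[float, float]]:
    """Pearson r between modulus K and stiffness k, plus the OLS line of k on K.

    Returns ``(r, (slope, intercept))``; raises on zero variance in either
    series.
    """
    K = np.asarray(K, dtype=float)
    k = np.asarray(k, dtype=float)
    if len(K) != len(k) or len(K) < 3:
        raise ValueError("need paired series of length >= 3")
    if np.std(K) == 0 or np.std(k) == 0:
        raise ValueError("degenerate series: zero variance")
    r = float(sps.pearsonr(K, k).statistic)
    slope, intercept = np.polyfit(K, k, 1)
    return r, (float(slope), float(intercept))


REPORT_COLUMNS = [
    "quantity", "n", "slope", "intercept", "constant", "F", "p",
    "adjusted_r2", "preferred", "predicted_K_at_T_ref",
    "relative_slope_pct_per_C",
]


def regression_report(
    summaries: pd.DataFrame,
    x_mode: str = "temperature",
    alpha: float = DEFAULT_ALPHA,
    T_ref: float = DEFAULT_T_REF,
) -> pd.DataFrame:
    """Temperature (or time) regression report over per-map summaries.

    One row per response — gray-matter median K, white-matter median K, and
    the gray-to-white ratio — each regressed on its own paired x: the
    per-compartment median temperature (or postmortem time) for the
    compartments, and the mean of the two medians for the ratio.
    """
    if x_mode == "temperature":
        xcols = {"gray": "median_temperature_gray_C",
                 "white": "median_temperature_white_C",
                 "ratio": "mean_temperature_C"}
    elif x_mode == "postmortem":
        xcols = {"gray": "median_postmortem_gray_h",
                 "white": "median_postmortem_white_h",
                 "ratio": "mean_postmortem_h"}
    else:
        raise ValueError(f"unknown x_mode {x_mode!r}")
    ycols = {"gray": "median_K_gray_Pa", "white": "median_K_white_Pa",
             "ratio": "ratio_gw"}
    rows = []
    for quantity in ("gray", "white", "ratio"):
        sub = summaries[[xcols[quantity], ycols[quantity]]].dropna()
        if len(sub) < 3:
            continue
        res = fit_linear_vs_constant(sub.iloc[:, 0], sub.iloc[:, 1], alpha=alpha)
        row = {
            "quantity": quantity, "n": res.n, "slope": res.slope,
            "intercept": res.intercept, "constant": res.constant,
            "F": res.F, "p": res.p, "adjusted_r2": res.adjusted_r2,
            "preferred": res.preferred,
            "predicted_K_at_T_ref": math.nan,
            "relative_slope_pct_per_C": math.nan,
        }
        if x_mode == "temperature":
            try:
                rel = relative_slope(res, T_ref)
                row["predicted_K_at_T_ref"] = rel.predicted_K_at_ref
                row["relative_slope_pct_per_C"] = rel.relative_slope
            except ValueError:
                pass
        rows.append(row)
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
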