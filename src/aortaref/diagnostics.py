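"""Normality and calibration checks on cohort z-scores.

A well-constructed reference chart standardises its own training cohort:
the z-scores should be standard normal (P-P plot on the diagonal,
Shapiro–Wilk non-significant), about 10% should fall outside ±1.6449 and
5% outside ±1.96, and there should be no residual trend of z on the
predictor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError


@dataclass(frozen=True)
class PPPlotData:
    """Probability–probability plot points and their maximum deviation.

    ``points`` are (empirical CDF, theoretical CDF) pairs sorted by the
    theoretical coordinate; both coordinates lie in [0, 1] and alignment
    with the diagonal indicates distributional fit.
    """

    points: tuple[tuple[float, float], ...]
    max_abs_deviation: float


def plotting_positions(
    n: int, convention: Literal["hazen", "weibull"] = "hazen"
) -> np.ndarray:
    """Empirical CDF levels for ranks 1..n.

    Hazen (default): (i − 0.5)/n.  Weibull: i/(n + 1).  The two differ by
    O(1/n) and either is acceptable for diagnostic plots.
    """
    i = np.arange(1, n + 1, dtype=float)
    if convention == "hazen":
        return (i - 0.5) / n
    if convention == "weibull":
        return i / (n + 1.0)
    raise ValueError(f"unknown plotting-position convention {convention!r}")


def pp_plot_data(
    values: Sequence[float],
    reference: Literal["standard_normal", "fitted_normal"] = "standard_normal",
    convention: Literal["hazen", "weibull"] = "hazen",
) -> PPPlotData:
    """P-P plot of a sample against a normal reference.

    ``fitted_normal`` standardises by the sample mean and SD before
    applying the normal CDF; ``standard_normal`` takes the values as
    already standardised (the usual choice for z-scores).
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 3:
        raise InsufficientDataError(f"P-P plot needs n >= 3, got {n}")
    if reference == "fitted_normal":
        sd = float(np.std(v, ddof=1))
        if sd == 0:
            raise DegenerateInputError("constant sample has no fitted normal")
        v_std = (v - float(np.mean(v))) / sd
    elif reference == "standard_normal":
        v_std = v
    else:
        raise ValueError(f"unknown reference {reference!r}")
    theoretical = stats.norm.cdf(v_std)
    empirical = plotting_positions(n, convention)
    deviation = float(np.max(np.abs(empirical - theoretical)))
    return PPPlotData(
        points=tuple(zip(empirical.tolist(), theoretical.tolist())),
        max_abs_deviation=deviation,
    )


def normality_test(z_values: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk statistic and p-value, the formal companion to the P-P plot."""
    z = np.asarray(z_values, dtype=float)
    if not 3 <= z.size <= 5000:
        raise InsufficientDataError(
            f"Shapiro-Wilk supported for 3 <= n <= 5000, got {z.size}"
        )
    if np.ptp(z) == 0:
        raise DegenerateInputError("constant input has no distribution to test")
    stat, p = stats.shapiro(z)
    return float(stat), float(p)


def coverage_check(z_values: Sequence[float], band: float) -> float:
    """Fraction of z-scores strictly outside ±band.

    For a calibrated chart this is ≈ 2·(1 − Φ(band)): 10% at 1.6449,
    5% at 1.96.
    """
    if band <= 0:
        raise ValueError(f"band must be > 0, got {band}")
    z = np.asarray(z_values, dtype=float)
    if z.size == 0:
        raise InsufficientDataError("no z-scores supplied")
    return float(np.mean(np.abs(z) > band))


def balance_check(
    z_values: Sequence[float], x_values: Sequence[float]
) -> tuple[float, float]:
    """OLS slope of z on the predictor with its two-sided p-value.

    A calibrated chart leaves no trend of z across the predictor range
    (slope ≈ 0); a non-zero slope signals a misspecified mean model.
    """
    z = np.asarray(z_values, dtype=float)
    x = np.asarray(x_values, dtype=float)
    if z.shape != x.shape or z.ndim != 1:
        raise ValueError("z and x must be 1-D arrays of equal length")
    if z.size < 10:
        raise InsufficientDataError(f"balance check needs n >= 10, got {z.size}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant predictor values")
    res = stats.linregress(x, z)
    return float(res.slope), float(res.pvalue)


@dataclass(frozen=True)
class DiagnosticsReport:
    """Bundle of all calibration diagnostics for one scored cohort."""

    n: int
    pp_max_deviation: float
    shapiro_stat: float
    shapiro_p: float
    coverage_1645: float
    coverage_196: float
    balance_slope: float | None
    balance_p: float | None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pp_max_deviation": self.pp_max_deviation,
            "shapiro_stat": self.shapiro_stat,
            "shapiro_p": self.shapiro_p,
            "coverage_1645": self.coverage_1645,
            "coverage_196": self.coverage_196,
            "balance_slope": self.balance_slope,
            "balance_p": self.balance_p,
        }


def diagnostics_report(
    z_values: Sequence[float],
    x_values: Sequence[float] | None = None,
) -> DiagnosticsReport:
    """Run the full diagnostic battery on cohort z-scores.

    Coverage is reported at both 1.6449 (the exact 90% band) and 1.96
    (the 95% band) because both conventions appear in reference-chart
    practice.
    """
    z = np.asarray(z_values, dtype=float)
    pp = pp_plot_data(z, reference="standard_normal")
    stat, p = normality_test(z)
    slope: float | None = None
    slope_p: float | None = None
    if x_values is not None:
        slope, slope_p = balance_check(z, x_values)
    return DiagnosticsReport(
        n=int(z.size),
        pp_max_deviation=pp.max_abs_deviation,
        shapiro_stat=stat,
        shapiro_p=p,
        coverage_1645=coverage_check(z, 1.6449),
        coverage_196=coverage_check(z, 1.96),
        balance_slope=slope,
        balance_p=slope_p,
    )
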