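"""Allometric scaling of subregion volume against total gray-matter volume.

A subregion whose volume V follows a power law V = b·Gᵃ of the total
gray-matter volume G is linear on log-log axes with slope a; a > 1 is
positive allometry (disproportionate growth of the part).  The fit is
ordinary least squares of ln V on ln G, pooled across species (either all
individuals or one mean point per species); left/right slope equality is
tested as the hemisphere × ln G interaction in a stacked linear model
(ANCOVA-style F test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "AllometryFit",
    "SlopeComparison",
    "allometric_fit",
    "compare_slopes",
    "species_mean_points",
]


@dataclass(frozen=True)
class AllometryFit:
    """OLS fit of ln(volume) on ln(GMV).

    ``slope`` is the dimensionless scaling exponent (a > 1 ⇒ positive
    allometry); ``intercept`` is ln b (natural-log scale); ``ci95`` bounds
    the slope via the t distribution.
    """

    slope: float
    intercept: float
    ci95: tuple[float, float]
    r_squared: float
    n: int
    df_resid: int

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.slope <= hi):
            raise ValueError("confidence interval must bracket the slope")


@dataclass(frozen=True)
class SlopeComparison:
    """Hemisphere × ln(GMV) interaction test (slope equality)."""

    slope_left: float
    slope_right: float
    f_stat: float
    p_value: float
    df: tuple[int, int]


def _validate_positive(values: np.ndarray, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError(f"{what} must be 1-D")
    if np.any(~np.isfinite(values)) or np.any(values <= 0):
        raise ValueError(f"{what} must be positive and finite (log scale)")
    return values


def allometric_fit(volumes, gmv) -> AllometryFit:
    """OLS of log(volume) on log(GMV) with a 95% slope CI.

    Requires at least 3 positive (volume, GMV) pairs and non-constant GMV.
    Rescaling either variable by a positive constant shifts only the
    intercept; a noise-free power law is recovered exactly.
    """
    v = _validate_positive(volumes, "volumes")
    g = _validate_positive(gmv, "gmv")
    if v.size != g.size:
        raise ValueError("volumes and gmv must have equal length")
    if v.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(g) == 0:
        raise ValueError("gmv is constant; slope is not identifiable")
    y = np.log(v)
    x = sm.add_constant(np.log(g))
    fit = sm.OLS(y, x).fit()
    ci = fit.conf_int(alpha=0.05)
    return AllometryFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        ci95=(float(ci[1, 0]), float(ci[1, 1])),
        r_squared=float(fit.rsquared),
        n=int(v.size),
        df_resid=int(fit.df_resid),
    )


def compare_slopes(vol_L, vol_R, gmv) -> SlopeComparison:
    """Test left/right slope equality via the interaction F statistic.

    Both hemispheres of the same subjects are stacked into one model
    ln V ~ ln G + hemisphere + ln G:hemisphere and the interaction term is
    F-tested (1 numerator df).  The two hemisphere samples are treated as
    independent for this test, mirroring a plot-level slope comparison.
    Bit-identical hemispheres return F = 0, p = 1 with a degenerate-fit
    warning (duplicated residuals).
    """
    left = _validate_positive(vol_L, "vol_L")
    right = _validate_positive(vol_R, "vol_R")
    g = _validate_positive(gmv, "gmv")
    if not (left.size == right.size == g.size):
        raise ValueError("hemisphere volumes and gmv must share subjects")
    if left.size < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(g) == 0:
        raise ValueError("gmv is constant; slopes are not identifiable")
    fit_l = allometric_fit(left, g)
    fit_r = allometric_fit(right, g)
    if np.array_equal(left, right):
        warnings.warn(
            "identical left/right volumes: degenerate stacked fit, "
            "interaction is exactly zero",
            stacklevel=2,
        )
        df_resid = 2 * left.size - 4
        return SlopeComparison(
            slope_left=fit_l.slope,
            slope_right=fit_r.slope,
            f_stat=0.0,
            p_value=1.0,
            df=(1, df_resid),
        )
    y = np.log(np.concatenate([left, right]))
    lg = np.log(np.concatenate([g, g]))
    hemi = np.concatenate([np.zeros(left.size), np.ones(right.size)])
    design = sm.add_constant(np.column_stack([lg, hemi, lg * hemi]))
    fit = sm.OLS(y, design).fit()
    ftest = fit.f_test(np.array([[0.0, 0.0, 0.0, 1.0]]))
    return SlopeComparison(
        slope_left=fit_l.slope,
        slope_right=fit_r.slope,
        f_stat=float(ftest.fvalue),
        p_value=float(ftest.pvalue),
        df=(1, int(fit.df_resid)),
    )


def species_mean_points(volumes: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Collapse a pooled multi-species volume table to one mean point per
    species (mean GMV, mean volume), the default pooling for cross-species
    scaling fits."""
    required = {"species", "gmv", value_col}
    missing = required - set(volumes.columns)
    if missing:
        raise ValueError(f"volume table lacks columns {sorted(missing)}")
    return (
        volumes.groupby("species", as_index=False)[["gmv", value_col]].mean()
    )
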