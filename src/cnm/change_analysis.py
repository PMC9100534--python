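"""Regression test of distribution change between climate scenarios.

Future occurrence probabilities are regressed on current ones at a common
set of random geographic coordinates, P_f = b0 + b1 * P_c, by ordinary
least squares. Under the null hypothesis that climate change leaves the
distribution unchanged, the fitted line coincides with the identity
(b0 = 0, b1 = 1); each coefficient is tested against its theoretical value
with a Student's t-test on n - 2 degrees of freedom. A positive intercept
with the fitted line lying above the identity over the observed range is
reported as an expansion signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grids import EnvGrid, GeoPoint, sample_random_points

logger = logging.getLogger(__name__)


def pair_probabilities(
    current: EnvGrid, future: EnvGrid, n: int = 10000, seed: int = 0
) -> pd.DataFrame:
    """Current/future probabilities at ``n`` random coordinates.

    Points are drawn uniformly over cells valid in both grids, so every row
    has both probabilities; rows are (lon, lat, p_current, p_future).
    """
    if not current.same_geometry(future):
        raise ValueError("grids must share geometry")
    joint_mask = current.nodata_mask | future.nodata_mask
    domain = EnvGrid(
        np.where(joint_mask, np.nan, 0.0),
        current.origin_lon, current.origin_lat, current.cell_size, joint_mask,
    )
    points = sample_random_points(domain, n, seed)
    rows = []
    for pt in points:
        r, c = current.cell_index(pt)
        rows.append((pt.lon, pt.lat, current.values[r, c], future.values[r, c]))
    return pd.DataFrame(rows, columns=["lon", "lat", "p_current", "p_future"])


@dataclass
class RegressionReport:
    """OLS estimates and identity-line tests for one scenario."""

    beta0: float
    beta1: float
    se_beta0: float
    se_beta1: float
    t0: float  # beta0 vs 0
    t1: float  # beta1 vs 1
    p0: float
    p1: float
    f_stat: float
    df: tuple[int, int]
    r_squared: float
    n: int
    degenerate_se: bool = False

    def function_string(self) -> str:
        s0 = "*" if self.p0 < 0.05 else ""
        s1 = "*" if self.p1 < 0.05 else ""
        return f"Pf = {self.beta0:.3f}{s0} + {self.beta1:.3f}{s1} * Pc"


def ols_fit(pairs: pd.DataFrame) -> RegressionReport:
    """Closed-form simple least squares of p_future on p_current.

    F is the regression mean square over the residual mean square with
    (1, n-2) degrees of freedom; t statistics test b0 against 0 and b1
    against 1. With a perfect fit the residual SE is zero and the t/p values
    are flagged degenerate.
    """
    x = pairs["p_current"].to_numpy(dtype=float)
    y = pairs["p_future"].to_numpy(dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("degenerate predictor: zero variance in p_current")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    beta1 = sxy / sxx
    beta0 = float(y.mean() - beta1 * x.mean())
    resid = y - (beta0 + beta1 * x)
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    ssr = sst - sse
    df2 = n - 2
    mse = sse / df2
    r_squared = 1.0 - sse / sst if sst > 0 else 1.0
    degenerate = mse <= 0 or np.isclose(mse, 0.0, atol=1e-30)
    if degenerate:
        se1 = se0 = 0.0
        t0 = t1 = np.nan
        p0 = p1 = np.nan
        f_stat = np.inf if ssr > 0 else np.nan
        logger.warning("zero residual variance: t-tests undefined")
    else:
        se1 = float(np.sqrt(mse / sxx))
        se0 = float(np.sqrt(mse * (1.0 / n + x.mean() ** 2 / sxx)))
        t0 = (beta0 - 0.0) / se0
        t1 = (beta1 - 1.0) / se1
        p0 = 2.0 * stats.t.sf(abs(t0), df2)
        p1 = 2.0 * stats.t.sf(abs(t1), df2)
        f_stat = ssr / mse
    return RegressionReport(
        beta0=beta0, beta1=beta1, se_beta0=se0, se_beta1=se1,
        t0=float(t0), t1=float(t1), p0=float(p0), p1=float(p1),
        f_stat=float(f_stat), df=(1, df2),
        r_squared=float(min(max(r_squared, 0.0), 1.0)), n=n,
        degenerate_se=degenerate,
    )


def test_against_theory(
    report: RegressionReport,
    beta0_null: float = 0.0,
    beta1_null: float = 1.0,
    alpha: float = 0.05,
    mean_pc: float | None = None,
) -> dict:
    """Student's t decisions against the theoretical identity line.

    Returns reject flags for each coefficient at ``alpha`` and an
    ``expansion`` flag: intercept above zero and the fitted line above the
    identity at the mean of the current probabilities (the fitted curve
    sits above the theoretical one).
    """
    if report.degenerate_se:
        return {"defined": False, "reject_beta0": None, "reject_beta1": None,
                "expansion": None}
    df2 = report.df[1]
    t0 = (report.beta0 - beta0_null) / report.se_beta0
    t1 = (report.beta1 - beta1_null) / report.se_beta1
    p0 = 2.0 * stats.t.sf(abs(t0), df2)
    p1 = 2.0 * stats.t.sf(abs(t1), df2)
    xc = 0.5 if mean_pc is None else mean_pc
    fitted_above = report.beta0 + report.beta1 * xc > xc
    return {
        "defined": True,
        "t0": float(t0), "t1": float(t1),
        "p0": float(p0), "p1": float(p1),
        "reject_beta0": bool(p0 < alpha),
        "reject_beta1": bool(p1 < alpha),
        "expansion": bool(report.beta0 > 0 and fitted_above),
    }


def regression_table(
    reports: dict[str, RegressionReport], alpha: float = 0.05
) -> pd.DataFrame:
    """One row per scenario: F(df), p, R-squared, fitted function string.

    No multiple-testing correction is applied across scenarios; each test is
    reported at the stated alpha.
    """
    rows = []
    for label, rep in reports.items():
        p_f = (
            stats.f.sf(rep.f_stat, *rep.df)
            if np.isfinite(rep.f_stat) else np.nan
        )
        rows.append(
            {
                "scenario": label,
                "F": rep.f_stat,
                "df1": rep.df[0],
                "df2": rep.df[1],
                "p_F": p_f,
                "r_squared": rep.r_squared,
                "beta0": rep.beta0,
                "beta1": rep.beta1,
                "p_beta0_vs_0": rep.p0,
                "p_beta1_vs_1": rep.p1,
                "function": rep.function_string(),
            }
        )
    return pd.DataFrame(rows)
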