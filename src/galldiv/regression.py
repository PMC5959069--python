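"""Local–regional richness regression (community saturation test).

For each regional unit (a mountain, by default) the response is the mean
richness of its member plots and the predictor is the unit's regional
richness (richness of the union of its plots). Fitting unit means rather
than pooled plots keeps the regional units as the independent replicates and
avoids pseudoreplication: the number of points equals the number of units.
A slope near the 45° line with high R² indicates unsaturated local
communities — local richness tracking regional richness proportionally
rather than being capped by local interactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import IncidenceMatrix, SiteHierarchy, aggregate_incidence

__all__ = ["RegressionFit", "DegenerateFitError", "local_regional_regression", "plot_fit"]


class DegenerateFitError(ValueError):
    """All regional richnesses equal: the slope is not identifiable."""


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of mean local richness on regional richness.

    One point per regional unit; F tests the slope with df (1, n − 2).
    """

    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    points: pd.DataFrame          # columns: unit, regional, local_mean
    residuals: np.ndarray

    def predict(self, regional: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(regional, dtype=float)


def local_regional_regression(
    m: IncidenceMatrix, h: SiteHierarchy, regional_level: str = "mountain"
) -> RegressionFit:
    """Regress mean within-unit plot richness on unit regional richness."""
    h._check_level(regional_level)
    h.validate_against(m)
    members = h.members(regional_level)
    if len(members) < 3:
        raise ValueError(f"need >= 3 regional units, got {len(members)}")
    regional_m = aggregate_incidence(m, h, regional_level)
    site_rich = m.richness
    units = list(members)
    x = regional_m.richness.loc[units].to_numpy(dtype=float)
    y = np.array([site_rich.loc[sites].mean() for sites in members.values()], dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateFitError("all regional richnesses are equal; slope undefined")

    fit = stats.linregress(x, y)
    n = len(x)
    resid = y - (fit.intercept + fit.slope * x)
    r2 = float(fit.rvalue**2)
    ss_res = float((resid**2).sum())
    if np.isclose(ss_res, 0.0):
        r2, f_stat, p = 1.0, float("inf"), 0.0
    else:
        f_stat = r2 / (1.0 - r2) * (n - 2)
        p = float(stats.f.sf(f_stat, 1, n - 2))
    points = pd.DataFrame({"unit": units, "regional": x, "local_mean": y})
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        f_statistic=float(f_stat),
        df_num=1,
        df_den=n - 2,
        p_value=p,
        points=points,
        residuals=resid,
    )


def plot_fit(fit: RegressionFit, path) -> None:
    """Scatter of the unit points, the OLS line, and the theoretical
    local = regional diagonal (for visual comparison only, not fitted)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    x = fit.points["regional"].to_numpy()
    ax.scatter(x, fit.points["local_mean"], marker="^", color="black", label="mean local richness")
    grid = np.linspace(0, x.max() * 1.05, 50)
    ax.plot(grid, fit.predict(grid), color="tab:blue", label="OLS fit")
    ax.plot(grid, grid, color="grey", linestyle="--", linewidth=1, label="local = regional")
    ax.set_xlabel("regional richness")
    ax.set_ylabel("mean local richness")
    ax.legend(frameon=False, fontsize=8)
    ax.set_title(
        f"R² = {fit.r_squared:.2f}, F({fit.df_num},{fit.df_den}) = {fit.f_statistic:.2f}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
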