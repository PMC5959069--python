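"""Multiple-site dissimilarity decomposition and subset resampling.

A single dissimilarity value for a whole set of *n* sites (not an average of
pairwise values). With ``b_ij`` the number of species present at site *i* but
not *j*, and

    Σmin = Σ_{i<j} min(b_ij, b_ji)
    Σmax = Σ_{i<j} max(b_ij, b_ji)
    K    = Σ_i S_i − S_T          (total incidence minus regional richness)

the multiple-site measures are

    β_SIM = Σmin / (Σmin + K)                       (turnover)
    β_SOR = (Σmin + Σmax) / (2K + Σmin + Σmax)      (total)
    β_SNE = β_SOR − β_SIM                           (nestedness-resultant)

Because β_SOR grows with the number of sites, sets of different sizes are
compared through resampling: the decomposition is recomputed for many random
equal-sized subsets of sites and the resulting distributions compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beta_pairwise import _require_non_empty
from .core_io import IncidenceMatrix

__all__ = [
    "MultisiteBeta",
    "BetaSampleDistribution",
    "DistributionComparison",
    "multisite_beta",
    "beta_sample",
    "distribution_difference",
]

_COMPONENTS = ("beta_sor", "beta_sim", "beta_sne")


@dataclass(frozen=True)
class MultisiteBeta:
    """The (β_SOR, β_SIM, β_SNE) triple for one set of sites."""

    beta_sor: float
    beta_sim: float
    beta_sne: float
    n_sites: int

    def as_dict(self) -> dict[str, float]:
        return {
            "beta_sor": self.beta_sor,
            "beta_sim": self.beta_sim,
            "beta_sne": self.beta_sne,
            "n_sites": self.n_sites,
        }


@dataclass(frozen=True)
class BetaSampleDistribution:
    """Resampling distribution of the multiple-site triple over random subsets.

    ``draws`` has one row per replicate with columns beta_sor/beta_sim/beta_sne;
    ``summary`` holds the per-component mean and standard deviation. The seed
    is retained so every draw is reproducible.
    """

    subset_size: int
    n_reps: int
    seed: int
    draws: pd.DataFrame
    summary: pd.DataFrame

    def component(self, name: str) -> np.ndarray:
        if name not in _COMPONENTS:
            raise KeyError(f"unknown component {name!r}; use one of {_COMPONENTS}")
        return self.draws[name].to_numpy()


@dataclass(frozen=True)
class DistributionComparison:
    """Summaries for comparing two resampling distributions of one component.

    ``prob_greater`` is P(X > Y) over all cross pairs with ties counted 0.5;
    the quantile pairs are each distribution's central 95% interval, and
    ``intervals_overlap`` flags whether those intervals intersect.
    """

    component: str
    prob_greater: float
    quantiles_1: tuple[float, float]
    quantiles_2: tuple[float, float]
    intervals_overlap: bool


def _multisite_from_array(x: np.ndarray) -> tuple[float, float, float]:
    x = x.astype(np.int64)
    shared = x @ x.T
    s = x.sum(axis=1)
    b = s[:, None] - shared
    iu = np.triu_indices(x.shape[0], k=1)
    bij, bji = b[iu], b.T[iu]
    sum_min = float(np.minimum(bij, bji).sum())
    sum_max = float(np.maximum(bij, bji).sum())
    k = float(s.sum() - (x.sum(axis=0) > 0).sum())
    if sum_min + sum_max == 0.0:  # all sites identical
        return 0.0, 0.0, 0.0
    sim = sum_min / (sum_min + k)
    sor = (sum_min + sum_max) / (2.0 * k + sum_min + sum_max)
    return sor, sim, sor - sim


def multisite_beta(m: IncidenceMatrix, drop_empty: bool = False) -> MultisiteBeta:
    """Multiple-site (β_SOR, β_SIM, β_SNE) for all sites of ``m``."""
    m = _require_non_empty(m, drop_empty)
    if m.n_sites < 2:
        raise ValueError("multiple-site dissimilarity needs at least 2 non-empty sites")
    sor, sim, sne = _multisite_from_array(m.presence)
    return MultisiteBeta(beta_sor=sor, beta_sim=sim, beta_sne=sne, n_sites=m.n_sites)


def beta_sample(
    m: IncidenceMatrix,
    subset_size: int = 10,
    n_reps: int = 1000,
    seed: int | None = None,
    drop_empty: bool = False,
) -> BetaSampleDistribution:
    """Recompute the multiple-site triple for ``n_reps`` random site subsets.

    Each replicate draws ``subset_size`` sites without replacement,
    independently of other replicates. Deterministic for a fixed ``seed``.
    """
    m = _require_non_empty(m, drop_empty)
    if subset_size < 2:
        raise ValueError("subset_size must be at least 2")
    if subset_size > m.n_sites:
        raise ValueError(f"subset_size {subset_size} exceeds available sites {m.n_sites}")
    if n_reps < 1:
        raise ValueError("n_reps must be positive")
    seed = 0 if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    x = m.presence
    out = np.empty((n_reps, 3))
    for r in range(n_reps):
        idx = rng.choice(m.n_sites, size=subset_size, replace=False)
        out[r] = _multisite_from_array(x[idx])
    draws = pd.DataFrame(out, columns=list(_COMPONENTS))
    summary = pd.DataFrame({"mean": draws.mean(), "sd": draws.std(ddof=1)})
    return BetaSampleDistribution(
        subset_size=subset_size, n_reps=n_reps, seed=seed, draws=draws, summary=summary
    )


def distribution_difference(
    d1: BetaSampleDistribution, d2: BetaSampleDistribution, component: str
) -> DistributionComparison:
    """Compare two resampling distributions of one component.

    Returns P(X > Y) over all cross pairs (ties split 0.5), each
    distribution's 2.5%/97.5% quantiles, and whether those 95% intervals
    overlap. Identical distributions give exactly 0.5.
    """
    x = d1.component(component)
    y = d2.component(component)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both distributions must be non-empty")
    ys = np.sort(y)
    n_less = np.searchsorted(ys, x, side="left")       # y < x
    n_leq = np.searchsorted(ys, x, side="right")       # y <= x
    prob = float((n_less + 0.5 * (n_leq - n_less)).sum() / (len(x) * len(y)))
    q1 = tuple(float(v) for v in np.quantile(x, (0.025, 0.975)))
    q2 = tuple(float(v) for v in np.quantile(y, (0.025, 0.975)))
    overlap = (q1[0] <= q2[1]) and (q2[0] <= q1[1])
    return DistributionComparison(
        component=component,
        prob_greater=prob,
        quantiles_1=q1,
        quantiles_2=q2,
        intervals_overlap=bool(overlap),
    )
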