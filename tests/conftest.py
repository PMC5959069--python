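import itertools

import numpy as np
import pandas as pd
import pytest

from galldiv import IncidenceMatrix, SiteHierarchy, SyntheticConfig, simulate_metacommunity


def matrix_from_sets(sets: dict[str, set[str]]) -> IncidenceMatrix:
    """Build an incidence matrix from {site: species set} (test convenience)."""
    species = []
    for s in sets.values():
        for sp in sorted(s):
            if sp not in species:
                species.append(sp)
    df = pd.DataFrame(0, index=list(sets), columns=species, dtype=int)
    for site, sps in sets.items():
        for sp in sps:
            df.loc[site, sp] = 1
    return IncidenceMatrix(df)


def random_incidence(rng: np.random.Generator, n_sites: int, n_species: int, p: float = 0.45):
    """Random binary matrix with no empty site and no all-zero species."""
    while True:
        x = (rng.random((n_sites, n_species)) < p).astype(int)
        if (x.sum(axis=1) > 0).all() and (x.sum(axis=0) > 0).all():
            return IncidenceMatrix(
                pd.DataFrame(
                    x,
                    index=[f"s{i}" for i in range(n_sites)],
                    columns=[f"sp{j}" for j in range(n_species)],
                )
            )


# ---------------------------------------------------------------------------
# independent brute-force oracles (set-based, no shared code with the package)
# ---------------------------------------------------------------------------


def site_sets(m: IncidenceMatrix) -> list[set[str]]:
    return [set(m.site_set(s)) for s in m.site_ids]


def brute_pairwise(si: set, sj: set) -> tuple[float, float, float]:
    a = len(si & sj)
    b = len(si - sj)
    c = len(sj - si)
    if b + c == 0:
        return 0.0, 0.0, 0.0
    sor = (b + c) / (2 * a + b + c)
    sim = min(b, c) / (a + min(b, c))
    return sor, sim, sor - sim


def brute_multisite(sets: list[set]) -> tuple[float, float, float]:
    sum_min = sum_max = 0
    for si, sj in itertools.combinations(sets, 2):
        bij, bji = len(si - sj), len(sj - si)
        sum_min += min(bij, bji)
        sum_max += max(bij, bji)
    k = sum(len(s) for s in sets) - len(set().union(*sets))
    if sum_min + sum_max == 0:
        return 0.0, 0.0, 0.0
    sim = sum_min / (sum_min + k)
    sor = (sum_min + sum_max) / (2 * k + sum_min + sum_max)
    return sor, sim, sor - sim


# ---------------------------------------------------------------------------
# shared fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def toy_two_sites():
    """A = {1,2,3}, B = {2,3,4,5}: the worked pairwise example."""
    return matrix_from_sets({"A": {"1", "2", "3"}, "B": {"2", "3", "4", "5"}})


@pytest.fixture
def toy_partition():
    """2 mountains x 2 plots: M1 = {1,2},{2,3}; M2 = {4,5},{5,6}."""
    m = matrix_from_sets(
        {
            "P1": {"1", "2"},
            "P2": {"2", "3"},
            "P3": {"4", "5"},
            "P4": {"5", "6"},
        }
    )
    h = SiteHierarchy(
        ("plot", "mountain"),
        pd.DataFrame(
            {"plot": ["P1", "P2", "P3", "P4"], "mountain": ["M1", "M1", "M2", "M2"]},
            index=["P1", "P2", "P3", "P4"],
        ),
    )
    return m, h


@pytest.fixture(scope="session")
def small_sim():
    """A reduced survey (2 ranges x (2,2) mountains x 4 plots) for fast tests."""
    cfg = SyntheticConfig(
        n_ranges=2,
        n_mountains_per_range=(2, 2),
        n_plots_per_mountain=4,
        individuals_per_plot=60,
        plant_pool_size=120,
        turnover_weight=0.7,
        seed=11,
    )
    return simulate_metacommunity(cfg)


@pytest.fixture(scope="session")
def study_sim():
    """One realization at the full bundled study design (110 plots)."""
    return simulate_metacommunity(SyntheticConfig(seed=5))
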