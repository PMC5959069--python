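"""Synthetic metacommunity generator for plant and gall incidence data.

The generator emulates a nested mountain-survey design: ``n_ranges``
mountain ranges, a fixed number of mountains per range, ``n_plots_per_mountain``
plots per mountain positioned along a within-mountain (altitudinal)
gradient, and a standardized census of ``individuals_per_plot`` woody
plant individuals per plot. The defaults mirror a two-range, 11-mountain,
110-plot survey of 100 individuals per plot.

Community structure mixes the two mechanisms that generate β-diversity:

* a fraction ``turnover_weight`` (w) of the plant pool assembles by
  **range-limited turnover**: these species sit on a 1-D gradient, each
  mountain occupies a contiguous block of it (mountains of a range are
  adjacent, so neighbours share species; block overlap shrinks as w grows),
  and within a mountain the block is tiled into contiguous windows so that
  adjacent plots replace species;
* the remaining fraction (1 − w) assembles by **strict nested loss**:
  species are ranked once, and a plot with capacity k holds exactly ranks
  1…k, with capacity declining along the gradient — species-poor plots are
  perfect subsets of species-rich ones.

Realized incidence then passes through a sampling filter: each plot's
individuals are drawn multinomially from a geometric-series (Motomura)
relative-abundance distribution over the locally available species, so rare
species can go undetected. ``exhaustive=True`` disables this filter (and
gall detection noise), which makes the forced limiting cases exact:
w = 1 gives equal-richness plots with all pairwise b = c (β_SNE = 0) and
w = 0 gives strict subset chains (β_SIM = 0).

Each plant species carries a Poisson(``gall_rate``) number of strictly
monophagous gall morphotypes (one host species each, the morphotype-on-host
operational species concept); a gall is recorded in a plot with probability
``gall_detection`` wherever its host was recorded.

Everything is reproducible bitwise from ``seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beta_multisite import multisite_beta
from .core_io import IncidenceMatrix, SiteHierarchy

__all__ = ["SyntheticConfig", "SyntheticTruth", "simulate_metacommunity", "recovery_curve"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults reproduce the bundled study design."""

    n_ranges: int = 2
    n_mountains_per_range: tuple[int, ...] | int = (7, 4)
    n_plots_per_mountain: int = 10
    individuals_per_plot: int = 100
    plant_pool_size: int = 600
    turnover_weight: float = 0.9
    gall_rate: float = 0.7
    gall_detection: float = 0.8
    abundance_shape: float = 0.25
    plots_per_window: int = 2
    exhaustive: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        mpr = self.n_mountains_per_range
        if isinstance(mpr, int):
            mpr = (mpr,) * self.n_ranges
        mpr = tuple(int(v) for v in mpr)
        if len(mpr) != self.n_ranges:
            raise ValueError("n_mountains_per_range length must equal n_ranges")
        object.__setattr__(self, "n_mountains_per_range", mpr)
        for name in (
            "n_ranges",
            "n_plots_per_mountain",
            "individuals_per_plot",
            "plant_pool_size",
            "plots_per_window",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if any(v < 1 for v in mpr):
            raise ValueError("each range needs at least one mountain")
        if not 0.0 <= self.turnover_weight <= 1.0:
            raise ValueError("turnover_weight must be in [0, 1]")
        if not 0.0 < self.gall_detection <= 1.0:
            raise ValueError("gall_detection must be in (0, 1]")
        if not 0.0 < self.abundance_shape < 1.0:
            raise ValueError("abundance_shape must be in (0, 1)")
        if self.gall_rate < 0:
            raise ValueError("gall_rate must be non-negative")

    @property
    def n_mountains(self) -> int:
        return sum(self.n_mountains_per_range)

    @property
    def n_plots(self) -> int:
        return self.n_mountains * self.n_plots_per_mountain


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth retained for parameter-recovery tests.

    ``species_rules`` records, per plant pool species, its assembly
    mechanism (turnover/nested) and either its gradient index or nested
    rank; ``mountain_blocks`` gives each mountain's (start, length) slice of
    the turnover gradient; ``host_of_gall`` maps each gall morphotype to its
    single host species.
    """

    config: SyntheticConfig
    species_rules: pd.DataFrame
    mountain_blocks: dict[str, tuple[int, int]]
    host_of_gall: dict[str, str]

    def to_json(self, path) -> None:
        payload = {
            "config": {
                **dataclasses.asdict(self.config),
                "n_mountains_per_range": list(self.config.n_mountains_per_range),
            },
            "species_rules": self.species_rules.to_dict(orient="list"),
            "mountain_blocks": {k: list(v) for k, v in self.mountain_blocks.items()},
            "host_of_gall": self.host_of_gall,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _mountain_blocks(n_turn: int, n_mountains: int, w: float) -> list[tuple[int, int]]:
    """(start, length) of each mountain's contiguous turnover-gradient block.

    Blocks are evenly spaced; their overlap shrinks as w grows (at w = 1
    they tile the gradient almost disjointly, at small w they nearly
    coincide), so mountains share a pool fraction controlled implicitly by w.
    """
    if n_turn == 0:
        return [(0, 0)] * n_mountains
    if n_mountains == 1:
        return [(0, n_turn)]
    length = max(1, int(round(n_turn / (1.0 + (n_mountains - 1) * w))))
    span = n_turn - length
    return [(int(round(m * span / (n_mountains - 1))), length) for m in range(n_mountains)]


def _interleave(groups: list[list[int]]) -> list[int]:
    """Merge ordered groups by even spacing, preserving within-group order."""
    keyed: list[tuple[float, int, int]] = []
    for g, members in enumerate(groups):
        n = len(members)
        for i, sp in enumerate(members):
            keyed.append(((i + 0.5) / n, g, sp))
    return [sp for _, _, sp in sorted(keyed)]


def simulate_metacommunity(
    cfg: SyntheticConfig,
) -> tuple[IncidenceMatrix, IncidenceMatrix, SiteHierarchy, SyntheticTruth]:
    """Generate (plants, galls, hierarchy, truth) for one survey realization."""
    rng = np.random.default_rng(cfg.seed)
    p_pool = cfg.plant_pool_size
    n_turn = int(round(cfg.turnover_weight * p_pool))
    n_nest = p_pool - n_turn
    n_plots = cfg.n_plots_per_mountain
    n_windows = -(-n_plots // cfg.plots_per_window)  # ceil

    # mountain / plot / range labels
    mountains: list[str] = []
    ranges_of: dict[str, str] = {}
    for r, n_m in enumerate(cfg.n_mountains_per_range):
        for m in range(n_m):
            lab = f"R{r + 1}M{m + 1:02d}"
            mountains.append(lab)
            ranges_of[lab] = f"R{r + 1}"

    blocks = _mountain_blocks(n_turn, cfg.n_mountains, cfg.turnover_weight)
    q = blocks[0][1] // n_windows if n_turn else 0
    if n_turn and q == 0:
        raise ValueError(
            "plant_pool_size too small: each gradient window would hold no species; "
            "increase plant_pool_size or lower n_plots_per_mountain"
        )
    k_min = int(round(n_nest / n_plots)) if n_nest else 0
    if (n_turn == 0 or q == 0) and k_min == 0 and n_nest == 0:
        raise ValueError("plant_pool_size too small for the requested richness structure")

    plant_ids = [f"plant_{i:04d}" for i in range(p_pool)]
    capacities = [int(round(n_nest * (n_plots - t) / n_plots)) for t in range(n_plots)]

    site_labels: list[str] = []
    site_mountain: list[str] = []
    available: list[tuple[list[int], list[int]]] = []  # (turnover ids, nested ids) per plot
    for m_idx, m_lab in enumerate(mountains):
        start, length = blocks[m_idx]
        for t in range(n_plots):
            site_labels.append(f"{m_lab}P{t + 1:02d}")
            site_mountain.append(m_lab)
            j = t // cfg.plots_per_window
            turn = list(range(start + j * q, start + (j + 1) * q)) if n_turn else []
            nest = [n_turn + r for r in range(capacities[t])]
            if not turn and not nest:
                raise ValueError(
                    "plant_pool_size too small: a plot has no available species"
                )
            available.append((turn, nest))

    # realize plant incidence
    n_sites = len(site_labels)
    plants = np.zeros((n_sites, p_pool), dtype=np.int8)
    s = cfg.abundance_shape
    for i, (turn, nest) in enumerate(available):
        local = _interleave([g for g in (turn, nest) if g])
        if cfg.exhaustive:
            plants[i, local] = 1
            continue
        weights = (1.0 - s) ** np.arange(len(local))
        counts = rng.multinomial(cfg.individuals_per_plot, weights / weights.sum())
        plants[i, np.asarray(local)[counts > 0]] = 1

    # galls: strictly monophagous, Poisson number per host, detection filter
    galls_per_host = rng.poisson(cfg.gall_rate, size=p_pool)
    gall_ids: list[str] = []
    gall_host_idx: list[int] = []
    host_of_gall: dict[str, str] = {}
    for h in range(p_pool):
        for k in range(galls_per_host[h]):
            gid = f"gall_{h:04d}_{k}"
            gall_ids.append(gid)
            gall_host_idx.append(h)
            host_of_gall[gid] = plant_ids[h]
    if not gall_ids:
        raise ValueError("gall_rate too low: no gall species were generated")
    host_presence = plants[:, gall_host_idx].astype(bool)
    if cfg.exhaustive or cfg.gall_detection >= 1.0:
        galls = host_presence.astype(np.int8)
    else:
        detected = rng.random(host_presence.shape) < cfg.gall_detection
        galls = (host_presence & detected).astype(np.int8)

    plants_df = pd.DataFrame(plants, index=site_labels, columns=plant_ids)
    plants_df = plants_df.loc[:, plants_df.sum(axis=0) > 0]
    galls_df = pd.DataFrame(galls, index=site_labels, columns=gall_ids)
    galls_df = galls_df.loc[:, galls_df.sum(axis=0) > 0]
    if galls_df.shape[1] == 0:
        raise ValueError("no gall species was ever detected; raise gall_detection")

    hierarchy = SiteHierarchy(
        ("plot", "mountain", "range"),
        pd.DataFrame(
            {
                "plot": site_labels,
                "mountain": site_mountain,
                "range": [ranges_of[m] for m in site_mountain],
            },
            index=site_labels,
        ),
    )

    mechanism = ["turnover"] * n_turn + ["nested"] * n_nest
    rules = pd.DataFrame(
        {
            "species": plant_ids,
            "mechanism": mechanism,
            "gradient_index": [i if i < n_turn else -1 for i in range(p_pool)],
            "nested_rank": [i - n_turn if i >= n_turn else -1 for i in range(p_pool)],
        }
    )
    truth = SyntheticTruth(
        config=cfg,
        species_rules=rules,
        mountain_blocks={m: blocks[i] for i, m in enumerate(mountains)},
        host_of_gall=host_of_gall,
    )
    return (
        IncidenceMatrix(plants_df),
        IncidenceMatrix(galls_df),
        hierarchy,
        truth,
    )


def turnover_share(m: IncidenceMatrix) -> float:
    """β_SIM / β_SOR over all sites; 0 when β_SOR = 0 (identical sites)."""
    beta = multisite_beta(m, drop_empty=True)
    return beta.beta_sim / beta.beta_sor if beta.beta_sor > 0 else 0.0


def recovery_curve(
    w_values,
    n_seeds: int = 10,
    base: SyntheticConfig | None = None,
) -> pd.DataFrame:
    """Mean ± sd of the turnover share β_SIM/β_SOR across seeds, per w.

    Runs the generator and the multiple-site decomposition for every
    combination of ``w_values`` and ``n_seeds`` replicate seeds (derived
    deterministically from ``base.seed``), for plants and galls. The share
    should rise from 0 (pure nested loss) to 1 (pure turnover) with w.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be positive")
    base = base if base is not None else SyntheticConfig()
    rows = []
    for w in w_values:
        shares = {"plants": [], "galls": []}
        for j in range(n_seeds):
            seed = (base.seed * 100003 + int(round(1000 * w)) * 1009 + j) % (2**31)
            cfg = dataclasses.replace(base, turnover_weight=float(w), seed=seed)
            plants, galls, _, _ = simulate_metacommunity(cfg)
            shares["plants"].append(turnover_share(plants))
            shares["galls"].append(turnover_share(galls))
        for community in ("plants", "galls"):
            arr = np.array(shares[community])
            rows.append(
                {
                    "w": float(w),
                    "community": community,
                    "mean_share": float(arr.mean()),
                    "sd_share": float(arr.std(ddof=1)) if n_seeds > 1 else 0.0,
                    "n_seeds": n_seeds,
                }
            )
    return pd.DataFrame(rows)
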