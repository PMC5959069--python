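"""Additive partitioning of regional richness across nested spatial scales.

Regional richness γ is split into components that share species units:

    γ = α_1 + β_1 + β_2 + … + β_K

where α_1 is the mean richness of the lowest-level units (plots), each
β_l = α_{l+1} − α_l is the richness added between units of level *l*, and
the top β is γ − α_top. α at a level is the mean richness of that level's
units, a unit's richness being the richness of the union of its member
sites. All components can therefore be read as numbers of species, or as
percentages of γ.

Significance is assessed by sample-based randomization: member units are
permuted among parent units (unit sizes fixed) and the partition recomputed,
yielding a null distribution and a two-tailed Monte-Carlo p-value per
component. Because each plot keeps its own species list under every
permutation, α_1 is invariant under the null (its null variance is 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import IncidenceMatrix, SiteHierarchy

__all__ = ["AdditivePartition", "additive_partition", "partition_significance"]


@dataclass(frozen=True)
class AdditivePartition:
    """Hierarchical α/β components in species units and as % of γ.

    ``components`` has one row per component, ordered α_1, β_1, …, β_K, with
    columns: level, species_units, percent, and (after a significance run)
    expected, expected_percent, p_value. ``alphas`` holds α_l per level
    (species units).
    """

    level_names: tuple[str, ...]
    gamma: int
    alphas: dict[str, float]
    components: pd.DataFrame
    n_null: int = 0
    seed: int | None = None

    @property
    def species_units(self) -> pd.Series:
        return self.components["species_units"]

    @property
    def percent(self) -> pd.Series:
        return self.components["percent"]


def _unit_richness(x: np.ndarray, groups: np.ndarray, n_units: int) -> np.ndarray:
    """Richness of the union of member rows for each of ``n_units`` groups."""
    out = np.empty(n_units, dtype=np.int64)
    for u in range(n_units):
        out[u] = int((x[groups == u].any(axis=0)).sum()) if (groups == u).any() else 0
    return out


def _alphas_from_codes(x: np.ndarray, codes: list[np.ndarray], n_units: list[int]) -> list[float]:
    """Mean unit richness per level; codes[l] maps sites to level-l units."""
    return [
        float(_unit_richness(x, codes[l], n_units[l]).mean()) for l in range(len(codes))
    ]


def _component_frame(levels, alphas, gamma) -> pd.DataFrame:
    names = [f"alpha_{levels[0]}"] + [f"beta_{lv}" for lv in levels]
    values = [alphas[0]]
    for l in range(len(levels) - 1):
        values.append(alphas[l + 1] - alphas[l])
    values.append(gamma - alphas[-1])
    comp = pd.DataFrame(
        {
            "level": [levels[0]] + list(levels),
            "species_units": values,
            "percent": [100.0 * v / gamma for v in values],
        },
        index=names,
    )
    return comp


def additive_partition(m: IncidenceMatrix, h: SiteHierarchy) -> AdditivePartition:
    """Observed additive partition of γ across the hierarchy's levels.

    Satisfies α_{l+1} = α_l + β_l and α_1 + Σ β_l = γ exactly in species
    units; percentages sum to 100.
    """
    h.validate_against(m)
    x = m.presence.astype(bool)
    codes, n_units = _site_codes(m, h)
    alphas = _alphas_from_codes(x, codes, n_units)
    comp = _component_frame(h.levels, alphas, m.gamma)
    return AdditivePartition(
        level_names=h.levels,
        gamma=m.gamma,
        alphas=dict(zip(h.levels, alphas)),
        components=comp,
    )


def _site_codes(m: IncidenceMatrix, h: SiteHierarchy) -> tuple[list[np.ndarray], list[int]]:
    """Integer unit codes per level, aligned to the incidence site order."""
    assign = h.assignment.loc[m.site_ids]
    codes, n_units = [], []
    for lv in h.levels:
        labels = assign[lv]
        uniq = list(dict.fromkeys(labels))
        mapping = {u: i for i, u in enumerate(uniq)}
        codes.append(np.array([mapping[v] for v in labels]))
        n_units.append(len(uniq))
    return codes, n_units


def partition_significance(
    m: IncidenceMatrix,
    h: SiteHierarchy,
    n_null: int = 999,
    seed: int | None = None,
    mode: str = "sample_based",
) -> AdditivePartition:
    """Additive partition with randomization-based expectations and p-values.

    The null permutes, at each level transition, the assignment of child
    units to parent units while keeping the number of children per parent
    fixed (sample-based randomization for presence/absence plot data). The
    two-tailed Monte-Carlo p-value with add-one correction is

        p = min(1, 2 (1 + #{null at least as extreme as observed,
                           in the deviation's direction}) / (n_null + 1)),

    so the minimum attainable value is 2 / (n_null + 1). A component whose
    null distribution is degenerate (no permutation can move it) reports
    p = 1 with a warning.
    """
    if mode != "sample_based":
        raise ValueError("only the sample-based null model is implemented")
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    h.validate_against(m)
    observed = additive_partition(m, h)
    x = m.presence.astype(bool)
    levels = h.levels
    k = len(levels)
    rng = np.random.default_rng(seed)

    # parent structure: child_parent[t] maps level-t unit code -> level-(t+1) unit code
    codes, n_units = _site_codes(m, h)
    child_parent: list[np.ndarray] = []
    for t in range(k - 1):
        cp = np.full(n_units[t], -1, dtype=np.int64)
        cp[codes[t]] = codes[t + 1]
        child_parent.append(cp)
        if n_units[t + 1] <= 1:
            warnings.warn(
                f"level {levels[t + 1]!r} has a single unit; permuting "
                f"{levels[t]!r} units among its parents is a no-op",
                stacklevel=2,
            )

    comp_names = list(observed.components.index)
    null = np.empty((n_null, len(comp_names)))
    for d in range(n_null):
        # permute child->parent assignments independently per transition
        perms = [cp[rng.permutation(len(cp))] for cp in child_parent]
        draw_codes = [codes[0]]
        for t in range(k - 1):
            draw_codes.append(perms[t][draw_codes[t]])
        alphas = _alphas_from_codes(x, draw_codes, n_units)
        comp = [alphas[0]]
        comp += [alphas[t + 1] - alphas[t] for t in range(k - 1)]
        comp.append(observed.gamma - alphas[-1])
        null[d] = comp

    obs = observed.components["species_units"].to_numpy()
    expected = null.mean(axis=0)
    p = np.ones(len(comp_names))
    degenerate = np.ptp(null, axis=0) == 0
    for idx in range(len(comp_names)):
        if degenerate[idx] and np.isclose(null[0, idx], obs[idx]):
            p[idx] = 1.0
            continue
        if obs[idx] >= expected[idx]:
            extreme = int((null[:, idx] >= obs[idx]).sum())
        else:
            extreme = int((null[:, idx] <= obs[idx]).sum())
        p[idx] = min(1.0, 2.0 * (1 + extreme) / (n_null + 1))

    comp = observed.components.copy()
    comp["expected"] = expected
    comp["expected_percent"] = 100.0 * expected / observed.gamma
    comp["p_value"] = p
    return AdditivePartition(
        level_names=levels,
        gamma=observed.gamma,
        alphas=observed.alphas,
        components=comp,
        n_null=n_null,
        seed=seed,
    )
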