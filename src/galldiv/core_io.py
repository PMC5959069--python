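"""Incidence matrices, site hierarchies, and their tabular readers/writers.

The central container is :class:`IncidenceMatrix`, a validated binary
site × species presence/absence table. Sampling designs with nested units
(plot within mountain within mountain range) are described by
:class:`SiteHierarchy`. Everything downstream — pairwise and multiple-site
dissimilarities, additive diversity partitions, regressions, clustering —
consumes these two objects.

Conventions
-----------
* Sites and species are indexed in order of first appearance in the input;
  runs over the same input are therefore reproducible.
* Species labels are matched exactly after trimming surrounding whitespace;
  there is no fuzzy taxon matching (silent merges corrupt richness counts).
* A species column that is all zeros is rejected at construction (a species
  must occur somewhere); readers drop such columns before construction and
  record them.
* Sites with zero recorded species are accepted and flagged
  (:attr:`IncidenceMatrix.empty_sites`); dissimilarity computations reject
  them unless asked to drop them, because 0/0 dissimilarities are undefined.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IncidenceFormatError",
    "HierarchyError",
    "EmptySiteError",
    "IncidenceMatrix",
    "SiteHierarchy",
    "RichnessSummary",
    "read_incidence",
    "read_incidence_workbook",
    "write_incidence",
    "read_hierarchy",
    "write_hierarchy",
    "aggregate_incidence",
    "richness_summary",
]


class IncidenceFormatError(ValueError):
    """Malformed incidence input (non-binary cell, duplicate labels, empty file)."""


class HierarchyError(ValueError):
    """Inconsistent site hierarchy (broken nesting, site mismatch, unknown level)."""


class EmptySiteError(ValueError):
    """A site with zero recorded species reached a computation that forbids it."""


def _dedup_order(labels: Iterable[str]) -> list[str]:
    seen: dict[str, None] = {}
    for lab in labels:
        seen.setdefault(lab, None)
    return list(seen)


@dataclass(frozen=True)
class IncidenceMatrix:
    """Binary site × species occurrence table.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are sites, columns are species, entries 0/1 (1 = recorded).
        Validated at construction: entries binary, labels unique, no
        all-zero species column.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise IncidenceFormatError("incidence matrix has no sites or no species")
        if df.index.duplicated().any():
            dups = sorted(set(df.index[df.index.duplicated()]))
            raise IncidenceFormatError(f"duplicate site labels: {dups}")
        if df.columns.duplicated().any():
            dups = sorted(set(df.columns[df.columns.duplicated()]))
            raise IncidenceFormatError(f"duplicate species labels: {dups}")
        values = df.to_numpy()
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise IncidenceFormatError(
                f"non-binary cell {values[i, j]!r} at site {df.index[i]!r}, "
                f"species {df.columns[j]!r}"
            )
        absent = df.columns[values.sum(axis=0) == 0]
        if len(absent):
            raise IncidenceFormatError(
                f"species recorded nowhere: {list(absent)}; drop them before construction"
            )
        object.__setattr__(self, "data", df.astype(np.int8))

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_occurrences(
        cls, occurrences: Iterable[tuple[str, str]], sites: Sequence[str] | None = None
    ) -> "IncidenceMatrix":
        """Build from (site, species) pairs; duplicates collapse to one record.

        ``sites`` optionally fixes the site set and order (allowing sites with
        no occurrences, which are kept and flagged as empty).
        """
        pairs = [(str(s).strip(), str(sp).strip()) for s, sp in occurrences]
        if not pairs and sites is None:
            raise IncidenceFormatError("no occurrences given")
        site_order = list(sites) if sites is not None else _dedup_order(s for s, _ in pairs)
        sp_order = _dedup_order(sp for _, sp in pairs)
        df = pd.DataFrame(0, index=site_order, columns=sp_order, dtype=np.int8)
        for s, sp in pairs:
            if s not in df.index:
                raise IncidenceFormatError(f"occurrence for unknown site {s!r}")
            df.loc[s, sp] = 1
        return cls(df)

    # -- basic queries ------------------------------------------------------

    @property
    def site_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_sites(self) -> int:
        return self.data.shape[0]

    @property
    def n_species(self) -> int:
        return self.data.shape[1]

    @property
    def presence(self) -> np.ndarray:
        """The 0/1 matrix as an int8 array (sites × species)."""
        return self.data.to_numpy()

    @property
    def richness(self) -> pd.Series:
        """Per-site species richness S_i (row sums)."""
        return self.data.sum(axis=1).rename("richness")

    @property
    def gamma(self) -> int:
        """Regional richness S_T: number of species occurring in ≥1 site."""
        return int((self.data.to_numpy().sum(axis=0) > 0).sum())

    @property
    def empty_sites(self) -> list[str]:
        """Sites with zero recorded species (accepted but flagged)."""
        r = self.richness
        return list(r.index[r == 0])

    def site_set(self, site: str) -> frozenset[str]:
        """The set of species recorded at ``site``."""
        row = self.data.loc[site]
        return frozenset(row.index[row == 1])

    def select_sites(self, sites: Sequence[str]) -> "IncidenceMatrix":
        """Subset to ``sites`` (kept in the given order).

        Species that no longer occur anywhere in the subset are dropped, so
        ``gamma`` reflects the subset.
        """
        missing = [s for s in sites if s not in self.data.index]
        if missing:
            raise KeyError(f"unknown sites: {missing}")
        sub = self.data.loc[list(sites)]
        sub = sub.loc[:, sub.sum(axis=0) > 0]
        if sub.shape[1] == 0:
            raise IncidenceFormatError("selected sites contain no species at all")
        return IncidenceMatrix(sub)

    def drop_empty_sites(self) -> "IncidenceMatrix":
        keep = [s for s in self.site_ids if s not in set(self.empty_sites)]
        return self.select_sites(keep)


@dataclass(frozen=True)
class SiteHierarchy:
    """Nested assignment of sites to units at ordered spatial levels.

    ``levels`` are ordered lowest first (e.g. ``["plot", "mountain",
    "range"]``). ``assignment`` has one row per site and one column per
    level. Nesting must be consistent: a unit at level *k* belongs to exactly
    one unit at level *k+1*. The lowest level has exactly one site per unit.
    """

    levels: tuple[str, ...]
    assignment: pd.DataFrame

    def __post_init__(self) -> None:
        levels = tuple(self.levels)
        object.__setattr__(self, "levels", levels)
        df = self.assignment
        if len(levels) == 0:
            raise HierarchyError("hierarchy needs at least one level")
        if list(df.columns) != list(levels):
            raise HierarchyError(
                f"assignment columns {list(df.columns)} do not match levels {list(levels)}"
            )
        if df.index.duplicated().any():
            raise HierarchyError("duplicate site labels in hierarchy")
        if df.isna().any().any():
            raise HierarchyError("missing unit label in hierarchy")
        low = df[levels[0]]
        if low.duplicated().any():
            dups = sorted(set(low[low.duplicated()]))
            raise HierarchyError(f"lowest level must have one site per unit; shared: {dups}")
        for child, parent in zip(levels[:-1], levels[1:]):
            n_parents = df.groupby(child, sort=False)[parent].nunique()
            bad = n_parents[n_parents > 1]
            if len(bad):
                raise HierarchyError(
                    f"inconsistent nesting: {child} unit(s) {list(bad.index)} "
                    f"belong to more than one {parent}"
                )
        object.__setattr__(self, "assignment", df.astype(str))

    @property
    def site_ids(self) -> list[str]:
        return list(self.assignment.index)

    def units(self, level: str) -> list[str]:
        """Unit labels at ``level``, in first-appearance order."""
        self._check_level(level)
        return _dedup_order(self.assignment[level])

    def members(self, level: str) -> dict[str, list[str]]:
        """Mapping unit label -> member site labels at ``level``."""
        self._check_level(level)
        out: dict[str, list[str]] = {u: [] for u in self.units(level)}
        for site, unit in self.assignment[level].items():
            out[unit].append(site)
        return out

    def parent_map(self, level: str) -> dict[str, str]:
        """Mapping from units at ``level`` to their parent unit one level up."""
        self._check_level(level)
        i = self.levels.index(level)
        if i == len(self.levels) - 1:
            raise HierarchyError(f"{level!r} is the top level; it has no parent")
        child, parent = self.levels[i], self.levels[i + 1]
        return dict(
            self.assignment.groupby(child, sort=False)[parent].first()
        )

    def subset(self, sites: Sequence[str]) -> "SiteHierarchy":
        missing = [s for s in sites if s not in self.assignment.index]
        if missing:
            raise HierarchyError(f"sites absent from hierarchy: {missing}")
        return SiteHierarchy(self.levels, self.assignment.loc[list(sites)])

    def with_assignment(self, assignment: pd.DataFrame) -> "SiteHierarchy":
        return SiteHierarchy(self.levels, assignment)

    def _check_level(self, level: str) -> None:
        if level not in self.levels:
            raise HierarchyError(f"unknown level {level!r}; levels are {list(self.levels)}")

    def validate_against(self, m: IncidenceMatrix) -> None:
        """Raise if the hierarchy and incidence matrix cover different sites."""
        h_sites, m_sites = set(self.site_ids), set(m.site_ids)
        only_h = sorted(h_sites - m_sites)
        only_m = sorted(m_sites - h_sites)
        if only_h or only_m:
            raise HierarchyError(
                f"site mismatch: only in hierarchy {only_h[:5]}, only in incidence {only_m[:5]}"
            )


@dataclass(frozen=True)
class RichnessSummary:
    """Per-site richness S_i, regional richness γ, and mean α."""

    per_site_richness: pd.Series
    gamma: int
    mean_alpha: float


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _detect_sep(source, sep: str | None) -> str:
    if sep is not None:
        return sep
    if isinstance(source, (str, pathlib.Path)):
        return "\t" if str(source).endswith((".tsv", ".tab")) else ","
    return ","


def read_incidence(source, layout: str = "wide", sep: str | None = None) -> IncidenceMatrix:
    """Read a presence/absence table from delimited text.

    ``layout="wide"``: first column holds site labels, remaining columns are
    species with 0/1 cells. ``layout="long"``: two columns (site, species),
    one row per occurrence; duplicates collapse. Both layouts expect a header
    row. The delimiter is auto-detected from the extension (``.tsv`` → tab,
    otherwise comma) unless ``sep`` is given.
    """
    delimiter = _detect_sep(source, sep)
    try:
        df = pd.read_csv(source, sep=delimiter, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise IncidenceFormatError(f"empty incidence file: {source!r}") from exc
    if df.shape[0] == 0:
        raise IncidenceFormatError(f"incidence file has a header but no rows: {source!r}")
    return incidence_from_frame(df, layout=layout)


def incidence_from_frame(df: pd.DataFrame, layout: str = "wide") -> IncidenceMatrix:
    """Build an :class:`IncidenceMatrix` from an already-loaded raw table."""
    if layout == "long":
        if df.shape[1] < 2:
            raise IncidenceFormatError("long layout needs two columns (site, species)")
        pairs = list(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
        return IncidenceMatrix.from_occurrences(pairs)
    if layout != "wide":
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    sites = df.iloc[:, 0].astype(str).str.strip()
    sites.name = None
    body = df.iloc[:, 1:].copy()
    body.columns = [str(c).strip() for c in body.columns]
    body.index = sites
    if sites.duplicated().any():
        dups = sorted(set(sites[sites.duplicated()]))
        raise IncidenceFormatError(f"duplicate site row labels: {dups}")
    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | ~numeric.isin((0, 1))
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise IncidenceFormatError(
            f"non-binary cell {body.iat[i, j]!r} at row {body.index[i]!r}, "
            f"column {body.columns[j]!r}"
        )
    numeric = numeric.astype(np.int8)
    numeric = numeric.loc[:, numeric.sum(axis=0) > 0]  # species must occur somewhere
    if numeric.shape[1] == 0:
        raise IncidenceFormatError("no species occurs at any site")
    return IncidenceMatrix(numeric)


def read_incidence_workbook(
    path,
    sheet: int | str = 0,
    layout: str = "wide",
    site_col: str | int = 0,
    species_col: str | int | None = None,
    drop_cols: Sequence[str] = (),
    header_row: int = 0,
) -> IncidenceMatrix:
    """Read an incidence table from a spreadsheet workbook (first sheet by default).

    The column mapping is configurable because deposited supplementary
    workbooks carry extra columns (richness totals, coordinates) next to the
    occurrence data: ``site_col`` names or indexes the site-label column,
    ``drop_cols`` removes pass-through columns (e.g. latitude/longitude),
    and for ``layout="long"`` ``species_col`` names the species column.
    """
    df = pd.read_excel(path, sheet_name=sheet, header=header_row)
    df = df.drop(columns=[c for c in drop_cols if c in df.columns])
    site = df.columns[site_col] if isinstance(site_col, int) else site_col
    if layout == "long":
        if species_col is None:
            raise ValueError("layout='long' requires species_col")
        sp = df.columns[species_col] if isinstance(species_col, int) else species_col
        return incidence_from_frame(df[[site, sp]], layout="long")
    cols = [site] + [c for c in df.columns if c != site]
    return incidence_from_frame(df[cols], layout="wide")


def write_incidence(m: IncidenceMatrix, path, layout: str = "wide", sep: str | None = None) -> None:
    """Write to delimited text in either layout; round-trips exactly."""
    delimiter = _detect_sep(path, sep)
    if layout == "wide":
        out = m.data.copy()
        out.insert(0, "site", out.index)
        out.to_csv(path, sep=delimiter, index=False)
    elif layout == "long":
        rows = [
            {"site": s, "species": sp}
            for s in m.site_ids
            for sp in m.species_ids
            if m.data.at[s, sp] == 1
        ]
        pd.DataFrame(rows, columns=["site", "species"]).to_csv(path, sep=delimiter, index=False)
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")


def read_hierarchy(source, sep: str | None = None) -> SiteHierarchy:
    """Read a site-hierarchy table: site label column, then one column per
    level, lowest to highest (header row names the levels)."""
    delimiter = _detect_sep(source, sep)
    try:
        df = pd.read_csv(source, sep=delimiter, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise HierarchyError(f"empty hierarchy file: {source!r}") from exc
    if df.shape[1] < 2:
        raise HierarchyError("hierarchy table needs a site column plus ≥1 level column")
    sites = df.iloc[:, 0].astype(str).str.strip()
    sites.name = None
    body = df.iloc[:, 1:].apply(lambda col: col.astype(str).str.strip())
    body.index = sites
    return SiteHierarchy(tuple(str(c).strip() for c in df.columns[1:]), body)


def write_hierarchy(h: SiteHierarchy, path, sep: str | None = None) -> None:
    delimiter = _detect_sep(path, sep)
    out = h.assignment.copy()
    out.insert(0, "site", out.index)
    out.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def aggregate_incidence(m: IncidenceMatrix, h: SiteHierarchy, level: str) -> IncidenceMatrix:
    """Union (logical OR) of member-site incidences at each unit of ``level``.

    One row per unit, in first-appearance order; γ is preserved.
    """
    h._check_level(level)
    h.validate_against(m)
    members = h.members(level)
    rows = {}
    for unit, sites in members.items():
        rows[unit] = (m.data.loc[sites].to_numpy().sum(axis=0) > 0).astype(np.int8)
    agg = pd.DataFrame.from_dict(rows, orient="index", columns=m.species_ids)
    return IncidenceMatrix(agg.loc[list(members)])


def richness_summary(m: IncidenceMatrix) -> RichnessSummary:
    """S_i per site, regional richness γ, and mean α (average S_i)."""
    r = m.richness
    return RichnessSummary(per_site_richness=r, gamma=m.gamma, mean_alpha=float(r.mean()))
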