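"""Pairwise Sørensen-family dissimilarities and their decomposition.

For two sites with ``a`` shared species, ``b`` exclusive to the first and
``c`` exclusive to the second:

* total dissimilarity (Sørensen)      β_sor = (b + c) / (2a + b + c)
* spatial turnover (Simpson)          β_sim = min(b, c) / (a + min(b, c))
* nestedness-resultant dissimilarity  β_sne = β_sor − β_sim

β_sim captures pure species replacement; β_sne is the extra dissimilarity
due to richness differences between nested assemblages. The three pairwise
site × site matrices feed the average-linkage clustering of turnover and
nestedness structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import EmptySiteError, IncidenceMatrix, _detect_sep

__all__ = [
    "PairComponents",
    "PairwiseBetaMatrices",
    "pair_components",
    "pairwise_beta_matrices",
    "write_square_matrix",
    "read_square_matrix",
]


@dataclass(frozen=True)
class PairComponents:
    """Shared/exclusive species counts for one site pair: a+b = S_first, a+c = S_second."""

    a: int
    b: int
    c: int


@dataclass(frozen=True)
class PairwiseBetaMatrices:
    """Symmetric zero-diagonal site × site matrices with β_sor = β_sim + β_sne."""

    beta_sor: pd.DataFrame
    beta_sim: pd.DataFrame
    beta_sne: pd.DataFrame

    def component(self, name: str) -> pd.DataFrame:
        try:
            return {"sor": self.beta_sor, "sim": self.beta_sim, "sne": self.beta_sne}[
                name.lower().removeprefix("beta_")
            ]
        except KeyError:
            raise KeyError(f"unknown component {name!r}; use beta_sor/beta_sim/beta_sne") from None


def _require_non_empty(m: IncidenceMatrix, drop_empty: bool) -> IncidenceMatrix:
    empties = m.empty_sites
    if not empties:
        return m
    if drop_empty:
        return m.drop_empty_sites()
    raise EmptySiteError(
        f"sites with zero species: {empties}; pass drop_empty=True to exclude them"
    )


def pair_components(m: IncidenceMatrix, i: str, j: str, drop_empty: bool = False) -> PairComponents:
    """Exact set counts (a, b, c) for sites ``i`` and ``j``."""
    if i == j:
        raise ValueError("pair components need two distinct sites")
    for s in (i, j):
        if s not in m.data.index:
            raise KeyError(f"unknown site {s!r}")
        if not drop_empty and m.data.loc[s].sum() == 0:
            raise EmptySiteError(f"site {s!r} has zero species")
    xi = m.data.loc[i].to_numpy()
    xj = m.data.loc[j].to_numpy()
    a = int((xi & xj).sum())
    b = int((xi & ~xj & 1).sum())
    c = int((xj & ~xi & 1).sum())
    return PairComponents(a=a, b=b, c=c)


def pairwise_beta_matrices(m: IncidenceMatrix, drop_empty: bool = False) -> PairwiseBetaMatrices:
    """All three pairwise dissimilarity matrices for every site pair.

    Requires ≥2 non-empty sites. When both ``b = c = 0`` and ``a > 0``
    (identical sites) all three measures are exactly 0.
    """
    m = _require_non_empty(m, drop_empty)
    if m.n_sites < 2:
        raise ValueError("need at least 2 non-empty sites")
    x = m.presence.astype(np.int64)
    shared = x @ x.T                      # a
    s = x.sum(axis=1)
    b = s[:, None] - shared               # exclusive to row site
    c = s[None, :] - shared               # exclusive to column site
    bc_min = np.minimum(b, c)
    with np.errstate(divide="ignore", invalid="ignore"):
        sor = (b + c) / (2 * shared + b + c)
        sim = bc_min / (shared + bc_min)
    # identical non-empty sites: b=c=0, a>0 -> 0/positive already 0; the only
    # 0/0 cases are on the diagonal, which is 0 by definition
    np.fill_diagonal(sor, 0.0)
    np.fill_diagonal(sim, 0.0)
    sne = sor - sim
    idx = m.site_ids
    as_df = lambda v: pd.DataFrame(v, index=idx, columns=idx)
    return PairwiseBetaMatrices(beta_sor=as_df(sor), beta_sim=as_df(sim), beta_sne=as_df(sne))


def write_square_matrix(d: pd.DataFrame, path, sep: str | None = None) -> None:
    """Write a labelled square dissimilarity matrix as delimited text."""
    delimiter = _detect_sep(path, sep)
    out = d.copy()
    out.insert(0, "site", out.index)
    out.to_csv(path, sep=delimiter, index=False)


def read_square_matrix(path, sep: str | None = None) -> pd.DataFrame:
    delimiter = _detect_sep(path, sep)
    df = pd.read_csv(path, sep=delimiter)
    df.index = df.iloc[:, 0].astype(str)
    df = df.iloc[:, 1:]
    df.columns = [str(c) for c in df.columns]
    df.index.name = None
    return df.astype(float)
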