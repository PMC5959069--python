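"""Average-linkage (UPGMA) clustering of dissimilarity matrices.

Unweighted pair-group agglomeration: at each step the two clusters at
minimum distance merge, and the distance from the merged cluster to any
other is the arithmetic mean of all cross-pair dissimilarities (maintained
by size-weighted averaging of the merged members' distances). Node height is
half the merge distance, so the tree is ultrametric: all leaves sit at
height 0 and the cophenetic distance between two leaves is twice their
lowest-common-ancestor height.

Ties in the minimum distance are broken by the lexicographic order of the
clusters' smallest member labels, making trees deterministic across runs
and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TreeNode", "UltrametricTree", "upgma", "tree_to_newick", "plot_dendrogram"]


@dataclass(frozen=True)
class TreeNode:
    """A node of an ultrametric tree; leaves have height 0 and a label."""

    height: float
    children: tuple["TreeNode", ...] = ()
    label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return [lab for ch in self.children for lab in ch.leaf_labels()]


@dataclass(frozen=True)
class UltrametricTree:
    """Result of a UPGMA run.

    ``merges`` lists, in agglomeration order, the two merged clusters (as
    tuples of leaf labels) and the merge height (= half the merge distance).
    ``linkage`` is a scipy-style linkage matrix for plotting.
    """

    root: TreeNode
    leaves: tuple[str, ...]
    merges: tuple[tuple[tuple[str, ...], tuple[str, ...], float], ...]
    linkage: np.ndarray

    def cophenetic(self, a: str, b: str) -> float:
        """Twice the height of the lowest common ancestor of leaves a and b."""
        if a == b:
            return 0.0
        node = self.root
        while True:
            sub = [ch for ch in node.children if a in ch.leaf_labels() and b in ch.leaf_labels()]
            if not sub:
                return 2.0 * node.height
            node = sub[0]


def _as_matrix(d, labels) -> tuple[np.ndarray, list[str]]:
    if isinstance(d, pd.DataFrame):
        labels = [str(c) for c in d.columns]
        if [str(i) for i in d.index] != labels:
            raise ValueError("dissimilarity DataFrame must have matching index and columns")
        return d.to_numpy(dtype=float), labels
    arr = np.asarray(d, dtype=float)
    if labels is None:
        labels = [f"item_{i}" for i in range(arr.shape[0])]
    return arr, list(labels)


def upgma(d, labels=None) -> UltrametricTree:
    """Unweighted average-linkage agglomeration of a dissimilarity matrix.

    ``d`` is a symmetric, zero-diagonal, non-negative square matrix (a
    labelled DataFrame or an array plus ``labels``) with at least 2 items.
    """
    dist, labels = _as_matrix(d, labels)
    n = dist.shape[0]
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    if len(set(labels)) != n:
        raise ValueError("duplicate item labels")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    if (dist < 0).any():
        raise ValueError("dissimilarity matrix must be non-negative")
    if not np.allclose(np.diag(dist), 0.0, atol=1e-12):
        raise ValueError("dissimilarity matrix must have a zero diagonal")

    dist = dist.copy()
    active: dict[int, dict] = {
        i: {"node": TreeNode(0.0, label=labels[i]), "size": 1, "min_label": labels[i], "row": i}
        for i in range(n)
    }
    # rows of `dist` are reused in place; `row` maps cluster id -> matrix row
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []
    linkage_rows = []
    next_id = n
    scipy_id = {i: i for i in range(n)}

    while len(active) > 1:
        ids = sorted(active)
        best = None
        for ii, ci in enumerate(ids):
            for cj in ids[ii + 1 :]:
                dij = dist[active[ci]["row"], active[cj]["row"]]
                la, lb = sorted((active[ci]["min_label"], active[cj]["min_label"]))
                key = (dij, la, lb)
                if best is None or key < best[0]:
                    best = (key, ci, cj)
        (dij, _, _), ci, cj = best
        a, b = active[ci], active[cj]
        # deterministic child order: smaller min-label first
        first, second = (a, b) if a["min_label"] <= b["min_label"] else (b, a)
        height = dij / 2.0
        node = TreeNode(height, children=(first["node"], second["node"]))
        merges.append(
            (tuple(first["node"].leaf_labels()), tuple(second["node"].leaf_labels()), height)
        )
        linkage_rows.append(
            [scipy_id[ci], scipy_id[cj], dij, a["size"] + b["size"]]
        )
        # unweighted average: size-weighted combination of the original means
        ra, rb = a["row"], b["row"]
        new_row = (a["size"] * dist[ra] + b["size"] * dist[rb]) / (a["size"] + b["size"])
        dist[ra] = new_row
        dist[:, ra] = new_row
        dist[ra, ra] = 0.0
        del active[cj]
        del active[ci]
        active[next_id] = {
            "node": node,
            "size": a["size"] + b["size"],
            "min_label": min(a["min_label"], b["min_label"]),
            "row": ra,
        }
        scipy_id[next_id] = n + len(linkage_rows) - 1
        next_id += 1

    root = active[next_id - 1]["node"]
    return UltrametricTree(
        root=root,
        leaves=tuple(labels),
        merges=tuple(merges),
        linkage=np.array(linkage_rows, dtype=float),
    )


_NEWICK_UNSAFE = set(" ()[]:;,'\"\t\n")


def _newick_label(label: str) -> str:
    if any(ch in _NEWICK_UNSAFE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _fmt(x: float) -> str:
    s = f"{x:.10g}"
    if "." not in s and "e" not in s and "inf" not in s and "nan" not in s:
        s += ".0"
    return s


def _newick_node(node: TreeNode, parent_height: float | None) -> str:
    if node.is_leaf:
        body = _newick_label(node.label)
    else:
        body = "(" + ",".join(_newick_node(ch, node.height) for ch in node.children) + ")"
    if parent_height is None:
        return body
    return f"{body}:{_fmt(parent_height - node.height)}"


def tree_to_newick(t: UltrametricTree) -> str:
    """Newick string with branch lengths; labels needing it are quoted."""
    return _newick_node(t.root, None) + ";"


def plot_dendrogram(t: UltrametricTree, path, title: str | None = None) -> None:
    """Dendrogram image of the tree (merge distances on the axis)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster import hierarchy as sch

    fig, ax = plt.subplots(figsize=(max(5, 0.12 * len(t.leaves)), 4))
    sch.dendrogram(t.linkage, labels=list(t.leaves), ax=ax, leaf_font_size=6)
    ax.set_ylabel("dissimilarity")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
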