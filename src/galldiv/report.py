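"""End-to-end analysis pipeline and serialized report bundle.

`run_full_analysis` reproduces the full analysis sequence on any incidence +
hierarchy input: per community (plants, and galls when supplied) and per
site set (all sites, then each top-level unit separately) it computes
richness summaries, the multiple-site β decomposition (full matrix and
subset-resampled), the hierarchical additive partition with randomization
significance, the local–regional richness regression, and UPGMA trees of
the pairwise β_sim and β_sne matrices. Results are written as one
machine-readable JSON summary plus delimited tables, Newick trees, and a
log recording seeds, package versions, and input checksums. Stage failures
are recorded per stage; independent stages still run.

All randomness flows from one master seed, split deterministically per
(community, scope, stage) with a hash, so reruns with the same inputs and
seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .beta_multisite import beta_sample, multisite_beta
from .beta_pairwise import pairwise_beta_matrices, write_square_matrix
from .cluster import tree_to_newick, upgma
from .core_io import (
    IncidenceMatrix,
    SiteHierarchy,
    read_hierarchy,
    read_incidence,
    richness_summary,
)
from .partition import additive_partition, partition_significance
from .regression import local_regional_regression

__all__ = ["AnalysisConfig", "run_full_analysis"]

_STAGES = ("richness", "multibeta", "resample", "partition", "regression", "cluster")


class _Skip(Exception):
    """Internal: a stage precondition is unmet; recorded as skipped."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of one full analysis run."""

    incidence_path: str
    hierarchy_path: str
    galls_path: str | None = None
    subset_size: int = 10
    n_resamples: int = 1000
    n_null: int = 999
    seed: int = 0
    out_dir: str = "galldiv_report"
    drop_empty_sites: bool = False
    stages: tuple[str, ...] = _STAGES
    regional_level: str | None = None  # default: second level of the hierarchy
    make_plots: bool = False

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in _STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {_STAGES}")
        for name in ("subset_size", "n_resamples", "n_null"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


def stage_seed(master: int, tag: str) -> int:
    """Deterministic, order-independent per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master}:{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _partition_payload(part) -> dict:
    comp = part.components
    payload = {
        "gamma": part.gamma,
        "levels": list(part.level_names),
        "alphas": part.alphas,
        "components": {
            name: {
                c: (float(comp.at[name, c]) if c != "level" else comp.at[name, c])
                for c in comp.columns
            }
            for name in comp.index
        },
        "n_null": part.n_null,
        "seed": part.seed,
    }
    return payload


def _analyze_scope(
    m: IncidenceMatrix,
    h: SiteHierarchy,
    cfg: AnalysisConfig,
    community: str,
    scope: str,
    out: pathlib.Path,
) -> dict:
    result: dict = {"n_sites": m.n_sites, "errors": {}}
    tag = f"{community}/{scope}"
    drop = cfg.drop_empty_sites

    if "richness" in cfg.stages:
        try:
            rs = richness_summary(m)
            result["richness"] = {
                "gamma": rs.gamma,
                "mean_alpha": rs.mean_alpha,
                "alpha_percent_of_gamma": 100.0 * rs.mean_alpha / rs.gamma,
                "beta_additive": rs.gamma - rs.mean_alpha,
                "beta_percent_of_gamma": 100.0 * (rs.gamma - rs.mean_alpha) / rs.gamma,
            }
            rs.per_site_richness.rename_axis("site").to_csv(
                out / f"richness_{community}_{scope}.csv"
            )
        except Exception as exc:  # pragma: no cover - defensive
            result["errors"]["richness"] = f"{type(exc).__name__}: {exc}"

    if "multibeta" in cfg.stages:
        try:
            beta = multisite_beta(m, drop_empty=drop)
            result["multisite_beta_full"] = beta.as_dict()
        except Exception as exc:
            result["errors"]["multibeta"] = f"{type(exc).__name__}: {exc}"

    if "resample" in cfg.stages:
        try:
            n_avail = m.n_sites if not drop else m.drop_empty_sites().n_sites
            size = min(cfg.subset_size, n_avail)
            dist = beta_sample(
                m,
                subset_size=size,
                n_reps=cfg.n_resamples,
                seed=stage_seed(cfg.seed, f"{tag}/resample"),
                drop_empty=drop,
            )
            result["multisite_beta_resampled"] = {
                "subset_size": dist.subset_size,
                "n_reps": dist.n_reps,
                "seed": dist.seed,
                "mean": dist.summary["mean"].to_dict(),
                "sd": dist.summary["sd"].to_dict(),
            }
            dist.draws.to_csv(out / f"beta_sample_{community}_{scope}.csv", index=False)
            if cfg.make_plots:
                _density_plot(dist, out / f"beta_sample_{community}_{scope}.png", tag)
        except Exception as exc:
            result["errors"]["resample"] = f"{type(exc).__name__}: {exc}"

    if "partition" in cfg.stages:
        try:
            part = partition_significance(
                m, h, n_null=cfg.n_null, seed=stage_seed(cfg.seed, f"{tag}/partition")
            )
            result["additive_partition"] = _partition_payload(part)
            part.components.rename_axis("component").to_csv(
                out / f"partition_{community}_{scope}.csv"
            )
        except Exception as exc:
            result["errors"]["partition"] = f"{type(exc).__name__}: {exc}"

    regional = cfg.regional_level or (h.levels[1] if len(h.levels) > 1 else None)
    if "regression" in cfg.stages:
        try:
            if regional is None:
                raise ValueError("hierarchy has no regional level above the plots")
            if regional in h.levels and len(h.units(regional)) < 3:
                # too few regional units is a design limit, not a failure
                result["local_regional_regression"] = {
                    "skipped": f"only {len(h.units(regional))} unit(s) at level "
                    f"{regional!r}; the fit needs at least 3",
                }
                raise _Skip
            fit = local_regional_regression(m, h, regional_level=regional)
            result["local_regional_regression"] = {
                "regional_level": regional,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "f_statistic": fit.f_statistic,
                "df": [fit.df_num, fit.df_den],
                "p_value": fit.p_value,
                "n_points": len(fit.points),
            }
            fit.points.to_csv(out / f"regression_points_{community}_{scope}.csv", index=False)
            if cfg.make_plots:
                from .regression import plot_fit

                plot_fit(fit, out / f"regression_{community}_{scope}.png")
        except _Skip:
            pass
        except Exception as exc:
            result["errors"]["regression"] = f"{type(exc).__name__}: {exc}"

    if "cluster" in cfg.stages:
        try:
            mats = pairwise_beta_matrices(m, drop_empty=drop)
            trees = {}
            for comp in ("beta_sim", "beta_sne"):
                tree = upgma(mats.component(comp))
                newick = tree_to_newick(tree)
                (out / f"upgma_{comp}_{community}_{scope}.nwk").write_text(
                    newick + "\n", encoding="utf-8"
                )
                trees[comp] = {"n_leaves": len(tree.leaves), "newick_chars": len(newick)}
                write_square_matrix(
                    mats.component(comp), out / f"pairwise_{comp}_{community}_{scope}.csv"
                )
                if cfg.make_plots:
                    from .cluster import plot_dendrogram

                    plot_dendrogram(
                        tree, out / f"upgma_{comp}_{community}_{scope}.png", title=f"{tag} {comp}"
                    )
            result["upgma"] = trees
        except Exception as exc:
            result["errors"]["cluster"] = f"{type(exc).__name__}: {exc}"

    if not result["errors"]:
        del result["errors"]
    return result


def _density_plot(dist, path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    styles = {"beta_sor": "-", "beta_sim": "--", "beta_sne": ":"}
    for comp, ls in styles.items():
        vals = dist.draws[comp]
        if vals.nunique() > 1:
            vals.plot.density(ax=ax, linestyle=ls, label=comp)
        else:
            ax.axvline(vals.iloc[0], linestyle=ls, label=comp)
    ax.set_xlabel("multiple-site dissimilarity")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_full_analysis(cfg: AnalysisConfig) -> dict:
    """Run every requested stage and write the report bundle to ``cfg.out_dir``.

    Returns the summary dictionary (also written to ``summary.json``).
    """
    out = pathlib.Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    plants = read_incidence(cfg.incidence_path, layout=_guess_layout(cfg.incidence_path))
    hierarchy = read_hierarchy(cfg.hierarchy_path)
    communities: dict[str, IncidenceMatrix] = {"plants": plants}
    checksums = {
        "incidence": _sha256(cfg.incidence_path),
        "hierarchy": _sha256(cfg.hierarchy_path),
    }
    if cfg.galls_path:
        communities["galls"] = read_incidence(cfg.galls_path, layout=_guess_layout(cfg.galls_path))
        checksums["galls"] = _sha256(cfg.galls_path)

    summary: dict = {
        "package": {"name": "galldiv", "version": __version__},
        "config": {
            **dataclasses.asdict(cfg),
            "stages": list(cfg.stages),
        },
        "input_checksums_sha256": checksums,
        "results": {},
    }

    top = hierarchy.levels[-1]
    scopes: list[tuple[str, list[str] | None]] = [("all", None)]
    if len(hierarchy.levels) > 1:
        for unit, sites in hierarchy.members(top).items():
            scopes.append((unit, sites))

    for community, matrix in communities.items():
        hierarchy.validate_against(matrix)
        summary["results"][community] = {}
        for scope, sites in scopes:
            if sites is None:
                m_s, h_s = matrix, hierarchy
            else:
                m_s = matrix.select_sites(sites)
                # drop the now-constant top level so partitions stay meaningful
                h_s = SiteHierarchy(
                    hierarchy.levels[:-1],
                    hierarchy.assignment.loc[sites, list(hierarchy.levels[:-1])],
                )
            summary["results"][community][scope] = _analyze_scope(
                m_s, h_s, cfg, community, scope, out
            )

    summary = _round_floats(summary)
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    _write_log(out / "log.txt", cfg, checksums)
    return summary


def _guess_layout(path) -> str:
    """Wide unless the header is exactly the two long-layout columns."""
    head = pd.read_csv(path, nrows=0, sep="\t" if str(path).endswith((".tsv", ".tab")) else ",")
    cols = [str(c).strip().lower() for c in head.columns]
    return "long" if cols == ["site", "species"] else "wide"


def _write_log(path, cfg: AnalysisConfig, checksums: dict) -> None:
    lines = [
        f"galldiv {__version__}",
        f"numpy {np.__version__}, pandas {pd.__version__}",
        f"master seed: {cfg.seed}",
        f"subset_size={cfg.subset_size} n_resamples={cfg.n_resamples} n_null={cfg.n_null}",
    ]
    lines += [f"sha256 {name}: {digest}" for name, digest in sorted(checksums.items())]
    pathlib.Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
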