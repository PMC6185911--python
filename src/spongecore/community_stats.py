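"""Diversity, dissimilarity, rank statistics and hierarchical clustering.

Thin, explicit wrappers over scipy/scikit-bio: Shannon diversity in nats,
Bray-Curtis distance matrices, Spearman rank correlation, Kruskal-Wallis,
UPGMA-style agglomerative clustering with Newick export, and the long-format
export behind seawater-core heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "SpearmanResult",
    "Dendrogram",
    "HeatmapExport",
    "shannon",
    "bray_curtis",
    "spearman",
    "kruskal_wallis",
    "hcluster",
    "heatmap_export",
]


@dataclass
class SpearmanResult:
    rho: float | None  # None when a vector is constant (rho undefined)
    p: float | None
    n: int

    @property
    def defined(self) -> bool:
        return self.rho is not None


def shannon(counts) -> float:
    """Shannon diversity H = −Σ p ln p in nats (zero terms contribute 0)."""
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("expected a 1-D vector of counts")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero vector has undefined diversity")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(data: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between the rows of ``data``.

    d(u, v) = Σ|u−v| / Σ(u+v); on relative abundances this is invariant to
    per-sample sequencing depth.
    """
    if data.shape[0] < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    mat = data.to_numpy(dtype=float)
    if (mat.sum(axis=1) == 0).any():
        raise ValueError("Bray-Curtis is undefined for an all-zero sample")
    condensed = pdist(mat, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(i) for i in data.index])


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties.

    A constant input makes rho undefined; that case is reported explicitly
    rather than as NaN so callers can surface it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(rho=None, p=None, n=len(x))
    res = scipy.stats.spearmanr(x, y)
    return SpearmanResult(rho=float(res.statistic), p=float(res.pvalue), n=len(x))


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p-value."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("empty group")
    if sum(len(a) for a in arrays) < 5:
        raise ValueError("too few observations for the chi-square approximation")
    try:
        h, p = scipy.stats.kruskal(*arrays)
    except ValueError:  # all values identical → H = 0 by definition
        return 0.0, 1.0
    return float(h), float(p)


@dataclass
class Dendrogram:
    """Agglomerative merge tree over ``ids`` (scipy linkage encoding)."""

    ids: list[str]
    linkage: np.ndarray
    method: str

    @property
    def leaf_order(self) -> list[str]:
        return [self.ids[i] for i in sch.leaves_list(self.linkage)]

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage, self.ids)
        return str(tree).strip()


def hcluster(dm: DistanceMatrix, method: str = "average") -> Dendrogram:
    """Agglomerative clustering (UPGMA by default) of a distance matrix.

    Ids are processed in lexicographic order so that equal-distance merges
    resolve deterministically regardless of input ordering.
    """
    if method not in {"average", "complete", "single"}:
        raise ValueError(f"unsupported linkage {method!r}")
    if dm.shape[0] < 2:
        raise ValueError("need at least 2 points to cluster")
    order = sorted(dm.ids)
    reordered = dm.filter(order)
    linkage = sch.linkage(reordered.condensed_form(), method=method)
    return Dendrogram(ids=list(order), linkage=linkage, method=method)


@dataclass
class HeatmapExport:
    """Species × taxon shared-abundance matrix plus clustering of both axes."""

    matrix: pd.DataFrame  # species rows, taxon columns, % of sponge core
    long: pd.DataFrame  # tidy (group, taxon, abundance_pct) rows
    row_dendrogram: Dendrogram | None
    col_dendrogram: Dendrogram | None


def heatmap_export(
    per_taxon: pd.DataFrame,
    abundance_floor: float = 1.0,
) -> HeatmapExport:
    """Heatmap data for seawater-core taxa across sponge cores.

    ``per_taxon`` is long-format with columns ``group``, ``taxon`` and
    ``sponge_core_pct`` (per-taxon share of the sponge core, in percent).
    Taxa reaching > ``abundance_floor`` percent in at least one sponge core
    are retained; both axes are clustered with Bray-Curtis + UPGMA.
    """
    required = {"group", "taxon", "sponge_core_pct"}
    if not required <= set(per_taxon.columns):
        raise ValueError(f"per-taxon table must have columns {sorted(required)}")
    wide = per_taxon.pivot_table(index="group", columns="taxon",
                                 values="sponge_core_pct", fill_value=0.0)
    keep = wide.columns[(wide > abundance_floor).any(axis=0)]
    if len(keep) == 0:
        import warnings

        warnings.warn("no taxon passes the heatmap abundance floor", stacklevel=2)
        empty = wide[[]]
        return HeatmapExport(matrix=empty, long=per_taxon.iloc[0:0], row_dendrogram=None,
                             col_dendrogram=None)
    mat = wide[keep]
    row_d = hcluster(bray_curtis(mat)) if mat.shape[0] >= 2 and (mat.sum(axis=1) > 0).all() else None
    col_d = hcluster(bray_curtis(mat.T)) if mat.shape[1] >= 2 and (mat.sum(axis=0) > 0).all() else None
    long = mat.reset_index().melt(id_vars="group", var_name="taxon",
                                  value_name="sponge_core_pct")
    return HeatmapExport(matrix=mat, long=long, row_dendrogram=row_d, col_dendrogram=col_d)
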