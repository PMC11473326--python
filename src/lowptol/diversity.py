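"""Phenotypic diversity: normalization, mean Euclidean distance, UPGMA, Mojena cut.

Line-level genotypic values are standardized per trait (mean 0, sd 1 with
the n-1 denominator) so traits on different scales contribute equally; the
pairwise dissimilarity is the root-mean-square difference over traits,

    d(i, j) = sqrt( (1/T) sum_t (z_it - z_jt)^2 ),

which is invariant to the number of traits.  Lines are clustered by UPGMA
(average linkage with cluster-size weighting) and the dendrogram is cut at
the Mojena threshold, mean + k * sd of the fusion levels (k defaults to
1.25, the Milligan-Cooper recommendation).  Merges exactly at the cutoff
are kept; only merges strictly above it are severed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "Dendrogram",
    "ClusterAssignment",
    "normalize_blups",
    "mean_euclidean",
    "upgma",
    "mojena_cut",
]


def normalize_blups(genotypic_values: pd.DataFrame) -> pd.DataFrame:
    """Standardize each trait column to mean 0, sd 1 (ddof=1)."""
    gv = genotypic_values.dropna()
    if gv.shape[0] < 2:
        raise ValueError("at least 2 lines are required")
    sd = gv.std(axis=0, ddof=1)
    constant = list(sd.index[sd == 0.0])
    if constant:
        raise ValueError(f"constant trait(s) cannot be normalized: {constant}")
    return (gv - gv.mean(axis=0)) / sd


def mean_euclidean(standardized: pd.DataFrame) -> pd.DataFrame:
    """Pairwise root-mean-square trait difference between lines."""
    arr = standardized.to_numpy(float)
    n, T = arr.shape
    sq = np.sum(arr**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (arr @ arr.T)
    d2 = np.maximum(d2, 0.0) / T
    d = np.sqrt(d2)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return pd.DataFrame(d, index=standardized.index, columns=standardized.index)


@dataclass
class Dendrogram:
    """UPGMA tree: scipy linkage matrix plus leaf labels.

    ``linkage[i] = (a, b, height, size)`` records the i-th merge; heights
    (fusion levels) are non-decreasing for average linkage on a metric
    input.  Branch lengths in the Newick export follow the ultrametric
    convention: each leaf sits at depth height/2 below its cluster's node.
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def fusion_levels(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def cophenetic(self) -> pd.DataFrame:
        """Square matrix of cophenetic (fusion-level) distances."""
        coph = hierarchy.cophenet(self.linkage)
        return pd.DataFrame(
            squareform(coph), index=self.labels, columns=self.labels
        )

    def to_newick(self) -> str:
        """Newick string with ultrametric branch lengths (height/2 depths)."""
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, self.labels)
        return str(tree).strip()


@dataclass
class ClusterAssignment:
    """Flat clusters from a Mojena cut of a dendrogram."""

    assignments: pd.Series  # line -> cluster id (1..k)
    cutoff: float
    k: int
    mojena_k: float

    def sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()


def upgma(dist: pd.DataFrame) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of a distance matrix."""
    arr = dist.to_numpy(float)
    if arr.shape[0] < 2:
        raise ValueError("at least 2 leaves are required")
    if np.isnan(arr).any():
        raise ValueError("distance matrix contains NaN")
    condensed = squareform(arr, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    return Dendrogram(linkage=Z, labels=[str(x) for x in dist.index])


def mojena_cut(tree: Dendrogram, k_const: float = 1.25) -> ClusterAssignment:
    """Cut a dendrogram at mean + k * sd of its fusion levels.

    The sd uses the n-1 denominator; with a single fusion level the cutoff
    is that level.  Merges at a height less than or equal to the cutoff are
    kept, so equal-height merges are never severed.
    """
    levels = tree.fusion_levels
    if levels.size == 0:
        raise ValueError("dendrogram has no fusion levels")
    sd = float(np.std(levels, ddof=1)) if levels.size > 1 else 0.0
    cutoff = float(np.mean(levels)) + k_const * sd
    flat = hierarchy.fcluster(tree.linkage, t=cutoff, criterion="distance")
    # relabel clusters by order of first appearance for determinism
    order: dict[int, int] = {}
    ids = []
    for c in flat:
        if c not in order:
            order[c] = len(order) + 1
        ids.append(order[c])
    assignments = pd.Series(ids, index=tree.labels, name="cluster")
    return ClusterAssignment(
        assignments=assignments,
        cutoff=cutoff,
        k=int(assignments.nunique()),
        mojena_k=float(k_const),
    )
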