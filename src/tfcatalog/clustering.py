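"""Temporal and spatial clustering with DBD-family enrichment.

Temporal analysis: expression profiles are normalized by their maximum,
hierarchically clustered with Ward's method on Euclidean distances, and cut
into flat clusters wherever the height gap between a parent node and a
child exceeds a threshold (default 5).  DBD-family over-representation in
each flat cluster is tested with Fisher's exact test (two-sided) and
controlled with Benjamini-Hochberg FDR (< 0.1 significant).

Spatial analysis: per-gene z-scores across the five region means are
correlated gene-by-gene; the correlation matrix rows are Ward-clustered,
and — within the dendrogram's free leaf rotations — leaves are ordered by
decreasing animal-cap / vegetal-mass TPM ratio, placing animally enriched
genes at one end and vegetally enriched genes at the other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class LinkageTree:
    """A hierarchical clustering result: scipy linkage matrix plus labels."""

    linkage: np.ndarray  # (n-1) x 4 scipy format
    labels: list[str]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage shape inconsistent with label count")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def normalize_by_max(profiles: pd.DataFrame) -> pd.DataFrame:
    """Divide each row by its maximum; all-zero rows are dropped with a warning."""
    row_max = profiles.max(axis=1)
    zero = row_max <= 0
    if zero.any():
        logger.warning("normalize_by_max: dropped %d all-zero profile(s)", int(zero.sum()))
    kept = profiles.loc[~zero]
    return kept.div(row_max[~zero], axis=0)


def ward_linkage(matrix: pd.DataFrame | np.ndarray,
                 labels: Optional[Sequence[str]] = None) -> LinkageTree:
    """Ward's minimum-variance agglomeration on Euclidean distances."""
    if isinstance(matrix, pd.DataFrame):
        labels = list(matrix.index)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        labels = list(labels) if labels is not None else [str(i) for i in range(X.shape[0])]
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows")
    if np.isnan(X).any():
        raise ValueError("matrix contains NaN")
    Z = hierarchy.linkage(X, method="ward")
    return LinkageTree(linkage=Z, labels=labels)


def flat_clusters(tree: LinkageTree, threshold: float = 5.0) -> dict[str, int]:
    """Cut the tree where the parent-child height gap exceeds ``threshold``.

    Every merge whose height exceeds a child's height (leaf height 0) by
    more than ``threshold`` is severed; the connected components of the
    remaining tree define the flat clusters.  Returns label -> cluster ID
    (consecutive integers ordered by first leaf appearance).
    """
    n = len(tree.labels)
    Z = tree.linkage
    parent = list(range(2 * n - 1))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    heights = np.concatenate([np.zeros(n), Z[:, 2]])
    for k in range(n - 1):
        node = n + k
        for child in (int(Z[k, 0]), int(Z[k, 1])):
            if heights[node] - heights[child] <= threshold:
                parent[find(child)] = find(node)
    comp_of_leaf = [find(i) for i in range(n)]
    ids: dict[int, int] = {}
    out: dict[str, int] = {}
    for leaf, comp in enumerate(comp_of_leaf):
        if comp not in ids:
            ids[comp] = len(ids)
        out[tree.labels[leaf]] = ids[comp]
    return out


def family_enrichment(
    clusters: Mapping[str, int],
    gene_families: Mapping[str, Sequence[str]],
    fdr_cutoff: float = 0.1,
) -> pd.DataFrame:
    """DBD-family over-representation per flat cluster.

    For each (cluster, family) pair, a 2x2 table over the tested universe
    (genes that are clustered and carry >= 1 family) is evaluated with a
    two-sided Fisher exact test; multi-family genes count once per family.
    Benjamini-Hochberg adjustment runs across all tested pairs; rows with
    ``fdr < fdr_cutoff`` are flagged significant.
    """
    universe = [g for g in clusters if gene_families.get(g)]
    n_univ = len(universe)
    if n_univ == 0:
        return pd.DataFrame(
            columns=["cluster_id", "family", "a", "b", "c", "d",
                     "odds_ratio", "p", "fdr", "significant"]
        )
    families = sorted({f for g in universe for f in gene_families[g]})
    cluster_ids = sorted(set(clusters[g] for g in universe))
    rows = []
    for cid in cluster_ids:
        in_cluster = {g for g in universe if clusters[g] == cid}
        for fam in families:
            in_family = {g for g in universe if fam in gene_families[g]}
            a = len(in_cluster & in_family)
            b = len(in_cluster - in_family)
            c = len(in_family - in_cluster)
            d = n_univ - a - b - c
            odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append((cid, fam, a, b, c, d, float(odds), float(p)))
    table = pd.DataFrame(
        rows, columns=["cluster_id", "family", "a", "b", "c", "d", "odds_ratio", "p"]
    )
    reject, q, _, _ = multipletests(table["p"], alpha=fdr_cutoff, method="fdr_bh")
    table["fdr"] = q
    table["significant"] = reject
    return table


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-score (sample sd, ddof=1); zero-variance rows dropped."""
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        logger.warning("zscore_rows: dropped %d zero-variance gene(s)", int((~keep).sum()))
    X = X[keep]
    z = (X - X.mean(axis=1, keepdims=True)) / X[:, :].std(axis=1, ddof=1, keepdims=True)
    return pd.DataFrame(z, index=matrix.index[keep], columns=matrix.columns)


def _ordered_leaves(Z: np.ndarray, key: np.ndarray) -> list[int]:
    """Leaf order under free rotations, sorting subtrees by decreasing key."""
    n = Z.shape[0] + 1
    mean_key: dict[int, float] = {i: float(key[i]) for i in range(n)}
    size: dict[int, int] = {i: 1 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for k in range(n - 1):
        a, b = int(Z[k, 0]), int(Z[k, 1])
        node = n + k
        children[node] = (a, b)
        size[node] = size[a] + size[b]
        mean_key[node] = (mean_key[a] * size[a] + mean_key[b] * size[b]) / size[node]

    def walk(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        first, second = (a, b) if mean_key[a] >= mean_key[b] else (b, a)
        return walk(first) + walk(second)

    return walk(2 * n - 2)


def spatial_zscore_cluster(
    region_mean_tpm: pd.DataFrame,
    gene_subset: Optional[Sequence[str]] = None,
    ac_region: str = "AC",
    veg_region: str = "VEG",
    eps: float = 0.01,
) -> dict:
    """Spatial z-score heatmap matrix with animal-to-vegetal leaf ordering.

    Steps: z-score each gene's profile across region means; build the
    gene x gene Pearson correlation matrix of z-profiles; Ward-cluster its
    rows; within the dendrogram's free leaf rotations order leaves by
    decreasing AC/VEG mean-TPM ratio (pseudocount ``eps``).

    Returns a dict with the ordered z-score matrix, the leaf order, the
    linkage tree and the AC/VEG ratios.
    """
    sub = region_mean_tpm if gene_subset is None else region_mean_tpm.loc[list(gene_subset)]
    z = zscore_rows(sub)
    if z.shape[0] < 2:
        raise ValueError("need >= 2 genes with varying profiles")
    corr = np.corrcoef(z.to_numpy())
    tree = ward_linkage(corr, labels=list(z.index))
    ratio = (sub.loc[z.index, ac_region] + eps) / (sub.loc[z.index, veg_region] + eps)
    order_idx = _ordered_leaves(tree.linkage, ratio.to_numpy(dtype=float))
    ordered = z.iloc[order_idx]
    return {
        "matrix": ordered,
        "leaf_order": list(ordered.index),
        "tree": tree,
        "ac_veg_ratio": ratio,
    }
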