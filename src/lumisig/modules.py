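"""Gene-module extraction from correlation-based hierarchical clustering.

Genes are clustered across samples by average-linkage agglomeration on
centered Pearson similarity. Each internal dendrogram node carries a
"node correlation" — the similarity at which its two branches merge
(1 minus the cophenetic distance). A module around a seed gene is the
subtree obtained by ascending from the seed leaf while the merges stay
at or above a threshold (0.65 by convention for the luminal/ESR1
cluster). Average linkage makes node correlations non-increasing toward
the root, so the threshold cut is well defined; centroid linkage is
offered behind a flag with the ascent truncated at the first inversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator

from .prep import median_center

__all__ = [
    "DendrogramNode",
    "OverlapReport",
    "NodeCorrelationModules",
    "correlation_dendrogram",
    "extract_node_module",
    "overlap_analysis",
    "to_newick",
]


@dataclass
class DendrogramNode:
    """Binary merge tree; internal nodes carry the similarity at merge."""

    id: int
    node_correlation: float | None = None   # None for leaves
    gene_id: str | None = None              # set for leaves
    left: "DendrogramNode | None" = None
    right: "DendrogramNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.gene_id is not None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.gene_id]
        return self.left.leaves() + self.right.leaves()


@dataclass
class OverlapReport:
    """Exclusive decomposition of a gene module against named signatures."""

    module_size: int
    counts: dict[str, int]          # per-signature exclusive + 'multiple' + 'none'
    percentages: dict[str, float]
    assignment: pd.Series = field(default=None)  # gene -> category

    def __post_init__(self):
        assert sum(self.counts.values()) == self.module_size


class NodeCorrelationModules(BaseEstimator):
    """Hierarchical gene clustering with node-correlation module extraction.

    Parameters
    ----------
    min_corr : float, default 0.65
        Node-correlation threshold for module extraction.
    linkage : {"average", "centroid"}, default "average"
    center : bool, default True
        Median-center gene rows across samples before correlating
        (Pearson correlation itself is centering-invariant; this affects
        only downstream consumers of the centered matrix).

    Attributes (after ``fit``)
    --------------------------
    linkage_ : scipy linkage matrix (distances = 1 - correlation)
    tree_ : :class:`DendrogramNode` root with node correlations
    gene_ids_ : genes actually clustered (constant genes are dropped)
    """

    def __init__(self, min_corr: float = 0.65, linkage: str = "average",
                 center: bool = True):
        self.min_corr = min_corr
        self.linkage = linkage
        self.center = center

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 genes to cluster")
        if X.shape[1] < 3:
            raise ValueError("need at least 3 samples to correlate genes")
        if self.linkage not in ("average", "centroid"):
            raise ValueError("linkage must be 'average' or 'centroid'")
        var = X.var(axis=1, skipna=True)
        constant = X.index[(var == 0) | var.isna()]
        if len(constant):
            warnings.warn(
                f"excluding {len(constant)} constant genes (undefined correlation)"
            )
            X = X.drop(index=constant)
        if self.center:
            X = median_center(X)
        vals = X.to_numpy(dtype=float)
        corr = np.corrcoef(vals)
        corr = np.clip(corr, -1.0, 1.0)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        from scipy.spatial.distance import squareform

        condensed = squareform(dist, checks=False)
        self.linkage_ = hierarchy.linkage(condensed, method=self.linkage)
        self.gene_ids_ = X.index
        self.excluded_genes_ = constant
        self.tree_ = _build_tree(self.linkage_, list(X.index))
        return self

    def extract(self, seed_gene: str, min_corr: float | None = None) -> list[str]:
        """Module around ``seed_gene``: ascend while node correlation >= threshold.

        Returns the leaf genes of the highest accepted ancestor, in leaf
        order; just the seed when even its first merge is below the
        threshold. With centroid linkage the ascent additionally stops at
        the first similarity inversion.
        """
        if not hasattr(self, "linkage_"):
            raise ValueError("fit the estimator first")
        thr = self.min_corr if min_corr is None else min_corr
        gene_ids = list(self.gene_ids_)
        try:
            leaf = gene_ids.index(seed_gene)
        except ValueError:
            raise KeyError(f"seed gene {seed_gene!r} not in the clustered genes")

        n = len(gene_ids)
        parent = np.full(2 * n - 1, -1)
        for k, (a, b, *_rest) in enumerate(self.linkage_):
            parent[int(a)] = n + k
            parent[int(b)] = n + k

        best = leaf
        node = parent[leaf]
        last_sim = np.inf
        while node != -1:
            sim = 1.0 - self.linkage_[node - n, 2]
            if sim < thr:
                break
            if self.linkage == "centroid" and sim > last_sim + 1e-12:
                break  # inversion: truncate ascent
            best = node
            last_sim = sim
            node = parent[node]
        if best < n:
            return [gene_ids[best]]
        members = hierarchy.leaves_list(self.linkage_)
        cluster_leaves = _subtree_leaves(self.linkage_, best, n)
        ordered = [i for i in members if i in cluster_leaves]
        return [gene_ids[i] for i in ordered]


def _subtree_leaves(Z: np.ndarray, node: int, n: int) -> set[int]:
    stack, out = [node], set()
    while stack:
        k = stack.pop()
        if k < n:
            out.add(k)
        else:
            a, b = int(Z[k - n, 0]), int(Z[k - n, 1])
            stack.extend((a, b))
    return out


def _build_tree(Z: np.ndarray, gene_ids: list[str]) -> DendrogramNode:
    n = len(gene_ids)
    nodes = {i: DendrogramNode(id=i, gene_id=gene_ids[i]) for i in range(n)}
    for k, (a, b, dist, _cnt) in enumerate(Z):
        nodes[n + k] = DendrogramNode(
            id=n + k,
            node_correlation=1.0 - float(dist),
            left=nodes[int(a)],
            right=nodes[int(b)],
        )
    return nodes[2 * n - 2]


def to_newick(node: DendrogramNode) -> str:
    """Serialize the tree to Newick; node correlations as internal labels."""

    def rec(nd: DendrogramNode) -> str:
        if nd.is_leaf:
            return nd.gene_id
        label = f"{nd.node_correlation:.6g}"
        return f"({rec(nd.left)},{rec(nd.right)}){label}"

    return rec(node) + ";"


def correlation_dendrogram(
    matrix: pd.DataFrame, linkage: str = "average", center: bool = True
) -> tuple[DendrogramNode, NodeCorrelationModules]:
    """Cluster gene rows; returns the tree and the fitted estimator."""
    est = NodeCorrelationModules(linkage=linkage, center=center).fit(matrix)
    return est.tree_, est


def extract_node_module(
    est_or_matrix, seed_gene: str, min_corr: float = 0.65
) -> list[str]:
    """Module genes around ``seed_gene`` at the given node-correlation threshold."""
    if isinstance(est_or_matrix, NodeCorrelationModules):
        est = est_or_matrix
    else:
        est = NodeCorrelationModules(min_corr=min_corr).fit(est_or_matrix)
    return est.extract(seed_gene, min_corr=min_corr)


def overlap_analysis(module_genes, signatures: dict) -> OverlapReport:
    """Exclusive overlap decomposition of a module against named gene sets.

    Each module gene lands in exactly one category: the single signature
    containing it, "multiple" when two or more signatures contain it, or
    "none". Percentages are count / module size * 100 and the exclusive
    counts sum to the module size exactly.
    """
    module = list(dict.fromkeys(module_genes))
    if not module:
        raise ValueError("module is empty")
    sig_sets = {name: set(g) for name, g in signatures.items()}
    cats = {}
    for g in module:
        hits = [name for name, s in sig_sets.items() if g in s]
        if len(hits) == 0:
            cats[g] = "none"
        elif len(hits) == 1:
            cats[g] = hits[0]
        else:
            cats[g] = "multiple"
    assignment = pd.Series(cats, name="category")
    labels = list(sig_sets) + ["multiple", "none"]
    counts = {lab: int((assignment == lab).sum()) for lab in labels}
    size = len(module)
    pct = {lab: 100.0 * c / size for lab, c in counts.items()}
    return OverlapReport(
        module_size=size, counts=counts, percentages=pct, assignment=assignment
    )
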