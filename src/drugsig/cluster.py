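"""Descriptive downstream analyses.

Hierarchical co-clustering of the most sensitivity-correlated genes
(Euclidean distance, complete linkage), Wilcoxon rank-sum differential
expression between sensitive and resistant groups, gene-list overlap, and
hypergeometric gene-set enrichment with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .containers import GeneSetCollection
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ClusteringResult:
    """Agglomerative tree over the clustered items.

    ``linkage`` is the scipy (n-1) x 4 merge table; heights are
    nondecreasing for complete linkage. ``labels_at`` cuts the tree into a
    requested number of flat clusters.
    """

    linkage: np.ndarray
    items: list[str]

    @property
    def leaf_order(self) -> list[str]:
        return [self.items[i] for i in hierarchy.leaves_list(self.linkage)]

    def labels_at(self, n_clusters: int) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return pd.Series(labels, index=self.items, name="cluster")

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.items[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def hierarchical_cluster(matrix: pd.DataFrame, axis: str = "samples") -> ClusteringResult:
    """Complete-linkage clustering on Euclidean distances.

    ``matrix`` is genes x samples; ``axis`` picks which margin to cluster.
    """
    if axis not in ("samples", "genes"):
        raise ValidationError(f"axis must be 'samples' or 'genes', got {axis!r}")
    data = matrix.T if axis == "samples" else matrix
    items = [str(i) for i in data.index]
    if len(items) < 2:
        raise ValidationError("need at least 2 items to cluster")
    Z = hierarchy.linkage(pdist(data.to_numpy(float), metric="euclidean"), method="complete")
    return ClusteringResult(Z, items)


def coclustering_agreement(clusters: pd.Series, true_labels: pd.Series) -> float:
    """Fraction of items grouped with their own class at a two-way cut.

    The two clusters are matched to the two true labels by the assignment
    maximizing agreement, so the returned fraction is label-permutation
    invariant.
    """
    labels = true_labels.reindex(clusters.index)
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValidationError("exactly two true labels are required")
    clus_ids = sorted(clusters.unique())
    if len(clus_ids) == 1:
        # one degenerate cluster: the best assignment puts everything in
        # the majority class
        return float(labels.value_counts().max()) / len(labels)
    match_a = ((clusters == clus_ids[0]) == (labels == classes[0])).sum()
    return float(max(match_a, len(labels) - match_a)) / len(labels)


def _rank_sum_statistic(a: np.ndarray, b: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([a, b]))  # midranks for ties
    return float(ranks[: a.size].sum())


def wilcoxon_rank_sum(group_a, group_b) -> tuple[float, float]:
    """Rank-sum W of group A and a two-sided p.

    Exact p (full enumeration over rank assignments) for groups of at most
    10 each with no ties; otherwise the normal approximation with
    continuity correction on midranks.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (a.size <= 10 and b.size <= 10) and not has_ties
    res = stats.mannwhitneyu(
        a, b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    w = _rank_sum_statistic(a, b)
    return w, float(res.pvalue)


def list_overlap(list_a: list[str], list_b: list[str]) -> tuple[list[str], float, float]:
    """Set intersection and the shared fraction of each list."""
    sa, sb = set(list_a), set(list_b)
    inter = sorted(sa & sb)
    frac_a = len(inter) / len(sa) if sa else 0.0
    frac_b = len(inter) / len(sb) if sb else 0.0
    return inter, frac_a, frac_b


@dataclass
class EnrichmentResult:
    """Per-set hypergeometric enrichment with BH-adjusted FDR."""

    table: pd.DataFrame  # index set, columns overlap/set_size/query_size/universe_size/p/fdr/significant
    fdr_threshold: float

    @property
    def significant_sets(self) -> list[str]:
        return self.table.index[self.table["significant"]].tolist()


def enrichment_test(
    query: list[str],
    sets: GeneSetCollection,
    universe: list[str],
    fdr_threshold: float = 0.05,
) -> EnrichmentResult:
    """Upper-tail hypergeometric test per gene set, BH-corrected.

    Query genes outside the universe are dropped with a warning; set
    members are intersected with the universe before testing.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("universe must be nonempty")
    q = [g for g in dict.fromkeys(query) if g in uni]
    dropped = len(set(query)) - len(q)
    if dropped:
        logger.warning("enrichment_test: dropped %d query gene(s) outside universe", dropped)
    if not q:
        raise ValidationError("query is empty (after universe restriction)")
    qset = set(q)
    M, N = len(uni), len(qset)
    rows = []
    for name, members in sets.sets.items():
        in_uni = set(members) & uni
        n = len(in_uni)
        k = len(in_uni & qset)
        # P(X >= k) for X ~ Hypergeom(M, n, N)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append(
            {"set": name, "overlap": k, "set_size": n, "query_size": N,
             "universe_size": M, "p": min(p, 1.0)}
        )
    df = pd.DataFrame(rows).set_index("set")
    _, fdr, _, _ = multipletests(df["p"].to_numpy(), method="fdr_bh")
    df["fdr"] = fdr
    df["significant"] = df["fdr"] <= fdr_threshold
    return EnrichmentResult(df, fdr_threshold)
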