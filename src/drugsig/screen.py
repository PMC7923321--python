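"""First funnel stage: correlation screen, biological filters, Relief ranking.

The screen keeps genes whose expression correlates (either sign) with drug
sensitivity, optionally narrows them by pathway membership shared with the
drug's target genes and/or by network adjacency, and finally ranks the
survivors with RReliefF, the Relief-family estimator for continuous
targets, keeping the top-``n`` for the prediction module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GeneSetCollection, InteractionNetwork
from .errors import PipelineError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    """Per-gene Pearson correlation against the sensitivity target.

    ``table`` has one row per gene with columns ``r``, ``p``, ``n``,
    ``sign``; genes with constant expression carry no row (they are listed
    in ``excluded``).
    """

    table: pd.DataFrame
    excluded: list[str]

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


@dataclass
class RankedGeneList:
    """Genes ordered by nonincreasing Relief weight (ties: lexicographic)."""

    table: pd.DataFrame  # index gene, column "weight", sorted

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    @property
    def weights(self) -> pd.Series:
        return self.table["weight"]


def pearson_screen(expr: ExpressionMatrix, y) -> CorrelationResult:
    """Pearson r and two-sided p of every gene against the target.

    p comes from the t transform ``t = r * sqrt((n-2)/(1-r^2))`` on n-2
    degrees of freedom. Zero-variance genes are excluded (logged); p values
    below the smallest positive normal double are reported at that floor.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 4:
        raise ValidationError("pearson_screen needs at least 4 samples")
    if n != len(expr.sample_ids):
        raise ValidationError("expression and target are not aligned")
    X = expr.values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    x_ss = np.einsum("ij,ij->i", Xc, Xc)
    y_ss = float(yc @ yc)
    if y_ss == 0.0:
        raise ValidationError("target has zero variance")
    ok = x_ss > 0
    excluded = [g for g, keep in zip(expr.gene_ids, ok) if not keep]
    if excluded:
        logger.info("pearson_screen: excluded %d constant gene(s)", len(excluded))
    r = np.full(X.shape[0], np.nan)
    r[ok] = (Xc[ok] @ yc) / np.sqrt(x_ss[ok] * y_ss)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    t[np.isinf(t)] = np.sign(r[np.isinf(t)]) * 1e308
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.maximum(p, np.finfo(float).tiny)
    table = pd.DataFrame(
        {
            "r": r[ok],
            "p": p[ok],
            "n": n,
            "sign": np.where(r[ok] >= 0, "+", "-"),
        },
        index=pd.Index([g for g, keep in zip(expr.gene_ids, ok) if keep], name="gene"),
    )
    return CorrelationResult(table, excluded)


def select_significant(corr: CorrelationResult, alpha: float = 0.05) -> list[str]:
    """Genes with p <= alpha, both correlation signs retained (inclusive)."""
    kept = corr.table.index[corr.table["p"] <= alpha].tolist()
    logger.info(
        "select_significant: %d of %d genes at p <= %g", len(kept), len(corr.table), alpha
    )
    return kept


def select_top_correlates(
    corr: CorrelationResult, n_pos: int, n_neg: int
) -> list[str]:
    """Top ``n_pos`` positively and ``n_neg`` negatively correlated genes.

    Sorted by r (descending for +, ascending for -); ties broken by gene id.
    Truncates with a warning when a sign has fewer genes than requested.
    """
    df = corr.table.reset_index()
    pos = df[df["r"] > 0].sort_values(["r", "gene"], ascending=[False, True])
    neg = df[df["r"] < 0].sort_values(["r", "gene"], ascending=[True, True])
    if len(pos) < n_pos or len(neg) < n_neg:
        logger.warning(
            "select_top_correlates: requested %d+/%d- but only %d+/%d- available",
            n_pos, n_neg, len(pos), len(neg),
        )
    return pos["gene"].head(n_pos).tolist() + neg["gene"].head(n_neg).tolist()


def pathway_filter(
    genes: list[str], sets: GeneSetCollection, target_genes: list[str]
) -> list[str]:
    """Keep genes sharing at least one gene set with a drug-target gene."""
    if not target_genes:
        raise ValidationError("pathway_filter requires at least one target gene")
    target = set(target_genes)
    relevant: set[str] = set()
    found_target = False
    for members in sets.sets.values():
        mset = set(members)
        if mset & target:
            found_target = True
            relevant |= mset
    if not found_target:
        raise PipelineError("no target gene found in any gene set")
    kept = [g for g in genes if g in relevant]
    logger.info("pathway_filter: %d of %d genes retained", len(kept), len(genes))
    return kept


def network_filter(
    genes: list[str],
    net: InteractionNetwork,
    measured_genes: list[str] | None = None,
) -> list[str]:
    """Input genes plus their direct network neighbors.

    Neighbors are restricted to ``measured_genes`` when given (genes absent
    from the expression matrix cannot enter the model). Input order is
    preserved, added neighbors follow in sorted order.
    """
    adj = net.adjacency()
    neighbors: set[str] = set()
    for g in genes:
        neighbors |= adj.get(g, set())
    neighbors -= set(genes)
    if measured_genes is not None:
        neighbors &= set(measured_genes)
    out = list(genes) + sorted(neighbors)
    logger.info(
        "network_filter: %d input + %d neighbor gene(s)", len(genes), len(neighbors)
    )
    return out


def relieff_rank(
    expr: ExpressionMatrix,
    y,
    k_neighbors: int = 10,
    n_iterations: int | None = None,
    seed: int = 0,
) -> RankedGeneList:
    """RReliefF feature weights for a continuous target.

    Features and the target are min-max scaled; instance distance is
    Manhattan on the scaled features; each sampled instance contributes its
    ``k_neighbors`` nearest neighbors with uniform weight. By default every
    sample is used once as the pivot (``n_iterations = n_samples``), which
    makes the ranking deterministic; a smaller ``n_iterations`` subsamples
    pivots with the given seed.

    Weights estimate P(feature differs | target differs) against
    P(feature differs | target similar): positive for informative features,
    near zero for noise.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n != len(expr.sample_ids):
        raise ValidationError("expression and target are not aligned")
    if n < k_neighbors + 1:
        raise ValidationError(
            f"need at least k_neighbors+1={k_neighbors + 1} samples, got {n}"
        )
    X = expr.values.to_numpy(dtype=float).T  # samples x features
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    Xs = (X - X.min(axis=0)) / span
    y_span = y.max() - y.min()
    ys = (y - y.min()) / (y_span if y_span > 0 else 1.0)

    if n_iterations is None or n_iterations >= n:
        pivots = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        pivots = rng.choice(n, size=n_iterations, replace=False)

    n_feat = Xs.shape[1]
    ndc = 0.0
    nda = np.zeros(n_feat)
    ndcda = np.zeros(n_feat)
    w_neighbor = 1.0 / k_neighbors
    total = 0.0
    for i in pivots:
        d = np.abs(Xs - Xs[i]).sum(axis=1)
        d[i] = np.inf
        order = np.argsort(d, kind="stable")[:k_neighbors]
        for j in order:
            dy = abs(ys[i] - ys[j])
            da = np.abs(Xs[i] - Xs[j])
            ndc += dy * w_neighbor
            nda += da * w_neighbor
            ndcda += dy * da * w_neighbor
            total += w_neighbor
    if ndc == 0.0 or total - ndc == 0.0:
        weights = np.zeros(n_feat)
    else:
        weights = ndcda / ndc - (nda - ndcda) / (total - ndc)
    table = (
        pd.DataFrame({"weight": weights}, index=pd.Index(expr.gene_ids, name="gene"))
        .reset_index()
        .sort_values(["weight", "gene"], ascending=[False, True], kind="stable")
        .set_index("gene")
    )
    return RankedGeneList(table)


def take_top(ranked: RankedGeneList, n: int = 100) -> list[str]:
    """First ``min(n, len)`` genes of the ranking (warns when short)."""
    genes = ranked.genes
    if len(genes) < n:
        logger.warning("take_top: only %d genes available, requested %d", len(genes), n)
    return genes[:n]
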