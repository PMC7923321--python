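"""Synthetic expression / IC50 panels with planted causal genes.

The generator emulates the data regime of a small cell-line drug screen: a
training cohort of ~52 solid-tumor lines (plus a resistant blood-derived
subgroup that is excluded before modeling), an independent blind cohort of
~37 lines drawn from the same generative law, thousands of genes of which a
sparse causal set drives sensitivity, and one dominant driver gene (the
analog of a bioactivating enzyme such as PTGR1).

Generative law
--------------
Per-gene log2 expression is Gaussian with gene-specific mean ~ U[4, 12] and
sd ~ U[0.5, 2]. The sensitivity target on the -log10(Molar IC50) scale is

    y = beta0 + sum_j beta_j * z_j + lineage_offset + eps,

where z_j is the causal gene's expression standardized by its *generative*
mean and sd (so train and blind partitions share one law exactly),
eps ~ N(0, noise_sd^2), and blood-lineage samples receive a negative offset
(toward resistance). IC50 (Molar) is 10**(-y).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GeneSetCollection,
    InteractionNetwork,
    SensitivityTable,
)
from .errors import ValidationError

logger = logging.getLogger(__name__)

TUMOR_TYPES = (
    "breast", "cns", "colon", "kidney", "lung", "melanoma", "ovarian", "prostate",
)


def _default_causal() -> list[tuple[int, float]]:
    # one dominant driver plus four weaker contributors
    return [(0, 1.5), (1, 0.4), (2, 0.4), (3, 0.4), (4, 0.4)]


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic panel; defaults mirror the emulated screen."""

    n_train: int = 52
    n_blind: int = 37
    n_genes: int = 2000
    causal_genes: list[tuple[int, float]] = field(default_factory=_default_causal)
    dominant_index: int = 0
    noise_sd: float = 0.3
    beta0: float = 6.5
    resistant_lineage_fraction: float = 6 / 58
    resistant_offset: float = 1.5
    n_tumor_types: int = 8
    block_correlation: float = 0.0
    block_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_train, self.n_blind, self.n_genes) <= 0:
            raise ValidationError("n_train, n_blind and n_genes must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0 <= self.resistant_lineage_fraction < 1:
            raise ValidationError("resistant_lineage_fraction must be in [0, 1)")
        idx = [i for i, _ in self.causal_genes]
        if len(set(idx)) != len(idx):
            raise ValidationError("causal gene indices must be unique")
        if any(i < 0 or i >= self.n_genes for i in idx):
            raise ValidationError("causal gene index out of range")
        if self.dominant_index not in idx:
            raise ValidationError("dominant_index must be one of the causal genes")
        if not 1 <= self.n_tumor_types <= len(TUMOR_TYPES):
            raise ValidationError(
                f"n_tumor_types must be in [1, {len(TUMOR_TYPES)}]"
            )
        if not 0 <= self.block_correlation < 1:
            raise ValidationError("block_correlation must be in [0, 1)")


@dataclass
class SyntheticDataset:
    """A generated train/blind pair plus the generative ground truth."""

    expression: ExpressionMatrix
    sensitivity: SensitivityTable
    blind_expression: ExpressionMatrix
    blind_sensitivity: SensitivityTable
    truth: dict

    def __post_init__(self) -> None:
        genes = set(self.expression.gene_ids)
        if not set(self.truth["causal_genes"]) <= genes:
            raise ValidationError("truth genes not all present in expression matrix")
        if set(self.expression.sample_ids) & set(self.blind_expression.sample_ids):
            raise ValidationError("train and blind sample ids overlap")


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def _draw_expression(
    rng: np.random.Generator,
    means: np.ndarray,
    sds: np.ndarray,
    n_samples: int,
    cfg: GeneratorConfig,
) -> np.ndarray:
    n_genes = means.size
    noise = rng.standard_normal((n_genes, n_samples))
    if cfg.block_correlation > 0 and cfg.block_size > 1:
        # shared latent factor per consecutive gene block (collinearity stress)
        n_blocks = -(-n_genes // cfg.block_size)
        shared = rng.standard_normal((n_blocks, n_samples))
        shared = np.repeat(shared, cfg.block_size, axis=0)[:n_genes]
        rho = cfg.block_correlation
        noise = np.sqrt(rho) * shared + np.sqrt(1 - rho) * noise
    return means[:, None] + sds[:, None] * noise


def generate_dataset(config: GeneratorConfig | None = None) -> SyntheticDataset:
    """Generate a reproducible train + blind synthetic panel.

    The training partition includes ``resistant_lineage_fraction`` of
    blood-lineage lines (resistant subgroup, to be excluded before model
    fitting, mirroring the screen's preprocessing); the blind partition is
    solid-tumor only.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    f = cfg.resistant_lineage_fraction
    n_blood = int(round(cfg.n_train * f / (1 - f))) if f > 0 else 0
    n_train_total = cfg.n_train + n_blood
    n_total = n_train_total + cfg.n_blind

    genes = _gene_ids(cfg.n_genes)
    means = rng.uniform(4.0, 12.0, size=cfg.n_genes)
    sds = rng.uniform(0.5, 2.0, size=cfg.n_genes)
    X = _draw_expression(rng, means, sds, n_total, cfg)

    causal_idx = np.array([i for i, _ in cfg.causal_genes])
    betas = np.array([b for _, b in cfg.causal_genes])
    z = (X[causal_idx] - means[causal_idx, None]) / sds[causal_idx, None]
    y = cfg.beta0 + betas @ z + rng.normal(0.0, cfg.noise_sd, size=n_total)

    lineage = np.array(["solid"] * n_total, dtype=object)
    tumor = rng.choice(TUMOR_TYPES[: cfg.n_tumor_types], size=n_total)
    if n_blood:
        blood_pos = np.arange(cfg.n_train, n_train_total)  # within train partition
        lineage[blood_pos] = "blood"
        tumor[blood_pos] = "leukemia"
        y[blood_pos] -= cfg.resistant_offset  # lower -log10 = more resistant

    train_ids = [f"TRAIN_{i + 1:03d}" for i in range(n_train_total)]
    blind_ids = [f"BLIND_{i + 1:03d}" for i in range(cfg.n_blind)]
    sample_ids = train_ids + blind_ids

    def _partition(cols: slice, ids: list[str]) -> tuple[ExpressionMatrix, SensitivityTable]:
        ann = pd.DataFrame(
            {"tumor_type": tumor[cols], "lineage": lineage[cols]}, index=ids
        )
        expr = ExpressionMatrix(
            pd.DataFrame(X[:, cols], index=genes, columns=ids), ann
        )
        table = pd.DataFrame(
            {
                "ic50_molar": np.power(10.0, -y[cols]),
                "tumor_type": tumor[cols],
                "lineage": lineage[cols],
            },
            index=pd.Index(ids, name="name"),
        )
        return expr, SensitivityTable(table)

    expr_train, sens_train = _partition(slice(0, n_train_total), train_ids)
    expr_blind, sens_blind = _partition(slice(n_train_total, n_total), blind_ids)

    truth = {
        "causal_genes": [genes[i] for i in causal_idx],
        "effect_sizes": dict(zip([genes[i] for i in causal_idx], betas.tolist())),
        "dominant_gene": genes[cfg.dominant_index],
        "noise_sd": cfg.noise_sd,
        "beta0": cfg.beta0,
        "resistant_offset": cfg.resistant_offset,
        "gene_means": dict(zip([genes[i] for i in causal_idx], means[causal_idx].tolist())),
        "gene_sds": dict(zip([genes[i] for i in causal_idx], sds[causal_idx].tolist())),
    }
    logger.info(
        "generated synthetic panel: %d train (%d blood) + %d blind samples, %d genes",
        n_train_total, n_blood, cfg.n_blind, cfg.n_genes,
    )
    return SyntheticDataset(expr_train, sens_train, expr_blind, sens_blind, truth)


def generate_gene_sets_fixture(
    genes: list[str],
    causal_genes: list[str],
    n_sets: int = 20,
    set_size: int = 25,
    include_causal_set: bool = True,
    seed: int = 0,
) -> GeneSetCollection:
    """Random gene sets over the synthetic universe.

    With ``include_causal_set`` the first set contains every causal gene —
    the analog of the drug's known target pathway.
    """
    if n_sets < 0 or set_size <= 0:
        raise ValidationError("n_sets must be >= 0 and set_size > 0")
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    start = 0
    if include_causal_set and n_sets > 0:
        extra = [g for g in genes if g not in set(causal_genes)]
        pad = rng.choice(extra, size=max(0, set_size - len(causal_genes)), replace=False)
        sets["SET_0001_target_pathway"] = list(causal_genes) + list(pad)
        start = 1
    for i in range(start, n_sets):
        members = rng.choice(genes, size=min(set_size, len(genes)), replace=False)
        sets[f"SET_{i + 1:04d}"] = list(members)
    return GeneSetCollection(sets, universe=list(genes))


def generate_network_fixture(
    genes: list[str],
    causal_genes: list[str] | None = None,
    degree_mean: float = 2.0,
    connect_causal: bool = True,
    seed: int = 0,
) -> InteractionNetwork:
    """Sparse Erdos-Renyi interaction network over the synthetic universe.

    Edge probability is ``degree_mean / (n - 1)``; with ``connect_causal``
    every causal pair is additionally wired as direct neighbors.
    """
    if degree_mean <= 0:
        raise ValidationError("degree_mean must be positive")
    rng = np.random.default_rng(seed)
    n = len(genes)
    p = min(1.0, degree_mean / max(1, n - 1))
    n_pairs = n * (n - 1) // 2
    m = rng.binomial(n_pairs, p)
    flat = rng.choice(n_pairs, size=min(m, n_pairs), replace=False)
    # map flat pair index k to (i, j), i < j, row-major over the upper triangle
    edges: list[tuple[str, str]] = []
    row_starts = np.cumsum([0] + [n - 1 - i for i in range(n - 1)])
    rows = np.searchsorted(row_starts, flat, side="right") - 1
    cols = rows + 1 + (flat - row_starts[rows])
    for i, j in zip(rows.tolist(), cols.tolist()):
        edges.append((genes[i], genes[j]))
    if connect_causal and causal_genes:
        for a_i, a in enumerate(causal_genes):
            for b in causal_genes[a_i + 1:]:
                edges.append((a, b))
    return InteractionNetwork(edges)
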