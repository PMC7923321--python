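"""End-to-end orchestration of the signature-derivation funnel.

The funnel mirrors a staged screen: align expression with IC50s, drop the
resistant lineage, keep genes correlated with sensitivity (p <= 0.05, both
signs), optionally narrow by pathway/network relevance, rank by RReliefF
and keep the top 100, confirm by Boruta, then eliminate genes one by one
under the two-fold + four-fold holdout criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

from .containers import (
    ExpressionMatrix,
    GeneSetCollection,
    InteractionNetwork,
    SensitivityTable,
)
from .errors import PipelineError, ValidationError
from .io import align_samples, exclude_lineage
from .screen import (
    CorrelationResult,
    RankedGeneList,
    pearson_screen,
    network_filter,
    pathway_filter,
    relieff_rank,
    select_significant,
    take_top,
)
from .select import (
    EliminationTrace,
    ModelSpec,
    SignatureModel,
    backward_eliminate,
    boruta_select,
    fit_regressor,
)

logger = logging.getLogger(__name__)

# fixed per-stage offsets from the master seed (no two stages share a stream)
STAGE_SEED_OFFSETS = {
    "simulate": 11,
    "relief": 23,
    "boruta": 37,
    "eliminate": 51,
    "split": 67,
}


def stage_seed(master_seed: int, stage: str) -> int:
    return (int(master_seed) + STAGE_SEED_OFFSETS[stage]) % (2**31)


@dataclass
class PipelineConfig:
    """Every tunable of the funnel, with the screen's defaults."""

    alpha_corr: float = 0.05
    alpha_boruta: float = 0.05
    boruta_max_iter: int = 50
    top_n_relief: int = 100
    relief_k_neighbors: int = 10
    cv_repeats: int = 5
    cv_folds: int = 10
    split_train: int = 41
    split_holdout: int = 11
    fold_thresholds: tuple[float, float] = (2.0, 4.0)
    tumor_threshold_pct: float = 60.0
    fdr_threshold: float = 0.05
    excluded_lineage: str = "blood"
    bio_filter_combine: str = "union"  # or "intersection"
    criterion_source: str = "holdout"  # or "cv"
    elimination_order: str = "relief"  # or "importance"
    model: ModelSpec = field(default_factory=ModelSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha_corr <= 1 or not 0 < self.alpha_boruta <= 1:
            raise ValidationError("alpha thresholds must be in (0, 1]")
        if self.top_n_relief < 1:
            raise ValidationError("top_n_relief must be >= 1")
        if self.split_holdout < 1:
            raise ValidationError("holdout size must be >= 1")
        if not 0 < self.tumor_threshold_pct < 100:
            raise ValidationError("tumor_threshold_pct must be in (0, 100)")
        if self.bio_filter_combine not in ("union", "intersection"):
            raise ValidationError("bio_filter_combine must be union or intersection")


@dataclass
class DerivationResult:
    """Everything the derive stage produced, for auditing and reuse."""

    correlation: CorrelationResult
    significant_genes: list[str]
    filtered_genes: list[str]
    ranking: RankedGeneList
    relief_top: list[str]
    boruta: object
    model: SignatureModel
    trace: EliminationTrace
    stage_counts: dict[str, int]
    expression: ExpressionMatrix  # aligned training expression (solid lines)
    sensitivity: SensitivityTable


def derive_signature(
    expr: ExpressionMatrix,
    sens: SensitivityTable,
    config: PipelineConfig | None = None,
    gene_sets: GeneSetCollection | None = None,
    network: InteractionNetwork | None = None,
    target_genes: list[str] | None = None,
    refit_full: bool = True,
) -> DerivationResult:
    """Run the full funnel and return the signature with its audit trail.

    ``gene_sets``/``network`` enable the optional biological filters
    (pathway membership shared with ``target_genes``, and direct network
    neighborhood); when absent the funnel goes straight from the
    correlation screen to Relief ranking. With ``refit_full`` the chosen
    genes and hyperparameters are refit on the whole training cohort for
    deployment; the internal-train model and its holdout trace stay in
    ``trace`` / ``model`` metadata.
    """
    cfg = config or PipelineConfig()
    counts: dict[str, int] = {"genes_in": len(expr.gene_ids)}

    sens = exclude_lineage(sens, cfg.excluded_lineage)
    expr, sens = align_samples(expr, sens)
    counts["samples"] = len(sens.sample_ids)
    y = sens.neglog10.to_numpy()

    corr = pearson_screen(expr, y)
    significant = select_significant(corr, cfg.alpha_corr)
    counts["correlated"] = len(significant)
    if not significant:
        raise PipelineError("no genes pass the correlation screen")

    filtered = list(significant)
    if gene_sets is not None or network is not None:
        kept: list[list[str]] = []
        if gene_sets is not None:
            if not target_genes:
                raise PipelineError("pathway filter requires target_genes")
            kept.append(pathway_filter(significant, gene_sets, target_genes))
        if network is not None:
            kept.append(network_filter(significant, network, expr.gene_ids))
        if len(kept) == 1:
            filtered = kept[0]
        elif cfg.bio_filter_combine == "union":
            union = dict.fromkeys(kept[0])
            union.update(dict.fromkeys(kept[1]))
            filtered = list(union)
        else:
            second = set(kept[1])
            filtered = [g for g in kept[0] if g in second]
        if not filtered:
            raise PipelineError("biological filters removed every candidate gene")
    counts["bio_filtered"] = len(filtered)

    ranking = relieff_rank(
        expr.subset_genes(filtered), y,
        k_neighbors=cfg.relief_k_neighbors,
        seed=stage_seed(cfg.seed, "relief"),
    )
    top = take_top(ranking, cfg.top_n_relief)
    counts["relief_top"] = len(top)

    X = expr.values.loc[top].T  # samples x genes
    boruta = boruta_select(
        X, y,
        spec=ModelSpec(
            ensemble_kind="random_forest", n_trees=100,
            seed=stage_seed(cfg.seed, "boruta"),
        ),
        alpha=cfg.alpha_boruta,
        max_iter=cfg.boruta_max_iter,
    )
    confirmed = boruta.confirmed
    counts["boruta_confirmed"] = len(confirmed)
    if len(confirmed) < 2:
        # degenerate but possible on weak data: top up with the best-ranked
        # tentative genes so elimination's precondition holds
        tentative_ranked = [g for g in ranking.genes if g in set(boruta.genes("tentative"))]
        extra = tentative_ranked[: 2 - len(confirmed)]
        if len(confirmed) + len(extra) < 2:
            raise PipelineError("fewer than 2 genes survive Boruta")
        logger.warning(
            "boruta confirmed %d gene(s); topping up with %d tentative",
            len(confirmed), len(extra),
        )
        confirmed = confirmed + extra

    if cfg.elimination_order == "importance":
        probe = fit_regressor(
            expr.values.loc[confirmed].T.to_numpy(float), y,
            cfg.model.replace(seed=stage_seed(cfg.seed, "eliminate")),
            feature_names=confirmed,
        )
        imp = pd.Series(probe.raw_importances(), index=confirmed)
        order_src = imp.sort_values(ascending=False, kind="stable").index.tolist()
    else:
        order_src = [g for g in ranking.genes if g in set(confirmed)]

    tumor = sens.table["tumor_type"].to_numpy()
    model, trace = backward_eliminate(
        expr.values.loc[confirmed].T,
        y,
        order_src,
        spec=cfg.model,
        cv_repeats=cfg.cv_repeats,
        cv_folds=cfg.cv_folds,
        split=(cfg.split_train, cfg.split_holdout),
        seed=stage_seed(cfg.seed, "eliminate"),
        tumor_type=tumor,
        criterion_source=cfg.criterion_source,
    )
    counts["signature"] = len(model.signature)
    logger.info(
        "funnel: %s", " -> ".join(f"{k}={v}" for k, v in counts.items())
    )

    if refit_full:
        from .select import _normalized_importances  # deployment refit

        full_fit = fit_regressor(
            expr.values.loc[model.signature].T.to_numpy(float), y,
            model.spec, feature_names=model.signature,
        )
        model = SignatureModel(
            signature=model.signature,
            regressor=full_fit,
            importances=_normalized_importances(full_fit),
            spec=model.spec,
            train_sample_ids=model.train_sample_ids,
            holdout_sample_ids=model.holdout_sample_ids,
        )

    return DerivationResult(
        correlation=corr,
        significant_genes=significant,
        filtered_genes=filtered,
        ranking=ranking,
        relief_top=top,
        boruta=boruta,
        model=model,
        trace=trace,
        stage_counts=counts,
        expression=expr,
        sensitivity=sens,
    )


def write_derivation_artifacts(result: DerivationResult, outdir: str | Path) -> dict[str, Path]:
    """Write the stage audit tables (TSV) and return their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    corr = result.correlation.table.copy()
    corr["significant"] = corr.index.isin(set(result.significant_genes))
    corr["bio_filtered"] = corr.index.isin(set(result.filtered_genes))
    paths["correlation"] = outdir / "correlation_screen.tsv"
    corr.to_csv(paths["correlation"], sep="\t", lineterminator="\n")

    paths["ranking"] = outdir / "relief_ranking.tsv"
    result.ranking.table.to_csv(paths["ranking"], sep="\t", lineterminator="\n")

    paths["boruta"] = outdir / "boruta_decisions.tsv"
    result.boruta.table.to_csv(paths["boruta"], sep="\t", lineterminator="\n")

    paths["trace"] = outdir / "elimination_trace.tsv"
    result.trace.table.to_csv(paths["trace"], sep="\t", index=False, lineterminator="\n")

    sig = pd.DataFrame(
        {"importance": result.model.importances},
    )
    sig.index.name = "gene"
    paths["signature"] = outdir / "signature.tsv"
    sig.to_csv(paths["signature"], sep="\t", lineterminator="\n")

    counts = pd.Series(result.stage_counts, name="count")
    counts.index.name = "stage"
    paths["counts"] = outdir / "stage_counts.tsv"
    counts.to_csv(paths["counts"], sep="\t", lineterminator="\n")
    return paths


def config_to_text(cfg: PipelineConfig) -> str:
    """Flat key=value rendering of a config (the run-manifest format)."""
    lines = []
    for f in fields(cfg):
        v = getattr(cfg, f.name)
        if isinstance(v, ModelSpec):
            for mf in fields(v):
                mv = getattr(v, mf.name)
                if isinstance(mv, tuple):
                    mv = ",".join(str(x) for x in mv)
                lines.append(f"model.{mf.name}={mv}")
        elif isinstance(v, tuple):
            lines.append(f"{f.name}={','.join(str(x) for x in v)}")
        else:
            lines.append(f"{f.name}={v}")
    return "\n".join(lines) + "\n"


def config_from_text(text: str) -> PipelineConfig:
    """Parse the key=value config dialect written by :func:`config_to_text`."""
    kv: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValidationError(f"config line {lineno}: expected key=value")
        key, val = line.split("=", 1)
        kv[key.strip()] = val.strip()

    def _convert(raw: str, target):
        if isinstance(target, bool):
            return raw.lower() in ("1", "true", "yes")
        if isinstance(target, int):
            return int(raw)
        if isinstance(target, float):
            return float(raw)
        if isinstance(target, tuple):
            parts = [p for p in raw.split(",") if p]
            return tuple(type(target[0])(p) for p in parts)
        return raw

    cfg_kwargs = {}
    model_kwargs = {}
    defaults = PipelineConfig()
    model_defaults = ModelSpec()
    for key, raw in kv.items():
        if key.startswith("model."):
            name = key[len("model."):]
            if not hasattr(model_defaults, name):
                raise ValidationError(f"unknown config key {key!r}")
            model_kwargs[name] = _convert(raw, getattr(model_defaults, name))
        else:
            if not hasattr(defaults, key) or key == "model":
                raise ValidationError(f"unknown config key {key!r}")
            cfg_kwargs[key] = _convert(raw, getattr(defaults, key))
    if model_kwargs:
        cfg_kwargs["model"] = ModelSpec(**{
            f.name: model_kwargs.get(f.name, getattr(model_defaults, f.name))
            for f in fields(model_defaults)
        })
    return PipelineConfig(**cfg_kwargs)
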