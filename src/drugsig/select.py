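"""Prediction module: Boruta confirmation and backward elimination.

Candidate genes surviving the screening funnel are confirmed or rejected by
the Boruta shadow-feature scheme (random-forest importances compared against
permuted copies, binomial test per feature). Confirmed genes then leave one
by one, worst-ranked first; at every set size a gradient-boosted tree
ensemble is tuned by repeated k-fold cross-validated RMSE on an internal
training split and scored on a held-out split by the sum of its two-fold and
four-fold IC50 accuracies. The gene set maximizing that sum (ties broken
toward fewer genes) is the signature.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import lightgbm as lgb
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import RepeatedKFold, train_test_split

from .errors import ValidationError
from .evaluate import fold_accuracy
from .screen import RankedGeneList

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1


@dataclass
class ModelSpec:
    """Tree-ensemble choice and hyperparameters.

    The default regression engine is gradient-boosted stumps with linear
    leaf models: on cohorts of ~50 lines with a wide continuous IC50
    range, piecewise-constant leaves quantize the response too coarsely to
    resolve two-/four-fold agreement, while linear leaves interpolate
    between lines and keep the tree's split-gain importance semantics.
    ``min_leaf`` (minimum samples per leaf) is the stability knob for tiny
    cohorts; ``min_leaf_grid`` is the small fixed grid searched by
    cross-validated RMSE during backward elimination.
    """

    ensemble_kind: str = "gradient_boosted_trees"
    n_trees: int = 300
    depth: int = 1
    learning_rate: float = 0.1
    min_leaf: int = 20
    min_leaf_grid: tuple[int, ...] = (10, 20)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.depth < 1:
            raise ValidationError("n_trees and depth must be >= 1")
        if self.min_leaf < 1:
            raise ValidationError("min_leaf must be >= 1")
        if self.ensemble_kind not in ("gradient_boosted_trees", "random_forest"):
            raise ValidationError(f"unknown ensemble kind {self.ensemble_kind!r}")

    def replace(self, **kw) -> "ModelSpec":
        d = self.__dict__ | kw
        return ModelSpec(**d)


class FittedRegressor:
    """Thin handle around a fitted tree ensemble: predict + raw importances."""

    def __init__(self, model, feature_names: list[str], spec: ModelSpec):
        self.model = model
        self.feature_names = list(feature_names)
        self.spec = spec

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValidationError(
                f"expected {len(self.feature_names)} feature column(s), got {X.shape}"
            )
        if isinstance(self.model, lgb.LGBMRegressor):
            X = pd.DataFrame(X, columns=self.feature_names)
        return np.asarray(self.model.predict(X), dtype=float)

    def raw_importances(self) -> np.ndarray:
        if isinstance(self.model, (lgb.LGBMRegressor, lgb.Booster)):
            booster = self.model if isinstance(self.model, lgb.Booster) else self.model.booster_
            return np.asarray(booster.feature_importance(importance_type="gain"), dtype=float)
        return np.asarray(self.model.feature_importances_, dtype=float)


def fit_regressor(X, y, spec: ModelSpec, feature_names: list[str] | None = None) -> FittedRegressor:
    """Fit the configured tree ensemble; deterministic for a fixed seed.

    A zero-variance target yields a constant predictor with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValidationError("X must be samples x features aligned with y")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValidationError("missing values are not allowed")
    if X.shape[0] < 5:
        raise ValidationError("need at least 5 samples to fit")
    if y.std() == 0:
        warnings.warn("target has zero variance; fitting a constant predictor")
    names = feature_names if feature_names is not None else [f"f{i}" for i in range(X.shape[1])]
    if spec.ensemble_kind == "gradient_boosted_trees":
        model = lgb.LGBMRegressor(
            linear_tree=True,
            n_estimators=spec.n_trees,
            max_depth=spec.depth,
            num_leaves=spec.depth + 1,
            learning_rate=spec.learning_rate,
            min_child_samples=min(spec.min_leaf, max(1, X.shape[0] // 2)),
            random_state=spec.seed % (2**31),
            deterministic=True,
            n_jobs=1,
            verbose=-1,
        )
        model.fit(pd.DataFrame(X, columns=names), y)
        return FittedRegressor(model, names, spec)
    else:
        model = RandomForestRegressor(
            n_estimators=spec.n_trees,
            max_depth=None,
            max_features=1 / 3,
            random_state=spec.seed % (2**31),
            n_jobs=1,
        )
    model.fit(X, y)
    return FittedRegressor(model, names, spec)


@dataclass
class SelectionDecision:
    """Boruta verdicts: one of confirmed/rejected/tentative per candidate."""

    table: pd.DataFrame  # index gene; columns verdict, hits, iterations
    iterations: int

    def genes(self, verdict: str) -> list[str]:
        return self.table.index[self.table["verdict"] == verdict].tolist()

    @property
    def confirmed(self) -> list[str]:
        return self.genes("confirmed")


def boruta_select(
    X: pd.DataFrame,
    y,
    spec: ModelSpec | None = None,
    alpha: float = 0.05,
    max_iter: int = 50,
) -> SelectionDecision:
    """Shadow-feature selection with a random forest.

    Each round appends a permuted (shadow) copy of every still-active
    feature, fits the forest, and records a hit for features whose
    importance beats the best shadow. From round 5 onward a two-sided
    binomial test at ``alpha`` with Bonferroni correction across all
    candidates confirms or rejects features; undecided features at
    ``max_iter`` are tentative. Rejected features leave the model matrix.
    """
    if max_iter < 5:
        raise ValidationError("max_iter must be >= 5 (binomial test is underpowered)")
    if X.shape[1] < 2:
        raise ValidationError("need at least 2 candidate genes")
    spec = spec or ModelSpec(ensemble_kind="random_forest", n_trees=100)
    rf_spec = spec if spec.ensemble_kind == "random_forest" else spec.replace(
        ensemble_kind="random_forest", n_trees=100
    )
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(rf_spec.seed)
    genes = list(X.columns)
    n_all = len(genes)
    active = list(genes)
    hits = {g: 0 for g in genes}
    verdict = {g: "tentative" for g in genes}
    it = 0
    for it in range(1, max_iter + 1):
        if not active:
            it -= 1
            break
        Xa = X[active].to_numpy(dtype=float)
        shadows = Xa.copy()
        for j in range(shadows.shape[1]):
            shadows[:, j] = rng.permutation(shadows[:, j])
        Xfull = np.hstack([Xa, shadows])
        fit = fit_regressor(
            Xfull, y, rf_spec.replace(seed=rf_spec.seed + it),
            feature_names=[*active, *(f"shadow_{g}" for g in active)],
        )
        imp = fit.raw_importances()
        real, shadow = imp[: len(active)], imp[len(active):]
        shadow_max = shadow.max()
        for g, v in zip(active, real):
            if v > shadow_max:
                hits[g] += 1
        if it >= 5:
            thr = alpha / n_all  # Bonferroni across candidates
            decided = []
            for g in active:
                p_hi = stats.binom.sf(hits[g] - 1, it, 0.5)
                p_lo = stats.binom.cdf(hits[g], it, 0.5)
                if p_hi < thr:
                    verdict[g] = "confirmed"
                    decided.append(g)
                elif p_lo < thr:
                    verdict[g] = "rejected"
                    decided.append(g)
            active = [g for g in active if g not in set(decided)]
    table = pd.DataFrame(
        {
            "verdict": [verdict[g] for g in genes],
            "hits": [hits[g] for g in genes],
            "iterations": it,
        },
        index=pd.Index(genes, name="gene"),
    )
    counts = table["verdict"].value_counts().to_dict()
    logger.info("boruta_select: %s after %d iteration(s)", counts, it)
    return SelectionDecision(table, it)


@dataclass
class EliminationTrace:
    """Audit table of the one-by-one elimination loop.

    One row per gene-set size, largest first: the gene set, the tuned
    depth, cross-validated RMSE, holdout two-/four-fold accuracies and
    their sum (the selection criterion), and the gene removed next.
    """

    table: pd.DataFrame
    gene_sets: list[list[str]]

    def as_frame(self) -> pd.DataFrame:
        return self.table.copy()


@dataclass
class SignatureModel:
    """The final signature: genes, fitted ensemble, normalized importances."""

    signature: list[str]
    regressor: FittedRegressor
    importances: pd.Series  # indexed by gene, sums to 1
    spec: ModelSpec
    train_sample_ids: list[str] = field(default_factory=list)
    holdout_sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(float(self.importances.sum()) - 1.0) > 1e-9:
            raise ValidationError("importances must sum to 1")
        if list(self.importances.index) != list(self.signature):
            self.importances = self.importances.reindex(self.signature)

    def predict(self, X) -> np.ndarray:
        return self.regressor.predict(X)


def variable_importance(model: SignatureModel) -> pd.DataFrame:
    """Normalized importances, descending, ties broken by gene id."""
    if model.regressor is None:
        raise ValidationError("model is not fitted")
    df = model.importances.rename("importance").reset_index()
    df.columns = ["gene", "importance"]
    return (
        df.sort_values(["importance", "gene"], ascending=[False, True], kind="stable")
        .set_index("gene")
    )


def _normalized_importances(fit: FittedRegressor) -> pd.Series:
    raw = fit.raw_importances()
    total = raw.sum()
    if total <= 0:
        warnings.warn("all raw importances are zero; assigning uniform weights")
        raw = np.ones_like(raw)
        total = raw.sum()
    return pd.Series(raw / total, index=fit.feature_names)


def _cv_rmse(
    X: np.ndarray, y: np.ndarray, spec: ModelSpec, repeats: int, folds: int, seed: int
) -> tuple[float, np.ndarray]:
    """Pooled RMSE over repeated k-fold CV, plus per-sample mean OOF prediction."""
    n = y.size
    folds = min(folds, n)
    rkf = RepeatedKFold(n_splits=folds, n_repeats=repeats, random_state=seed % (2**31))
    sq_errs: list[np.ndarray] = []
    oof_sum = np.zeros(n)
    oof_cnt = np.zeros(n)
    for fold_i, (tr, va) in enumerate(rkf.split(X)):
        fit = fit_regressor(X[tr], y[tr], spec.replace(seed=seed + fold_i))
        pred = fit.predict(X[va])
        sq_errs.append((pred - y[va]) ** 2)
        oof_sum[va] += pred
        oof_cnt[va] += 1
    rmse_val = float(np.sqrt(np.concatenate(sq_errs).mean()))
    return rmse_val, oof_sum / oof_cnt


def _split_samples(
    n: int,
    split: tuple[int, int] | float,
    seed: int,
    strata: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(split, tuple):
        n_train, n_hold = split
        if n_train + n_hold == n:
            test_size: float | int = n_hold
        else:
            test_size = max(1, int(round(n * n_hold / (n_train + n_hold))))
    else:
        test_size = split
    idx = np.arange(n)
    kwargs = dict(test_size=test_size, random_state=seed % (2**31), shuffle=True)
    if strata is not None:
        _, counts = np.unique(strata, return_counts=True)
        if counts.min() >= 2 and len(counts) <= (
            test_size if isinstance(test_size, int) else int(n * test_size)
        ):
            try:
                return train_test_split(idx, stratify=strata, **kwargs)
            except ValueError:
                pass  # fall through to unstratified
    return train_test_split(idx, **kwargs)


def backward_eliminate(
    X: pd.DataFrame,
    y,
    rank_order: RankedGeneList | list[str],
    spec: ModelSpec | None = None,
    cv_repeats: int = 5,
    cv_folds: int = 10,
    split: tuple[int, int] | float = (41, 11),
    seed: int = 0,
    tumor_type=None,
    criterion_source: str = "holdout",
) -> tuple[SignatureModel, EliminationTrace]:
    """One-by-one elimination under the two-fold + four-fold criterion.

    Parameters
    ----------
    X, y
        Samples x confirmed-genes matrix and the -log10(Molar) target.
    rank_order
        Screening ranking; the worst-ranked remaining gene leaves at each
        step. Genes in X absent from the ranking leave first.
    split
        Internal-train / holdout sizes. When the sizes do not add up to the
        cohort, the holdout proportion is preserved. A single random split,
        stratified by ``tumor_type`` when feasible.
    criterion_source
        ``holdout`` scores each step's accuracies on the held-out split
        (default); ``cv`` scores them on pooled out-of-fold predictions.
    """
    spec = spec or ModelSpec()
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise ValidationError("X and y are misaligned")
    if X.shape[0] < cv_folds and criterion_source == "holdout":
        cv_folds = min(cv_folds, X.shape[0])
    if isinstance(split, tuple) and split[1] == 0:
        raise ValidationError("holdout size must be positive")
    if criterion_source not in ("holdout", "cv"):
        raise ValidationError(f"unknown criterion_source {criterion_source!r}")

    ranked = rank_order.genes if isinstance(rank_order, RankedGeneList) else list(rank_order)
    in_rank = [g for g in ranked if g in set(X.columns)]
    unranked = sorted(g for g in X.columns if g not in set(ranked))
    order = in_rank + unranked  # best ... worst; unranked treated as worst
    order = list(dict.fromkeys(order))
    if len(order) < 2:
        raise ValidationError("need at least 2 confirmed genes")
    if unranked:
        logger.warning("backward_eliminate: %d gene(s) missing from ranking", len(unranked))

    strata = np.asarray(tumor_type) if tumor_type is not None else None
    tr_idx, ho_idx = _split_samples(X.shape[0], split, seed, strata)
    tr_idx, ho_idx = np.sort(tr_idx), np.sort(ho_idx)
    Xtr_all = X.iloc[tr_idx]
    Xho_all = X.iloc[ho_idx]
    ytr, yho = y[tr_idx], y[ho_idx]

    rows = []
    gene_sets: list[list[str]] = []
    current = list(order)
    step = 0
    while current:
        step += 1
        Xtr = Xtr_all[current].to_numpy(dtype=float)
        best = None
        for min_leaf in spec.min_leaf_grid:
            cand = spec.replace(min_leaf=min_leaf)
            rmse_val, oof = _cv_rmse(Xtr, ytr, cand, cv_repeats, cv_folds, seed + step)
            if best is None or rmse_val < best[0] - 1e-12:
                best = (rmse_val, cand, oof)
        rmse_val, tuned, oof = best
        fit = fit_regressor(
            Xtr, ytr, tuned.replace(seed=seed + step), feature_names=current
        )
        if criterion_source == "holdout":
            pred = fit.predict(Xho_all[current].to_numpy(dtype=float))
            ref = yho
        else:
            pred, ref = oof, ytr
        pm, am = np.power(10.0, -pred), np.power(10.0, -ref)
        two = fold_accuracy(pm, am, 2.0)
        four = fold_accuracy(pm, am, 4.0)
        removed = current[-1] if len(current) > 1 else ""
        rows.append(
            {
                "step": step,
                "n_genes": len(current),
                "removed_gene": removed,
                "min_leaf": tuned.min_leaf,
                "cv_rmse": rmse_val,
                "twofold": two,
                "fourfold": four,
                "criterion": two + four,
            }
        )
        gene_sets.append(list(current))
        current = current[:-1]

    trace_df = pd.DataFrame(rows)
    # argmax of the criterion; ">=" walks toward later (smaller) sets on ties
    best_i = 0
    for i in range(len(rows)):
        if rows[i]["criterion"] >= rows[best_i]["criterion"] - 1e-12 and (
            rows[i]["criterion"] > rows[best_i]["criterion"] + 1e-12
            or rows[i]["n_genes"] < rows[best_i]["n_genes"]
        ):
            best_i = i
    best_genes = gene_sets[best_i]
    best_min_leaf = int(trace_df.loc[best_i, "min_leaf"])
    final_spec = spec.replace(min_leaf=best_min_leaf, seed=seed + best_i + 1)
    final_fit = fit_regressor(
        Xtr_all[best_genes].to_numpy(dtype=float), ytr, final_spec, feature_names=best_genes
    )
    model = SignatureModel(
        signature=best_genes,
        regressor=final_fit,
        importances=_normalized_importances(final_fit),
        spec=final_spec,
        train_sample_ids=[str(s) for s in X.index[tr_idx]],
        holdout_sample_ids=[str(s) for s in X.index[ho_idx]],
    )
    logger.info(
        "backward_eliminate: chose %d gene(s) at criterion %.3f (step %d of %d)",
        len(best_genes), rows[best_i]["criterion"], best_i + 1, len(rows),
    )
    return model, EliminationTrace(trace_df, gene_sets)


def save_signature_model(model: SignatureModel, path) -> None:
    """Serialize gene list, importances and the boosted-tree blob as JSON."""
    if model.spec.ensemble_kind != "gradient_boosted_trees":
        raise ValidationError("only gradient_boosted_trees models are serializable")
    reg = model.regressor.model
    booster = reg if isinstance(reg, lgb.Booster) else reg.booster_
    payload = {
        "format_version": FORMAT_VERSION,
        "signature": model.signature,
        "importances": {g: float(v) for g, v in model.importances.items()},
        "spec": {
            "ensemble_kind": model.spec.ensemble_kind,
            "n_trees": model.spec.n_trees,
            "depth": model.spec.depth,
            "learning_rate": model.spec.learning_rate,
            "min_leaf": model.spec.min_leaf,
            "seed": model.spec.seed,
        },
        "train_sample_ids": model.train_sample_ids,
        "holdout_sample_ids": model.holdout_sample_ids,
        "booster": booster.model_to_string(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_signature_model(path) -> SignatureModel:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format_version") != FORMAT_VERSION:
        raise ValidationError("unsupported model format version")
    spec = ModelSpec(
        ensemble_kind=payload["spec"]["ensemble_kind"],
        n_trees=payload["spec"]["n_trees"],
        depth=payload["spec"]["depth"],
        learning_rate=payload["spec"]["learning_rate"],
        min_leaf=payload["spec"].get("min_leaf", 20),
        seed=payload["spec"]["seed"],
    )
    booster = lgb.Booster(model_str=payload["booster"])
    fitted = FittedRegressor(booster, payload["signature"], spec)
    return SignatureModel(
        signature=payload["signature"],
        regressor=fitted,
        importances=pd.Series(payload["importances"]).reindex(payload["signature"]),
        spec=spec,
        train_sample_ids=payload.get("train_sample_ids", []),
        holdout_sample_ids=payload.get("holdout_sample_ids", []),
    )
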