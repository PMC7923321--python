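"""Blind-set evaluation: predictions, fold accuracy, agreement, classification.

Fold accuracy is the screen's headline metric: the fraction of lines whose
predicted and actual IC50 differ by at most a factor of k (k = 2 and 4).
Samples are then classified sensitive/resistant by the z-score of predicted
sensitivity within the cohort, and tumor types by a >60% majority of their
lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .errors import ValidationError

logger = logging.getLogger(__name__)

# relative slack so that exactly-k-fold pairs stay "within k" despite
# floating-point log/ratio rounding (boundary is inclusive by design)
_FOLD_RTOL = 1e-9


@dataclass
class PredictionResult:
    """Per-sample predictions on both scales plus cohort z-scores/classes.

    ``table``: index sample, columns ``pred_neglog10``, ``pred_ic50_molar``,
    ``z``, ``call`` and (when known) ``tumor_type`` / ``lineage``.
    z is computed on the -log10(Molar) sensitivity scale, so z > 0 means
    more sensitive than the cohort mean.
    """

    table: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass
class AgreementReport:
    n: int
    twofold: float
    fourfold: float
    pearson_r: float
    pearson_p: float
    rmse: float

    def __post_init__(self) -> None:
        if self.fourfold + 1e-12 < self.twofold:
            raise ValidationError("four-fold accuracy cannot be below two-fold")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": [self.n],
                "twofold_pct": [round(100 * self.twofold, 2)],
                "fourfold_pct": [round(100 * self.fourfold, 2)],
                "pearson_r": [self.pearson_r],
                "pearson_p": [self.pearson_p],
                "rmse_neglog10": [self.rmse],
            }
        )


@dataclass
class TumorTypeSummary:
    """Per tumor type: line count, % predicted sensitive, majority class."""

    table: pd.DataFrame  # index tumor_type, columns n, pct_sensitive, call
    n_excluded_unlabeled: int = 0


def predict_ic50(model, expr: ExpressionMatrix) -> PredictionResult:
    """Apply a fitted signature model to an expression cohort.

    ``model`` is a :class:`~drugsig.select.SignatureModel`. All signature
    genes must be measured; cohorts of one sample have no defined z-score
    and are rejected (use ``model.predict`` directly for raw values).
    """
    missing = [g for g in model.signature if g not in set(expr.gene_ids)]
    if missing:
        raise ValidationError(f"signature genes missing from expression data: {missing}")
    if len(expr.sample_ids) < 2:
        raise ValidationError(
            "cohort of <2 samples has no z-score; call model.predict for raw values"
        )
    X = expr.values.loc[model.signature].to_numpy(dtype=float).T
    pred = np.asarray(model.predict(X), dtype=float)
    sd = pred.std(ddof=0)
    if sd <= 1e-12 * max(1.0, float(np.abs(pred).max())):
        raise ValidationError("all predictions identical; z-scores undefined")
    z = (pred - pred.mean()) / sd
    table = pd.DataFrame(
        {
            "pred_neglog10": pred,
            "pred_ic50_molar": np.power(10.0, -pred),
            "z": z,
            "call": np.where(z > 0, "sensitive", "resistant"),
        },
        index=pd.Index(expr.sample_ids, name="name"),
    )
    ann = expr.sample_annotations
    for col in ("tumor_type", "lineage"):
        if col in ann.columns:
            table[col] = ann.reindex(table.index)[col]
    logger.info(
        "predict_ic50: %d samples, %d sensitive / %d resistant",
        len(table), int((z > 0).sum()), int((z <= 0).sum()),
    )
    return PredictionResult(table)


def fold_accuracy(predicted, actual, k: float) -> float:
    """Fraction of pairs whose IC50s (Molar) agree within a factor of k.

    "Within k-fold" means max(p, a) / min(p, a) <= k, boundary inclusive;
    symmetric in its arguments and invariant to a common rescaling.
    """
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape:
        raise ValidationError("predicted and actual have different lengths")
    if p.size == 0:
        raise ValidationError("empty input")
    if not ((p > 0).all() and (a > 0).all()):
        raise ValidationError("IC50 values must be positive")
    if k < 1:
        raise ValidationError("fold threshold must be >= 1")
    ratio = np.maximum(p, a) / np.minimum(p, a)
    within = ratio <= k * (1.0 + _FOLD_RTOL)
    return float(within.sum()) / p.size


def pearson_agreement(predicted, actual) -> tuple[float, float]:
    """Pearson r and two-sided p between predicted and actual -log10 IC50."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape:
        raise ValidationError("predicted and actual have different lengths")
    if p.size < 4:
        raise ValidationError("need at least 4 pairs")
    if p.std() == 0 or a.std() == 0:
        raise ValidationError("zero-variance vector; correlation undefined")
    res = stats.pearsonr(p, a)
    return float(res.statistic), float(res.pvalue)


def rmse(predicted, actual) -> float:
    """Root-mean-square error on the -log10(Molar) scale."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape:
        raise ValidationError("predicted and actual have different lengths")
    return float(np.sqrt(np.mean((p - a) ** 2)))


def agreement_report(pred_neglog10, actual_neglog10) -> AgreementReport:
    """Bundle two-/four-fold accuracy, Pearson agreement and RMSE."""
    p = np.asarray(pred_neglog10, dtype=float)
    a = np.asarray(actual_neglog10, dtype=float)
    pm, am = np.power(10.0, -p), np.power(10.0, -a)
    r, pv = pearson_agreement(p, a)
    return AgreementReport(
        n=p.size,
        twofold=fold_accuracy(pm, am, 2.0),
        fourfold=fold_accuracy(pm, am, 4.0),
        pearson_r=r,
        pearson_p=pv,
        rmse=rmse(p, a),
    )


def zscore_classify(values_neglog10, sample_ids=None) -> pd.DataFrame:
    """Standardize a sensitivity cohort and call sensitive/resistant.

    z is computed on the -log10(Molar) scale (higher = more sensitive);
    z > 0 is called sensitive, z <= 0 resistant (ties go to resistant).
    """
    v = np.asarray(values_neglog10, dtype=float)
    if v.size < 2:
        raise ValidationError("z-score classification needs a cohort of >= 2")
    sd = v.std(ddof=0)
    if sd <= 1e-12 * max(1.0, float(np.abs(v).max())):
        raise ValidationError("zero-variance cohort; z-scores undefined")
    z = (v - v.mean()) / sd
    idx = pd.Index(sample_ids if sample_ids is not None else range(v.size), name="name")
    out = pd.DataFrame(
        {"neglog10": v, "z": z, "call": np.where(z > 0, "sensitive", "resistant")},
        index=idx,
    )
    logger.info(
        "zscore_classify: %d sensitive, %d resistant of %d",
        int((z > 0).sum()), int((z <= 0).sum()), v.size,
    )
    return out


def tumor_type_classify(
    predictions: PredictionResult, threshold_pct: float = 60.0
) -> TumorTypeSummary:
    """Call each tumor type sensitive/resistant/mixed by a strict majority.

    A type is sensitive when strictly more than ``threshold_pct`` percent of
    its lines are predicted sensitive; resistant symmetrically; otherwise
    mixed. Unlabeled samples are excluded (count logged).
    """
    df = predictions.table
    if "tumor_type" not in df.columns:
        raise ValidationError("predictions carry no tumor_type labels")
    labeled = df[df["tumor_type"].notna() & (df["tumor_type"].astype(str) != "")]
    n_excluded = len(df) - len(labeled)
    if n_excluded:
        logger.info("tumor_type_classify: excluded %d unlabeled sample(s)", n_excluded)
    rows = []
    for ttype, group in labeled.groupby("tumor_type", sort=True):
        n = len(group)
        pct = 100.0 * (group["call"] == "sensitive").sum() / n
        if pct > threshold_pct:
            call = "sensitive"
        elif (100.0 - pct) > threshold_pct:
            call = "resistant"
        else:
            call = "mixed"
        rows.append({"tumor_type": ttype, "n": n, "pct_sensitive": pct, "call": call})
    table = pd.DataFrame(rows).set_index("tumor_type")
    return TumorTypeSummary(table, n_excluded)
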