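"""Fold accuracy, agreement metrics and responder classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drugsig import (
    ExpressionMatrix,
    ModelSpec,
    SignatureModel,
    ValidationError,
    agreement_report,
    fit_regressor,
    fold_accuracy,
    pearson_agreement,
    predict_ic50,
    rmse,
    tumor_type_classify,
    zscore_classify,
)
from drugsig.evaluate import PredictionResult

molar = st.floats(min_value=1e-10, max_value=1e-3)


class TestFoldAccuracy:
    def test_exact_agreement_is_one(self):
        v = [1e-7, 3e-6, 5e-8]
        assert fold_accuracy(v, v, 2) == 1.0
        assert fold_accuracy(v, v, 1) == 1.0

    def test_boundary_exactly_twofold_is_within(self):
        assert fold_accuracy([2e-7], [1e-7], 2) == 1.0
        assert fold_accuracy([1e-7], [2e-7], 2) == 1.0
        assert fold_accuracy([2.1e-7], [1e-7], 2) == 0.0

    def test_thirty_two_of_thirty_seven_within_fourfold(self):
        actual = np.full(37, 1e-6)
        predicted = np.concatenate([np.full(32, 3.9e-6), np.full(5, 5e-6)])
        acc = fold_accuracy(predicted, actual, 4)
        assert acc == pytest.approx(32 / 37)
        assert f"{100 * acc:.2f}" == "86.49"

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(molar, molar), min_size=1, max_size=30),
           st.sampled_from([2.0, 4.0]))
    def test_symmetry_and_scale_invariance(self, pairs, k):
        p = np.array([a for a, _ in pairs])
        a = np.array([b for _, b in pairs])
        assert fold_accuracy(p, a, k) == fold_accuracy(a, p, k)
        assert fold_accuracy(p * 37.0, a * 37.0, k) == pytest.approx(fold_accuracy(p, a, k))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(molar, molar), min_size=1, max_size=30))
    def test_fourfold_at_least_twofold(self, pairs):
        p = np.array([a for a, _ in pairs])
        a = np.array([b for _, b in pairs])
        assert fold_accuracy(p, a, 4) >= fold_accuracy(p, a, 2)

    def test_validation(self):
        with pytest.raises(ValidationError):
            fold_accuracy([1e-7], [1e-7, 1e-6], 2)
        with pytest.raises(ValidationError):
            fold_accuracy([0.0], [1e-7], 2)


class TestAgreement:
    def test_perfect_and_inverted_correlation(self):
        x = np.array([5.0, 6.0, 7.0, 8.0])
        r, _ = pearson_agreement(x, x)
        assert r == pytest.approx(1.0)
        r, _ = pearson_agreement(x, -x + 13.0)
        assert r == pytest.approx(-1.0)

    def test_matches_bruteforce_formulas(self, rng):
        p = rng.normal(6, 1, size=10)
        a = rng.normal(6, 1, size=10)
        r, pval = pearson_agreement(p, a)
        mp, ma = p.mean(), a.mean()
        num = float(((p - mp) * (a - ma)).sum())
        den = math.sqrt(float(((p - mp) ** 2).sum() * ((a - ma) ** 2).sum()))
        r_exp = num / den
        assert r == pytest.approx(r_exp, abs=1e-10)
        from scipy.stats import t as tdist

        t = r_exp * math.sqrt(8 / (1 - r_exp**2))
        assert pval == pytest.approx(2 * tdist.sf(abs(t), 8), rel=1e-8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson_agreement(np.ones(5), np.arange(5.0))

    def test_rmse_closed_forms(self, rng):
        x = rng.normal(size=12)
        assert rmse(x, x) == 0.0
        assert rmse(x + 0.7, x) == pytest.approx(0.7, abs=1e-12)
        y = rng.normal(size=12)
        assert rmse(x, y) == pytest.approx(math.sqrt(np.mean((x - y) ** 2)), abs=1e-12)

    def test_agreement_report_invariant(self, rng):
        p = rng.normal(6, 1, size=20)
        a = p + rng.normal(0, 0.4, size=20)
        rep = agreement_report(p, a)
        assert rep.fourfold >= rep.twofold
        assert 0 <= rep.twofold <= 1 and 0 <= rep.fourfold <= 1


class TestZScoreClassify:
    def test_two_sample_cohort_splits(self):
        out = zscore_classify([7.0, 6.0], ["A", "B"])
        assert out.loc["A", "call"] == "sensitive"
        assert out.loc["B", "call"] == "resistant"

    def test_classes_partition_cohort(self, rng):
        v = rng.normal(6, 1, size=200)
        out = zscore_classify(v)
        n_sens = (out["call"] == "sensitive").sum()
        n_res = (out["call"] == "resistant").sum()
        assert n_sens + n_res == 200

    def test_z_exactly_zero_called_resistant(self):
        out = zscore_classify([5.0, 5.0, 6.0, 4.0], list("ABCD"))
        assert out.loc["A", "z"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["A", "call"] == "resistant"

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=3, max_value=9), min_size=3, max_size=30).filter(
            lambda v: max(v) - min(v) > 1e-6
        ),
        st.floats(min_value=0.1, max_value=5),
        st.floats(min_value=-3, max_value=3),
    )
    def test_affine_invariance(self, values, slope, shift):
        base = zscore_classify(values)
        moved = zscore_classify([slope * v + shift for v in values])
        assert list(base["call"]) == list(moved["call"])
        assert np.allclose(base["z"], moved["z"], atol=1e-6)

    def test_degenerate_cohorts_rejected(self):
        with pytest.raises(ValidationError):
            zscore_classify([5.0])
        with pytest.raises(ValidationError):
            zscore_classify([5.0, 5.0, 5.0])


class TestTumorTypeClassify:
    def _predictions(self, rows):
        df = pd.DataFrame(rows, columns=["name", "call", "tumor_type"]).set_index("name")
        df["z"] = np.where(df["call"] == "sensitive", 1.0, -1.0)
        df["pred_neglog10"] = 6.0 + df["z"]
        return PredictionResult(df)

    def test_strict_majority_rule(self):
        rows = [(f"S{i}", "sensitive" if i < 7 else "resistant", "ovarian") for i in range(10)]
        summary = tumor_type_classify(self._predictions(rows))
        assert summary.table.loc["ovarian", "call"] == "sensitive"
        assert summary.table.loc["ovarian", "pct_sensitive"] == pytest.approx(70.0)

    def test_exact_sixty_percent_is_mixed(self):
        rows = [(f"S{i}", "sensitive" if i < 6 else "resistant", "lung") for i in range(10)]
        summary = tumor_type_classify(self._predictions(rows))
        assert summary.table.loc["lung", "call"] == "mixed"

    def test_three_type_tally_matches_counting_oracle(self, rng):
        rows = []
        for i in range(60):
            ttype = ["breast", "colon", "skin"][i % 3]
            call = "sensitive" if rng.uniform() < 0.5 else "resistant"
            rows.append((f"S{i}", call, ttype))
        summary = tumor_type_classify(self._predictions(rows))
        df = pd.DataFrame(rows, columns=["name", "call", "tumor_type"])
        for ttype, group in df.groupby("tumor_type"):
            pct = 100 * (group["call"] == "sensitive").mean()
            expected = "sensitive" if pct > 60 else "resistant" if (100 - pct) > 60 else "mixed"
            assert summary.table.loc[ttype, "call"] == expected
            assert summary.table.loc[ttype, "pct_sensitive"] == pytest.approx(pct)

    def test_unlabeled_samples_excluded(self):
        rows = [("S0", "sensitive", "lung"), ("S1", "resistant", "lung"),
                ("S2", "sensitive", "")]
        summary = tumor_type_classify(self._predictions(rows))
        assert summary.n_excluded_unlabeled == 1
        assert summary.table.loc["lung", "n"] == 2


class TestPredictIC50:
    def _model(self, rng, genes):
        X = rng.normal(size=(30, len(genes)))
        y = 2.0 * X[:, 0] + 6.0 + rng.normal(size=30) * 0.1
        fit = fit_regressor(X, y, ModelSpec(seed=0), feature_names=genes)
        imp = pd.Series(np.full(len(genes), 1 / len(genes)), index=genes)
        return SignatureModel(signature=genes, regressor=fit, importances=imp,
                              spec=ModelSpec(seed=0))

    def _expr(self, rng, genes, samples):
        return ExpressionMatrix(
            pd.DataFrame(rng.normal(size=(len(genes), len(samples))),
                         index=genes, columns=samples)
        )

    def test_missing_signature_gene_lists_it(self, rng):
        model = self._model(rng, ["A", "B"])
        expr = self._expr(rng, ["A"], ["S1", "S2"])
        with pytest.raises(ValidationError, match="B"):
            predict_ic50(model, expr)

    def test_z_has_mean_zero_sd_one(self, rng):
        model = self._model(rng, ["A", "B"])
        expr = self._expr(rng, ["A", "B"], [f"S{i}" for i in range(12)])
        pred = predict_ic50(model, expr)
        assert pred.table["z"].mean() == pytest.approx(0.0, abs=1e-9)
        assert pred.table["z"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(pred.table["pred_ic50_molar"],
                           10.0 ** -pred.table["pred_neglog10"])

    def test_identical_profiles_rejected_for_z(self, rng):
        model = self._model(rng, ["A", "B"])
        col = rng.normal(size=2)
        expr = ExpressionMatrix(
            pd.DataFrame(np.tile(col[:, None], 3), index=["A", "B"],
                         columns=["S1", "S2", "S3"])
        )
        with pytest.raises(ValidationError):
            predict_ic50(model, expr)

    def test_sample_order_equivariance(self, rng):
        model = self._model(rng, ["A", "B"])
        samples = [f"S{i}" for i in range(8)]
        expr = self._expr(rng, ["A", "B"], samples)
        pred1 = predict_ic50(model, expr)
        perm = list(reversed(samples))
        pred2 = predict_ic50(model, expr.subset_samples(perm))
        pd.testing.assert_frame_equal(
            pred1.table.loc[perm].drop(columns=["tumor_type", "lineage"], errors="ignore"),
            pred2.table.drop(columns=["tumor_type", "lineage"], errors="ignore"),
        )

    def test_single_sample_cohort_rejected(self, rng):
        model = self._model(rng, ["A"])
        expr = self._expr(rng, ["A"], ["S1"])
        with pytest.raises(ValidationError):
            predict_ic50(model, expr)
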