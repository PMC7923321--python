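"""Correlation screen, biological filters and Relief ranking."""

import math

import numpy as np
import pandas as pd
import pytest

from drugsig import (
    ExpressionMatrix,
    GeneSetCollection,
    InteractionNetwork,
    PipelineError,
    ValidationError,
    network_filter,
    pathway_filter,
    pearson_screen,
    relieff_rank,
    select_significant,
    select_top_correlates,
    take_top,
)


def _expr(arr, genes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"G{i:03d}" for i in range(arr.shape[0])]
    samples = samples or [f"S{i:03d}" for i in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples))


def _pearson_oracle(x, y):
    """Brute-force two-pass product-moment formulas, plain Python loops."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    r = num / den
    t = r * math.sqrt((n - 2) / (1 - r * r))
    from scipy.stats import t as tdist

    return r, 2 * tdist.sf(abs(t), n - 2)


class TestPearsonScreen:
    def test_gene_identical_to_target_has_r_one(self):
        y = np.array([1.0, 2.0, 5.0, 3.0, 4.0])
        expr = _expr(np.vstack([y, np.ones(5) + [0, 1, 0, 1, 0]]))
        res = pearson_screen(expr, y)
        assert res.table.loc["G000", "r"] == pytest.approx(1.0)
        assert res.table.loc["G000", "p"] > 0  # reported at the smallest positive float

    def test_worked_five_sample_vectors(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        r_exp, p_exp = _pearson_oracle(x, y)
        res = pearson_screen(_expr([x, [1, 2, 2, 1, 2]]), np.array(y))
        assert res.table.loc["G000", "r"] == pytest.approx(r_exp, abs=1e-12)
        assert res.table.loc["G000", "p"] == pytest.approx(p_exp, rel=1e-10)
        assert res.table.loc["G000", "r"] == pytest.approx(0.8)

    def test_matches_bruteforce_on_random_matrix(self, rng):
        X = rng.normal(size=(20, 30))
        y = rng.normal(size=30)
        res = pearson_screen(_expr(X), y)
        for i, gene in enumerate(res.table.index):
            r_exp, p_exp = _pearson_oracle(list(X[i]), list(y))
            assert res.table.loc[gene, "r"] == pytest.approx(r_exp, abs=1e-10)
            assert res.table.loc[gene, "p"] == pytest.approx(p_exp, rel=1e-8)

    def test_p_magnitude_at_screen_scale(self):
        """r = 0.775 at n = 52 maps to p ~ 1.5e-11 through the t transform."""
        r = 0.775
        n = 52
        t = r * math.sqrt((n - 2) / (1 - r * r))
        from scipy.stats import t as tdist

        p = 2 * tdist.sf(t, n - 2)
        assert 0.3e-11 < p < 5e-11

    def test_t_transform_p_agrees_with_permutation(self, rng):
        x = rng.normal(size=10)
        y = x * 0.8 + rng.normal(size=10) * 0.8
        res = pearson_screen(_expr([x, rng.normal(size=10)]), y)
        p_model = res.table.loc["G000", "p"]
        r_obs = abs(res.table.loc["G000", "r"])
        hits = 0
        n_perm = 10_000
        for _ in range(n_perm):
            r_p, _ = _pearson_oracle(list(rng.permutation(x)), list(y))
            hits += abs(r_p) >= r_obs
        p_perm = hits / n_perm
        se = math.sqrt(max(p_perm, 1 / n_perm) * (1 - p_perm) / n_perm)
        assert abs(p_model - p_perm) < 4 * se + 0.01

    def test_constant_gene_excluded(self):
        expr = _expr([[1, 1, 1, 1], [1, 2, 3, 4]])
        res = pearson_screen(expr, np.array([1.0, 2.0, 3.0, 4.0]))
        assert res.excluded == ["G000"]
        assert list(res.table.index) == ["G001"]

    def test_misaligned_inputs_error(self, tiny_expression):
        with pytest.raises(ValidationError):
            pearson_screen(tiny_expression, np.arange(5.0))


class TestSelection:
    def _corr(self, p_values, r_values=None):
        n = len(p_values)
        r = r_values if r_values is not None else np.linspace(-0.9, 0.9, n)
        from drugsig.screen import CorrelationResult

        return CorrelationResult(
            pd.DataFrame(
                {"r": r, "p": p_values, "n": 10, "sign": np.where(np.asarray(r) >= 0, "+", "-")},
                index=pd.Index([f"G{i:03d}" for i in range(n)], name="gene"),
            ),
            [],
        )

    def test_all_insignificant_gives_empty(self):
        assert select_significant(self._corr([1.0, 1.0, 1.0])) == []

    def test_boundary_p_is_retained_inclusive(self):
        kept = select_significant(self._corr([0.05, 0.0501, 0.01]))
        assert kept == ["G000", "G002"]

    def test_mixed_case_equals_bruteforce(self, rng):
        p = rng.uniform(size=40)
        kept = select_significant(self._corr(list(p)))
        expected = [f"G{i:03d}" for i in range(40) if p[i] <= 0.05]
        assert kept == expected

    def test_top_correlates_counts(self):
        r = np.concatenate([np.linspace(0.1, 0.9, 15), np.linspace(-0.9, -0.1, 15)])
        corr = self._corr(list(np.full(30, 0.01)), list(r))
        top20 = select_top_correlates(corr, 10, 10)
        assert len(top20) == 20
        top200 = select_top_correlates(corr, 100, 100)
        assert len(top200) == 30  # truncated with warning

    def test_take_top_truncation(self, rng):
        from drugsig.screen import RankedGeneList

        tbl = pd.DataFrame(
            {"weight": np.sort(rng.normal(size=50))[::-1]},
            index=pd.Index([f"G{i}" for i in range(50)], name="gene"),
        )
        ranked = RankedGeneList(tbl)
        assert len(take_top(ranked, 100)) == 50
        assert take_top(ranked, 0) == []
        assert take_top(ranked, 10) == ranked.genes[:10]


class TestBiologicalFilters:
    def test_pathway_filter_membership(self):
        sets = GeneSetCollection({"S1": ["TARGET", "A", "B"], "S2": ["C", "D"]})
        kept = pathway_filter(["A", "C", "B"], sets, ["TARGET"])
        assert kept == ["A", "B"]

    def test_pathway_filter_no_target_anywhere(self):
        sets = GeneSetCollection({"S1": ["A", "B"]})
        with pytest.raises(PipelineError):
            pathway_filter(["A"], sets, ["TARGET"])

    def test_pathway_filter_equals_bruteforce(self, rng):
        genes = [f"G{i:02d}" for i in range(10)]
        sets = {}
        for s in range(6):
            members = list(rng.choice(genes + ["T1", "T2"], size=4, replace=False))
            sets[f"S{s}"] = members
        sets["Sx"] = ["T1", "G00"]  # guarantee a target is annotated
        coll = GeneSetCollection(sets)
        targets = ["T1", "T2"]
        kept = pathway_filter(genes, coll, targets)
        expected = [
            g for g in genes
            if any(g in m and any(t in m for t in targets) for m in sets.values())
        ]
        assert kept == expected

    def test_network_filter_star_and_isolated(self):
        net = InteractionNetwork([("HUB", f"L{i}") for i in range(4)])
        out = network_filter(["HUB"], net, measured_genes=["HUB", "L0", "L1", "L2", "L3"])
        assert set(out) == {"HUB", "L0", "L1", "L2", "L3"}
        assert network_filter(["LONER"], net, measured_genes=["LONER"]) == ["LONER"]

    def test_network_filter_equals_adjacency_oracle(self, rng):
        genes = [f"G{i:02d}" for i in range(20)]
        edges = [tuple(rng.choice(genes, size=2, replace=False)) for _ in range(30)]
        net = InteractionNetwork(edges)
        inputs = genes[:5]
        out = network_filter(inputs, net, measured_genes=genes)
        adj = {}
        for a, b in net.edges:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        expected = set(inputs) | set().union(*(adj.get(g, set()) for g in inputs))
        assert set(out) == expected & set(genes)

    def test_filters_idempotent(self):
        sets = GeneSetCollection({"S1": ["TARGET", "A", "B"]})
        once = pathway_filter(["A", "B", "C"], sets, ["TARGET"])
        assert pathway_filter(once, sets, ["TARGET"]) == once
        net = InteractionNetwork([("A", "B"), ("B", "C")])
        measured = ["A", "B", "C"]
        once_n = network_filter(["A", "B", "C"], net, measured)
        assert set(network_filter(once_n, net, measured)) == set(once_n)


class TestRelieff:
    def test_monotone_driver_ranks_first(self, rng):
        n = 40
        driver = np.linspace(0, 1, n)
        noise = rng.normal(size=(8, n))
        y = driver * 2.0
        expr = _expr(np.vstack([driver, noise]))
        ranked = relieff_rank(expr, y, k_neighbors=5, seed=0)
        assert ranked.genes[0] == "G000"
        assert ranked.weights.iloc[0] > 0

    def test_identical_copies_get_equal_weights_ties_lexicographic(self):
        x = np.array([0.1, 0.9, 0.4, 0.6, 0.2, 0.8, 0.3, 0.7, 0.0, 1.0, 0.5, 0.45])
        expr = _expr(np.vstack([x, x, x]), genes=["B", "A", "C"])
        ranked = relieff_rank(expr, x, k_neighbors=3)
        assert ranked.weights.nunique() == 1
        assert ranked.genes == ["A", "B", "C"]

    def test_noise_feature_weights_center_near_zero(self):
        means = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            expr = _expr(r.normal(size=(10, 30)))
            y = r.normal(size=30)
            ranked = relieff_rank(expr, y, k_neighbors=5, seed=seed)
            means.append(ranked.weights.mean())
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 3 * se + 0.01

    def test_permutation_equivariance(self, rng):
        X = rng.normal(size=(12, 25))
        y = X[0] + rng.normal(size=25) * 0.3
        genes = [f"G{i:02d}" for i in range(12)]
        e1 = _expr(X, genes=genes)
        perm = rng.permutation(12)
        e2 = _expr(X[perm], genes=[genes[i] for i in perm])
        r1 = relieff_rank(e1, y, k_neighbors=5)
        r2 = relieff_rank(e2, y, k_neighbors=5)
        pd.testing.assert_series_equal(
            r1.weights.sort_index(), r2.weights.sort_index(), atol=1e-12, rtol=0
        )

    def test_too_few_samples_error(self, rng):
        expr = _expr(rng.normal(size=(3, 8)))
        with pytest.raises(ValidationError):
            relieff_rank(expr, rng.normal(size=8), k_neighbors=10)
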