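import numpy as np
import pytest

from extendscore.exprio import ExpressionMatrix, rank_within_sample
from extendscore.scoring import (
    ConstituentAbsentError,
    GeneSignature,
    SignatureError,
    adjustment_factor,
    component_contribution,
    constituent_score,
    default_signature,
    extend_score,
    marker_score,
)
from extendscore.exprio import ValidationError
from oracles import extend_score_oracle


class TestGeneSignature:
    def test_disjointness_enforced(self):
        with pytest.raises(ValidationError, match="overlap"):
            GeneSignature(("TERT", "TERC"), ["TERT", "A"])

    def test_markers_required(self):
        with pytest.raises(ValidationError, match="non-empty"):
            GeneSignature(("TERT", "TERC"), [])

    def test_file_round_trip(self, tmp_path):
        sig = GeneSignature(("A", "B"), ["C", "D"], name="x")
        for name in ("s.yaml", "s.json"):
            sig.to_file(tmp_path / name)
            back = GeneSignature.from_file(tmp_path / name)
            assert back.constituent == ("A", "B")
            assert back.markers == ["C", "D"]

    def test_default_signature_structure(self):
        sig = default_signature()
        assert len(sig.constituent) == 2
        assert len(sig.markers) == 11
        assert len(set(sig.genes)) == 13


class TestConstituentScore:
    def test_max_of_pair(self):
        # TERT rank 100 vs TERC rank 80 in a 100-gene sample -> 100
        genes = ["TERT", "TERC"] + [f"B{i}" for i in range(98)]
        values = np.concatenate([[200.0, 150.0], np.arange(98.0)])[:, None]
        expr = ExpressionMatrix(genes, ["S1"], values)
        sig = GeneSignature(("TERT", "TERC"), ["B0"])
        ranks = rank_within_sample(expr)
        assert constituent_score(ranks, sig)[0] == 100.0

    def test_singleton_when_one_absent(self):
        genes = ["TERT"] + [f"B{i}" for i in range(59)]
        values = np.concatenate([[40.5], np.arange(59.0)])[:, None]  # TERT rank 42
        expr = ExpressionMatrix(genes, ["S1"], values)
        sig = GeneSignature(("TERT", "TERC"), ["B0"])
        assert constituent_score(rank_within_sample(expr), sig)[0] == 42.0

    def test_both_absent_signals(self, random_expr):
        expr = random_expr(20, 4)
        sig = GeneSignature(("NOPE1", "NOPE2"), [expr.gene_ids[0]])
        with pytest.raises(ConstituentAbsentError):
            constituent_score(rank_within_sample(expr), sig)

    def test_elementwise_max_oracle(self, random_expr):
        expr = random_expr(50, 10, seed=5)
        sig = GeneSignature((expr.gene_ids[3], expr.gene_ids[17]), [expr.gene_ids[8]])
        ranks = rank_within_sample(expr)
        got = constituent_score(ranks, sig)
        idx = ranks.gene_index()
        expected = [
            max(ranks.ranks[idx[sig.constituent[0]], j], ranks.ranks[idx[sig.constituent[1]], j])
            for j in range(expr.n_samples)
        ]
        np.testing.assert_array_equal(got, expected)


class TestMarkerScore:
    def test_simple_sum(self):
        # markers placed so they land exactly at ranks 10, 20, 30 of 50 genes
        genes = ["M1", "M2", "M3"] + [f"B{i}" for i in range(47)]
        base = np.delete(np.arange(1.0, 51.0), [9, 19, 29])
        values = np.concatenate([[9.6, 19.6, 29.6], base])[:, None]
        expr = ExpressionMatrix(genes, ["S1"], values)
        sig = GeneSignature(("X1", "X2"), ["M1", "M2", "M3"])
        v, present = marker_score(rank_within_sample(expr), sig)
        assert v[0] == 60.0
        assert present == ["M1", "M2", "M3"]

    def test_all_markers_tied_at_bottom(self):
        # 11 markers all zero among 50 genes: midrank (1+...+11)/11 = 6 -> sum 66
        markers = [f"M{i}" for i in range(11)]
        genes = markers + [f"B{i}" for i in range(39)]
        values = np.concatenate([np.zeros(11), np.arange(1.0, 40.0)])[:, None]
        expr = ExpressionMatrix(genes, ["S1"], values)
        sig = GeneSignature(("X1", "X2"), markers)
        v, _ = marker_score(rank_within_sample(expr), sig)
        assert v[0] == 66.0

    def test_zero_markers_present_is_error(self, random_expr):
        expr = random_expr(10, 3)
        sig = GeneSignature(("X1", "X2"), ["NOPE"])
        with pytest.raises(SignatureError, match="marker"):
            marker_score(rank_within_sample(expr), sig)

    def test_rank_sum_oracle(self, random_expr, random_signature):
        expr = random_expr(500, 20, seed=9)
        sig = random_signature(expr, seed=9)
        ranks = rank_within_sample(expr)
        v, present = marker_score(ranks, sig)
        idx = ranks.gene_index()
        expected = np.zeros(20)
        for g in sig.markers:
            expected += ranks.ranks[idx[g]]
        np.testing.assert_allclose(v, expected, atol=1e-12)
        assert len(present) == 11


class TestAdjustmentFactor:
    def test_rho_zero_gives_one(self):
        # permutation (2,4,1,3) of (1,2,3,4): sum d^2 = 10 -> rho = 0 exactly
        assert adjustment_factor(np.array([1, 2, 3, 4.0]), np.array([2, 4, 1, 3.0])) == 1.0

    def test_rho_half_gives_two(self):
        # (1,2,3) vs (2,1,3): sum d^2 = 2 -> rho = 1 - 12/24 = 0.5 -> delta = 2
        assert adjustment_factor(np.array([1, 2, 3.0]), np.array([2, 1, 3.0])) == 2.0

    def test_perfect_correlation_clamped(self):
        x = np.arange(10.0)
        assert adjustment_factor(x, 2 * x + 1) == 20.0

    def test_anticorrelation_lower_bound(self):
        x = np.arange(10.0)
        assert adjustment_factor(x, -x) == 0.5

    def test_degenerate_inputs_default_to_one(self):
        assert adjustment_factor(np.array([1.0, 2.0]), np.array([2.0, 1.0])) == 1.0
        assert adjustment_factor(np.full(5, 3.0), np.arange(5.0)) == 1.0


class TestExtendScore:
    def test_toy_matrix_frozen_oracle(self, toy_expr, toy_signature):
        """Hand-computed on paper: ranks per sample, V_const=(4,1,3),
        V_marker=(9,8.5,8), Spearman rho=0.5 so delta=2, N_g*N_m=18."""
        res = extend_score(toy_expr, toy_signature)
        assert res.delta == 2.0
        assert res.n_g == 6 and res.n_m == 3
        np.testing.assert_allclose(res.raw_score, [17 / 18, 10.5 / 18, 14 / 18], atol=1e-12)
        np.testing.assert_allclose(res.scaled_score, [1.0, 0.0, 3.5 / 6.5], atol=1e-12)
        assert res.missing_genes == ["C2"]

    def test_extremes_scale_to_unit_interval(self):
        # sample A holds all signature genes at the top, sample B at the bottom
        sig_genes = ["T1", "T2", "M1", "M2", "M3"]
        genes = sig_genes + [f"B{i}" for i in range(15)]
        top = np.concatenate([np.arange(100.0, 105.0), np.arange(1.0, 16.0)])
        bottom = np.concatenate([np.arange(0.01, 0.06, 0.01), np.arange(10.0, 25.0)])
        expr = ExpressionMatrix(genes, ["A", "B"], np.column_stack([top, bottom]))
        res = extend_score(expr, GeneSignature(("T1", "T2"), ["M1", "M2", "M3"]))
        np.testing.assert_allclose(res.scaled_score, [1.0, 0.0])

    def test_marker_only_fallback_identity(self, random_expr):
        expr = random_expr(80, 12, seed=21)
        markers = list(expr.gene_ids[5:16])
        values = expr.values.copy()
        genes = ["TERT", "TERC"] + list(expr.gene_ids)
        values = np.vstack([np.zeros((2, 12)), values])  # constituents all-zero
        expr2 = ExpressionMatrix(genes, list(expr.sample_ids), values)
        sig = GeneSignature(("TERT", "TERC"), markers)
        res = extend_score(expr2, sig)
        assert np.all(np.isfinite(res.raw_score))
        assert res.constituent_present == []
        marker_only = GeneSignature(("ABSENT1", "ABSENT2"), markers)
        res2 = extend_score(expr2, marker_only)
        np.testing.assert_array_equal(res.raw_score, res2.raw_score)
        assert res.n_m == res2.n_m == 11

    def test_single_sample_scaling_skipped(self, random_expr, random_signature):
        expr = random_expr(30, 1, seed=2)
        sig = random_signature(expr, n_markers=5, seed=2)
        res = extend_score(expr, sig)
        np.testing.assert_array_equal(res.scaled_score, res.raw_score)

    def test_identical_raw_scores_map_to_half(self):
        genes = ["T1", "T2", "M1", "B1"]
        values = np.tile(np.array([[4.0], [3.0], [2.0], [1.0]]), (1, 3))
        expr = ExpressionMatrix(genes, ["S1", "S2", "S3"], values)
        res = extend_score(expr, GeneSignature(("T1", "T2"), ["M1"]))
        np.testing.assert_array_equal(res.scaled_score, [0.5, 0.5, 0.5])

    @pytest.mark.parametrize("shape", [(50, 5), (200, 20), (1000, 50)])
    def test_loop_oracle_equivalence(self, shape, random_expr, random_signature):
        expr = random_expr(*shape, seed=shape[0])
        sig = random_signature(expr, seed=shape[0])
        res = extend_score(expr, sig)
        oracle = extend_score_oracle(expr.values, expr.gene_ids, sig.constituent, sig.markers)
        np.testing.assert_allclose(res.raw_score, oracle["raw"], atol=1e-12, rtol=0)
        np.testing.assert_allclose(res.scaled_score, oracle["scaled"], atol=1e-12, rtol=0)
        assert res.delta == pytest.approx(oracle["delta"], abs=1e-12)

    @pytest.mark.parametrize(
        "transform", [lambda x: np.log2(x + 1), lambda x: x**3]
    )
    def test_monotone_invariance_bit_identical(self, transform, random_expr, random_signature):
        expr = random_expr(150, 25, seed=31)
        sig = random_signature(expr, seed=31)
        res = extend_score(expr, sig)
        expr_t = ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids), transform(expr.values))
        res_t = extend_score(expr_t, sig)
        np.testing.assert_array_equal(res.raw_score, res_t.raw_score)
        np.testing.assert_array_equal(res.scaled_score, res_t.scaled_score)
        assert res.delta == res_t.delta

    def test_sample_permutation_equivariance(self, random_expr, random_signature):
        expr = random_expr(100, 15, seed=41)
        sig = random_signature(expr, seed=41)
        res = extend_score(expr, sig)
        rng = np.random.default_rng(0)
        perm = rng.permutation(15)
        expr_p = ExpressionMatrix(
            list(expr.gene_ids), [expr.sample_ids[j] for j in perm], expr.values[:, perm]
        )
        res_p = extend_score(expr_p, sig)
        np.testing.assert_array_equal(res.raw_score[perm], res_p.raw_score)
        assert res.delta == res_p.delta

    def test_marker_bump_never_decreases_raw(self, random_expr):
        # marker-only signature isolates rank-sum monotonicity from delta shifts
        expr = random_expr(60, 8, seed=51)
        markers = list(expr.gene_ids[10:21])
        sig = GeneSignature(("ABS1", "ABS2"), markers)
        base = extend_score(expr, sig, scale=False).raw_score
        rng = np.random.default_rng(1)
        for _ in range(20):
            g = int(rng.integers(10, 21))
            j = int(rng.integers(0, 8))
            bumped = expr.values.copy()
            bumped[g, j] += rng.uniform(0.1, 500.0)
            expr_b = ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids), bumped)
            raw_b = extend_score(expr_b, sig, scale=False).raw_score
            assert raw_b[j] >= base[j] - 1e-12

    def test_scaled_scores_in_unit_interval(self, random_expr, random_signature):
        expr = random_expr(120, 30, seed=61)
        sig = random_signature(expr, seed=61)
        res = extend_score(expr, sig)
        assert res.scaled_score.min() == 0.0
        assert res.scaled_score.max() == 1.0
        assert np.all((res.scaled_score >= 0) & (res.scaled_score <= 1))


class TestContributions:
    def test_contributions_sum_to_raw(self, random_expr, random_signature):
        expr = random_expr(300, 25, seed=71)
        sig = random_signature(expr, seed=71)
        res = extend_score(expr, sig)
        np.testing.assert_allclose(
            res.contributions.sum(axis=0).to_numpy(), res.raw_score, atol=1e-9
        )

    def test_fractions_sum_to_one(self, random_expr, random_signature):
        expr = random_expr(300, 25, seed=72)
        sig = random_signature(expr, seed=72)
        res = extend_score(expr, sig)
        frac = component_contribution(res)
        per_gene = frac.drop(index="constituent")
        np.testing.assert_allclose(per_gene.sum(axis=0).to_numpy(), 1.0, atol=1e-9)

    def test_constituent_fraction_formula(self, random_expr, random_signature):
        expr = random_expr(200, 20, seed=73)
        sig = random_signature(expr, seed=73)
        res = extend_score(expr, sig)
        frac = component_contribution(res)
        expected = (res.delta * res.components.v_const) / (
            res.delta * res.components.v_const + res.components.v_marker
        )
        np.testing.assert_allclose(frac.loc["constituent"].to_numpy(), expected, atol=1e-12)

    def test_marker_only_constituent_fraction_zero(self, random_expr):
        expr = random_expr(50, 6, seed=74)
        sig = GeneSignature(("NO1", "NO2"), list(expr.gene_ids[:5]))
        res = extend_score(expr, sig)
        frac = component_contribution(res)
        np.testing.assert_array_equal(frac.loc["constituent"].to_numpy(), 0.0)

    def test_delta_one_tenth_example(self):
        # delta=1, V_const=100, V_marker=900 -> constituent share 0.1
        v_const, v_marker, delta = 100.0, 900.0, 1.0
        assert delta * v_const / (delta * v_const + v_marker) == 0.1

    def test_recomputation_oracle_on_cohort(self):
        from extendscore.simulate import simulate_bulk

        cohort = simulate_bulk(n_genes=300, n_samples=1000, seed=99)
        res = extend_score(cohort.expr, cohort.planted_signature)
        frac = component_contribution(res).loc["constituent"].to_numpy()
        oracle = extend_score_oracle(
            cohort.expr.values,
            cohort.expr.gene_ids,
            cohort.planted_signature.constituent,
            cohort.planted_signature.markers,
        )
        expected = oracle["delta"] * oracle["v_const"] / (
            oracle["delta"] * oracle["v_const"] + oracle["v_marker"]
        )
        np.testing.assert_allclose(frac, expected, atol=1e-9)
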