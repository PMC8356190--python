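import numpy as np
import pandas as pd
import pytest

import tmescore as tm
from tmescore import CoverageError, ValidationError

from conftest import pc1_oracle


def _counts(genes, samples, values):
    return tm.ExpressionMatrix(genes, samples, np.asarray(values, float),
                               "linear_counts")


class TestNormalizeHousekeeping:
    def test_identical_housekeeping_gives_unit_factors(self, rng):
        hk = ["HK1", "HK2"]
        vals = np.vstack([np.tile([10.0, 100.0], (2, 1)).T.reshape(2, 2),
                          rng.poisson(50, size=(3, 2))])
        m = _counts(hk + ["G1", "G2", "G3"], ["S1", "S2"],
                    np.vstack([[[10, 10], [100, 100]], rng.poisson(50, (3, 2))]))
        out, report = tm.normalize_housekeeping(m, hk)
        np.testing.assert_allclose(report.scale_factor, 1.0)
        np.testing.assert_allclose(out.values, np.log2(m.values + 1), rtol=1e-12)

    def test_geomean_toy_matches_recomputation_oracle(self):
        # one housekeeping gene with +1-offset geomeans exactly (10, 20, 40)
        m = _counts(["HK1", "G1"], ["S1", "S2", "S3"],
                    [[9.0, 19.0, 39.0], [5.0, 6.0, 7.0]])
        out, report = tm.normalize_housekeeping(m, ["HK1"])
        mean_g = np.mean([10.0, 20.0, 40.0])
        np.testing.assert_allclose(report.scale_factor,
                                   mean_g / np.array([10.0, 20.0, 40.0]), rtol=1e-12)
        # oracle: recompute housekeeping geometric means from the output
        hk_linear = np.exp2(out.values[0])
        np.testing.assert_allclose(hk_linear, mean_g, rtol=1e-12)

    def test_scaled_sample_normalizes_to_same_profile(self, rng):
        # doubling every count is undone up to the +1 pseudo-count, whose
        # effect vanishes for large counts
        base = rng.uniform(1e6, 4e6, size=5)
        m = _counts([f"G{i}" for i in range(5)], ["S1", "S2", "S3"],
                    np.column_stack([base, 2 * base, 4 * base]))
        out, _ = tm.normalize_housekeeping(m, [f"G{i}" for i in range(5)])
        np.testing.assert_allclose(out.values[:, 1], out.values[:, 0], atol=1e-5)
        np.testing.assert_allclose(out.values[:, 2], out.values[:, 0], atol=1e-5)

    def test_equalizes_geomeans_and_is_idempotent(self, fixture_panel):
        expr, _, _ = fixture_panel
        out, report = tm.normalize_housekeeping(expr, tm.HOUSEKEEPING_GENES)
        hk = out.subset_genes(report.housekeeping_used)
        geomeans = np.exp(np.mean(np.log(np.exp2(hk.values)), axis=0))
        assert np.ptp(geomeans) / geomeans.mean() <= 1e-9
        # idempotence: re-normalizing the output's linear-scale counts is a no-op
        linear = tm.ExpressionMatrix(out.gene_ids, out.sample_ids,
                                     np.exp2(out.values) - 1.0, "linear_counts")
        out2, report2 = tm.normalize_housekeeping(linear, tm.HOUSEKEEPING_GENES)
        np.testing.assert_allclose(report2.scale_factor, 1.0, rtol=1e-12)
        np.testing.assert_allclose(out2.values, out.values, rtol=1e-12)

    def test_missing_housekeeping_errors_listing_genes(self, small_matrix):
        m = tm.ExpressionMatrix(small_matrix.gene_ids, small_matrix.sample_ids,
                                np.abs(small_matrix.values), "linear_counts")
        with pytest.raises(CoverageError, match="HKX"):
            tm.normalize_housekeeping(m, ["G0", "HKX", "HKY", "HKZ"])

    def test_all_zero_housekeeping_sample_named(self):
        m = _counts(["HK1", "G1"], ["S1", "S2"], [[0.0, 5.0], [1.0, 2.0]])
        with pytest.raises(ValidationError, match="S1"):
            tm.normalize_housekeeping(m, ["HK1"])


class TestStandardize:
    def test_simple_row(self):
        m = tm.ExpressionMatrix(["G1"], ["S1", "S2", "S3"],
                                np.array([[1.0, 2.0, 3.0]]), "log2")
        z = tm.standardize_genes(m)
        np.testing.assert_allclose(z.values, [[-1.0, 0.0, 1.0]], atol=1e-15)

    def test_constant_gene_dropped_or_rejected(self):
        m = tm.ExpressionMatrix(["G1", "G2"], ["S1", "S2", "S3"],
                                np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]), "log2")
        z = tm.standardize_genes(m, zero_variance="drop")
        assert z.gene_ids == ["G1"]
        with pytest.raises(ValidationError, match="G2"):
            tm.standardize_genes(m, zero_variance="error")

    def test_moments_and_inverse_transform(self, rng):
        vals = rng.normal(5, 2, size=(10, 6))
        m = tm.ExpressionMatrix([f"G{i}" for i in range(10)],
                                [f"S{i}" for i in range(6)], vals, "log2")
        z = tm.standardize_genes(m)
        assert np.abs(z.values.mean(axis=1)).max() <= 1e-12
        assert np.abs(z.values.std(axis=1, ddof=1) - 1).max() <= 1e-12
        recovered = (z.values * vals.std(axis=1, ddof=1, keepdims=True)
                     + vals.mean(axis=1, keepdims=True))
        np.testing.assert_allclose(recovered, vals, atol=1e-10)


class TestPc1Score:
    def test_single_gene_degenerates_to_zscores(self, small_matrix):
        sig = tm.GeneSignature("one", ["G3"], +1)
        with pytest.warns(UserWarning, match="single usable gene"):
            score = tm.pc1_signature_score(small_matrix, sig, min_coverage=0.5)
        z = tm.standardize_genes(small_matrix, ["G3"])
        np.testing.assert_allclose(score.to_numpy(), z.values[0], atol=1e-12)

    def test_two_identical_zrows_give_sqrt2_scores(self, rng):
        row = rng.normal(0, 1, 6)
        m = tm.ExpressionMatrix(["A", "B"], [f"S{i}" for i in range(6)],
                                np.vstack([row, 2 * row + 5]), "log2")
        score = tm.pc1_signature_score(m, tm.GeneSignature("dup", ["A", "B"]))
        z = tm.standardize_genes(m, ["A"]).values[0]
        np.testing.assert_allclose(score.to_numpy(), np.sqrt(2) * z, atol=1e-10)

    def test_matches_eigendecomposition_oracle(self, rng):
        for _ in range(20):
            vals = rng.normal(0, 1, size=(6, 10))
            genes = [f"G{i}" for i in range(6)]
            m = tm.ExpressionMatrix(genes, [f"S{i}" for i in range(10)], vals, "log2")
            score = tm.pc1_signature_score(m, tm.GeneSignature("s", genes))
            np.testing.assert_allclose(score.to_numpy(), pc1_oracle(vals, genes),
                                       atol=1e-10)

    def test_invariant_to_gene_ordering(self, rng):
        vals = rng.normal(0, 1, size=(5, 12))
        genes = [f"G{i}" for i in range(5)]
        m = tm.ExpressionMatrix(genes, [f"S{i}" for i in range(12)], vals, "log2")
        ref = tm.pc1_signature_score(m, tm.GeneSignature("s", genes))
        perm = rng.permutation(5)
        m2 = tm.ExpressionMatrix([genes[i] for i in perm],
                                 m.sample_ids, vals[perm], "log2")
        out = tm.pc1_signature_score(m2, tm.GeneSignature("s", [genes[i] for i in perm]))
        np.testing.assert_allclose(out.to_numpy(), ref.to_numpy(), atol=1e-10)

    def test_mean_zero_variance_eigenvalue(self, rng):
        vals = rng.normal(0, 1, size=(8, 30))
        genes = [f"G{i}" for i in range(8)]
        m = tm.ExpressionMatrix(genes, [f"S{i}" for i in range(30)], vals, "log2")
        score = tm.pc1_signature_score(m, tm.GeneSignature("s", genes)).to_numpy()
        assert abs(score.mean()) <= 1e-10
        z = tm.standardize_genes(m).values.T
        lead = np.linalg.eigvalsh(np.cov(z, rowvar=False, ddof=1)).max()
        assert abs(score.var(ddof=1) - lead) / lead <= 1e-9

    def test_correlates_positively_with_mean_z(self, rng):
        for _ in range(10):
            vals = rng.normal(0, 1, (6, 15)) + rng.normal(0, 1, (1, 15))
            genes = [f"G{i}" for i in range(6)]
            m = tm.ExpressionMatrix(genes, [f"S{i}" for i in range(15)], vals, "log2")
            score = tm.pc1_signature_score(m, tm.GeneSignature("s", genes)).to_numpy()
            meanz = tm.standardize_genes(m).values.mean(axis=0)
            assert np.corrcoef(score, meanz)[0, 1] >= 0

    def test_coverage_error_reports_counts(self, small_matrix):
        sig = tm.GeneSignature("mostly_absent", ["G0", "X1", "X2", "X3"], +1)
        with pytest.raises(CoverageError, match="1/4"):
            tm.pc1_signature_score(small_matrix, sig, min_coverage=0.5)


class TestSsgsea:
    def test_monotone_transform_invariance(self, rng):
        genes = [f"G{i}" for i in range(20)]
        vals = rng.uniform(1, 10, size=(20, 4))
        m = tm.ExpressionMatrix(genes, list("ABCD"), vals, "log2")
        sig = tm.GeneSignature("s", genes[:5])
        base = tm.ssgsea_score(m, sig)
        cubed = tm.ExpressionMatrix(genes, list("ABCD"), vals ** 3, "log2")
        np.testing.assert_allclose(tm.ssgsea_score(cubed, sig).to_numpy(),
                                   base.to_numpy(), atol=1e-12)

    def test_top_placement_maximizes_over_all_placements(self):
        from itertools import combinations
        genes = [f"G{i}" for i in range(5)]
        vals = np.array([[5.0], [4.0], [3.0], [2.0], [1.0]]).repeat(2, axis=1)
        m = tm.ExpressionMatrix(genes, ["S1", "S2"], vals, "log2")
        scores = {pair: tm.ssgsea_score(m, tm.GeneSignature("s", list(pair))).iloc[0]
                  for pair in combinations(genes, 2)}
        assert max(scores, key=scores.get) == ("G0", "G1")  # the two top-ranked genes

    def test_alpha_zero_matches_hand_computed_ks_sum(self):
        # 4 genes, expression 4>3>2>1, set = top gene:
        # P_in = (1,1,1,1); P_out = (0,1/3,2/3,1); sum of differences = 2
        genes = ["G1", "G2", "G3", "G4"]
        m = tm.ExpressionMatrix(genes, ["S1", "S2"],
                                np.array([[4.0], [3.0], [2.0], [1.0]]).repeat(2, 1),
                                "log2")
        sig = tm.GeneSignature("s", ["G1"])
        score = tm.ssgsea_score(m, sig, tm.SsgseaConfig(alpha=0.0))
        np.testing.assert_allclose(score.to_numpy(), [2.0, 2.0], atol=1e-12)

    def test_deterministic_tie_break_by_gene_id(self):
        genes = ["B", "A", "C", "D"]
        vals = np.array([[1.0], [1.0], [1.0], [0.0]]).repeat(2, 1)
        m = tm.ExpressionMatrix(genes, ["S1", "S2"], vals, "log2")
        s1 = tm.ssgsea_score(m, tm.GeneSignature("s", ["A"]))
        # reordering rows must not change anything: ties resolved by id
        m2 = tm.ExpressionMatrix(["A", "B", "C", "D"], ["S1", "S2"],
                                 np.array([[1.0], [1.0], [1.0], [0.0]]).repeat(2, 1),
                                 "log2")
        s2 = tm.ssgsea_score(m2, tm.GeneSignature("s", ["A"]))
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-15)

    def test_whole_matrix_set_rejected(self, small_matrix):
        with pytest.raises(ValidationError, match="every gene"):
            tm.ssgsea_score(small_matrix, tm.GeneSignature("all", small_matrix.gene_ids))


class TestTmescoreAssembly:
    def test_score_table_dispatch_and_shapes(self, small_matrix):
        coll = tm.SignatureCollection([
            tm.GeneSignature("a", ["G0", "G1", "G2"], +1),
            tm.GeneSignature("b", ["G5", "G6"], -1),
        ])
        for method in ("pca_pc1", "ssgsea", "zscore_mean"):
            table = tm.compute_signature_scores(small_matrix, coll, method=method)
            assert table.scores.shape == (small_matrix.n_samples, 2)
            assert table.signature_names == ["a", "b"]

    def test_zscore_mean_is_mean_of_zrows(self, small_matrix):
        coll = tm.SignatureCollection([tm.GeneSignature("a", ["G0", "G1"], +1)])
        table = tm.compute_signature_scores(small_matrix, coll, method="zscore_mean")
        z = tm.standardize_genes(small_matrix, ["G0", "G1"]).values
        np.testing.assert_allclose(table.scores["a"].to_numpy(),
                                   (z[0] + z[1]) / 2, atol=1e-12)

    def test_simple_assembly(self):
        table = tm.SignatureScoreTable(
            pd.DataFrame({"a": [1.5], "b": [0.5]}, index=["S1"]), "pca_pc1")
        table.scores.loc["S2"] = [0.0, 0.0]
        coll = tm.SignatureCollection([tm.GeneSignature("a", ["X"], +1),
                                       tm.GeneSignature("b", ["Y"], -1)])
        res = tm.compute_tmescore(table, coll)
        assert res.tmescore_a.loc["S1"] == 1.5
        assert res.tmescore_b.loc["S1"] == 0.5
        assert res.tmescore.loc["S1"] == 1.0

    def test_all_positive_directions(self):
        table = tm.SignatureScoreTable(
            pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]}, index=["S1", "S2"]),
            "pca_pc1")
        coll = tm.SignatureCollection([tm.GeneSignature("a", ["X"], +1),
                                       tm.GeneSignature("b", ["Y"], +1)])
        res = tm.compute_tmescore(table, coll)
        assert (res.tmescore_b == 0).all()
        np.testing.assert_array_equal(res.tmescore, res.tmescore_a)

    def test_matches_column_sum_oracle_exactly(self, rng):
        cols = {f"p{i}": rng.normal(size=20) for i in range(3)}
        cols.update({f"n{i}": rng.normal(size=20) for i in range(2)})
        df = pd.DataFrame(cols, index=[f"S{i}" for i in range(20)])
        coll = tm.SignatureCollection(
            [tm.GeneSignature(f"p{i}", ["X"], +1) for i in range(3)]
            + [tm.GeneSignature(f"n{i}", ["X"], -1) for i in range(2)])
        res = tm.compute_tmescore(tm.SignatureScoreTable(df, "pca_pc1"), coll)
        a = df[["p0", "p1", "p2"]].sum(axis=1)
        b = df[["n0", "n1"]].sum(axis=1)
        np.testing.assert_array_equal(res.tmescore.to_numpy(), (a - b).to_numpy())

    def test_identity_holds_bitwise(self, default_cohort):
        table = tm.compute_signature_scores(default_cohort.expression,
                                            default_cohort.signatures)
        res = tm.compute_tmescore(table, default_cohort.signatures)
        diff = res.tmescore - (res.tmescore_a - res.tmescore_b)
        assert (diff == 0.0).all()

    def test_missing_direction_rejected(self):
        table = tm.SignatureScoreTable(
            pd.DataFrame({"a": [1.0, 2.0]}, index=["S1", "S2"]), "pca_pc1")
        coll = tm.SignatureCollection([tm.GeneSignature("other", ["X"], +1)])
        with pytest.raises(ValidationError, match="a"):
            tm.compute_tmescore(table, coll)


class TestClassify:
    def test_boundary_goes_low(self):
        labels = tm.classify_by_cutoff(pd.Series([-1.0, 0.08, 0.09]), 0.08)
        assert labels.tolist() == ["low", "low", "high"]

    def test_extreme_cutoffs(self, rng):
        s = pd.Series(rng.normal(size=10))
        assert (tm.classify_by_cutoff(s, s.min() - 1) == "high").all()
        assert (tm.classify_by_cutoff(s, s.max()) == "low").all()
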