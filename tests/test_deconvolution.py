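import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import phdecon
from phdecon.deconvolution import (
    CONTRASTS,
    ComponentEstimate,
    DeconvolutionConfig,
    ValidationError,
    _test_components_arr,
    build_design_matrix,
    classify_gene,
    compute_fold_changes,
    fit_gene,
    load_group_table,
    normalize_matrix,
    prefilter_de_genes,
    run_deconvolution,
    test_component as component_test,
)


class TestNormalize:
    def test_column_sum_2e7_halved(self, toy_matrix):
        toy_matrix.counts.iloc[:, 0] = [1e7, 0.5e7, 0.5e7]
        out = normalize_matrix(toy_matrix)
        col = toy_matrix.design["sample_id"].iloc[0]
        np.testing.assert_allclose(
            out.counts[col].to_numpy(), [0.5e7, 0.25e7, 0.25e7]
        )

    def test_already_normalized_unchanged(self, toy_matrix):
        toy_matrix.counts.iloc[:, 1] = [5e6, 3e6, 2e6]
        out = normalize_matrix(toy_matrix)
        col = toy_matrix.design["sample_id"].iloc[1]
        np.testing.assert_allclose(out.counts[col].to_numpy(), [5e6, 3e6, 2e6])

    def test_scale_factors(self, toy_matrix):
        cols = list(toy_matrix.design["sample_id"][:2])
        toy_matrix.counts[cols[0]] = [4e6, 0.5e6, 0.5e6]  # sums 5e6 -> x2
        toy_matrix.counts[cols[1]] = [1e7, 0.5e7, 0.5e7]  # sums 2e7 -> x0.5
        out = normalize_matrix(toy_matrix)
        assert out.counts[cols[0]].iloc[0] == pytest.approx(8e6)
        assert out.counts[cols[1]].iloc[0] == pytest.approx(5e6)

    def test_all_zero_sample_rejected(self, toy_matrix):
        toy_matrix.counts.iloc[:, 0] = 0.0
        with pytest.raises(ValidationError, match="all-zero"):
            normalize_matrix(toy_matrix)

    def test_column_sums_invariant(self, toy_matrix):
        out = normalize_matrix(toy_matrix)
        sums = out.counts[list(out.design["sample_id"])].sum(axis=0)
        np.testing.assert_allclose(sums, 1e7, rtol=1e-3)


class TestDesignMatrix:
    def test_single_replicate_rows(self):
        X = build_design_matrix(1)
        expected = np.array(
            [[1, 0, 0], [0, 1, 0], [1, 0, 1], [0, 1, 1], [1, 1, 1]], dtype=float
        )
        np.testing.assert_array_equal(X, expected)

    def test_two_replicates_ten_rows(self):
        X = build_design_matrix(2)
        assert X.shape == (10, 3)
        np.testing.assert_array_equal(X[:5], X[5:])

    @pytest.mark.parametrize("n", [1, 2, 3, 7])
    def test_column_rank_three(self, n):
        assert np.linalg.matrix_rank(build_design_matrix(n)) == 3

    def test_rejects_zero_replicates(self):
        with pytest.raises(ValueError):
            build_design_matrix(0)

    def test_contrast_loadings_match_comparisons(self):
        loadings = [load for _, _, load in CONTRASTS]
        assert loadings == [(1, 0, 0), (0, 1, 0), (1, 0, 1), (0, 1, 1), (1, 1, 1)]


class TestFoldChanges:
    def test_all_zero_counts_give_zero_y(self):
        y = compute_fold_changes(np.zeros((2, 4)))
        np.testing.assert_array_equal(y, 0.0)

    def test_direct_arithmetic(self):
        # pH74=100, pH74_LPS=798 -> first contrast log2(800/102)
        counts = np.array([[100.0, 798.0, 100.0, 100.0]])
        y = compute_fold_changes(counts, pseudocount=2.0)
        assert y[0] == pytest.approx(2.971430847803229, abs=1e-12)

    def test_equal_counts_give_zero_vector(self):
        y = compute_fold_changes(np.full((2, 4), 123.0))
        np.testing.assert_array_equal(y, 0.0)

    def test_rejects_wrong_shape(self):
        with pytest.raises(ValueError):
            compute_fold_changes(np.zeros((2, 3)))


class TestFitGene:
    def test_exact_recovery_no_noise(self):
        X = build_design_matrix(2)
        beta = np.array([2.0, -1.0, 0.5])
        est = fit_gene(X @ beta, X)
        np.testing.assert_allclose(est.beta, beta, atol=1e-12)
        assert est.sigma2 == pytest.approx(0.0, abs=1e-20)
        assert est.r2 == pytest.approx(1.0)
        assert est.df == 7

    def test_zero_y_gives_zero_beta(self):
        X = build_design_matrix(2)
        est = fit_gene(np.zeros(10), X)
        np.testing.assert_array_equal(est.beta, 0.0)
        assert est.r2 == 0.0  # constant y convention

    def test_rank_deficient_rejected(self):
        X = np.ones((10, 3))
        with pytest.raises(ValueError, match="rank"):
            fit_gene(np.zeros(10), X)

    def test_statsmodels_oracle_small_instances(self):
        """OLS estimates match an independent library solver to 1e-10."""
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        X = build_design_matrix(2)
        for _ in range(50):
            y = rng.normal(size=10)
            est = fit_gene(y, X)
            ref = sm.OLS(y, X).fit()
            np.testing.assert_allclose(est.beta, ref.params, atol=1e-10)
            np.testing.assert_allclose(est.se, ref.bse, atol=1e-10)
            # statsmodels reports uncentered R^2 without an intercept;
            # recompute the centred version from its residuals
            centred = 1.0 - ref.ssr / np.sum((y - y.mean()) ** 2)
            assert est.r2 == pytest.approx(centred, abs=1e-10)

    def test_monte_carlo_se_matches_analytic(self):
        """Empirical sd of beta over 10,000 noisy fits matches analytic se."""
        rng = np.random.default_rng(12)
        X = build_design_matrix(2)
        beta_star = np.array([1.0, -0.5, 0.25])
        sd = 0.25
        betas = np.empty((10_000, 3))
        for i in range(10_000):
            y = X @ beta_star + rng.normal(0, sd, size=10)
            betas[i] = fit_gene(y, X).beta
        analytic_se = sd * np.sqrt(np.diag(np.linalg.inv(X.T @ X)))
        np.testing.assert_allclose(betas.mean(axis=0), beta_star, atol=0.01)
        np.testing.assert_allclose(betas.std(axis=0), analytic_se, rtol=0.03)


class TestShiftedNull:
    def _est(self, beta, se, df=7):
        return ComponentEstimate(
            gene_id="g", y=np.zeros(10), beta=np.asarray(beta, float),
            se=np.asarray(se, float), sigma2=1.0, r2=1.0, df=df,
        )

    def test_null_boundary_p_half(self):
        est = self._est([np.log2(1.5)] * 3, [0.5] * 3)
        t, p = component_test(est)
        np.testing.assert_allclose(t, 0.0, atol=1e-12)
        np.testing.assert_allclose(p, 0.5)

    def test_zero_beta_p_at_least_half(self):
        est = self._est([0.0, 0.0, 0.0], [0.3] * 3)
        _, p = component_test(est)
        assert (p >= 0.5).all()

    def test_negative_beta_lower_tail(self):
        est = self._est([-2.0, -2.0, -2.0], [0.2] * 3)
        _, p = component_test(est)
        assert (p < 0.05).all()

    def test_se_zero_conventions(self):
        est = self._est([2.0, 0.1, -2.0], [0.0, 0.0, 0.0])
        _, p = component_test(est)
        assert p[0] == 0.0  # beyond the null
        assert p[1] == 1.0  # inside the null
        assert p[2] == 0.0

    def test_rejects_bad_args(self):
        est = self._est([0.0] * 3, [1.0] * 3, df=0)
        with pytest.raises(ValueError):
            component_test(est)
        est2 = self._est([0.0] * 3, [1.0] * 3)
        with pytest.raises(ValueError):
            component_test(est2, beta0_fold=1.0)

    def test_calibration_small(self):
        """Type-I error at the null boundary ~ 5% (5,000 simulations)."""
        rng = np.random.default_rng(13)
        X = build_design_matrix(2)
        beta_star = np.array([np.log2(1.5), 0.0, 0.0])
        n_sim, sd = 5000, 0.25
        rejected = 0
        for _ in range(n_sim):
            est = fit_gene(X @ beta_star + rng.normal(0, sd, size=10), X)
            _, p = component_test(est)
            rejected += p[0] < 0.05
        rate = rejected / n_sim
        ci = 2.576 * np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) < ci

    def test_power_monotone_in_effect_size(self):
        rng = np.random.default_rng(14)
        X = build_design_matrix(2)
        rates = []
        for b in (0.585, 1.0, 2.0):
            rej = 0
            for _ in range(800):
                est = fit_gene(
                    X @ np.array([b, 0, 0]) + rng.normal(0, 0.25, size=10), X
                )
                _, p = component_test(est)
                rej += p[0] < 0.05
            rates.append(rej / 800)
        assert rates[0] < rates[1] < rates[2]


class TestClassification:
    def _est(self, beta, p, r2=0.95):
        est = ComponentEstimate(
            gene_id="g", y=np.zeros(10), beta=np.asarray(beta, float),
            se=np.full(3, 0.1), sigma2=1.0, r2=r2, df=7,
        )
        est.t = np.zeros(3)
        est.p = np.asarray(p, float)
        return est

    def test_lps_only_is_ph_insensitive(self):
        cls = classify_gene(self._est([2.0, 0.0, 0.0], [0.001, 0.9, 0.9]))
        assert cls.category == "pH_insensitive"
        assert cls.sign_pattern == ("+", "0", "0")
        assert cls.group_id == 3

    def test_opposite_signs_antagonistic(self):
        cls = classify_gene(self._est([2.0, 0.0, -2.0], [0.001, 0.9, 0.001]))
        assert cls.category == "pH_antagonistic"
        assert cls.group_id == 9

    def test_same_signs_synergistic(self):
        cls = classify_gene(self._est([2.0, 0.0, 2.0], [0.001, 0.9, 0.001]))
        assert cls.category == "pH_synergistic"
        assert cls.group_id == 15

    def test_ph_only(self):
        cls = classify_gene(self._est([0.0, -2.0, 0.0], [0.9, 0.001, 0.9]))
        assert cls.category == "pH_only"
        assert cls.group_id == 2

    def test_low_r2_unassigned(self):
        cls = classify_gene(self._est([2.0, 2.0, 2.0], [0.001] * 3, r2=0.5))
        assert cls.category == "unassigned"
        assert cls.group_id == "unassigned"

    def test_group_table_is_complete_and_unique(self):
        tbl = load_group_table()
        assert len(tbl) == 20
        assert tbl["group_id"].tolist() == list(range(1, 21))
        patterns = list(zip(tbl["LPS"], tbl["pH"], tbl["INT"]))
        assert len(set(patterns)) == 20
        assert ("0", "0", "0") not in patterns

    @given(
        beta=st.tuples(*[st.floats(-4, 4) for _ in range(3)]),
        p=st.tuples(*[st.floats(0, 1) for _ in range(3)]),
        r2=st.floats(0, 1),
    )
    @settings(max_examples=300, deadline=None)
    def test_category_invariants_property(self, beta, p, r2):
        cls = classify_gene(self._est(beta, p, r2=r2))
        sig_lps, sig_ph, sig_int = cls.sig_flags
        for b, pp, s in zip(beta, p, cls.sig_flags):
            assert s == (abs(b) >= 1.0 and pp < 0.05 and r2 > 0.8)
        if cls.category == "pH_insensitive":
            assert sig_lps and not sig_int
        elif cls.category == "pH_antagonistic":
            assert sig_lps and sig_int
            assert cls.sign_pattern[0] != cls.sign_pattern[2]
        elif cls.category == "pH_synergistic":
            assert sig_lps and sig_int
            assert cls.sign_pattern[0] == cls.sign_pattern[2]
        elif cls.category == "pH_only":
            assert sig_ph and not sig_lps and not sig_int
        elif cls.category == "unassigned":
            assert not any(cls.sig_flags)
        for s, sign in zip(cls.sig_flags, cls.sign_pattern):
            assert (sign == "0") == (not s)


class TestPrefilter:
    def _matrix(self, values_by_condition, n_reps=2):
        design_rows = []
        counts = {}
        for rep in range(1, n_reps + 1):
            for cond in phdecon.CONDITIONS:
                sid = f"{cond}_r{rep}"
                design_rows.append(
                    {"sample_id": sid, "condition": cond, "replicate_set": rep}
                )
                counts[sid] = values_by_condition[cond]
        design = pd.DataFrame(design_rows)
        idx = [f"g{i}" for i in range(len(next(iter(values_by_condition.values()))))]
        return phdecon.ExpressionMatrix(pd.DataFrame(counts, index=idx), design)

    def test_flat_gene_excluded(self):
        m = self._matrix({c: [100.0] for c in phdecon.CONDITIONS})
        assert len(prefilter_de_genes(m)) == 0

    def test_low_mean_excluded(self):
        m = self._matrix({c: [4.0] for c in phdecon.CONDITIONS})
        assert len(prefilter_de_genes(m)) == 0

    def test_planted_strong_gene_included(self):
        # three replicate sets: with only two, the per-gene Welch test has
        # ~2 df and BH-adjusted p-values cannot clear 0.05 at this noise level
        matrix, truths = phdecon.simulate_expression(
            n_genes=2000,
            group_mix={"null": 0.9, "pH_insensitive_up": 0.1},
            effect_scale=3.0,
            noise_sd=0.1,
            baseline_range=(8.0, 8.0),
            n_replicate_sets=3,
            seed=21,
        )
        kept = set(prefilter_de_genes(matrix))
        planted = {
            t.gene_id for t in truths if t.group_true == "pH_insensitive_up"
        }
        assert planted <= kept

    def test_single_replicate_disables_p(self, caplog):
        m = self._matrix(
            {"pH74": [10.0], "pH74_LPS": [500.0], "pH65": [10.0], "pH65_LPS": [500.0]},
            n_reps=1,
        )
        with caplog.at_level("WARNING"):
            kept = prefilter_de_genes(m)
        assert len(kept) == 1
        assert any("replicate" in r.message for r in caplog.records)


class TestRunDeconvolution:
    def test_noise_free_truth_agreement(self):
        matrix, truths = phdecon.simulate_expression(
            n_genes=800, noise_sd=0.0, baseline_range=(14, 18), seed=31
        )
        res, summary = run_deconvolution(matrix, DeconvolutionConfig(normalize=False))
        tt = phdecon.truth_table(truths)
        merged = tt.merge(res[["gene_id", "category"]], on="gene_id", how="left")
        merged["category"] = merged["category"].fillna("unassigned")
        assert (merged["category"] == merged["category_true"]).all()

    def test_empty_post_prefilter(self, toy_matrix):
        res, summary = run_deconvolution(toy_matrix, DeconvolutionConfig(normalize=False))
        assert len(res) == 0
        assert list(res.columns) == phdecon.deconvolution.RESULT_COLUMNS
        assert summary["n_genes_prefiltered"] == 0

    def test_determinism_bytes(self, tmp_path):
        matrix, _ = phdecon.simulate_expression(n_genes=300, seed=5)
        outs = []
        for name in ("a.tsv", "b.tsv"):
            res, _ = run_deconvolution(matrix)
            p = tmp_path / name
            res.to_csv(p, sep="\t", index=False, lineterminator="\n")
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]

    def test_df_invariant(self):
        matrix, _ = phdecon.simulate_expression(n_genes=100, seed=6)
        _, summary = run_deconvolution(matrix)
        assert summary["df"] == 7
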