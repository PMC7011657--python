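"""MLR conditioning, dispersion statistics, covariance summaries,
category attribution, and permutation significance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from statefish.decomposition import (
    VarianceDecomposition,
    calcium_feature_significance,
    category_explained_variance,
    condition_expression,
    correlation_structure,
    dispersion_stats,
    fit_gene_mlr,
    sequential_decomposition,
)


def normal_equations_oracle(X, y):
    """Brute-force OLS via explicit (X'X)^-1 X'y."""
    return np.linalg.inv(X.T @ X) @ X.T @ y


class TestFitGeneMLR:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        F = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        Y = pd.DataFrame(rng.normal(size=(50, 4)))
        fit = fit_gene_mlr(Y, F)
        X = np.column_stack([np.ones(50), F.to_numpy()])
        for j in range(4):
            expected = normal_equations_oracle(X, Y.iloc[:, j].to_numpy())
            np.testing.assert_allclose(fit.coef.iloc[:, j].to_numpy(), expected, rtol=1e-8)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        F = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("wxyz"))
        y = pd.DataFrame({"g": rng.poisson(10, 80).astype(float)})
        fit = fit_gene_mlr(y, F)
        ref = sm.OLS(y["g"], sm.add_constant(F)).fit()
        np.testing.assert_allclose(fit.coef["g"].to_numpy(), ref.params.to_numpy(), rtol=1e-8)
        assert fit.r_squared["g"] == pytest.approx(ref.rsquared, rel=1e-10)

    def test_exact_linear_gene_has_unit_r2_and_zero_residuals(self, rng):
        F = pd.DataFrame(rng.normal(size=(100, 2)), columns=["u", "v"])
        y = pd.DataFrame({"g": 2.0 + 3.0 * F["u"] - 1.5 * F["v"]})
        fit = fit_gene_mlr(y, F)
        assert fit.r_squared["g"] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(fit.residuals["g"], 0.0, atol=1e-10)

    def test_orthogonal_feature_changes_nothing(self, rng):
        n = 4000
        u = rng.normal(size=n)
        y = pd.DataFrame({"g": 5.0 + u + rng.normal(size=n)})
        # Gram-Schmidt: w orthogonal to the intercept, to u, and to the
        # part of the gene not already explained by (1, u)
        X0 = np.column_stack([np.ones(n), u])
        gres = y["g"].to_numpy() - X0 @ np.linalg.lstsq(X0, y["g"].to_numpy(), rcond=None)[0]
        w = rng.normal(size=n)
        for v in (np.ones(n), u, gres):
            w = w - (w @ v) / (v @ v) * v
        with_w = fit_gene_mlr(y, pd.DataFrame({"u": u, "w": w}))
        without = fit_gene_mlr(y, pd.DataFrame({"u": u}))
        assert with_w.coef.loc["w", "g"] == pytest.approx(0.0, abs=1e-10)
        assert with_w.r_squared["g"] == pytest.approx(without.r_squared["g"], abs=1e-10)

    def test_rank_deficient_design_names_collinear_features(self, rng):
        u = rng.normal(size=50)
        F = pd.DataFrame({"u": u, "v": 2 * u, "w": rng.normal(size=50)})
        with pytest.raises(ValueError, match="v"):
            fit_gene_mlr(pd.DataFrame({"g": rng.normal(size=50)}), F)

    def test_too_few_cells_rejected(self, rng):
        F = pd.DataFrame(rng.normal(size=(4, 3)))
        with pytest.raises(ValueError, match="n_cells"):
            fit_gene_mlr(pd.DataFrame(rng.normal(size=(4, 2))), F)


class TestConditioning:
    def test_mean_add_back_preserves_gene_means(self, rng):
        counts = pd.DataFrame(rng.poisson(8.0, size=(200, 5)).astype(float))
        feats = pd.DataFrame(rng.normal(size=(200, 3)))
        cond = condition_expression(counts, feats)
        np.testing.assert_allclose(
            cond.values.mean(axis=0), counts.mean(axis=0), rtol=1e-10
        )

    def test_perfectly_explained_gene_collapses_to_its_mean(self, rng):
        f = rng.normal(size=300)
        counts = pd.DataFrame({"g": 4.0 + 2.0 * f})
        cond = condition_expression(counts, pd.DataFrame({"f": f}))
        assert np.allclose(cond.values["g"], 4.0 + 2.0 * f.mean(), atol=1e-10)
        assert cond.values["g"].var() == pytest.approx(0.0, abs=1e-16)

    def test_uninformative_features_leave_counts_unchanged(self, rng):
        counts = pd.DataFrame(rng.poisson(5.0, size=(2000, 3)).astype(float))
        # feature orthogonalized against every gene: coefficients ~ 0
        f = rng.normal(size=2000)
        cond = condition_expression(counts, pd.DataFrame({"f": f}))
        # residual+mean differs from raw only through the tiny fitted slope
        assert np.abs(cond.values.to_numpy() - counts.to_numpy()).max() < 0.5
        np.testing.assert_allclose(
            cond.values.var(axis=0, ddof=1), counts.var(axis=0, ddof=1), rtol=0.01
        )

    def test_negative_conditioned_values_are_preserved(self, rng):
        # low counts with a strong state dependence: cells observed at 0
        # while fitted high produce residuals below -mean
        f = rng.normal(size=2000)
        counts = pd.DataFrame({"g": rng.poisson(np.exp(1.0 + 0.8 * f)).astype(float)})
        cond = condition_expression(counts, pd.DataFrame({"f": f}))
        assert (cond.values["g"] < 0).any()


class TestDispersion:
    def test_hand_computed_example(self):
        cond = pd.DataFrame({"g": [0.0, 2.0, 4.0]})
        out = dispersion_stats(cond, raw_means=np.array([2.0]))
        assert out.loc["g", "fano"] == pytest.approx(2.0)
        assert out.loc["g", "cv2"] == pytest.approx(1.0)

    def test_constant_column_has_zero_fano(self):
        out = dispersion_stats(pd.DataFrame({"g": [3.0] * 10}), np.array([3.0]))
        assert out.loc["g", "fano"] == 0.0

    def test_poisson_draws_fano_near_one(self, rng):
        x = rng.poisson(7.0, 100_000).astype(float)
        out = dispersion_stats(pd.DataFrame({"g": x}), np.array([x.mean()]))
        assert 0.98 <= out.loc["g", "fano"] <= 1.02

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="zero raw mean"):
            dispersion_stats(pd.DataFrame({"g": [0.0, 1.0]}), np.array([0.0]))

    @settings(max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_fano_and_cv2_consistency(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.poisson(rng.uniform(1, 20), 50).astype(float)
        if x.mean() == 0:
            return
        out = dispersion_stats(pd.DataFrame({"g": x}), np.array([x.mean()]))
        assert out.loc["g", "cv2"] == pytest.approx(out.loc["g", "fano"] / x.mean())
        assert out.loc["g", "fano"] >= 0


class TestCorrelationStructure:
    def test_two_perfectly_correlated_genes(self, rng):
        base = rng.normal(size=500)
        mat = pd.DataFrame({"a": base, "b": 2.0 * base + 1.0})
        out = correlation_structure(mat, k=1)
        assert out.correlation.loc["a", "b"] == pytest.approx(1.0)
        assert out.pc_explained_variance == pytest.approx(1.0)

    def test_independent_genes_pc_variance_near_2_over_g(self, rng):
        G, n = 10, 20000
        mat = pd.DataFrame(rng.normal(size=(n, G)))
        out = correlation_structure(mat, k=2)
        expected = 2.0 / G
        assert expected - 0.01 < out.pc_explained_variance < expected + 3 * np.sqrt(G / n)

    def test_shuffling_destroys_shared_factor(self, rng):
        shared = rng.normal(size=2000)
        mat = pd.DataFrame(
            {f"g{i}": shared + rng.normal(size=2000) for i in range(12)}
        )
        out = correlation_structure(mat, k=2, shuffle_seed=0)
        assert out.shuffled_pc_explained_variance < out.pc_explained_variance

    def test_zero_variance_gene_excluded_with_warning(self, rng):
        mat = pd.DataFrame({"a": rng.normal(size=100), "b": rng.normal(size=100), "c": 1.0})
        with pytest.warns(UserWarning, match="zero-variance"):
            out = correlation_structure(mat, k=1)
        assert out.excluded_genes == ("c",)
        assert list(out.correlation.columns) == ["a", "b"]

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError, match="at least"):
            correlation_structure(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))


class TestSequentialDecomposition:
    def test_empty_first_stage_reproduces_raw_counts(self, small_dataset):
        res = sequential_decomposition(
            small_dataset.expression,
            small_dataset.features,
            stage_plan=[("raw", ()), ("volume", ("volume",))],
            n_hidden=0,
        )
        np.testing.assert_allclose(
            res["raw"].conditioned.values.to_numpy(),
            small_dataset.expression.to_numpy().astype(float),
        )

    def test_non_nested_plan_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="nested"):
            sequential_decomposition(
                small_dataset.expression,
                small_dataset.features,
                stage_plan=[("a", ("volume",)), ("b", ("s_score",))],
            )

    def test_constant_rate_data_stays_at_the_poisson_limit(self):
        # no state structure: every stage leaves Fano within Monte-Carlo
        # error of 1
        from statefish.simulate import generate_cell_states, generate_expression
        from test_simulate import constant_rate_models

        states = generate_cell_states(6000, seed=13)
        ds = generate_expression(states, constant_rate_models(100, 10.0), seed=14)
        res = sequential_decomposition(ds.expression, ds.features, n_hidden=2, shuffle_seed=1)
        for st_ in res.stages:
            # the hidden stage overfits slightly (its two PCs are picked
            # from the noise itself), so allow a small downward excursion
            assert st_.dispersion["fano"].median() == pytest.approx(1.0, abs=0.05)

    def test_conditioning_reduces_dispersion_and_covariance(self, small_dataset):
        res = sequential_decomposition(
            small_dataset.expression, small_dataset.features, n_hidden=2, shuffle_seed=7
        )
        fanos = [s.median_fano for s in res.stages]
        assert fanos[0] > 1.5  # raw data clearly over-dispersed
        assert res.final.median_fano < 1.2
        # covariance summaries shrink from raw through the full model to
        # the hidden stage (intermediate stages need not be monotone)
        pc = {s.name: s.correlation.pc_explained_variance for s in res.stages}
        assert pc["raw"] > pc["all_observed"] > pc["hidden"]

    def test_hidden_stage_recovers_injected_factor(self, small_dataset):
        res = sequential_decomposition(
            small_dataset.expression, small_dataset.features, n_hidden=2, shuffle_seed=7
        )
        h = small_dataset.states[["hidden_0", "hidden_1"]].to_numpy()
        scores = res.hidden_factors.to_numpy()
        X = np.column_stack([np.ones(len(scores)), scores])
        r2 = []
        for j in range(2):
            beta, *_ = np.linalg.lstsq(X, h[:, j], rcond=None)
            resid = h[:, j] - X @ beta
            r2.append(1 - resid.var() / h[:, j].var())
        # the two principal components jointly recover both hidden axes
        assert max(r2) > 0.5
        assert min(r2) > 0.3

    def test_results_summary_is_printable(self, small_dataset):
        res = VarianceDecomposition.from_dataset(small_dataset, shuffle_seed=1).fit()
        text = res.summary()
        assert "median_fano" in res.summary_frame().columns
        assert "Poisson limit" in text
        assert res.stage_names[-1] == "hidden"


class TestCategoryAttribution:
    @pytest.fixture()
    def toy(self, rng):
        n = 10000
        feats = pd.DataFrame(
            {
                "volume": rng.normal(size=n),
                "s_score": rng.normal(size=n),
                "ca_a": rng.normal(size=n),
            }
        )
        cats = {"volume": "volume", "s_score": "cell_cycle", "ca_a": "calcium"}
        return feats, cats, rng

    def test_volume_only_gene_attributes_to_volume_in_any_order(self, toy):
        feats, cats, rng = toy
        counts = pd.DataFrame({"g": 3.0 * feats["volume"] + rng.normal(size=len(feats))})
        for order in [("volume", "cell_cycle", "calcium"), ("calcium", "cell_cycle", "volume")]:
            ev = category_explained_variance(counts, feats, cats, order=order)
            assert ev.loc["g", "volume"] > 0.8
            assert abs(ev.loc["g", "calcium"]) < 0.02
            assert abs(ev.loc["g", "cell_cycle"]) < 0.02

    def test_shares_telescope_to_full_model_r2(self, toy):
        feats, cats, rng = toy
        counts = pd.DataFrame(
            {f"g{i}": rng.normal(size=len(feats)) for i in range(3)}
        )
        ev = category_explained_variance(counts, feats, cats, order=("volume", "cell_cycle", "calcium"))
        full = fit_gene_mlr(counts, feats).r_squared
        np.testing.assert_allclose(ev.sum(axis=1), full, atol=1e-10)

    def test_equal_independent_contributions_share_equally(self, toy):
        feats, cats, rng = toy
        counts = pd.DataFrame(
            {"g": feats["volume"] + feats["ca_a"] + rng.normal(size=len(feats))}
        )
        ev = category_explained_variance(counts, feats, cats, order=("volume", "cell_cycle", "calcium"))
        assert ev.loc["g", "volume"] == pytest.approx(ev.loc["g", "calcium"], rel=0.10)

    def test_incomplete_partition_rejected(self, toy):
        feats, cats, _ = toy
        bad = dict(cats)
        del bad["ca_a"]
        with pytest.raises(ValueError, match="partition"):
            category_explained_variance(pd.DataFrame({"g": feats["volume"]}), feats, bad)


class TestCalciumSignificance:
    def test_feature_identical_to_gene_is_maximally_significant(self, rng):
        n = 300
        feats = pd.DataFrame(rng.normal(size=(n, 3)), columns=["f0", "f1", "f2"])
        counts = pd.DataFrame({"g": 2.0 * feats["f0"] + 5.0})
        out = calcium_feature_significance(counts, feats, n_resamples=200, seed=1)
        row = out[(out["gene"] == "g") & (out["feature"] == "f0")].iloc[0]
        assert abs(row["z"]) > 10
        assert row["significant"]

    def test_p_value_floor_is_one_over_resamples(self, rng):
        n = 300
        feats = pd.DataFrame(rng.normal(size=(n, 2)), columns=["f0", "f1"])
        counts = pd.DataFrame({"g": 3.0 * feats["f0"]})
        out = calcium_feature_significance(counts, feats, n_resamples=200, seed=2)
        row = out[(out["gene"] == "g") & (out["feature"] == "f0")].iloc[0]
        assert row["p_value"] == pytest.approx(1.0 / 200)

    def test_null_slopes_centered_on_zero(self, rng):
        n = 200
        feats = pd.DataFrame(rng.normal(size=(n, 2)), columns=["f0", "f1"])
        counts = pd.DataFrame({"g": rng.poisson(10.0, n).astype(float)})
        out = calcium_feature_significance(counts, feats, n_resamples=150, seed=3)
        assert np.abs(out["null_mean"]).max() < 0.2
        assert (np.abs(out["z"]) < 4).all()

    def test_too_few_resamples_rejected(self, rng):
        feats = pd.DataFrame(rng.normal(size=(50, 2)))
        with pytest.raises(ValueError, match="unstable"):
            calcium_feature_significance(
                pd.DataFrame({"g": rng.normal(size=50)}), feats, n_resamples=50
            )

    def test_bonferroni_adjustment_and_bookkeeping(self, rng):
        feats = pd.DataFrame(rng.normal(size=(100, 2)), columns=["f0", "f1"])
        counts = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        out = calcium_feature_significance(counts, feats, n_resamples=120, seed=4)
        assert out.attrs["n_tests"] == 6
        np.testing.assert_allclose(
            out["p_adjusted"], np.minimum(1.0, out["p_value"] * 6)
        )


class TestParameterRecovery:
    def test_generator_coefficients_recovered_within_3_se(self):
        # with small coefficients the exponential link is near-linear:
        # OLS slope on the z-scored feature ~= mean rate * coefficient
        from statefish.simulate import (
            FEATURE_ORDER,
            GeneModel,
            generate_cell_states,
            generate_expression,
        )

        states = generate_cell_states(5000, seed=17)
        coef = np.zeros(len(FEATURE_ORDER))
        coef[0], coef[1] = 0.03, -0.02  # volume, s_score
        model = GeneModel("g", float(np.log(20.0)), coef)
        ds = generate_expression(states, [model], seed=18)
        # fit on the five morphological features (the calcium block is
        # nearly collinear through the non-responder sentinels, which
        # makes individual slopes there unidentifiable)
        morpho = list(FEATURE_ORDER[:5])
        z = (ds.features[morpho] - ds.features[morpho].mean()) / ds.features[morpho].std(ddof=0)
        fit = fit_gene_mlr(ds.expression.astype(float), z)
        X = np.column_stack([np.ones(len(z)), z.to_numpy()])
        resid = fit.residuals["g"].to_numpy()
        sigma2 = resid @ resid / (len(z) - X.shape[1])
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))[1:]
        mean_rate = ds.expression["g"].mean()
        for j in range(len(morpho)):
            assert abs(fit.coef.iloc[1 + j]["g"] - mean_rate * coef[j]) < 3 * se[j]
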