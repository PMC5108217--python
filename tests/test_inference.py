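import numpy as np
import pandas as pd
import pytest

from gxevar import (
    McmcSettings,
    ModelSpec,
    PriorSpec,
    build_design,
    conditional_family_means,
    deviance,
    dic,
    gibbs_sample,
    heritability_draws,
    stepwise_select,
    tail_area_from_count,
    variance_ratio_test,
    yolk_growth_regression,
)


class TestTailArea:
    def test_exact_fraction(self):
        assert tail_area_from_count(3900, 3900) == 0.0
        assert tail_area_from_count(0, 3900) == 1.0
        assert tail_area_from_count(3, 4) == pytest.approx(0.25)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            tail_area_from_count(5, 4)
        with pytest.raises(ValueError):
            tail_area_from_count(-1, 4)
        with pytest.raises(ValueError):
            tail_area_from_count(0, 0)


class TestVarianceRatioTest:
    def test_identical_vectors_boundary_of_strict_inequality(self):
        draws = np.linspace(0.5, 2.0, 100)
        comp = variance_ratio_test(draws, draws)
        assert comp.n_exceeding_one == 0
        assert comp.tail_area == 1.0

    def test_forward_and_reverse_counts_partition_draws(self):
        rng = np.random.default_rng(0)
        a = rng.gamma(4.0, 0.5, size=500)
        b = rng.gamma(4.0, 0.5, size=500)
        fwd = variance_ratio_test(a, b)
        with pytest.warns(UserWarning, match="median"):
            # whichever direction has median ratio < 1 warns; force both
            variance_ratio_test(np.full(10, 0.5), np.full(10, 1.0))
        rev = variance_ratio_test(b, a)
        ties = int(np.sum(a == b))
        assert fwd.n_exceeding_one + rev.n_exceeding_one + ties == 500

    def test_mismatched_vectors_rejected(self):
        with pytest.raises(ValueError):
            variance_ratio_test(np.ones(5), np.ones(6))
        with pytest.raises(ValueError):
            variance_ratio_test(np.array([]), np.array([]))


class TestHeritability:
    def test_point_mass_components(self):
        fam = np.full(20, 0.36)
        res = np.full(20, 2.69)
        h2 = heritability_draws(fam, res)
        assert h2.mode == pytest.approx(2 * 0.36 / (0.36 + 2.69), abs=1e-12)

    def test_degenerate_family_variances(self):
        res = np.full(20, 1.3)
        assert heritability_draws(np.zeros(20), res).mode == 0.0
        assert heritability_draws(res, res).mode == 1.0  # 2f/(f+f)

    def test_scale_invariance_of_draws(self):
        rng = np.random.default_rng(1)
        fam = rng.gamma(3.0, 0.2, size=400)
        res = rng.gamma(5.0, 0.5, size=400)
        base = heritability_draws(fam, res)
        scaled = heritability_draws(7.0 * fam, 7.0 * res)
        assert np.allclose(base.draws, scaled.draws)

    def test_negative_draws_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            heritability_draws(np.array([-0.1] * 20), np.ones(20))


class TestDic:
    def test_degenerate_chain_has_zero_pd(self, hatch_fit):
        design, draws = hatch_fit
        frozen = draws.draws[:1].repeat(50, axis=0)
        degenerate = type(draws)(draws.labels, frozen, draws.settings)
        result = dic(degenerate, design)
        assert result.pd == pytest.approx(0.0, abs=1e-8)
        assert result.dic == pytest.approx(result.dhat, abs=1e-6)

    def test_matches_brute_force_two_pass(self, hatch_fit):
        design, draws = hatch_fit
        small = type(draws)(draws.labels, draws.draws[:40], draws.settings)
        p = design.n_location
        k = len(design.components)
        devs = [
            deviance(design, row[:p], row[p + k:]) for row in small.draws
        ]
        dbar = np.mean(devs)
        dhat = deviance(
            design, small.draws[:, :p].mean(axis=0),
            small.draws[:, p + k:].mean(axis=0),
        )
        result = dic(small, design)
        assert result.dbar == pytest.approx(dbar)
        assert result.pd == pytest.approx(dbar - dhat)
        assert result.dic == pytest.approx(2 * dbar - dhat)

    def test_pd_approximates_free_parameter_count(self):
        # fixed-effects-only Gaussian model: pD ~ #location params (+ ~1 for
        # the sampled variance)
        rng = np.random.default_rng(2)
        n = 1200
        treatment = np.repeat(["cold", "amb", "var", "warm"], n // 4)
        effects = {"cold": 0.0, "amb": 0.3, "var": 0.6, "warm": 1.0}
        y = np.array([10 + effects[t] for t in treatment]) + rng.normal(0, 1, n)
        table = pd.DataFrame(
            {"body_length_mm": y, "treatment": treatment,
             "hs_family": ["F1"] * n}
        )
        spec = ModelSpec("body_length_mm", random=(), heterogeneous_residual=False)
        design = build_design(table, spec)
        draws = gibbs_sample(design, PriorSpec(), McmcSettings(4000, 500, 2, seed=3))
        result = dic(draws, design)
        assert 3.0 < result.pd < 7.0

    def test_mismatched_draws_rejected(self, hatch_fit):
        design, draws = hatch_fit
        wrong = type(draws)(draws.labels[:-1], draws.draws[:, :-1], draws.settings)
        with pytest.raises(ValueError, match="layout"):
            dic(wrong, design)


class TestStepwiseSelect:
    def test_chosen_model_within_two_dic_of_minimum(self, hatch_table):
        candidates = [
            ModelSpec("body_length_mm", random=("family", "family_by_treatment")),
            ModelSpec("body_length_mm", random=("family_by_treatment",)),
            ModelSpec("body_length_mm", random=("family",)),
        ]
        selection = stepwise_select(
            candidates, hatch_table, PriorSpec(), McmcSettings(3000, 500, 5, seed=4)
        )
        frame = selection.to_frame()
        fitted = frame[frame["model"].isin([c.label for c in candidates])]
        assert selection.chosen is not None
        chosen_dic = frame.loc[
            frame["decision"].str.startswith("chosen"), "dic"
        ].iloc[0]
        assert chosen_dic <= fitted["dic"].min() + 2.0
        assert {"model", "dic", "pd", "ci_spans_zero", "decision"} <= set(frame)

    def test_null_covariate_flagged_by_credible_interval(self, emergence_table):
        # raceways are randomised with zero true effect, so their contrast
        # CIs should span zero and be flagged for pruning
        spec = ModelSpec(
            "days_to_emergence",
            fixed=("intercept", "treatment", "mean_t", "raceway"),
            random=("family",),
            family_column="fs_family",
            heterogeneous_residual=False,
        )
        selection = stepwise_select(
            [spec], emergence_table, PriorSpec(), McmcSettings(4000, 500, 4, seed=5)
        )
        flagged = selection.to_frame().iloc[0]["ci_spans_zero"]
        assert "raceway[2]" in flagged and "raceway[3]" in flagged

    def test_no_candidates_rejected(self, hatch_table):
        with pytest.raises(ValueError, match="no candidate"):
            stepwise_select([], hatch_table)


class TestConditionalFamilyMeans:
    def test_recovers_true_family_ranking(self, hatch_table, hatch_fit):
        from scipy.stats import spearmanr

        design, draws = hatch_fit
        norms = conditional_family_means(draws, design)
        assert len(norms) == 40
        truth = hatch_table.attrs["true_effects"]
        # rank agreement within each treatment: a reaction norm orders
        # families within an environment
        for treatment, sub in norms.groupby("treatment"):
            true_vals = [
                truth[("body_length_mm", fam, treatment)] for fam in sub["family"]
            ]
            rho = spearmanr(sub["mean"], true_vals).statistic
            assert rho > 0.9, f"poor recovery in {treatment}: rho={rho:.3f}"
        assert (norms["lower"] < norms["upper"]).all()

    def test_intervals_widen_with_residual_variance(self, hatch_table):
        from gxevar import SimConfig, TraitParams, simulate_hatch_phenotypes

        def fit_widths(scale):
            params = TraitParams(
                mean=12.0,
                treatment_effects={t: 0.0 for t in ("cold", "amb", "var", "warm")},
                family_variances={t: 0.4 for t in ("cold", "amb", "var", "warm")},
                residual_variances={
                    t: 0.5 * scale for t in ("cold", "amb", "var", "warm")
                },
            )
            config = SimConfig(hatch_traits={"body_length_mm": params})
            table = simulate_hatch_phenotypes(config, seed=6)
            design = build_design(table, ModelSpec("body_length_mm"))
            draws = gibbs_sample(
                design, PriorSpec(), McmcSettings(3000, 500, 5, seed=7)
            )
            norms = conditional_family_means(draws, design)
            return (norms["upper"] - norms["lower"]).mean()

        assert fit_widths(8.0) > fit_widths(1.0)

    def test_requires_family_random_effects(self, hatch_table):
        spec = ModelSpec("body_length_mm", random=())
        design = build_design(hatch_table, spec)
        draws = gibbs_sample(design, PriorSpec(), McmcSettings(300, 50, 1, seed=8))
        with pytest.raises(ValueError, match="random effects"):
            conditional_family_means(draws, design)


class TestYolkGrowthRegression:
    def test_exact_line_r_squared_one(self):
        table = pd.DataFrame(
            {
                "yolk_sac_area_mm2": np.arange(1.0, 11.0),
                "growth_mm": 2.0 * np.arange(1.0, 11.0),
                "emerged": True,
            }
        )
        fit = yolk_growth_regression(table)
        assert fit.slope == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_independent_predictor_r_squared_near_zero(self):
        rng = np.random.default_rng(9)
        table = pd.DataFrame(
            {
                "yolk_sac_area_mm2": rng.normal(7, 1, 2000),
                "growth_mm": rng.normal(13, 2, 2000),
                "emerged": True,
            }
        )
        assert yolk_growth_regression(table).r_squared < 0.01

    def test_matches_closed_form_ols(self):
        x = np.array([6.2, 7.1, 7.9, 8.4, 6.8, 7.5])
        y = np.array([11.0, 13.2, 12.1, 14.8, 12.4, 12.9])
        table = pd.DataFrame(
            {"yolk_sac_area_mm2": x, "growth_mm": y, "emerged": True}
        )
        fit = yolk_growth_regression(table)
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * x.mean()
        r2 = 1 - np.sum((y - intercept - slope * x) ** 2) / np.sum(
            (y - y.mean()) ** 2
        )
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(intercept)
        assert fit.r_squared == pytest.approx(r2)

    def test_constant_predictor_rejected(self):
        table = pd.DataFrame(
            {"yolk_sac_area_mm2": [7.0] * 5, "growth_mm": np.arange(5.0),
             "emerged": True}
        )
        with pytest.raises(ValueError, match="constant"):
            yolk_growth_regression(table)

    def test_requires_three_emerged_rows(self):
        table = pd.DataFrame(
            {"yolk_sac_area_mm2": [7.0, 8.0], "growth_mm": [12.0, 13.0],
             "emerged": True}
        )
        with pytest.raises(ValueError, match="at least 3"):
            yolk_growth_regression(table)
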