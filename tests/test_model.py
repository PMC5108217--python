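import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gxevar import (
    DesignMatrices,
    McmcSettings,
    ModelSpec,
    PosteriorDraws,
    PriorSpec,
    build_design,
    deviance,
    gibbs_sample,
    retained_draw_count,
)
from gxevar.model import RandomComponent


class TestModelSpec:
    def test_requires_intercept(self):
        with pytest.raises(ValueError, match="intercept"):
            ModelSpec("body_length_mm", fixed=("treatment",))

    def test_interaction_requires_treatment(self):
        with pytest.raises(ValueError, match="treatment"):
            ModelSpec("body_length_mm", fixed=("intercept",),
                      random=("family_by_treatment",))

    def test_unknown_terms_rejected(self):
        with pytest.raises(ValueError, match="unknown fixed"):
            ModelSpec("body_length_mm", fixed=("intercept", "salinity"))


class TestBuildDesign:
    def test_heterogeneous_residual_groups_are_treatments(self, hatch_table):
        design = build_design(hatch_table, ModelSpec("body_length_mm"))
        assert len(design.residual_labels) == 4
        assert design.n_obs == 1200

    def test_homogeneous_residual_single_group(self, hatch_table):
        spec = ModelSpec("body_length_mm", heterogeneous_residual=False)
        design = build_design(hatch_table, spec)
        assert design.residual_labels == ["residual"]

    def test_interaction_levels_grouped_per_treatment(self, hatch_table):
        design = build_design(hatch_table, ModelSpec("body_length_mm"))
        assert len(design.random_labels) == 40  # 10 families x 4 treatments
        assert len(design.components) == 4
        for comp in design.components:
            assert len(comp.levels) == 10

    def test_treatment_contrasts_reference_cold(self, hatch_table):
        design = build_design(hatch_table, ModelSpec("body_length_mm"))
        assert design.fixed_labels == [
            "intercept", "treatment[amb]", "treatment[var]", "treatment[warm]"
        ]

    def test_missing_response_rows_dropped(self, hatch_table):
        table = hatch_table.copy()
        table.loc[table.index[:17], "body_length_mm"] = np.nan
        design = build_design(table, ModelSpec("body_length_mm"))
        assert design.n_obs == 1200 - 17

    def test_unknown_treatment_label_rejected(self, hatch_table):
        table = hatch_table.copy()
        table.loc[table.index[0], "treatment"] = "scalding"
        with pytest.raises(ValueError, match="scalding"):
            build_design(table, ModelSpec("body_length_mm"))

    def test_constant_covariate_rejected(self, emergence_table):
        table = emergence_table.copy()
        table["mean_t_c"] = 12.0
        spec = ModelSpec(
            "days_to_emergence",
            fixed=("intercept", "treatment", "mean_t"),
            random=("family",),
            family_column="fs_family",
        )
        with pytest.raises(ValueError, match="constant"):
            build_design(table, spec)


class TestRetainedDrawCount:
    @pytest.mark.parametrize(
        "total,burn,thin,expected",
        [(400_000, 10_000, 100, 3900), (1000, 0, 1, 1000), (1050, 50, 100, 10)],
    )
    def test_floor_arithmetic(self, total, burn, thin, expected):
        assert retained_draw_count(McmcSettings(total, burn, thin)) == expected

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            McmcSettings(100, 100, 1)
        with pytest.raises(ValueError):
            McmcSettings(100, 10, 0)


def intercept_only_design(y):
    y = np.asarray(y, dtype=float)
    return DesignMatrices(
        y=y,
        X=np.ones((len(y), 1)),
        fixed_labels=["intercept"],
        Z=np.empty((len(y), 0)),
        random_labels=[],
        components=[],
        residual_labels=["residual"],
        residual_index=np.zeros(len(y), dtype=np.intp),
        frame=pd.DataFrame({"y": y}),
        spec=ModelSpec("y"),
    )


class TestDeviance:
    def test_single_observation_closed_form(self):
        design = intercept_only_design([3.0])
        dev = deviance(design, np.array([3.0]), np.array([1.0]))
        assert dev == pytest.approx(math.log(2 * math.pi))

    def test_perfect_fit_n_observations(self):
        design = intercept_only_design([2.0] * 7)
        dev = deviance(design, np.array([2.0]), np.array([1.0]))
        assert dev == pytest.approx(7 * math.log(2 * math.pi))

    def test_matches_per_observation_normal_logpdf(self, hatch_table):
        design = build_design(hatch_table.head(60), ModelSpec("body_length_mm"))
        rng = np.random.default_rng(5)
        theta = rng.normal(size=design.n_location)
        resvar = rng.uniform(0.5, 2.0, size=len(design.residual_labels))
        mu = design.W @ theta
        oracle = -2 * sum(
            stats.norm.logpdf(y, m, np.sqrt(resvar[g]))
            for y, m, g in zip(design.y, mu, design.residual_index)
        )
        assert deviance(design, theta, resvar) == pytest.approx(oracle)

    def test_non_positive_residual_variance_rejected(self):
        design = intercept_only_design([1.0, 2.0])
        with pytest.raises(ValueError, match="positive"):
            deviance(design, np.array([1.5]), np.array([0.0]))


class TestGibbsSampler:
    def test_same_seed_identical_draws(self, hatch_table):
        design = build_design(hatch_table, ModelSpec("body_length_mm"))
        settings = McmcSettings(600, 100, 2, seed=42)
        a = gibbs_sample(design, PriorSpec(), settings)
        b = gibbs_sample(design, PriorSpec(), settings)
        assert np.array_equal(a.draws, b.draws)
        assert a.n_retained == retained_draw_count(settings)

    def test_variance_draws_strictly_positive(self, hatch_fit):
        _, draws = hatch_fit
        for label in draws.variance_labels():
            assert (draws.get(label) > 0).all()

    def test_posterior_summaries_seed_invariant(self):
        rng = np.random.default_rng(1)
        y = rng.normal(10.0, 2.0, size=200)
        design = intercept_only_design(y)
        means = []
        for seed in (1, 2):
            draws = gibbs_sample(
                design, PriorSpec(), McmcSettings(6000, 1000, 1, seed=seed)
            )
            means.append(draws.get("intercept").mean())
        assert means[0] == pytest.approx(means[1], abs=4 * 2.0 / np.sqrt(200) / 10)

    def test_intercept_conditional_matches_analytic_posterior(self):
        rng = np.random.default_rng(2)
        sigma2, n = 2.5, 80
        y = rng.normal(5.0, np.sqrt(sigma2), size=n)
        design = intercept_only_design(y)
        draws = gibbs_sample(
            design,
            PriorSpec(),
            McmcSettings(11_000, 1000, 1, seed=3),
            fix_residual_variances=np.array([sigma2]),
        )
        mu = draws.get("intercept")
        se = np.sqrt(sigma2 / n)
        assert mu.mean() == pytest.approx(y.mean(), abs=4 * se / np.sqrt(100))
        assert mu.var() == pytest.approx(sigma2 / n, rel=0.1)

    def test_empty_residual_group_rejected(self, hatch_table):
        design = build_design(hatch_table, ModelSpec("body_length_mm"))
        design.residual_index = np.where(design.residual_index == 3, 0,
                                         design.residual_index)
        with pytest.raises(ValueError, match="residual group"):
            gibbs_sample(design, PriorSpec(), McmcSettings(100, 10, 1))


class TestPosteriorDraws:
    def test_round_trips_through_csv(self, tmp_path, hatch_fit):
        _, draws = hatch_fit
        path = tmp_path / "draws.csv"
        draws.to_csv(path)
        loaded = PosteriorDraws.from_csv(path)
        assert loaded.labels == draws.labels
        assert np.allclose(loaded.draws, draws.draws)

    def test_get_unknown_label(self, hatch_fit):
        _, draws = hatch_fit
        with pytest.raises(KeyError):
            draws.get("var[salinity]")
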