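import warnings

import numpy as np
import pytest

from glucotrend.model import (
    ModelConfig,
    PosteriorDraws,
    fit_model,
    posterior_prob_increase,
    predict_prevalence,
)
from glucotrend.synthetic import (
    WorldConfig,
    build_world,
    make_survey_plan,
    simulate_surveys,
    who_standard_population,
)
from glucotrend.types import AGE_GROUPS, HierarchySpec, StandardPopulation

from conftest import flat_world_config


def _quiet_fit(pts, world, mc):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_model(pts, world.covariates, world.population, mc)


def micro_world(seed, **overrides):
    cfg = WorldConfig(
        n_super_regions=1, n_regions_per_super=2, n_countries_per_region=2,
        sexes=("female",), **overrides,
    )
    return build_world(cfg, seed=seed)


def test_config_defaults_and_validation():
    mc = ModelConfig()
    assert mc.draws == 5000  # paper-scale default for retained samples
    assert mc.chains >= 2
    h = HierarchySpec((("C0", "R0", "S0"),))
    with pytest.raises(ValueError, match="2 chains"):
        ModelConfig(hierarchy=h, chains=1).validate()
    with pytest.raises(ValueError, match="2 years"):
        ModelConfig(hierarchy=h, year_start=2000, year_end=2000).validate()
    with pytest.raises(ValueError, match="hierarchy"):
        ModelConfig().validate()


def test_non_harmonised_definitions_rejected():
    w = micro_world(0)
    plan = make_survey_plan(
        w, studies_per_country=1, seed=1, sexes=("female",),
        definition_probs={"OGTT_11_1": 1.0},
    )
    pts = simulate_surveys(w, plan, seed=2)
    mc = ModelConfig(hierarchy=w.hierarchy, burnin=5, draws=10, seed=0)
    with pytest.raises(ValueError, match="cross-walk"):
        fit_model(pts, w.covariates, w.population, mc)


def test_dense_unbiased_toy_world_recovered_within_one_point():
    # near-degenerate hierarchy: every country equals the global surface;
    # dense national data must pin the trajectory within 1pp everywhere
    cfg = flat_world_config(
        n_super_regions=1, n_regions_per_super=1, n_countries_per_region=2,
        trend_per_decade=0.12, age_amplitude=0.85, age_steepness=0.25,
    )
    w = build_world(cfg, seed=3)
    plan = make_survey_plan(
        w, studies_per_country=12, seed=4, sexes=("female",),
        scope_probs=(1.0, 0.0, 0.0), urbanicity_probs=(1.0, 0.0, 0.0),
    )
    pts = simulate_surveys(w, plan, seed=5)
    mc = ModelConfig(hierarchy=w.hierarchy, chains=2, burnin=300, draws=600,
                     seed=6)
    draws = _quiet_fit(pts, w, mc)
    sp = who_standard_population()
    for c in w.hierarchy.country_ids:
        traj = draws.age_standardised(c, "female", sp).mean(axis=0)
        truth = np.array(
            [w.true_summary(c, int(y), "female", sp) for y in w.years]
        )
        assert np.max(np.abs(traj - truth)) < 0.01


def test_retained_draw_count_matches_config(small_world, small_world_datapoints):
    mc = ModelConfig(hierarchy=small_world.hierarchy, chains=2, burnin=50,
                     draws=121, seed=1)
    draws = _quiet_fit(small_world_datapoints, small_world, mc)
    assert draws.n_draws == 121
    assert draws.prevalence.shape == (121, 12, 35, 1, len(AGE_GROUPS))
    assert "female" in draws.diagnostics
    assert isinstance(draws.diagnostics["female"]["converged"], bool)


def test_short_chains_flag_convergence_failure(small_world,
                                               small_world_datapoints):
    mc = ModelConfig(hierarchy=small_world.hierarchy, chains=2, burnin=0,
                     draws=8, seed=2)
    with pytest.warns(RuntimeWarning, match="convergence"):
        draws = fit_model(
            small_world_datapoints, small_world.covariates,
            small_world.population, mc,
        )
    assert draws.diagnostics["female"]["converged"] is False


def test_monotone_link_refit_on_toy_world():
    # raising one datapoint's observed prevalence must not lower that
    # country-year's posterior mean
    cfg = flat_world_config(
        n_super_regions=1, n_regions_per_super=1, n_countries_per_region=2,
        trend_per_decade=0.1, age_amplitude=0.85,
    )
    w = build_world(cfg, seed=7)
    plan = make_survey_plan(
        w, studies_per_country=6, seed=8, sexes=("female",),
        scope_probs=(1.0, 0.0, 0.0), urbanicity_probs=(1.0, 0.0, 0.0),
    )
    pts = simulate_surveys(w, plan, seed=9)
    mc = ModelConfig(hierarchy=w.hierarchy, chains=2, burnin=300, draws=600,
                     seed=10)
    base = _quiet_fit(pts, w, mc)
    target = pts[0]
    bumped = [
        dp.copy(prevalence=min(dp.prevalence + 0.10, 1.0)) if dp is target
        else dp
        for dp in pts
    ]
    alt = _quiet_fit(bumped, w, mc)
    sp = who_standard_population()
    y = target.mid_year
    before = base.age_standardised(target.country_id, "female", sp)[
        :, y - 1980].mean()
    after = alt.age_standardised(target.country_id, "female", sp)[
        :, y - 1980].mean()
    assert after >= before


def test_datapoint_order_does_not_change_the_posterior(small_world):
    plan = make_survey_plan(small_world, studies_per_country=2, seed=20,
                            sexes=("female",))
    pts = simulate_surveys(small_world, plan, seed=21)
    mc = ModelConfig(hierarchy=small_world.hierarchy, chains=2, burnin=50,
                     draws=100, seed=22)
    d1 = _quiet_fit(pts, small_world, mc)
    rng = np.random.default_rng(23)
    shuffled = list(pts)
    rng.shuffle(shuffled)
    d2 = _quiet_fit(shuffled, small_world, mc)
    assert np.array_equal(d1.prevalence, d2.prevalence)


def test_parameter_recovery_coverage_pooled_over_replicate_worlds():
    # 95% credible intervals should cover the true age-standardised
    # prevalence for 85-99% of country-years, pooled over replicate worlds
    sp = who_standard_population()
    covered = total = 0
    for seed in range(10):
        w = micro_world(30 + seed)
        plan = make_survey_plan(w, studies_per_country=5, seed=60 + seed,
                                sexes=("female",))
        pts = simulate_surveys(w, plan, seed=90 + seed)
        mc = ModelConfig(hierarchy=w.hierarchy, chains=2, burnin=250,
                         draws=500, seed=120 + seed)
        draws = _quiet_fit(pts, w, mc)
        for c in w.hierarchy.country_ids:
            traj = draws.age_standardised(c, "female", sp)
            lo = np.percentile(traj, 2.5, axis=0)
            hi = np.percentile(traj, 97.5, axis=0)
            truth = np.array(
                [w.true_summary(c, int(y), "female", sp) for y in w.years]
            )
            covered += int(np.sum((lo <= truth) & (truth <= hi)))
            total += len(truth)
    coverage = 100.0 * covered / total
    assert 85.0 <= coverage <= 99.0


class TestPosteriorDrawsInterface:
    def _draws(self, traj_by_country, n_draws=50, seed=0):
        countries = sorted(traj_by_country)
        hierarchy = HierarchySpec(
            tuple((c, "R0", "S0") for c in countries)
        )
        years = np.arange(2000, 2010)
        rng = np.random.default_rng(seed)
        prev = np.empty(
            (n_draws, len(countries), len(years), 1, len(AGE_GROUPS)),
            dtype=np.float32,
        )
        for ci, c in enumerate(countries):
            base = traj_by_country[c]
            prev[:, ci, :, 0, :] = np.asarray(base)[None, :, None]
        pop = np.ones((len(countries), len(years), 1, len(AGE_GROUPS)))
        return PosteriorDraws(
            prevalence=prev, countries=countries, years=years,
            sexes=("female",), hierarchy=hierarchy, diagnostics={},
            coefficients={}, population=pop,
        )

    def test_predictions_in_unit_interval_and_repeatable(self):
        d = self._draws({"C0": np.linspace(0.05, 0.1, 10)})
        a = predict_prevalence(d, "C0", 2005, "female")
        b = predict_prevalence(d, "C0", 2005, "female")
        assert np.all((a >= 0) & (a <= 1))
        assert np.array_equal(a, b)
        with pytest.raises(KeyError):
            predict_prevalence(d, "C0", 2030, "female")
        with pytest.raises(KeyError):
            predict_prevalence(d, "NOPE", 2005, "female")

    def test_region_aggregate_equals_bruteforce_population_weighting(self):
        d = self._draws(
            {"C0": np.linspace(0.05, 0.1, 10), "C1": np.linspace(0.2, 0.3, 10)}
        )
        # unequal populations
        d.population[0] *= 3.0
        sp = who_standard_population()
        agg = d.age_standardised("R0", "female", sp)
        w = sp.vector()
        expect = np.zeros_like(agg)
        tot = np.zeros(len(d.years))
        for ci in range(2):
            std = d.prevalence[:, ci, :, 0, :].astype(float) @ w
            pop = d.population[ci, :, 0, :].sum(axis=-1)
            expect += std * pop
            tot += pop
        expect /= tot
        assert np.allclose(agg, expect, rtol=1e-12)

    def test_probability_of_increase_conventions(self):
        rising = self._draws({"C0": np.linspace(0.05, 0.1, 10)})
        sp = who_standard_population()
        assert posterior_prob_increase(
            rising, "C0", "female", 2000, 2009, sp
        ) == 1.0
        assert posterior_prob_increase(
            rising, "C0", "female", 2005, 2005, sp
        ) == 0.0
        with pytest.raises(KeyError):
            posterior_prob_increase(rising, "C0", "female", 2000, 2030, sp)
        # symmetric noise: probability within Monte-Carlo bounds of 0.5
        n = 2000
        rng = np.random.default_rng(1)
        d = self._draws({"C0": np.full(10, 0.1)}, n_draws=n)
        d.prevalence[:, 0, -1, 0, :] = np.float32(0.1) + rng.normal(
            0, 0.01, n
        ).astype(np.float32)[:, None]
        p = posterior_prob_increase(d, "C0", "female", 2000, 2009, sp)
        assert abs(p - 0.5) <= 3 * np.sqrt(0.25 / n)

    def test_save_load_roundtrip(self, tmp_path):
        d = self._draws({"C0": np.linspace(0.05, 0.1, 10)})
        d.coefficients = {"female": {"trend": np.arange(50.0)}}
        d.diagnostics = {"female": {"converged": True}}
        path = tmp_path / "draws.zarr"
        d.save(path)
        back = PosteriorDraws.load(path)
        assert np.allclose(back.prevalence, d.prevalence)
        assert back.countries == d.countries
        assert np.array_equal(back.years, d.years)
        assert back.hierarchy == d.hierarchy
        assert np.allclose(back.coefficients["female"]["trend"], np.arange(50.0))

    def test_rejects_prevalence_outside_unit_interval(self):
        with pytest.raises(ValueError, match="outside"):
            PosteriorDraws(
                prevalence=np.full((2, 1, 1, 1, 1), 1.5, dtype=np.float32),
                countries=["C0"], years=np.array([2000]), sexes=("female",),
                hierarchy=HierarchySpec((("C0", "R0", "S0"),)),
                diagnostics={}, coefficients={},
            )
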