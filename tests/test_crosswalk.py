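import numpy as np
import pytest
import statsmodels.api as sm

from glucotrend.crosswalk import (
    CrosswalkModel,
    apply_crosswalk,
    filter_min_sample,
    fit_crosswalk,
    predict_probit,
)
from glucotrend.synthetic import DefinitionMap, simulate_paired_observations
from glucotrend.transforms import inv_probit, probit
from glucotrend.types import MEAN_FPG, OGTT_11_1, PRIMARY_FPG7, SurveyDatapoint


def _dp(n=100, prevalence=0.1, definition=OGTT_11_1, **kw):
    base = dict(
        study_id="s", country_id="R1_C0", mid_year=2000, sex="female",
        age_lo=40, age_hi=50, n_examined=n, prevalence=prevalence,
        se=float(np.sqrt(prevalence * (1 - prevalence) / n)),
        definition=definition,
    )
    base.update(kw)
    return SurveyDatapoint(**base)


def identity_model(source=OGTT_11_1):
    names = ["const", "source", "age", "sex", "year"]
    coefs = np.array([0.0, 1.0, 0.0, 0.0, 0.0])
    return CrosswalkModel(
        source_definition=source, coef_names=names, coefficients=coefs,
        cov_params=np.zeros((5, 5)), residual_variance=0.0,
        random_effect_variance=None, interactions=(), n_train=100,
        bic=0.0, bic_no_interaction=0.0,
    )


class TestMinSampleFilter:
    def test_threshold_is_25_examined(self):
        pts = [_dp(n) for n in (10, 24, 25, 100)]
        kept = filter_min_sample(pts)
        assert [d.n_examined for d in kept] == [25, 100]

    def test_identity_when_all_large(self):
        pts = [_dp(n) for n in (25, 40, 1000)]
        assert filter_min_sample(pts) == pts

    def test_matches_bruteforce_recount(self):
        rng = np.random.default_rng(1)
        pts = [_dp(int(n)) for n in rng.integers(1, 200, size=1000)]
        kept = filter_min_sample(pts)
        assert len(kept) == sum(1 for d in pts if d.n_examined >= 25)
        # order preserved
        it = iter(pts)
        assert all(any(d is e for e in it) for d in kept)


class TestFitCrosswalk:
    def test_regional_random_effects_toggle_at_400(self):
        paired = simulate_paired_observations(500, OGTT_11_1, seed=2)
        m_big = fit_crosswalk(paired, OGTT_11_1)
        assert m_big.random_effect_variance is not None
        m_small = fit_crosswalk(paired[:300], OGTT_11_1)
        assert m_small.random_effect_variance is None

    def test_slope_recovery_without_interactions(self):
        dmap = DefinitionMap(intercept=0.2, slope=0.9, noise_sd=0.05)
        paired = simulate_paired_observations(2000, OGTT_11_1, dmap=dmap, seed=3)
        m = fit_crosswalk(paired, OGTT_11_1)
        assert 0.85 <= m.coef["source"] <= 0.95
        assert m.interactions == ()
        assert m.bic <= m.bic_no_interaction

    def test_bic_detects_source_age_interaction(self):
        dmap = DefinitionMap(
            intercept=0.2, slope=0.9, interactions={"source:age": 0.3},
            noise_sd=0.08,
        )
        paired = simulate_paired_observations(800, OGTT_11_1, dmap=dmap, seed=4)
        m = fit_crosswalk(paired, OGTT_11_1)
        assert "source:age" in m.interactions
        assert m.bic <= m.bic_no_interaction

    def test_too_few_observations_rejected(self):
        paired = simulate_paired_observations(40, OGTT_11_1, seed=5)
        with pytest.raises(ValueError, match=">= 50"):
            fit_crosswalk(paired, OGTT_11_1)

    def test_collinear_design_reported(self):
        paired = simulate_paired_observations(120, OGTT_11_1, seed=6)
        for d in paired:  # make age, sex, year constant -> collinear with const
            d.age_lo, d.age_hi = 40, 50
            d.mid_year = 2000
            d.sex = "female"
        with pytest.raises(ValueError, match="collinear"):
            fit_crosswalk(paired, OGTT_11_1)

    def test_mean_fpg_sources_use_concentration_scale(self):
        paired = simulate_paired_observations(300, MEAN_FPG, seed=7)
        m = fit_crosswalk(paired, MEAN_FPG)
        dp = _dp(500, prevalence=5.9, definition=MEAN_FPG, se=0.05)
        out = apply_crosswalk(m, dp)
        assert out.definition == PRIMARY_FPG7
        assert 0.0 < out.prevalence < 1.0


class TestApplyCrosswalk:
    def test_identity_model_leaves_datapoint_unchanged(self):
        dp = _dp(400, prevalence=0.12)
        out = apply_crosswalk(identity_model(), dp)
        assert out.definition == PRIMARY_FPG7
        assert out.prevalence == pytest.approx(0.12, rel=1e-9)
        assert out.se == pytest.approx(dp.se, rel=1e-6)

    def test_definition_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            apply_crosswalk(identity_model(), _dp(definition=MEAN_FPG))

    def test_output_contract_on_random_models(self):
        rng = np.random.default_rng(8)
        paired = simulate_paired_observations(600, OGTT_11_1, seed=9)
        m = fit_crosswalk(paired, OGTT_11_1)
        for _ in range(50):
            dp = _dp(
                int(rng.integers(30, 5000)),
                prevalence=float(rng.uniform(0.01, 0.6)),
                mid_year=int(rng.integers(1980, 2015)),
            )
            out = apply_crosswalk(m, dp)
            assert 0.0 <= out.prevalence <= 1.0
            assert out.se >= dp.se

    def test_se_matches_numerical_delta_method_oracle(self):
        # residual SD 0.1 on the probit scale, negligible sampling error:
        # the output SE must match a finite-difference delta-method oracle
        m = identity_model()
        m.residual_variance = 0.01
        dp = _dp(5_000_000, prevalence=0.15)
        out = apply_crosswalk(m, dp)

        def pred(p_src):
            yhat, _ = predict_probit(m, _dp(5_000_000, prevalence=p_src))
            return float(inv_probit(yhat))

        h = 1e-5
        dp_dsrc = (pred(0.15 + h) - pred(0.15 - h)) / (2 * h)
        yhat, _ = predict_probit(m, dp)
        dens = float(np.exp(-0.5 * yhat**2) / np.sqrt(2 * np.pi))
        oracle = np.sqrt(
            dp_dsrc**2 * dp.se**2 + dens**2 * m.residual_variance
        )
        assert out.se == pytest.approx(oracle, rel=0.02)


class TestRoundTrip:
    def test_crosswalking_reduces_mse_against_truth(self):
        dmap = DefinitionMap(intercept=0.35, slope=0.9, noise_sd=0.08)
        train = simulate_paired_observations(800, OGTT_11_1, dmap=dmap, seed=10)
        m = fit_crosswalk(train, OGTT_11_1)
        test = simulate_paired_observations(
            500, OGTT_11_1, dmap=dmap, seed=11
        )
        converted = [apply_crosswalk(m, d) for d in test]
        mse_converted = np.mean(
            [(c.prevalence - d.primary_prevalence) ** 2
             for c, d in zip(converted, test)]
        )
        mse_raw = np.mean(
            [(d.prevalence - d.primary_prevalence) ** 2 for d in test]
        )
        assert mse_converted < mse_raw

    def test_refit_on_converted_data_recovers_unit_slope(self):
        dmap = DefinitionMap(intercept=0.3, slope=0.85, noise_sd=0.08)
        train = simulate_paired_observations(1500, OGTT_11_1, dmap=dmap, seed=12)
        m = fit_crosswalk(train, OGTT_11_1)
        test = simulate_paired_observations(800, OGTT_11_1, dmap=dmap, seed=13)
        converted = [apply_crosswalk(m, d) for d in test]
        y = probit([d.primary_prevalence for d in test])
        x = sm.add_constant(probit([c.prevalence for c in converted]))
        res = sm.OLS(y, x).fit()
        slope, se = res.params[1], res.bse[1]
        assert abs(slope - 1.0) <= 3 * se


def test_model_json_roundtrip():
    paired = simulate_paired_observations(200, OGTT_11_1, seed=14)
    m = fit_crosswalk(paired, OGTT_11_1)
    m2 = CrosswalkModel.from_json(m.to_json())
    assert m2.coef_names == m.coef_names
    assert np.allclose(m2.coefficients, m.coefficients)
    assert m2.interactions == m.interactions
    assert m2.n_train == m.n_train
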