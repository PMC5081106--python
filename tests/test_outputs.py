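import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glucotrend.outputs import (
    age_standardise,
    component_shares,
    crude_and_counts,
    decompose_change,
    project_post2000,
    target_probability,
)
from glucotrend.transforms import inv_probit, probit
from glucotrend.types import StandardPopulation


class TestAgeStandardise:
    def test_constant_prevalence_is_invariant_to_weights(self):
        sp = StandardPopulation({(18, 20): 1.0, (20, 25): 4.0, (25, 30): 2.0})
        assert age_standardise([0.07, 0.07, 0.07], sp) == pytest.approx(0.07)

    def test_weighted_arithmetic(self):
        assert age_standardise([0.10, 0.20], np.array([0.6, 0.4])) == (
            pytest.approx(0.14)
        )

    def test_matches_bruteforce_loop_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            k = int(rng.integers(2, 15))
            prev = rng.uniform(0, 1, k)
            w = rng.uniform(0.1, 1, k)
            expected = sum(
                prev[i] * (w[i] / w.sum()) for i in range(k)
            )
            assert age_standardise(prev, w) == pytest.approx(expected, rel=1e-12)

    def test_applies_per_draw(self):
        draws = np.array([[0.1, 0.2], [0.3, 0.4]])
        out = age_standardise(draws, np.array([0.5, 0.5]))
        assert out == pytest.approx([0.15, 0.35])

    def test_weight_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            age_standardise([0.1, 0.2, 0.3], np.array([0.5, 0.5]))

    def test_invariant_to_population_size_but_crude_is_not(self):
        prev = np.array([0.05, 0.25])
        pop = np.array([800.0, 200.0])
        w = np.array([0.5, 0.5])
        std1 = age_standardise(prev, w)
        crude1, _ = crude_and_counts(prev, pop)
        # doubling the old-age population changes crude, not standardised
        pop2 = pop * np.array([1.0, 2.0])
        crude2, _ = crude_and_counts(prev, pop2)
        assert age_standardise(prev, w) == std1
        assert crude2 != pytest.approx(crude1)


class TestCrudeAndCounts:
    def test_zero_prevalence(self):
        crude, count = crude_and_counts([0.0, 0.0], [500.0, 500.0])
        assert crude == 0.0 and count == 0.0

    def test_single_group_arithmetic(self):
        crude, count = crude_and_counts([0.25], [1000.0])
        assert crude == pytest.approx(0.25)
        assert count == pytest.approx(250.0)

    def test_crude_equals_standardised_with_population_weights(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            prev = rng.uniform(0, 0.5, 6)
            pop = rng.uniform(10, 1e5, 6)
            crude, _ = crude_and_counts(prev, pop)
            assert crude == pytest.approx(age_standardise(prev, pop), rel=1e-12)

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError, match="population"):
            crude_and_counts([0.1], [0.0])


class TestDecomposition:
    def test_reported_component_magnitudes_give_reported_shares(self):
        # growth/ageing 124.8M, prevalence rise 89.7M, interaction 99.9M
        shares = component_shares([124.8e6, 89.7e6, 99.9e6])
        assert round(shares[0], 1) == 39.7
        assert round(shares[1], 1) == 28.5
        assert round(shares[2], 1) == 31.8

    def test_static_population_attributes_all_change_to_prevalence(self):
        p0, p1 = np.array([0.1, 0.2]), np.array([0.15, 0.3])
        pop = np.array([1000.0, 500.0])
        r = decompose_change(p0, p1, pop, pop)
        assert r.component_growth_ageing == 0.0
        assert r.component_interaction == 0.0
        assert r.component_prevalence == pytest.approx(r.total_change)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_identity_and_symmetry_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 15))
        p0, p1 = rng.uniform(0, 1, k), rng.uniform(0, 1, k)
        n0, n1 = rng.uniform(0, 1e7, k), rng.uniform(0, 1e7, k)
        r = decompose_change(p0, p1, n0, n1)
        total = float(n1 @ p1 - n0 @ p0)
        assert r.total_change == pytest.approx(total, rel=1e-9, abs=1e-6)
        comps = (
            r.component_growth_ageing + r.component_prevalence
            + r.component_interaction
        )
        assert comps == pytest.approx(total, rel=1e-9, abs=1e-6)
        back = decompose_change(p1, p0, n1, n0)
        assert back.total_change == pytest.approx(-r.total_change, rel=1e-9,
                                                  abs=1e-6)

    def test_mismatched_age_groups_rejected(self):
        with pytest.raises(ValueError, match="match"):
            decompose_change([0.1], [0.1, 0.2], [1.0], [1.0])


class _TrajDraws:
    """Minimal stand-in exposing the trajectory interface of PosteriorDraws."""

    def __init__(self, traj, years):
        self.traj = np.asarray(traj, dtype=float)
        self.years = np.asarray(years)

    def age_standardised(self, unit, sex, weights, population=None):
        return self.traj

    def _yidx(self, year):
        return int(year - self.years[0])


class TestProjection:
    years = np.arange(1980, 2015)

    def test_flat_trajectory_projects_to_itself(self):
        d = _TrajDraws(np.full((10, 35), 0.08), self.years)
        proj = project_post2000(d, "world", "female", None)
        assert proj == pytest.approx(np.full(10, 0.08))

    def test_linear_probit_trajectory_extends_analytically(self):
        z0, slope = -1.5, 0.02
        z = z0 + slope * (self.years - 2000)
        d = _TrajDraws(inv_probit(z)[None, :].repeat(3, axis=0), self.years)
        proj = project_post2000(d, "world", "female", None, target_year=2025)
        assert proj == pytest.approx(
            np.full(3, inv_probit(z0 + slope * 25)), rel=1e-9
        )

    def test_matches_independent_least_squares_oracle(self):
        rng = np.random.default_rng(3)
        traj = inv_probit(rng.normal(-1.5, 0.2, size=(20, 35)))
        d = _TrajDraws(traj, self.years)
        proj = project_post2000(d, "world", "female", None)
        sel = self.years >= 2000
        for i in range(20):
            coeffs = np.polyfit(
                self.years[sel].astype(float), probit(traj[i, sel]), 1
            )
            expected = inv_probit(np.polyval(coeffs, 2025.0))
            assert proj[i] == pytest.approx(expected, rel=1e-9)

    def test_short_window_rejected(self):
        d = _TrajDraws(np.full((5, 35), 0.1), self.years)
        with pytest.raises(ValueError, match="3 years"):
            project_post2000(d, "world", "female", None, window_start=2013)
        with pytest.raises(ValueError, match="beyond"):
            project_post2000(d, "world", "female", None, target_year=2010)


class TestTargetProbability:
    def test_flat_draws_meet_target_with_ties(self):
        flat = np.full(100, 0.08)
        assert target_probability(flat, flat).probability_met == 1.0

    def test_strictly_rising_draws_fail_target(self):
        t = target_probability(np.full(100, 0.12), np.full(100, 0.08))
        assert t.probability_met == 0.0

    def test_symmetric_noise_gives_half(self):
        rng = np.random.default_rng(4)
        n = 4000
        base = np.full(n, 0.10)
        proj = inv_probit(probit(base) + rng.normal(0, 0.05, n))
        p = target_probability(proj, base).probability_met
        assert abs(p - 0.5) <= 3 * np.sqrt(0.25 / n)

    def test_unpaired_draws_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            target_probability(np.zeros(10), np.zeros(11))
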