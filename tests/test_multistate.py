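"""Process-model contracts: transition/observation matrices, linear
predictors, and priors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.special import expit

from lynxmark.multistate import (ModelSpec, ParameterSet, PriorSpec,
                                 StateSpace, annualize,
                                 build_observation_matrix,
                                 build_transition_matrix, detection_logit,
                                 half_t_logpdf, interval_survival, log_prior,
                                 recovery_logit, survival_logit)

SPACES = [StateSpace("two_subarea"), StateSpace("one_area")]


def random_sm(space, rng):
    """Random valid interval survivals and movement for a layout."""
    s = rng.uniform(0, 1, space.n_areas)
    if space.layout == "two_subarea":
        m = np.concatenate([rng.dirichlet([1, 1, 1])[:2],
                            rng.dirichlet([1, 1, 1])[:2]])
    else:
        m = rng.uniform(0, 1, 1)
    return s, m


class TestIntervalSurvival:
    def test_fixed_points(self):
        assert interval_survival(1.0, 6) == 1.0
        assert interval_survival(0.0, 12) == 0.0

    def test_round_trip_with_annualize(self):
        s = interval_survival(0.78, 6)
        assert s == pytest.approx(0.78 ** (1 / 6), abs=1e-15)
        assert annualize(s, 6) == pytest.approx(0.78, abs=1e-12)
        assert annualize(0.95, 12) == pytest.approx(0.95 ** 12, abs=1e-15)

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            interval_survival(1.2, 6)
        with pytest.raises(ValueError):
            interval_survival(0.5, 4)


class TestTransitionMatrix:
    def test_identity_when_immortal_and_static(self):
        space = StateSpace("two_subarea")
        T = build_transition_matrix([1, 1, 1], [0, 0, 0, 0], space)
        for a in range(3):
            i = space.alive_state(a)
            assert T[i, i] == 1.0

    def test_printed_row_entries(self):
        space = StateSpace("two_subarea")
        T = build_transition_matrix([0.9, 0.9, 0.9], [0.1, 0, 0, 0], space)
        assert T[0, 2] == pytest.approx(0.09)   # alive sub1 -> alive sub2
        assert T[0, 1] == pytest.approx(0.1)    # alive sub1 -> died sub1
        assert T[0, 0] == pytest.approx(0.81)

    def test_died_states_absorb_to_dead_before(self):
        for space in SPACES:
            s = np.full(space.n_areas, 0.5)
            m = np.zeros(4 if space.layout == "two_subarea" else 1)
            T = build_transition_matrix(s, m, space)
            for a in range(space.n_areas):
                row = T[space.died_state(a)]
                assert row[space.dead_before] == 1.0 and row.sum() == 1.0
            assert T[space.dead_before, space.dead_before] == 1.0

    @given(st.integers(0, 2 ** 31 - 1), st.sampled_from([0, 1]))
    @settings(max_examples=200, deadline=None)
    def test_rows_stochastic_for_random_parameters(self, seed, which):
        space = SPACES[which]
        rng = np.random.default_rng(seed)
        s, m = random_sm(space, rng)
        T = build_transition_matrix(s, m, space)
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-12)
        assert (T >= 0).all()

    def test_monotone_in_survival(self):
        space = StateSpace("two_subarea")
        m = [0.1, 0.05, 0.2, 0.02]
        T1 = build_transition_matrix([0.8, 0.8, 0.8], m, space)
        T2 = build_transition_matrix([0.9, 0.9, 0.9], m, space)
        for a in range(3):
            i = space.alive_state(a)
            for b in range(3):
                j = space.alive_state(b)
                if T1[i, j] > 0:
                    assert T2[i, j] > T1[i, j]
            assert T2[i, space.died_state(a)] < T1[i, space.died_state(a)]

    def test_recovery_mass_independent_of_movement(self):
        """Mortality happens before movement: the alive->died entry does not
        depend on any movement probability (finite differences)."""
        space = StateSpace("two_subarea")
        s = [0.85, 0.9, 0.8]
        base = build_transition_matrix(s, [0.1, 0.05, 0.2, 0.02], space)
        for k in range(4):
            m = np.array([0.1, 0.05, 0.2, 0.02])
            m[k] += 1e-4
            T = build_transition_matrix(s, m, space)
            for a in range(3):
                i = space.alive_state(a)
                d = space.died_state(a)
                assert T[i, d] == pytest.approx(base[i, d], abs=0)

    def test_invalid_movement_sum(self):
        space = StateSpace("two_subarea")
        with pytest.raises(ValueError):
            build_transition_matrix([0.9] * 3, [0.7, 0.4, 0, 0], space)


class TestObservationMatrix:
    def test_certain_emissions(self):
        for space in SPACES:
            O = build_observation_matrix(np.ones(space.n_areas),
                                         np.ones(space.n_areas), space)
            for a in range(space.n_areas):
                assert O[space.alive_state(a), space.code_detected(a)] == 1.0
                assert O[space.died_state(a), space.code_recovered(a)] == 1.0

    def test_two_outcome_row(self):
        space = StateSpace("two_subarea")
        O = build_observation_matrix([0.4, 0.2, 0.1], [0.5, 0.5, 0.5], space)
        assert O[0, space.code_detected(0)] == pytest.approx(0.4)
        assert O[0, 0] == pytest.approx(0.6)

    def test_dead_before_is_silent(self):
        for space in SPACES:
            O = build_observation_matrix(np.full(space.n_areas, 0.3),
                                         np.full(space.n_areas, 0.3), space)
            assert O[space.dead_before, 0] == 1.0

    @given(st.integers(0, 2 ** 31 - 1), st.sampled_from([0, 1]))
    @settings(max_examples=200, deadline=None)
    def test_rows_stochastic(self, seed, which):
        space = SPACES[which]
        rng = np.random.default_rng(seed)
        O = build_observation_matrix(rng.uniform(0, 1, space.n_areas),
                                     rng.uniform(0, 1, space.n_areas), space)
        assert np.allclose(O.sum(axis=1), 1.0, atol=1e-12)


class TestLinearPredictors:
    def setup_method(self):
        self.spec2 = ModelSpec(layout="two_subarea", intervals_per_year=6,
                               n_years=5)
        self.spec1 = ModelSpec(layout="one_area", intervals_per_year=12,
                               n_years=5)

    def test_survival_intercept_only_when_sigma_zero(self):
        p = ParameterSet.zeros(self.spec2)
        p.b0[0, 0, 2] = 1.3
        p.gamma[:] = 2.0   # irrelevant because sigma_S = 0
        for year in range(5):
            assert survival_logit(p, self.spec2, 0, 0, 2, year) == 1.3

    def test_year_effect_shifts_logit_linearly(self):
        p = ParameterSet.zeros(self.spec2)
        p.sigma_S[:] = 0.3
        p.gamma[0, 2] = 1.0
        assert survival_logit(p, self.spec2, 0, 0, 0, 2) == pytest.approx(0.3)

    def test_outside_survival_is_overall_mean(self):
        p = ParameterSet.zeros(self.spec2)
        p.b_out = -0.5
        p.b0[:] = 3.0
        assert survival_logit(p, self.spec2, 2, 1, 2, 4) == -0.5

    def test_systmon_effect_on_log_odds(self):
        p = ParameterSet.zeros(self.spec2)
        p.a1 = 0.45
        lg0 = detection_logit(p, self.spec2, 0, 0, 2, False, systmon=0.0)
        lg1 = detection_logit(p, self.spec2, 0, 0, 2, False, systmon=1.0)
        assert lg1 - lg0 == pytest.approx(0.45)

    def test_oppmon_centered_at_baseline(self):
        p = ParameterSet.zeros(self.spec2)
        p.a2 = 0.6
        lg = detection_logit(p, self.spec2, 0, 0, 2, False, oppmon=1.0)
        assert lg == pytest.approx(p.a0[0, 0, 2, 0])

    def test_telemetry_fixed_to_one_in_one_area_layout(self):
        p = ParameterSet.zeros(self.spec1)
        p.a0[:] = -3.0
        lg = detection_logit(p, self.spec1, 0, 1, 1, True)
        assert np.isposinf(lg)
        assert expit(lg) == 1.0

    def test_telemetry_intercept_tied_across_sex_age(self):
        p = ParameterSet.zeros(self.spec2)
        p.a0[0, 0, 0, 1] = 2.2
        p.a0[0, 1, 2, 1] = -9.9   # overridden by the constraint
        lg = detection_logit(p, self.spec2, 0, 1, 2, True)
        assert lg == pytest.approx(2.2)

    def test_recovery_additive_subarea_offsets(self):
        p = ParameterSet.zeros(self.spec2)
        p.d0[1, 0] = -1.0
        p.d_area = np.array([0.0, 0.4, -2.0])
        assert recovery_logit(p, self.spec2, 0, 1, 0) == pytest.approx(-1.0)
        assert recovery_logit(p, self.spec2, 1, 1, 0) == pytest.approx(-0.6)
        assert recovery_logit(p, self.spec2, 2, 1, 0) == pytest.approx(-3.0)
        # offsets are the same for every sex/age cell
        for s in range(2):
            for g in range(3):
                diff = (recovery_logit(p, self.spec2, 1, s, g)
                        - recovery_logit(p, self.spec2, 0, s, g))
                assert diff == pytest.approx(0.4)


class TestModelSpecSerialization:
    def test_yaml_round_trip(self):
        import yaml
        spec = ModelSpec(layout="two_subarea", intervals_per_year=6,
                         n_years=7, year_effects=False,
                         priors=PriorSpec(sigma_scale=0.4))
        text = yaml.safe_dump(spec.to_dict())
        back = ModelSpec.from_dict(yaml.safe_load(text))
        assert back.to_dict() == spec.to_dict()
        assert back.priors.sigma_scale == 0.4


class TestPriors:
    def test_movement_constraint_violation(self):
        spec = ModelSpec(layout="two_subarea", intervals_per_year=6,
                         n_years=3)
        p = ParameterSet.zeros(spec)
        assert np.isfinite(log_prior(p, spec))
        p.m[0, 0, :2] = [0.7, 0.5]
        assert log_prior(p, spec) == -np.inf

    def test_intercept_at_zero_is_normal_mode(self):
        spec = ModelSpec(layout="one_area", intervals_per_year=12, n_years=3,
                         year_effects=False, individual_effects=False,
                         effort_effects=False, telemetry=False)
        p = ParameterSet.zeros(spec)
        lp0 = log_prior(p, spec)
        p.b0[0, 0, 0] = 0.5
        assert log_prior(p, spec) < lp0

    def test_half_t_density_integrates_to_one(self):
        val, err = integrate.quad(
            lambda x: np.exp(half_t_logpdf(x, scale=1.0, df=2.0)), 0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-8)
        val2, _ = integrate.quad(
            lambda x: np.exp(half_t_logpdf(x, scale=0.4, df=2.0)), 0, np.inf)
        assert val2 == pytest.approx(1.0, abs=1e-8)

    def test_movement_prior_density_integrates_to_one(self):
        # uniform on {m12 + m13 <= 1}: density 2 on the triangle
        spec = ModelSpec(layout="two_subarea", intervals_per_year=6,
                         n_years=2, year_effects=False,
                         individual_effects=False, effort_effects=False,
                         telemetry=False)
        p = ParameterSet.zeros(spec)
        base = log_prior(p, spec)

        def density(m12, m13):
            q = ParameterSet.zeros(spec)
            q.m[0, 0, :2] = [m12, m13]
            lp = log_prior(q, spec)
            return np.exp(lp - base)

        val, _ = integrate.dblquad(lambda y, x: density(x, y),
                                   0, 1, 0, lambda x: 1 - x)
        # relative to the baseline at m=0 the density is constant (=1 here),
        # so the integral over the triangle is 1/2 of the constant 2
        assert val == pytest.approx(0.5, abs=1e-6)
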