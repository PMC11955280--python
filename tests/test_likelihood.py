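"""Forward-algorithm likelihood against exhaustive enumeration and other
independent oracles."""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

from lynxmark.data_model import (EffortCovariates, MultiStateDataset,
                                 OccasionGrid)
from lynxmark.likelihood import (dataset_loglik, forward_loglik,
                                 history_matrices, per_individual_loglik,
                                 sex_marginal_loglik, smoothed_state_probs,
                                 total_loglik)
from lynxmark.multistate import (ModelSpec, ParameterSet, StateSpace,
                                 build_observation_matrix,
                                 build_transition_matrix)

SPACES = {"two_subarea": StateSpace("two_subarea"),
          "one_area": StateSpace("one_area")}


def random_matrices(space, n_occ, rng, interior=False):
    """Random per-occasion transition and emission matrices."""
    lo, hi = (0.05, 0.95) if interior else (0.0, 1.0)
    T_seq, O_seq = [], []
    for _ in range(n_occ):
        s = rng.uniform(lo, hi, space.n_areas)
        if space.layout == "two_subarea":
            m = np.concatenate([rng.dirichlet([1, 1, 1])[:2],
                                rng.dirichlet([1, 1, 1])[:2]])
        else:
            m = rng.uniform(lo, hi, 1)
        T_seq.append(build_transition_matrix(s, m, space))
        O_seq.append(build_observation_matrix(
            rng.uniform(lo, hi, space.n_areas),
            rng.uniform(lo, hi, space.n_areas), space))
    return T_seq, O_seq


def enumeration_loglik(codes, first, T_seq, O_seq, space, last=None):
    """Independent oracle: explicit sum over all latent state paths."""
    if last is None:
        last = len(codes)
    z0 = space.state_of_code(int(codes[first]))
    total = 0.0
    n_free = last - first - 1
    for path in itertools.product(range(space.n_states), repeat=n_free):
        prob = 1.0
        prev = z0
        for k, z in enumerate(path):
            t = first + 1 + k
            prob *= T_seq[t - 1][prev, z] * O_seq[t][z, int(codes[t])]
            prev = z
        total += prob
    return np.log(total) if total > 0 else -np.inf


class TestForwardAlgorithm:
    def test_length_one_history_gives_zero(self):
        space = SPACES["one_area"]
        rng = np.random.default_rng(0)
        T_seq, O_seq = random_matrices(space, 1, rng)
        codes = [space.code_detected(0)]
        assert forward_loglik(codes, 0, T_seq, O_seq, space) == 0.0

    def test_single_death_and_recovery_path(self):
        """Alive at t, recovered dead in the same area at t+1:
        probability (1 - s) * r straight from the printed matrices."""
        space = SPACES["two_subarea"]
        s, r1 = 0.85, 0.3
        T = build_transition_matrix([s, 0.9, 0.8], [0.1, 0.05, 0, 0], space)
        O = build_observation_matrix([0.4, 0.4, 0.1], [r1, 0.2, 0.1], space)
        codes = [space.code_detected(0), space.code_recovered(0)]
        ll = forward_loglik(codes, 0, [T, T], [O, O], space)
        assert ll == pytest.approx(np.log((1 - s) * r1), abs=1e-12)

    @pytest.mark.parametrize("layout", ["two_subarea", "one_area"])
    def test_matches_exhaustive_enumeration(self, layout):
        """Forward recursion equals brute-force path enumeration on random
        instances with up to 4 occasions."""
        space = SPACES[layout]
        rng = np.random.default_rng(123)
        checked = 0
        while checked < 60:
            n_occ = int(rng.integers(2, 5))
            T_seq, O_seq = random_matrices(space, n_occ, rng)
            codes = rng.integers(0, space.n_codes, n_occ)
            codes[0] = space.code_detected(rng.integers(0, space.n_areas))
            ll_f = forward_loglik(codes, 0, T_seq, O_seq, space)
            ll_e = enumeration_loglik(codes, 0, T_seq, O_seq, space)
            if np.isfinite(ll_e):
                assert ll_f == pytest.approx(ll_e, abs=1e-10)
            else:
                assert ll_f == -np.inf
            checked += 1

    def test_impossible_history_is_minus_inf(self):
        space = SPACES["one_area"]
        rng = np.random.default_rng(5)
        T_seq, O_seq = random_matrices(space, 3, rng)
        codes = [space.code_detected(0), space.code_recovered(0),
                 space.code_detected(0)]   # detection after dead recovery
        assert forward_loglik(codes, 0, T_seq, O_seq, space) == -np.inf

    def test_censoring_drops_tail(self):
        space = SPACES["one_area"]
        rng = np.random.default_rng(9)
        T_seq, O_seq = random_matrices(space, 5, rng)
        codes = [space.code_detected(0), 0, space.code_detected(0), 0, 0]
        full = forward_loglik(codes, 0, T_seq, O_seq, space, last=3)
        again = forward_loglik(codes[:3], 0, T_seq[:3], O_seq[:3], space)
        assert full == pytest.approx(again, abs=1e-12)

    def test_emission_completeness(self):
        """Summing the likelihood over every possible observation sequence
        of fixed length equals 1 (p, r strictly interior)."""
        space = SPACES["one_area"]
        rng = np.random.default_rng(21)
        n_occ = 3
        T_seq, O_seq = random_matrices(space, n_occ, rng, interior=True)
        total = 0.0
        for tail in itertools.product(range(space.n_codes), repeat=n_occ - 1):
            codes = [space.code_detected(0)] + list(tail)
            ll = forward_loglik(codes, 0, T_seq, O_seq, space)
            if np.isfinite(ll):
                total += np.exp(ll)
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_long_history_numerically_stable(self):
        space = SPACES["one_area"]
        n_occ = 200
        s = np.array([1 - 1e-12, 1 - 1e-12])
        T = build_transition_matrix(s, [1e-12], space)
        O = build_observation_matrix([1e-12, 1e-12], [1e-12, 1e-12], space)
        codes = np.zeros(n_occ, dtype=int)
        codes[0] = space.code_detected(0)
        ll = forward_loglik(codes, 0, [T] * n_occ, [O] * n_occ, space)
        assert np.isfinite(ll)

    def test_smoothed_probs_normalized(self):
        space = SPACES["one_area"]
        rng = np.random.default_rng(3)
        T_seq, O_seq = random_matrices(space, 6, rng, interior=True)
        codes = [space.code_detected(0), 0, 0, space.code_detected(0), 0, 0]
        post = smoothed_state_probs(codes, 0, T_seq, O_seq, space)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-10)
        assert post[3, space.alive_state(0)] == pytest.approx(1.0)


class TestSexMarginal:
    def _seqs(self, space, rng):
        T_f, O_f = random_matrices(space, 4, rng)
        T_m, O_m = random_matrices(space, 4, rng)
        return {0: (T_f, O_f), 1: (T_m, O_m)}

    def test_degenerate_mixture_equals_female(self):
        space = SPACES["one_area"]
        rng = np.random.default_rng(2)
        seqs = self._seqs(space, rng)
        codes = [space.code_detected(0), 0, space.code_detected(0), 0]
        lu = sex_marginal_loglik(codes, 0, -1, lambda s: seqs[s],
                                 [1.0, 0.0], space)
        lf = forward_loglik(codes, 0, *seqs[0], space)
        assert lu == pytest.approx(lf, abs=1e-12)

    def test_random_mixture_equals_direct_sum(self):
        space = SPACES["two_subarea"]
        rng = np.random.default_rng(4)
        seqs = self._seqs(space, rng)
        codes = [space.code_detected(1), 0, space.code_detected(0), 0]
        psi = [0.37, 0.63]
        lu = sex_marginal_loglik(codes, 0, -1, lambda s: seqs[s], psi, space)
        parts = [forward_loglik(codes, 0, *seqs[s], space) for s in range(2)]
        assert lu == pytest.approx(
            logsumexp(np.log(psi) + np.array(parts)), abs=1e-12)

    def test_known_sex_uses_that_component(self):
        space = SPACES["one_area"]
        rng = np.random.default_rng(6)
        seqs = self._seqs(space, rng)
        codes = [space.code_detected(0), 0, 0, space.code_detected(0)]
        lm = sex_marginal_loglik(codes, 0, 1, lambda s: seqs[s],
                                 [0.5, 0.5], space)
        assert lm == pytest.approx(forward_loglik(codes, 0, *seqs[1], space))


@pytest.fixture(scope="module")
def small_dataset():
    from lynxmark.experiments import recovery_config
    from lynxmark.simulate import simulate_population
    sim = simulate_population(
        recovery_config(cohort_juveniles=6, cohort_subadults=3,
                        cohort_adults=6, n_extra_carcasses=20), seed=77)
    ds, _ = sim.to_dataset()
    return sim, ds


class TestDatasetLoglik:
    def test_vectorized_equals_reference_per_history(self, small_dataset):
        """The fitting-path likelihood agrees with the transparent
        per-history forward recursion for every individual."""
        sim, ds = small_dataset
        params, spec = sim.params, sim.spec
        lls = per_individual_loglik(ds, params, spec)
        for i in range(ds.n_individuals):
            if ds.sex[i] >= 0:
                T_seq, O_seq = history_matrices(params, spec, ds, i,
                                                int(ds.sex[i]))
                ref = forward_loglik(ds.codes[i], int(ds.first[i]), T_seq,
                                     O_seq, ds.space, int(ds.last[i]))
            else:
                parts = []
                for s in range(2):
                    T_seq, O_seq = history_matrices(params, spec, ds, i, s)
                    parts.append(forward_loglik(
                        ds.codes[i], int(ds.first[i]), T_seq, O_seq,
                        ds.space, int(ds.last[i])))
                ref = logsumexp(np.log(params.psi) + np.array(parts))
            assert lls[i] == pytest.approx(ref, abs=1e-9)

    def test_duplicated_dataset_doubles_loglik(self, small_dataset):
        sim, ds = small_dataset
        double = MultiStateDataset(
            ds.space, ds.grid, ds.ids + ds.ids,
            np.vstack([ds.codes, ds.codes]),
            np.concatenate([ds.first, ds.first]),
            np.concatenate([ds.last, ds.last]),
            np.vstack([ds.age, ds.age]),
            np.vstack([ds.telemetry, ds.telemetry]),
            np.concatenate([ds.sex, ds.sex]), ds.effort, ds.year_index)
        l1 = dataset_loglik(ds, sim.params, sim.spec)
        l2 = dataset_loglik(double, sim.params, sim.spec)
        assert l2 == pytest.approx(2 * l1, rel=1e-10)

    def test_total_additivity_and_empty_dataset(self, small_dataset):
        sim, ds = small_dataset
        lp_only = total_loglik(None, sim.params, sim.spec)
        from lynxmark.multistate import log_prior
        assert lp_only == pytest.approx(log_prior(sim.params, sim.spec))
        full = total_loglik(ds, sim.params, sim.spec,
                            age_records=sim.age_records)
        no_age = total_loglik(ds, sim.params, sim.spec)
        assert full < no_age  # age records only subtract log-probability

    def test_deterministic_repeated_calls(self, small_dataset):
        sim, ds = small_dataset
        a = dataset_loglik(ds, sim.params, sim.spec)
        b = dataset_loglik(ds, sim.params, sim.spec)
        assert a == b

    def test_unknown_sex_placeholder_invariance(self, small_dataset):
        """Relabeling the arbitrary sex placeholder of unknown-sex
        individuals leaves the likelihood unchanged (it is marginalized)."""
        sim, ds = small_dataset
        ll = dataset_loglik(ds, sim.params, sim.spec)
        flipped = MultiStateDataset(
            ds.space, ds.grid, ds.ids, ds.codes, ds.first, ds.last, ds.age,
            ds.telemetry, np.where(ds.sex < 0, -2, ds.sex).astype(np.int8),
            ds.effort, ds.year_index)
        assert dataset_loglik(flipped, sim.params, sim.spec) == \
            pytest.approx(ll, abs=1e-12)
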