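"""Synchronous spontaneous dynamics, fixed points, and attractor census."""

import itertools

import numpy as np
import pytest

from priornet import (
    CYCLE2,
    FIXED_POINT,
    PERIODIC,
    TuningConfig,
    classify_attractor,
    default_defect_cap,
    enumerate_attractors,
    find_fixed_point,
    internal_current,
    periodic_candidate_nus,
    probe_patterns,
    step_pattern,
    step_spontaneous,
)

SIG = TuningConfig()
PER = TuningConfig(PERIODIC)


def rank_one_sign_matrix(xi):
    """J_ij = xi_i xi_j off-diagonal: the fully trained matrix of one pattern."""
    J = np.outer(xi, xi).astype(np.int8)
    np.fill_diagonal(J, 0)
    return J


def prefix_pattern(N, k):
    return np.concatenate([np.ones(k, np.int8), -np.ones(N - k, np.int8)])


def brute_force_fixed_points(J):
    """Exhaustive fixed-point enumeration over all 2^N states."""
    N = J.shape[0]
    out = []
    for bits in itertools.product([-1, 1], repeat=N):
        x = np.array(bits, dtype=np.int8)
        if np.array_equal(step_spontaneous(J, x), x):
            out.append(x)
    return out


class TestInternalCurrent:
    def test_two_neuron_examples(self):
        J = np.array([[0, 1], [1, 0]])
        assert np.allclose(internal_current(J, np.array([1, 1])), [0.25, 0.25])
        assert np.allclose(internal_current(J, np.array([1, -1])), [-0.25, 0.25])

    def test_magnitude_bound(self, rng):
        N = 31
        J = rank_one_sign_matrix(prefix_pattern(N, 11))
        x = np.where(rng.random(N) < 0.5, 1, -1).astype(np.int8)
        assert np.all(np.abs(internal_current(J, x)) <= (N - 1) / (2 * N))

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="dimension|square"):
            internal_current(np.zeros((3, 3)), np.ones(4))


class TestStepDynamics:
    def test_mutual_excitation_fixed_point(self):
        J = np.array([[0, 1], [1, 0]])
        assert step_spontaneous(J, np.array([1, 1])).tolist() == [1, 1]

    def test_stored_pattern_is_fixed_point(self):
        xi = prefix_pattern(8, 3)
        J = rank_one_sign_matrix(xi)
        assert np.array_equal(step_spontaneous(J, xi), xi)

    def test_orthogonal_state_two_cycle(self):
        # xi . x = 0 leaves only the -x/2N self-term: x -> -x -> x
        xi = prefix_pattern(8, 4)
        x = np.array([1, -1, 1, -1, 1, -1, 1, -1], dtype=np.int8)
        assert xi @ x == 0
        J = rank_one_sign_matrix(xi)
        assert np.array_equal(step_spontaneous(J, x), -x)
        res = find_fixed_point(J, x)
        assert res.outcome == CYCLE2

    def test_basin_of_stored_pattern(self):
        # every Hamming-1 neighbour of xi falls back to xi (oracle:
        # direct iteration is itself checked against one-step algebra)
        xi = prefix_pattern(8, 3)
        J = rank_one_sign_matrix(xi)
        for i in range(8):
            x0 = xi.copy()
            x0[i] *= -1
            res = find_fixed_point(J, x0)
            assert res.outcome == FIXED_POINT
            assert np.array_equal(res.pattern, xi)

    def test_fixed_initial_state_detected_in_one_step(self):
        xi = prefix_pattern(8, 3)
        res = find_fixed_point(rank_one_sign_matrix(xi), xi)
        assert res.outcome == FIXED_POINT and res.steps == 1


class TestRetrievedPatterns:
    def test_step_pattern_examples(self):
        mu = np.array([0.125, 0.375, 0.625, 0.875])
        assert step_pattern(0.5, mu, SIG).tolist() == [1, 1, -1, -1]
        assert step_pattern(0.05, mu, SIG).tolist() == [-1, -1, -1, -1]
        assert step_pattern(0.95, mu, SIG).tolist() == [1, 1, 1, 1]
        assert step_pattern(0.625, mu, SIG)[2] == 1  # sign(0) = +1 tie-break

    def test_classify_conforming_midpoint(self):
        mu = np.array([0.125, 0.375, 0.625, 0.875])
        rec = classify_attractor(np.array([1, 1, -1, -1], np.int8), mu, SIG)
        assert rec.conforming and rec.defects == 0
        assert np.isclose(rec.nu, 0.5)

    def test_classify_boundary_interval(self):
        mu = np.array([0.125, 0.375, 0.625, 0.875])
        rec = classify_attractor(np.ones(4, np.int8), mu, SIG)
        assert rec.conforming and np.isclose(rec.nu, (0.875 + 1.0) / 2)
        rec = classify_attractor(-np.ones(4, np.int8), mu, SIG)
        assert rec.conforming and np.isclose(rec.nu, 0.125 / 2)

    def test_classify_non_step_pattern(self):
        mu = np.array([0.125, 0.375, 0.625, 0.875])
        rec = classify_attractor(np.array([1, -1, 1, -1], np.int8), mu, SIG)
        assert not rec.conforming
        assert rec.defects == 1
        assert rec.nu is not None

    def test_classify_labels_defective_state_with_nearest_nu(self):
        N = 100
        mu = (np.arange(1, N + 1) - 0.5) / N
        x = prefix_pattern(N, 40)
        x[37] = -1  # one interior defect near the boundary
        rec = classify_attractor(x, mu, SIG)
        assert not rec.conforming and rec.defects == 1
        assert abs(rec.nu - 0.40) < 0.02

    def test_periodic_classify_roundtrip(self, rng):
        mu = np.sort(rng.random(20))
        for nu in rng.random(5):
            pat = step_pattern(nu, mu, PER)
            rec = classify_attractor(pat, mu, PER)
            assert rec.conforming
            assert np.array_equal(step_pattern(rec.nu, mu, PER), pat)

    def test_periodic_candidates_cover_all_half_rings(self, rng):
        mu = np.sort(rng.random(12))
        pats = {step_pattern(nu, mu, PER).tobytes() for nu in periodic_candidate_nus(mu)}
        dense = {step_pattern(nu, mu, PER).tobytes() for nu in np.linspace(0, 1, 5000)}
        assert dense <= pats


class TestEnumeration:
    def test_probe_set_is_all_step_patterns(self):
        mu = (np.arange(1, 9) - 0.5) / 8
        X = probe_patterns(mu, SIG)
        assert X.shape == (8, 9)
        for k in range(9):
            assert np.array_equal(X[:, k], prefix_pattern(8, k))

    def test_single_trained_pattern_yields_single_attractor(self):
        N = 200
        mu = (np.arange(1, N + 1) - 0.5) / N
        xi = step_pattern(0.3, mu, SIG)
        J = rank_one_sign_matrix(xi)
        census = enumerate_attractors(J, mu, SIG)
        assert len(census.attractors) == 1
        rec = census.attractors[0]
        assert rec.conforming and abs(rec.nu - 0.3) < 1 / N
        # the sign-flip twin is stable but is not a retrieved pattern
        assert census.n_spurious == 1
        assert census.n_cycles >= 0

    def test_two_cycles_are_counted_not_recorded(self):
        xi = prefix_pattern(8, 4)
        J = rank_one_sign_matrix(xi)
        census = enumerate_attractors(J, (np.arange(1, 9) - 0.5) / 8, SIG)
        assert census.n_cycles >= 1
        assert all(rec.pattern @ xi != 0 for rec in census.attractors)

    def test_probing_is_pure_and_repeatable(self, rng):
        from priornet import init_network

        state = init_network(40, rng)
        j_bytes, mu_bytes = state.J.tobytes(), state.mu.tobytes()
        c1 = enumerate_attractors(state.J, state.mu, SIG)
        c2 = enumerate_attractors(state.J, state.mu, SIG)
        assert state.J.tobytes() == j_bytes and state.mu.tobytes() == mu_bytes
        assert [r.pattern.tobytes() for r in c1.attractors] == [
            r.pattern.tobytes() for r in c2.attractors
        ]

    @pytest.mark.parametrize("n", [5, 8, 10])
    def test_conforming_census_matches_exhaustive_enumeration(self, n):
        # oracle: all 2^N states, keep fixed points, intersect with the
        # exactly-conforming (step) patterns; 100 random symmetric J at n=8
        mu = (np.arange(1, n + 1) - 0.5) / n
        n_matrices = 100 if n == 8 else 20
        rng = np.random.default_rng(n)
        steps = {prefix_pattern(n, k).tobytes() for k in range(n + 1)}
        for _ in range(n_matrices):
            J = np.triu(np.where(rng.random((n, n)) < 0.5, 1, -1), k=1).astype(np.int8)
            J = J + J.T
            oracle = {
                x.tobytes() for x in brute_force_fixed_points(J) if x.tobytes() in steps
            }
            census = enumerate_attractors(J, mu, SIG, max_defects=0)
            found = {r.pattern.tobytes() for r in census.attractors if r.conforming}
            assert found == oracle

    def test_every_reported_attractor_is_self_consistent(self, rng):
        from priornet import init_network

        state = init_network(60, rng)
        census = enumerate_attractors(state.J, state.mu, SIG)
        for rec in census.attractors:
            assert np.array_equal(step_spontaneous(state.J, rec.pattern), rec.pattern)


def test_defect_cap_grows_like_sqrt_n():
    assert default_defect_cap(100) == 20
    assert default_defect_cap(1000) == 64
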