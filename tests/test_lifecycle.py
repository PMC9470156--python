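"""Projection-matrix assembly, eigen-analysis and the fitness measures.

The anchor example throughout is the two-class cycle with
A = [[0.5, 1.0], [0.2, 0.6]], whose dominant eigenvalue is exactly 1
(closed-form 2x2 quadratic), so F = f3 = 0 while f1 = ln 1.2 and
f2 = ln 0.7 — three distinct particle-fitness values on one organism.
"""

import numpy as np
import pytest

import etidyn as e
from etidyn.lifecycle import DegenerateSpectrumError, InvalidParameterError

from conftest import random_primitive_lifecycle


@pytest.mark.parametrize(
    "N, rule, expected",
    [
        (3, "doubling", [1, 2, 4]),
        (1, "doubling", [1]),
        (5, "linear", [1, 2, 3, 4, 5]),
    ],
)
def test_default_k(N, rule, expected):
    assert np.array_equal(e.default_k(N, rule), expected)


def test_default_k_rejects_empty():
    with pytest.raises(InvalidParameterError):
        e.default_k(0)


class TestProjectionMatrix:
    def test_single_class_staying_plus_propagules(self):
        lc = e.LifeCycle(gamma=[0.0], mu=[0.0], delta=[0.5], beta=[1.5])
        assert np.allclose(e.build_projection_matrix(lc), [[2.0]])

    def test_two_class_hand_assembly(self, n2_lifecycle):
        # alpha = (0.3, 0.6); row 1 gets beta everywhere plus mu_2
        A = e.build_projection_matrix(n2_lifecycle)
        assert np.allclose(A, [[0.5, 1.0], [0.2, 0.6]])

    def test_no_events_gives_identity(self):
        lc = e.LifeCycle(gamma=[0, 0, 0], mu=[0, 0, 0], delta=[0, 0, 0], beta=[0, 0, 0])
        assert np.array_equal(e.build_projection_matrix(lc), np.eye(3))

    def test_rate_sum_validation_names_class(self):
        with pytest.raises(InvalidParameterError, match="class 2"):
            e.LifeCycle(gamma=[0.2, 0.0], mu=[0.0, 0.5], delta=[0.1, 0.6], beta=[0, 0])

    def test_structural_invariants_enforced(self):
        with pytest.raises(InvalidParameterError):  # gamma_N != 0
            e.LifeCycle(gamma=[0.1, 0.1], mu=[0, 0], delta=[0, 0], beta=[0, 0])
        with pytest.raises(InvalidParameterError):  # mu_1 != 0
            e.LifeCycle(gamma=[0.1, 0.0], mu=[0.1, 0], delta=[0, 0], beta=[0, 0])
        with pytest.raises(InvalidParameterError):  # k not increasing
            e.LifeCycle(gamma=[0.1, 0.0], mu=[0, 0], delta=[0, 0], beta=[0, 0], k=[2, 2])


class TestDominantEigenpair:
    def test_symmetric_rank_one(self):
        res = e.dominant_eigenpair(np.ones((2, 2)))
        assert res.lam == pytest.approx(2.0, rel=1e-12)
        assert np.allclose(res.w, [0.5, 0.5])

    def test_two_by_two_closed_form(self, n2_lifecycle):
        A = e.build_projection_matrix(n2_lifecycle)
        a, b, c, d = A[0, 0], A[0, 1], A[1, 0], A[1, 1]
        lam_exact = ((a + d) + np.sqrt((a - d) ** 2 + 4 * b * c)) / 2
        res = e.dominant_eigenpair(A)
        assert res.lam == pytest.approx(lam_exact, rel=1e-12)
        assert lam_exact == pytest.approx(1.0)

    def test_matches_dense_solver_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            A = rng.uniform(0.05, 1.0, (5, 5))  # strictly positive: primitive
            res = e.dominant_eigenpair(A)
            vals, vecs = np.linalg.eig(A)
            i = np.argmax(np.abs(vals))
            w = np.abs(np.real(vecs[:, i]))
            assert res.lam == pytest.approx(float(np.real(vals[i])), rel=1e-10)
            assert np.allclose(res.w, w / w.sum(), atol=1e-10)

    def test_eigen_residual_invariant(self, n2_lifecycle):
        A = e.build_projection_matrix(n2_lifecycle)
        res = e.dominant_eigenpair(A, tol=1e-12)
        assert np.max(np.abs(A @ res.w - res.lam * res.w)) <= 1e-10 * res.lam

    def test_zero_matrix_rejected(self):
        with pytest.raises(DegenerateSpectrumError):
            e.dominant_eigenpair(np.zeros((3, 3)))


class TestPrimitivity:
    def test_sufficient_condition_implies_primitive(self):
        rng = np.random.default_rng(7)
        for N in (2, 5, 8):
            lc = random_primitive_lifecycle(rng, N)
            assert e.check_primitive(e.build_projection_matrix(lc))

    def test_identity_not_primitive(self):
        assert not e.check_primitive(np.eye(3))

    def test_periodic_not_primitive(self):
        assert not e.check_primitive(np.array([[0.0, 1.0], [1.0, 0.0]]))


class TestCollectiveFitness:
    def test_scalar_case(self):
        lc = e.LifeCycle(gamma=[0.0], mu=[0.0], delta=[0.5], beta=[1.5])
        assert e.collective_fitness(lc, warn_nonprimitive=False) == pytest.approx(np.log(2))

    def test_two_class_zero_growth_rate(self, n2_lifecycle):
        assert e.collective_fitness(n2_lifecycle) == pytest.approx(0.0, abs=1e-12)

    def test_scaling_beta_by_e_is_not_additive_in_F(self, n2_lifecycle):
        # fecundity enters lambda through the characteristic polynomial,
        # not multiplicatively, so F(e*beta) != F(beta) + 1 in general
        lc2 = e.LifeCycle(
            gamma=n2_lifecycle.gamma, mu=n2_lifecycle.mu,
            delta=n2_lifecycle.delta, beta=np.e * np.asarray(n2_lifecycle.beta),
        )
        shift = e.collective_fitness(lc2) - e.collective_fitness(n2_lifecycle)
        assert abs(shift - 1.0) > 0.05


class TestSimulate:
    def test_identity_cycle_is_stationary(self):
        lc = e.LifeCycle(gamma=[0, 0], mu=[0, 0], delta=[0, 0], beta=[0, 0])
        traj = e.simulate(lc, [2.0, 3.0], 10)
        assert np.all(traj.c == [2.0, 3.0])
        assert np.all(traj.n == 2.0 * 1 + 3.0 * 2)

    def test_matches_matrix_power(self, n2_lifecycle):
        A = e.build_projection_matrix(n2_lifecycle)
        traj = e.simulate(n2_lifecycle, [1.0, 0.0], 50)
        expected = np.linalg.matrix_power(A, 50) @ np.array([1.0, 0.0])
        assert np.allclose(traj.c[-1], expected, rtol=1e-12)
        assert np.all(traj.c >= 0)

    def test_structure_converges_to_stable_distribution(self, n2_lifecycle):
        A = e.build_projection_matrix(n2_lifecycle)
        w = e.dominant_eigenpair(A).w
        traj = e.simulate(n2_lifecycle, [1.0, 0.0], 200)
        structure = traj.c[-1] / traj.c[-1].sum()
        assert np.abs(structure - w).sum() < 1e-10

    def test_invalid_inputs(self, n2_lifecycle):
        with pytest.raises(InvalidParameterError):
            e.simulate(n2_lifecycle, [1.0, 0.0], -1)
        with pytest.raises(InvalidParameterError):
            e.simulate(n2_lifecycle, [0.0, 0.0], 5)


class TestParticleFitnessF1:
    def test_no_events_zero(self):
        assert e.particle_fitness_f1(mu1=0.0, gamma1=0.0, k2=2) == 0.0

    def test_printed_form(self):
        assert e.particle_fitness_f1(mu1=0.0, gamma1=0.2, k2=2) == pytest.approx(np.log(1.2))

    def test_branching_oracle(self):
        """The class-1 lineage is a Bienaymé-Galton-Watson process; a
        Monte-Carlo estimate of its growth rate matches the log-mean-
        offspring form, which differs from the printed closed form by
        O(mu1*gamma1)."""
        mu1, gamma1, k2 = 0.2, 0.3, 2
        rng = np.random.default_rng(11)
        # MC: average offspring over many lineage draws
        draws = rng.choice(
            [0, 1, k2],
            p=[mu1, (1 - mu1) * (1 - gamma1), (1 - mu1) * gamma1],
            size=400_000,
        )
        mc_rate = np.log(draws.mean())
        bgw = e.f1_branching(mu1, gamma1, k2)
        printed = e.particle_fitness_f1(mu1=mu1, gamma1=gamma1, k2=k2)
        assert mc_rate == pytest.approx(bgw, abs=2e-3)
        # the gap between conventions is O(mu1*gamma1), small but nonzero
        assert 0 < abs(bgw - printed) < mu1 * gamma1

    def test_f1_independent_of_delta_and_beta(self, n2_lifecycle):
        lc2 = e.LifeCycle(
            gamma=n2_lifecycle.gamma, mu=n2_lifecycle.mu,
            delta=[0.1, 0.1], beta=[2.0, 2.0],
        )
        assert e.particle_fitness_f1(lc2) == e.particle_fitness_f1(n2_lifecycle)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            e.particle_fitness_f1(mu1=1.0, gamma1=0.0, k2=2)


class TestParticleFitnessF2:
    def test_no_events_zero(self):
        lc = e.LifeCycle(gamma=[0, 0], mu=[0, 0], delta=[0, 0.2], beta=[0, 0.5])
        assert e.particle_fitness_f2(lc) == 0.0

    def test_printed_form(self, n2_lifecycle):
        assert e.particle_fitness_f2(n2_lifecycle) == pytest.approx(np.log(0.7))

    def test_independent_of_gamma(self, n2_lifecycle):
        lc2 = e.LifeCycle(
            gamma=[0.45, 0.0], mu=n2_lifecycle.mu,
            delta=n2_lifecycle.delta, beta=n2_lifecycle.beta,
        )
        assert e.particle_fitness_f2(lc2) == e.particle_fitness_f2(n2_lifecycle)


class TestParticleFitnessF3:
    def test_two_class_zero_by_both_methods(self, n2_lifecycle):
        assert e.particle_fitness_f3(n2_lifecycle, "eigen") == pytest.approx(0.0, abs=1e-12)
        assert e.particle_fitness_f3(n2_lifecycle, "trajectory") == pytest.approx(0.0, abs=1e-9)

    def test_scalar_case(self):
        lc = e.LifeCycle(gamma=[0.0], mu=[0.0], delta=[0.5], beta=[1.5])
        assert e.particle_fitness_f3(lc, "eigen") == pytest.approx(np.log(2))

    def test_trajectory_agrees_with_eigenvalue(self):
        """f3 counts every event in the particle lineage, and the particle
        count n(t) grows asymptotically at the collective rate lambda —
        the identity f3 = ln(lambda) = F, here on random primitive
        cycles with the trajectory-slope estimator."""
        rng = np.random.default_rng(3)
        for _ in range(25):
            N = int(rng.integers(2, 11))
            lc = random_primitive_lifecycle(rng, N)
            f3_traj = e.particle_fitness_f3(lc, method="trajectory")
            f3_eig = e.particle_fitness_f3(lc, method="eigen")
            assert f3_traj == pytest.approx(f3_eig, abs=1e-6)


class TestFitnessReport:
    def test_three_distinct_measures(self, n2_lifecycle):
        rep = e.fitness_report(n2_lifecycle)
        assert rep.F == pytest.approx(0.0, abs=1e-12)
        assert rep.f1 == pytest.approx(np.log(1.2))
        assert rep.f2 == pytest.approx(np.log(0.7))
        assert rep.f3 == pytest.approx(rep.F, abs=1e-9)
        assert rep.measures_differ

    def test_no_event_cycle_rejected(self):
        lc = e.LifeCycle(gamma=[0, 0], mu=[0, 0], delta=[0, 0], beta=[0, 0])
        with pytest.raises(InvalidParameterError, match="primitive"):
            e.fitness_report(lc)

    def test_f3_equals_F_on_random_cycles(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            lc = random_primitive_lifecycle(rng, int(rng.integers(2, 8)))
            rep = e.fitness_report(lc)
            assert rep.f3 == pytest.approx(rep.F, abs=1e-9)


class TestFitnessIdentityProperty:
    """Property-based sweep of the f3 = ln(lambda) = F identity and the
    Perron structure over arbitrary valid primitive life cycles."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    def _lifecycle_from_draw(N, raw):
        raw = np.asarray(raw[: 4 * N]).reshape(4, N)
        # map unit draws into rates obeying the sufficient primitivity
        # condition: each of gamma/mu/delta in [0.02, 0.3], beta > 0
        gamma, mu, delta, beta = 0.02 + 0.28 * raw
        gamma[-1] = 0.0
        mu[0] = 0.0
        return e.LifeCycle(gamma=gamma, mu=mu, delta=delta, beta=0.1 + beta)

    @given(
        N=st.integers(2, 8),
        raw=st.lists(st.floats(0, 1, allow_nan=False), min_size=32, max_size=32),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_identity_and_perron_structure(self, N, raw):
        lc = self._lifecycle_from_draw(N, raw)
        A = e.build_projection_matrix(lc)
        assert e.check_primitive(A)
        res = e.dominant_eigenpair(A)
        assert res.lam > 0
        assert np.all(res.w > 0)  # Perron vector strictly positive
        assert res.w.sum() == pytest.approx(1.0, abs=1e-12)
        f3 = e.particle_fitness_f3(lc, method="trajectory", T=1000)
        assert f3 == pytest.approx(np.log(res.lam), abs=1e-6)


def test_collective_trajectory_frame(n2_lifecycle):
    frame = e.simulate(n2_lifecycle, [1.0, 0.0], 5).to_frame()
    assert list(frame.columns) == ["t", "c_1", "c_2", "n"]
    assert np.allclose(frame["n"], frame["c_1"] + 2 * frame["c_2"])


def test_lifecycle_json_round_trip(n2_lifecycle):
    d = n2_lifecycle.to_dict()
    lc2 = e.LifeCycle.from_dict(d)
    assert np.array_equal(lc2.gamma, n2_lifecycle.gamma)
    assert np.array_equal(lc2.k, n2_lifecycle.k)
    lc3 = e.LifeCycle.from_dict(
        {"N": 3, "gamma": [0.1, 0.1, 0], "mu": [0, 0, 0], "delta": [0.2, 0.2, 0.2],
         "beta": [0.5, 0.5, 0.5], "k": {"rule": "doubling"}}
    )
    assert np.array_equal(lc3.k, [1, 2, 4])
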