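"""Minimum control energy: closed forms, discretised oracle, aggregation."""

import numpy as np
import pytest
from scipy.linalg import expm

from statenergy.dynamics import StateSequence
from statenergy.energy import (NetworkControlModel, build_control_system,
                               controllability_gramian, energy_transition_matrix,
                               framewise_energy, min_control_energy,
                               normalize_adjacency, summarize_energy,
                               zscore_vs_controls)
from statenergy.exceptions import DegenerateInputError, InvalidParameterError


def random_connectome(n, rng):
    W = np.abs(rng.standard_normal((n, n)))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    return W


def euler_min_energy(A, T, x0, xf, n_steps=1000):
    """Discretised least-squares optimal-control oracle.

    Forward-Euler discretisation x_{t+1} = x_t + dt (A x_t + u_t); the
    minimum-norm input reaching xf gives energy dt * sum ||u_t||^2 =
    v' W_d^{-1} v / dt with W_d = sum_i A_d^i A_d'^i, A_d = I + dt A.
    """
    n = A.shape[0]
    dt = T / n_steps
    Ad = np.eye(n) + dt * A
    W_d = np.zeros((n, n))
    M = np.eye(n)
    for _ in range(n_steps):
        W_d += M @ M.T
        M = Ad @ M
    v = xf - M @ x0                      # M = Ad^n_steps after the loop
    return float(v @ np.linalg.solve(W_d, v)) / dt


class TestNormalizeAdjacency:
    def test_two_node_closed_form(self):
        A = normalize_adjacency(np.array([[0.0, 1.0], [1.0, 0.0]]), c=1.0)
        np.testing.assert_allclose(A, [[-1.0, 0.5], [0.5, -1.0]])
        np.testing.assert_allclose(np.linalg.eigvalsh(A), [-1.5, -0.5])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_spectrum_stable_in_range(self, seed):
        rng = np.random.default_rng(seed)
        W = random_connectome(8, rng)
        for scale in (1.0, 0.1, 25.0):
            eig = np.linalg.eigvalsh(normalize_adjacency(scale * W))
            assert eig.max() < 0
            assert eig.min() >= -2.0

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            normalize_adjacency(np.zeros((4, 4)))


class TestMinControlEnergy:
    def test_scalar_closed_form(self):
        """A = -1, T = 1: W_T = (1 - e^-2)/2, Emin(0 -> 1) = 1/W_T."""
        A = np.array([[-1.0]])
        gram = controllability_gramian(A, 1.0)
        assert gram[0, 0] == pytest.approx((1 - np.exp(-2)) / 2, abs=1e-12)
        from statenergy.energy import ControlSystem
        sys = ControlSystem(A=A, horizon=1.0, gramian=gram, expm_AT=expm(A),
                            condition_number=1.0)
        total = min_control_energy(sys, [0.0], [1.0])
        assert total == pytest.approx(2 / (1 - np.exp(-2)), rel=1e-10)

    def test_zero_on_natural_trajectory(self, rng):
        sys = build_control_system(random_connectome(6, rng))
        x0 = rng.standard_normal(6)
        assert min_control_energy(sys, x0, sys.expm_AT @ x0) == pytest.approx(0.0, abs=1e-18)

    def test_matches_discretised_oracle(self):
        """Closed-form Gramian energy vs 1000-step Euler least squares."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(2, 11))
            sys = build_control_system(random_connectome(n, rng))
            x0 = rng.standard_normal(n)
            xf = rng.standard_normal(n)
            exact = min_control_energy(sys, x0, xf)
            approx = euler_min_energy(sys.A, 1.0, x0, xf)
            assert approx == pytest.approx(exact, rel=5e-3)

    def test_regional_decomposition_sums_to_total(self, rng):
        sys = build_control_system(random_connectome(7, rng))
        total, regional = min_control_energy(sys, rng.standard_normal(7),
                                             rng.standard_normal(7),
                                             return_regional=True)
        assert regional.shape == (7,)
        assert np.all(regional >= 0)
        assert regional.sum() == pytest.approx(total, rel=1e-8)


class TestFramewiseEnergy:
    def test_count_and_nonnegativity(self, rng):
        sys = build_control_system(random_connectome(5, rng))
        z = rng.standard_normal((200, 5))
        e = framewise_energy(z, sys)
        assert e.shape == (199,)
        assert np.all(e >= 0)

    def test_staying_put_costs_energy(self, rng):
        sys = build_control_system(random_connectome(5, rng))
        x = rng.standard_normal(5)
        e = framewise_energy(np.vstack([x, x]), sys)
        assert e[0] > 0

    def test_quadratic_homogeneity(self, rng):
        sys = build_control_system(random_connectome(5, rng))
        z = rng.standard_normal((3, 5))
        e1 = framewise_energy(z, sys)
        e2 = framewise_energy(2 * z, sys)
        np.testing.assert_allclose(e2, 4 * e1, rtol=1e-10)

    def test_region_mismatch_rejected(self, rng):
        sys = build_control_system(random_connectome(5, rng))
        with pytest.raises(InvalidParameterError):
            framewise_energy(rng.standard_normal((10, 6)), sys)

    def test_estimator_wrapper(self, rng):
        W = random_connectome(5, rng)
        z = rng.standard_normal((20, 5))
        model = NetworkControlModel(horizon=2.0).fit(W)
        np.testing.assert_allclose(
            model.transform(z),
            framewise_energy(z, build_control_system(W, horizon=2.0)))
        assert model.get_params()["horizon"] == 2.0


class TestEnergyTransitionMatrix:
    def test_direct_assignment(self):
        s = StateSequence("s", np.array([1, 1, 2]), k=2)
        m = energy_transition_matrix([5.0, 7.0], s)
        assert m[0, 0] == 5.0 and m[0, 1] == 7.0
        assert np.isnan(m[1, 0]) and np.isnan(m[1, 1])

    def test_repeated_transitions_averaged(self):
        s = StateSequence("s", np.array([1, 2, 1, 2]), k=2)
        m = energy_transition_matrix([4.0, 1.0, 6.0], s)
        assert m[0, 1] == pytest.approx(5.0)

    def test_single_visited_state(self):
        s = StateSequence("s", np.array([1] * 10), k=4)
        m = energy_transition_matrix(np.ones(9), s)
        assert m[0, 0] == 1.0
        assert np.isnan(np.delete(m.ravel(), 0)).all()


class TestZscoreVsControls:
    def test_at_hc_mean_is_zero(self):
        mats = {"h1": np.array([[1.0]]), "h2": np.array([[2.0]]),
                "h3": np.array([[3.0]]), "p": np.array([[2.0]])}
        z = zscore_vs_controls(mats, ["h1", "h2", "h3"])
        assert z["p"][0, 0] == pytest.approx(0.0)

    def test_two_point_sample_sd(self):
        mats = {"h1": np.array([[1.0]]), "h2": np.array([[3.0]]),
                "p": np.array([[3.0]])}
        z = zscore_vs_controls(mats, ["h1", "h2"])
        assert z["p"][0, 0] == pytest.approx(1 / np.sqrt(2))

    def test_hc_self_reference(self, rng):
        mats = {f"h{i}": rng.random((3, 3)) for i in range(10)}
        z = zscore_vs_controls(mats, list(mats))
        stack = np.stack(list(z.values()))
        np.testing.assert_allclose(stack.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(stack.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_degenerate_hc_cell_flagged(self):
        mats = {"h1": np.array([[1.0]]), "h2": np.array([[1.0]]),
                "p": np.array([[5.0]])}
        with pytest.warns(UserWarning, match="HC"):
            z = zscore_vs_controls(mats, ["h1", "h2"])
        assert np.isnan(z["p"][0, 0])


class TestSummarizeEnergy:
    def test_full_matrix(self):
        s = summarize_energy(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert (s.total, s.persistence, s.transition) == (2.5, 2.5, 2.5)

    def test_missing_cells(self):
        s = summarize_energy(np.array([[1.0, np.nan], [np.nan, 3.0]]))
        assert s.total == 2.0 and s.persistence == 2.0
        assert np.isnan(s.transition)

    def test_all_missing_rejected(self):
        with pytest.raises(DegenerateInputError):
            summarize_energy(np.full((2, 2), np.nan))
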