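"""Low-rank network representation and simulation."""

import numpy as np
import pytest
from hypothesis import given, strategies as hst

import latentloop as ll
from latentloop.network import InputSpec, LowRankNetwork, transfer, transfer_gain


def _random_net(rng, N=12, P=3, rmax_const=None):
    X = rng.standard_normal((N, P))
    U, R = np.linalg.qr(X)
    U *= np.sign(np.diag(R))
    A = 0.04 * rng.standard_normal((P, P))
    rmax = (
        np.full(N, rmax_const)
        if rmax_const
        else rng.uniform(10, 50, N)
    )
    return LowRankNetwork(U=U, A=A, rmax=rmax, n_coding=min(3, P))


class TestTransfer:
    def test_zero_input_gives_half_max(self):
        rmax = np.array([10.0, 40.0])
        assert np.allclose(transfer(0.0, rmax), rmax / 2)

    def test_saturates_at_rmax(self):
        assert np.isclose(transfer(30.0, 20.0), 20.0)
        assert transfer(5.0, 20.0) < 20.0

    @pytest.mark.parametrize("x", [-3.0, -0.5, 0.0, 1.2])
    def test_odd_symmetry_about_half_max(self, x):
        rmax = 28.0
        assert np.isclose(transfer(x, rmax) + transfer(-x, rmax), rmax)

    def test_gain_matches_numeric_derivative(self):
        x = np.linspace(-2, 2, 9)
        num = (transfer(x + 1e-6, 30.0) - transfer(x - 1e-6, 30.0)) / 2e-6
        assert np.allclose(transfer_gain(x, 30.0), num, atol=1e-5)


class TestConnectivity:
    def test_zero_interaction_gives_zero_matrix(self, rng):
        U = np.linalg.qr(rng.standard_normal((8, 2)))[0]
        assert np.all(ll.build_connectivity(U, np.zeros((2, 2))) == 0)

    def test_rank_one_outer_product(self, rng):
        u = rng.standard_normal((6, 1))
        u /= np.linalg.norm(u)
        J = ll.build_connectivity(u, np.array([[2.5]]))
        assert np.allclose(J, 2.5 * np.outer(u, u))
        assert np.linalg.matrix_rank(J) == 1

    def test_triple_sum_oracle(self, rng):
        N, P = 10, 3
        U = rng.standard_normal((N, P))
        A = rng.standard_normal((P, P))
        J = ll.build_connectivity(U, A)
        expected = np.zeros((N, N))
        for i in range(N):
            for j in range(N):
                for l in range(P):
                    for lp in range(P):
                        expected[i, j] += A[l, lp] * U[i, l] * U[j, lp]
        assert np.allclose(J, expected, atol=1e-12)

    def test_rank_bounded_by_latent_dim(self, rng):
        for _ in range(5):
            U = rng.standard_normal((15, 4))
            A = rng.standard_normal((4, 4))
            assert np.linalg.matrix_rank(ll.build_connectivity(U, A)) <= 4

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="shape"):
            ll.build_connectivity(rng.standard_normal((5, 2)), np.eye(3))


class TestTaskInput:
    def _spec(self, P=3):
        I = np.zeros(P)
        low, high, go = I.copy(), I.copy(), I.copy()
        low[0], high[0], go[-1] = -1.0, 1.0, 2.0
        return InputSpec(low, high, go)

    def test_zero_during_delay(self, rng):
        U = np.linalg.qr(rng.standard_normal((7, 3)))[0]
        assert np.all(ll.task_input(-1.0, "left", self._spec(), U) == 0)

    def test_tone_window_routes_condition_input(self, rng):
        U = np.linalg.qr(rng.standard_normal((7, 3)))[0]
        spec = self._spec()
        assert np.allclose(ll.task_input(-1.75, "left", spec, U), U @ spec.I_low)
        assert np.allclose(ll.task_input(-1.5, "right", spec, U), U @ spec.I_high)

    def test_go_window(self, rng):
        U = np.linalg.qr(rng.standard_normal((7, 3)))[0]
        spec = self._spec()
        assert np.allclose(ll.task_input(0.05, "left", spec, U), U @ spec.I_go)
        # half-open window: the go input is off at exactly 0.1
        assert np.all(ll.task_input(0.1, "left", spec, U) == 0)

    def test_unknown_condition_raises(self, rng):
        U = np.linalg.qr(rng.standard_normal((7, 3)))[0]
        with pytest.raises(ValueError, match="condition"):
            ll.task_input(0.0, "up", self._spec(), U)


class TestSimulate:
    def test_zero_input_relaxes_to_half_max(self, rng):
        net = _random_net(rng)
        net = LowRankNetwork(U=net.U, A=np.zeros_like(net.A), rmax=net.rmax,
                             n_coding=net.n_coding)
        traj = ll.simulate(net, InputSpec.zeros(3), "left", span=(-0.5, 0.0),
                           initial_state=np.zeros(net.n_neurons))
        assert np.allclose(traj.rates[-1], net.rmax / 2, rtol=1e-4)

    def test_constant_input_steady_state(self, rng):
        # A = 0 and constant input I: the fixed point is r = phi(I); the
        # exponential approach leaves < 1e-4 relative error after 10 tau
        N, P = 10, 2
        U = np.linalg.qr(rng.standard_normal((N, P)))[0]
        rmax = rng.uniform(20, 40, N)
        net = LowRankNetwork(U=U, A=np.zeros((P, P)), rmax=rmax, n_coding=1)
        I_go = np.array([0.7, -0.3])
        spec = InputSpec(np.zeros(P), np.zeros(P), I_go, go_window=(0.0, 10.0))
        traj = ll.simulate(net, spec, "left", span=(0.0, 10 * net.tau), dt=0.002)
        expected = transfer(U @ I_go, rmax)
        assert np.allclose(traj.rates[-1], expected, rtol=1e-4)

    def test_matches_dense_oracle(self, rng):
        net = _random_net(rng, N=12, P=3)
        spec = InputSpec(*(0.3 * rng.standard_normal((3, 3))))
        traj = ll.simulate(net, spec, "right", span=(-2.0, 0.2), dt=0.005)
        # independent dense integration with explicitly materialized J
        J = net.U @ net.A @ net.U.T
        r = net.rmax / 2
        dense = [r]
        for t in traj.time[:-1]:
            I = ll.task_input(t, "right", spec, net.U)
            r = r + 0.005 / net.tau * (-r + transfer(J @ r + I, net.rmax))
            dense.append(r)
        assert np.max(np.abs(traj.rates - np.array(dense))) < 1e-8

    def test_rates_bounded_by_rmax(self, small_gt):
        traj = ll.simulate(small_gt.network, small_gt.spec, "right")
        assert traj.rates.min() >= 0.0
        assert traj.rates.max() <= small_gt.network.rmax.max() + 1e-9

    def test_grid_refinement_first_order(self, rng):
        net = _random_net(rng)
        spec = InputSpec(*(0.2 * rng.standard_normal((3, 3))))
        ends = {}
        for dt in (0.008, 0.004, 0.002):
            ends[dt] = ll.simulate(net, spec, "left", span=(-2.0, 0.1),
                                   dt=dt).rates[-1]
        e1 = np.linalg.norm(ends[0.008] - ends[0.002])
        e2 = np.linalg.norm(ends[0.004] - ends[0.002])
        assert e2 < e1  # halving dt shrinks the error

    def test_coarse_dt_rejected(self, rng):
        net = _random_net(rng)
        with pytest.raises(ValueError, match="dt"):
            ll.simulate(net, InputSpec.zeros(3), "left", dt=net.tau)

    def test_rk4_close_to_euler(self, rng):
        net = _random_net(rng)
        spec = InputSpec(*(0.2 * rng.standard_normal((3, 3))))
        e = ll.simulate(net, spec, "left", span=(-2.0, 0.0), dt=0.002)
        r = ll.simulate(net, spec, "left", span=(-2.0, 0.0), dt=0.002,
                        method="rk4")
        assert np.max(np.abs(e.rates - r.rates)) < 0.5


class TestLatentReduction:
    def test_projection_of_aligned_state(self, rng):
        U = np.linalg.qr(rng.standard_normal((9, 3)))[0]
        r = 4.0 * U[:, 0]
        traj = ll.Trajectory(time=np.zeros(1), rates=r[None, :])
        m = ll.project_latent(traj, U).m[0]
        assert np.allclose(m, [4.0, 0.0, 0.0], atol=1e-12)

    def test_projection_of_orthogonal_state(self, rng):
        U, _ = np.linalg.qr(rng.standard_normal((9, 4)))
        r = U[:, 3]  # orthogonal to the first three columns
        traj = ll.Trajectory(time=np.zeros(1), rates=r[None, :])
        assert np.allclose(ll.project_latent(traj, U[:, :3]).m, 0.0, atol=1e-12)

    def test_latent_ode_matches_projected_full_simulation(self, small_gt):
        # the latent dynamics are exactly closed: Euler agrees step for step
        net, spec = small_gt.network, small_gt.spec
        full = ll.simulate(net, spec, "right", span=(-2.2, 0.2), dt=0.005)
        lat = ll.simulate_latent(net, spec, "right", span=(-2.2, 0.2), dt=0.005)
        assert np.max(np.abs(full.rates @ net.U - lat.m)) < 1e-6


class TestValidation:
    def test_dimension_preconditions(self, rng):
        U = np.linalg.qr(rng.standard_normal((5, 3)))[0]
        with pytest.raises(ValueError):
            LowRankNetwork(U=U, A=np.zeros((3, 3)), rmax=-np.ones(5))
        with pytest.raises(ValueError):
            LowRankNetwork(U=U, A=np.zeros((2, 2)), rmax=np.ones(5))

    @given(hst.integers(min_value=1, max_value=4))
    def test_orthonormality_defect_zero_for_qr_basis(self, P):
        rng = np.random.default_rng(P)
        U = np.linalg.qr(rng.standard_normal((8, P)))[0]
        net = LowRankNetwork(U=U, A=np.zeros((P, P)), rmax=np.ones(8),
                             n_coding=1)
        assert net.orthonormality_defect() < 1e-10
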