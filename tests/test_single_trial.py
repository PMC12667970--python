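"""Single-trial input biases, error axes, and interpolation."""


import numpy as np
import pytest

import latentloop as ll
from latentloop.fitting import OptimizerConfig
from latentloop.single_trial import (
    TrialBias,
    epoch_average_loss,
    estimate_error_axis,
    fit_test_trial_biases,
    interpolate_error_axis,
    jittered_start,
    projection_loss,
    train_single_trial,
    trial_bias_input,
)
from latentloop.synthetic import condition_average


class TestTrialBiasInput:
    def test_zero_column_zero_input(self, rng):
        U = np.linalg.qr(rng.standard_normal((8, 3)))[0]
        T = np.zeros((3, 5))
        assert np.all(trial_bias_input(T, 2, U) == 0)

    def test_unit_column_selects_basis_column(self, rng):
        U = np.linalg.qr(rng.standard_normal((8, 3)))[0]
        T = np.zeros((3, 4))
        T[0, 1] = 1.0
        assert np.allclose(trial_bias_input(T, 1, U), U[:, 0])

    def test_double_sum_oracle(self, rng):
        U = rng.standard_normal((6, 4))
        T = rng.standard_normal((4, 3))
        out = trial_bias_input(T, 2, U)
        expected = np.array(
            [sum(U[i, l] * T[l, 2] for l in range(4)) for i in range(6)]
        )
        assert np.allclose(out, expected)

    def test_index_out_of_range(self, rng):
        U = np.eye(4)[:, :2]
        with pytest.raises(IndexError):
            trial_bias_input(np.zeros((2, 3)), 3, U)


class TestEpochLoss:
    def _setup(self, rng, K=4, T=50, N=3):
        time = np.linspace(-2.5, 0.4, T, endpoint=False)
        epochs = {"a": (-2.5, -1.0), "b": (-1.0, 0.4)}
        data = rng.standard_normal((K, T, N))
        return time, epochs, data

    def test_identical_tensors_zero(self, rng):
        time, epochs, data = self._setup(rng)
        assert epoch_average_loss(data, data, time, epochs) == 0.0

    def test_constant_offset_closed_form(self, rng):
        time, epochs, data = self._setup(rng, K=5, N=4)
        delta = 0.7
        loss = epoch_average_loss(data + delta, data, time, epochs)
        assert np.isclose(loss, len(epochs) * 5 * 4 * delta**2)

    def test_invariant_to_time_permutation_within_epoch(self, rng):
        time, epochs, data = self._setup(rng)
        model = data + rng.standard_normal(data.shape)
        mask = (time >= -1.0) & (time < 0.4)
        idx = np.flatnonzero(mask)
        perm = idx[rng.permutation(idx.size)]
        shuffled = model.copy()
        shuffled[:, idx] = model[:, perm]
        a = epoch_average_loss(model, data, time, epochs)
        b = epoch_average_loss(shuffled, data, time, epochs)
        assert np.isclose(a, b)

    def test_empty_epoch_rejected(self, rng):
        time, _, data = self._setup(rng)
        with pytest.raises(ValueError, match="epoch"):
            epoch_average_loss(data, data, time, {"x": (5.0, 6.0)})


class TestProjectionLoss:
    def test_equal_projections_zero(self, rng):
        p = rng.standard_normal((4, 10, 3))
        assert projection_loss(p, p) == 0.0

    def test_sign_flip_identity(self, rng):
        # model projections = -data projections: loss = 4 sum(proj^2)
        p = rng.standard_normal((4, 10, 3))
        assert np.isclose(projection_loss(-p, p), 4 * np.sum(p**2))

    def test_depends_only_on_projections(self, rng):
        p = rng.standard_normal((2, 5, 3))
        q = rng.standard_normal((2, 5, 3))
        assert np.isclose(
            projection_loss(p, q), np.sum((p - q) ** 2)
        )


class TestJitter:
    def test_range_and_determinism(self):
        a = jittered_start(42, 1000)
        b = jittered_start(42, 1000)
        assert np.array_equal(a, b)
        assert a.min() >= -4.35 and a.max() <= -2.35

    def test_mean_within_three_standard_errors(self):
        draws = jittered_start(7, 10_000)
        se = (2.0 / np.sqrt(12)) / np.sqrt(draws.size)
        assert abs(draws.mean() - (-3.35)) < 3 * se


@pytest.fixture(scope="module")
def bias_gt():
    """Ground truth with planted biases large enough to recover."""
    return ll.make_ground_truth(30, 4, 3, seed=5, bias_scale=0.05,
                                drift_timescale=5.0)


@pytest.fixture(scope="module")
def bias_recordings(bias_gt):
    return ll.generate_recordings(bias_gt, 10, dt=0.01)


class TestFitTestTrialBiases:
    def test_network_parameters_frozen(self, bias_gt, bias_recordings):
        net = bias_gt.network
        U0, A0 = net.U.copy(), net.A.copy()
        fit_test_trial_biases(
            net, bias_gt.spec, bias_recordings,
            opt=OptimizerConfig(learning_rate=5e-3, max_iterations=40),
        )
        assert np.array_equal(net.U, U0)
        assert np.array_equal(net.A, A0)

    def test_planted_bias_recovery(self, bias_gt, bias_recordings):
        """Frozen-truth optimization recovers the planted per-trial biases."""
        bias, ev = fit_test_trial_biases(
            bias_gt.network, bias_gt.spec, bias_recordings,
            c_reg=0.01,
            opt=OptimizerConfig(learning_rate=2e-3, max_iterations=400,
                                lr_decay="cosine"),
        )
        true = bias_recordings.trial_bias  # (K, P)
        cos = [
            abs(bias.T_matrix[:, k] @ true[k])
            / (np.linalg.norm(bias.T_matrix[:, k]) * np.linalg.norm(true[k]))
            for k in range(true.shape[0])
        ]
        assert np.median(cos) >= 0.7
        assert ev > 0.5

    def test_regularization_shrinks_biases(self, bias_gt, bias_recordings):
        norms = []
        for c_reg in (0.01, 10.0, 1000.0):
            bias, _ = fit_test_trial_biases(
                bias_gt.network, bias_gt.spec, bias_recordings, c_reg=c_reg,
                opt=OptimizerConfig(learning_rate=2e-3, max_iterations=150,
                                    lr_decay="cosine"),
            )
            norms.append(np.linalg.norm(bias.T_matrix))
        assert norms[0] > norms[1] > norms[2]


class TestTrainSingleTrial:
    def test_joint_fit_reduces_loss_and_aligns(self, bias_gt, bias_recordings):
        basis = ll.coding_basis_from_averages(
            condition_average(bias_recordings, 0),
            condition_average(bias_recordings, 1),
            bias_recordings.time,
        )
        opt = OptimizerConfig(learning_rate=1.5e-3, max_iterations=250,
                              log_every=50, lr_decay="cosine")
        fit = train_single_trial(
            bias_recordings, basis, 4, opt=opt, jitter=True
        )
        log = fit.log
        assert log["loss_recon"].iloc[-1] < 0.5 * log["loss_recon"].iloc[0]
        assert fit.trial_bias.T_matrix.shape == (4, 20)
        assert fit.network.orthonormality_defect() < 1e-10

    def test_huge_regularization_drives_biases_to_zero(
        self, bias_gt, bias_recordings
    ):
        basis = ll.coding_basis_from_averages(
            condition_average(bias_recordings, 0),
            condition_average(bias_recordings, 1),
            bias_recordings.time,
        )
        norms = {}
        for c_reg in (0.1, 1e7):
            w = ll.SingleTrialLossWeights(c_reg=c_reg)
            opt = OptimizerConfig(learning_rate=1.5e-3, max_iterations=150,
                                  lr_decay="cosine")
            fit = train_single_trial(
                bias_recordings, basis, 4, weights=w, opt=opt, jitter=False
            )
            norms[c_reg] = np.linalg.norm(fit.trial_bias.T_matrix)
        # the optimizer dithers around zero at learning-rate scale, so the
        # limit is assessed relative to the weakly regularized fit
        assert norms[1e7] < 0.25 * norms[0.1]
        assert np.abs(fit.trial_bias.T_matrix).max() < 5e-2

    def test_stimulus_ablation_control_exists(self, bias_gt, bias_recordings):
        basis = ll.coding_basis_from_averages(
            condition_average(bias_recordings, 0),
            condition_average(bias_recordings, 1),
            bias_recordings.time,
        )
        opt = OptimizerConfig(learning_rate=1.5e-3, max_iterations=40)
        fit = train_single_trial(
            bias_recordings, basis, 4, opt=opt, jitter=False,
            ablate_stimulus=True,
        )
        assert np.all(fit.input_spec.I_low == 0)
        assert np.all(fit.input_spec.I_high == 0)


class TestErrorAxis:
    def _planted(self, rng, P=6, n=120, offset_scale=2.0):
        # hit biases sit at -offset, misses at +offset (hit + known shift),
        # mirroring how a drifting bias pushes trials across the boundary;
        # a through-origin decoder can then separate the clouds
        offset = rng.standard_normal(P)
        offset /= np.linalg.norm(offset)
        T = 0.4 * rng.standard_normal((P, 2 * n)) - 0.5 * offset_scale * offset[:, None]
        condition = np.repeat([0, 1], n)
        outcome = np.ones(2 * n, dtype=int)
        miss = np.concatenate(
            [rng.choice(n, n // 4, replace=False),
             n + rng.choice(n, n // 4, replace=False)]
        )
        outcome[miss] = 0
        T[:, miss] += offset_scale * offset[:, None]
        return TrialBias(T, condition, outcome), offset

    def test_planted_offset_recovered(self, rng):
        bias, offset = self._planted(rng)
        axis = estimate_error_axis(bias, n_bootstrap=50, seed=0)
        for w in (axis.weights_left, axis.weights_right):
            assert abs(w @ offset) >= 0.95
        assert axis.accuracy_left > 0.8 and axis.accuracy_right > 0.8
        assert axis.bootstrap_sd_left.shape == (6,)

    def test_label_permutation_gives_chance_accuracy(self, rng):
        bias, _ = self._planted(rng, n=200)
        perm = rng.permutation(bias.outcome.size)
        shuffled = TrialBias(bias.T_matrix, bias.condition, bias.outcome[perm])
        axis = estimate_error_axis(shuffled, n_bootstrap=5, seed=1)
        # binomial null around 0.5 on the held-out 20%
        for acc in (axis.accuracy_left, axis.accuracy_right):
            assert abs(acc - 0.5) < 0.25

    def test_single_class_rejected(self, rng):
        T = rng.standard_normal((4, 20))
        bias = TrialBias(T, np.repeat([0, 1], 10), np.ones(20, dtype=int))
        with pytest.raises(ValueError, match="miss"):
            estimate_error_axis(bias, n_bootstrap=2)


class TestInterpolation:
    def test_alpha_zero_returns_normalized_axis(self, rng):
        v = rng.standard_normal(7)
        out = interpolate_error_axis(v, 0.0, 3)
        assert np.allclose(out, v / np.linalg.norm(v))

    def test_endpoints_are_pure_components(self, rng):
        v = rng.standard_normal(7)
        cod = np.zeros(7)
        cod[:3] = v[:3]
        res = v - cod
        plus = interpolate_error_axis(v, 1.0, 3)
        minus = interpolate_error_axis(v, -1.0, 3)
        assert np.allclose(plus, res / np.linalg.norm(res))
        assert np.allclose(minus, cod / np.linalg.norm(cod))

    def test_unit_norm_for_all_alpha(self, rng):
        v = rng.standard_normal(5)
        for alpha in np.linspace(-1, 1, 9):
            assert np.isclose(
                np.linalg.norm(interpolate_error_axis(v, alpha, 2)), 1.0
            )

    def test_alpha_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError, match="alpha"):
            interpolate_error_axis(rng.standard_normal(5), 1.5, 2)

    def test_zero_component_rejected(self):
        v = np.array([0.0, 0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="component"):
            interpolate_error_axis(v, 0.5, 2)
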