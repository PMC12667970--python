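"""Losses, gradients, and condition-averaged training."""

import numpy as np
import pytest

import latentloop as ll
from latentloop import _bptt
from latentloop.fitting import (
    LossWeights,
    OptimizerConfig,
    _split_trials,
    alignment_loss,
    _alignment_grad,
    cross_validate,
    explained_variance,
    orthogonality_loss,
    _orthogonality_grad,
    predict_rates,
    reconstruction_loss,
    train_condition_averaged,
)
from latentloop.synthetic import condition_average


class TestReconstructionLoss:
    def test_perfect_prediction_is_zero(self, rng):
        y = rng.standard_normal((7, 4))
        assert reconstruction_loss(y, y, y, y) == 0.0

    def test_unit_offset_counts_every_entry(self, rng):
        T, N = 9, 5
        y = rng.standard_normal((T, N))
        assert np.isclose(
            reconstruction_loss(y + 1, y + 1, y, y), 2 * T * N
        )

    def test_label_swap_symmetry(self, rng):
        pL, pR, dL, dR = rng.standard_normal((4, 6, 3))
        assert np.isclose(
            reconstruction_loss(pL, pR, dL, dR),
            reconstruction_loss(pR, pL, dR, dL),
        )


class TestAlignmentLoss:
    def test_perfect_alignment(self, rng):
        V = np.linalg.qr(rng.standard_normal((10, 3)))[0]
        assert np.isclose(alignment_loss(V, 3.0 * V), 0.0, atol=1e-12)

    def test_orthogonal_dims_give_four(self, rng):
        Q = np.linalg.qr(rng.standard_normal((10, 6)))[0]
        assert np.isclose(alignment_loss(Q[:, :3], Q[:, 3:]), 4.0, atol=1e-12)

    def test_antialigned_choice(self, rng):
        V = np.linalg.qr(rng.standard_normal((10, 3)))[0]
        model = V.copy()
        model[:, 1] *= -1
        # 4 - 1 + 2 - 1 = 4
        assert np.isclose(alignment_loss(model, V), 4.0, atol=1e-12)

    def test_zero_column_rejected(self, rng):
        V = np.linalg.qr(rng.standard_normal((10, 3)))[0]
        bad = V.copy()
        bad[:, 0] = 0
        with pytest.raises(ValueError, match="zero-norm"):
            alignment_loss(bad, V)

    def test_gradient_matches_finite_differences(self, rng):
        U = rng.standard_normal((8, 4))
        V = np.linalg.qr(rng.standard_normal((8, 3)))[0]
        g = _alignment_grad(U, V, 2.0)
        eps = 1e-6
        for idx in [(0, 0), (3, 1), (7, 2)]:
            Up, Um = U.copy(), U.copy()
            Up[idx] += eps
            Um[idx] -= eps
            num = (
                alignment_loss(Up[:, :3], V) - alignment_loss(Um[:, :3], V)
            ) / (2 * eps)
            assert np.isclose(g[idx], num, atol=1e-6)


class TestOrthogonalityLoss:
    def test_orthonormal_is_zero(self, rng):
        Q = np.linalg.qr(rng.standard_normal((9, 4)))[0]
        assert orthogonality_loss(Q) < 1e-20

    def test_scaled_basis_closed_form(self, rng):
        Q = np.linalg.qr(rng.standard_normal((9, 4)))[0]
        # ||I - 4 I||_F^2 = 9 P
        assert np.isclose(orthogonality_loss(2.0 * Q), 9 * 4)

    def test_duplicated_column_strictly_raises_loss(self, rng):
        Q = np.linalg.qr(rng.standard_normal((9, 3)))[0]
        dup = Q.copy()
        dup[:, 2] = dup[:, 1]
        assert orthogonality_loss(dup) > orthogonality_loss(Q)

    def test_gradient_matches_finite_differences(self, rng):
        U = rng.standard_normal((6, 3))
        g = _orthogonality_grad(U)
        eps = 1e-6
        for idx in [(0, 0), (5, 2)]:
            Up, Um = U.copy(), U.copy()
            Up[idx] += eps
            Um[idx] -= eps
            num = (orthogonality_loss(Up) - orthogonality_loss(Um)) / (2 * eps)
            assert np.isclose(g[idx], num, atol=1e-5)


class TestExplainedVariance:
    def test_hand_built_example(self):
        data = np.array([[1.0, 3.0], [2.0, 4.0]])  # grand mean 2.5, SStot 5
        pred = np.array([[1.0, 3.0], [2.0, 3.0]])  # SSE 1
        assert np.isclose(explained_variance(pred, data), 1 - 1 / 5)

    def test_perfect_prediction(self, rng):
        y = rng.standard_normal((3, 4))
        assert explained_variance(y, y) == 1.0


class TestBPTTGradients:
    def test_against_finite_differences(self, rng):
        """The hand-derived recurrent gradients match central differences."""
        N, P, K, T = 6, 2, 2, 10
        a = 0.2
        U = 0.4 * rng.standard_normal((N, P))
        A = 0.3 * rng.standard_normal((P, P))
        rmax = rng.uniform(10, 40, N)
        r0 = rmax / 2
        iota = 0.1 * rng.standard_normal((K, T - 1, P))
        lick_vec = 0.05 * rng.standard_normal((K, N))
        lick_rate = rng.uniform(0, 2, (K, T - 1))
        start = np.array([0, 3])
        y = rng.uniform(0, 30, (K, T, N))

        def loss(U=U, A=A, rmax=rmax, iota=iota, lick_vec=lick_vec, r0=r0):
            rates, _ = _bptt.forward(
                U, A, rmax, r0, iota, start, a, lick_vec, lick_rate
            )
            return np.sum((rates - y) ** 2)

        rates, caches = _bptt.forward(
            U, A, rmax, r0, iota, start, a, lick_vec, lick_rate
        )
        g = 2 * (rates - y)
        dU, dA, drmax, diota, dlick, dr0 = _bptt.backward(
            U, A, rmax, g, rates, caches, a
        )
        eps = 1e-6

        def check(analytic, base, name, samples):
            for idx in samples:
                xp = base.copy()
                xp[idx] += eps
                xm = base.copy()
                xm[idx] -= eps
                num = (loss(**{name: xp}) - loss(**{name: xm})) / (2 * eps)
                assert np.isclose(analytic[idx], num, rtol=1e-4, atol=1e-4), (
                    name, idx
                )

        check(dU, U, "U", [(0, 0), (5, 1), (3, 0)])
        check(dA, A, "A", [(0, 0), (1, 1)])
        check(drmax, rmax, "rmax", [(0,), (4,)])
        check(diota, iota, "iota", [(0, 2, 1), (1, 5, 0)])
        check(dlick, lick_vec, "lick_vec", [(0, 1), (1, 4)])
        check(dr0, r0, "r0", [(2,), (5,)])


class TestTraining:
    def test_warm_start_at_truth_stays_put(self, small_gt):
        """Refitting data the network itself generated keeps the loss tiny."""
        gt = ll.make_ground_truth(25, 4, 3, seed=6, bias_scale=0.0, noise_sd=0.0)
        data = ll.generate_recordings(gt, 2, dt=0.01, smooth=False)
        basis = ll.CodingBasis(
            vectors=gt.network.U[:, :3],
            windows=ll.default_windows(),
        )
        init = {
            "U": gt.network.U,
            "A": gt.network.A,
            "rmax": gt.network.rmax,
            "I_low": gt.spec.I_low,
            "I_high": gt.spec.I_high,
            "I_go": gt.spec.I_go,
            "I_lick_left": gt.spec.I_lick_left,
            "I_lick_right": gt.spec.I_lick_right,
        }
        opt = OptimizerConfig(learning_rate=1e-5, max_iterations=30, log_every=1)
        fit = train_condition_averaged(
            data, basis, 4, opt=opt, init_params=init
        )
        recon = fit.log["loss_recon"].to_numpy()
        # data were generated by this exact network: near-zero throughout
        scale = float(np.sum(data.rates**2))
        assert recon[0] < 1e-6 * scale
        assert recon[-1] < 1e-5 * scale

    def test_loss_decreases_on_synthetic_problem(self, small_recordings, small_basis):
        opt = OptimizerConfig(
            learning_rate=1.5e-3, max_iterations=600, log_every=100,
            lr_decay="cosine",
        )
        fit = train_condition_averaged(
            small_recordings, small_basis, 5, opt=opt, fit_dt=0.01
        )
        log = fit.log["loss_total"].to_numpy()
        assert log[-1] < 0.3 * log[0]
        assert fit.train_explained_variance > 0.5

    def test_large_orthogonality_weight_enforces_constraint(
        self, small_recordings, small_basis
    ):
        # the raw optimizer defect ||I - U^T U|| (pre-canonicalization, from
        # the log) shrinks as the orthogonality weight grows, and a dominant
        # weight pins it below 1e-2
        defects = []
        for lam in (5e2, 5e4, 5e6):
            opt = OptimizerConfig(
                learning_rate=1.5e-3, max_iterations=600, lr_decay="cosine",
                log_every=600,
            )
            fit = train_condition_averaged(
                small_recordings, small_basis, 5,
                weights=LossWeights(lambda_orth=lam), opt=opt, fit_dt=0.01,
            )
            defects.append(float(np.sqrt(fit.log["loss_orth"].to_numpy()[-1])))
        assert defects[0] > defects[1] > defects[2]
        assert defects[-1] < 1e-2
        # and the returned network is exactly orthonormal by construction
        assert fit.network.orthonormality_defect() < 1e-10

    def test_canonicalization_preserves_dynamics(
        self, small_recordings, small_basis
    ):
        opt = OptimizerConfig(learning_rate=1.5e-3, max_iterations=150)
        raw = train_condition_averaged(
            small_recordings, small_basis, 5, opt=opt, fit_dt=0.01,
            canonicalize=False,
        )
        canon = train_condition_averaged(
            small_recordings, small_basis, 5, opt=opt, fit_dt=0.01,
            canonicalize=True,
        )
        p_raw = predict_rates(raw.network, raw.input_spec, raw.time)
        p_canon = predict_rates(canon.network, canon.input_spec, canon.time)
        assert np.max(np.abs(p_raw - p_canon)) < 1e-8

    def test_fixed_coding_mode_freezes_columns(
        self, small_recordings, small_basis
    ):
        opt = OptimizerConfig(learning_rate=1e-3, max_iterations=50)
        fit = train_condition_averaged(
            small_recordings, small_basis, 5, opt=opt, fit_dt=0.01,
            fixed_coding=True,
        )
        assert np.allclose(fit.network.U[:, :3], small_basis.vectors)

    def test_p_below_coding_count_rejected(self, small_recordings, small_basis):
        with pytest.raises(ValueError, match="P="):
            train_condition_averaged(small_recordings, small_basis, 2)


class TestCrossValidation:
    def test_same_seed_same_folds(self, small_recordings):
        rng1 = np.random.default_rng(7)
        rng2 = np.random.default_rng(7)
        a = _split_trials(small_recordings, 0.8, rng1)
        b = _split_trials(small_recordings, 0.8, rng2)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_split_is_stratified_partition(self, small_recordings):
        train, test = _split_trials(
            small_recordings, 0.8, np.random.default_rng(0)
        )
        assert len(set(train) & set(test)) == 0
        hits = np.flatnonzero(small_recordings.outcome == 1)
        assert set(train) | set(test) == set(hits)

    def test_table_schema_and_determinism(self, small_recordings):
        opt = OptimizerConfig(learning_rate=1.5e-3, max_iterations=60)
        t1 = cross_validate(
            small_recordings, [3, 4], n_splits=2, opt=opt, fit_dt=0.01, seed=5
        )
        t2 = cross_validate(
            small_recordings, [3, 4], n_splits=2, opt=opt, fit_dt=0.01, seed=5
        )
        assert list(t1.columns[:3]) == ["P", "test_mse", "test_mse_se"]
        assert np.allclose(t1["test_mse"], t2["test_mse"])
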