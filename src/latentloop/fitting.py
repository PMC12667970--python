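"""Train low-rank networks on condition-averaged activity, and cross-validate.

The training objective combines three terms: a reconstruction loss (squared
error between the model's simulated rates and the condition-averaged data
for left and right hit trials), a cosine-similarity alignment loss pulling
the first three columns of U toward the data-derived LDA coding axes (the
choice term weighted twice), and an orthogonality penalty ||I - U^T U||_F^2.
Default weights: lambda_recon = 0.7, lambda_align = 0.5, lambda_orth = 500.

Trainable parameters are U (N x P), the interaction matrix A (P x P), the
per-neuron maximum rates rmax, the three latent task-input vectors, and —
when a lick-rate series is supplied — the two length-N lick input vectors.
Optimization is Adam with gradient clipping on hand-derived
backprop-through-time gradients (see ``_bptt``).

Initialization is informed rather than random: coding columns of U start at
the LDA axes, residual columns at the leading principal components of the
data outside the coding subspace, and rmax just above each neuron's
observed peak rate.  This is what makes desk-scale fits converge in
thousands rather than hundreds of thousands of iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _bptt
from .coding import CodingBasis, coding_basis_from_averages
from .network import InputSpec, LowRankNetwork
from .synthetic import ActivityTensor, condition_average

__all__ = [
    "LossWeights",
    "OptimizerConfig",
    "FitResult",
    "reconstruction_loss",
    "alignment_loss",
    "orthogonality_loss",
    "explained_variance",
    "train_condition_averaged",
    "predict_rates",
    "cross_validate",
]


@dataclass
class LossWeights:
    """Weights of the condition-averaged training objective."""

    lambda_recon: float = 0.7
    lambda_align: float = 0.5
    lambda_orth: float = 500.0
    choice_align_weight: float = 2.0

    def __post_init__(self) -> None:
        if min(self.lambda_recon, self.lambda_align, self.lambda_orth,
               self.choice_align_weight) < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass
class OptimizerConfig:
    """Adam settings.  The conservative learning-rate default (5e-4) suits
    long training runs; desk-scale fits typically pass a larger rate and a
    much smaller iteration cap."""

    learning_rate: float = 5e-4
    max_iterations: int = 400_000
    gradient_clip_norm: float = 1.0
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    rel_tol: float = 1e-7
    tol_window: int = 1000
    log_every: int = 50
    lr_decay: str = "none"  # "none" (reference protocol) or "cosine"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class FitResult:
    """A fitted network, its input parameters, and the training log."""

    network: LowRankNetwork
    input_spec: InputSpec
    log: pd.DataFrame
    train_explained_variance: float
    time: np.ndarray = field(default_factory=lambda: np.empty(0))


def reconstruction_loss(pred_L, pred_R, data_L, data_R) -> float:
    """Summed squared error over time and neurons, both conditions."""
    pred_L, pred_R = np.asarray(pred_L), np.asarray(pred_R)
    data_L, data_R = np.asarray(data_L), np.asarray(data_R)
    if pred_L.shape != data_L.shape or pred_R.shape != data_R.shape:
        raise ValueError("prediction/data shape mismatch")
    return float(np.sum((pred_L - data_L) ** 2) + np.sum((pred_R - data_R) ** 2))


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("alignment loss undefined for a zero-norm column")
    return float(u @ v / (nu * nv))


def alignment_loss(
    model_dims: np.ndarray, target_dims: np.ndarray, choice_weight: float = 2.0
) -> float:
    """4 - cos(u1, v_sample) - w_choice cos(u2, v_choice) - cos(u3, v_response)."""
    model_dims = np.asarray(model_dims, dtype=float)
    target_dims = np.asarray(target_dims, dtype=float)
    w = np.array([1.0, choice_weight, 1.0])
    cs = [
        _cosine(model_dims[:, j], target_dims[:, j]) for j in range(3)
    ]
    return float(2.0 + choice_weight - np.sum(w * cs))


def _alignment_grad(
    U: np.ndarray, targets: np.ndarray, choice_weight: float
) -> np.ndarray:
    """d(alignment loss)/dU, nonzero only on the first three columns."""
    dU = np.zeros_like(U)
    w = (1.0, choice_weight, 1.0)
    for j in range(3):
        u, v = U[:, j], targets[:, j]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        c = u @ v / (nu * nv)
        dU[:, j] = -w[j] * (v / (nu * nv) - c * u / nu**2)
    return dU


def orthogonality_loss(U: np.ndarray) -> float:
    """Squared Frobenius norm of I - U^T U."""
    U = np.asarray(U, dtype=float)
    P = U.shape[1]
    D = np.eye(P) - U.T @ U
    return float(np.sum(D * D))


def _orthogonality_grad(U: np.ndarray) -> np.ndarray:
    P = U.shape[1]
    return -4.0 * U @ (np.eye(P) - U.T @ U)


def explained_variance(pred: np.ndarray, data: np.ndarray) -> float:
    """Pooled 1 - SSE/SStot over neurons, time, and conditions."""
    pred, data = np.asarray(pred), np.asarray(data)
    sse = np.sum((pred - data) ** 2)
    sstot = np.sum((data - data.mean()) ** 2)
    return float(1.0 - sse / sstot)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], cfg: OptimizerConfig):
        self.cfg = cfg
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(
        self,
        params: dict[str, np.ndarray],
        grads: dict[str, np.ndarray],
        lr_factor: float = 1.0,
    ):
        c = self.cfg
        total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
        scale = min(1.0, c.gradient_clip_norm / (total + 1e-12))
        self.t += 1
        b1t = 1 - c.beta1**self.t
        b2t = 1 - c.beta2**self.t
        lr = c.learning_rate * lr_factor
        for k, g in grads.items():
            g = g * scale
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g * g
            params[k] -= (
                lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + c.eps)
            )


def _window_step_mask(
    time: np.ndarray, window: tuple[float, float]
) -> np.ndarray:
    """Steps (left grid points) whose interval start lies in the window."""
    t = time[:-1]
    return (t >= window[0] - 1e-9) & (t < window[1] - 1e-9)


def latent_input_schedule(
    time: np.ndarray, spec: InputSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean step masks (tone, go) plus the per-condition tone sign.

    Returns (tone_mask, go_mask) over the T-1 integration steps.
    """
    tone = np.zeros(time.size - 1, dtype=bool)
    for w in spec.tone_windows:
        tone |= _window_step_mask(time, w)
    go = _window_step_mask(time, spec.go_window)
    return tone, go


def _build_iota(
    time: np.ndarray, params: dict[str, np.ndarray], spec: InputSpec
) -> np.ndarray:
    """Latent input (2, T-1, P): row 0 = left (low tone), row 1 = right."""
    tone, go = latent_input_schedule(time, spec)
    P = params["I_low"].size
    iota = np.zeros((2, time.size - 1, P))
    iota[0, tone] = params["I_low"]
    iota[1, tone] = params["I_high"]
    iota[:, go] += params["I_go"]
    return iota


def _init_params(
    y: np.ndarray,
    basis: CodingBasis,
    P: int,
    time: np.ndarray,
    a: float,
    spec: InputSpec,
    lick_profile: np.ndarray | None,
) -> dict[str, np.ndarray]:
    """Data-informed (teacher-forced) initialization.

    U starts at the LDA axes plus leading principal components of the
    residual data; rmax just above each neuron's observed peak.  A and the
    input vectors are then initialized by inverting the transfer function
    on the data itself: from consecutive data frames the Euler update gives
    the target drive h_t = arctanh(2 phi_t / rmax - 1), and the latent
    regression U^T h_t ~ A m_t + iota_t is solved by least squares.  This
    starts gradient descent near a self-consistent solution instead of at
    a silent network.
    """
    N = y.shape[2]
    C = basis.n_coding
    U = np.zeros((N, P))
    U[:, :C] = basis.vectors
    if P > C:
        flat = y.reshape(-1, N) - y.reshape(-1, N).mean(axis=0)
        flat = flat - (flat @ basis.vectors) @ basis.vectors.T
        _, _, Vt = np.linalg.svd(flat, full_matrices=False)
        U[:, C:] = Vt[: P - C].T
    Q, R = np.linalg.qr(U)
    U = Q * np.sign(np.diag(R))
    rmax = np.maximum(y.max(axis=(0, 1)) * 1.05, 1.0) + 0.5

    # teacher forcing: phi(h_t) = (y_{t+1} - (1-a) y_t) / a
    phi = (y[:, 1:] - (1 - a) * y[:, :-1]) / a
    ratio = np.clip(2 * phi / rmax - 1.0, -0.999, 0.999)
    h = np.arctanh(ratio)  # (2, T-1, N)
    z = h @ U  # latent target drive (2, T-1, P)
    m = y[:, :-1] @ U
    tone, go = latent_input_schedule(time, spec)
    Tm1 = time.size - 1
    cols = [
        np.vstack([m[0], m[1]]),  # latent state, both conditions stacked
        np.concatenate([tone, np.zeros(Tm1)])[:, None],  # low tone (left)
        np.concatenate([np.zeros(Tm1), tone])[:, None],  # high tone (right)
        np.concatenate([go, go])[:, None],
    ]
    if lick_profile is not None:
        cols.append(
            np.concatenate([lick_profile[0], np.zeros(Tm1)])[:, None]
        )
        cols.append(
            np.concatenate([np.zeros(Tm1), lick_profile[1]])[:, None]
        )
    X = np.hstack(cols)
    Z = np.vstack([z[0], z[1]])
    coef, *_ = np.linalg.lstsq(X, Z, rcond=None)
    params = {
        "U": U,
        "A": coef[:P].T.copy(),
        "rmax": rmax,
        "I_low": coef[P].copy(),
        "I_high": coef[P + 1].copy(),
        "I_go": coef[P + 2].copy(),
    }
    if lick_profile is not None:
        # regression recovers only the in-span part of the lick vectors
        params["I_lick_left"] = U @ coef[P + 3]
        params["I_lick_right"] = U @ coef[P + 4]
    return params


def train_condition_averaged(
    data: ActivityTensor,
    basis: CodingBasis,
    P: int,
    weights: LossWeights | None = None,
    opt: OptimizerConfig | None = None,
    fit_dt: float | None = None,
    tau: float = 0.040,
    fixed_coding: bool = False,
    init_params: dict[str, np.ndarray] | None = None,
    canonicalize: bool = True,
) -> FitResult:
    """Fit the low-rank network to left/right condition averages (hit trials).

    ``fit_dt`` subsamples the data grid for integration (must be a multiple
    of the recording dt and at most tau/4).  ``fixed_coding`` freezes the
    first C columns of U at the supplied basis (the hard-alignment control);
    the default co-optimizes them under the alignment penalty.
    ``canonicalize`` re-orthonormalizes the returned U by the exact
    QR reparameterization (dynamics unchanged); the training log's
    orthogonality column still reports the raw optimizer state.
    """
    weights = weights or LossWeights()
    opt = opt or OptimizerConfig()
    C = basis.n_coding
    if P < C:
        raise ValueError(f"P={P} must be at least C={C}")

    stride = 1 if fit_dt is None else int(round(fit_dt / data.dt))
    time = data.time[::stride]
    dt = float(time[1] - time[0])
    if dt > tau / 4 + 1e-12:
        raise ValueError(f"fit dt={dt} too coarse; need <= tau/4")
    a = dt / tau
    y = np.stack(
        [condition_average(data, c)[::stride] for c in (0, 1)]
    )  # (2, T, N)

    N = y.shape[2]
    has_lick = data.lick_rate is not None
    lick_profile = (
        np.tile(np.asarray(data.lick_rate, float)[::stride][:-1], (2, 1))
        if has_lick
        else None
    )
    spec_proto = InputSpec.zeros(P)
    spec_proto = InputSpec(
        spec_proto.I_low, spec_proto.I_high, spec_proto.I_go,
        tone_windows=data.tone_windows, go_window=data.go_window,
    )
    params = init_params or _init_params(
        y, basis, P, time, a, spec_proto, lick_profile
    )
    params = {k: np.array(v, dtype=float) for k, v in params.items()}
    if fixed_coding:
        params["U"][:, :C] = basis.vectors
    if has_lick:
        params.setdefault("I_lick_left", np.zeros(N))
        params.setdefault("I_lick_right", np.zeros(N))

    adam = _Adam(params, opt)
    records: list[dict[str, float]] = []
    recent: list[float] = []
    for it in range(opt.max_iterations):
        iota = _build_iota(time, params, spec_proto)
        r0 = params["rmax"] / 2.0
        lick_vec = (
            np.stack([params["I_lick_left"], params["I_lick_right"]])
            if has_lick
            else None
        )
        rates, caches = _bptt.forward(
            params["U"], params["A"], params["rmax"], r0, iota, a=a,
            lick_vec=lick_vec, lick_rate=lick_profile,
        )
        resid = rates - y
        l_recon = float(np.sum(resid * resid))
        l_align = alignment_loss(
            params["U"][:, :3], basis.vectors, weights.choice_align_weight
        )
        l_orth = orthogonality_loss(params["U"])
        total = (
            weights.lambda_recon * l_recon
            + weights.lambda_align * l_align
            + weights.lambda_orth * l_orth
        )
        if not np.isfinite(total):
            raise FloatingPointError(
                f"training diverged at iteration {it} (loss not finite)"
            )

        g = 2.0 * weights.lambda_recon * resid
        dU, dA, drmax, diota, dlick, dr0 = _bptt.backward(
            params["U"], params["A"], params["rmax"], g, rates, caches, a=a
        )
        drmax = drmax + 0.5 * dr0  # r0 = rmax/2
        dU = dU + weights.lambda_align * _alignment_grad(
            params["U"], basis.vectors, weights.choice_align_weight
        )
        dU = dU + weights.lambda_orth * _orthogonality_grad(params["U"])
        if fixed_coding:
            dU[:, :C] = 0.0
        tone, go = latent_input_schedule(time, spec_proto)
        grads = {
            "U": dU,
            "A": dA,
            "rmax": drmax,
            "I_low": diota[0, tone].sum(axis=0),
            "I_high": diota[1, tone].sum(axis=0),
            "I_go": diota[:, go].sum(axis=(0, 1)),
        }
        if has_lick:
            grads["I_lick_left"] = dlick[0]
            grads["I_lick_right"] = dlick[1]
        if opt.lr_decay == "cosine":
            frac = it / max(opt.max_iterations - 1, 1)
            lr_factor = 0.05 + 0.95 * 0.5 * (1 + np.cos(np.pi * frac))
        else:
            lr_factor = 1.0
        adam.step(params, grads, lr_factor)
        np.maximum(params["rmax"], 0.5, out=params["rmax"])

        if it % opt.log_every == 0 or it == opt.max_iterations - 1:
            records.append(
                {
                    "iteration": it,
                    "loss_total": total,
                    "loss_recon": l_recon,
                    "loss_align": l_align,
                    "loss_orth": l_orth,
                }
            )
        recent.append(total)
        if len(recent) > opt.tol_window:
            old = recent.pop(0)
            if abs(old - total) < opt.rel_tol * max(abs(old), 1e-12):
                break

    if canonicalize:
        # exact reparameterization: with U = QR, J = U A U^T = Q (RAR^T) Q^T
        # and U I = Q (R I), so the returned network has exactly orthonormal
        # columns and bit-identical dynamics
        Q, R = np.linalg.qr(params["U"])
        s = np.sign(np.diag(R))
        Q, R = Q * s, (R.T * s).T
        params["U"] = Q
        params["A"] = R @ params["A"] @ R.T
        for key in ("I_low", "I_high", "I_go"):
            params[key] = R @ params[key]
    net = LowRankNetwork(
        U=params["U"], A=params["A"], rmax=params["rmax"], tau=tau, n_coding=C
    )
    spec = InputSpec(
        I_low=params["I_low"],
        I_high=params["I_high"],
        I_go=params["I_go"],
        I_lick_left=params.get("I_lick_left"),
        I_lick_right=params.get("I_lick_right"),
        lick_times=time[:-1].copy() if has_lick else None,
        lick_rates=lick_profile[0].copy() if has_lick else None,
        tone_windows=data.tone_windows,
        go_window=data.go_window,
    )
    pred = predict_rates(net, spec, time)
    ev = explained_variance(pred, y)
    return FitResult(
        network=net,
        input_spec=spec,
        log=pd.DataFrame.from_records(records),
        train_explained_variance=ev,
        time=time,
    )


def predict_rates(
    net: LowRankNetwork, spec: InputSpec, time: np.ndarray
) -> np.ndarray:
    """Model condition-averaged rates (2, T, N) on the given grid."""
    dt = float(time[1] - time[0])
    a = dt / net.tau
    params = {"I_low": spec.I_low, "I_high": spec.I_high, "I_go": spec.I_go}
    time = np.asarray(time, float)
    iota = _build_iota(time, params, spec)
    lick_vec = lick_profile = None
    if spec.I_lick_left is not None and spec.lick_times is not None:
        lick_vec = np.stack([spec.I_lick_left, spec.I_lick_right])
        prof = np.array([spec.lick_rate(t) for t in time[:-1]])
        lick_profile = np.tile(prof, (2, 1))
    rates, _ = _bptt.forward(
        net.U, net.A, net.rmax, net.rmax / 2.0, iota, a=a,
        lick_vec=lick_vec, lick_rate=lick_profile,
    )
    return rates


def _split_trials(
    data: ActivityTensor, train_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified (per condition) hit-trial split into train/test indices."""
    train, test = [], []
    for c in (0, 1):
        idx = np.flatnonzero((data.condition == c) & (data.outcome == 1))
        idx = rng.permutation(idx)
        n_train = max(1, int(round(train_frac * idx.size)))
        if idx.size < 2:
            raise ValueError(f"condition {c} has too few hit trials to split")
        n_train = min(n_train, idx.size - 1)
        train.extend(idx[:n_train])
        test.extend(idx[n_train:])
    return np.array(sorted(train)), np.array(sorted(test))


def _subset(data: ActivityTensor, idx: np.ndarray) -> ActivityTensor:
    return ActivityTensor(
        rates=data.rates[idx],
        time=data.time,
        condition=data.condition[idx],
        outcome=data.outcome[idx],
        tone_windows=data.tone_windows,
        go_window=data.go_window,
        dt=data.dt,
        seed=data.seed,
        lick_rate=data.lick_rate,
    )


def cross_validate(
    data: ActivityTensor,
    P_grid: list[int] | np.ndarray,
    n_splits: int = 5,
    train_frac: float = 0.8,
    weights: LossWeights | None = None,
    opt: OptimizerConfig | None = None,
    fit_dt: float | None = None,
    seed: int = 0,
    smooth_points: int | None = None,
) -> pd.DataFrame:
    """Trial-level cross-validation of the latent dimensionality P.

    For each split, 80% of the hit trials (stratified by condition) form
    the training condition averages and the data-derived LDA basis; the fit
    is scored by the MSE of its predicted rates against the held-out-trial
    condition averages and by the mean |cosine| between its coding columns
    and the training LDA axes.  Reports mean and standard error over
    splits; ``smooth_points`` applies a moving average over the P axis.
    """
    P_grid = list(P_grid)
    rng = np.random.default_rng(seed)
    split_seeds = [rng.integers(2**31) for _ in range(n_splits)]
    rows = []
    for P in P_grid:
        mses, coss = [], []
        for s in split_seeds:
            srng = np.random.default_rng(s)
            train_idx, test_idx = _split_trials(data, train_frac, srng)
            d_train, d_test = _subset(data, train_idx), _subset(data, test_idx)
            avgL = condition_average(d_train, 0)
            avgR = condition_average(d_train, 1)
            basis = coding_basis_from_averages(avgL, avgR, data.time)
            fit = train_condition_averaged(
                d_train, basis, P, weights=weights, opt=opt, fit_dt=fit_dt
            )
            stride = 1 if fit_dt is None else int(round(fit_dt / data.dt))
            y_test = np.stack(
                [condition_average(d_test, c)[::stride] for c in (0, 1)]
            )
            pred = predict_rates(fit.network, fit.input_spec, fit.time)
            mses.append(float(np.mean((pred - y_test) ** 2)))
            coss.append(
                float(
                    np.mean(
                        [
                            abs(_cosine(fit.network.U[:, j], basis.vectors[:, j]))
                            for j in range(3)
                        ]
                    )
                )
            )
        rows.append(
            {
                "P": P,
                "test_mse": float(np.mean(mses)),
                "test_mse_se": float(np.std(mses, ddof=1) / np.sqrt(len(mses)))
                if len(mses) > 1
                else 0.0,
                "cosine": float(np.mean(coss)),
                "cosine_se": float(np.std(coss, ddof=1) / np.sqrt(len(coss)))
                if len(coss) > 1
                else 0.0,
            }
        )
    table = pd.DataFrame(rows)
    if smooth_points and smooth_points > 1:
        for col in ("test_mse", "cosine"):
            table[col + "_smooth"] = (
                table[col].rolling(smooth_points, center=True, min_periods=1).mean()
            )
    return table
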