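"""Trial-specific input biases, error axes, and coding/residual interpolation.

Trial-to-trial variability is modeled as a constant, low-dimensional input
offset per trial: on trial k the network receives I^(k) = U T[:, k] in
addition to the task inputs, with the recurrent dynamics shared across
trials.  The bias matrix T (P x K) is trained jointly with the network on
summary statistics of the single-trial tensor y_kti — condition averages,
within-epoch time averages, and projections onto the coding dimensions —
plus the alignment/orthogonality penalties and an L2 penalty on T.
Default weights: c_recon = 0.65, c_epoch = 0.1666, c_proj = 0.02,
c_align = 0.5, c_orth = 500, c_reg = 0.1.

Trial start times are jittered (uniform on [-4.35, -2.35] s relative to
the go cue, redrawn each iteration) so the network cannot memorize a
mapping from the constant bias to the response and must instead integrate
the stimulus.

Error axes live in the P-dimensional input-bias space: no-intercept
logistic decoders separating hit from miss trials, fitted per side; their
normalized weights point along the bias pattern that predicts errors.  An
interpolation I(alpha) = I_err - alpha I_coding + alpha I_residual
(normalized) morphs a perturbation from purely coding (alpha = -1) to
purely residual (alpha = +1) composition at fixed magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import _bptt
from .coding import CodingBasis
from .fitting import (
    LossWeights,
    OptimizerConfig,
    _Adam,
    _init_params,
    alignment_loss,
    _alignment_grad,
    orthogonality_loss,
    _orthogonality_grad,
    explained_variance,
    latent_input_schedule,
)
from .network import InputSpec, LowRankNetwork
from .synthetic import ActivityTensor, default_epochs

__all__ = [
    "TrialBias",
    "ErrorAxis",
    "SingleTrialLossWeights",
    "SingleTrialFit",
    "trial_bias_input",
    "epoch_average_loss",
    "projection_loss",
    "jittered_start",
    "train_single_trial",
    "fit_test_trial_biases",
    "estimate_error_axis",
    "interpolate_error_axis",
]

JITTER_RANGE = (-4.35, -2.35)


@dataclass
class TrialBias:
    """Per-trial latent input offsets: column k of T is trial k's bias."""

    T_matrix: np.ndarray  # (P, K)
    condition: np.ndarray  # (K,)
    outcome: np.ndarray  # (K,)

    @property
    def n_trials(self) -> int:
        return self.T_matrix.shape[1]


@dataclass
class ErrorAxis:
    """Normalized no-intercept decoder weights in input-bias space."""

    weights_left: np.ndarray
    weights_right: np.ndarray
    accuracy_left: float
    accuracy_right: float
    bootstrap_sd_left: np.ndarray | None = None
    bootstrap_sd_right: np.ndarray | None = None


@dataclass
class SingleTrialLossWeights:
    c_recon: float = 0.65
    c_epoch: float = 0.1666
    c_proj: float = 0.02
    c_align: float = 0.5
    c_orth: float = 500.0
    c_reg: float = 0.1

    def __post_init__(self) -> None:
        if min(self.c_recon, self.c_epoch, self.c_proj, self.c_align,
               self.c_orth, self.c_reg) < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass
class SingleTrialFit:
    network: LowRankNetwork
    input_spec: InputSpec
    trial_bias: TrialBias
    log: pd.DataFrame
    time: np.ndarray = field(default_factory=lambda: np.empty(0))


def trial_bias_input(T_matrix: np.ndarray, k: int, U: np.ndarray) -> np.ndarray:
    """Constant input I^(k) = U T[:, k] for trial k (length N)."""
    T_matrix = np.asarray(T_matrix, dtype=float)
    if not 0 <= k < T_matrix.shape[1]:
        raise IndexError(f"trial index {k} out of range")
    return np.asarray(U, dtype=float) @ T_matrix[:, k]


def _epoch_masks(
    time: np.ndarray, epochs: dict[str, tuple[float, float]]
) -> dict[str, np.ndarray]:
    masks = {}
    for name, (a, b) in epochs.items():
        m = (time >= a - 1e-9) & (time < b - 1e-9)
        if not m.any():
            raise ValueError(f"epoch {name!r} contains no time samples")
        masks[name] = m
    return masks


def epoch_average_loss(
    model: np.ndarray,
    data: np.ndarray,
    time: np.ndarray,
    epochs: dict[str, tuple[float, float]],
) -> float:
    """Sum over epochs, trials, neurons of squared within-epoch mean error."""
    model, data = np.asarray(model, float), np.asarray(data, float)
    if model.shape != data.shape:
        raise ValueError("model/data tensor shape mismatch")
    total = 0.0
    for mask in _epoch_masks(np.asarray(time, float), epochs).values():
        d = model[:, mask].mean(axis=1) - data[:, mask].mean(axis=1)
        total += float(np.sum(d * d))
    return total


def projection_loss(model_proj: np.ndarray, data_proj: np.ndarray) -> float:
    """Squared error between model and data coding-dimension projections.

    Both arguments are (K, T, C) arrays: model rates projected on the first
    C columns of U, data projected on the LDA axes.
    """
    model_proj, data_proj = np.asarray(model_proj), np.asarray(data_proj)
    if model_proj.shape != data_proj.shape:
        raise ValueError("projection shape mismatch")
    return float(np.sum((model_proj - data_proj) ** 2))


def jittered_start(
    rng: int | np.random.Generator, n_trials: int
) -> np.ndarray:
    """Per-trial input-onset offsets, i.i.d. uniform on [-4.35, -2.35] s."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return rng.uniform(*JITTER_RANGE, size=n_trials)


def _sim_grid(
    data_time: np.ndarray, stride: int, jitter: bool
) -> tuple[np.ndarray, int]:
    """Simulation grid: the (subsampled) data grid, extended left for jitter."""
    t = data_time[::stride]
    dt = float(t[1] - t[0])
    if not jitter:
        return t, 0
    n_ext = int(np.ceil((t[0] - JITTER_RANGE[0]) / dt))
    ext = t[0] - dt * np.arange(n_ext, 0, -1)
    return np.concatenate([ext, t]), n_ext


def _trial_iota(
    time: np.ndarray,
    params: dict[str, np.ndarray],
    spec: InputSpec,
    conditions: np.ndarray,
    T_matrix: np.ndarray,
) -> np.ndarray:
    """Latent input (K, T-1, P): task schedule by condition plus the bias."""
    tone, go = latent_input_schedule(time, spec)
    K = conditions.size
    P = params["I_low"].size
    iota = np.zeros((K, time.size - 1, P))
    left = conditions == 0
    iota[np.ix_(left, tone)] = params["I_low"]
    iota[np.ix_(~left, tone)] = params["I_high"]
    iota[:, go] += params["I_go"]
    iota += T_matrix.T[:, None, :]
    return iota


def train_single_trial(
    data: ActivityTensor,
    basis: CodingBasis,
    P: int,
    weights: SingleTrialLossWeights | None = None,
    opt: OptimizerConfig | None = None,
    fit_dt: float | None = None,
    tau: float = 0.040,
    jitter: bool = True,
    stage_threshold: float = 0.10,
    epochs: dict[str, tuple[float, float]] | None = None,
    ablate_stimulus: bool = False,
) -> SingleTrialFit:
    """Jointly fit the network and the per-trial input biases.

    The condition-average (reconstruction) term is computed over hit trials
    of each condition; epoch-average and projection terms run over all
    trials.  The full loss suite is activated once the trial-averaged
    reconstruction falls below ``stage_threshold`` times its initial value;
    until then only reconstruction (plus alignment/orthogonality) trains.
    ``ablate_stimulus`` zeroes and freezes the tone inputs (control
    experiment).
    """
    weights = weights or SingleTrialLossWeights()
    opt = opt or OptimizerConfig()
    C = basis.n_coding
    if P < C:
        raise ValueError(f"P={P} must be at least C={C}")
    stride = 1 if fit_dt is None else int(round(fit_dt / data.dt))
    time, n_ext = _sim_grid(data.time, stride, jitter)
    dt = float(time[1] - time[0])
    if dt > tau / 4 + 1e-12:
        raise ValueError(f"fit dt={dt} too coarse; need <= tau/4")
    a = dt / tau
    y = data.rates[:, ::stride]  # (K, Td, N)
    K, Td, N = y.shape
    data_idx = slice(n_ext, n_ext + Td)
    cond = data.condition
    hits = data.outcome == 1
    epochs = epochs or default_epochs(data.span)
    e_masks = _epoch_masks(time[data_idx], epochs)

    spec_proto = InputSpec.zeros(P)
    spec_proto = InputSpec(
        spec_proto.I_low, spec_proto.I_high, spec_proto.I_go,
        tone_windows=data.tone_windows, go_window=data.go_window,
    )
    # initialize network parameters from the condition-averaged fit recipe
    y_avg = np.stack([
        y[(cond == c) & hits].mean(axis=0) for c in (0, 1)
    ])
    lick_profile_avg = None
    has_lick = data.lick_rate is not None
    if has_lick:
        prof = np.asarray(data.lick_rate, float)[::stride][:-1]
        lick_profile_avg = np.tile(prof, (2, 1))
    params = _init_params(
        y_avg, basis, P, time[data_idx], a, spec_proto, lick_profile_avg
    )
    params["T"] = np.zeros((P, K))
    if has_lick:
        params.setdefault("I_lick_left", np.zeros(N))
        params.setdefault("I_lick_right", np.zeros(N))
        # licks follow the executed (not instructed) side
        lick_side = np.where(hits, cond, 1 - cond)
        prof_full = np.zeros(time.size - 1)
        prof_full[n_ext : n_ext + Td - 1] = prof
        lick_rate_k = np.tile(prof_full, (K, 1))
    if ablate_stimulus:
        params["I_low"][:] = 0.0
        params["I_high"][:] = 0.0

    rng = np.random.default_rng(opt.seed)
    adam = _Adam(params, opt)
    records = []
    recon0 = None
    full_losses_on = False
    v_lda = basis.vectors  # (N, C)

    for it in range(opt.max_iterations):
        if jitter:
            starts = jittered_start(rng, K)
            start_idx = np.round((starts - time[0]) / dt).astype(np.int64)
            start_idx = np.clip(start_idx, 0, n_ext)
        else:
            start_idx = np.zeros(K, dtype=np.int64)
        iota = _trial_iota(time, params, spec_proto, cond, params["T"])
        lick_vec = None
        lick_rate = None
        if has_lick:
            lick_vec = np.where(
                lick_side[:, None] == 0,
                params["I_lick_left"][None, :],
                params["I_lick_right"][None, :],
            )
            lick_rate = lick_rate_k
        r0 = params["rmax"] / 2.0
        rates, caches = _bptt.forward(
            params["U"], params["A"], params["rmax"], r0, iota,
            start_idx=start_idx, a=a, lick_vec=lick_vec, lick_rate=lick_rate,
        )
        rd = rates[:, data_idx]  # (K, Td, N)
        g = np.zeros_like(rates)
        gd = g[:, data_idx]

        # trial-averaged (condition-average) reconstruction, hit trials
        l_recon = 0.0
        for c in (0, 1):
            sel = (cond == c) & hits
            nc = int(sel.sum())
            diff = rd[sel].mean(axis=0) - y_avg[c]
            l_recon += float(np.sum(diff * diff))
            gd[sel] += 2.0 * weights.c_recon * diff / nc
        if recon0 is None:
            recon0 = max(l_recon, 1e-12)
        if not full_losses_on and l_recon < stage_threshold * recon0:
            full_losses_on = True

        l_epoch = l_proj = 0.0
        dU_extra = np.zeros_like(params["U"])
        if full_losses_on:
            for mask in e_masks.values():
                nt = int(mask.sum())
                d = rd[:, mask].mean(axis=1) - y[:, mask].mean(axis=1)
                l_epoch += float(np.sum(d * d))
                gd[:, mask] += (2.0 * weights.c_epoch / nt) * d[:, None, :]
            mp = rd @ params["U"][:, :C]  # model projections (K, Td, C)
            dp = y @ v_lda
            e = mp - dp
            l_proj = float(np.sum(e * e))
            gd += 2.0 * weights.c_proj * (e @ params["U"][:, :C].T)
            dU_extra[:, :C] = 2.0 * weights.c_proj * np.einsum(
                "ktn,ktc->nc", rd, e
            )

        l_align = alignment_loss(params["U"][:, :3], v_lda)
        l_orth = orthogonality_loss(params["U"])
        l_reg = float(np.sum(params["T"] ** 2))
        total = (
            weights.c_recon * l_recon
            + weights.c_epoch * l_epoch
            + weights.c_proj * l_proj
            + weights.c_align * l_align
            + weights.c_orth * l_orth
            + weights.c_reg * l_reg
        )
        if not np.isfinite(total):
            raise FloatingPointError(f"training diverged at iteration {it}")

        dU, dA, drmax, diota, dlick, dr0 = _bptt.backward(
            params["U"], params["A"], params["rmax"], g, rates, caches, a=a
        )
        drmax = drmax + 0.5 * dr0
        dU = dU + dU_extra
        dU += weights.c_align * _alignment_grad(params["U"], v_lda, 2.0)
        dU += weights.c_orth * _orthogonality_grad(params["U"])
        tone, go = latent_input_schedule(time, spec_proto)
        left = cond == 0
        dT = diota.sum(axis=1).T + 2.0 * weights.c_reg * params["T"]
        grads = {
            "U": dU,
            "A": dA,
            "rmax": drmax,
            "T": dT,
            "I_low": diota[np.ix_(left, tone)].sum(axis=(0, 1)),
            "I_high": diota[np.ix_(~left, tone)].sum(axis=(0, 1)),
            "I_go": diota[:, go].sum(axis=(0, 1)),
        }
        if ablate_stimulus:
            grads["I_low"][:] = 0.0
            grads["I_high"][:] = 0.0
        if has_lick:
            grads["I_lick_left"] = dlick[lick_side == 0].sum(axis=0)
            grads["I_lick_right"] = dlick[lick_side == 1].sum(axis=0)
        lr_factor = 1.0
        if opt.lr_decay == "cosine":
            frac = it / max(opt.max_iterations - 1, 1)
            lr_factor = 0.05 + 0.95 * 0.5 * (1 + np.cos(np.pi * frac))
        adam.step(params, grads, lr_factor)
        np.maximum(params["rmax"], 0.5, out=params["rmax"])

        if it % opt.log_every == 0 or it == opt.max_iterations - 1:
            records.append(
                {
                    "iteration": it,
                    "loss_total": total,
                    "loss_recon": l_recon,
                    "loss_epoch": l_epoch,
                    "loss_proj": l_proj,
                    "loss_align": l_align,
                    "loss_orth": l_orth,
                    "loss_reg": l_reg,
                    "full_losses": float(full_losses_on),
                }
            )

    # exact QR reparameterization: orthonormal U, identical dynamics
    Q, R = np.linalg.qr(params["U"])
    s = np.sign(np.diag(R))
    Q, R = Q * s, (R.T * s).T
    params["U"] = Q
    params["A"] = R @ params["A"] @ R.T
    for key in ("I_low", "I_high", "I_go"):
        params[key] = R @ params[key]
    params["T"] = R @ params["T"]
    net = LowRankNetwork(
        U=params["U"], A=params["A"], rmax=params["rmax"], tau=tau, n_coding=C
    )
    spec = InputSpec(
        I_low=params["I_low"],
        I_high=params["I_high"],
        I_go=params["I_go"],
        I_lick_left=params.get("I_lick_left"),
        I_lick_right=params.get("I_lick_right"),
        lick_times=time[data_idx][:-1].copy() if has_lick else None,
        lick_rates=prof.copy() if has_lick else None,
        tone_windows=data.tone_windows,
        go_window=data.go_window,
    )
    bias = TrialBias(
        T_matrix=params["T"], condition=cond.copy(), outcome=data.outcome.copy()
    )
    return SingleTrialFit(
        network=net,
        input_spec=spec,
        trial_bias=bias,
        log=pd.DataFrame.from_records(records),
        time=time[data_idx],
    )


def fit_test_trial_biases(
    net: LowRankNetwork,
    spec: InputSpec,
    data: ActivityTensor,
    c_reg: float = 0.1,
    opt: OptimizerConfig | None = None,
    fit_dt: float | None = None,
) -> tuple[TrialBias, float]:
    """Optimize per-trial input biases with all network parameters frozen.

    Minimizes the per-trial squared error sum_kt ||r_kt - y_kt||^2 plus the
    L2 bias penalty; returns the fitted biases and the pooled explained
    variance on these (held-out) trials.
    """
    opt = opt or OptimizerConfig(learning_rate=5e-3, max_iterations=400)
    stride = 1 if fit_dt is None else int(round(fit_dt / data.dt))
    time = data.time[::stride]
    dt = float(time[1] - time[0])
    a = dt / net.tau
    y = data.rates[:, ::stride]
    K, Td, N = y.shape
    P = net.n_latent
    cond = data.condition
    params = {"T": np.zeros((P, K))}
    io_params = {"I_low": spec.I_low, "I_high": spec.I_high, "I_go": spec.I_go}

    has_lick = (
        spec.I_lick_left is not None and data.lick_rate is not None
    )
    lick_vec = lick_rate = None
    if has_lick:
        lick_side = np.where(data.outcome == 1, cond, 1 - cond)
        lick_vec = np.where(
            lick_side[:, None] == 0, spec.I_lick_left[None, :],
            spec.I_lick_right[None, :],
        )
        lick_rate = np.tile(
            np.asarray(data.lick_rate, float)[::stride][:-1], (K, 1)
        )

    adam = _Adam(params, opt)
    for it in range(opt.max_iterations):
        iota = _trial_iota(time, io_params, spec, cond, params["T"])
        rates, caches = _bptt.forward(
            net.U, net.A, net.rmax, net.rmax / 2.0, iota, a=a,
            lick_vec=lick_vec, lick_rate=lick_rate,
        )
        g = 2.0 * (rates - y)
        _, _, _, diota, _, _ = _bptt.backward(
            net.U, net.A, net.rmax, g, rates, caches, a=a
        )
        dT = diota.sum(axis=1).T + 2.0 * c_reg * params["T"]
        lr_factor = 1.0
        if opt.lr_decay == "cosine":
            frac = it / max(opt.max_iterations - 1, 1)
            lr_factor = 0.05 + 0.95 * 0.5 * (1 + np.cos(np.pi * frac))
        adam.step(params, {"T": dT}, lr_factor)
    iota = _trial_iota(time, io_params, spec, cond, params["T"])
    rates, _ = _bptt.forward(
        net.U, net.A, net.rmax, net.rmax / 2.0, iota, a=a,
        lick_vec=lick_vec, lick_rate=lick_rate,
    )
    ev = explained_variance(rates, y)
    return (
        TrialBias(
            T_matrix=params["T"],
            condition=cond.copy(),
            outcome=data.outcome.copy(),
        ),
        ev,
    )


def _fit_side_decoder(
    X: np.ndarray,
    miss: np.ndarray,
    rng: np.random.Generator,
    n_bootstrap: int,
    test_frac: float,
) -> tuple[np.ndarray, float, np.ndarray]:
    if len(np.unique(miss)) < 2:
        raise ValueError("need both hit and miss trials to estimate an error axis")
    # L2 strength by small stratified grid search on the training split
    Xtr, Xte, ytr, yte = train_test_split(
        X, miss, test_size=test_frac, stratify=miss,
        random_state=int(rng.integers(2**31)),
    )
    best_C, best_score = 1.0, -np.inf
    n_splits = max(2, min(3, int(np.bincount(ytr).min())))
    if n_splits >= 2 and np.bincount(ytr).min() >= 2:
        for Cval in (0.1, 1.0, 10.0):
            scores = []
            skf = StratifiedKFold(
                n_splits=n_splits, shuffle=True,
                random_state=int(rng.integers(2**31)),
            )
            for tr, va in skf.split(Xtr, ytr):
                clf = LogisticRegression(fit_intercept=False, C=Cval)
                clf.fit(Xtr[tr], ytr[tr])
                scores.append(clf.score(Xtr[va], ytr[va]))
            if np.mean(scores) > best_score:
                best_C, best_score = Cval, float(np.mean(scores))
    clf = LogisticRegression(fit_intercept=False, C=best_C)
    clf.fit(Xtr, ytr)
    acc = float(clf.score(Xte, yte))
    w = clf.coef_.ravel()
    w = w / np.linalg.norm(w)

    boots = []
    n80 = max(2, int(round(0.8 * X.shape[0])))
    for _ in range(n_bootstrap):
        idx = rng.choice(X.shape[0], size=n80, replace=True)
        if len(np.unique(miss[idx])) < 2:
            continue
        b = LogisticRegression(fit_intercept=False, C=best_C)
        b.fit(X[idx], miss[idx])
        bw = b.coef_.ravel()
        boots.append(bw / np.linalg.norm(bw) * np.sign(bw @ w))
    sd = np.std(boots, axis=0) if boots else np.full(X.shape[1], np.nan)
    return w, acc, sd


def estimate_error_axis(
    trial_bias: TrialBias,
    n_bootstrap: int = 1000,
    test_frac: float = 0.2,
    seed: int = 0,
) -> ErrorAxis:
    """Per-side no-intercept logistic decoders of hit vs miss on the biases.

    Features are the P-dimensional bias vectors; accuracy comes from a
    stratified 80/20 split and weight SDs from bootstrap resampling of 80%
    of the trials.  The normalized weights are the error axes.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for side, c in (("left", 0), ("right", 1)):
        sel = trial_bias.condition == c
        X = trial_bias.T_matrix[:, sel].T
        miss = (trial_bias.outcome[sel] == 0).astype(int)
        out[side] = _fit_side_decoder(X, miss, rng, n_bootstrap, test_frac)
    return ErrorAxis(
        weights_left=out["left"][0],
        weights_right=out["right"][0],
        accuracy_left=out["left"][1],
        accuracy_right=out["right"][1],
        bootstrap_sd_left=out["left"][2],
        bootstrap_sd_right=out["right"][2],
    )


def interpolate_error_axis(
    error_axis: np.ndarray, alpha: float, n_coding: int
) -> np.ndarray:
    """Unit bias vector I(alpha) = I_err - alpha I_coding + alpha I_residual.

    ``I_coding``/``I_residual`` are the error axis's components on the
    first ``n_coding`` latent coordinates and on the rest.  alpha = -1
    returns the normalized pure coding component, alpha = +1 the pure
    residual component, alpha = 0 the normalized axis itself.
    """
    if not -1.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [-1, 1]")
    v = np.asarray(error_axis, dtype=float).copy()
    cod = np.zeros_like(v)
    cod[:n_coding] = v[:n_coding]
    res = v - cod
    if np.linalg.norm(cod) == 0 or np.linalg.norm(res) == 0:
        raise ValueError(
            "error axis must have nonzero coding and residual components"
        )
    out = v - alpha * cod + alpha * res
    return out / np.linalg.norm(out)
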