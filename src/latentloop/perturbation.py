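"""Dimension-aligned, random-orthogonal, and neuron-targeted perturbations.

The causal probe of the model: brief (100 ms) input pulses along a latent
dimension u_l (I_pert = g u_l), along a random direction orthogonal to all
of U, or into a ranked subset of neurons, delivered during the delay while
the go cue is withheld.  The readout is the *choice flip rate*: with x_L,
x_R the unperturbed endpoints of the left/right trajectories projected on
the choice direction, a perturbed left trial counts as flipped to right
when its endpoint lands within the margin eps = 0.25 (x_R - x_L) of x_R
(and symmetrically for right trials).

Choice projections are reported relative to the network's zero-input
operating point phi(0) = rmax/2, so left/right carry opposite signs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import (
    DELAY_PERIOD,
    InputSpec,
    LowRankNetwork,
    Trajectory,
    transfer,
)

__all__ = [
    "PerturbationSpec",
    "FlipResult",
    "choice_projection",
    "perturb_dimension",
    "random_orthogonal_direction",
    "random_orthogonal_perturbation",
    "flip_rate",
    "flip_rate_sweep",
    "rank_neurons",
    "perturb_topk_neurons",
]

#: Simulations continue this long past the nominal go-cue time.
POST_GO_RUN = 0.9


@dataclass
class PerturbationSpec:
    """One perturbation protocol entry."""

    target: int | np.ndarray  # latent dimension index or explicit N-vector
    magnitude: float = 0.0
    window: tuple[float, float] = (DELAY_PERIOD[0], DELAY_PERIOD[0] + 0.100)
    n_trials: int = 40


@dataclass
class FlipResult:
    """Choice-flip counts under the symmetric margin rule."""

    epsilon: float
    x_L: float
    x_R: float
    flips_to_right: int
    flips_to_left: int
    n_trials: int
    rate: float


def choice_projection(
    rates: np.ndarray, net: LowRankNetwork, direction: np.ndarray | None = None
) -> np.ndarray:
    """Baseline-centered projection of rates onto the choice direction."""
    v = net.U[:, 1] if direction is None else np.asarray(direction, float)
    return (np.asarray(rates, float) - net.baseline_rates()) @ v


def _simulate_batch(
    net: LowRankNetwork,
    spec: InputSpec,
    conditions: np.ndarray,
    extra: np.ndarray,
    window: tuple[float, float],
    span: tuple[float, float],
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler roll-out of B runs with per-run constant extra input in window.

    ``conditions`` is (B,) of 0/1 (left/right), ``extra`` (B, N).  Returns
    (time, rates (B, T, N)).  Matches :func:`latentloop.simulate` step for
    step for each row.
    """
    U, A, rmax, tau = net.U, net.A, net.rmax, net.tau
    B = conditions.size
    n_steps = int(round((span[1] - span[0]) / dt))
    time = span[0] + dt * np.arange(n_steps + 1)
    right = conditions.astype(bool)
    lick_vecs = np.zeros((B, net.n_neurons))
    if spec.I_lick_left is not None and spec.I_lick_right is not None:
        lick_vecs[~right] = spec.I_lick_left
        lick_vecs[right] = spec.I_lick_right

    r = np.tile(net.baseline_rates(), (B, 1))
    rates = np.empty((B, time.size, net.n_neurons))
    rates[:, 0] = r
    eps = 1e-9
    for k in range(n_steps):
        t = time[k]
        lat = np.zeros((B, U.shape[1]))
        if any(w[0] - eps <= t < w[1] - eps for w in spec.tone_windows):
            lat[~right] = spec.I_low
            lat[right] = spec.I_high
        elif spec.go_window[0] - eps <= t < spec.go_window[1] - eps:
            lat[:] = spec.I_go
        h = ((r @ U) @ A.T + lat) @ U.T
        if window[0] - eps <= t < window[1] - eps:
            h = h + extra
        lick = spec.lick_rate(t)
        if lick != 0.0:
            h = h + lick_vecs * lick
        r = r + dt / tau * (-r + transfer(h, rmax))
        rates[:, k + 1] = r
    return time, rates


def _withheld_go(spec: InputSpec) -> InputSpec:
    """Withhold the go cue; no go also means no licks."""
    import dataclasses

    return dataclasses.replace(
        spec.without_go(), I_lick_left=None, I_lick_right=None,
        lick_times=None, lick_rates=None,
    )


def perturb_dimension(
    net: LowRankNetwork,
    spec: InputSpec,
    condition: str,
    target: int | np.ndarray,
    g: float,
    window: tuple[float, float] = (DELAY_PERIOD[0], DELAY_PERIOD[0] + 0.100),
    span_start: float = -3.0,
    dt: float = 0.005,
) -> Trajectory:
    """Perturbed trajectory: I_pert = g u_l during the window, go withheld.

    ``target`` is a latent dimension index (mapped to N-space through U) or
    an explicit length-N direction.  The run continues 0.9 s past the
    nominal go-cue time.
    """
    if isinstance(target, (int, np.integer)):
        direction = net.U[:, int(target)]
    else:
        direction = np.asarray(target, dtype=float)
        if direction.shape != (net.n_neurons,):
            raise ValueError("explicit perturbation direction must have length N")
    cond_idx = np.array([0 if condition == "left" else 1])
    go_time = spec.go_window[0]
    time, rates = _simulate_batch(
        net,
        _withheld_go(spec),
        cond_idx,
        (g * direction)[None, :],
        window,
        (span_start, go_time + POST_GO_RUN),
        dt,
    )
    return Trajectory(time=time, rates=rates[0], condition=condition)


def random_orthogonal_direction(
    net: LowRankNetwork, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Unit vector orthogonal to every column of U (via the QR complement)."""
    N, P = net.U.shape
    if P >= N:
        raise ValueError("no orthogonal complement: P >= N")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator
    ) else seed
    Q, _ = np.linalg.qr(net.U, mode="complete")
    U_perp = Q[:, P:]
    z = rng.standard_normal(N - P)
    d = U_perp @ z
    return d / np.linalg.norm(d)


def random_orthogonal_perturbation(
    net: LowRankNetwork,
    spec: InputSpec,
    condition: str,
    g: float,
    window: tuple[float, float] = (DELAY_PERIOD[0], DELAY_PERIOD[0] + 0.100),
    seed: int = 0,
    dt: float = 0.005,
) -> tuple[Trajectory, np.ndarray]:
    """Perturbation along a random direction in the orthocomplement of U."""
    direction = random_orthogonal_direction(net, seed)
    traj = perturb_dimension(
        net, spec, condition, direction, g, window=window, dt=dt
    )
    return traj, direction


def flip_rate(
    x_L: float,
    x_R: float,
    perturbed_left: np.ndarray | float = (),
    perturbed_right: np.ndarray | float = (),
) -> FlipResult:
    """Choice flips under the margin rule eps = 0.25 (x_R - x_L).

    ``perturbed_left``/``perturbed_right`` are the choice-projection
    endpoints of perturbed left/right trials.
    """
    if x_R == x_L:
        raise ValueError("degenerate unperturbed endpoints: x_R == x_L")
    eps = 0.25 * (x_R - x_L)
    xhat_L = np.atleast_1d(np.asarray(perturbed_left, dtype=float))
    xhat_R = np.atleast_1d(np.asarray(perturbed_right, dtype=float))
    to_right = int(np.sum(np.abs(xhat_L - x_R) < abs(eps)))
    to_left = int(np.sum(np.abs(xhat_R - x_L) < abs(eps)))
    n = xhat_L.size + xhat_R.size
    return FlipResult(
        epsilon=abs(eps),
        x_L=float(x_L),
        x_R=float(x_R),
        flips_to_right=to_right,
        flips_to_left=to_left,
        n_trials=n,
        rate=(to_right + to_left) / n if n else 0.0,
    )


def flip_rate_sweep(
    net: LowRankNetwork,
    spec: InputSpec,
    dims: list[int] | None = None,
    n_windows: int = 12,
    window_length: float = 0.100,
    magnitudes: np.ndarray | None = None,
    delay: tuple[float, float] = DELAY_PERIOD,
    choice_direction: np.ndarray | None = None,
    dt: float = 0.005,
    directions: np.ndarray | None = None,
) -> dict:
    """Full (dimension x window x magnitude) choice-flip sweep, go withheld.

    Windows are ``n_windows`` evenly spaced 100 ms intervals starting in the
    delay period; magnitudes default to 31 points in [-15, 15].  Endpoints
    are taken 0.9 s past the nominal go time.  ``directions`` (optional,
    (D, N)) overrides latent-dimension targets — used e.g. to perturb Schur
    modes via Q.  Returns a dict with the rate tensor and axis labels.
    """
    if magnitudes is None:
        magnitudes = np.linspace(-15.0, 15.0, 31)
    magnitudes = np.asarray(magnitudes, dtype=float)
    if directions is None:
        dims = list(range(net.n_latent)) if dims is None else list(dims)
        dir_mat = net.U[:, dims].T  # (D, N)
    else:
        dir_mat = np.asarray(directions, dtype=float)
        dims = list(range(dir_mat.shape[0]))
    starts = np.linspace(delay[0], delay[1] - window_length, n_windows)
    go_time = spec.go_window[0]
    spec_ng = _withheld_go(spec)
    span = (-3.0, go_time + POST_GO_RUN)

    # unperturbed endpoints
    _, base = _simulate_batch(
        net, spec_ng, np.array([0, 1]), np.zeros((2, net.n_neurons)),
        (0.0, 0.0), span, dt,
    )
    v = net.U[:, 1] if choice_direction is None else choice_direction
    base_proj = (base[:, -1] - net.baseline_rates()) @ v
    x_L, x_R = float(base_proj[0]), float(base_proj[1])

    D, M = dir_mat.shape[0], magnitudes.size
    rates_tensor = np.zeros((D, n_windows, M))
    # batch over (dim x magnitude x condition) per window
    gs = np.repeat(magnitudes[None, :], D, axis=0)  # (D, M)
    extra = gs[..., None] * dir_mat[:, None, :]  # (D, M, N)
    extra2 = np.repeat(extra.reshape(D * M, -1), 2, axis=0)
    conds = np.tile([0, 1], D * M)
    for wi, t0 in enumerate(starts):
        _, out = _simulate_batch(
            net, spec_ng, conds, extra2, (t0, t0 + window_length), span, dt
        )
        proj = (out[:, -1] - net.baseline_rates()) @ v
        proj = proj.reshape(D, M, 2)
        res = flip_rate  # margin rule per cell
        for di in range(D):
            for mi in range(M):
                fr = res(x_L, x_R, proj[di, mi, 0], proj[di, mi, 1])
                rates_tensor[di, wi, mi] = fr.rate
    return {
        "rates": rates_tensor,
        "dims": dims,
        "window_starts": starts,
        "magnitudes": magnitudes,
        "x_L": x_L,
        "x_R": x_R,
    }


def rank_neurons(U: np.ndarray, column: int | str) -> np.ndarray:
    """Neuron indices sorted by |loading| on a column of U, descending.

    ``column`` may be a latent index or 'choice' (column 1).  Ties are
    broken toward the lower neuron index (stable sort).
    """
    U = np.asarray(U, dtype=float)
    col = 1 if column == "choice" else int(column)
    return np.argsort(-np.abs(U[:, col]), kind="stable")


def perturb_topk_neurons(
    net: LowRankNetwork,
    spec: InputSpec,
    ranked: np.ndarray,
    K: int,
    alpha: float,
    window: tuple[float, float] = (DELAY_PERIOD[0], DELAY_PERIOD[0] + 0.100),
    measure_window: tuple[float, float] = (-0.100, 0.0),
    choice_direction: np.ndarray | None = None,
    dt: float = 0.005,
) -> dict:
    """K-hot perturbation: amplitude alpha/K to each of the top-K neurons.

    Runs both conditions with the standard go cue and reports the
    left/right separation on the choice projection averaged over the
    100 ms preceding the go cue, plus both trajectories.
    """
    if K < 1 or K > net.n_neurons:
        raise ValueError("K out of range")
    pert = np.zeros(net.n_neurons)
    pert[np.asarray(ranked)[:K]] = alpha / K
    time, out = _simulate_batch(
        net, spec, np.array([0, 1]), np.tile(pert, (2, 1)),
        window, (-3.0, 0.4), dt,
    )
    v = net.U[:, 1] if choice_direction is None else choice_direction
    proj = (out - net.baseline_rates()) @ v  # (2, T)
    mask = (time >= measure_window[0] - 1e-9) & (time < measure_window[1] - 1e-9)
    separation = float(np.abs(proj[0, mask] - proj[1, mask]).mean())
    return {
        "time": time,
        "trajectory_left": out[0],
        "trajectory_right": out[1],
        "input_vector": pert,
        "separation": separation,
    }
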