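"""Low-rank rate networks and their exact latent-space reduction.

The core model is a recurrent rate network

    tau dr/dt = -r + phi(J r + I(t)),    phi_i(x) = rmax_i/2 (tanh x + 1),

whose connectivity is constrained to be low rank, J = U A U^T, with U an
N x P (column-)orthonormal basis and A a P x P interaction matrix.  The
first ``C`` columns of U are task-coding directions (sample, choice,
response); the remaining ``R = P - C`` are residual directions.  Because
the recurrent drive J r = U A (U^T r) depends on the state only through
the latent projection m = U^T r, the latent dynamics

    tau dm/dt = -m + U^T phi(U A m + I(t))

are exactly closed in m, which is what makes the reduced description
faithful rather than approximate.

Inputs follow the delayed-response task schedule: three tone pulses during
the sample epoch, a go pulse at time zero (time is measured relative to
the go cue), and an optional lick-rate-weighted proprioceptive input that
is only active after the go cue.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "TONE_WINDOWS",
    "GO_WINDOW",
    "SAMPLE_PERIOD",
    "DELAY_PERIOD",
    "LowRankNetwork",
    "InputSpec",
    "Trajectory",
    "LatentTrajectory",
    "transfer",
    "transfer_gain",
    "build_connectivity",
    "task_input",
    "simulate",
    "simulate_latent",
    "project_latent",
]

# Task schedule, in seconds relative to the go cue.  Windows are half-open
# [start, end).
TONE_WINDOWS: tuple[tuple[float, float], ...] = (
    (-1.85, -1.70),
    (-1.60, -1.45),
    (-1.35, -1.20),
)
GO_WINDOW: tuple[float, float] = (0.0, 0.1)
SAMPLE_PERIOD: tuple[float, float] = (-1.85, -1.20)
DELAY_PERIOD: tuple[float, float] = (-1.20, 0.0)

_WINDOW_EPS = 1e-9


def _in_window(t: float, window: Sequence[float]) -> bool:
    return window[0] - _WINDOW_EPS <= t < window[1] - _WINDOW_EPS


@dataclass
class LowRankNetwork:
    """Rate network with connectivity J = U A U^T.

    Parameters
    ----------
    U : (N, P) array
        Orthonormal columns; the first ``n_coding`` are coding directions.
    A : (P, P) array
        Latent interaction matrix (generally non-normal).
    rmax : (N,) array
        Per-neuron maximum firing rate in spikes/s, strictly positive.
    tau : float
        Membrane/integration time constant in seconds (default 40 ms).
    n_coding : int
        Number of coding columns C (default 3: sample, choice, response).
    """

    U: np.ndarray
    A: np.ndarray
    rmax: np.ndarray
    tau: float = 0.040
    n_coding: int = 3

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.rmax = np.asarray(self.rmax, dtype=float)
        if self.U.ndim != 2:
            raise ValueError("U must be an N x P matrix")
        N, P = self.U.shape
        if self.A.shape != (P, P):
            raise ValueError(f"A must be {P} x {P}, got {self.A.shape}")
        if self.rmax.shape != (N,):
            raise ValueError(f"rmax must have length {N}")
        if np.any(self.rmax <= 0):
            raise ValueError("rmax must be strictly positive")
        if not (0 < self.n_coding <= P <= N):
            raise ValueError("need 0 < C <= P <= N")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    @property
    def n_neurons(self) -> int:
        return self.U.shape[0]

    @property
    def n_latent(self) -> int:
        return self.U.shape[1]

    @property
    def n_residual(self) -> int:
        return self.U.shape[1] - self.n_coding

    def orthonormality_defect(self) -> float:
        P = self.n_latent
        return float(np.linalg.norm(np.eye(P) - self.U.T @ self.U))

    def connectivity(self) -> np.ndarray:
        """Materialize the dense N x N connectivity J = U A U^T."""
        return build_connectivity(self.U, self.A)

    def baseline_rates(self) -> np.ndarray:
        """phi(0) = rmax/2, the zero-input operating point."""
        return self.rmax / 2.0


@dataclass
class InputSpec:
    """Task input parameters for one network.

    ``I_low``/``I_high``/``I_go`` are latent (length-P) input vectors mapped
    into neural space through U; the lick inputs are full length-N vectors
    weighted by the measured lick rate and are zero for t <= 0.
    """

    I_low: np.ndarray
    I_high: np.ndarray
    I_go: np.ndarray
    I_lick_left: np.ndarray | None = None
    I_lick_right: np.ndarray | None = None
    lick_times: np.ndarray | None = None
    lick_rates: np.ndarray | None = None
    tone_windows: tuple[tuple[float, float], ...] = TONE_WINDOWS
    go_window: tuple[float, float] = GO_WINDOW

    def __post_init__(self) -> None:
        self.I_low = np.asarray(self.I_low, dtype=float)
        self.I_high = np.asarray(self.I_high, dtype=float)
        self.I_go = np.asarray(self.I_go, dtype=float)
        if not (self.I_low.shape == self.I_high.shape == self.I_go.shape):
            raise ValueError("latent input vectors must share shape (P,)")

    @classmethod
    def zeros(cls, P: int) -> "InputSpec":
        return cls(np.zeros(P), np.zeros(P), np.zeros(P))

    def without_go(self) -> "InputSpec":
        """Copy of the spec with the go input removed (withheld go cue)."""
        return replace(self, I_go=np.zeros_like(self.I_go))

    def with_go_window(self, window: tuple[float, float]) -> "InputSpec":
        return replace(self, go_window=window)

    def lick_rate(self, t: float) -> float:
        """Interpolated lick rate; zero for t <= 0 or if no series given."""
        if t <= 0 or self.lick_times is None or self.lick_rates is None:
            return 0.0
        return float(np.interp(t, self.lick_times, self.lick_rates))


@dataclass
class Trajectory:
    """Simulated firing rates on a time grid (rates in spikes/s)."""

    time: np.ndarray
    rates: np.ndarray  # (T, N)
    condition: str = ""

    def final_state(self) -> np.ndarray:
        return self.rates[-1]


@dataclass
class LatentTrajectory:
    """Latent variables m(t) = U^T r(t) on a time grid."""

    time: np.ndarray
    m: np.ndarray  # (T, P)
    condition: str = ""


def transfer(x: np.ndarray, rmax: np.ndarray | float) -> np.ndarray:
    """Saturating transfer function phi(x) = rmax/2 (tanh x + 1)."""
    return 0.5 * np.asarray(rmax) * (np.tanh(x) + 1.0)


def transfer_gain(x: np.ndarray, rmax: np.ndarray | float) -> np.ndarray:
    """Derivative phi'(x) = rmax/2 (1 - tanh^2 x)."""
    th = np.tanh(x)
    return 0.5 * np.asarray(rmax) * (1.0 - th * th)


def build_connectivity(U: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Dense low-rank connectivity J_ij = sum_{l,l'} A_{ll'} u_i^l u_j^{l'}."""
    U = np.asarray(U, dtype=float)
    A = np.asarray(A, dtype=float)
    if U.ndim != 2 or A.shape != (U.shape[1], U.shape[1]):
        raise ValueError(
            f"shape mismatch: U is {U.shape}, A is {A.shape}; need A = P x P"
        )
    return U @ A @ U.T


def _latent_task_input(t: float, condition: str, spec: InputSpec) -> np.ndarray:
    if condition not in ("left", "right"):
        raise ValueError(f"unknown condition label: {condition!r}")
    for w in spec.tone_windows:
        if _in_window(t, w):
            # Convention: left trials are cued by the low tone.
            return spec.I_low if condition == "left" else spec.I_high
    if _in_window(t, spec.go_window):
        return spec.I_go
    return np.zeros_like(spec.I_go)


def task_input(
    t: float, condition: str, spec: InputSpec, U: np.ndarray
) -> np.ndarray:
    """External input vector I(t) in neural space for one condition.

    Tone and go inputs are latent vectors mapped through U; the lick input
    (if configured) adds ``I_lick_side * lick_rate(t)`` for t > 0.
    """
    I = U @ _latent_task_input(t, condition, spec)
    rate = spec.lick_rate(t)
    if rate != 0.0:
        lick = spec.I_lick_left if condition == "left" else spec.I_lick_right
        if lick is not None:
            I = I + np.asarray(lick, dtype=float) * rate
    return I


def _make_grid(span: tuple[float, float], dt: float) -> np.ndarray:
    t0, t1 = span
    n_steps = int(round((t1 - t0) / dt))
    if n_steps < 1 or t1 <= t0:
        raise ValueError("empty simulation span")
    return t0 + dt * np.arange(n_steps + 1)


def simulate(
    net: LowRankNetwork,
    spec: InputSpec,
    condition: str,
    span: tuple[float, float] = (-3.0, 0.4),
    dt: float = 0.005,
    initial_state: np.ndarray | None = None,
    extra_input: Callable[[float], np.ndarray] | None = None,
    method: str = "euler",
) -> Trajectory:
    """Integrate tau dr/dt = -r + phi(J r + I(t)) on a fixed grid.

    Forward Euler by default (``method='rk4'`` for the higher-order
    integrator); the recurrent drive is applied in factored form
    U (A (U^T r)) so the dense J is never materialized.  ``extra_input``
    is an optional time-dependent additive input (used for perturbations
    and trial biases).
    """
    if dt > net.tau / 4 + 1e-12:
        raise ValueError(f"dt={dt} too coarse; need dt <= tau/4 = {net.tau / 4}")
    if method not in ("euler", "rk4"):
        raise ValueError(f"unknown integration method {method!r}")
    time = _make_grid(span, dt)
    N = net.n_neurons
    U, A, rmax, tau = net.U, net.A, net.rmax, net.tau

    r = net.baseline_rates().copy() if initial_state is None else np.asarray(
        initial_state, dtype=float
    ).copy()
    if r.shape != (N,):
        raise ValueError("initial_state must have length N")

    def drive(t: float) -> np.ndarray:
        I = task_input(t, condition, spec, U)
        if extra_input is not None:
            I = I + extra_input(t)
        return I

    def flow(t: float, state: np.ndarray) -> np.ndarray:
        h = U @ (A @ (U.T @ state)) + drive(t)
        return (-state + transfer(h, rmax)) / tau

    rates = np.empty((time.size, N))
    rates[0] = r
    for k in range(time.size - 1):
        t = time[k]
        if method == "euler":
            r = r + dt * flow(t, r)
        else:
            k1 = flow(t, r)
            k2 = flow(t + dt / 2, r + dt / 2 * k1)
            k3 = flow(t + dt / 2, r + dt / 2 * k2)
            k4 = flow(t + dt, r + dt * k3)
            r = r + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(r)):
            raise FloatingPointError(
                f"non-finite state at t={time[k + 1]:.4f}s (condition {condition})"
            )
        rates[k + 1] = r
    return Trajectory(time=time, rates=rates, condition=condition)


def simulate_latent(
    net: LowRankNetwork,
    spec: InputSpec,
    condition: str,
    span: tuple[float, float] = (-3.0, 0.4),
    dt: float = 0.005,
    initial_m: np.ndarray | None = None,
    extra_input: Callable[[float], np.ndarray] | None = None,
) -> LatentTrajectory:
    """Integrate the exact P-dimensional latent ODE.

    tau dm/dt = -m + U^T phi(U A m + I(t)), with the full per-neuron sum
    over nonlinearities (heterogeneous rmax respected).  With matching
    initial latent state this reproduces U^T r(t) of :func:`simulate`
    step for step under forward Euler.
    """
    if dt > net.tau / 4 + 1e-12:
        raise ValueError(f"dt={dt} too coarse; need dt <= tau/4 = {net.tau / 4}")
    time = _make_grid(span, dt)
    U, A, rmax, tau = net.U, net.A, net.rmax, net.tau
    P = net.n_latent
    m = (
        U.T @ net.baseline_rates()
        if initial_m is None
        else np.asarray(initial_m, dtype=float).copy()
    )
    if m.shape != (P,):
        raise ValueError("initial_m must have length P")

    ms = np.empty((time.size, P))
    ms[0] = m
    for k in range(time.size - 1):
        t = time[k]
        I = task_input(t, condition, spec, U)
        if extra_input is not None:
            I = I + extra_input(t)
        h = U @ (A @ m) + I
        m = m + dt / tau * (-m + U.T @ transfer(h, rmax))
        ms[k + 1] = m
    return LatentTrajectory(time=time, m=ms, condition=condition)


def project_latent(traj: Trajectory, U: np.ndarray) -> LatentTrajectory:
    """Latent variables m(t) = U^T r(t) of a simulated trajectory."""
    U = np.asarray(U, dtype=float)
    if traj.rates.shape[1] != U.shape[0]:
        raise ValueError("trajectory and basis disagree on neuron count")
    return LatentTrajectory(
        time=traj.time, m=traj.rates @ U, condition=traj.condition
    )
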