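"""Fixed-point attractors under a withheld go cue, and their stability.

When the go cue never arrives, a well-trained network settles into one of
two condition-selective attractor states.  This module locates those
states by simulation (optionally polished by Newton's method), linearizes
the dynamics around them — the Jacobian of tau dr/dt = -r + phi(J r + I)
is M = -I + D J with D the diagonal of transfer-function gains — and
classifies stability from the largest real part of M's spectrum.  It also
simulates catch trials, in which the go cue is delayed past the nominal
delay end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .network import (
    InputSpec,
    LowRankNetwork,
    Trajectory,
    simulate,
    transfer,
    transfer_gain,
)
from .perturbation import _withheld_go, choice_projection

__all__ = [
    "FixedPointReport",
    "find_fixed_point",
    "jacobian",
    "reduced_jacobian_eigs",
    "stability_spectrum",
    "catch_trial",
]

#: Default extraction time, seconds after the nominal go cue.
EXTRACTION_TIME = 1.05
STABILITY_TOL = 1e-4


@dataclass
class FixedPointReport:
    """A candidate fixed point and its local linearization."""

    state: np.ndarray
    condition: str
    residual: float
    converged: bool
    gains: np.ndarray  # diagonal of D at the state
    jacobian_eigs: np.ndarray | None = None
    max_real: float | None = None


def _flow_residual(
    net: LowRankNetwork, r: np.ndarray, I: np.ndarray
) -> np.ndarray:
    h = net.U @ (net.A @ (net.U.T @ r)) + I
    return -r + transfer(h, net.rmax)


def find_fixed_point(
    net: LowRankNetwork,
    spec: InputSpec,
    condition: str,
    extraction_time: float = EXTRACTION_TIME,
    dt: float = 0.005,
    span_start: float = -3.0,
    tol: float = 1e-6,
    polish: bool = False,
) -> FixedPointReport:
    """Simulate with the go cue withheld and extract the late network state.

    The state at ``extraction_time`` after the nominal go cue is the
    candidate fixed point; its residual ||-r + phi(Jr)|| / ||r|| decides
    convergence.  ``polish=True`` refines it by Newton root-finding with
    the analytic Jacobian.
    """
    spec_ng = _withheld_go(spec)
    go_time = spec.go_window[0]
    traj = simulate(
        net, spec_ng, condition, span=(span_start, go_time + extraction_time),
        dt=dt,
    )
    r = traj.rates[-1].copy()
    I = np.zeros(net.n_neurons)  # withheld go, no licks: zero late input
    if polish:
        sol = scipy.optimize.root(
            lambda x: _flow_residual(net, x, I),
            r,
            jac=lambda x: jacobian(net, x, I),
            method="hybr",
        )
        if sol.success:
            r = sol.x
    res = float(np.linalg.norm(_flow_residual(net, r, I)) / max(np.linalg.norm(r), 1e-12))
    h = net.U @ (net.A @ (net.U.T @ r)) + I
    return FixedPointReport(
        state=r,
        condition=condition,
        residual=res,
        converged=res < tol,
        gains=transfer_gain(h, net.rmax),
    )


def jacobian(
    net: LowRankNetwork, state: np.ndarray, input_vec: np.ndarray | None = None
) -> np.ndarray:
    """Linearization M = -I + D J at a state (time in units of tau).

    D_ii = (rmax_i / 2)(1 - tanh^2 h_i) with h_i the input current at the
    state; J = U A U^T.
    """
    state = np.asarray(state, dtype=float)
    I = np.zeros(net.n_neurons) if input_vec is None else input_vec
    h = net.U @ (net.A @ (net.U.T @ state)) + I
    D = transfer_gain(h, net.rmax)
    J = net.U @ net.A @ net.U.T
    return -np.eye(net.n_neurons) + D[:, None] * J


def reduced_jacobian_eigs(
    net: LowRankNetwork, state: np.ndarray, input_vec: np.ndarray | None = None
) -> np.ndarray:
    """Nontrivial eigenvalues of M via the P x P reduction.

    M = -I + D U A U^T has eigenvalue -1 with multiplicity N - P; the rest
    are the eigenvalues of -I_P + (U^T D U) A.  Used for N too large to
    diagonalize directly.
    """
    I = np.zeros(net.n_neurons) if input_vec is None else input_vec
    h = net.U @ (net.A @ (net.U.T @ state)) + I
    D = transfer_gain(h, net.rmax)
    core = -np.eye(net.n_latent) + (net.U.T * D) @ net.U @ net.A
    return np.linalg.eigvals(core)


def stability_spectrum(
    net: LowRankNetwork,
    report: FixedPointReport,
    dense_limit: int = 2000,
) -> FixedPointReport:
    """Attach the Jacobian spectrum and a stability verdict to a report.

    Stable iff the largest real part is below -1e-4; values within
    +/- 1e-4 of zero are marginal (reported via ``verdict`` attribute on
    the returned report's ``max_real``).
    """
    if net.n_neurons <= dense_limit:
        eigs = np.linalg.eigvals(jacobian(net, report.state))
    else:
        reduced = reduced_jacobian_eigs(net, report.state)
        eigs = np.concatenate([reduced, [-1.0 + 0j]])
    report.jacobian_eigs = eigs
    report.max_real = float(np.max(np.real(eigs)))
    return report


def stability_verdict(max_real: float, tol: float = STABILITY_TOL) -> str:
    if max_real < -tol:
        return "stable"
    if max_real <= tol:
        return "marginal"
    return "unstable"


def catch_trial(
    net: LowRankNetwork,
    spec: InputSpec,
    condition: str,
    go_time: float,
    span_end: float | None = None,
    dt: float = 0.005,
    choice_direction: np.ndarray | None = None,
) -> tuple[Trajectory, np.ndarray]:
    """Trial with the go cue delayed to ``go_time`` (inf = withheld).

    Returns the trajectory and its baseline-centered choice projection over
    the extended delay.  ``go_time`` may not precede the nominal go cue.
    """
    nominal = spec.go_window[0]
    width = spec.go_window[1] - spec.go_window[0]
    if np.isinf(go_time):
        spec_run = _withheld_go(spec)
        end = span_end if span_end is not None else nominal + EXTRACTION_TIME
    else:
        if go_time < nominal - 1e-12:
            raise ValueError("catch-trial go cue cannot precede the nominal one")
        import dataclasses

        spec_run = spec.with_go_window((go_time, go_time + width))
        if spec_run.lick_times is not None:
            spec_run = dataclasses.replace(
                spec_run, lick_times=spec_run.lick_times + (go_time - nominal)
            )
        end = span_end if span_end is not None else go_time + 0.4
    traj = simulate(net, spec_run, condition, span=(-3.0, end), dt=dt)
    proj = choice_projection(traj.rates, net, choice_direction)
    return traj, proj
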