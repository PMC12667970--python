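"""Two-area model: low-rank cortex reciprocally coupled to a non-recurrent
thalamus through low-dimensional bottlenecks.

Cortex follows the usual low-rank rate dynamics with recurrence
J_cc = U_c A_cc U_c^T; the thalamus has no recurrent connectivity and a
time constant one third of the cortical one.  The inter-area projections
are rank-limited products

    J_ct = U_c  W_ct_post  B_ct  W_ct_pre  U_th^T     (thalamus -> cortex)
    J_tc = U_th W_tc_post  B_tc  W_tc_pre  U_c^T      (cortex -> thalamus)

so only a P_ct- (resp. P_tc-) dimensional subspace of activity crosses the
loop; the remaining dimensions stay private to each area.  Task routing
follows the physiology: the sample tones drive cortex, the go cue drives
thalamus.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .network import (
    GO_WINDOW,
    TONE_WINDOWS,
    InputSpec,
    LowRankNetwork,
    Trajectory,
    transfer,
)
from .synthetic import _orthonormal_basis

__all__ = [
    "TwoAreaNetwork",
    "bottleneck_connectivity",
    "simulate_loop",
    "disconnect",
    "activity_reduction",
    "thalamic_perturbation_sweep",
    "make_ground_truth_two_area",
]


@dataclass
class TwoAreaNetwork:
    """Cortex + thalamus with bottleneck-coupled projections."""

    cortex: LowRankNetwork
    U_th: np.ndarray  # (N_th, P_th), orthonormal columns
    rmax_th: np.ndarray  # (N_th,)
    ct_pre: np.ndarray  # (P_ct, P_th)  readout from thalamic latents
    B_ct: np.ndarray  # (P_ct, P_ct)
    ct_post: np.ndarray  # (P_c, P_ct)  projection into cortical latents
    tc_pre: np.ndarray  # (P_tc, P_c)
    B_tc: np.ndarray  # (P_tc, P_tc)
    tc_post: np.ndarray  # (P_th, P_tc)
    spec_cortex: InputSpec  # tones (and licks) routed to cortex; no go
    I_go_th: np.ndarray  # (P_th,) go input routed to thalamus
    go_window: tuple[float, float] = GO_WINDOW

    def __post_init__(self) -> None:
        P_c = self.cortex.n_latent
        P_th = self.U_th.shape[1]
        P_ct = self.B_ct.shape[0]
        P_tc = self.B_tc.shape[0]
        if self.ct_pre.shape != (P_ct, P_th) or self.ct_post.shape != (P_c, P_ct):
            raise ValueError("thalamocortical bottleneck shapes inconsistent")
        if self.tc_pre.shape != (P_tc, P_c) or self.tc_post.shape != (P_th, P_tc):
            raise ValueError("corticothalamic bottleneck shapes inconsistent")
        if P_ct > min(P_th, P_c) or P_tc > min(P_c, P_th):
            raise ValueError("bottleneck dimension exceeds an area's latent dim")

    @property
    def tau_th(self) -> float:
        return self.cortex.tau / 3.0

    @property
    def n_thalamus(self) -> int:
        return self.U_th.shape[0]

    def J_ct(self) -> np.ndarray:
        return bottleneck_connectivity(
            self.cortex.U, self.ct_post, self.B_ct, self.ct_pre, self.U_th
        )

    def J_tc(self) -> np.ndarray:
        return bottleneck_connectivity(
            self.U_th, self.tc_post, self.B_tc, self.tc_pre, self.cortex.U
        )


def bottleneck_connectivity(
    U_post: np.ndarray,
    post_map: np.ndarray,
    B: np.ndarray,
    pre_map: np.ndarray,
    U_pre: np.ndarray,
) -> np.ndarray:
    """Inter-area matrix U_post post_map B pre_map U_pre^T (rank <= dim B)."""
    U_post, U_pre = np.asarray(U_post, float), np.asarray(U_pre, float)
    post_map, B, pre_map = (
        np.asarray(post_map, float),
        np.asarray(B, float),
        np.asarray(pre_map, float),
    )
    try:
        return U_post @ post_map @ B @ pre_map @ U_pre.T
    except ValueError as exc:
        raise ValueError(f"bottleneck shape mismatch: {exc}") from exc


def simulate_loop(
    net: TwoAreaNetwork,
    condition: str,
    span: tuple[float, float] = (-3.0, 0.4),
    dt: float = 0.0025,
    withhold_go: bool = False,
    extra_input_th: np.ndarray | None = None,
    extra_window: tuple[float, float] = (0.0, 0.0),
) -> tuple[Trajectory, Trajectory]:
    """Coupled Euler integration of the loop.

    The tones drive cortex through its InputSpec; the go pulse drives the
    thalamus (latent vector ``I_go_th`` through U_th).  ``extra_input_th``
    (length N_th) is added to the thalamic drive inside ``extra_window`` —
    the thalamic perturbation hook.
    """
    cx = net.cortex
    tau_th = net.tau_th
    if dt > tau_th / 4 + 1e-12:
        raise ValueError(f"dt={dt} too coarse; need dt <= tau_th/4 = {tau_th / 4}")
    if condition not in ("left", "right"):
        raise ValueError(f"unknown condition label: {condition!r}")
    n_steps = int(round((span[1] - span[0]) / dt))
    time = span[0] + dt * np.arange(n_steps + 1)

    U_c, A_cc, rmax_c, tau_c = cx.U, cx.A, cx.rmax, cx.tau
    U_th, rmax_th = net.U_th, net.rmax_th
    # factored inter-area maps
    M_ct = net.ct_post @ net.B_ct @ net.ct_pre  # (P_c, P_th)
    M_tc = net.tc_post @ net.B_tc @ net.tc_pre  # (P_th, P_c)

    spec = net.spec_cortex
    tone_lat = spec.I_low if condition == "left" else spec.I_high
    eps = 1e-9
    r_c = rmax_c / 2.0
    r_t = rmax_th / 2.0
    T = time.size
    rates_c = np.empty((T, cx.n_neurons))
    rates_t = np.empty((T, net.n_thalamus))
    rates_c[0], rates_t[0] = r_c, r_t
    for k in range(n_steps):
        t = time[k]
        lat_c = np.zeros(cx.n_latent)
        if any(w[0] - eps <= t < w[1] - eps for w in spec.tone_windows):
            lat_c = tone_lat
        I_c = U_c @ (A_cc @ (U_c.T @ r_c) + M_ct @ (U_th.T @ r_t) + lat_c)
        lick = spec.lick_rate(t)
        if lick != 0.0 and spec.I_lick_left is not None:
            vec = spec.I_lick_left if condition == "left" else spec.I_lick_right
            I_c = I_c + vec * lick
        lat_t = np.zeros(U_th.shape[1])
        if (
            not withhold_go
            and net.go_window[0] - eps <= t < net.go_window[1] - eps
        ):
            lat_t = net.I_go_th
        I_t = U_th @ (M_tc @ (U_c.T @ r_c) + lat_t)
        if extra_input_th is not None and (
            extra_window[0] - eps <= t < extra_window[1] - eps
        ):
            I_t = I_t + extra_input_th
        r_c = r_c + dt / tau_c * (-r_c + transfer(I_c, rmax_c))
        r_t = r_t + dt / tau_th * (-r_t + transfer(I_t, rmax_th))
        if not (np.all(np.isfinite(r_c)) and np.all(np.isfinite(r_t))):
            raise FloatingPointError(f"non-finite state at t={time[k + 1]:.4f}s")
        rates_c[k + 1], rates_t[k + 1] = r_c, r_t
    return (
        Trajectory(time=time, rates=rates_c, condition=condition),
        Trajectory(time=time, rates=rates_t, condition=condition),
    )


def disconnect(net: TwoAreaNetwork, which: str) -> TwoAreaNetwork:
    """Copy of the network with one projection severed (bottleneck zeroed).

    ``which`` is 'ct' (thalamus -> cortex) or 'tc' (cortex -> thalamus).
    Idempotent.
    """
    if which == "ct":
        return replace(net, B_ct=np.zeros_like(net.B_ct))
    if which == "tc":
        return replace(net, B_tc=np.zeros_like(net.B_tc))
    raise ValueError("which must be 'ct' or 'tc'")


def activity_reduction(
    net: TwoAreaNetwork,
    which: str,
    condition: str = "right",
    delay: tuple[float, float] = (-1.2, 0.0),
    span: tuple[float, float] = (-3.0, 0.4),
    dt: float = 0.0025,
) -> dict[str, float]:
    """Delay-period activity ratio (disconnected / intact) per area.

    Activity is the mean absolute deviation of rates from the zero-input
    operating point phi(0) during the delay.
    """
    def _measure(n: TwoAreaNetwork) -> tuple[float, float]:
        tc, tt = simulate_loop(n, condition, span=span, dt=dt)
        mask = (tc.time >= delay[0] - 1e-9) & (tc.time < delay[1] - 1e-9)
        base_c = n.cortex.baseline_rates()
        base_t = n.rmax_th / 2.0
        return (
            float(np.abs(tc.rates[mask] - base_c).mean()),
            float(np.abs(tt.rates[mask] - base_t).mean()),
        )

    c0, t0 = _measure(net)
    c1, t1 = _measure(disconnect(net, which))
    return {
        "cortex_ratio": c1 / max(c0, 1e-12),
        "thalamus_ratio": t1 / max(t0, 1e-12),
    }


def thalamic_perturbation_sweep(
    net: TwoAreaNetwork,
    choice_axis_th: np.ndarray,
    mode: str = "random-residual",
    n_directions: int = 120,
    magnitudes: np.ndarray | None = None,
    window: tuple[float, float] = (-1.2, -1.1),
    span: tuple[float, float] = (-3.0, 0.4),
    dt: float = 0.0025,
    seed: int = 0,
    conditions: tuple[str, ...] = ("left", "right"),
) -> dict:
    """Thalamic perturbations along the choice axis or random residual
    directions; effect = MSE between perturbed and unperturbed activity.

    ``choice_axis_th`` is the thalamic choice direction (length N_th).
    Residual directions are unit Gaussian vectors inside span(U_th) but
    orthogonal to the choice axis.  Defaults: 40 magnitudes linearly spaced
    in [1, 6]; 120 random directions.  MSE pools both areas and conditions.
    """
    if magnitudes is None:
        magnitudes = np.linspace(1.0, 6.0, 40)
    magnitudes = np.asarray(magnitudes, float)
    rng = np.random.default_rng(seed)
    v = np.asarray(choice_axis_th, float)
    v = v / np.linalg.norm(v)
    if mode == "choice-axis":
        dirs = v[None, :]
    elif mode == "random-residual":
        U_th = net.U_th
        dirs = np.empty((n_directions, net.n_thalamus))
        for i in range(n_directions):
            z = rng.standard_normal(U_th.shape[1])
            d = U_th @ z
            d -= (d @ v) * v  # stay off the choice axis
            dirs[i] = d / np.linalg.norm(d)
    else:
        raise ValueError("mode must be 'choice-axis' or 'random-residual'")

    base = {
        c: simulate_loop(net, c, span=span, dt=dt) for c in conditions
    }
    mse = np.zeros((dirs.shape[0], magnitudes.size))
    for di, d in enumerate(dirs):
        for mi, g in enumerate(magnitudes):
            err, count = 0.0, 0
            for c in conditions:
                pc, pt = simulate_loop(
                    net, c, span=span, dt=dt,
                    extra_input_th=g * d, extra_window=window,
                )
                bc, bt = base[c]
                err += float(np.sum((pc.rates - bc.rates) ** 2)) + float(
                    np.sum((pt.rates - bt.rates) ** 2)
                )
                count += pc.rates.size + pt.rates.size
            mse[di, mi] = err / count
    return {"mse": mse, "magnitudes": magnitudes, "directions": dirs, "mode": mode}


def make_ground_truth_two_area(
    N_cortex: int = 60,
    N_thalamus: int = 40,
    P_cortex: int = 10,
    P_thalamus: int = 10,
    P_ct: int = 5,
    P_tc: int = 5,
    seed: int = 0,
    loop_gain: float = 1.12,
    local_gain: float = 0.40,
    relay_selectivity: float = 0.15,
    rmax: float = 40.0,
) -> TwoAreaNetwork:
    """Constructed two-area ground truth whose delay activity lives in the loop.

    The cortical choice dimension has only weak local recurrence
    (``local_gain`` < 1); persistent selectivity arises through the loop,
    with round-trip gain ``loop_gain`` > 1.  Two thalamic pathways mirror
    the dissociation seen in fitted models: cortical choice drives a
    strongly selective thalamic dimension (latent 1, which the delay-period
    discriminant will find as the thalamic choice axis) that does NOT
    project back, and — weakly (``relay_selectivity``) — a residual relay
    dimension (latent 3) whose return projection to the cortical choice
    latent is amplified.  Severing either projection collapses delay
    activity; perturbing the weakly selective residual relay disrupts
    cortex far more than perturbing the thalamic choice axis.
    """
    rng = np.random.default_rng(seed)
    U_c = _orthonormal_basis(rng, N_cortex, P_cortex)
    U_th = _orthonormal_basis(rng, N_thalamus, P_thalamus)
    rmax_c = np.full(N_cortex, float(rmax))
    rmax_th = np.full(N_thalamus, float(rmax))
    half = rmax / 2.0

    # cortical local gain: sample feeds choice, everything subcritical alone
    gain_cc = np.zeros((P_cortex, P_cortex))
    gain_cc[0, 0] = 0.10
    gain_cc[1, 1] = local_gain
    gain_cc[1, 0] = 1.20
    gain_cc[2, 1] = 0.50
    for r in range(3, P_cortex):
        gain_cc[r, r] = 0.30
    A_cc = gain_cc / half

    # cortex -> thalamus: the choice latent drives the selective thalamic
    # dimension (dead end) and, weakly, the residual relay; the sample
    # latent is relayed to its own thalamic dimension so the thalamic
    # sample and choice discriminants are distinct directions
    tc_pre = np.zeros((P_tc, P_cortex))
    tc_pre[0, 1] = 1.0  # read out cortical choice
    tc_pre[1, 0] = 1.0  # read out cortical sample
    B_tc = np.eye(P_tc)
    tc_post = np.zeros((P_thalamus, P_tc))
    tc_post[1, 0] = 0.40 / half  # selective thalamic dimension (dead end)
    tc_post[3, 0] = relay_selectivity / half  # weakly selective relay
    tc_post[2, 1] = 0.80 / half  # thalamic sample relay (dead end)

    # thalamus -> cortex: only the residual relay returns, amplified so the
    # round-trip gain closes at loop_gain
    g_return = (loop_gain - local_gain) / relay_selectivity
    ct_pre = np.zeros((P_ct, P_thalamus))
    ct_pre[0, 3] = 1.0
    B_ct = np.eye(P_ct)
    ct_post = np.zeros((P_cortex, P_ct))
    ct_post[1, 0] = g_return / half

    stim = 0.080
    I_low = np.zeros(P_cortex)
    I_high = np.zeros(P_cortex)
    I_low[0] = -stim
    I_high[0] = stim
    spec_cx = InputSpec(
        I_low=I_low,
        I_high=I_high,
        I_go=np.zeros(P_cortex),
        tone_windows=TONE_WINDOWS,
        go_window=GO_WINDOW,
    )
    I_go_th = np.zeros(P_thalamus)
    I_go_th[0] = 0.060

    cortex = LowRankNetwork(U=U_c, A=A_cc, rmax=rmax_c, n_coding=3)
    return TwoAreaNetwork(
        cortex=cortex,
        U_th=U_th,
        rmax_th=rmax_th,
        ct_pre=ct_pre,
        B_ct=B_ct,
        ct_post=ct_post,
        tc_pre=tc_pre,
        B_tc=B_tc,
        tc_post=tc_post,
        spec_cortex=spec_cx,
        I_go_th=I_go_th,
    )
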