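"""Ground-truth networks and simulated recordings for the delayed-response task.

The generator emulates the statistical structure of pseudopopulation
recordings in a two-alternative memory-guided licking task: two stimulus
conditions (low/high tone -> left/right), three 150 ms tone pulses during
the sample epoch, a 1.2 s delay, a 100 ms go pulse at time zero, rates in
spikes/s causally smoothed with a 50 ms exponential kernel, and slow
across-trial drift of a low-dimensional input bias.

The ground-truth network is constructed, not fitted: its latent
interaction matrix contains a bistable choice dimension (effective gain
above one, saturating into two attractors), a feedforward sample->choice
drive, and residual dimensions that feed the choice dimension through an
asymmetric (non-normal) chain.  With constant ``rmax`` and a basis U
orthogonal to the all-ones vector, the zero-input fixed point is exactly
r = rmax/2 with vanishing latent state, which keeps the operating point of
the designed dynamics clean.

Trial-to-trial variability is an AR(1) latent input bias across the trial
sequence (correlation exp(-1/drift_timescale)); a trial's outcome (hit or
miss) is read out behaviorally from its delay-end choice projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import (
    GO_WINDOW,
    TONE_WINDOWS,
    InputSpec,
    LowRankNetwork,
    simulate,
    transfer,
)

__all__ = [
    "GroundTruth",
    "ActivityTensor",
    "make_ground_truth",
    "generate_recordings",
    "generate_catch_trials",
    "condition_average",
    "default_epochs",
    "SMOOTHING_TAU",
]

#: Causal exponential smoothing timescale applied to rates, seconds.
SMOOTHING_TAU = 0.050


@dataclass
class GroundTruth:
    """A known low-rank network plus the noise model used to record from it."""

    network: LowRankNetwork
    spec: InputSpec
    true_coding_basis: np.ndarray  # N x C, orthonormal columns
    bias_scale: float = 0.0015
    drift_timescale: float = 20.0  # trials
    noise_sd: float = 2.0  # spikes/s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bias_scale < 0 or self.noise_sd < 0:
            raise ValueError("bias_scale and noise_sd must be nonnegative")
        if self.drift_timescale <= 0:
            raise ValueError("drift_timescale must be positive")
        C = self.true_coding_basis.shape[1]
        defect = np.linalg.norm(
            np.eye(C) - self.true_coding_basis.T @ self.true_coding_basis
        )
        if defect > 1e-8:
            raise ValueError("true_coding_basis columns must be orthonormal")


@dataclass
class ActivityTensor:
    """Simulated (or loaded) population recording.

    ``rates`` is trials x time x neurons in spikes/s; ``condition`` is 0 for
    left and 1 for right; ``outcome`` is 1 for hit, 0 for miss.
    """

    rates: np.ndarray  # (K, T, N)
    time: np.ndarray  # (T,)
    condition: np.ndarray  # (K,) int
    outcome: np.ndarray  # (K,) int
    tone_windows: tuple[tuple[float, float], ...] = TONE_WINDOWS
    go_window: tuple[float, float] = GO_WINDOW
    dt: float = 0.005
    seed: int = 0
    trial_bias: np.ndarray | None = None  # (K, P) generator-side ground truth
    lick_rate: np.ndarray | None = None  # (T,) licks/s, zero before the go cue

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[2]

    @property
    def span(self) -> tuple[float, float]:
        return float(self.time[0]), float(self.time[-1])


def default_epochs(span: tuple[float, float]) -> dict[str, tuple[float, float]]:
    """Task epochs (pre-sample, sample, delay, response) for a given span."""
    return {
        "presample": (span[0], -1.85),
        "sample": (-1.85, -1.20),
        "delay": (-1.20, 0.0),
        "response": (0.0, span[1] + 1e-9),
    }


def _orthonormal_basis(rng: np.random.Generator, N: int, P: int) -> np.ndarray:
    """Random N x P basis orthogonal to the all-ones vector, fixed signs."""
    X = rng.standard_normal((N, P))
    ones = np.ones(N) / np.sqrt(N)
    X -= np.outer(ones, ones @ X)
    Q, R = np.linalg.qr(X)
    Q *= np.sign(np.diag(R))  # deterministic orientation
    return Q


def make_ground_truth(
    N: int,
    P: int,
    C: int = 3,
    seed: int = 0,
    bias_scale: float = 0.0015,
    drift_timescale: float = 20.0,
    noise_sd: float = 2.0,
    rmax: float = 40.0,
) -> GroundTruth:
    """Construct a condition-selective, bistable ground-truth network.

    Latent dimensions are ordered sample, choice, response, then residuals.
    The effective latent gain around the operating point is (rmax/2) * A,
    so A is specified as a designed gain matrix divided by rmax/2: the
    choice dimension is supralinear (bistable under saturation), the sample
    dimension feeds it feedforwardly, and residual dimensions relay sample
    drive into choice through an asymmetric chain, making A distinctly
    non-normal.
    """
    if not (1 <= C <= P <= N):
        raise ValueError(f"need 1 <= C <= P <= N, got N={N}, P={P}, C={C}")
    rng = np.random.default_rng(seed)
    U = _orthonormal_basis(rng, N, P)

    gain = np.zeros((P, P))
    gain[0, 0] = 0.10  # sample: leaky
    i_choice = min(1, P - 1)
    gain[i_choice, i_choice] = 1.12  # choice: weakly supralinear, bistable
    if P > 1:
        gain[i_choice, 0] = 1.20  # sample -> choice (feedforward)
    if C >= 3:
        gain[2, 2] = 0.0
        gain[2, 1] = 0.50  # choice -> response (kept moderate before the go cue)
    for r in range(C, P):
        gain[r, r] = 0.50
        gain[r, 0] = 0.90 * (-1.0) ** r  # sample -> residual
        gain[i_choice, r] = 0.60 * (-1.0) ** r  # residual -> choice
    # Seeded jitter restricted to DAG-respecting couplings (sample ->
    # residuals -> choice -> response).  The coupling graph stays acyclic,
    # so the spectrum equals the designed diagonal exactly — full-matrix
    # jitter would create feedback loops whose eigenvalues are
    # hypersensitive precisely because the matrix is so non-normal.
    order = [0, *range(C, P)]
    if i_choice != 0:
        order.append(i_choice)
    if C >= 3:
        order.append(2)
    for a_idx, src in enumerate(order):
        for dst in order[a_idx + 1 :]:
            gain[dst, src] += 0.08 * rng.standard_normal()
    for d in order:
        if d != i_choice:
            gain[d, d] += 0.03 * rng.standard_normal()

    rmax_vec = np.full(N, float(rmax))
    net = LowRankNetwork(U=U, A=gain / (rmax / 2.0), rmax=rmax_vec, n_coding=C)

    stim = 0.080  # latent input units; effective latent drive = (rmax/2)*stim
    I_low = np.zeros(P)
    I_high = np.zeros(P)
    I_low[0] = -stim  # low tone (left): negative sample drive -> negative choice
    I_high[0] = stim  # high tone (right): positive choice projection
    I_go = np.zeros(P)
    if C >= 3:
        I_go[2] = 0.060
    # Condition-specific proprioceptive lick input after the go cue: the
    # average lick rate ramps to a plateau over 200 ms, weighted by random
    # per-neuron vectors that differ between left and right licking.  This
    # is what gives the response epoch selectivity beyond the persisting
    # delay activity (and what defines a stable response axis).
    lick_t = np.array([0.0, 0.2, 3.0])
    lick_r = np.array([0.0, 6.0, 6.0])
    spec = InputSpec(
        I_low=I_low,
        I_high=I_high,
        I_go=I_go,
        I_lick_left=0.10 * rng.standard_normal(N),
        I_lick_right=0.10 * rng.standard_normal(N),
        lick_times=lick_t,
        lick_rates=lick_r,
    )

    # Coding dimensions are operationally defined: the orthogonalized LDA
    # axes of the generator's own noiseless condition averages, exactly as
    # the analysis pipeline would extract them from recordings.  (For
    # C != 3 tasks there is no sample/choice/response triplet; fall back to
    # the nominal latent coordinates.)
    if C == 3:
        from .coding import coding_basis_from_averages

        trL = simulate(net, spec, "left", span=(-3.0, 0.4), dt=0.005)
        trR = simulate(net, spec, "right", span=(-3.0, 0.4), dt=0.005)
        true_basis = coding_basis_from_averages(
            trL.rates, trR.rates, trL.time
        ).vectors
    else:
        true_basis = U[:, :C].copy()

    return GroundTruth(
        network=net,
        spec=spec,
        true_coding_basis=true_basis,
        bias_scale=bias_scale,
        drift_timescale=drift_timescale,
        noise_sd=noise_sd,
        seed=seed,
    )


def _exp_smooth(rates: np.ndarray, dt: float, tau: float = SMOOTHING_TAU) -> np.ndarray:
    """Causal exponential filter along the time axis (axis -2 of K x T x N)."""
    a = np.exp(-dt / tau)
    out = np.empty_like(rates)
    out[..., 0, :] = rates[..., 0, :]
    for t in range(1, rates.shape[-2]):
        out[..., t, :] = a * out[..., t - 1, :] + (1 - a) * rates[..., t, :]
    return out


def _simulate_trials(
    net: LowRankNetwork,
    spec: InputSpec,
    conditions: np.ndarray,
    bias_latent: np.ndarray,
    span: tuple[float, float],
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched forward-Euler integration of K trials with constant latent biases.

    Returns (time, rates) with rates of shape (K, T, N).
    """
    U, A, rmax, tau = net.U, net.A, net.rmax, net.tau
    K = conditions.size
    n_steps = int(round((span[1] - span[0]) / dt))
    time = span[0] + dt * np.arange(n_steps + 1)
    right = conditions.astype(bool)

    bias_N = bias_latent @ U.T  # (K, N), constant within trial
    lick_vecs = np.zeros((K, net.n_neurons))
    if spec.I_lick_left is not None and spec.I_lick_right is not None:
        lick_vecs[~right] = spec.I_lick_left
        lick_vecs[right] = spec.I_lick_right
    r = np.tile(net.baseline_rates(), (K, 1))
    rates = np.empty((K, time.size, net.n_neurons))
    rates[:, 0] = r
    eps = 1e-9
    for k in range(n_steps):
        t = time[k]
        lat = np.zeros((K, U.shape[1]))
        if any(w[0] - eps <= t < w[1] - eps for w in spec.tone_windows):
            lat[~right] = spec.I_low
            lat[right] = spec.I_high
        elif spec.go_window[0] - eps <= t < spec.go_window[1] - eps:
            lat[:] = spec.I_go
        h = ((r @ U) @ A.T + lat) @ U.T + bias_N
        lick = spec.lick_rate(t)
        if lick != 0.0:
            h = h + lick_vecs * lick
        r = r + dt / tau * (-r + transfer(h, rmax))
        rates[:, k + 1] = r
    return time, rates


def _unperturbed_endpoints(
    gt: GroundTruth, span: tuple[float, float], dt: float
) -> tuple[float, float]:
    """Delay-end choice projections of the noiseless left/right trajectories."""
    v = gt.true_coding_basis[:, min(1, gt.true_coding_basis.shape[1] - 1)]
    ends = {}
    for cond in ("left", "right"):
        traj = simulate(gt.network, gt.spec, cond, span=(span[0], 0.0), dt=dt)
        ends[cond] = float(traj.rates[-1] @ v)
    return ends["left"], ends["right"]


def generate_recordings(
    gt: GroundTruth,
    n_trials_per_condition: int,
    dt: float = 0.005,
    span: tuple[float, float] = (-3.0, 0.4),
    smooth: bool = True,
    noise: str = "gaussian",
) -> ActivityTensor:
    """Simulate a session of single trials from the ground truth.

    Per trial: ground-truth dynamics driven by the task inputs plus a
    constant latent input bias drawn from an AR(1) process across the
    (interleaved, shuffled) trial sequence, then additive observation
    noise on the rates (``noise='poisson'`` for count noise at resolution
    dt instead), causal 50 ms exponential smoothing, and clipping at zero.
    Outcome labels are behavioral: a trial is a hit when its delay-end
    choice projection falls on its own condition's side.
    """
    if n_trials_per_condition < 1:
        raise ValueError("need at least one trial per condition")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([gt.seed, 2**20 + 7]))
    K = 2 * n_trials_per_condition
    conditions = np.array([0, 1] * n_trials_per_condition)
    rng.shuffle(conditions)

    P = gt.network.n_latent
    rho = np.exp(-1.0 / gt.drift_timescale)
    bias = np.zeros((K, P))
    if gt.bias_scale > 0:
        b = gt.bias_scale * rng.standard_normal(P)
        for k in range(K):
            bias[k] = b
            b = rho * b + np.sqrt(1 - rho**2) * gt.bias_scale * rng.standard_normal(P)

    time, rates = _simulate_trials(gt.network, gt.spec, conditions, bias, span, dt)

    # behavioral outcome from the delay-end choice projection
    v = gt.true_coding_basis[:, min(1, gt.true_coding_basis.shape[1] - 1)]
    i_end = int(np.argmin(np.abs(time - 0.0)))
    x_L, x_R = _unperturbed_endpoints(gt, span, dt)
    proj = rates[:, i_end] @ v
    chose_right = np.abs(proj - x_R) < np.abs(proj - x_L)
    outcome = (chose_right == conditions.astype(bool)).astype(int)

    if gt.noise_sd > 0:
        if noise == "gaussian":
            rates = rates + gt.noise_sd * rng.standard_normal(rates.shape)
        elif noise == "poisson":
            counts = rng.poisson(np.clip(rates, 0, None) * dt)
            rates = counts / dt
        else:
            raise ValueError(f"unknown noise model {noise!r}")
    if smooth:
        rates = _exp_smooth(rates, dt)
    rates = np.clip(rates, 0.0, None)

    return ActivityTensor(
        rates=rates,
        time=time,
        condition=conditions,
        outcome=outcome,
        tone_windows=gt.spec.tone_windows,
        go_window=gt.spec.go_window,
        dt=dt,
        seed=gt.seed,
        trial_bias=bias,
        lick_rate=np.array([gt.spec.lick_rate(t) for t in time]),
    )


def generate_catch_trials(
    gt: GroundTruth,
    go_time: float,
    n_trials_per_condition: int = 1,
    dt: float = 0.005,
    span: tuple[float, float] | None = None,
) -> ActivityTensor:
    """Recordings with the go cue delayed to ``go_time`` (same stimulus schedule).

    ``go_time`` is in seconds relative to the nominal go cue; it must not
    precede the nominal delay end (go_time >= 0).
    """
    nominal = gt.spec.go_window[0]
    if go_time < nominal - 1e-12:
        raise ValueError(
            f"go_time={go_time} precedes the nominal go cue at {nominal}"
        )
    width = gt.spec.go_window[1] - gt.spec.go_window[0]
    shifted = gt.spec.with_go_window((go_time, go_time + width))
    if shifted.lick_times is not None:
        # licking follows the (delayed) go cue
        import dataclasses

        shifted = dataclasses.replace(
            shifted, lick_times=shifted.lick_times + (go_time - nominal)
        )
    gt_shift = GroundTruth(
        network=gt.network,
        spec=shifted,
        true_coding_basis=gt.true_coding_basis,
        bias_scale=gt.bias_scale,
        drift_timescale=gt.drift_timescale,
        noise_sd=gt.noise_sd,
        seed=gt.seed,
    )
    if span is None:
        span = (-3.0, go_time + 0.4)
    return generate_recordings(gt_shift, n_trials_per_condition, dt=dt, span=span)


def condition_average(
    tensor: ActivityTensor, condition: int, hits_only: bool = True
) -> np.ndarray:
    """Mean rates (T x N) over trials of one condition (hit trials by default)."""
    mask = tensor.condition == condition
    if hits_only:
        mask &= tensor.outcome == 1
    if not mask.any():
        raise ValueError(f"no trials for condition {condition} (hits_only={hits_only})")
    return tensor.rates[mask].mean(axis=0)
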