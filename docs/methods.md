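# Methods

## Model

The network is a standard rate model with a saturating transfer function,

    tau dr_i/dt = -r_i + phi_i( sum_j J_ij r_j + I_i(t) ),
    phi_i(x) = (rmax_i / 2)(tanh x + 1),

with `tau = 40 ms` and per-neuron maximum rates `rmax_i > 0` (spikes/s,
trainable).  Connectivity is constrained to the low-rank form
`J = U A U^T` where `U` (N × P) has orthonormal columns and `A` (P × P) is
an unconstrained interaction matrix.  The first C = 3 columns of U are the
task-coding directions (sample, choice, response); the remaining R = P − C
columns are residual directions learned from the data.

Because `J r = U A (U^T r)`, the recurrent drive depends on the state only
through the latent projection `m = U^T r`, and the latent dynamics

    tau dm_s/dt = -m_s + sum_j u_j^s phi_j( (U A m)_j + I_j(t) )

are *exactly* closed: under forward Euler the latent integration reproduces
`U^T r(t)` of the full integration step for step (the per-neuron sum over
heterogeneous nonlinearities is kept; no mean-field shortcut).

### Task inputs

Time is measured relative to the go cue.  Three tone pulses at
[−1.85, −1.7), [−1.6, −1.45), [−1.35, −1.2) s deliver `U · I_low` (left,
low tone) or `U · I_high` (right); the go pulse at [0, 0.1) delivers
`U · I_go`; all windows are half-open.  An optional proprioceptive lick
input `I_lick_side · Rate_lick(t)` (length-N vectors, one per lick side;
zero for t ≤ 0) models the sensory consequences of licking.  The latent
input vectors (P each), the lick vectors (N each), `rmax`, `U`, and `A` are
the trainable parameters.

## Training on condition-averaged activity

The loss is a weighted sum of

- reconstruction: summed squared error between the model's simulated rates
  and the left/right condition averages over hit trials (both conditions),
- coding alignment: `4 − cos(u1, v_sample) − 2 cos(u2, v_choice) −
  cos(u3, v_response)` against the data-derived axes (choice doubled),
- orthogonality: `||I − U^T U||_F^2`,

with default weights `lambda_recon = 0.7, lambda_align = 0.5,
lambda_orth = 500`.  Optimization is Adam (default learning rate 5e-4, up
to 400 000 iterations, gradients clipped to global norm 1) on hand-derived
backprop-through-time gradients; the recurrent kernels are compiled with
numba.  Desk-scale fits pass a larger rate (1.5e-3), a cosine decay to 5%
of the initial rate, and a cap of a few thousand iterations; convergence
additionally stops when the relative loss change over 1000 iterations falls
below 1e-7.

Two implementation choices matter for fitting at small iteration budgets:

1. **Teacher-forced initialization.**  U starts at the LDA axes plus the
   leading principal components of the residual data; `rmax` just above each
   neuron's observed peak.  A and the input vectors are then initialized by
   inverting the transfer function on the data itself: consecutive data
   frames give the target drive `h_t = arctanh(2 phi_t / rmax − 1)`, and the
   latent regression `U^T h_t ≈ A m_t + iota_t` is solved by least squares.
   This starts gradient descent near a self-consistent solution rather than
   at a silent network.
2. **Exact post-fit canonicalization.**  Adam balances the orthogonality
   penalty against the (much larger) reconstruction gradient, so the raw
   optimizer U retains a visible orthonormality defect at small iteration
   counts.  Since `J = U A U^T` and `U I` are invariant under `U → Q`,
   `A → R A R^T`, `I → R I` with `U = QR`, the returned network is
   re-orthonormalized by this exact reparameterization — identical dynamics,
   orthonormal columns.  The training log keeps the raw penalty values.

Integration uses forward Euler (RK4 available) with default dt = 5 ms
(τ/8); fits may subsample the recording grid down to τ/4 = 10 ms.  The
initial state is the zero-input operating point phi(0) = rmax/2.

Cross-validation splits hit trials 80/20 per condition; the fit is scored
by the MSE of its predicted rates against held-out-trial condition averages
and by the cosine between its coding columns and the training-set LDA axes;
means and standard errors are reported over seeded splits, with an optional
five-point moving average across P.  Explained variance is pooled:
`1 − SSE / SStot` over neurons, time bins, and conditions, with SStot taken
about the grand mean.

## Coding axes

Each axis is a two-class discriminant computed with the per-time-bin
condition-averaged population vectors inside its window as observations
(sample: first 600 ms of the sample period; choice: last 600 ms of the
delay; response: first 350 ms after the go cue), followed by Gram–Schmidt
in the order sample → choice → response, with the choice axis oriented so
the right condition projects positively.

The discriminant is `Sw^{-1}(mu_R − mu_L)` with a shrunk within-class
scatter `Sw = (1 − γ) S + γ (tr S / N) I`.  The 50 ms smoothing makes
adjacent time bins strongly correlated, so a window contributes far fewer
effective samples than neurons; inverting the resulting scatter rotates the
discriminant into sampling-noise directions that are unstable from session
to session.  The default is therefore the fully shrunk limit γ = 1 — the
class-mean-difference "coding direction" standard in this field — with
Ledoit–Wolf (`shrinkage="ledoit-wolf"`), any intermediate γ, and the plain
pseudo-inverse (`shrinkage=None`) available.  Per-trial observations (as
opposed to time-bin observations) can be used by passing single-trial
matrices directly.

## Synthetic-data generator

`make_ground_truth(N, P, C, seed)` constructs a network whose latent gain
matrix `G = (rmax/2) A` is a directed acyclic design: a leaky sample
dimension, a weakly supralinear choice dimension (gain 1.12, bistable under
saturation), a response dimension driven by choice, and residual dimensions
that relay sample drive into choice through an asymmetric chain.  Seeded
jitter is applied only to DAG-respecting couplings: because the designed
matrix is strongly non-normal, its spectrum is hypersensitive to arbitrary
jitter (feedback loops shift eigenvalues by roots of the perturbation), and
restricting jitter to the acyclic entries keeps the spectrum equal to the
designed diagonal.  With constant `rmax = 40` spikes/s and U constructed
orthogonal to the all-ones vector, the zero-input fixed point is exactly
r = rmax/2 with vanishing latent state, so the designed gains act around a
clean operating point.  A condition-specific lick input (rate ramping to
6 licks/s over 200 ms after the go cue) gives the response epoch
selectivity beyond the persisting delay activity.

The generator's *coding basis* is defined operationally: the orthogonalized
LDA axes of the generator's own noiseless condition averages — exactly what
the analysis pipeline extracts from data — rather than the internal latent
coordinates.  Coding dimensions are discriminant-defined quantities, and
this definition makes recovery claims self-consistent.

Trial-to-trial variability is an AR(1) latent input bias across the trial
sequence, `b_{k+1} = ρ b_k + sqrt(1 − ρ²) σ ξ` with
`ρ = exp(−1/drift_timescale)` (default 20 trials) and σ = `bias_scale`
(default 0.0015 latent input units, calibrated once so that sessions show
roughly 75–100% hits — errors arise when the integrated bias outweighs the
stimulus seed of the choice attractor).  Observation noise is additive
Gaussian on rates (default 2 spikes/s; a Poisson option exists), rates are
causally smoothed with a 50 ms exponential kernel and clipped at zero.
Outcome labels are behavioral: a trial is a hit when its (pre-noise)
delay-end choice projection falls nearer its own condition's unperturbed
endpoint.

What the generator does *not* emulate: spiking statistics, session-level
nonstationarity beyond the AR(1) bias, heterogeneous per-neuron time
constants, and multi-area inputs (except in the two-area model).  Tests
that pass on this generator demonstrate correctness of the machinery and
recoverability under the stated conditions, not performance on real
recordings.

## Perturbations

Pulses last 100 ms by default and are applied at 12 evenly spaced start
times in the delay with the go cue withheld (and hence no licks); runs
continue 0.9 s past the nominal go time.  Magnitudes default to 31 points
in [−15, 15].  Choice projections are reported relative to phi(0), so
left/right attractors carry opposite signs.  A flip toward right is counted
when `|x̂_L − x_R| < eps` with `eps = 0.25 (x_R − x_L)` (symmetrically for
left).  Neuron-targeted perturbations deliver amplitude α/K to each of the
top-K neurons ranked by |loading| (ties to the lower index) on the chosen
column of U; the entries then sum to α and the L2 norm is α/√K.  The
protocol's 100 ms / 12 windows are the defaults; alternative durations and
window counts (e.g. 150 ms, 11 windows) are plain arguments.

## Spectral diagnostics

`henrici_index` clamps tiny negative round-off under the square root and
rejects the zero matrix (the normalization is undefined).  The resolvent
norm is computed as `1 / sigma_min(zI − A)` and reported as infinite within
tolerance of the spectrum.  Pseudospectrum grids default to 201 × 201 over
a box 1.5× the spectral radius, with reporting contours at
5e-2 … 5e-3.  The alignment map takes, at each z, the top right-singular
vector of the resolvent (the left-singular vector of `zI − A` at
sigma_min) and measures its norm on the residual latent coordinates
C+1 … P.  The Schur form is real and ordered with negative-real
eigenvalues first (2 × 2 blocks for complex pairs); Schur projections use
`s = Q^T m` with Schur vectors as the *columns* of Q — an orthogonal change
of coordinates either way, so norms are preserved under either convention.
The strictly triangular ("feedforward") energy is computed from the complex
Schur factor, where it exactly equals `||A||_F^2 − Σ|λ_i|^2`; the
standardized real form spreads complex-pair imaginary parts asymmetrically
across its 2 × 2 blocks, so its strict-triangle energy does not satisfy the
identity exactly.

## Attractors

Fixed points are located by simulating with the go input (and licks)
removed until 1.05 s past the nominal go time, with optional Newton
polishing (`scipy.optimize.root` with the analytic Jacobian).  Convergence
is declared when `||−r + phi(Jr)|| / ||r|| < 1e-6`.  The Jacobian
`M = −I + D J` (time in units of tau) is diagonalized directly for
N ≤ 2000; above that the nontrivial spectrum comes from the P × P reduction
`−I_P + (U^T D U) A` (the remaining eigenvalues are −1).  Stability:
max Re < −1e-4 is stable, |max Re| ≤ 1e-4 marginal, otherwise unstable.

## Single-trial model

Trial k receives a constant latent bias `I^(k) = U T[:, k]`.  Training
jointly optimizes the network and T against tensor contractions: the
condition-averaged reconstruction (hit trials), within-epoch time averages
(pre-sample, sample, delay, response — all four epochs, configurable),
projections onto the coding dimensions against the data's LDA projections,
plus alignment, orthogonality, and `c_reg ||T||^2` regularization
(defaults `c_recon = 0.65, c_epoch = 0.1666, c_proj = 0.02, c_align = 0.5,
c_orth = 500, c_reg = 0.1`).  The full loss suite activates once the
trial-averaged reconstruction falls below 10% of its initial value (the
activation threshold is otherwise unspecified in the protocol).  Trial
start times are jittered i.i.d. uniform on [−4.35, −2.35] s, redrawn every
iteration, so the network must integrate the stimulus instead of mapping
the constant bias directly to the response; the state is held at the
operating point before each trial's onset.  A stimulus-ablation flag
implements the corresponding control.  Lick inputs follow the *executed*
side (condition for hits, the opposite for misses).

At test time only T is optimized (per-trial squared error plus the L2
penalty) with every network parameter frozen.  Bias-recovery experiments
plant biases at scale 0.08 latent units for P = 8 (0.05 suffices at P = 4);
below roughly 0.04 the per-trial bias effect drops under the observation
noise floor and directions are no longer identifiable trial by trial.

Error axes: per side (grouped by instructed condition), a no-intercept
logistic regression separates hit from miss trials in bias space; the L2
strength is chosen by a small stratified grid search on the 80% training
split, accuracy is reported on the held-out 20%, and weight standard
deviations come from bootstrap resampling (default 1000 draws of 80% of
trials, signs aligned to the point estimate).  The axis split into its
coding (first C coordinates) and residual components defines the
interpolation `I(α) = I_err − α I_coding + α I_residual`, normalized, so
α = −1 and α = +1 return the unit coding and residual components exactly.
The error-axis trial split is drawn independently of the model's
train/test split (both splits are exposed).

## Thalamocortical loop

Cortex is the low-rank model above; the thalamus has no recurrence, its own
`rmax`, and `tau_th = tau/3`.  Inter-area projections are rank-limited
products `J_ct = U_c · post · B_ct · pre · U_th^T` (and symmetrically for
J_tc), with default dimensions P_c = P_th = 10 and bottlenecks
P_ct = P_tc = 5.  Tones drive cortex; the go cue drives thalamus.  The
constructed two-area ground truth places the delay instability *in the
loop*: cortical choice has subcritical local gain (0.4) and closes a
round-trip gain of 1.12 through a weakly selective thalamic residual relay,
while a strongly selective thalamic dimension receives cortical choice but
does not project back.  Disconnecting either projection therefore collapses
delay activity, and perturbing random thalamic residual directions disrupts
cortex far more than perturbing the thalamic choice axis (40 magnitudes in
[1, 6], 120 unit-norm Gaussian directions by default; effects measured as
the MSE between perturbed and unperturbed activity pooled over both areas
and conditions).  Joint two-area training is not implemented; the module's
operations run on constructed or separately fitted networks.

## Problem sizes

Default experiment scales, chosen as desk-scale analogues: parameter
recovery uses N = 100 neurons, P_true = 5, 200 trials per condition,
10 000 Adam iterations for the main fit and 2000 per cross-validation fold
over P ∈ {3 … 8}; bias recovery uses N = 60, P = 8, 40 trials, 400
iterations of frozen-network bias optimization; the two-area model uses
N_cortex = 40–60, N_thalamus = 25–40.

## Known limitations

- Forward Euler is first-order; oracle tests at 1e-8 compare like against
  like (the same discretization), while physical accuracy is O(dt).
- The fully shrunk LDA default trades discriminant optimality for
  session-to-session stability; with many independent trials and mild
  smoothing, intermediate shrinkage may recover axes with less
  cross-contamination.
- Adam is scale-free per parameter, so loss weights act through gradient
  *competition* rather than absolute magnitude; the orthogonality weight
  controls the raw defect only logarithmically (hence the exact post-fit
  canonicalization).
- The generator's condition-averaged trajectories are dominated by a single
  unstable latent mode late in the trial, so its window discriminants are
  more collinear than real data's; Gram–Schmidt then leaves a modest
  fraction of the raw separation on the choice axis.  All recovery claims
  are made against the operationally defined axes, which is what the
  pipeline estimates.
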