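# Methods

## The sensorimotor loop

The model is a discrete-time control loop integrated at dt = 10 ms.

**Arm.** A planar two-link arm (shoulder + elbow) moving in the horizontal
plane — no gravity term — with state `x = [θ_elb, θ_sho, θ̇_elb, θ̇_sho]`
(radians; two-joint vectors such as torques are ordered (shoulder, elbow)).
The rigid-body dynamics are the standard inertia + Coriolis/centripetal
equations with diagonal joint viscosity, advanced by forward Euler. Link
parameters are the planar-arm set used throughout the optimal-control
reaching literature: l₁ = 0.30 m, l₂ = 0.33 m, m₁ = 1.4 kg, m₂ = 1.0 kg,
I₁ = 0.025 kg m², I₂ = 0.045 kg m², centres of mass d₁ = 0.11 m,
d₂ = 0.16 m, viscosity 0.05 N m s/rad. All are dataclass fields and can be
overridden.

**Muscles.** Six lumped actuators — shoulder flexor/extensor, elbow
flexor/extensor, and a biarticular pair — with a constant moment-arm matrix
(2 cm magnitude monoarticular; 1.5 cm shoulder / 2 cm elbow for the
biarticulars) and maximal force 40 N each. Muscle force is
`m · F_max · FL(l̃) · FV(ṽ)`: normalized length and velocity follow
linearly from the joint state through the moment arms
(`l̃ = 1 − A(θ − θ_ref)/L₀`, L₀ = 0.10 m, reference posture
θ_sho = 45°, θ_elb = 90°). FL is a Gaussian of width 0.3 around the
optimum; FV is hyperbolic, zero at a maximal shortening velocity of 10
optimal lengths/s, 1 at rest, saturating at 1.3 for fast lengthening.
These are smooth surrogates: published muscle models differ in their exact
constants, and the analyses here depend on F-L/F-V only through smooth gain
modulation. The force-velocity slope at rest is a few percent of the joint
viscosity in damping terms — see *Limitations*.

**Controller.** Two tanh layers with leaky integration
(τ_n = 20 ms ⇒ leak fraction 0.5) and a rectified leaky muscle stage
(τ_m = 50 ms ⇒ 0.2):

    h[t+1] = (1−l_n) h[t] + l_n tanh(W_sh I[t] + W_hh h[t] + b_h)
    o[t+1] = (1−l_n) o[t] + l_n tanh(W_ho h[t] + W_oo o[t] + b_o)
    m[t+1] = (1−l_m) m[t] + l_m [W_ou o[t]]₊

Inputs `I[t]` concatenate the task-goal channels with sensory feedback
delayed by Δ = 50 ms: the joint state `x[t−Δ]` (or hand position/velocity in
the cartesian variant) and the muscle activations `m[t−Δ]`. Delay lines are
pre-filled with the trial's initial state so t = 0 carries no artificial
transient. The NO-REC variant pins `W_hh = W_oo = 0` *and* drops the leak
terms, making each layer a memoryless function of its input — any temporal
structure in a NO-REC network is inherited from its inputs.

Weights are initialized uniformly on ±1/√N_inp per matrix (N_inp = fan-in),
biases at zero; a Gaussian scheme N(0, (g/√N_inp)²) with g = 1.5 is
available for strong-recurrence initialization. A `literal_n_scaling` flag
reproduces a ±1/N_inp variant whose coupling vanishes at scale; it is kept
for comparison only.

## Tasks and cost

All trials start at θ_sho = 45°, θ_elb = 90° with zero velocity.

* **Posture** (2.0 s): after a 500 ms hold, one of eight constant joint
  torques of 0.2 N m (elbow ±, shoulder ±, and the four combinations —
  summing to zero over the set) is applied to trial end. A ninth, load-free
  condition is included in training; analyses use the eight loaded
  conditions. The network receives *no* task input — only delayed feedback
  signals the load.
* **Reach** (1.5 s): the target (1 of 32: 16 uniform directions × 2 cm/5 cm)
  is shown as a step input (its joint angles) from trial start; a GO cue
  (high = hold, low = move, smoothed with a 20 ms SD Gaussian) drops at
  500 ms; the target must be acquired within 500 ms and held.
* **Tracking** (1.5 s): after 300 ms of rest the target ramps radially
  outward at constant velocity, reaching 5 cm at trial end (15 directions).
  The ramping target (joint angles) is the task input; no GO cue.

The cost is `J = 1/(2CT) Σ_c Σ_t [ q_t ‖x_t − x*_t‖² + α_t ‖m_t‖² +
β‖h_t‖² + γ‖o_t‖² ]`. The kinematic window `q_t` covers the initial hold
plus, for posture, everything from 1000 ms after load onset (return
accuracy + stable hold), for reach everything from 500 ms after GO, and for
tracking every step (the desired trajectory carries the target's joint
velocities, so velocity matching is penalized too). Each penalty weight
takes one of two values (α ∈ {1e−4, 1e−3}, β and γ ∈ {1e−5, 1e−6}); the
per-task assignment here is posture α = 1e−4, β = γ = 1e−5; reach
α = 1e−3, β = γ = 1e−6; tracking α = 1e−3, β = γ = 1e−5. Tracking gets the
stronger activity penalty deliberately: with the weak one the optimizer
discovers a high-gain strategy whose output layer oscillates at
~1/(2 × loop delay) (≈13 Hz), a regime the modeled system plainly does not
occupy (tracking dynamics are the slowest of the three tasks); the stronger
penalty suppresses it. During the posture pre-load hold the muscle penalty
is raised to α_hold = 1e−2 so the arm does not brace by co-contraction.

## Optimization

Backpropagation-through-time with a hand-written reverse pass: the network
equations are linearized analytically, the plant contributes its analytic
step Jacobians (∂x'/∂x, ∂x'/∂m), and feedback delays route adjoints
backwards by Δ/dt steps. With zero rectifier leak the gradient is exact to
machine precision (verified against central finite differences in the test
suite).

Training uses full-batch Adam (all conditions per step), global-norm
gradient clipping at 1.0, and cosine learning-rate decay to 5% of the base
rate. Two optimization details matter in practice and are deliberate
choices:

* **Rectifier leak (0.1–0.3).** In the backward pass only, the muscle
  rectifier's zero branch is given a small slope. Without it the hold-period
  penalties drive every muscle command negative early in training and the
  muscle pathway goes silent permanently (rectifier death) — the reach task
  then never learns to move at all. The forward model is untouched.
* **Convergence rule.** Training stops when the loss is below 5e−4 and its
  500-epoch running mean changes by less than 1e−6, otherwise at the epoch
  cap, returning the best checkpoint with a warning.

Desk scale — used by the tests, the acceptance script and the examples — is
100 units per layer with base learning rate 3e−3 (the larger step suits the
smaller network; 500 units with 1e−3 reproduces the full-scale
configuration) and epoch caps of 2k (posture), 4k (reach) and 2k
(tracking — its loss plateaus there; see *Limitations* for what happens
with much longer training), chosen so a full four-network study trains in
roughly a quarter hour on one core.

## Rotational-dynamics analysis

Given a units × conditions × time tensor: divide each unit by its activity
range plus a soft-normalization constant (5e−4 for network activity, 5 sp/s
for spike rates, 0 for muscle and kinematic signals), subtract the
cross-condition mean at each time point, reduce to the top principal
components (6 for network/spike tensors, 4 for the six muscle signals, 2
for the four kinematic signals), and fit `Ẋ = M X` by least squares with
the derivative taken as within-condition first differences (the final
sample of each condition is dropped; no difference spans a condition
boundary). The constrained fit solves the normal equations over the
15-dimensional skew-symmetric subspace in closed form. R² uses the
column-mean-removed derivative as its reference for both fits so the two
values share a denominator. Eigen-pairs of `M_skew` give planes (orthonormal
real/imaginary parts), frequencies (|λ|/2π, in Hz), and per-plane variance
fractions measured against the *total* preprocessed variance; ties are
broken by a stable descending sort.

Analysis windows: posture 70–370 ms after load onset (the 50 ms feedback
delay plus network latency shifts the earliest informative sample; with a
delay of Δ the window starts at Δ + 20 ms, at 0–300 ms for Δ = 0); reach the
first 300 ms after movement onset (first sample whose hand speed exceeds 5%
of that condition's peak); tracking from movement onset to trial end.

**TME surrogates.** The null preserves the observed covariance along each
tensor mode (units, conditions, time; computed as scatter matrices of the
grand-mean-removed tensor, so the three share a trace) but no cross-mode
interactions. The maximum-entropy Gaussian with those expected marginals is
diagonal in the Kronecker product of the mode eigenbases with spectrum
`s_ijk = 1/(2(λᵢ + λⱼ + λₖ))`; the multipliers λ come from minimizing the
convex dual by L-BFGS under a log reparametrization (eigenvalues floored at
1e−10; the fit is rejected if the marginal constraint error exceeds 5%).
Surrogates are three mode-products of a scaled white tensor; the test
re-runs the reduction + fits on each and reports add-one-smoothed p-values,
`p = (1 + #{surrogate ≥ observed}) / (n + 1)`. Populations under 30 units
are refused (the test is unreliable there) — few-signal comparisons use the
down-sampling control instead: repeatedly sample k units, re-run the
analysis at the matching component count, and locate the few-signal R²
in that distribution.

**Feedback decoding.** Ordinary least squares (with intercept) from the
delayed kinematic + muscle feedback the network actually received (plus the
GO cue and static target channels for reach) to the reduced trajectories,
over the same analysis window; reported pooled over all planes and
per plane.

## Synthetic ground truth

`planted_rotation_population` builds tensors whose latents follow
`ż = Sz` with S block-diagonal skew (exact per-step rotation matrices, so
no integration error) plus an optional symmetric expansion mode; conditions
share the dynamics and differ only in random phase and amplitude
(0.5–1.5×); latents map to units through a random orthonormal loading, plus
iid Gaussian noise. Because S, the loading and the latents are returned,
frequency recovery, constrained/unconstrained behaviour and surrogate-test
power are all checkable against ground truth. Two discretization facts the
tests account for: the first-difference derivative of a sampled rotation
contains a symmetric part of order ω²dt/2, so the constrained R² on perfect
rotations is slightly below 1; and a slow plane needs enough arc to be
identified (0.5 Hz is tested over a 1 s window).

What the generator does *not* emulate: spiking variability, non-Gaussian
noise, heterogeneous single-unit timescales, or condition structure beyond
shared-dynamics-with-random-initial-conditions. Passing tests on planted
data validate the analysis pipeline, not claims about any particular real
dataset.

`smooth_spikes` converts timestamps to rates on the 10 ms grid with a 30 ms
SD Gaussian kernel, or a causal half-Gaussian (zero strictly before each
spike) for display; both are area-normalized per spike in the continuum, so
an on-grid spike inflates a Riemann sum by about one kernel-peak × dt.

## Numerical choices and edge cases

* State ordering `[θ_elb, θ_sho, θ̇_elb, θ̇_sho]` everywhere; time is the
  0-based sample index × dt.
* Rank-deficient tensors: the reduction keeps the available rank and warns;
  singular normal equations fall back to a small ridge with a warning.
* Degenerate (zero-frequency) planes are completed deterministically.
* The skew fit, PCA and TME sampling are exactly seed-reproducible;
  rollouts are deterministic given weights.
* TME sampling is chunked (128 surrogates at a time) to bound memory.

## Limitations

* No tendon/activation dynamics, gravity, 3-D kinematics or contact; the
  muscle F-L/F-V constants are surrogates, and their shallow force-velocity
  slope near rest provides little intrinsic damping. As a result the
  delayed loop admits a lightly damped resonance around
  1/(2 × loop delay) ≈ 7–13 Hz, and given enough training the optimizer
  will exploit high-gain strategies that live on it (tracking error keeps
  creeping down while the output layer starts ringing). The reach task's
  fast top-plane frequencies and some of the tracking constrained-fit
  variance reflect this mode; the tracking epoch cap sits at the loss
  plateau before the resonant regime takes over.
* Reduced-scale (100-unit) networks carry seed-to-seed spread of roughly
  ±0.1 in fit R²; quantitative comparisons should average seeds or use the
  bands the tests use.
* The TME dual solver assumes positive Lagrange multipliers (log
  parametrization); extremely anisotropic covariances could in principle
  require negative multipliers, which the constraint-error check would
  surface as a failure rather than silently mis-sample.
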