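# Methods

This note records the models, parameter choices, and numerical decisions
behind the package, and what the synthetic-data experiments do and do
not demonstrate.

## Desired-force-curve design

The empirical controller's reference is built from blocked-motor force
recordings of the two artificial muscles over one normalized gait cycle
(phase 0 = touchdown, stance before swing).  The workflow is

1. difference of the HAM and RF force traces,
2. least-squares fit of an 8th-order real trigonometric polynomial
   (on a uniform grid this equals the discrete Fourier projection; the
   OLS form also handles non-uniform grids),
3. analytic term-wise differentiation of the Fourier representation
   (chosen over numerical differencing of samples for noise
   robustness),
4. circular convolution with a wrapped Gaussian kernel,
5. uniform rescaling so that max |F_d| equals the hardware force range,
6. a re-fit so the final curve is again stored as Fourier coefficients.

Two free parameters are not dictated by the hardware: the smoothing
width (default σ = 0.03 of a cycle) and the rescaling target (default
23 N, the top of the measured artificial-HAM range).  Both are exposed
in configuration.

**Sign convention.** Positive F_d means "pull the artificial HAM",
negative means "pull the artificial RF".  The HAM−RF difference falls
through stance and recovers through swing, so its derivative is negative
exactly where the HAM should pull; the design stage therefore uses the
*negated* derivative, which yields a curve that is positive over the
bulk of stance and negative over the bulk of swing for the default
templates.

## Serial-elastic correction and PD cascade

The motor correction angle is

    ΔΘ = (F_d/k − F_HAM/k_HAM − F_RF/k_RF) / r_m

with k the stiffness of the spring the desired force engages (HAM spring
for F_d ≥ 0, RF spring otherwise).  `motor_correction` implements this
form verbatim; it satisfies the tracking-equilibrium identity
(ΔΘ = 0 when F_d/k = F_HAM/k_HAM + F_RF/k_RF), is linear in each force,
and scales as 1/r_m.

For closed-loop operation the package uses the signed variant

    ΔΘ = (F_d/k_active − (F_HAM/k_HAM − F_RF/k_RF)) / r_m

in which the measured spring stretches enter as their difference.  With
the antagonistic single-motor layout (positive rotation loads the HAM
spring and unloads the RF spring) the two forms coincide whenever the
inactive spring is slack; the difference form, however, keeps the
feedback sign correct on both sides of the zero crossing and is the form
implied by comparing the *difference* of spring lengths to the desired
value.  Using the magnitude form as a signed law is unstable on the
RF side, which is a numerical, not physical, artifact of treating a
per-muscle magnitude relation as a bidirectional error.

The PD cascade maps the angle error to a velocity setpoint (outer
proportional loop, default 60 (rad/s)/rad) and the velocity error to the
motor drive (inner PD, defaults k_p = 4, k_d = 0.001, saturation 50).
Defaults were tuned on the packaged first-order motor plant
(J = 0.02 kg·m², b = 0.5 N·m·s) for fast, overshoot-free settling
(≈60 ms to 2%); larger derivative gains interact badly with the raw
sampled derivative at a 500 Hz loop rate.  Spring stiffness defaults to
3 N/mm (3000 N/m); the soft identification springs are printed
ambiguously in hardware documentation conventions (N/m vs N/mm), so the
value is configuration, not physics, here.

## Gait-phase tracking

A touchdown is an upward crossing of the 30 N GRF threshold preceded by
a swing interval: at least 50 ms of GRF below 5 N.  Qualifying the
debounce on the *low* interval alone (rather than on time since swing
began relative to the crossing) makes the number of detected steps
monotone non-increasing in the threshold.  Cycle duration is the mean of
up to the last five inter-touchdown intervals; phase is elapsed time
since touchdown over that estimate, clamped to [0, 1).  Before the first
complete interval the phase is undefined and the controller commands
zero drive.

## Walking environment

The training environment is a deliberately small planar stand-in for a
full musculoskeletal simulation; it preserves the interfaces, not the
anthropometrics:

- **Skeleton.** Seven segments (trunk, thigh/shank/foot per leg)
  represented by point masses at segment endpoints (74 kg total,
  standing center of mass ≈ 0.95 m) joined by stiff damped springs
  (k = 4·10⁴ N/m), with weak damped rotational springs centering each
  joint.  This compliant formulation keeps every internal force either
  conservative or dissipative, so with zero activation the total
  mechanical energy (kinetic + gravitational + elastic) is
  non-increasing by construction — a property the test suite checks
  step by step.
- **Muscles.** Nine per leg (iliopsoas, gluteus maximus, RF, VAS, HAM,
  short biceps femoris, GAS, TA, SOL), first-order activation dynamics
  with τ = 10 ms, torque = activation × F_max × constant moment arm;
  biarticular muscles span two joints.  No Hill-type force-length or
  force-velocity curves: the fiber-length observation is a normalized
  actuator length from joint angles.
- **Contact.** Vertical spring-damper ground (3·10⁴ N/m, 120 N·s/m —
  inside the explicit-integration stability region for the lightest
  node) with a bounded Coulomb friction law; every node contacts the
  ground so a collapsed model comes to rest.  Per-side GRF sums the
  foot-node normal forces.
- **Integration.** Semi-implicit Euler at 1 ms.
- **Contract.** Observation of length 44 packed as 18 fiber lengths,
  18 muscle forces, orientation (trunk angle, cos, sin), velocity
  (CoM vx, vy, trunk angular rate), and right/left vertical GRF — the
  18+18+3+3+2 split is one documented reading of the stated
  constituents.  A run ends after ten detected steps (30 N rule), when
  the CoM drops below 0.8 m (read as meters; geometry scaled so nominal
  standing CoM ≈ 1 m), or at a 20 s safety cap.
- **Exosuit emulation.** Per leg, the error between desired and modeled
  HAM−RF force is split onto hip and knee coordinate actuators through
  0.10 m and 0.05 m lever arms (setpoint ratio exactly 2), each tracked
  by first-order actuator dynamics standing in for the actuator PD.
  Learned curves are uniformly rescaled — never saturated — into the
  23 N hardware range, preserving the waveform shape.

The model is not expected to walk well, and nothing in the package
claims it reproduces human gait traces; it exists to exercise the
training loop and the environment contract at desk scale.

## Reward

    reward = v_min + (v − v_min) / max(ε, mean(a)) + r_alive·[alive]

with v_min = 0.2 m/s, r_alive = 0.1 and an effort floor ε = 0.05 that
bounds the term for near-zero activations.  The rendered form of the
velocity-effort interaction is typographically ambiguous; division by
mean activation is the default (`reward_form="divide"`, matching "the
lower the effort, the bigger the reward") and a multiplicative
`(1 − mean a)` reading is available as `reward_form="one_minus"`.  Both
readings agree on the two identities the tests rely on: an aborted
timestep at v = v_min earns exactly v_min, and surviving a timestep adds
exactly r_alive.

## PPO trainer

Actor and critic are tanh MLPs with two hidden layers of 64 units
(hand-written NumPy forward/backward passes; gradient correctness is
pinned by a central-difference check at 10⁻³ relative tolerance).  The
actor's output layer is split into a per-timestep head (18 muscle
activations, Gaussian with state-independent log-stds, samples clipped
to [0, 1] — the raw sample is kept for the log-probability bookkeeping)
and a run-level head (17 Fourier coefficients + actuator gains) sampled
once per reset; its log-probability is attributed to the run's first
transition, so that transition's combined log-probability is the sum of
both heads.

Advantages use TD + GAE with episode-boundary truncation and a value
bootstrap for collection-truncated segments.  Updates happen every 2048
timesteps, reusing each batch for 10 shuffled minibatch epochs, with the
clipped surrogate objective, entropy bonus, global gradient-norm
clipping, an L2 penalty on the critic weight matrices, and Adam.
Hyperparameters the source material does not fix (learning rate 3e−4,
γ = 0.99, λ = 0.95, clip 0.2, minibatch 256, entropy 0.01, L2 1e−4) are
standard PPO practice and all configurable.  An optional linear
learning-rate anneal with a 10% floor is available; "updated every 2048
episodes" is read as every 2048 environment timesteps, since an episode
is defined as one 1 ms timestep in the training loop's terminology.

**Demonstration budgets.**  Training at the full 5-million-run scale is
out of scope; learning is demonstrated on two bundled tasks with frozen
desk-scale budgets: the 1-DoF hover task (32 updates × 512 steps,
lr 5e−4, initial σ = e⁻¹ — chosen so late training stays stable) and
the curve-parameter inverse problem (300 updates × 256 one-step
episodes, lr 1e−2 with the floored anneal: coarse moves first, fine
convergence after).  The walker training run in the demo pipeline is a
micro-budget smoke (2048 steps) whose purpose is exercising the hybrid
action plumbing, not producing a competent policy.

## Synthetic data

Base shapes are mixtures of wrapped Gaussians on the phase circle —
the measured anchors are ranges and peak timings, and everything between
anchors is an explicit modeling choice:

- **Force templates.** HAM spans 6–23 N with its peak pinned at 92% of
  the cycle and a broad early-stance shoulder; RF spans 4–22.5 N peaking
  at 60% (the toe-off region).  With noise off and the default 200-point
  grid the ranges and discrete argmax locations are exact.
- **GRF.** Double-hump stance profile (loading and push-off peaks,
  mid-stance valley), exactly zero through swing, default stance
  fraction 0.61, peak 800 N, optional clamped Gaussian noise.
- **sEMG envelopes.** Five muscles (HAM, RF, VAS, GAS, SOL) with
  standard activation timings, tiled over steps.  A subject's envelope is
  base template × condition MAV multiplier × subject lognormal factor
  (sd 0.2 default) + clamped noise.  Because the subject factor is
  shared across conditions it cancels exactly in percent changes against
  the NE baseline — by design, the analysis stage works on relative
  changes only (the sEMG normalization convention is left open).
- **Condition effects.** Default multipliers follow the qualitative
  pattern of assisted slow walking — both controllers reduce
  posterior-chain activity and raise anterior activity, the learned
  controller more so on RF/VAS/SOL — and per-condition step durations
  default to 1.333/1.340/1.309/1.334 s (NE/NC/Emp/RL, slow protocol)
  and 1.054/1.089/1.048/1.163 s (preferred-speed protocol).  These are
  generator defaults for producing structured test data, not
  reproduction claims about any particular human cohort.
- **Protocol subjects.** A simulated subject transitions to running at
  its true transition speed and gives ±1 comfort feedback around its
  true preferred speed, with optional Gaussian feedback noise.

What passing tests show: the pipeline recovers injected effect sizes,
its statistics are calibrated under the null, and its stages compose
deterministically.  What they do not show: anything about real sEMG
(no raw-signal artifacts, electrode noise, crosstalk, fatigue or
day-to-day drift), real gait variability (steps are exactly periodic up
to additive noise), or hardware behavior.

## Statistics

Per subject, envelopes are segmented at touchdowns and resampled to 101
points (0–100% of the gait cycle).  Group traces average per-subject
means after excluding subjects whose MAV deviates from the group median
by more than 3 scaled median absolute deviations (the outlier rule is
otherwise unspecified; MAD was chosen for robustness at n = 4 and can be
disabled).  MAV is the mean absolute value over the cycle; peak is the
maximum of the subject-averaged trace (a per-step-max variant is a
config switch).  Condition comparisons use one-way ANOVA per
muscle × metric at α = 0.05 — the repeated-measures structure of a
within-subject design is deliberately ignored by default to mirror the
plain-ANOVA description, with the caveat that this is conservative in
power, not in type-I error — followed by Tukey HSD (Bonferroni-corrected
t-tests available).  Degenerate all-equal groups are flagged rather than
raised.  The preferred-walking-speed protocol ramps until the walk-run
transition, initializes the preferred speed at 75% of the transition
speed, and titrates up/down until the comfort feedback alternates.

## Known limitations

- The walker is a compliant-skeleton caricature: no 3-D dynamics, no
  Hill muscles, no reflex circuitry, and no claim of gait realism.
- The learned-control condition in the demo pipeline uses a micro-budget
  policy; its curve is plumbing-correct but not optimized.
- Synthetic envelopes are smooth and periodic; statistical power
  estimates on them will be optimistic relative to real recordings.
- The single-motor antagonistic coupling is modeled kinematically
  (one spring loaded at a time, optional pretension not modeled).
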