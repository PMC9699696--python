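# Methods

`reachloop` simulates a closed sensorimotor loop: a 74-unit firing-rate
network spanning somatosensory cortex, motor cortex and a spinal circuit
controls a two-link planar arm with six Hill-type muscles, and configures its
own input-output structure with differential Hebbian and input-correlation
plasticity.  This note records the model equations as implemented, the
parameters that matter, and the design decisions taken where the design was
genuinely open.

## The control principle

A reach is commanded in sensory coordinates.  The prescribed pattern SP is
set to the somatosensory activity the arm would produce at the target
posture; the loop then acts to make perceived activity SA match SP.  Each
muscle's length error is represented by a *dual pair* of rectified units in
SPA (one per error sign, mutually inhibitory), which drives motor cortex M
one-to-one; M projects to spinal excitatory/inhibitory interneuron pairs
(CE/CI) and alpha motoneurons, organized by the agonist–antagonist structure
of the six muscles.  Muscle spindles (Ia, II) and Golgi tendon organs (Ib)
close the loop through an afferent relay A.  Every connection carries a
transmission delay (5 ms local, 10 ms for cortico-spinal, spino-cortical and
subcortico-cortical edges; both configurable).

Three configurations share this topology: `spinal_learning` (plastic
M→CE/CI and M→alpha), `cortical_learning` (plastic SPA→M), and `static`
(all weights hand-set by the wiring policy below).

## Units

* Sigmoidal units: `tau_u du/dt = sigma(I) − u` with the increasing logistic
  `sigma(I) = 1/(1+exp(−beta (I−eta)))` and `I` the delayed, weighted input
  sum.  Time constants default to 20 ms (10 ms for the afferent relay).
* Noisy sigmoidal units (the exploration population: CE/CI, or M in the
  cortical-learning configuration) add white noise of amplitude `sigma_noise`
  (default 0.3) and integrate by Euler–Maruyama; activities are clipped to
  [0, 1].
* Afferent relay units use a rectified-logarithm activation,
  `tau_a da/dt = log([1 + I − T]_+) − a`, with the activation clamped at
  zero so steady-state rates are never negative (population A feeds
  excitatory synapses).
* ACT, the exploration controller, is a leaky integrator of the total SPA
  activity: it decays whenever its sigmoided input is below `theta_ACT`
  (default 0.55), grows toward 1 above it — with the growth boosted by a
  recent *increase* of the error (`gamma`, default 2, times
  `sigma(I) − sigma(I~)` where `I~` is a 1-s low-pass of `I`) — and resets
  at 40 s⁻¹ while the change detector CHG is active.
* CHG is a sigmoidal unit whose SP synapses relax quickly (20 ms) toward
  `alpha_chg |dSP/dt|`, so it fires a pulse at every target switch.  Its
  threshold is set so that its baseline activity stays below the ACT reset
  gate (0.1): otherwise ACT would be held in permanent reset.
* When ACT's output exceeds 0.8, each exploration unit whose adaptation
  current has decayed below 0.2 receives `I_adapt = (u_slow)^2`, the square
  of a 2-s low-pass of its own activity, subtracted from its input with
  weight `g_adapt` (default 1.5).  The most active units are inhibited the
  most, which shifts the dominant pattern and enlarges exploratory
  oscillations when the arm is stuck.

## Learning rules

**Differential Hebbian rule** (the motor-command map).  The raw drive for
the edge from presynaptic unit j (carrying an error e) to postsynaptic unit
i (carrying a command c) is

    Delta_ij = −(e''_j − ⟨e''⟩) (c'_i(t − Δt) − ⟨c'(t − Δt)⟩)

with population-centered derivative estimates, and the weight update is

    dw_ij/dt = alpha w_ij (Delta_ij + lambda [0.5 (zeta_sa + zeta_sb) − 1])

where `zeta_sa = w_sa / (outgoing sum of j)` and `zeta_sb = w_sb /
(incoming sum at i)`.  The multiplicative `w_ij` factor is the soft bound
(weights never change sign); the bracketed term is multiplicative sum
normalization.  Two sign conventions deserve comment:

* *Normalization sign.*  The implemented sign is the stabilizing one: sums
  above target shrink the weights.  With the opposite sign the normalization
  is anti-stabilizing and the weight matrix diverges within one training
  phase (verified numerically); since the normalization exists to control
  the weight magnitude, the stabilizing sign is the faithful reading.
* *Drive sign and causality lag.*  `DiffHebbParams.drive_sign` exposes the
  sign of the Hebbian term so the convention can be validated against the
  functional requirement (training reduces the error).  The default (+1,
  i.e. the form above) was validated by cross-correlating the centered
  derivative signals of a running loop against the known-good wiring
  pattern: the drive favors the correct edges for lags near the sensorimotor
  loop latency and flips sign at lags about half an oscillation period away.
  The default lag `delta_t = 130 ms` sits at the measured optimum
  (motor + muscle-activation + sensory + relay delays plus three unit time
  constants ≈ 100–150 ms), the lag whose drive stayed positive across both
  the random-weight and the solved operating regimes.

Derivatives are estimated by cascaded exponential smoothers: the difference
of a fast (20 ms) and a mid (40 ms) low-pass of x, divided by the difference
of time constants, approximates x'; applying the same construction to the
estimate yields x''.  Plasticity advances with the same 1-ms Euler step as
the unit activities.

**Input-correlation rule** (afferent edges A→M and A→C).  Per edge,
`dw_k/dt = alpha_IC w_k u_k dI_PA/dt`, with `u_k` the edge's presynaptic
afferent activity and `I_PA` the unit's error/command input sum; after each
update the weight group at a unit is rescaled to its target sum and clipped
at `w_max`.  (Written with a scalar afferent sum the rule would scale all
weights of a group identically and be annulled by the normalization, so the
per-edge presynaptic factor — the standard form of input-correlation
learning — is used.)  Afferents that fire just before the error grows take
over the group budget, which damps oscillations of the loop.

Initial plastic weights are positive uniform (spread ±50% around the mean),
scaled so that every presynaptic row meets its sum target; group-sum targets
equal the initial sums.

## Plant

Rigid dynamics: a compound double pendulum of two uniform 1-kg cylinders of
length 0.3 m (inertia mL²/12 about the center), no gravity, viscous joint
friction 3 N·m·s/rad.  Shoulder at the origin; rest posture with the elbow
at (0.3, 0) and the hand at (0.3, 0.3).

Muscles follow the linear Hill-type viscoelastic form
`dT/dt = (K_SE/b)[g·I + K_PE Δx + b dx/dt − (1 + K_PE/K_SE) T]` with
defaults K_SE = 200 N/m, K_PE = 60 N/m, b = 20 N·s/m, input gain
g = 60 N; `Δx` is the length above the total rest length, which is
calibrated from the rest posture so all tensions vanish there.  Negative
tensions are clamped to zero in the torque mapping (muscles pull, never
push), but the tension state itself is not clamped; a test verifies no
sustained large negative tensions in normal operation.

Each muscle carries one static and one dynamic nuclear bag fiber with the
same tension equation (no input term; static bag b_s = 10, dynamic
b_d = 100 N·s/m — the heavy damping makes the dynamic bag velocity
sensitive).  Bag rest lengths are 0.45 of the muscle rest length, chosen so
the fibers never go slack over the full excursion range (a slack spindle
would blind the loop exactly when a muscle contracts strongly).  Ia and II
outputs are linear combinations of the serial-element lengths (read as
tension/stiffness): `Ia = g_Ia [(f_Ia/K_SE_s) T_s + ((1−f_Ia)/K_SE_d) T_d]`,
`II = g_II [(f_II/K_SE_s) T_s + ((1−f_II)/K_PE_s)(T_s − b_s dx/dt)]`.  The
Golgi tendon organ produces `r = g_Ib log(T_+/T_0 + 1)` filtered at 30 ms.

**Muscle paths.**  The attachment points (torso, upper arm, forearm frames)
define each muscle's rest length and rest moment arms through the straight
chord between them.  The simulated path, however, is a joint-capsule
*pulley*: moment arms stay at their rest-chord values everywhere, and length
is linear in joint excursion.  A straight chord crosses the joint center at
extreme postures within the target-sampling region, silently reversing the
muscle's action and making whole regions of the workspace unreachable; a
wrapping path keeps the action sign-stable, as real muscles do.  At the rest
posture both models agree exactly.

**Integration.**  Unit equations advance by forward Euler at dt = 1 ms
(halving dt changes a 5-s reach endpoint by < 1 mm; see the convergence
test).  The plant advances over each neural step, drives held constant, with
an adaptive Dormand–Prince 5(4) stepper at rtol 1e-5 / atol 1e-7.  dt must
not exceed the smallest transmission delay (enforced).

## Wiring policy and threshold calibration

The static network's weights implement the policy: the M unit commanding
contraction of muscle i excites CE_i, alpha_i, the CI of i's antagonist,
and (at half weight) the CE/alpha of i's partial agonists; its dual applies
the same pattern to the antagonist.  Ib_i excites CI_i, the CE/alpha of
i's antagonist, and the M unit commanding relaxation of muscle i; Ia edges
repeat the pattern at 0.8 weight.  Only excitatory weights appear in the
policy; signed (inhibitory) weights occur only inside the dual pairs and
the E–I circuit.

Unit thresholds are calibrated at build time so that the rest posture is an
exact network fixed point with configured baseline activities (SPA 0.15,
M 0.2, CE 0.25, CI 0.35, alpha 0.15) — inhibitory interneuron activity
dominating excitatory, as required for stability.  The SA thresholds equal
each unit's rest input, placing SA mid-range (0.5) at rest.

The loop gain knob is the slope of the M and SA sigmoids.  Defaults
(beta_M = 1.5, beta_SA = 6) put the learning configurations just below the
onset of endpoint oscillation; the static configuration uses beta_M = 2.0,
slightly above, so oscillation is visible — each configuration is tuned
separately, as the original optimization also treated configurations
independently.

## Protocols

* **Training**: 16 SP targets, 40 s each, sampled uniformly in joint angles
  (shoulder −20°…110°, elbow 10°…150°, rejecting postures outside a
  0.12–0.55 m hand annulus), with unit noise and the ACT/CHG machinery
  active.  Success = time-averaged hand–target distance < 10 cm over the
  last four presentations.
* **Center-out**: 8 targets on a 10-cm ring around the rest hand position,
  6 repetitions in random order, 5 s per reach, a 5-s center reach before
  each, noise off.  48 peripheral reaches.
* **PD drift**: 40 further reaches at 10 targets, learning on, noise off.
* **Mass change**: center-out at 0.8 kg then 1.2 kg per link.
* **Spinal stimulation**: all populations except CE/CI/alpha silenced;
  for each point of a 5×5 grid spanning 20×20 cm around rest, the arm is
  held for 0.4 s while the stimulated circuit settles, then released; the
  direction-field vector is the direction of hand displacement over the
  first 150 ms.  Stimulation adds 0.3 to the input of a site's CE and CI
  units — the largest amplitude at which single-site fields remain
  convergent with fixed points inside the grid and summation stays
  near-linear (swept in tests).

## Analyses

* **Rates** for tuning analyses are averaged over the first 4 s of each
  5-s reach: in a gravity-free plant, holding a reached posture needs no
  net drive, so the directional signal lives in the transit phase.
* **PD vectors** come from an ordinary least-squares plane fit of mean rate
  on shifted target coordinates; the PD is the in-plane gradient, which
  equals the projection of the plane's downward normal (an equivalence the
  test suite checks on cosine-tuned fixtures).  Tuning significance uses a
  10,000-shuffle bootstrap of target labels at the 99.9 % criterion.
* **PD prediction**: per-muscle maximum-contraction vectors
  `v_i = Σ_k [(l_i0 − l_ik)/l_i0]_+ r_k` over the 8 targets, combined with
  the signed SPA→M weights.  Angle residuals are minimal rotations, scaled
  by each unit's PD norm relative to the mean norm (long PD vectors are
  measured more reliably); R² uses the conventional 1 − SS_res/SS_tot with
  SS_tot from the raw PD angles.
* **Main axis**: angles in the lower half-plane are reflected by +180°, and
  the axis is the direction of the length-weighted resultant, reported in
  [0°, 180°).
* **Axial bimodality** uses the 180°-doubled Rayleigh statistic
  `r = [(Σ cos 2φ)² + (Σ sin 2φ)²]/N` (the printed source sums the cosine
  term twice — an evident typo; the sine reading is implemented) against
  100,000 uniform-null draws at the 99.9 % criterion.
* **jPCA**: per-condition trial-averaged M traces over 0.05–0.55 s after
  target onset at 10-ms cadence, cross-condition mean removed, no PCA
  preprocessing.  The dynamics matrix solves `Xdot = X M` by least squares
  (central-difference derivative); planes come from the conjugate
  eigenvector pairs of the skew-symmetric part and are reported in order of
  captured variance, so the plane-1 fraction is the strength of the
  strongest rotational component.
* **Direction-field linearity**: gamma is the grid-mean *absolute* minimal
  angle between the joint-stimulation field D(a+b) and the vector sum
  D(a)+D(b) (a signed mean would cancel and make the shuffle comparison
  meaningless), averaged over the 15 site pairs.  The null re-pairs each
  joint field with the summed singles of a different random pair, 400
  times, at the 99 % criterion.

## What the synthetic generator does and does not emulate

All inputs are generated internally; there is no external data.  The
synthetic fixtures (cosine-tuned rates, embedded rotations, additive field
triples, scripted lag-coupled signal pairs) provide exact ground truth for
the analysis and plasticity code, but they idealize away the closed-loop
couplings — oscillation harmonics in rates, saturation, drift — so passing
them shows correctness of the statistics, not of the model.  The simulation
protocols themselves are the model-level evidence.

## Problem sizes

Default experiment sizes are those of the protocols above: 16×40 s
training, 48 center-out reaches, 25-point stimulation grids, 10,000
tuning shuffles, 100,000 bimodality null draws, 400 field shuffles.  The
acceptance script runs 5 training seeds per configuration.

## Known limitations

* Most numeric constants (unit slopes, weights, muscle stiffnesses,
  learning rates) are this package's own calibration; the original values
  were never published and were found there by a population-based parameter
  search that is out of scope here.  Quantities that depend on those
  constants (the main-axis angle, R², gamma values) reproduce the reported
  phenomena at similar, not identical, values.
* Learning acquisition from random weights is the least robust part:
  the differential Hebbian rule reliably *maintains* a working map (a
  policy-initialized plastic network stays functional through training),
  but acquiring one within 16 presentations succeeds in only part of the
  seeds at these hand-tuned constants, short of the near-perfect rate the
  phenomenon can reach with searched parameters.
* With the calibrated constants the static network's rotational (jPCA
  plane-1) variance fraction and the axial concentration of its PD
  distribution come out somewhat stronger than the values the model family
  is reported to produce; both track the oscillation gain and the
  muscle-insertion geometry, neither of which is published.
* The pulley muscle paths trade the length nonlinearity of straight chords
  for global sign stability; moment arms are constant in posture.
* No cerebellum, no visual feedback, no force-length/force-velocity Hill
  curves, no fatigue; movements are deliberately slow.
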