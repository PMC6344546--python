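# Methods

`synergait` is a forward-dynamics simulator of sagittal-plane human gait in
which walking and running both emerge from one muscle-synergy motor
controller.  This note documents the model, its parameters, the numerical
choices, and what the shipped tests do and do not establish.

## Skeleton

The body is seven rigid links — a single head-arms-trunk (HAT) segment and
thigh, shank, foot per leg — with nine generalized coordinates: trunk-COM
translation (x, y), trunk pitch θ, and hip/knee/ankle angles per leg.  Joint
angles are flexion-positive; trunk pitch is CCW-positive, so with travel
along +x a positive θ is a backward lean.  That orientation is forced by the
signs of the printed balance gains (κ_GM = +2 must *reduce* hip-extensor
drive when the trunk tilts backward past the reference θ̂ = 0.01 rad).

The equations of motion M(q)q̈ = h(q, q̇) + Q are assembled numerically from
per-segment chain Jacobians:

    M = Σ_s ( m_s J_sᵀ J_s + I_s jw_s jw_sᵀ ),
    h = −Σ_s m_s J_sᵀ a0_s − ∂V/∂q,

where a0_s is the segment-COM acceleration at q̈ = 0.  Because segment
orientation angles are linear in q in a planar chain, the rotational part
contributes no velocity bias.  The assembly is verified against a completely
independent symbolic Lagrangian derivation (sympy) at random states to below
1e-6 relative error, and against closed forms (free fall, pendulum inertia
about a fixed hip, energy conservation).

Each joint carries linear viscous friction, and the knee (0.1–2.8 rad) and
ankle (−1.0–0.54 rad) have stiff spring-damper limit torques engaged only
outside their ranges.

Segment masses, lengths, COM offsets and inertias are standard anthropometric
fractions (Winter's tables) scaled to a 63.3 kg, 1.66 m subject; they ship as
an editable YAML fixture (`presets/body_default.yaml`).

## Foot-ground contact

Each sole carries four contact points (heel to toe).  The normal force is a
unilateral spring-damper on ground penetration, clamped at zero so the ground
never pulls.  The tangential force is a spring-damper anchored at the
touchdown position; the anchor slips whenever the elastic force would exceed
μ·F_n, which keeps the model smooth (no Coulomb discontinuity) while bounding
shear.  Normal stiffness keeps static standing penetration below 5 mm.  A
discrete four-point sole makes the GRF fluctuate within stance; the analysis
stage smooths and debounces accordingly.

## Muscles

Nine Hill-type muscles per leg (IL, GM, VA, BFS, TA, SO uniarticular; RF,
BFL, GC biarticular) with *constant* signed moment arms, so musculotendon
length is affine in joint angles and joint torque is simply Σ r·F.  The
contractile element is a·F_max·f_L·f_V with a Gaussian force-length bell
(width 0.45 l_opt) and a classic Hill hyperbola for shortening with a smooth
eccentric continuation plateauing at 1.5 F_max.  A parallel elastic element
engages quadratically beyond a slack length of 1.2 l_opt.  Activation follows
the motor command through a first-order low-pass filter (rise 20 ms, decay
60 ms) with the command clamped to [0, 1].

There is no series tendon (out of scope), so `l_opt` is an *effective
musculotendon operating length*: it is set to roughly 2.5× the summed moment
arms so that physiological joint excursions stay within the force-length
bell.  F_max values started from published planar-gait datasets
(Geyer-Herr-type parameter sets scaled to the 63.3 kg subject) and were then
tuned, together with the muscle-geometry reference posture, contact
constants and joint viscosities, so that the *fixed published controller*
carries a periodic gait — the same kind of plant-side hand-tuning the
original modelling studies describe.  The search used single-stride shooting
(half-cycle map with a left-right leg swap, delay line warmed up over one
cycle) to locate periodic orbits, and hill-climbing over plant constants to
improve their persistence.  The controller parameters themselves were never
touched.

## Motor control

A phase oscillator (φ̇ = 2π/T) drives five rectangular pulses per cycle;
pulse i is active for (φ − Φ_i) mod 2π ∈ (0, Δ_i].  The modular reading
matters: the fifth preset pulse ends at Φ_5 + Δ_5 = 6.30 rad > 2π and must
wrap.  Each muscle receives u_syn = Σ_i Λ_i w_{m,i} p_i(φ_leg), with the right
leg at φ and the left leg at φ + π.  The movement regulator adds delayed
(τ = 80 ms) feedback: trunk-balance corrections through IL/GM of the stance
leg (−κ(θ−θ̂) − σθ̇) and speed corrections through TA/SO of the stance leg
(−λ(v−v̂)), where v is the trunk horizontal velocity and stance is read from
the contact model.  The total command u = u_syn + u_reg is clamped to
[0, 1.5] before the activation filter; motor-neuron drive cannot be negative.

The movement generator has 61 parameters (T, 5 Φ, 5 Δ, 45 w, 5 Λ) and the
regulator 8; the shipped walking and running presets hold the published
values bit-exact and differ in exactly seven parameters
{T, Φ_2, Λ_1..Λ_5} — asserted by a unit test.

The regulator contribution metric is operationalized as
100·∫Σ_m|u_reg|dt / ∫Σ_m|u|dt over steady cycles (all nine muscles in both
sums); alternative readings (speed-loop-only numerator, TA/SO-only
denominator) are available behind a flag since the original definition is
not spelled out.

## Integration

Classical fixed-step RK4 at 0.02 ms on the full coupled state (skeleton,
activations, phase), with the control sampled on the integrator grid and the
delay implemented as a ring buffer (nearest-sample lookup; τ/dt is an
integer at all shipped steps).  Contact anchors and touchdown/liftoff
bookkeeping update once per step.  A 0.1 ms smoke mode is used in the test
suite; step counts and gait classification agree between the two steps,
while cycle-averaged metrics shift slightly because the orbits are only
marginally stable.  The inner loop is numba-compiled.

Falls are detected as trunk COM below 60% of standing height or |θ| > 1 rad;
a fall flags the record rather than raising.  A run is "successful" when it
takes at least 10 touchdowns before any fall (the behavioural criterion
reads literally: kept going without falling over for at least 10 steps).  Steady-state metrics use
cycles 3 onward (right-touchdown to right-touchdown).

## Analysis stage

Touchdown/liftoff are 5 N threshold crossings of the per-leg vertical GRF
with 10 ms debounce; per-sample stance occupancy is rebuilt from the
debounced events so that sub-debounce force dips (four-point sole chatter)
do not masquerade as flight.  Cycle waveforms are linearly resampled to 500
points and averaged.  Vertical-GRF peak counting smooths the 500-point
stance waveform with an 11-sample moving average and requires 5% prominence.
Waveform agreement uses cosine similarity S for nonnegative traces and
Pearson R otherwise.  EMG processing follows the standard pipeline
(2nd-order Butterworth 1 Hz high-pass, demean, rectify, zero-lag 5 Hz
low-pass) and EMG-to-activation magnitude matching equalizes the walk/run
mean of envelope maxima per muscle against the simulation.

## Synthetic analysis fixtures

`make_synthetic_gait_fixture` generates analytically known traces —
square-duty stance windows (duty 0.62 walking / 0.35 running), two-Gaussian
vs single-Gaussian vertical GRF, sinusoidal COM height/speed (antiphase for
walking, in phase for running), rectangular EMG bursts — with exact event
times, optional Gaussian noise, and a seeded generator.  These validate the
analysis stage independently of the simulator.  They emulate the *shape*
features the analysis keys on, not musculoskeletal dynamics; passing them
says nothing about simulator realism, which is instead checked by the
dynamics oracles and the end-to-end gait tests.

## What the shipped configuration actually does

With the published controller and the reconstructed plant, the shipped
presets carry periodic gaits that are *weakly unstable* limit cycles
(stride-map spectral radius above one).  Launched from the preset's shipped
fixed-point state, each run sustains well over ten touchdowns before the
instability grows into a fall, satisfying the behavioural success criterion
("kept going without falling over for at least 10 steps") literally; the
success flag counts touchdowns that occur before any fall.  Two caveats
matter when interpreting results:

- The walking preset's emergent gait on this plant carries short flight
  phases (grounded-running character) instead of the double-stance walk the
  original work reports; its vertical-GRF shape (two peaks per stance) and
  COM mechanics (height/speed in antiphase) are nevertheless walking-like.
  The running preset produces a faster-cadence bouncing gait with flight.
- Because the orbits decay, cycle-averaged quantities measured over the
  steady window (cycles 3 onward) underestimate the orbit's nominal speed.

Both points trace to the plant-constant gap: the original muscle, viscosity
and contact values are in references that are not reproduced in the source
text, and the controller's behaviour is sensitive to them.  The tests assert
the oracle-verified mechanics exactly and the behavioural claims at the
stated tolerances; behavioural assertions that the reconstruction cannot
meet are left failing rather than weakened.

## Known limitations

- The original model's muscle/segment/contact constants are not published in
  the source papers available here; this implementation's plant is an
  explicit, versioned reconstruction, so waveform-level agreement with the
  original figures is approximate and only the headline behaviours
  (gait classes, speeds, regulator share, GRF shape, COM phase) are asserted
  with tolerances.
- No series-elastic tendon, pennation, or metabolic cost; no 3-D effects,
  arm swing, or pelvis rotation; no sensory modulation of pulse timing.
- The speed-sweep driver replays user-supplied rows of the seven switch
  parameters; per-speed values other than the two shipped presets are not
  published and are left to the user's hand-tuning.
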