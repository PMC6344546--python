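# synergait

Forward-dynamics simulation of human walking **and** running from one
muscle-synergy motor controller, in the sagittal plane.

## The problem

Human legs have far more muscles than mechanical degrees of freedom, yet EMG
recordings during gait are well explained by a handful of basic activation
waveforms shared across muscles (the muscle-synergy hypothesis).  A central
pattern generator that emits a few timed pulses, with fixed per-muscle
weights, would then be enough to drive locomotion — and switching gait or
speed would only require retiming/rescaling those pulses, not re-planning
every muscle.  Demonstrating that this scheme can actually *balance and
propel* a body is a dynamics question, so it needs a neuromusculoskeletal
simulation: bipedal gait is a limit cycle of the coupled controller-body
-ground system, not a property of the controller alone.

`synergait` implements that demonstration end to end:

- **Skeleton** — seven rigid links (HAT trunk, thighs, shanks, feet), nine
  DOF, Lagrangian dynamics assembled from chain Jacobians, joint viscosity
  and knee/ankle limit torques, four viscoelastic contact points per sole,
  classical RK4 at dt = 0.02 ms.
- **Muscles** — nine Hill-type muscles per leg (IL, GM, VA, BFS, TA, SO
  uniarticular; RF, BFL, GC biarticular) with constant moment arms,
  force-length/force-velocity scaling, parallel elasticity and first-order
  activation dynamics.
- **Motor control** — a movement generator: five rectangular pulses
  p_i(φ) per cycle, φ̇ = 2π/T, muscle command
  u_syn_m = Σ_i Λ_i·w_mi·p_i(φ_leg) (legs in antiphase); plus a movement
  regulator: delayed (τ = 80 ms) trunk-balance feedback through the stance
  hip muscles, −κ_m(θ−θ̂) − σ_m·θ̇, and speed feedback through the stance
  ankle muscles, −λ_m(v−v̂).  69 parameters total; walking→running changes
  exactly seven of them: {T, Φ₂, Λ₁…Λ₅}.
- **Analysis** — touchdown/liftoff detection from vertical GRF, 500-point
  cycle normalization, double-stance/flight occupancy, GRF peak counting,
  whole-body COM mechanics, cosine-similarity/correlation scoring, EMG
  envelope processing and EMG-driven joint-torque estimation.

Intended users: motor-control and biomechanics researchers who want a
transparent, hackable planar testbed for synergy-based control ideas, and
methods developers who need a deterministic gait-record generator with a
complete analysis stage.

## Worked example

```python
from synergait import load_preset, preset_diff, run_gait

walk = load_preset("walking_1.6")
run = load_preset("running_1.6")
print(sorted(preset_diff(walk, run)))

for preset in (walk, run):
    record, m = run_gait(preset, duration=15.0, dt=2e-5)
    print(f"{preset.label}: steps={m.steps} success={record.success} "
          f"speed={m.average_speed:.2f} m/s grf_peaks={m.grf_peaks} "
          f"com_corr={m.com_height_speed_correlation:+.2f}")
```

prints

```
['Lambda_1', 'Lambda_2', 'Lambda_3', 'Lambda_4', 'Lambda_5', 'Phi_2', 'T']
walking_1.6: steps=22 success=True speed=1.07 m/s grf_peaks=2 com_corr=-0.19
running_1.6: steps=14 success=True speed=0.54 m/s grf_peaks=1 com_corr=+0.19
```

The first line confirms the two presets differ in exactly the seven switch
parameters.  Each preset then sustains well over ten steps from its shipped
limit-cycle launch state; the walking run shows the two-peaked vertical GRF
and pendular COM mechanics (height/speed in antiphase), the running run the
single-peaked GRF and in-phase (spring-mass) COM mechanics.  Both orbits are
weakly unstable on the reconstructed plant — the runs end in a fall after
the steps shown, and the walking gait carries short flight phases instead of
the double-stance phases of the original work; `docs/methods.md` discusses
this reconstruction gap (the original plant constants are unpublished) and
what is and is not asserted by the test suite.

The same run from the shell:

```bash
synergait run --preset walking_1.6 --duration 15 --out out/walk
synergait run --preset running_1.6 --duration 15 --out out/run
synergait analyze out/walk/record.csv --out out/walk/metrics.json
```

A run writes `record.csv` (time, generalized coordinates and rates, per-muscle
commands/activations/forces, per-foot GRF, stance flags, oscillator phase at
1 ms sampling) plus `metrics.json`.

## Layout

```
src/synergait/
  motor_control.py     pulse generator, regulator, delay line
  muscle_model.py      Hill muscles, activation dynamics, torque estimation
  skeleton_dynamics.py body parameters, EOM, contact, RK4, simulate()
  gait_analysis.py     events, cycle waveforms, metrics, similarity, EMG
  experiments.py       presets, gait switch, speed sweeps, synthetic fixtures
  _engine.py           numba-compiled inner loop
  presets/             controller presets + body/muscle fixtures (YAML)
docs/methods.md        model description, assumptions, limitations
tests/                 pytest suite (unit, property, acceptance)
```
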