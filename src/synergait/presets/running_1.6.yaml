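# Motor-control preset: running at desired speed 1.6 m/s.
# Differs from walking_1.6 in exactly seven parameters:
# T, Phi_2 and the five pulse amplitudes Lambda_1..5.
label: running_1.6
provenance: published seven-parameter switch from the walking set
pulses:
  T: 0.8
  onset: [0.0, 0.16, 2.44, 3.69, 5.36]
  duration: [0.75, 1.10, 1.20, 1.07, 0.94]
  amplitude: [1.34, 1.29, 0.73, 0.62, 0.50]
  weights:
    IL:  [0.0, 0.0, 0.99, 0.0, 0.0]
    GM:  [0.33, 0.0, 0.0, 0.0, 1.17]
    VA:  [1.02, 0.0, 0.0, 0.23, 0.0]
    BFS: [0.0, 0.0, 0.34, 0.0, 0.76]
    TA:  [0.27, 0.0, 0.97, 0.15, 0.0]
    SO:  [0.0, 1.09, 0.0, 0.0, 0.0]
    RF:  [0.0, 0.0, 0.02, 0.0, 0.29]
    BFL: [0.0, 0.0, 0.0, 0.0, 0.14]
    GC:  [0.0, 0.84, 0.65, 0.0, 0.0]
regulator:
  kappa_IL: -1.0
  kappa_GM: 2.0
  sigma_IL: -0.2
  sigma_GM: 0.4
  lambda_TA: -0.2
  lambda_SO: 0.04
  theta_ref: 0.01
  v_ref: 1.6
  tau: 0.08
# Limit-cycle launch state for the shipped body/muscle
# fixtures (packed q, qd, activations, oscillator phase)
launch:
  state: [0.0, 1.2846357258, -0.063500577, 0.5087448074, 0.4662700849, 0.5918456314,
    1.1013140433, -0.4073409235, 0.5737426598, 2.184383623, 0.0713941033, 0.0593320661,
    -0.2037897997, 1.3279989927, 4.0513613847, -0.4800919412, 0.3476820443, 5.4342426375,
    0.1631931403, 0.6660680993, 0.0955180707, 0.4570585133, 0.1435861736, 0.2735432027,
    0.0718301709, 0.3292835139, 0.3173499378, 0.6405672652, 0.2525376222, 0.1565589665,
    0.8240056122, 0.5610607865, 0.2969092688, 0.2223409651, 0.0990626943, 0.1115723625,
    5.9690260418]
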