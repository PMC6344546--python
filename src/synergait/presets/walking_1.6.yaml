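# Motor-control preset: walking at desired speed 1.6 m/s.
# 61 movement-generator parameters (T, Phi_i, Delta_i, w_{m,i}, Lambda_i)
# and 8 movement-regulator parameters plus the neural delay tau.
label: walking_1.6
provenance: published hand-tuned walking parameter set, desired speed 1.6 m/s
pulses:
  T: 1.0
  onset: [0.0, 1.59, 2.44, 3.69, 5.36]
  duration: [0.75, 1.10, 1.20, 1.07, 0.94]
  amplitude: [1.0, 1.0, 1.0, 1.0, 1.0]
  # weights w_{m,i}: muscle -> five pulse coefficients (omitted entries are 0)
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
  state: [0.0, 1.2157294878, -0.0369220246, 0.4403611351, 0.0493307349, 0.3915618201,
    -0.047531404, 0.3263673746, -0.0831933174, 1.5838026382, -0.0638472549, 0.3340796135,
    -1.1089224381, -0.8468529072, -1.7827276413, -0.7990952452, 0.7629572496, 7.784867616,
    0.0191827253, 0.9903849097, 0.1867064939, 0.8417247634, 0.0080734553, 0.0988053483,
    0.313497178, 0.144078975, 0.0091393683, 0.9608542481, 0.0258924855, 0.1197725737,
    0.2913915589, 0.9543937943, 0.0734870121, 0.1161690676, 0.0544090369, 0.6380600872,
    5.9690260418]
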