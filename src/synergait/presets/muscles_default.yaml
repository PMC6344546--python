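# Hill-muscle fixture for the planar nine-muscle leg.
# Values adapted from published human lower-limb datasets and tuned for this
# planar constant-moment-arm abstraction (no series tendon, so l_opt is an
# effective musculotendon operating length).  Positive moment arm = flexion
# torque.  v_max in m/s; slack in units of l_opt.
tau_rise: 0.02
tau_fall: 0.06
curves:
  fl_width: 0.45
  fv_shape: 0.25
  fv_ecc: 1.5
  pe_width: 0.5
ref_angles:
- 0.16207793030878226
- 0.47707262643925535
- -0.013664485251718499
muscles:
  IL:
    f_max: 1478.0272828784482
    l_opt: 0.2
    v_max: 2.4
    r_hip: 0.08
    r_knee: 0.0
    r_ankle: 0.0
    slack: 1.2
  GM:
    f_max: 1286.7682158471134
    l_opt: 0.2
    v_max: 2.4
    r_hip: -0.08
    r_knee: 0.0
    r_ankle: 0.0
    slack: 1.2
  VA:
    f_max: 4608.088924968648
    l_opt: 0.15
    v_max: 1.8
    r_hip: 0.0
    r_knee: -0.06
    r_ankle: 0.0
    slack: 1.2
  BFS:
    f_max: 562.5658917712565
    l_opt: 0.11
    v_max: 1.35
    r_hip: 0.0
    r_knee: 0.045
    r_ankle: 0.0
    slack: 1.2
  TA:
    f_max: 1100.9716511995389
    l_opt: 0.1
    v_max: 1.2
    r_hip: 0.0
    r_knee: 0.0
    r_ankle: 0.04
    slack: 1.2
  SO:
    f_max: 4041.5094395048854
    l_opt: 0.125
    v_max: 1.0
    r_hip: 0.0
    r_knee: 0.0
    r_ankle: -0.05
    slack: 1.2
  RF:
    f_max: 935.7194958608081
    l_opt: 0.25
    v_max: 3.0
    r_hip: 0.08
    r_knee: -0.05
    r_ankle: 0.0
    slack: 1.2
  BFL:
    f_max: 2157.640884100759
    l_opt: 0.25
    v_max: 3.0
    r_hip: -0.08
    r_knee: 0.05
    r_ankle: 0.0
    slack: 1.2
  GC:
    f_max: 1519.041292211294
    l_opt: 0.25
    v_max: 2.5
    r_hip: 0.0
    r_knee: 0.05
    r_ankle: -0.05
    slack: 1.2
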