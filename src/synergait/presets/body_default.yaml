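# Anthropometric body fixture: Winter segment fractions scaled to a
# 63.3 kg, 1.66 m subject; viscoelastic sole-contact, joint viscosity and
# joint-limit constants tuned (with the published controller held fixed)
# so the closed loop carries a periodic gait.
m_trunk: 42.92
i_trunk: 2.833811527415346
d_hip: 0.2554095984700599
m_thigh: 6.33
i_thigh: 0.109
l_thigh: 0.407
c_thigh: 0.176
m_shank: 2.94
i_shank: 0.045
l_shank: 0.408
c_shank: 0.177
m_foot: 0.9349770887930969
i_foot: 0.013211632776424195
c_foot_ax: 0.06
c_foot_pp: 0.04
h_sole: 0.065
sole_offsets:
- -0.0630775023618097
- 0.020024603924384033
- 0.10012301962192016
- 0.1852275863005523
k_contact: 86832.57772613782
c_contact: 1424.15845392321
k_tangent: 20529.051321746454
c_tangent: 611.1357569553077
mu: 1.0163894725986358
g: 9.81
c_hip: 3.6559653321305774
c_knee: 3.6559653321305774
c_ankle: 2.437310221420385
knee_limits:
- 0.1
- 2.8
ankle_limits:
- -1.0
- 0.54
k_limit: 1000.0
c_limit: 50.0
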