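pKa: 9.3
pH: 7.4
diffusion: 5500.0
concentration: 1.0e-05
d: 0.7
T: 295.0
kd0_charged_open: 1.12e-05
kd_neutral_open: 0.0004
kd_neutral_closed: 0.0008
kd_neutral_inactivated: 5.4e-06
closed_ref_voltage: -100.0
ax1: 1.0
bx1: 1.0
a13c: 1.0
a22: 1.0
b33: 1.0
a33: 1.0
a44: 1.0
b44: 1.0
ax2: 1.0
a13n: 1.0
a_22: 1.0
b_33: 1.0
a_44: 1.0
b_44: 1.0
ki_on: 5500.0
ki_off: 0.0297
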