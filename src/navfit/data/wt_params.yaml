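a11_v1: 0.1
a11_v2: 17.0
a12: 1.0
a13: 1.0
b11_v1: 5.0
b11_v2: 22.0
b12: 1.0
b13: 1.0
a3_v1: 3.8e-07
a3_v2: 7.7
b3_v1: 0.2
b3_v2: 40.0
a2_v1: 3.0
a2_v2: 30.0
ax: 0.05
bx: 0.022222222222222223
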