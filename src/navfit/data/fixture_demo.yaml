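# Demo fixture recipe: the six drug-free protocols plus a 10 uM flecainide
# use-dependent-block condition, with 1% Gaussian noise on the readouts.
noise_sd: 0.01
seed: 2026
protocols:
- {protocol: SSA}
- {protocol: ACT}
- {protocol: RFI}
- {protocol: RUDB}
- {protocol: TAU50}
- {protocol: MOT}
- {protocol: UDB, concentration: 1.0e-05}
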