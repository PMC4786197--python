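- name: SSA
  holding: -100.0
  segments:
  - {level: sweep, duration: 500.0}
  - {level: -20.0, duration: 25.0, record: true, tag: test}
  sweep: [-140.0, -120.0, -110.0, -100.0, -90.0, -80.0, -70.0, -60.0, -40.0]
  readout: {statistic: availability, test: test, normalize: max}
  sweep_unit: mV
  sweep_kind: segment
  drug_start: equilibrated
- name: ACT
  holding: -100.0
  segments:
  - {level: sweep, duration: 25.0, record: true, tag: test}
  sweep: [-60.0, -50.0, -40.0, -30.0, -20.0, -10.0, 0.0, 10.0]
  readout: {statistic: activation, test: test, normalize: max}
  sweep_unit: mV
  sweep_kind: segment
  drug_start: equilibrated
- name: RFI
  holding: -100.0
  segments:
  - {level: -20.0, duration: 100.0, record: true, tag: ref}
  - {level: -100.0, duration: sweep}
  - {level: -20.0, duration: 25.0, record: true, tag: test}
  sweep: [1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0]
  readout: {statistic: recovery_fraction, test: test, reference: ref, normalize: none}
  sweep_unit: ms
  sweep_kind: segment
  drug_start: equilibrated
- name: RUDB
  holding: -100.0
  segments:
  - level: -20.0
    duration: 25.0
    repeat: 20
    period: 40.0
    record_pulses: [1]
  - {level: -100.0, duration: sweep}
  - {level: -20.0, duration: 25.0, record: true, tag: test}
  sweep: [1.0, 10.0, 100.0, 1000.0, 10000.0]
  readout: {statistic: recovery_fraction, test: test, reference: P1, normalize: none}
  sweep_unit: ms
  sweep_kind: segment
  drug_start: equilibrated
- name: TAU50
  holding: -100.0
  segments:
  - {level: sweep, duration: 25.0, record: true, tag: test}
  sweep: [-30.0, -20.0, -10.0, 0.0, 10.0]
  readout: {statistic: tau50, test: test, normalize: none}
  sweep_unit: mV
  sweep_kind: segment
  drug_start: equilibrated
- name: MOT
  holding: -100.0
  segments:
  - {level: sweep, duration: 1.0}
  sweep: [-30.0]
  readout: {statistic: mot, test: test, normalize: none}
  sweep_unit: mV
  sweep_kind: segment
  drug_start: equilibrated
- name: SSA_DRUG
  holding: -100.0
  segments:
  - {level: sweep, duration: 500.0}
  - {level: -20.0, duration: 25.0, record: true, tag: test}
  sweep: [-140.0, -120.0, -110.0, -100.0, -90.0, -80.0, -70.0, -60.0, -40.0]
  readout: {statistic: availability, test: test, normalize: max}
  sweep_unit: mV
  sweep_kind: segment
  drug_start: equilibrated
- name: TB
  holding: -100.0
  segments:
  - {level: sweep, duration: 25.0, record: true, tag: test}
  sweep: [-20.0]
  readout: {statistic: peak, test: test, normalize: drug_free}
  sweep_unit: mV
  sweep_kind: segment
  drug_start: equilibrated
- name: UDB
  holding: -100.0
  segments:
  - {level: -20.0, duration: 25.0, repeat: 30, period: 100.0}
  sweep: [2.0, 5.0, 10.0, 20.0, 30.0]
  readout: {statistic: pulse_ratio, test: P30, reference: P1, normalize: none}
  sweep_unit: pulse
  sweep_kind: pulse_index
  drug_start: equilibrated
- name: RUDB_DRUG
  holding: -100.0
  segments:
  - level: -20.0
    duration: 25.0
    repeat: 30
    period: 100.0
    record_pulses: [1]
  - {level: -100.0, duration: sweep}
  - {level: -20.0, duration: 25.0, record: true, tag: test}
  sweep: [10.0, 100.0, 1000.0, 5000.0, 20000.0]
  readout: {statistic: recovery_fraction, test: test, reference: P1, normalize: none}
  sweep_unit: ms
  sweep_kind: segment
  drug_start: equilibrated
- name: FDUDB
  holding: -100.0
  segments:
  - level: -20.0
    duration: 25.0
    repeat: 30
    period: sweep_period
    record_pulses: [1, 30]
  sweep: [2.0, 5.0, 10.0, 20.0]
  readout: {statistic: pulse_ratio, test: P30, reference: P1, normalize: none}
  sweep_unit: Hz
  sweep_kind: segment
  drug_start: equilibrated
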