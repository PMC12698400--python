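# Hypocapnic hypoxia: PaO2 100 -> 29 mmHg with PaCO2 falling 40 -> 27 mmHg
# (hyperventilation-induced). Outputs of interest: MV and RR.
name: study3_hypocapnic_hypoxia
mode: open_loop_gas
duration_min: 16.0
schedules:
  pao2:
    times: [0.0, 4.0, 12.0, 16.0]
    values: [100.0, 100.0, 29.0, 100.0]
    interp: linear
  paco2:
    times: [0.0, 4.0, 12.0, 16.0]
    values: [40.0, 40.0, 27.0, 40.0]
    interp: linear
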