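# Progressive hypoxia with mild CO2 drift; prescribed arterial gases drive
# the respiratory control + mechanics components open-loop (subject-1 style
# envelope: PaO2 36-120 mmHg, PaCO2 32-37 mmHg). Output of interest: MV.
name: study1_hypoxia
mode: open_loop_gas
duration_min: 16.0
schedules:
  pao2:
    times: [0.0, 3.0, 8.0, 13.0, 16.0]
    values: [100.0, 100.0, 36.0, 115.0, 120.0]
    interp: linear
  paco2:
    times: [0.0, 3.0, 8.0, 13.0, 16.0]
    values: [33.0, 33.0, 37.0, 33.0, 32.0]
    interp: linear
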