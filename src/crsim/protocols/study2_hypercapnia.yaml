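# Stepwise hypercapnia at constant hypoxic PaO2 (40 mmHg); PaCO2 raised
# 40 -> 48 mmHg in 2-mmHg steps. Output of interest: steady-state MV.
name: study2_hypercapnia
mode: open_loop_gas
duration_min: 25.0
schedules:
  pao2:
    times: [0.0]
    values: [40.0]
    interp: hold
  paco2:
    times: [0.0, 5.0, 10.0, 15.0, 20.0]
    values: [40.0, 42.0, 44.0, 46.0, 48.0]
    interp: hold
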