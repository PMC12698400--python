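# Graded inspired CO2 (0 -> 3%) at room-air FiO2. Outputs MV and RR.
name: study5_fico2
mode: closed_loop
duration_min: 30.0
schedules:
  fico2:
    times: [0.0, 5.0, 10.0, 15.0, 25.0]
    values: [0.0, 0.01, 0.02, 0.03, 0.0]
    interp: hold
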