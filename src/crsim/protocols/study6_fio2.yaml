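# Graded hypoxic gas mixtures (FiO2 21% -> 9%). Outputs MV and RR.
name: study6_fio2
mode: closed_loop
duration_min: 30.0
schedules:
  fio2:
    times: [0.0, 5.0, 10.0, 15.0, 25.0]
    values: [0.21, 0.15, 0.12, 0.09, 0.21]
    interp: hold
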