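# Inspired-gas challenge: FiO2 lowered 21% -> 10% with 2% inspired CO2,
# then return to room air. Closed-loop; outputs SpO2, ETCO2, MAP, HR.
name: study4_fio2_fico2
mode: closed_loop
duration_min: 30.0
schedules:
  fio2:
    times: [0.0, 10.0, 20.0]
    values: [0.21, 0.10, 0.21]
    interp: hold
  fico2:
    times: [0.0, 10.0, 20.0]
    values: [0.0, 0.02, 0.0]
    interp: hold
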