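# Slow graded airway obstruction at the mouth-larynx segment:
# 2 min baseline, then 25/50/75% for 8 min each, 3 min complete (100%)
# obstruction, then release. Outputs SpO2, ETCO2, SBP, HR.
name: study7_slow
mode: closed_loop
duration_min: 31.0
fao_location: ml
schedules:
  fao:
    times: [0.0, 2.0, 10.0, 18.0, 26.0, 29.0]
    values: [0.0, 0.25, 0.5, 0.75, 1.0, 0.0]
    interp: hold
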