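# Controlled hemorrhage (25% of a 5-L blood volume over 20 min, i.e.
# 0.0625 L/min) followed by spontaneous ventilation.
name: study8_spontaneous
mode: closed_loop
duration_min: 90.0
schedules:
  hemorrhage_rate:
    times: [0.0, 20.0]
    values: [0.0625, 0.0]
    interp: hold
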