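# Hemorrhage (25% blood volume over 20 min) followed by 60 min of
# positive-pressure ventilation (representative inspiratory P_ao; use the
# airway-pressure matching operation to hit a specific target MV), then
# return to spontaneous ventilation.
name: study8_ventilated
mode: closed_loop
duration_min: 90.0
schedules:
  hemorrhage_rate:
    times: [0.0, 20.0]
    values: [0.0625, 0.0]
    interp: hold
  pao:
    times: [0.0, 20.0, 80.0]
    values: [0.0, 4.0, 0.0]
    interp: hold
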