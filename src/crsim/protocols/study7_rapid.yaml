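# Rapid protocol: 3 min of complete obstruction at the mouth-larynx
# segment, then release.
name: study7_rapid
mode: closed_loop
duration_min: 8.0
fao_location: ml
schedules:
  fao:
    times: [0.0, 3.0, 6.0]
    values: [0.0, 1.0, 0.0]
    interp: hold
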