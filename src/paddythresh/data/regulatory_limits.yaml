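# National limits used by the threshold workflow (mg·kg⁻¹).
# mac: food-standard maximum allowable concentration in milled rice (GB 2762).
# rsv/riv: soil risk screening / intervention values (GB 15618), pH-binned:
#   neutral = 6.5 < pH <= 7.5, alkaline = pH > 7.5.
mac:
  Cd: 0.2
  As: 0.5
limits:
  - {element: Cd, ph_bin: neutral, rsv: 0.6, riv: 3.0}
  - {element: Cd, ph_bin: alkaline, rsv: 0.8, riv: 4.0}
  - {element: As, ph_bin: neutral, rsv: 25.0, riv: 120.0}
  - {element: As, ph_bin: alkaline, rsv: 20.0, riv: 100.0}
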