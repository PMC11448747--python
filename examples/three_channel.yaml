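# Three-channel brightfield microscope: one 4.5 mm / NA 0.65 objective,
# 45 mm tube lenses, Raspberry-Pi-class cameras (1.12 um pixels),
# channel path lengths 300 / 350 / 400 mm, 532 nm illumination.
objective:
  f_o_mm: 4.5
  na: 0.65
wavelength_nm: 532
channels:
  - {label: bf300, d_total_mm: 300, f_tube_mm: 45, pixel_pitch_um: 1.12}
  - {label: bf350, d_total_mm: 350, f_tube_mm: 45, pixel_pitch_um: 1.12}
  - {label: bf400, d_total_mm: 400, f_tube_mm: 45, pixel_pitch_um: 1.12}
reference_channel: bf300
estimation_channel: bf400
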