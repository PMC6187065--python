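# Full pipeline fixture: network morphometrics + flux partition + AP metrics.
seed: 7
out_dir: tatnet_out
network:
  cell_length: 25.0
  cell_width: 9.0
  segment_length_mean: 5.0
  segment_length_sd: 2.0
imaging:
  pixel_size: 114.0
  psf_fwhm: 280.0
preprocess:
  exclude_margin: 0.5      # um stripped from the cell border
transients:
  k_syst: 2.0              # s^-1
  k_caff: 0.68             # s^-1
  noise_sd: 0.03
ap:
  true_onset_delay: 2.0    # ms
  noise_sd: 0.002
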