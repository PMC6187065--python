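# Synthetic network at the atrial-tissue regime, rendered at confocal scale.
network:
  cell_length: 30.0        # um
  cell_width: 10.0         # um
  segment_length_mean: 5.0 # um
  segment_length_sd: 2.0   # um
imaging:
  pixel_size: 114.0        # nm (confocal); 16.23 for STED
  psf_fwhm: 280.0          # nm
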