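# Demo: bead phantom under the 32x / 0.8 NA light-field configuration,
# scaled down (9x9 lenslets, geometric PSF) so the whole chain runs in
# seconds.  Switch psf_model to "wave" for quantitative resolution work.
seed: 7
optics:
  magnification: 32.0
  numerical_aperture: 0.8
  emission_wavelength: 0.52
  medium_refractive_index: 1.33
  lenslet_pitch: 150.0
  lenslet_focal_length: 3000.0
  camera_pixel_pitch: 10.0
  lenslet_grid: [9, 9]
  supersampling: 3
  psf_model: geometric
  z_min: -20.0
  z_max: 20.0
  z_step: 4.0
illumination:
  mode: selective
  z_center: 0.0
  z_extent: 100.0
  edge_width: 5.0
phantom:
  kind: beads
  n: 4
  diameter_um: 1.0
reconstruction:
  z_extent: 40.0
  z_sampling: 4.0
  iterations: 10
metrics:
  moving_average_window: 1
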