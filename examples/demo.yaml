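# Demo configuration for `enmfactorial all --config examples/demo.yaml`.
# A 150x150-cell synthetic world (0.5 deg cells), 6 smooth climate-like and
# 8 complex edaphic-like layers, 24 soil-specialist virtual species inside
# broad climatic envelopes.
world:
  shape: [150, 150]
  n_climate: 6
  n_edaphic: 8
  climate_range: 40.0      # autocorrelation range, cells
  edaphic_range: 4.0
  climate_correlation: 0.6
  edaphic_correlation: 0.3
  mask_hole_fraction: 0.03
  cell_size: 0.5
  seed: 0

n_species: 24
n_records: 60
niche_family: edaphic
n_niche_layers: 2
breadth: 0.5               # sharp edaphic niche (field SD units)
envelope_breadth: 1.0      # broad climatic tolerance envelope
pca_threshold: 0.95
r_min: 0.5                 # checkerboard candidate resolutions (degrees)
r_max: 15.0
r_step: 0.5
algorithms: [GAM, MElq, RF, SVM]
predictor_labels: [C, E, CE]
pa_mode: spatial
connectivity: 4
seed: 0
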