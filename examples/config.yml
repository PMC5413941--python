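# Example run configuration for `geolca`.
#
# Exactly one landscape source must be given: `synthetic` (parameters for
# the built-in generator) or `files` (a directory previously written by
# `geolca generate` / geolca.synth.write_landscape).

landscape:
  synthetic:
    shape: [200, 200]          # rows, cols
    cell_size: 500.0           # metres; 500 m cells = 25 ha each
    correlation_length: 8.0    # cells; smoothness of soil/climate fields
    riparian_width: 1          # cells of riparian vegetation along streams
    seed: 1

scenarios:
  # HDPE production volumes in tonnes; the defaults span company- to
  # sector-scale demand
  volumes: [23000, 86000, 321000]
  chain:                       # t input per t output along the feedstock chain
    ethylene_per_hdpe: 1.0
    ethanol_per_ethylene: 1.74
    crop_per_ethanol: 3.0
  closure_fraction: 0.2        # fraction of the yield gap closed by
                               # intensification before expansion
  feedstock_label: maize

allocator: logistic            # logistic | proximity

standard_factors:
  luc_gwp_factor: 0.02         # t CO2e per ha per yr (direct land-use change)
  land_occupation: 0.11        # ha*yr per t crop
  erosion_per_ha: 5.0          # t/ha/yr
  water_per_tonne: 60.0        # m3 per t crop
  eutroph_per_tonne: 2.5       # kg N per t crop
  pnv_msa: 0.95
  current_msa: 0.30

impact_models:
  amortization_years: 20
  stream_threshold: 50         # flow-accumulation cells defining a stream
  edge:
    enabled: false             # forest-edge carbon depression
    interior_fraction_at_edge: 0.6
    e_fold_distance: 500.0     # metres
  response:                    # intensification input-response slopes
    slope_n: 20.0              # kg N/ha per t/ha yield increment
    leach_fraction: 0.25
    slope_w: 30.0              # mm irrigation per t/ha yield increment

# optional: two-corner sensitivity ranges around the central run
sensitivity:
  - parameter: impact_models.fert_gwp_per_kg_n
    low: 0.004
    central: 0.0056
    high: 0.008
  - parameter: scenarios.closure_fraction
    low: 0.1
    central: 0.2
    high: 0.3

seed: 1
output_dir: geolca_run
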