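# Demo run: synthetic shelf-station inputs through the full pipeline.
# omzflux run --config examples/demo_config.yaml -o demo_out
output_dir: demo_out
seed: 42
simulate: true

# Isotope context: labelling ratio derived from the standard spike recipe
# (1 g 13C-bicarbonate in 50 mL stock, 4.5 mL into a 4.5 L bottle, 2.2 mM
# ambient DIC); 24-h incubation.
r_dic: null
incubation_days: 1.0
qc_threshold: 0.05
biovolume_variant: printed

kz_m2_s: 1.4e-4
flux_windows:
  NO3: [12, 30]
  H2S: [30, 40]
  S0: [20, 30]
integration_window: [30, 65]
yields: [0.35, 0.58]
stoich_mode: full_to_sulfate

sim:
  station: U1
  depths: [5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 55, 60, 65]
  cells:
    n_cells: 200
    true_rate_mean: 0.19
    true_rate_cv: 0.3
  profiles:
    - {analyte: NO3, surface_conc: 25.0, bottom_conc: 0.0, chemocline_depth: 30.0, noise_sd: 0.3}
    - {analyte: H2S, surface_conc: 0.0, bottom_conc: 7.0, chemocline_depth: 33.0, noise_sd: 0.1}
    - {analyte: S0, surface_conc: 0.0, bottom_conc: 4.0, chemocline_depth: 27.0, noise_sd: 0.1}
    - {analyte: cells_SUP05, surface_conc: 1.0e+8, bottom_conc: 1.7e+9, chemocline_depth: 30.0, noise_sd: 0.0}
    - {analyte: rate_volumetric, surface_conc: 100.0, bottom_conc: 600.0, chemocline_depth: 30.0, noise_sd: 0.0}
  incubation:
    true_denitrification: 10.0
    true_anammox: 2.0
    labeled_fraction: 0.5
    noise_sd: 0.5
    n_replicates: 3
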