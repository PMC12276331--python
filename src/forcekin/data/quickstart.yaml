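# Quickstart pipeline configuration: a small simulated dataset that runs the
# full chain (simulate -> detect -> segment -> Bell-Evans -> kinetics ->
# rate table) in a couple of minutes on one CPU. All units are explicit.
scenario:
  pulling_speeds_um_s: [0.75, 1.5, 3.0, 6.0, 12.0]
  cantilever_k_pN_nm: 10.0
  tether_contour_length_nm: 8.0
  tether_persistence_length_nm: 0.38
  surface_stiffness_pN_nm: 5.0
  bond:
    k_off_per_s: 0.03
    x_beta_nm: 0.5
    kBT_pN_nm: 4.114
    temperature_K: 298.15
  binding_A: 0.4
  binding_t0_s: 0.01
  binding_tau_s: 0.2
  second_bond_A: 0.3
  second_bond_tau_s: 0.25
  noise_sigma_range_pN: [4.0, 6.0]
  sample_rate_per_nm: 10.0
  curves_per_condition: 120
  contact_times_s: [0.05, 0.1, 0.2, 0.35, 0.6, 1.0]
  seed: 7
detection:
  min_drop_sigma: 4.0
  max_drop_width_nm: 2.0
  slope_window_nm: 10.0
  min_drop_abs_pN: 2.0
kinetics:
  tether_radius_nm: 12.0
  n_ligands: 1
  construct_name: quickstart
n_mixture_components: 2
output_dir: forcekin_results
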