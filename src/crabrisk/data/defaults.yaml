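# Default parameterisation of the green-crab shellfish value-at-risk model.
# Every value here can be overridden from a user config file or CLI flags.
#
# Units:
#   cal_per_mg_afdw          small calories per mg ash-free dry weight of flesh
#   afdw_percent_of_wet_weight  AFDW as a percent of landed wet weight [lo, hi]
#   densities                adult crabs per km^2
#   area                     km^2 of commercial harvest ground
#   diet                     fraction of one crab's diet that is the focal species

energetics:
  hardshell_clam:
    cal_per_mg_afdw: 6.15
    afdw_percent_of_wet_weight: [5.2, 6.4]
  oyster:
    cal_per_mg_afdw: 4.85
    afdw_percent_of_wet_weight: [1.7, 1.7]
  mussel:
    cal_per_mg_afdw: 5.47
    afdw_percent_of_wet_weight: [2.5, 6.7]

scenario_densities:
  low: 10000
  medium: 50000
  high: 100000

uncertain_inputs:
  area_km2_mid: 523.71
  area_km2_halfwidth: 75.0
  diet_lo: 0.20
  diet_hi: 0.35

monte_carlo:
  n_reps: 10000
  seed: 1

benefit_transfer:
  bc_harvesting_usd_m: 139.0
  bc_processing_usd_m: 71.0
  bc_distribution_usd_m: 32.0
  bc_labour_usd_m: 95.0
  bc_employment_py: 2580
  distribution_rate: 0.15

sensitivity:
  n_samples: 10000
  den_high: 100000
  diet_total_lo: 0.60
  diet_total_hi: 1.00
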