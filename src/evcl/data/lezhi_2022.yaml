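# Valuation constants for the Lezhi County (Sichuan) 2022 one-year assessment.
# Sources: county statistical yearbook and land-use change survey figures as
# used in the bundled replication run; prices are 1990 constant-price shadow
# prices (reservoir cost 0.67 CNY/m3, Swedish carbon tax 828 CNY/t CO2).
ag_output_value: 3343400000.0    # CNY/a, farm output (agriculture+forestry+husbandry+fishery)
paddy_area: 23068.63             # ha, paddy fields only (water-storage service)
total_area: 75336.09             # ha, all cultivated land incl. field margins
storage_height: 0.2              # m, national-standard paddy water storage height
precip: 923.3                    # mm/a, county mean annual precipitation
evapotrans: null                 # mm/a, not surveyed; water-balance mode unavailable
water_price: 0.67                # CNY/m3, shadow-engineering reservoir cost
biomass: 745196.0                # t/a, biological yield on cultivated land
co2_per_dm: 1.63                 # t CO2 absorbed per t dry matter
o2_per_dm: 1.19                  # t O2 released per t dry matter
carbon_fraction: 0.2729          # C / CO2 mass ratio
carbon_price: 828.0              # CNY/t CO2 (1200 SEK/t)
o2_price: 400.0                  # CNY/t industrial oxygen
erosion: 2672500.0               # t/a, annual soil erosion on cultivated land
bulk_density: 1.22               # soil bulk weight as printed (kg/m3 label, t/m3 magnitude)
topsoil: 0.2                     # m, topsoil thickness
nutrient_fractions:              # soil mass fractions
  N: 0.00092
  P: 0.00121
  K: 0.02397
nutrient_prices:                 # CNY/t after fertilizer-price discounting
  N: 162.450
  P: 98.400
  K: 1410.682
silt_rate: 0.24                  # share of eroded sediment deposited in reservoirs/rivers
reservoir_cost: 0.67             # CNY/m3 reservoir construction cost
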