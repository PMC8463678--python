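# Bundled reference transfer models (published regional coefficients).
# Units: slope in target units per ‰; intercept and extra_offset in target units.
# The extra_offset is a small additive constant published with the equations
# and is kept separate from the fitted intercept.
july_precipitation:
  proxy: d13C_cell
  target: july_precipitation_mm
  slope: -16.723
  intercept: -357.791
  extra_offset: 0.15
  calibration_period: [1966, 2009]
ao_may:
  proxy: d18O_cell
  target: ao_index_may
  slope: 0.320
  intercept: -7.075
  extra_offset: 0.15
  calibration_period: [1969, 2009]
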