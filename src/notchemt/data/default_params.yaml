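# Default parameter set of the coupled Notch-Delta-Jagged / EMT model.
# Units: production rates g_* in molecules/h (g_zeb, g_snail are per-mRNA
# translation rates in 1/h); degradation rates k_* in 1/h; binding rate
# constants kt_* / kc_* in 1/(molecule h); Hill thresholds and microRNA
# thresholds in molecules; fold changes dimensionless.
production:
  g_notch: 16.0        # molecules/h
  g_delta: 60.0        # molecules/h (one-cell default; tissue protocols sweep this)
  g_jagged: 25.0       # molecules/h (one-cell default; tissue protocols sweep this)
  g_mir200: 2100.0     # molecules/h
  g_zeb_mrna: 12.0     # molecules/h
  g_zeb: 100.0         # 1/h per mRNA
  g_mir34: 1350.0      # molecules/h
  g_snail_mrna: 90.0   # molecules/h
  g_snail: 100.0       # 1/h per mRNA
degradation:
  k_notch: 0.1         # 1/h
  k_delta: 0.05        # 1/h
  k_jagged: 0.05       # 1/h
  k_nicd: 0.5          # 1/h
  k_mir200: 0.05       # 1/h
  k_zeb_mrna: 0.5      # 1/h
  k_zeb: 0.1           # 1/h
  k_mir34: 0.05        # 1/h
  k_snail_mrna: 0.5    # 1/h
  k_snail: 0.125       # 1/h
interaction:
  kt_delta: 3.0e-5     # 1/(molecule h): Notch binding Delta (trans)
  kt_jagged: 4.0e-5    # 1/(molecule h): Notch binding Jagged (trans)
  kc_delta: 3.0e-3     # 1/(molecule h): Notch-Delta cis-inhibition
  kc_jagged: 3.0e-4    # 1/(molecule h): Notch-Jagged cis-inhibition
edges:                  # shifted-Hill specs {threshold (molecules), coefficient, fold_change}
  nicd_on_notch:  {threshold: 8.0, coefficient: 2, fold_change: 6.0}
  nicd_on_delta:  {threshold: 8.0, coefficient: 2, fold_change: 0.0}
  nicd_on_jagged: {threshold: 8.0, coefficient: 2, fold_change: 3.0}
  nicd_on_snail:  {threshold: 45.0, coefficient: 2, fold_change: 6.4}
  zeb_on_mir200:  {threshold: 3.0e+5, coefficient: 3, fold_change: 0.1}
  snail_on_mir200: {threshold: 1.95e+5, coefficient: 2, fold_change: 0.1}
  zeb_on_zeb:     {threshold: 2.5e+4, coefficient: 2, fold_change: 7.5}
  snail_on_zeb:   {threshold: 1.8e+5, coefficient: 2, fold_change: 10.0}
  snail_on_mir34: {threshold: 2.0e+5, coefficient: 2, fold_change: 0.1}
  zeb_on_mir34:   {threshold: 6.0e+5, coefficient: 2, fold_change: 0.5}
  snail_on_snail: {threshold: 4.0e+5, coefficient: 1, fold_change: 0.1}
  iext_on_snail:  {threshold: 50.0, coefficient: 2, fold_change: 10.0}
mirna:                  # multi-site microRNA records; sites use the canonical
                        # occupancy ramps l = (1, .6, .3, .1, .05, .05, .05),
                        # gamma_m = (0, .04, .2, 1, 1, 1, 1), gamma_mu = (0, .005, .05, .5, .5, .5, .5)
  mir34_on_notch:      {sites: 1, threshold: 1.0e+4}
  mir34_on_delta:      {sites: 2, threshold: 1.0e+4}
  mir200_on_jagged:    {sites: 3, threshold: 1.0e+4}
  mir200_on_zeb_mrna:  {sites: 6, threshold: 1.0e+4}
  mir34_on_snail_mrna: {sites: 2, threshold: 1.0e+4}
fringe:
  enabled: false
  production: {threshold: 30.0, coefficient: 2, fold_change: 10.0}
  delta_boost: 2.0     # multiplies kt_delta at full Fringe activity
  jagged_drop: 0.5     # multiplies kt_jagged at full Fringe activity
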