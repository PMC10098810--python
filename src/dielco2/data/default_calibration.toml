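# Default calibration of the synthetic surface-ocean generator.
#
# These values define the study conditions: a latitude-resolved cell
# ensemble whose preindustrial diurnal pCO2-amplitude statistics (area-
# weighted mean, 99th and 99.9th percentiles) are calibrated against
# published global-model statistics.  The same configuration is then kept
# frozen for all scenario experiments, so scenario responses emerge from
# the carbonate chemistry alone.

[grid]
n_cells = 200
lat_min = -75.0
lat_max = 75.0
# multiplicative per-cell heterogeneity (lognormal sigma) applied to the
# diurnal SST amplitude and NCP profiles
cell_jitter_sigma = 0.15

[mean_state]
t_polar = -1.0          # degC, annual mean at the poleward edge
t_equator = 28.0        # degC, annual mean at the equator
seas_half_base = 1.0    # degC, seasonal half-amplitude, equator
seas_half_midlat = 2.5  # degC, extra seasonal half-amplitude ~ sin^2(2 lat)
seas_half_polar = 1.0   # degC, extra seasonal half-amplitude ~ sin^2(lat)
s_background = 34.0     # practical salinity away from the gyres
s_gyre_bump = 1.5       # subtropical salinity maximum (Gaussian in |lat|)
s_gyre_lat = 25.0       # deg, centre of the salinity maximum
s_gyre_width = 20.0     # deg
alk_at_s35 = 2305.0     # µmol kg-1, total alkalinity at S = 35
alk_per_s = 58.0        # µmol kg-1 per salinity unit
po4_polar = 1.2         # µmol kg-1  (phosphate ~ sin^4 profile)
po4_equator = 0.1
si_polar = 40.0         # µmol kg-1  (silicate ~ sin^4 profile)
si_equator = 2.0

[sst_diurnal]
# mean daily peak-to-peak SST amplitude: amp_polar + (amp_eq - amp_polar) cos^2(lat)
amp_equator = 0.31      # degC
amp_polar = 0.06        # degC
# day-to-day amplitude factors: lognormal (mean 1) with AR(1) memory
lognormal_sigma = 0.72
ar1_daily = 0.6
sst_floor = -1.8        # degC, freezing cutoff applied to the full series

[ncp]
# gross daylight DIC drawdown: gross_polar + (gross_eq - gross_polar) cos^2(lat)
gross_equator = 1.2     # µmol kg-1 day-1
gross_polar = 0.4
net_daily = 0.0         # balanced community: no secular DIC drift
calc_frac = 0.0

[wind]
median = 6.5            # m s-1
sigma = 0.35            # lognormal sigma of 3-h winds
ar1_slot = 0.97

[mixed_layer]
depth = 30.0            # m

[chemistry]
disequilibrium = 0.0    # µatm, fixed air-sea pCO2 offset of the background
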