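# Methods

This note documents the science inside `dielco2`: the model equations and
their assumptions, the synthetic-data generator and its calibration, the
numerical choices, and what the test suite does and does not demonstrate
about the real ocean.

## 1. Carbonate-system solver

The solver closes the seawater CO2 system from the pair (C_T, A_T) at
given T, S, phosphate and silicate, at surface pressure (0 dbar) and in
gravimetric units (µmol kg⁻¹) throughout. [H+] on the total pH scale is
the root of the total-alkalinity balance

    A_T = [HCO3⁻] + 2[CO3²⁻] + [B(OH)4⁻] + [OH⁻]
        + ([HPO4²⁻] + 2[PO4³⁻] − [H3PO4]) + [SiO(OH)3⁻]
        − [H+]_free − [HSO4⁻] − [HF]

Constants follow the OMIP conventions: K1/K2 of Lueker et al. (2000, total
scale), KB of Dickson (1990), KW, phosphate and silicate constants of
Millero (1995; seawater scale, converted to total through the
sulfate/fluoride speciation), KS of Dickson (1990, free scale), KF of
Perez & Fraga (1987), K0 of Weiss (1974), solubility products of Mucci
(1983), borate from salinity per Uppström (1974), and calcium
0.02128/40.087·S/1.80655 mol kg⁻¹. The implementation reproduces the
printed check values of those formulations at T = 25 °C, S = 35 (pK1
5.8472, pK2 8.9660, K0 2.839×10⁻², pKsp 6.3693/6.1883) to the published
precision, and an independently coded brute-force reference solver
(`tests/reference_chemistry.py`, bracketed root finding over pH with its
own transcription of the constants) agrees with the production solver to
within 1 µatm pCO2, 0.002 pH and 0.01 Ω over a 1000-state Latin-hypercube
sample of surface conditions.

pCO2 (not fCO2) is the reported variable; the Weiss virial fugacity
factor is available (`fugacity_factor`) but applied nowhere by default.
Pressure dependence below the surface, alternative constants options and
isotopes are out of scope.

**Root finding.** Vectorized safeguarded Newton in ln[H+] with an
analytic derivative of the alkalinity balance, per-element bisection
fallback on the bracket [10⁻¹², 10⁻²] mol kg⁻¹, relative tolerance 10⁻⁸,
at most 100 iterations. The bracket is checked before iterating and an
unattainable alkalinity raises with diagnostics rather than returning a
bad value. Warm-starting from the previous time step's root (used by the
box model) typically converges in 2–3 iterations.

**Atmospheric equilibration.** `equilibrate_to_atmosphere` Newton-iterates
on DIC with a 1 µmol kg⁻¹ finite-difference slope until the solved pCO2
matches the target mixing ratio within 0.01 µatm. The scenario background
states treat the atmospheric value as the target seawater pCO2, i.e. zero
air–sea disequilibrium by default (configurable offset in the generator
config).

## 2. Mixed-layer box model

A 0-D box of fixed depth (default 30 m) carries DIC and alkalinity at 3-h
steps. Per step: temperature is set to the forcing SST; the CO2 system is
solved; the air–sea flux F = k·K0·ρ·(pCO2ᵃᵗᵐ − pCO2ᵒᶜ)·(1 − ice) updates
DIC by F·Δt/(h·ρ); a biological term adds the NCP tendency. The gas
transfer velocity is quadratic in the 10-m wind, k = 0.251 cm h⁻¹
(m s⁻¹)⁻²·u10²·(Sc/660)^(−1/2), with the CO2-in-seawater Schmidt-number
polynomial valid on [−2, 40] °C. Density is Millero & Poisson (1981) at
0 dbar.

Assumptions, deliberately strong so the chemistry mechanism is isolated:

- **SST is prescribed** — no heat budget. The diurnal temperature cycle
  is an input, so amplification of pCO2 cycles can only come from the
  carbonate chemistry, not from simulated physics.
- **NCP is the only biology.** Gross daylight production proportional to
  PAR minus a constant community respiration; the daily integral equals a
  prescribed net NCP (default 0: a balanced community redistributing DIC
  within the day without secular drift). Zooplankton respiration, DOM
  remineralization and CaCO3 dissolution are subsumed into the single
  respiration term; optional calcification removes alkalinity and DIC at
  2:1 as a fixed fraction of production (off by default).
- **Salinity and (absent calcification) alkalinity are constant within a
  day**; mixed-layer depth is fixed per cell and controls only the air–sea
  relaxation time (~4–5 months at 30 m and 7 m s⁻¹ winds — the diurnal
  cycle is far from flux equilibrium, as it should be).

Carbon is conserved to round-off over any run: the change in DIC equals
the time-integrated flux plus the biological term (checked to 10⁻⁹
relative in tests).

## 3. Amplitudes and extremes

The diurnal amplitude of a variable is the max − min of its eight 3-h
values within one local-solar day; the seasonal amplitude is the max − min
of the twelve monthly means within a year (365-day no-leap calendar,
standard month lengths). Period statistics are means of per-day (per-year)
amplitudes, not amplitudes of period means. Days are bounded at local
solar midnight, which keeps each thermal cycle inside one day — the
natural choice when the metric is the peak-to-peak range of that cycle.
Global statistics are area-weighted means (weights ∝ cos latitude).

Extremes are defined against a fixed baseline: per cell, the 99th and
99.9th percentiles (order statistics, linear interpolation — the numpy
default, stated so results are bit-reproducible) of baseline daily
amplitudes become thresholds; exceedance is strict (>), which keeps the
baseline's self-exceedance at or below the nominal probability. The
probability ratio Pr = Pi/Pc uses the constructed baseline probabilities
Pc = 0.01 and 0.001. Global Pr is the area-weighted mean of per-cell Pr
with non-finite cells excluded and counted — a reading chosen over pooling
probabilities globally, since extremes are defined locally. Return
periods are round(baseline_days/Pr). No extreme-value-theory fits: the
method is pure counting, as befits ~10⁴-day baselines.

The desk-scale baseline is 50 synthetic years (≥ 18 000 days per cell),
scaled down from multi-century model output; the 99.9th percentile is the
quantity most sensitive to this choice, and `percentile_threshold` warns
whenever it is asked for a 99.9th percentile from under 1000 days.

## 4. Thermal/nonthermal decomposition

The mean diurnal cycle of pCO2 at a cell (slot-wise average of the 3-h
fields over an analysis window) is split to first order around the
daily-mean state:

    ΔpCO2(slot) ≈ (∂pCO2/∂T)·ΔT + (∂pCO2/∂C_T)·ΔC_T
                + (∂pCO2/∂A_T)·ΔA_T + (∂pCO2/∂S)·ΔS

The first term is the thermal component; the remaining three sum to the
nonthermal component. Sensitivities are central finite differences of the
full solver at the daily-mean state (steps 0.05 °C, 1 µmol kg⁻¹, 0.05
salinity — well below diurnal anomaly scales, well above solver
tolerance; halving them moves no sensitivity by more than 0.1 %).
Evaluating once at the daily mean rather than per slot is the standard
Taylor-expansion reading and satisfies the closure requirement below.
Phosphate and silicate are held at daily means: they shape the
sensitivities but carry no anomaly terms. The decomposition is applied to
pCO2 only.

Closure is quantified per cell as max-slot |reconstructed − direct| /
peak-to-peak(direct), with the direct cycle solved slot-by-slot from the
mean input fields; the residual statistic reported for an ensemble is the
median across cells, and for realistic open-ocean amplitudes (|ΔT| ≤
0.5 °C, |ΔC_T| ≤ 5 µmol kg⁻¹) it stays below 1 %.

## 5. Synthetic surface-ocean generator

The generator replaces a global model grid with a latitude-resolved cell
ensemble (default 200 cells, latitudes −75°…75°, area weights ∝ cos
latitude, per-cell lognormal parameter jitter σ = 0.15 so latitude bands
are not degenerate). Profiles are simple and documented in
`src/dielco2/data/default_calibration.toml`: annual-mean SST −1…28 °C
(cos² in latitude), subtropical salinity maximum, alkalinity tied to
salinity, nutrients increasing poleward, hemispherically phased seasonal
SST cycles, solar-geometry PAR, log-normal AR(1) 3-h winds (median
6.5 m s⁻¹).

**Diurnal SST.** Each day's cycle is a fixed zero-mean shape (unit
peak-to-peak, maximum at 15:00, minimum at 06:00 local solar time)
multiplied by a day-to-day amplitude: the cell's mean amplitude (0.06 °C
poleward to 0.31 °C at the equator) times a log-normal factor (mean 1,
σ = 0.72) with AR(1) day-to-day memory (ρ = 0.6) through a Gaussian
copula. The log-normal family was chosen because the target statistics —
extreme amplitudes ~5× (99th percentile) and ~9× (99.9th) the mean —
pin two tail ratios that a gamma cannot satisfy simultaneously; for a
log-normal both are closed-form (exp(2.326σ − σ²/2), exp(3.090σ − σ²/2))
and σ = 0.72 matches them together. A freezing floor at −1.8 °C truncates
polar winter cycles.

**Scenario design.** Atmospheric xCO2 trajectories interpolate the
prescribed anchors monotonically (PCHIP): preindustrial constant 284 ppm;
historical 284→398 ppm over 1850–2014; SSP1-2.6 peaking at 474 ppm around
2063–2064 then declining to 446 ppm; SSP5-8.5 reaching 1135 ppm in 2100.
Backgrounds equilibrate each cell's DIC to the year's xCO2 at annual-mean
temperature. **Scenarios change only the background state**: diurnal SST,
wind and NCP statistics stay at the preindustrial calibration — outside
ice-covered seas the diurnal SST amplitude changes little with warming,
and freezing it isolates the chemistry mechanism. (Sea-ice-driven Arctic
amplification is correspondingly not represented; an ice fraction can be
supplied to the flux but no ice model is included.)

**Calibration.** The two amplitude-profile scalars and σ were set so the
preindustrial ensemble reproduces published global-model statistics of
diurnal pCO2 amplitude — area-weighted mean ≈ 2.1 µatm, 99th percentile
≈ 10 µatm, 99.9th ≈ 19 µatm — and then frozen. Everything downstream
(historical and SSP amplitude changes, probability ratios, the [H+]/Ω
asymmetry) is emergent. With the shipped defaults the ensemble also lands
near the published extreme statistics it was *not* tuned to (99th/99.9th
percentile SST amplitudes ≈ 0.95/1.6 °C; [H+] ≈ 0.22/0.39 nmol kg⁻¹).

**Determinism.** Every (scenario, year) pair draws from its own substream
of the single experiment seed, so results are independent of how years
are chunked into batches and bit-reproducible end to end.

## 6. Experiment pipeline and problem sizes

The standard experiment runs a 50-year preindustrial baseline plus
20-year windows (end-of-historical 1995–2014; 2081–2100 under SSP1-2.6
and/or SSP5-8.5) on 200 cells — about 90 simulated years × 200 cells ×
2920 3-h steps ≈ 5×10⁷ equilibrium solves, vectorized over (cell, year)
boxes in blocks of 10 years; this keeps the full chain to a few minutes
on one CPU and under ~2 GB. The "1850–1869" early-industrial reference is
the first 20 years of the preindustrial baseline (atmospheric CO2 is
within a few ppm of 284 there, and it avoids manufacturing a trajectory
shape between the two printed historical anchors, which interpolate
linearly here rather than along the real convex emissions path).

## 7. What the synthetic tests do and do not show

The generator emulates *statistics* of surface-ocean diurnal forcing, not
the ocean: there is no spatial correlation between cells, no advection or
mixing, no interannual modes, no coastal processes (kelp, seagrass,
reefs, tides — where observed diurnal variability is biologically
dominated and much larger), no sea ice, and the diurnal DIC cycle is a
smooth PAR-shaped drawdown rather than resolved plankton dynamics.
Passing tests therefore demonstrate that *given realistic diurnal forcing
statistics and background CO2, the carbonate chemistry produces the
documented amplification/attenuation pattern and extreme-probability
shifts* — a mechanism statement, not a forecast for any particular place.
Agreement of the scenario responses with published global-model values at
±30 % is meaningful precisely because the spatial structure here is
emulated, not reproduced.

## 8. Known limitations

- Constants options are fixed (no alternative K1/K2 menus); mocsy-style
  option flags other than the defaults are not reproduced.
- The historical xCO2 path is linear between its two anchors; mid-century
  historical windows are therefore only approximate analogues.
- Per-cell q99.9 thresholds from 50-year baselines carry a few percent
  sampling noise; the area-weighted global mean suppresses most of it.
- pH-amplitude changes are small differences of small numbers and are the
  least robust of the reported diagnostics (as they are in global models).
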