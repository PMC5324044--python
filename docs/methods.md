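# Methods

This note documents the models implemented in `ptgrowth`, the choices made
where the published record is silent, what the synthetic worlds do and do
not emulate, and the known limitations. It states no empirical result that
the test suite or the analysis drivers do not themselves compute.

## The P model (monthly photosynthesis)

For each calendar month the model computes, from temperature T (°C), vapour
pressure deficit D (Pa), air pressure p (Pa), ambient CO2 cₐ (converted from
ppm to Pa at site pressure), absorbed PAR (mol photon m⁻² month⁻¹) and the
moisture index α:

* **Compensation point.** Γ* = 4.331 Pa × exp(0.0512 (T − 25)) × p/p₀.
  The single-exponential form is the standard light-use-efficiency-model
  approximation to the Arrhenius response (ΔH = 37 830 J mol⁻¹). Anchored
  at 25 °C it tracks the Arrhenius curve within 2% over roughly 15–35 °C
  but runs ~12% high at 0 °C; no anchored exponential can hold 2% over the
  full 0–35 °C range (the minimax error is several percent), so the warm
  band is the honest domain of validity. Γ* scales linearly with pressure
  because it is a partial-pressure quantity.
* **Effective Michaelis–Menten coefficient.** K = Kc (1 + pO₂/Ko) with
  Bernacchi-type constants (Kc₂₅ = 39.97 Pa, Ko₂₅ = 27 480 Pa, activation
  energies 79 430 and 36 380 J mol⁻¹), Kc and Ko scaled linearly with
  pressure, pO₂ = 0.20946 p.
* **Viscosity ratio.** η* = μ(T)/μ(25 °C) by monotone (PCHIP)
  interpolation of CRC-handbook pure-water viscosities from −20 to 45 °C
  (supercooled values below 0 °C). Tabulated handbook values were chosen
  over a Vogel-type fit because the fits are ~3% off at 0 °C where the
  handbook ratio (1.793/0.8904 ≈ 2.01) is exact.
* **Least-cost cᵢ.** cᵢ = Γ* + (cₐ − Γ*) ξ/(ξ + √D) with
  ξ = √(β (K + Γ*)/(1.6 η*)). β defaults to 240 (dimensionless unit-cost
  ratio at 25 °C) and is the single most sensitivity-relevant constant in
  the configuration. cₐ below Γ* is flagged by returning cᵢ = cₐ, which
  zeroes assimilation downstream.
* **GPP.** GPP = Φ₀ · PAR · m · (α/1.26)^¼ per growing-season month, with
  Φ₀ = 0.816 g C mol⁻¹ photon (= 0.085 mol C mol⁻¹ photon × 12 g mol⁻¹ ×
  leaf absorptance 0.8) and m = (cᵢ − Γ*)/(cᵢ + 2Γ*) floored at 0. The
  growing season is every month with mean temperature strictly above
  −1 °C. The drought factor is applied monthly by default; a config switch
  applies each calendar year's growing-season mean α instead.
* **Diagnostics.** V_cmax from the coordination hypothesis
  (V_cmax = Φ₀ PAR (cᵢ + K)/(cᵢ + 2Γ*), normalized to 25 °C by inverse
  Arrhenius with ΔH = 65 330 J mol⁻¹) and stomatal conductance from Fick's
  law (gs = 1.6 A/(cₐ − cᵢ), molar units). Both are reconstructed output
  quantities; neither feeds back into GPP.

### Derived drivers

* **VPD** from the Magnus saturation curve
  (e_sat = 611.21 exp(17.502 T/(T + 240.97)) Pa), clipped at 0.
* **PAR** from analytic daily top-of-atmosphere insolation (solar constant
  1361 W m⁻², 365-day calendar, declination 23.45° sin-form, sunset-hour
  closed form), an Ångström transmissivity τ = (0.25 + 0.50 (1 − cloud)) ×
  (1 + 2.67×10⁻⁵ × elevation), and 2.04 µmol photon per J of total
  shortwave (a convention that already embeds the ~50% PAR fraction). All
  coefficients are module constants, configurable at call sites.
* **Pressure** from the standard-atmosphere barometric formula
  (101 325 Pa at sea level; 73.5 kPa at 2630 m).
* **α** from a single-store monthly bucket (capacity 150 mm): equilibrium
  evapotranspiration from net radiation (shortwave × (1 − 0.17 albedo))
  via the Priestley–Taylor slope factor; actual ET limited by the month's
  precipitation plus the store and by 1.26 × equilibrium; α = AET/EET
  capped at 1.26, so the drought factor (α/1.26)^¼ lies in [0, 1]. One
  climatology year of spin-up precedes the reported pass; zero-demand
  months report the cap.
* **Climatology corrections.** Elevation downscaling is additive for
  temperature and vapour pressure and multiplicative for precipitation and
  cloud (additive fallback where a coarse normal is zero); the glacial
  bias correction is additive for every variable per calendar month
  (ratio option for precipitation via config), so the corrected glacial
  climatology differs from the raw one by exactly the control-run bias.

## The T model (annual growth)

Geometry from diameter d: height H = H_max (1 − e^(−a d/H_max)); crown
area A_c = (π c / 4a) d H (initial crown:stem-section ratio c); paraboloid
stem mass (π/8) ρ d² H; foliage A_c L/σ; fine roots ζ L A_c; pipe-model
sapwood ρ (A_c L / huber) H/2.

NPP = y (GPP A_c fAPAR (1 − f_foliage) − r_s W_sapwood − r_r W_root),
floored at 0, with fAPAR = 1 − e^(−k L). Annual potential GPP enters
through the 24-month accumulation window (July of year −2 through June of
the ring year, sum divided by 2), so the first two ring years of any run
are unavailable. The diameter increment solves
NPP = ΔW_stem + ΔW_foliage + ΔW_root + turnover, where turnover is
W_f/τ_f + W_r/τ_r: the analytic marginal-mass derivative provides the
first-order increment and a few Newton steps on the exact mass difference
refine it to machine precision. A purely linearized solve was rejected
because its error reaches ~2% at increments of 5% of the diameter, which
breaks both the carbon-balance identity and the 1% solver tolerance the
tests demand. Ring width = Δd/2; twice the summed widths equals the total
diameter change exactly. Allocation fractions use the exact per-pool mass
differences plus the pool's turnover, and sum to 1 whenever NPP > 0.

Species defaults describe a squat, slow-growing juniper-like conifer:
a = 60, c = 150, H_max = 12 m, ρ = 205 kg C m⁻³, L = 1.8, σ = 7 m² kg⁻¹ C,
τ_f = 4 a, τ_r = 1.25 a, r_s = 0.04 a⁻¹, r_r = 0.913 a⁻¹, ζ = 0.6 kg C m⁻²,
y = 0.6, k = 0.5, huber = 3000, foliage respiration 10% of GPP. These were
fixed once so that the synthetic montane world yields ~1.5 mm mean rings —
the scale real juniper chronologies show — and are deliberately sensitive
to ζ: the forward mean ring width drops about tenfold as ζ goes from 0.4
to 0.7, which is precisely the lever the allocation-buffering analysis
turns.

**A known trajectory property.** Under a repeated constant climatology the
simulated rings rise gently toward a plateau rather than declining with
age. With crown area ∝ d·H, assimilation, turnover and the marginal cost
of growth all scale together once height saturates, so the increment
approaches a constant from below; only a respiration term growing faster
than A_c (e.g. whole-stem maintenance) would force a decline, and the
pipe-model sapwood term is far too small. Age-related ring decline in real
chronologies therefore lies outside what this reconstruction produces.

## ABC calibration

Rejection sampling: independent draws from truncated-normal priors
(location = median of published values, sd = median/2, truncated at 0 and
4 × median), acceptance when |simulated mean ring width − target| ≤ 2.5%
of the target, point estimate = posterior mean (median available via
config). Zero acceptances raise an error rather than silently widening the
band. The two-parameter (L, ζ) optimization holds every other species
parameter fixed.

Because the summary statistic is a single number, the joint (L, ζ)
posterior concentrates on a ridge rather than a point. ζ is steeply and
monotonically identified; L is not — the forward mean ring width is
hump-shaped in L (self-shading gains saturate while foliage and root costs
grow linearly), so the acceptance region crosses the target band on both
flanks of the hump and the L posterior is bimodal. Parameter-recovery
tests on truth-known synthetic rings recover ζ within a few percent but
recover L only up to this ridge ambiguity; downstream experiments
accordingly lean on ζ, and L results should be read as weakly constrained,
matching the small L shifts the calibration reports along the CO2
gradient.

## Synthetic worlds

The generator produces: temperature = annual mean + seasonal sinusoid
(July peak; southern-hemisphere flag swaps the phase) + AR(1) noise;
precipitation = winter/summer split with i.i.d. multiplicative lognormal
noise (mean-preserving); vapour pressure = mean RH × Magnus saturation at
the month's temperature; cloud = constant + jitter proportional to the
temperature noise (so zero-noise configs repeat exactly). Anomaly
scenarios shift temperature and precipitation additively per calendar
month and shift relative humidity before recomputing vapour pressure, so
negating an anomaly inverts it exactly wherever nothing was clipped.

Two stated worlds are fixed in `ptgrowth.worlds`: a montane world
(36.95° N, 2630 m, MAT 7.5 °C, 600 mm at 75% winter share, RH 0.55,
cloud 0.35, 1903–1985, CO2 ramp 296→339 ppm) for validation, calibration
and the window diagnostic; and a lowland pair (34.06° N, 80 m, MAT
16.6 °C, 380 mm at 85% winter share) whose glacial member applies the
mid-range glacial anomaly (−4 °C, +200 mm yr⁻¹, +0.05 RH — the centre of
the reconstructed 2–6 °C cooling and 100–300 mm wetting for the region)
with CO2 fixed at 180 ppm, against a 320 ppm modern reference. The glacial
experiments run at the lowland site because the direction of the
temperature substitution depends on it: at a warm site, imposing modern
(warmer, drier) conditions raises VPD, photorespiration and drought stress
and reduces growth, whereas at a cold montane site warming would instead
lengthen the growing season.

What the generator does **not** emulate: seasonally varying relative
humidity (summer VPD is therefore biased low, and simulated cᵢ/cₐ sits
near 0.64–0.76 rather than the 0.5–0.6 observed at dry-summer sites —
directions and sensitivities, not levels, are what the synthetic tests
establish), spatial fields, daily weather, weather-regime persistence
beyond AR(1), volcanic/solar forcing, and observational ring-dating error.

## Numerical conventions

365-day no-leap calendar; months indexed 1–12 (0-based indexing never
crosses an interface); ring years are calendar years of formation; the
growing-season threshold is a strict inequality at −1 °C; α capping at
1.26 precedes the drought factor; NPP is floored at 0 (no reserve pool or
mortality); increments are floored at 0 when turnover exceeds NPP;
GPP-weighted annual summaries fall back to unweighted means when all
weights vanish; all random streams are NumPy `default_rng` seeded from
explicit config fields.

## Limitations

No Jmax limitation, temperature-dependent quantum yield, C4 pathway, or
nutrient effects in the P model; no stand competition, mortality, bark or
density correction in the T model; the RWL writer emits the plain decadal
dialect (0.01 mm or 0.001 mm units) without header blocks; gridded NetCDF
ingestion is out of scope — users supply site-extracted monthly tables.
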