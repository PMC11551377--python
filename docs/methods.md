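# Methods

## Chamber mass balance

A flow-through leaf chamber at steady state obeys
`F = (χ_out − χ_in − χ_bg) · ṅ / A` with molar air flow
`ṅ = P V̇ / (R T_gas)` evaluated at the *recorded* gas temperature and
pressure. Mixing ratios are mole fractions (ppbv), so the ppbv→mol and
mol→nmol factors cancel and F is returned directly in nmol m⁻² s⁻¹ on a
one-sided leaf-area basis. Assuming STP instead of recorded conditions
would bias fluxes by several percent, which is why T_gas and P are
explicit record fields (defaults 298.15 K, 101325 Pa). Negative fluxes
(outlet below inlet) are physically meaningful apparent uptake or
depletion; they are retained with a logged warning and excluded later by
the log-space fit. An optional per-record `background` offset supports
empty-chamber correction; no instrument-level (PTR-TOF-MS) processing is
included.

## Exponential Q10 response and its fit

The temperature response is `E(T) = E_ref · Q10^((T − T_ref)/10)` with
T_ref = 30 °C, so the normalized activity `γ(T) = Q10^((T − T_ref)/10)`
equals 1 at the reference. Taking logs makes the model linear:
`ln E = ln E_ref + ((T − T_ref)/10) · ln Q10`, and the default fit is
ordinary least squares on ln E. This was chosen over nonlinear least
squares on E because (a) it is closed-form and therefore exactly recovers
noiseless synthetic curves, and (b) it matches the multiplicative error
structure of chamber data, where scatter is proportional to the emission
level. NLS on the raw fluxes is available (`method="nls"`) as a
sensitivity check; it weights hot, high-flux points more heavily.

Filtering before the fit: observations with leaf temperature above
`t_fit_max` (default 35 °C, where sedge emission becomes unstable) and
non-positive fluxes are excluded, with both counts reported on the fit
object. The cutoff is inclusive (`T ≤ 35` kept) by default and
configurable (`include_boundary`), since "below 35 °C" leaves the
boundary convention open.

Confidence intervals: the default is the normal-theory (Student-t) CI on
the log slope mapped through the exponential, `exp(ln Q10 ± t·SE)`. A
seeded nonparametric bootstrap (resampling observations, default 1000
replicates, percentile interval) is available because the method behind
published CI bands on such curves is typically unstated; degenerate
bootstrap resamples with a single distinct temperature carry no slope
information and are skipped. On the synthetic study conditions (n = 30,
5% noise) the t-based CI covers the true Q10 at 94–96% over 200 seeds,
consistent with its nominal 95%.

`effective_q10(γ, T_low, T_high) = (γ(T_high)/γ(T_low))^(10/(T_high − T_low))`
summarizes any temperature-activity function as the single exponential
matching its total rise over an interval. For an exponential response it
returns the response's own Q10 regardless of interval; for the curved
MEGAN default it is interval-dependent (≈3.19 over 20–35 °C, ≈2.98 over
25–35 °C at standard acclimation), bracketing the Q10 ≈ 3 commonly
quoted for that model. The interval is an explicit argument, never
hard-coded.

## Leaf-scale emission model

Ground-area flux is `F = EF · LAI · γ_P · γ_T`, a single-layer leaf-scale
product with no canopy radiative transfer: the scientific comparison here
is driven entirely by swapping γ_T, and the γ factors are isolated behind
one interface so a canopy scheme could be added later. Age, soil-moisture
and CO₂ activity factors are fixed at 1. Leaf temperature is taken equal
to air temperature — an explicit assumption forced by met stations
measuring only air temperature.

Temperature activity (MEGANv2.1 default, temperatures in K):

```
Topt = 313 + 0.6·(T240 − 297)
Eopt = 2.034 · exp(0.05(T24 − 297)) · exp(0.05(T240 − 297))
x    = (1/Topt − 1/T) / 0.00831
γ_T  = Eopt · C_T2 · exp(C_T1·x) / (C_T2 − C_T1·(1 − exp(C_T2·x)))
```

with C_T1 = 95 and C_T2 = 230 kJ mol⁻¹. The coefficients are the
published MEGANv2.1 isoprene set and sit in a frozen dataclass that can
be overridden for sensitivity studies. γ_T equals Eopt exactly at
T = Topt, and equals 1.0001 at the model's standard point (303 K leaf,
297 K acclimation). Note that at 30 °C = 303.15 K it is 1.0172, not 1:
the rising limb has a local Q10 near 3, so even 0.15 K moves the value by
~1.7%. Exponential arguments are clipped at 700 to guard overflow for
unphysical inputs.

Light activity:

```
α   = 0.004 − 0.0005·ln(P240)
C_P = 0.0468 · exp(0.0005·(P24 − 200)) · P240^0.6
γ_P = C_P · α·PPFD / sqrt(1 + α²·PPFD²)
```

γ_P is 0 in the dark (consistent with the observation that sedge
emission falls to ~zero when the light goes off — no storage pool) and
saturates toward C_P at high PPFD (0.904 at PPFD = 1000 with standard
acclimation P24 = P240 = 200 µmol m⁻² s⁻¹). Steps with no daylight
history (P240 = 0) return 0 with a logged note instead of evaluating
ln(0).

The exponential sedge response replaces γ_T only; γ_P and its
acclimation are retained for both response kinds, because sedge isoprene
emission is light-dependent just like that of other emitters.

Acclimation averages are trailing means: T24/T240 of air temperature
over 24 h/240 h windows, P24/P240 of PPFD over *daytime* steps
(PPFD > 0) within the same windows. At the start of a series the
windows expand from one step rather than discarding 10 days of spin-up;
a `trim_spinup_days` pipeline option drops the transient from analyses
when desired. Timestamps must be strictly increasing with a uniform
step.

## Synthetic study conditions

The chamber generator draws leaf temperatures evenly on [t_min, t_max]
and multiplies the on-curve expectation by mean-one lognormal factors
(`σ² = ln(1 + cv²)`, `µ = −σ²/2`), preserving positivity and the
proportional-error structure of real chamber data. Defaults: Q10 = 8,
E_ref = 2 nmol m⁻² s⁻¹, 20–45 °C, 30 points, cv = 0.05, constant
PPFD = 1000. Points are treated as independent equilibrium observations;
no ramp-rate or equilibration dynamics are emulated.

The met generator produces a regular series (default 30-min step) of
baseline days followed by heat-wave days: temperature is a sinusoid
around the baseline mean (default 295 K, amplitude 7 K) peaking at
15:00, PPFD a half-sinusoid over 06:00–18:00 peaking at solar noon
(default 1500 µmol m⁻² s⁻¹), and the heat wave adds a constant boost
(default 8 K) over whole days — magnitudes chosen as typical of a
southern-California late summer, not a statistical fit to any observed
record (no humidity, wind, or soil moisture). The additive whole-day
boost makes the expected amplification analytic: an exponential response
scales by exactly Q10^(boost/10), giving +385% for Q10 = 7.2 at +8 K
versus +185% for Q10 = 3.7 — the ordering that makes steep-response
sedges a heat-wave-specific source. Passing these tests therefore
demonstrates internal consistency of the chain under idealized forcing,
not agreement with any particular field campaign; reproducing measured
urban fluxes additionally requires observed meteorology and
species-specific EF/LAI values.

## Periods and statistics

Analysis periods are half-open `[start, end)` in the series' local time,
so a boundary timestamp belongs to the period starting there and
adjacent periods partition the series unambiguously. Period statistics
(arithmetic mean, maximum, step count) run over all steps by default,
with a daytime-only option (PPFD > 0) since nights contribute zeros for
a light-dependent emitter. `percent_change` is
`100·(mean_during − mean_before)/mean_before` and is undefined for a
zero baseline; because the model is linear in EF·LAI, within-species
percent change is exactly invariant to rescaling either. Cross-species
comparisons require identical timestamps and report the mean ratio and
peak excess in percent. Heat-wave boundaries are inputs (configurable
periods, or the markers a synthetic series carries); no automatic
percentile-based heat-wave detection is attempted.

## Numerical and interface choices

* All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); equal configs and seeds give
  bit-identical outputs, and the pipeline echoes its full configuration
  and seed next to every output.
* Met CSV reading tolerates `#`-prefixed station-header lines, named
  columns, temperatures in °C or K and light as PPFD or shortwave
  (converted at 2.1 µmol J⁻¹, configurable) — units must be declared,
  never guessed. Rows with missing values are dropped and counted;
  duplicated or non-monotonic timestamps are errors.
* Degenerate fitting inputs fail loudly: fewer than two usable points, or
  a single distinct temperature, raise typed errors rather than
  returning unstable estimates.
* Problem sizes in the shipped tests and acceptance script (30-point
  chamber ramps, 200-seed recovery studies, 15-day half-hourly met
  series) were chosen as the smallest designs at which the recovery and
  coverage statistics are stable.

## Known limitations

Single-layer leaf-scale model only (no canopy profile, no leaf energy
balance); leaf temperature equals air temperature; γ_age, soil-moisture
and CO₂ factors fixed at 1; synthetic meteorology is idealized sinusoidal
forcing; emission factors and LAI are user inputs with no species
database shipped.
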