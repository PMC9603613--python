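# Methods

## Accounting model

The accounts follow the classical ecological-footprint scheme on six land
classes: cropland, grassland, forest, water, construction and fossil-energy
land. Per-capita footprint of class *i* aggregates item demand through
world-average yields, `EF_i = eqf_i · Σ_j (quantity_j / yield_j) / N`; its
biocapacity is `BC_i = area_i · yf_i · eqf_i · (1 − d) / N`. All areas are in
hectares (hm²) and per-capita results in hm²/person. The default factor table
is the standard one for Chinese provincial accounts (equivalence factors from
the WWF Living Planet series — cropland and construction 2.21, forest and
fossil-energy 1.34, grassland 0.49, water 0.36 — and NPP-based national yield
factors 0.46/1.13/0.50/1.13/0.19/0.00); any table can be supplied via
`factors.csv`. Fossil-energy land is the carbon-absorption area of energy
consumption: its yield factor is pinned to 0, so its biocapacity is
identically zero and it is always a deficit class.

**Biodiversity deduction.** The 12% set-aside for wild species is a
convention of the classical model rather than a universal choice; the package
applies it by default (`d = 0.12`), exposes it as a parameter everywhere, and
records the value used in the run manifest. Energy-to-area conversion is
expected upstream: `global_avg_yield` for energy items is the world-average
calorific yield per hectare of fossil-fuel land, so no calorific tables are
embedded. Construction-land electricity demand is modelled as ordinary
consumption records with an energy-type yield — no special case.

## Three-dimensional footprint

Depth and size are computed per class before summation, so a surplus in one
class cannot offset a deficit in another:

* depth = 1 + Σ_i max(EF_i − BC_i, 0) / Σ_i BC_i, defined only when total BC
  is positive (a zero-biocapacity region raises an explicit error);
* size = Σ_i min(EF_i, BC_i); EF3D = depth × size.

When every class is in deficit EF3D collapses to Σ EF_i, and when every class
is in surplus depth is exactly 1 ("natural original length" of flow capital)
— both are exercised as algebraic identities in the tests.

The flow/stock indicators carry side conditions: γ_FLOW = EF/BC × 100% only
for classes with EF ≤ BC, λ = (EF − BC)/BC only for classes with EF > BC
(per class λ equals that class's depth − 1). Requests outside the condition
raise a `NotApplicableError`; tabular output stores NaN. Regional
aggregation is a genuine design choice because the per-class definitions do
not pin one down; this package uses

* regional γ = Σ_i min(EF_i, BC_i) / Σ_i BC_i × 100 — the only aggregation
  whose numerator and denominator both extend the per-class formula, and
* regional λ = Σ_deficit (EF_i − BC_i) / Σ_deficit BC_i.

These are package conventions, recorded in output metadata; other published
regional series may aggregate differently, so cross-study comparison of
regional λ values should be made with care. Fossil-energy land contributes
its full EF to the depth and λ numerators and zero to every BC denominator;
its per-class λ is reported as +inf.

## Security indices

* **EFDI** = −Σ p_i ln p_i over the six classes' EF shares (zero shares drop
  out), in nats; bounded by ln 6 ≈ 1.79.
* **I_comprehensive** is footprint depth, reported separately because it is
  graded as a pressure reading (values above 1 mean renewable flows are
  insufficient).
* **ETI** = ef′/ec, where ef′ sums EF over the renewable classes (default:
  everything except fossil-energy land; the mask is configurable) and ec is
  total per-capita biocapacity. Grading uses the six-level WWF-style scale;
  the printed two-decimal gaps in the conventional table (0.50–0.51, …) are
  closed as half-open intervals [lower, upper) with boundaries 0.5, 0.8, 1.0,
  1.5, 2.0, overridable via `GradeTable`.
* **ECC** = (EPI + 1)/√(EPI² + 1), strictly increasing on [0, 1], maximal at
  √2 when EPI = 1, strictly decreasing beyond; at EPI = 0 it returns exactly
  1 and reports treat that as degenerate. The package evaluates ECC at
  EPI = ETI. Published series are not always self-consistent here — a 2011
  ETI printed as 2.13 alongside an ECC of 1.4068 back-solves to EPI ≈ 1.23 —
  so the identification of the two quantities is documented rather than
  assumed to match any one source.
* **Average annual growth** uses the compound form
  (v_end/v_start)^(1/periods) − 1 with the divisor equal to the full span in
  years (2011→2020 is 10 periods), matching the reporting convention of
  provincial footprint studies.
* **Correlation matrices** are plain Pearson r over any labeled panel
  (indices and socio-economic drivers alike); zero-variance series yield NaN
  plus a warning, never a silent zero. The bundled pipeline correlates the
  seven indicator series it computes; driver series (population, GDP, etc.)
  can be merged in by the caller when available.

## Grey analysis

**GM(1,1).** The fit solves the grey difference equation
x(0)(k) + a·z(1)(k) = b by least squares on the accumulated series
(z(1) is the two-point mean of the 1-AGO), restores fitted values through the
whitening-equation time response, and forces x̂(0)(1) = x(0)(1). Development
coefficients with |a| < 1e-12 switch to the constant branch (a constant
series is fitted exactly with a = 0, b equal to the level). Forecasts use
either first differences of the accumulated response or the equivalent
closed form (1 − e^a)(x(0)(1) − b/a)e^(−ak); the two agree to rounding and
both are exposed. Forecast labels continue the input's year index. The
posterior-error test uses population (1/n) standard deviations: C = S2/S1
with S1 the std of the data and S2 the std of the residuals, and
p = P(|ε(k) − ε̄| < 0.6745·S1). Relative errors |ε|/x(0) are reported
alongside but do not enter C or p. Accuracy grades use the standard table
(grade 1: C ≤ 0.35 and p ≥ 0.95; 2: C ≤ 0.50, p ≥ 0.80; 3: C ≤ 0.65,
p ≥ 0.70; else 4), configurable. GM(1,1) requires at least four strictly
positive values; variants (GM(1,N), background-value optimization, rolling
windows) are out of scope.

**Grey relational degrees.** Deng's procedure with the three conventional
choices, each configurable and recorded in output: mean-value normalization
of every series, per-point coefficient
ξ(k) = (Δmin + ρΔmax)/(Δ(k) + ρΔmax) with the extremes taken over all
comparison series jointly, resolution coefficient ρ = 0.5, and the
arithmetic mean over k as the degree. A comparison identical — or, under
mean normalization, proportional — to the reference scores exactly 1, and
degrees are invariant to common positive rescaling.

## Synthetic data

Real inputs are statistical-yearbook tables that cannot be redistributed, so
the generator produces complete panels with known ground truth. A scenario
fixes, per region and class, a per-capita BC trajectory and an EF/BC ratio
trajectory (fossil-energy land takes a per-capita EF trajectory directly),
plus a population path; everything evolves by smooth multiplicative growth.
Quantities and areas are obtained by inverting the accounting formulas, so a
zero-noise panel reproduces the configured per-class EF and BC to rounding —
the tests verify recovery of depth, size and ETI to 1e-6 across random
configurations. Noise is multiplicative log-normal with unit mean
(exp N(−σ²/2, σ²)) applied to quantities only: per-capita EF stays
mean-unbiased for its target (checked over 200 seeds against Monte-Carlo
standard errors) and all series stay positive, as GM(1,1) requires. Item
disaggregation within a class is an equal split across three synthetic items;
only class totals are contractual.

The packaged default scenario has four regions labelled QH, GS, NX and NMG
over 2011–2020, sized so that the zero-noise pipeline shows the qualitative
structure typical of the upper-Yellow-River provinces in every year: depth
ordered NX > GS > NMG > QH, size ordered NMG > QH > GS > NX, and every
region's pressure index above 1, with fossil-energy demand the dominant
deficit. Magnitudes are plausible for provincial accounts (total BC between
roughly 0.4 and 1.8 hm²/person) but deliberately **not** calibrated to any
published provincial values — the inputs behind those are undeposited, and
fitting them would make the fixture circular. Consequently, passing tests
demonstrate the correctness of the accounting, index and grey machinery and
the qualitative regime structure; they do not validate any particular
region's published numbers. Features of real data the generator does not
emulate: trade adjustment (production vs consumption footprints), item-mix
shifts within a class, yearbook revisions and measurement error in areas or
population, and abrupt policy-driven breaks in trends.

## Numerical choices and degenerate inputs

* Depth with zero total biocapacity raises `UndefinedDepthError`; regional λ
  with no deficit class raises `NotApplicableError`; both become NaN in CSVs.
* EFDI requires shares summing to 1 within 1e-9; 0·ln 0 := 0.
* Grade bins are half-open, so boundary values classify into the higher bin.
* GM(1,1) uses `numpy.linalg.lstsq` for the 2-parameter solve (checked in
  tests against hand-solved normal equations); |a| < 1e-12 is treated as
  zero dynamics.
* CSV output: UTF-8, comma, '.' decimals, 6 significant digits, except the
  index outputs at 4 decimal places to match conventional reporting
  precision. Reruns on identical inputs and configuration are byte-identical;
  the run manifest hashes configuration and inputs and embeds the seed.

## Limitations

* Regional γ/λ aggregation conventions differ between studies (see above).
* The ETI grading table and GM(1,1) grade thresholds are conventions, not
  fitted quantities; both are configurable.
* Grey relational degrees depend on the normalization and ρ; values are
  comparable only across series scored in one call.
* The pipeline's correlation stage only sees the indicator series it
  computes unless driver series are supplied by the caller.
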