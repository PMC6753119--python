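# Methods

## The accounting model

The package estimates two quantities for populations of passive
suspension-feeding octocorals (gorgonians): their contribution to
benthic-pelagic coupling — the net carbon flux they mediate between
the water column and the benthos — and their value as blue-carbon
sinks — the carbon immobilized annually in skeletal and tissue growth.

Everything is driven by a single observable per colony: its maximum
height `h` (cm). Gorgonians are ramified, so the quantities that
matter physiologically scale allometrically with height:

- total branch length `L(h) = a·h^b` (cm), typically with `b > 1`;
- colony surface area `A(h) = a'·h^b'` (cm²), used only for the
  autotrophic input of symbiont-bearing colonies;
- biomass `B(h) = L(h)·AFDM` (g ash-free dry mass), with AFDM the
  organic mass per cm of branch (mg cm⁻¹);
- polyp number `P(h) = L(h)·p` with `p` polyps cm⁻¹, or a published
  per-size-class polyp table where that is how the data exist.

Power laws are fitted by OLS on log-transformed pairs
(`log y = log a + b·log x`), the standard estimator in allometry;
R² is reported in log space and 95 % confidence intervals are kept for
both parameters. Point estimates drive the budget; the CIs are
reporting-only. On noiseless input the fit recovers the generating
parameters to machine precision (tested to 1e-6 relative error).

### Daily carbon budget per colony

Ingestion sums up to three channels, each in the units its source
measurements use:

```
I = r_zoo · P(h) / 10⁶            [ug C polyp⁻¹ d⁻¹ · polyps]
  + r_ses · B(h) / 10⁶            [ug C g AFDM⁻¹ d⁻¹ · g]
  + r_auto · A(h) / 10⁶           [ug C cm⁻² d⁻¹ · cm², mixotrophs]
```

Hourly seston rates are converted with ×24; every rate records its
time base explicitly. Respiration converts oxygen consumption to
carbon with a fixed respiratory coefficient of 0.281 mg C per mg O₂:

```
R = r_O2 · 24 · B(h) · 0.281 / 1000     [g C d⁻¹]
```

Temperature dependence is *not* modelled: rates are single-season
values at a stated reference temperature (16 °C shallow, 14 °C deep),
kept as metadata.

Net flux is `F = I − R` (may be negative outside the productive
season; logged, not rejected). Seasonal integration multiplies the
daily net by `season_days`, default 90 — the length of the spring
productive window in the NW Mediterranean, the only season in which
these populations run a positive balance. Published seasonal totals
divided by published daily fluxes cluster at 89.9–90.1 wherever the
daily value carries three significant digits, which is what pins the
default.

### Annual carbon sink

Two dispatch modes per species:

- `length_increment` (default): annual height growth `Δh` (cm yr⁻¹,
  the mean of the cited growth studies) is chained through the length
  allometry, `ΔL = L(h+Δh) − L(h)`, and multiplied by the carbon
  content per cm of branch (mg C cm⁻¹).
- `per_size_class_table`: a published per-size-class annual carbon
  investment (g C colony⁻¹ yr⁻¹) is looked up directly. This is used
  for species whose growth data exist in that form (the red gorgonian
  *Paramuricea clavata*); the table itself is user-supplied because
  only its range endpoints are public.

### Aggregation

Colonies partition into a shallow (depth ≤ 35 m, inclusive boundary)
and a deep (> 35 m) zone — the depth at which light-limited
precoralligenous/shallow coralligenous assemblages give way to deep
coralligenous ones. Budgets aggregate per species × zone compartment;
species totals are the exact sums of their compartments, an identity
asserted on every output row. All intermediate arithmetic is full
double precision; rounding to two decimals happens only at report
serialization.

Per-m² means ± SD are descriptive reporting under a *declared*
denominator convention (per-transect values divided by transect area,
averaged over all transects or only occupied ones, configurable).
Published per-m² figures do not state their denominator, so these
summaries are deliberately not reconciled against anything.

### Effective-rate calibration (closure)

The literature channel rates behind published compartment budgets are
frequently not reprinted alongside them. `back_solve_effective_rates`
recovers effective per-biomass rates (mg C g AFDM⁻¹ d⁻¹) from a
compartment's biomass and daily totals, and
`effective_parameters_from_totals` re-expresses them on the standard
bases (seston channel in µg C g⁻¹ d⁻¹; respiration in mg O₂ g⁻¹ h⁻¹
via the 0.281 factor) so that the ordinary budget chain regenerates
the input totals exactly. Parameter sets built this way are flagged
`effective_rates=True`: they are calibration constructs that compress
all channels into one biomass-specific rate, not measured rates. The
closure round trip is tested to ≤ 0.01 g C d⁻¹ on every packaged
compartment and holds to machine precision.

### Upscaling

Potential colony numbers over the wider study region are
`area_ha × 10⁴ × total_density`, using the *total* per-assemblage
density (mean over occupied and empty sampling units alike) — the
on-patch density would double-count patchiness that suitability maps
cannot resolve, and the API rejects a bare number to keep the two from
being confused. Potential budgets multiply potential colonies by the
mean per-colony flux and sink of the matching species × zone
compartment; shallow assemblages use the shallow compartment and deep
the deep one. Per-hectare sinks divide by the suitable area
(kg C ha⁻¹ yr⁻¹), and species values combine by summation with a
kg→t conversion. All stages are linear in area and density;
per-hectare quantities are invariant to uniform area rescaling.

The packaged habitat-area table is synthetic (placeholder hectares of
realistic magnitude, marked as such in the filename and header): the
real per-assemblage suitable areas are not public. The three published
per-species per-hectare sinks are therefore treated as inputs to the
combined-total computation, not as reproducible outputs.

## Statistics

Cross-species comparisons of biomass, flux and sink follow the field's
standard recipe: square-root transform to stabilize variance, one-way
ANOVA, Tukey HSD for pairwise family-wise-adjusted comparisons. The
observational unit is configurable and defaults to per-transect
per-species values. ANOVA and Tukey are backed by
`scipy.stats.f_oneway` and `scipy.stats.tukey_hsd`; the degenerate
all-constant case returns (F = 0, p = 1) explicitly. A seeded null
simulation (1000 replicates, 3 groups × 10) checks that the empirical
type-I error rate at α = 0.05 sits inside the binomial 95 % band.

## The synthetic survey generator

The generator emulates the *structure* of an ROV gorgonian survey so
every stage is testable without field data:

- **Heights**: truncated lognormal per species × zone (default medians
  12–18 cm, log-SD 0.5–0.6, truncation 60–90 cm), reproducing the
  right-skew of real size structures — many recruits, few large
  colonies.
- **Counts per sampling unit**: zero-inflated negative binomial — a
  Bernoulli occupancy draw (default 0.3–0.4) times an overdispersed
  count (NB size 1.5, mean 2–3; size → ∞ recovers Poisson). This is
  what makes on-patch density far exceed total density, as in real
  assemblage tables, and exercises the total/patch distinction.
- **Ground truth**: computed inline with plain per-colony arithmetic,
  deliberately independent of the budget module, so a pipeline run on
  the generated survey can be compared against it; the deterministic
  stages agree to ~1e-10 relative error and the stochastic density
  stage recovers the generating mean within three standard errors.

What the generator does **not** emulate: measurement error on colony
heights, ROV optics and laser-scaling geometry, spatial autocorrelation
between neighbouring sampling units, within-season rate variability,
and carbon losses to reproduction, predation or mortality (the model
itself excludes these, so its sink estimates are conservative upper
bounds on *net* sequestration only in the no-loss sense). Passing
tests therefore demonstrate correctness of the accounting arithmetic
and the sampling summaries, not realism of any particular rate value.

## Numerical and design choices

- Height 0 evaluates every power law to 0 (limit convention, avoids
  0^b issues); negative heights are domain errors.
- Size-class lookups use half-open `[lower, upper)` intervals; a
  boundary height belongs to the upper class. Out-of-range heights
  clamp to the end classes with a logged warning rather than erroring:
  the laws are applied across the full observed size range.
- The orange-gorgonian (*Leptogorgia sarmentosa*) height-to-length
  coefficient is published inconsistently (2.1167 in the source's
  summary table vs 0.21167 in its text, same exponent). The default
  config ships the table value — it yields total length > height, as
  expected for a ramified colony — with both values recorded in the
  config comment and the choice overridable.
- Per-polyp data for the red gorgonian exist per size class and only
  the range endpoints (630–26 175 polyps) are public; the default
  config leaves the table unset and tests use synthetic monotone
  interiors marked as such.
- Deep white-gorgonian (*Eunicella singularis*) heterotrophic rates
  default to the shallow values in calibration-free configs, a known
  likely underestimate of deep feeding; the config allows distinct
  values per zone.
- Sampling-unit area is configurable (default 1 m²) and carried
  explicitly, since densities are per m².
- Problem sizes in the test suite and acceptance script (hundreds of
  sampling units, ~10³ colonies, 10³ null-simulation replicates) are
  chosen to make sampling error negligible relative to the tested
  tolerances while keeping a full run in seconds.

## Known limitations

- No uncertainty propagation through the budget beyond carrying input
  SDs/SEs; published spatial SDs are descriptive.
- No temperature–respiration response; single-season snapshot only.
- Habitat suitability is an input label, not modelled.
- Effective calibrated rates cannot be decomposed back into feeding
  channels; they are for closure and end-to-end runs, not biology.
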