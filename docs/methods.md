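# Methods

This note records the statistical models, the defaults and the design
choices behind `woodmap`, in the spirit of a model-description appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Register ingestion

A certificate register is a long table with one row per certificate;
properties can hold several certificates (new build, sale, rental,
renovation). Cleaning proceeds in a fixed order:

1. **Deduplication.** Rows identical on every field after whitespace
   normalisation collapse to one; rows sharing a certificate id but
   differing elsewhere keep the later inspection date (ties: the
   lexicographically last record). Rows without a certificate id are
   rejected and counted. The dedup key is deliberately conservative —
   full-record equality — because register extracts commonly duplicate
   whole rows rather than ids.
2. **Heat-source classification** is case-insensitive substring matching
   over the main and secondary heat descriptions. The shipped keyword
   lists (wood: *wood, log, logs, biomass, pellet, wood chip*; solid:
   wood ∪ *solid fuel, coal, anthracite, smokeless, multi-fuel,
   multifuel, peat*) are defaults meant to be overridden from a YAML
   ruleset file; the ruleset constructor folds the wood set into the
   solid set so `wood ⇒ solid` holds by construction. Classification is
   monotone in the ruleset: adding a keyword can only switch flags on.
3. **Harmonisation** maps raw property type × built form onto the census
   categories (detached / semi-detached / terrace / flat / other). A
   house whose built form is unrecorded keeps a missing category rather
   than being forced into *other*, mirroring how register publications
   report a "house, form missing" row. Tenure maps to new-build /
   owner-occupied / rented (private) / rented (social), with a
   transaction type containing "new dwelling" taking precedence.
4. **Latest-certificate flag.** Per property (UPRN) the certificate with
   the maximum inspection date wins; date ties go to the greatest
   certificate id so the flag is deterministic and auditable.
   Certificates with unparseable dates never win.
5. **Geography linkage** through a UPRN lookup that must be a function
   (duplicated UPRNs are a hard error); unmatched records are retained
   with null codes and counted.

## 2. Census post-stratification

The register over-represents property types that transact often. The
correction assumes that *within* an LSOA × property-type stratum,
register inclusion is independent of fuel status — defensible because
LSOAs are small (400–1,200 households) and homogeneous. Under that
assumption the stratum register rate is unbiased for the stock rate and

    est[l,t] = p_hat[l,t] · N_census[l,t]

Strata with fewer than `min_epc = 20` certificates are suppressed.
Suppressed strata are excluded from both the numerator and denominator of
any downstream rate (no imputation); a `borrow` option instead fills the
pooled local-authority rate for the same property type, for users who
prefer complete maps over strict empiricism. Unsuppressed strata are
computed in the ratio form `n_fuel · N_census / n_epc`, which reduces
exactly to the observed count when the census stock equals the register
count (the correction identity used as a test oracle).

Prevalence is restricted to houses because flats rarely have the capacity
for a wood burner; concentration (count per km²) is a property of the
land area and therefore counts every type. Areas are planar areas of the
boundary polygons, which are expected in a projected metric CRS (for
Great Britain, the national grid; the `crs` config key is metadata — no
reprojection is performed). Aggregation to ward / district / region sums
counts, house numerators, house denominators and areas, then recomputes
rates, so totals are conserved to float precision. For choropleth
display, values are clipped to the 5th–95th percentile range (linear
interpolation between order statistics — the common percentile default;
no source definition was available to prefer another).

## 3. Temporal trends

Annual prevalence uses **all** certificates issued in a year, not only
the latest per property, because a property's fuel status changes over
time and each certificate is a dated observation. Year is the calendar
year of the inspection date (`date_field` is configurable; the choice
between inspection and lodgement date is not observable in the shipped
synthetic data). Deprivation deciles are computed within urban and rural
LSOA subsets separately, decile 1 being the most deprived tenth; ties
break by LSOA code rank for determinism.

The renovation analysis orders certificates within property, groups
properties by their total number of certificates (2–4; five or more are
excluded for small sample size) and reports prevalence at each
certificate order. With installations and no removals, prevalence is
non-decreasing in order up to binomial noise.

## 4. Monitor validation

- **Peak/off-peak statistic:** mean PM2.5 over hours {19–23, 0} minus
  mean over hours {5–16}, within season (DJF / JJA) and day-type
  (Mon–Fri / Sat–Sun). The 00:xx hour's day-type follows its own
  calendar date (a Saturday-00:30 observation is weekend even though the
  burning evening began Friday); both hour sets are configurable. A side
  with fewer than 24 valid hours yields a null — an invented but
  necessary rule that prevents unstable differences at sparse sites.
- **Exposure:** the estimated burner count is an LSOA-level quantity, so
  it is apportioned into a disc by intersection area assuming uniform
  density within each LSOA. A point mode (counting synthetic per-property
  coordinates) exists and agrees with the areal mode under spatial
  uniformity, which is a test. Grid-square counts use half-open 1 km
  cells aligned to the projection origin and conserve the national total
  exactly.
- **Correlation:** Spearman's R on mid-ranks (via `scipy`); zero rank
  variance yields null. Confidence intervals are BCa bootstrap with
  B = 10,000 by default, resampling **sites** — the site is the sampling
  unit, as the statistic's uncertainty comes from which monitors exist,
  not from hourly noise. The bias term is z₀ = Φ⁻¹(#{θ\* < θ̂}/B),
  clamped to ±4 when the bootstrap distribution degenerates; the
  acceleration is the jackknife third/second-moment ratio; a fully
  degenerate bootstrap collapses the interval to (θ̂, θ̂). The
  winter−summer difference resamples sites once per replicate and
  evaluates both seasonal correlations on the same resample (paired;
  an unpaired variant resamples the two seasons independently).
- **Negative control:** the same correlation path with the housing count
  within 1 km replacing the burner count. Because Spearman is rank-based,
  the log transform used for display cannot change R — asserted exactly
  in tests.

## 5. Beta regression

Prevalence is bounded in [0, 1], so the association model is
y ~ Beta(μφ, (1−μ)φ) with logit(μ) = Xβ and constant precision φ.
Exact zeros (common in low-prevalence areas) are moved off the boundary
with the standard compression y′ = (y(n−1) + 0.5)/n. Covariates enter
untransformed so a coefficient is the change in the logit of expected
prevalence per covariate unit; region enters as indicator contrasts
against a configurable reference. Estimation is maximum likelihood over
(β, log φ) by BFGS with the analytic score; standard errors come from
the inverse observed information (central-difference Hessian at the
optimum); Wald intervals are β ± 1.96·SE. A covariate that is constant
within a stratum (e.g. smoke-control status among rural areas) is
dropped with a warning rather than failing the fit; genuine rank
deficiency is an error. The all-LSOA model includes the urban indicator;
urban-only and rural-only strata drop it. Constant φ is a modelling
choice — the package does not implement covariate-dependent precision.

## 6. Synthetic-data generator

The generator defines the reference study conditions:

- **Geography:** a 10 × 10 grid of 1 km² square LSOAs; cells more than
  one cell from the edge form an 8 × 8 urban core; a contiguous quarter
  of the core is a smoke-control area; wards are 2 × 2 cell blocks,
  districts 5 × 5, regions the two grid halves. Covariates: IMD ~
  Gamma(2, 10) (+4 in urban cells), median age ~ N(42, 5²) truncated to
  [25, 65] (+4 rural), % white ethnic background ~ logit-normal,
  population ~ N(1600, 200²).
- **Stock and register:** mean properties per LSOA by type (detached
  100, semi 120, terrace 130, flat 60, other 5; flats ×2 urban, detached
  ×1.5 rural), drawn Poisson. Register inclusion by type: detached 0.4,
  semi 0.6, terrace 0.7, flat 0.9, other 0.5 — flats over-represented,
  detached under-represented, the bias the correction removes. The
  planted wood-burner model is logit(p) = −2.1 − 0.012·IMD +
  0.03·(age − 40) − 0.5·urban + type effect (detached +0.8, semi 0,
  terrace −0.3, flat −3.5, other −1), giving ≈ 9 % of properties a wood
  burner, concentrated in affluent, older, rural/edge areas — the
  qualitative structure observed in national registers. 3 % of rows are
  exact duplicates; 30 % of certificated properties receive 2–4
  certificates and 1 % five (excluded downstream); non-wood properties
  convert at 5 % per later certificate (installation, never removal).
  Free-text heat descriptions are rendered from templates so that a text
  contains a wood keyword iff the certificate's planted status is wood —
  classification is invertible by construction, a deliberate idealisation
  that makes recovery testable; a noisy mode perturbs case and
  whitespace.
- **Monitoring:** 60 urban-background monitors at distinct urban cell
  centroids (plus 2 non-background sites the analysis must exclude), two
  years of hourly PM2.5 in fixed-offset local clock time (no
  daylight-saving shift — an irrelevance deliberately removed): winter-
  peaking seasonal background (8 + 3·cos annual), a diurnal cycle whose
  means over the peak and off-peak hour windows are subtracted out, so
  the planted winter-evening term κ·density (κ = 0.05 µg/m³ per
  burner/km² within 1 km) is *exactly* the expected peak/off-peak
  difference; Gaussian noise σ = 2 µg/m³; 5 % of hours missing.

What the generator does **not** emulate: real urban morphology and
irregular LSOA shapes, meteorology (wind direction/speed confounding),
co-pollutants (cooking, traffic), daylight-saving time, spatially
correlated missingness, and free-text messiness beyond case/whitespace.
Passing tests therefore demonstrate the statistical machinery under the
stated assumptions, not robustness to those real-data features.

## 7. Evaluation experiments and problem sizes

`woodmap.experiments` fixes the study sizes used by the test suite and
the reproduction script:

- published characteristics-table percentages from the printed counts
  (shipped as package data; pure arithmetic);
- selection-bias recovery on 500 LSOAs (20 × 25 grid, ≈ 200,000
  properties) with installations disabled: between-certificate
  installation makes register inclusion informative about fuel status
  *within* strata, violating the correction's independence assumption,
  so the recovery experiment isolates the type-dependent selection the
  correction is built for (with installs active the corrected estimate
  picks up the installation uplift of certificated properties, ≈ +0.9 pp
  under the defaults — a real phenomenon, but a different estimand);
- BCa coverage for a normal mean: 500 simulations, n = 50, B = 2,000;
- peak-amplitude recovery: the ratio mean(winter diff)/mean(true
  density) across the 60 sites — a ratio rather than a regression slope
  because the planted between-site density spread is small relative to
  hourly noise, making a slope estimator needlessly variable;
- end-to-end seasonality: 200 monitoring replicates over one fixed
  register, paired season-difference intervals at B = 1,000 (the
  pipeline default stays B = 10,000; the replicate study measures CI
  exclusion frequency, for which 1,000 resamples per replicate are
  ample);
- beta-regression recovery: 200 simulations at n = 5,000 with a planted
  deprivation effect of −0.012 per IMD unit on the logit scale, and
  oracle agreement with an independent maximiser of the same likelihood
  (`statsmodels` BetaModel) to 1e-4 relative on one fixed dataset.

## 8. Known limitations

- Point estimates only: no uncertainty intervals on area estimates, no
  spatial smoothing, no spatial-autocorrelation adjustment in the beta
  regression, and no causal reading of its coefficients.
- The register cannot distinguish appliance types or usage intensity; a
  heat source present is not a heat source used.
- The areal buffer apportionment assumes uniform within-LSOA density;
  with irregular real boundaries this is an approximation the synthetic
  square grid does not stress.
- The validation statistic does not adjust for meteorology; the housing-
  density control addresses confounding by generic urban activity only.
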