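# woodmap

Small-area mapping of residential wood-burning heat sources from energy
performance certificate (EPC) registers.

Residential wood burning is a growing source of fine particulate matter
(PM2.5) in many high-income countries, yet existing emissions inventories
are too coarse, and too out of date, to target local interventions.
Certificate registers record each property's primary and secondary heat
source, are continuously updated, and can be linked to small statistical
areas — but they are a *biased sample* of the housing stock (flats are
over-represented, detached houses under-represented). This package turns a
certificate register into census-corrected small-area estimates of the
prevalence and concentration of wood burners, tracks temporal trends,
validates the concentration metric against hourly PM2.5 from
urban-background monitors, and models socio-economic associations. It is
aimed at air-quality and public-health analysts.

## Method

**Census post-stratification.** Within LSOA ℓ and property type *t*, the
register fuel rate p̂<sub>ℓt</sub> = n<sup>fuel</sup><sub>ℓt</sub> /
n<sup>EPC</sup><sub>ℓt</sub> is assumed unbiased for the stock rate
(inclusion independent of fuel status within a stratum). The corrected
count and the two outcome metrics are

- est<sub>ℓt</sub> = p̂<sub>ℓt</sub> · N<sup>census</sup><sub>ℓt</sub>,
- prevalence<sub>ℓ</sub> = 100 · Σ<sub>t∈houses</sub> est<sub>ℓt</sub> /
  Σ<sub>t∈houses</sub> N<sub>ℓt</sub>  (houses = detached, semi-detached,
  terrace),
- concentration<sub>ℓ</sub> = Σ<sub>t</sub> est<sub>ℓt</sub> /
  area<sub>ℓ</sub> (all property types, per km²).

Strata with fewer than 20 certificates are suppressed (excluded from
numerator and denominator).

**Monitor validation.** Wood smoke has a diagnostic diurnal fingerprint:
the statistic is mean PM2.5 during peak burning hours (7pm–1am) minus
off-peak hours (5am–5pm), within season (DJF winter / JJA summer) and
day-type. Site exposure is the area-weighted apportionment of estimated
burners into a circular buffer (default 1 km) around each urban-background
monitor. Association is the Spearman rank correlation *R* with
bias-corrected accelerated (BCa) bootstrap confidence intervals resampled
over sites, plus a paired bootstrap interval for R<sub>winter</sub> −
R<sub>summer</sub> and a housing-density negative control.

**Socio-economic association.** LSOA prevalence is a proportion, so
associations with deprivation (IMD score), median age, ethnic composition,
urbanicity and smoke-control-area status are modelled with beta
regression: y ~ Beta(μφ, (1−μ)φ), logit(μ) = Xβ, constant φ, fitted by
maximum likelihood with an all-LSOA model plus urban/rural strata.

A first-class synthetic-data generator emits every input the pipeline
consumes — geography, covariates, a biased register with free-text heat
descriptions, census stock, monitors and hourly PM2.5 — with known ground
truth, so every stage is testable end to end without any download.

## Worked example

```python
import numpy as np
from woodmap import experiments, smallarea, validation

# synthetic national study: biased register + census + monitors
scenario, latest, estimates = experiments.reference_study(seed=1)
print(estimates.nlargest(3, "concentration_per_km2")[
    ["geography", "est_count", "prevalence_pct", "concentration_per_km2"]])

national = smallarea.aggregate(estimates, scenario.geography.hierarchy,
                               "region")
print("corrected wood-fuel prevalence: "
      f"{100 * national['est_count_houses'].sum() / national['n_census_houses'].sum():.1f}%")

est = estimates.set_index("geography")["est_count"]
ub = scenario.sites[scenario.sites["classification"] == "Urban Background"]
x = [validation.buffer_count(est, scenario.geography.polygons,
                             (s.easting, s.northing), 1000.0)
     for s in ub.itertuples()]
yw = validation.peak_offpeak_diff(scenario.pm25, "winter",
                                  "weekday")[ub["site_id"]]
r, ci = validation.spearman_with_ci(x, yw.to_numpy(), B=10_000,
                                    rng=np.random.default_rng(1))
print(f"winter weekday R = {r:.2f} [{ci.low:.2f}, {ci.high:.2f}]")
```

prints

```
geography  est_count  prevalence_pct  concentration_per_km2
  L009005      102.9            26.3                  102.9
  L000004       93.0            23.1                   93.0
  L000006       81.1            19.3                   81.1
corrected wood-fuel prevalence: 11.2%
winter weekday R = 0.76 [0.60, 0.86]
```

The three listed LSOAs are the synthetic hotspots (highest estimated
burners per km²); the national prevalence is the census-corrected share of
houses whose latest certificate indicates a wood-fuel heat source; and the
final line shows that on winter weekdays the evening PM2.5 excess at
monitors rank-correlates strongly with the estimated burner count around
them — the planted wood-smoke signal recovered end to end.

The same pipeline is scriptable from the shell:

```bash
woodmap --outdir run --seed 1 all   # simulate → ingest → estimate →
                                    # trends → validate → associate → report
```

## Layout

- `woodmap.ingest` — register reading, deduplication, keyword heat-source
  classification, census-aligned harmonisation, geography linkage
- `woodmap.smallarea` — stratum rates, census correction, prevalence /
  concentration, hierarchy aggregation, map truncation
- `woodmap.trends` — annual prevalence by stratum, within-urban/rural IMD
  deciles, repeat-certificate renovation analysis
- `woodmap.validation` — buffer/grid apportionment, peak/off-peak
  statistic, Spearman + BCa bootstrap, season differences
- `woodmap.association` — `BetaRegression` model / results objects,
  decile summary tables
- `woodmap.synthetic` — scenario generator with ground truth
- `woodmap.experiments` — self-contained reproduction experiments
- `woodmap.cli` — `woodmap` command-line pipeline

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
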