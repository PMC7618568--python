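"""Synthetic study generator with known ground truth.

Emulates the statistical structure of a national certificate register and
its companion datasets on a square grid of LSOAs:

- a full property stock (the census), with an LSOA × property-type count
  table, and a certificate register that is a *biased* sample of it
  (inclusion probabilities depend on property type, the selection bias the
  census correction removes);
- free-text heat-source descriptions rendered from keyword templates, so
  keyword classification is invertible by construction (a deliberate
  idealisation; a noisy mode perturbs case and whitespace);
- repeat certificates with wood-burner installation between certificates,
  exact duplicate rows, and optionally UPRNs missing from the geography
  lookup;
- spatially heterogeneous burner density via a logistic model on area
  deprivation, median age, urbanicity and property type;
- hourly PM2.5 at urban-background monitors: seasonal background, a
  diurnal cycle orthogonalised to the peak/off-peak windows, Gaussian
  noise, and a winter-evening wood-smoke term equal to
  kappa × (true local burner density) on peak hours, so the planted
  peak/off-peak difference is exact in expectation.

Every output is reproducible from the scenario seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from shapely.geometry import box

from woodmap import geo
from woodmap.ingest import HOUSE_TYPES, PROPERTY_TYPES
from woodmap.validation import PEAK_HOURS, OFFPEAK_HOURS, SEASON_MONTHS

_TYPE_RENDER = {
    "detached": ("House", "Detached"),
    "semi_detached": ("House", "Semi-Detached"),
    "terrace": ("House", "Mid-Terrace"),
    "flat": ("Flat", ""),
    "other": ("Park home", ""),
}

_WOOD_TEMPLATES = (
    "Room heaters, wood logs",
    "Boiler and radiators, wood pellets",
    "Room heaters, biomass",
)
_SOLID_TEMPLATES = (
    "Room heaters, anthracite",
    "Room heaters, smokeless fuel",
)
_CLEAN_TEMPLATES = (
    "Boiler and radiators, mains gas",
    "Room heaters, electric",
    "Air source heat pump",
)

_TENURE_RENDER = {
    "owner_occupied": "Owner-occupied",
    "rented_private": "Rented (private)",
    "rented_social": "Rented (social)",
}


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic study.

    Defaults describe the reference scenario: a 10 × 10 grid of 1 km² LSOAs
    with an 8 × 8 urban core, type-dependent register inclusion between
    0.4 (detached) and 0.9 (flats), a wood-burner model with a −0.012
    deprivation effect per IMD unit on the logit scale, 3 % duplicated
    certificate rows, 60 urban-background monitors, and two years of
    hourly PM2.5 with a winter-evening signal of 0.05 µg/m³ per burner/km²
    and noise σ = 2 µg/m³.
    """

    seed: int = 0
    # geography
    grid_rows: int = 10
    grid_cols: int = 10
    cell_size_m: float = 1000.0
    urban_margin: int = 1          # cells further than this from the edge are urban
    ward_block: int = 2            # wards are ward_block × ward_block cell groups
    lad_block: int = 5
    # property stock: mean count per LSOA by type
    properties_per_lsoa: dict = field(
        default_factory=lambda: {
            "detached": 100, "semi_detached": 120, "terrace": 130,
            "flat": 60, "other": 5,
        }
    )
    flat_urban_multiplier: float = 2.0
    detached_rural_multiplier: float = 1.5
    # register inclusion probability by property type (selection bias)
    inclusion_prob: dict = field(
        default_factory=lambda: {
            "detached": 0.4, "semi_detached": 0.6, "terrace": 0.7,
            "flat": 0.9, "other": 0.5,
        }
    )
    # wood-burner probability model, logit scale
    wood_intercept: float = -2.1
    wood_imd_coef: float = -0.012   # per IMD-score unit; negative = affluent areas burn more
    wood_age_coef: float = 0.03     # per year of median age, centred at 40
    wood_urban_coef: float = -0.5
    wood_type_effects: dict = field(
        default_factory=lambda: {
            "detached": 0.8, "semi_detached": 0.0, "terrace": -0.3,
            "flat": -3.5, "other": -1.0,
        }
    )
    solid_only_prob: float = 0.01   # coal/anthracite without wood
    # register structure
    duplication_rate: float = 0.03
    multi_epc_rate: float = 0.30
    extra_cert_split: tuple = (0.7, 0.2, 0.1)  # of multi: 2, 3, 4 certificates
    five_plus_rate: float = 0.01               # properties with 5 certificates
    installation_rate: float = 0.05            # becomes wood at each later certificate
    unmatched_rate: float = 0.0                # UPRNs planted missing from lookup
    study_start: str = "2009-01-01"
    study_end: str = "2024-12-31"
    noisy_text: bool = False
    # monitoring
    n_monitors: int = 60
    n_non_background: int = 2       # extra non-urban-background sites (excluded downstream)
    pm_years: tuple = (2022, 2023)
    pm_background: float = 8.0      # µg/m³
    pm_seasonal_amp: float = 3.0    # winter-peaking annual cycle
    pm_diurnal_amp: float = 1.5
    kappa: float = 0.05             # µg/m³ per (burner per km²), winter peak hours
    pm_noise_sd: float = 2.0
    pm_missing_rate: float = 0.05
    buffer_radius_m: float = 1000.0


@dataclass
class Geography:
    polygons: dict
    covariates: pd.DataFrame   # lsoa, imd_score, median_age, pct_white, urban, sca, region, population
    hierarchy: pd.DataFrame    # lsoa, ward, lad, region
    lookup: pd.DataFrame       # uprn, lsoa, ward, lad, region
    properties: pd.DataFrame   # uprn, lsoa, property_type, x, y
    n_unmatched_planted: int = 0


@dataclass
class GroundTruth:
    properties: pd.DataFrame      # uprn, wood_initial, wood_final, solid_final, included, n_certs
    lsoa: pd.DataFrame            # per-LSOA true counts, prevalence, concentration
    coefficients: dict
    n_duplicates_planted: int = 0
    site_density: pd.Series | None = None  # true burners per km² in the site buffer


def generate_geography(cfg: ScenarioConfig, rng: np.random.Generator) -> Geography:
    """Square-cell LSOAs tiling a region, with covariates and hierarchy."""
    if cfg.grid_rows <= 0 or cfg.grid_cols <= 0 or cfg.cell_size_m <= 0:
        raise ValueError("grid dimensions and cell size must be positive")
    s = cfg.cell_size_m
    cells = [(r, c) for r in range(cfg.grid_rows) for c in range(cfg.grid_cols)]
    codes = [f"L{r:03d}{c:03d}" for r, c in cells]
    polygons = {
        code: box(c * s, r * s, (c + 1) * s, (r + 1) * s)
        for code, (r, c) in zip(codes, cells)
    }

    rows, cols = np.array([rc[0] for rc in cells]), np.array([rc[1] for rc in cells])
    m = cfg.urban_margin
    urban = (
        (rows >= m) & (rows < cfg.grid_rows - m)
        & (cols >= m) & (cols < cfg.grid_cols - m)
    )
    # smoke control area: a contiguous block inside the urban core
    sca = urban & (rows < cfg.grid_rows // 2) & (cols < cfg.grid_cols // 2)
    region = np.where(cols < cfg.grid_cols / 2, "R1", "R2")
    ward = [f"W{r // cfg.ward_block:02d}{c // cfg.ward_block:02d}"
            for r, c in cells]
    lad = [f"D{r // cfg.lad_block:02d}{c // cfg.lad_block:02d}"
           for r, c in cells]

    n = len(cells)
    imd = rng.gamma(shape=2.0, scale=10.0, size=n) + np.where(urban, 4.0, 0.0)
    age = np.clip(rng.normal(42.0, 5.0, n) + np.where(urban, 0.0, 4.0), 25, 65)
    pct_white = 100.0 * expit(rng.normal(2.0, 1.0, n))
    population = rng.normal(1600, 200, n).round().astype(int).clip(400)

    covariates = pd.DataFrame(
        {
            "lsoa": codes,
            "imd_score": imd,
            "median_age": age,
            "pct_white": pct_white,
            "urban": urban,
            "sca": sca,
            "region": region,
            "population": population,
        }
    )
    hierarchy = pd.DataFrame(
        {"lsoa": codes, "ward": ward, "lad": lad, "region": region}
    )

    # full property stock with coordinates uniform within the LSOA cell
    prop_rows = []
    uprn_counter = 100000001
    for i, (code, (r, c)) in enumerate(zip(codes, cells)):
        for ptype in PROPERTY_TYPES:
            mean = cfg.properties_per_lsoa.get(ptype, 0)
            if ptype == "flat" and urban[i]:
                mean *= cfg.flat_urban_multiplier
            if ptype == "detached" and not urban[i]:
                mean *= cfg.detached_rural_multiplier
            count = rng.poisson(mean)
            if count == 0:
                continue
            xs = rng.uniform(c * s, (c + 1) * s, count)
            ys = rng.uniform(r * s, (r + 1) * s, count)
            for k in range(count):
                prop_rows.append((str(uprn_counter), code, ptype, xs[k], ys[k]))
                uprn_counter += 1
    properties = pd.DataFrame(
        prop_rows, columns=["uprn", "lsoa", "property_type", "x", "y"]
    )

    lookup = properties[["uprn", "lsoa"]].merge(hierarchy, on="lsoa")
    n_unmatched = int(round(cfg.unmatched_rate * len(lookup)))
    if n_unmatched:
        drop = rng.choice(len(lookup), size=n_unmatched, replace=False)
        lookup = lookup.drop(lookup.index[drop]).reset_index(drop=True)

    return Geography(polygons, covariates, hierarchy, lookup, properties,
                     n_unmatched_planted=n_unmatched)


def _wood_probability(cfg: ScenarioConfig, geo_: Geography) -> np.ndarray:
    props = geo_.properties.merge(geo_.covariates, on="lsoa", how="left")
    logit = (
        cfg.wood_intercept
        + cfg.wood_imd_coef * props["imd_score"].to_numpy()
        + cfg.wood_age_coef * (props["median_age"].to_numpy() - 40.0)
        + cfg.wood_urban_coef * props["urban"].to_numpy().astype(float)
        + props["property_type"].map(cfg.wood_type_effects).to_numpy()
    )
    return expit(logit)


def _maybe_noisy(texts: pd.Series, cfg: ScenarioConfig,
                 rng: np.random.Generator) -> pd.Series:
    if not cfg.noisy_text:
        return texts
    out = texts.copy()
    flip = rng.random(len(out)) < 0.5
    out[flip] = out[flip].str.upper()
    pad = rng.random(len(out)) < 0.5
    out[pad] = "  " + out[pad] + "   "
    return out


def generate_registry(
    cfg: ScenarioConfig, geo_: Geography, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Certificate register, census stock table and ground truth.

    Returns ``(certificates, census_stock, truth)``; the register uses the
    open-register column dialect so it round-trips through the ingest
    module unchanged.
    """
    props = geo_.properties.copy()
    n = len(props)
    p_wood = _wood_probability(cfg, geo_)
    wood_initial = rng.random(n) < p_wood
    solid_only = (~wood_initial) & (rng.random(n) < cfg.solid_only_prob)
    included = rng.random(n) < props["property_type"].map(cfg.inclusion_prob).to_numpy()

    # number of certificates per included property
    n_certs = np.where(included, 1, 0)
    multi = included & (rng.random(n) < cfg.multi_epc_rate)
    extra = rng.choice([2, 3, 4], size=n, p=list(cfg.extra_cert_split))
    n_certs = np.where(multi, extra, n_certs)
    five = included & (rng.random(n) < cfg.five_plus_rate)
    n_certs = np.where(five, 5, n_certs)

    start = pd.Timestamp(cfg.study_start)
    end = pd.Timestamp(cfg.study_end)
    span_days = (end - start).days

    # explode into certificates; wood status may switch on at later certificates
    rep = np.repeat(np.arange(n), n_certs)
    order = np.concatenate([np.arange(k) for k in n_certs if k > 0]) if rep.size else np.array([], dtype=int)
    total = rep.size
    wood_cert = wood_initial[rep].copy()
    installs = (~wood_initial[rep]) & (order > 0) & (
        rng.random(total) < cfg.installation_rate
    )
    # installation persists for every subsequent certificate of the property
    cert_df = pd.DataFrame({"prop": rep, "order": order, "install": installs})
    cum_install = cert_df.groupby("prop")["install"].cummax().to_numpy()
    wood_cert |= cum_install
    solid_cert = wood_cert | solid_only[rep]

    # sort dates within each property so certificate order follows time
    date_days = rng.integers(0, span_days + 1, size=total)
    cert_df["days"] = date_days
    cert_df["days"] = cert_df.groupby("prop")["days"].transform(np.sort)
    dates = start + pd.to_timedelta(cert_df["days"].to_numpy(), unit="D")

    ptype = props["property_type"].to_numpy()[rep]
    ptype_raw = np.array([_TYPE_RENDER[t][0] for t in ptype])
    bform_raw = np.array([_TYPE_RENDER[t][1] for t in ptype])

    tenure_choice = rng.choice(
        ["owner_occupied", "rented_private", "rented_social", "new_build"],
        size=total, p=[0.60, 0.20, 0.15, 0.05],
    )
    tenure_raw = np.array(
        [_TENURE_RENDER.get(t, "unknown") for t in tenure_choice]
    )
    tx_raw = np.where(tenure_choice == "new_build",
                      "new dwelling", "marketed sale")

    main_heat = np.array(
        [_CLEAN_TEMPLATES[i] for i in rng.integers(0, len(_CLEAN_TEMPLATES), total)]
    )
    second = np.where(
        wood_cert,
        np.array([_WOOD_TEMPLATES[i]
                  for i in rng.integers(0, len(_WOOD_TEMPLATES), total)]),
        np.where(
            solid_cert,
            np.array([_SOLID_TEMPLATES[i]
                      for i in rng.integers(0, len(_SOLID_TEMPLATES), total)]),
            "",
        ),
    )

    certificates = pd.DataFrame(
        {
            "LMK_KEY": [f"C{i:09d}" for i in range(total)],
            "UPRN": props["uprn"].to_numpy()[rep],
            "INSPECTION_DATE": dates.strftime("%Y-%m-%d"),
            "PROPERTY_TYPE": ptype_raw,
            "BUILT_FORM": bform_raw,
            "TENURE": tenure_raw,
            "TRANSACTION_TYPE": tx_raw,
            "MAINHEAT_DESCRIPTION": main_heat,
            "SECONDHEAT_DESCRIPTION": _maybe_noisy(pd.Series(second), cfg, rng),
        }
    )

    # plant exact duplicates
    n_dup = int(round(cfg.duplication_rate * len(certificates)))
    if n_dup:
        dup_rows = certificates.iloc[
            rng.choice(len(certificates), size=n_dup, replace=False)
        ]
        certificates = pd.concat([certificates, dup_rows], ignore_index=True)
        certificates = certificates.iloc[
            rng.permutation(len(certificates))
        ].reset_index(drop=True)

    census_stock = (
        props.groupby(["lsoa", "property_type"], observed=True)
        .size()
        .rename("n_census")
        .reset_index()
    )

    # ground truth: final wood status is the status at the last certificate,
    # or the initial status for properties not in the register
    final_by_prop = pd.Series(wood_cert).groupby(rep).max()
    wood_final = wood_initial.copy()
    wood_final[final_by_prop.index.to_numpy()] = final_by_prop.to_numpy().astype(bool)

    truth_props = pd.DataFrame(
        {
            "uprn": props["uprn"],
            "lsoa": props["lsoa"],
            "property_type": props["property_type"],
            "x": props["x"],
            "y": props["y"],
            "wood_initial": wood_initial,
            "wood_final": wood_final,
            "solid_final": wood_final | solid_only,
            "included": included,
            "n_certs": n_certs,
        }
    )
    areas = geo.polygon_areas_km2(geo_.polygons)
    is_house = truth_props["property_type"].isin(HOUSE_TYPES)
    lsoa_truth = (
        truth_props.groupby("lsoa")
        .agg(
            n_properties=("uprn", "size"),
            true_wood_count=("wood_final", "sum"),
        )
        .reset_index()
    )
    houses = truth_props[is_house].groupby("lsoa").agg(
        n_houses=("uprn", "size"), wood_houses=("wood_final", "sum")
    )
    lsoa_truth = lsoa_truth.merge(houses, on="lsoa", how="left")
    lsoa_truth["true_prevalence_pct"] = (
        100.0 * lsoa_truth["wood_houses"] / lsoa_truth["n_houses"]
    )
    lsoa_truth["true_concentration_per_km2"] = (
        lsoa_truth["true_wood_count"] / lsoa_truth["lsoa"].map(areas)
    )

    truth = GroundTruth(
        properties=truth_props,
        lsoa=lsoa_truth,
        coefficients={
            "intercept": cfg.wood_intercept,
            "imd_score": cfg.wood_imd_coef,
            "median_age": cfg.wood_age_coef,
            "urban": cfg.wood_urban_coef,
            **{f"type[{t}]": v for t, v in cfg.wood_type_effects.items()},
        },
        n_duplicates_planted=n_dup,
    )
    return certificates, census_stock, truth


def _diurnal_profile(cfg: ScenarioConfig) -> np.ndarray:
    """24-hour cycle whose mean is zero over the peak AND off-peak windows.

    The within-window means are subtracted so the planted peak/off-peak
    difference comes only from the wood-smoke term.
    """
    hours = np.arange(24)
    v = cfg.pm_diurnal_amp * np.cos(2 * np.pi * (hours - 14) / 24.0)
    peak = np.isin(hours, PEAK_HOURS)
    off = np.isin(hours, OFFPEAK_HOURS)
    v[peak] -= v[peak].mean()
    v[off] -= v[off].mean()
    return v


def generate_monitoring(
    cfg: ScenarioConfig,
    geo_: Geography,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monitor sites and hourly PM2.5 with a planted winter-evening signal.

    Sites sit at centroids of distinct urban LSOAs.  The wood-smoke term
    adds ``kappa × density`` to every winter peak hour, where density is
    the true number of wood burners within the buffer radius per km², so
    the expected winter peak/off-peak difference at a site is exactly
    ``kappa × density``.  Updates ``truth.site_density``.
    """
    urban_codes = geo_.covariates.loc[geo_.covariates["urban"], "lsoa"].tolist()
    if cfg.n_monitors > len(urban_codes):
        raise ValueError("more monitors requested than urban LSOAs")
    chosen = rng.choice(len(urban_codes), size=cfg.n_monitors, replace=False)
    site_rows = []
    for k, i in enumerate(sorted(chosen)):
        cent = geo_.polygons[urban_codes[i]].centroid
        site_rows.append(
            (f"S{k:03d}", cent.x, cent.y, "Urban Background", "AURN")
        )
    # a few non-background sites that the analysis must exclude
    rural_codes = geo_.covariates.loc[~geo_.covariates["urban"], "lsoa"].tolist()
    for k in range(cfg.n_non_background):
        cent = geo_.polygons[rural_codes[k % len(rural_codes)]].centroid
        site_rows.append(
            (f"T{k:03d}", cent.x, cent.y, "Urban Traffic", "AQE")
        )
    sites = pd.DataFrame(
        site_rows, columns=["site_id", "easting", "northing",
                            "classification", "network"]
    )

    burners = truth.properties.loc[truth.properties["wood_final"],
                                   ["x", "y"]].to_numpy()
    r = cfg.buffer_radius_m
    buffer_km2 = np.pi * r * r / 1e6
    density = {}
    for _, s in sites.iterrows():
        d2 = (burners[:, 0] - s["easting"]) ** 2 + (burners[:, 1] - s["northing"]) ** 2
        density[s["site_id"]] = float((d2 <= r * r).sum()) / buffer_km2
    truth.site_density = pd.Series(density, name="true_density_per_km2")

    t0 = pd.Timestamp(f"{cfg.pm_years[0]}-01-01 00:00")
    t1 = pd.Timestamp(f"{cfg.pm_years[-1]}-12-31 23:00")
    stamps = pd.date_range(t0, t1, freq="h")
    hours = stamps.hour.to_numpy()
    months = stamps.month.to_numpy()
    doy = stamps.dayofyear.to_numpy()

    diurnal = _diurnal_profile(cfg)[hours]
    seasonal = cfg.pm_background + cfg.pm_seasonal_amp * np.cos(
        2 * np.pi * (doy - 15) / 365.25
    )
    winter_peak = np.isin(months, SEASON_MONTHS["winter"]) & np.isin(
        hours, PEAK_HOURS
    )

    n_sites, n_hours = len(sites), len(stamps)
    base = seasonal + diurnal
    dens = np.array([density[sid] for sid in sites["site_id"]])
    pm = (
        base[None, :]
        + cfg.kappa * dens[:, None] * winter_peak[None, :]
        + rng.normal(0.0, cfg.pm_noise_sd, (n_sites, n_hours))
    )
    pm = np.maximum(pm, 0.0)
    keep = rng.random((n_sites, n_hours)) >= cfg.pm_missing_rate
    site_ids = np.repeat(sites["site_id"].to_numpy(), keep.sum(axis=1))
    stamp_arr = stamps.to_numpy()
    series = pd.DataFrame(
        {
            "site_id": site_ids,
            "timestamp": np.concatenate([stamp_arr[k] for k in keep]),
            "pm25": np.round(pm[keep], 3),
        }
    )
    return sites, series


@dataclass
class Scenario:
    cfg: ScenarioConfig
    geography: Geography
    certificates: pd.DataFrame
    census_stock: pd.DataFrame
    truth: GroundTruth
    sites: pd.DataFrame
    pm25: pd.DataFrame

    def write(self, outdir) -> None:
        """Emit every pipeline input file plus truth tables and a manifest."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        geo.write_polygons(self.geography.polygons, out / "lsoas.geojson")
        self.geography.covariates.to_csv(out / "covariates.csv", index=False)
        self.geography.hierarchy.to_csv(out / "hierarchy.csv", index=False)
        lookup = self.geography.lookup.rename(
            columns={"uprn": "UPRN", "lsoa": "LSOA21CD", "ward": "WD22CD",
                     "lad": "LAD22CD", "region": "RGN22CD"}
        )
        lookup.to_csv(out / "uprn_lookup.csv", index=False)
        self.certificates.to_csv(out / "epc.csv", index=False)
        self.census_stock.to_csv(out / "census_stock.csv", index=False)
        self.sites.to_csv(out / "sites.csv", index=False)
        self.pm25.to_csv(out / "pm25.csv", index=False,
                         date_format="%Y-%m-%dT%H:%M")
        self.truth.lsoa.to_csv(out / "truth_lsoa.csv", index=False)
        self.truth.properties.to_csv(out / "truth_properties.csv", index=False)
        manifest = {
            "seed": self.cfg.seed,
            "n_lsoas": len(self.geography.polygons),
            "n_properties": len(self.geography.properties),
            "n_certificates": len(self.certificates),
            "n_duplicates_planted": self.truth.n_duplicates_planted,
            "n_unmatched_planted": self.geography.n_unmatched_planted,
            "coefficients": self.truth.coefficients,
            "config": {k: v for k, v in asdict(self.cfg).items()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def generate_scenario(cfg: ScenarioConfig | None = None,
                      seed: int | None = None) -> Scenario:
    """Generate a full scenario (geography, registry, monitoring) from a seed."""
    cfg = cfg or ScenarioConfig()
    if seed is not None:
        cfg.seed = seed
    rng = np.random.default_rng(cfg.seed)
    geography = generate_geography(cfg, rng)
    certificates, census_stock, truth = generate_registry(cfg, geography, rng)
    sites, pm25 = generate_monitoring(cfg, geography, truth, rng)
    return Scenario(cfg, geography, certificates, census_stock, truth,
                    sites, pm25)
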