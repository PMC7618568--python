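"""Reproducibility experiments: property-based evaluations of the pipeline.

Each function runs a self-contained study on synthetic data with known
ground truth (or on the published characteristics-table counts, shipped as
package data) and returns the measured quantities.  They back the
acceptance checks and the reproduction script, and double as worked
examples of how the pieces compose.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from woodmap import geo, ingest, smallarea, validation
from woodmap.association import BetaRegression
from woodmap.synthetic import (
    ScenarioConfig,
    generate_geography,
    generate_monitoring,
    generate_registry,
    generate_scenario,
)
from scipy.special import expit


# ---------------------------------------------------------------------------
# published characteristics table
# ---------------------------------------------------------------------------

def load_characteristics_counts() -> pd.DataFrame:
    """Published property counts by wood-burner presence (England & Wales)."""
    with resources.files("woodmap.data").joinpath(
        "characteristics_counts.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    return df


def characteristics_percentages() -> pd.DataFrame:
    """Within-column percentages recomputed from the published counts."""
    counts = load_characteristics_counts()
    frames = []
    for char, grp in counts.groupby("characteristic"):
        df = grp.rename(columns={"level": char})[
            [char, "wood_fuel", "count"]
        ]
        out = ingest.summarise_by_flag(
            df, characteristics=[char], weight="count")
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# reference synthetic study
# ---------------------------------------------------------------------------

def ingest_register(certificates: pd.DataFrame, lookup: pd.DataFrame,
                    report: ingest.IngestReport | None = None) -> pd.DataFrame:
    """Run the full ingest chain on an in-memory register."""
    df = certificates.rename(columns=ingest.REGISTER_COLUMNS).copy()
    df["inspection_date"] = pd.to_datetime(df["inspection_date"])
    df = ingest.deduplicate(df, report)
    df = ingest.classify_heat_source(df)
    df = ingest.harmonise_property_type(df)
    df = ingest.harmonise_tenure(df)
    df = ingest.flag_most_recent(df)
    lk = lookup.rename(columns={"uprn": "UPRN", "lsoa": "LSOA21CD",
                                "ward": "WD22CD", "lad": "LAD22CD",
                                "region": "RGN22CD"})
    return ingest.link_geography(df, lk, report)


def reference_study(seed: int, cfg: ScenarioConfig | None = None):
    """Default scenario pushed through ingest and small-area estimation.

    Returns ``(scenario, latest, lsoa_estimates)``.
    """
    cfg = cfg or ScenarioConfig()
    cfg.seed = seed
    scenario = generate_scenario(cfg)
    df = ingest_register(scenario.certificates, scenario.geography.lookup)
    latest = df[df["is_latest"]]
    rates = smallarea.stratum_rates(latest)
    counts = smallarea.corrected_counts(rates, scenario.census_stock)
    areas = geo.polygon_areas_km2(scenario.geography.polygons)
    estimates = smallarea.area_estimates(counts, areas)
    return scenario, latest, estimates


# ---------------------------------------------------------------------------
# selection-bias recovery
# ---------------------------------------------------------------------------

def selection_bias_recovery(seed: int = 7, grid_rows: int = 20,
                            grid_cols: int = 25) -> dict:
    """Census correction vs raw register rates under biased inclusion.

    500 LSOAs (default) with type-dependent register inclusion between 0.4
    and 0.9.  The scenario turns off between-certificate installations so
    register inclusion is independent of wood status within strata — the
    assumption under which the correction is unbiased.  Returns per-LSOA
    prevalence RMSEs and mean biases (percentage points) of the corrected
    and uncorrected estimators against planted truth, plus the relative
    error of the corrected national burner count.
    """
    cfg = ScenarioConfig(seed=seed, grid_rows=grid_rows, grid_cols=grid_cols,
                         installation_rate=0.0)
    rng = np.random.default_rng(seed)
    geography = generate_geography(cfg, rng)
    certs, stock, truth = generate_registry(cfg, geography, rng)
    df = ingest_register(certs, geography.lookup)
    latest = df[df["is_latest"]]
    rates = smallarea.stratum_rates(latest, min_epc=20)
    counts = smallarea.corrected_counts(rates, stock)
    areas = geo.polygon_areas_km2(geography.polygons)
    est = smallarea.area_estimates(counts, areas)

    houses = latest[latest["property_type"].astype(str).isin(
        ingest.HOUSE_TYPES)]
    uncorrected = houses.groupby("lsoa")["wood_fuel"].mean() * 100

    truth_prev = truth.lsoa.set_index("lsoa")["true_prevalence_pct"]
    corrected = est.set_index("geography")["prevalence_pct"]
    joined = pd.DataFrame({
        "truth": truth_prev, "corrected": corrected,
        "uncorrected": uncorrected,
    }).dropna()

    def rmse(col):
        return float(np.sqrt(((joined[col] - joined["truth"]) ** 2).mean()))

    total = est["est_count"].sum()
    total_truth = truth.lsoa["true_wood_count"].sum()
    return {
        "n_lsoas": len(joined),
        "rmse_corrected": rmse("corrected"),
        "rmse_uncorrected": rmse("uncorrected"),
        "bias_corrected": float(
            (joined["corrected"] - joined["truth"]).mean()),
        "bias_uncorrected": float(
            (joined["uncorrected"] - joined["truth"]).mean()),
        "total_count_rel_error": float((total - total_truth) / total_truth),
    }


# ---------------------------------------------------------------------------
# bootstrap calibration
# ---------------------------------------------------------------------------

def bca_coverage(seed: int = 0, n_sims: int = 500, n: int = 50,
                 B: int = 2000, alpha: float = 0.05) -> dict:
    """Empirical coverage of the BCa interval for a normal mean."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        data = rng.normal(size=n)
        lo, hi = validation.bca_ci(data, np.mean, B=B, alpha=alpha, rng=rng)
        hits += lo <= 0.0 <= hi
    return {"coverage": hits / n_sims, "n_sims": n_sims, "n": n, "B": B}


# ---------------------------------------------------------------------------
# peak/off-peak amplitude recovery
# ---------------------------------------------------------------------------

def peak_amplitude_recovery(seed: int = 0) -> dict:
    """Recover the planted winter-evening amplitude from hourly PM2.5.

    The estimator is the ratio of the mean winter peak/off-peak difference
    to the mean true buffer density over urban-background sites, which
    should equal the planted kappa.
    """
    cfg = ScenarioConfig(seed=seed)
    rng = np.random.default_rng(seed)
    geography = generate_geography(cfg, rng)
    certs, stock, truth = generate_registry(cfg, geography, rng)
    sites, pm = generate_monitoring(cfg, geography, truth, rng)
    ub = sites[sites["classification"] == "Urban Background"]["site_id"]
    diff = validation.peak_offpeak_diff(pm, "winter")[ub]
    summer = validation.peak_offpeak_diff(pm, "summer")[ub]
    density = truth.site_density[ub]
    kappa_hat = float(diff.mean() / density.mean())
    return {
        "kappa": cfg.kappa,
        "kappa_hat": kappa_hat,
        "relative_error": abs(kappa_hat - cfg.kappa) / cfg.kappa,
        "summer_mean_diff": float(summer.mean()),
        "n_sites": int(len(ub)),
    }


# ---------------------------------------------------------------------------
# end-to-end seasonality
# ---------------------------------------------------------------------------

def seasonality_replicates(seed: int = 0, n_replicates: int = 200,
                           B: int = 1000) -> dict:
    """Winter vs summer correlation of the concentration metric.

    One fixed register (default scenario) and fresh monitoring data per
    replicate: sites are re-placed, hourly PM2.5 re-drawn.  For each
    replicate the pipeline computes buffer burner counts from the
    census-corrected estimates, winter- and summer-weekday peak/off-peak
    differences, their Spearman correlations, and a paired BCa interval
    for the winter − summer difference.  Success = winter R exceeds summer
    R and the interval excludes zero.
    """
    cfg = ScenarioConfig(seed=seed)
    rng = np.random.default_rng(seed)
    geography = generate_geography(cfg, rng)
    certs, stock, truth = generate_registry(cfg, geography, rng)
    df = ingest_register(certs, geography.lookup)
    latest = df[df["is_latest"]]
    rates = smallarea.stratum_rates(latest)
    counts = smallarea.corrected_counts(rates, stock)
    areas = geo.polygon_areas_km2(geography.polygons)
    est = smallarea.area_estimates(counts, areas).set_index(
        "geography")["est_count"]

    n_success = 0
    r_winter, r_summer = [], []
    for rep in range(n_replicates):
        rep_rng = np.random.default_rng(seed * 100_003 + rep + 1)
        sites, pm = generate_monitoring(cfg, geography, truth, rep_rng)
        ub = sites[sites["classification"] == "Urban Background"]
        x = np.array([
            validation.buffer_count(est, geography.polygons,
                                    (s.easting, s.northing), 1000.0)
            for s in ub.itertuples()
        ])
        yw = validation.peak_offpeak_diff(
            pm, "winter", "weekday")[ub["site_id"]].to_numpy()
        ys = validation.peak_offpeak_diff(
            pm, "summer", "weekday")[ub["site_id"]].to_numpy()
        rw = validation.spearman(x, yw)
        rs = validation.spearman(x, ys)
        _, ci = validation.season_difference_ci(x, yw, ys, B=B, rng=rep_rng)
        excludes_zero = ci.low > 0.0 or ci.high < 0.0
        n_success += (rw > rs) and excludes_zero
        r_winter.append(rw)
        r_summer.append(rs)
    return {
        "success_rate": n_success / n_replicates,
        "mean_winter_R": float(np.mean(r_winter)),
        "mean_summer_R": float(np.mean(r_summer)),
        "n_replicates": n_replicates,
        "n_sites": int(len(ub)),
        "B": B,
    }


# ---------------------------------------------------------------------------
# beta-regression recovery
# ---------------------------------------------------------------------------

def beta_regression_recovery(seed: int = 0, n_sims: int = 200,
                             n: int = 5000, beta0: float = -2.0,
                             beta_imd: float = -0.012,
                             phi: float = 50.0) -> dict:
    """Planted-coefficient recovery for the beta regression MLE.

    Each simulation draws a deprivation-like covariate, generates
    beta-distributed prevalences with a logit mean link, fits the model,
    and records whether every coefficient lies within 3 standard errors of
    its planted value.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    est_imd = []
    for _ in range(n_sims):
        imd = rng.gamma(2.0, 10.0, n)
        X = np.column_stack([np.ones(n), imd])
        mu = expit(beta0 + beta_imd * imd)
        y = rng.beta(mu * phi, (1 - mu) * phi)
        fit = BetaRegression(y, X, ["intercept", "imd_score"]).fit()
        ok = (
            abs(fit.params["intercept"] - beta0) < 3 * fit.bse["intercept"]
            and abs(fit.params["imd_score"] - beta_imd)
            < 3 * fit.bse["imd_score"]
        )
        hits += ok
        est_imd.append(fit.params["imd_score"])
    return {
        "within_3se_rate": hits / n_sims,
        "mean_imd_coefficient": float(np.mean(est_imd)),
        "planted_imd_coefficient": beta_imd,
        "n_sims": n_sims,
        "n": n,
    }
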