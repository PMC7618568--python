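"""Census post-stratification correction and small-area estimates.

The certificate register is a biased sample of the housing stock: inclusion
probabilities differ by property type (flats are over-represented, houses
under-represented).  Within an LSOA and property type, fuel status is
assumed independent of register inclusion, so the stratum fuel rate
estimated from certificates can be reweighted by the census count of
properties in that stratum:

    est_count[lsoa, type] = p_hat[lsoa, type] * n_census[lsoa, type]

Strata with fewer than ``min_epc`` certificates (default 20) are suppressed
and excluded from both the numerator and the denominator of downstream
rates.  Prevalence is restricted to houses (detached, semi-detached,
terrace); concentration counts all property types per km² of geography.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from woodmap.ingest import HOUSE_TYPES, PROPERTY_TYPES

logger = logging.getLogger(__name__)

DEFAULT_MIN_EPC = 20


def stratum_rates(
    latest: pd.DataFrame,
    flag: str = "wood_fuel",
    min_epc: int = DEFAULT_MIN_EPC,
) -> pd.DataFrame:
    """Per-(lsoa, property_type) fuel rates from latest certificates.

    Returns columns ``lsoa, property_type, n_epc, n_fuel, p_hat,
    suppressed``; ``p_hat`` is null where the stratum has fewer than
    ``min_epc`` certificates.
    """
    df = latest[latest["lsoa"].notna() & latest["property_type"].notna()]
    g = (
        df.groupby(["lsoa", "property_type"], observed=True)[flag]
        .agg(n_epc="size", n_fuel="sum")
        .reset_index()
    )
    g["suppressed"] = g["n_epc"] < min_epc
    g["p_hat"] = np.where(g["suppressed"], np.nan, g["n_fuel"] / g["n_epc"])
    return g


def corrected_counts(
    rates: pd.DataFrame,
    stock: pd.DataFrame,
    suppressed_strategy: str = "exclude",
    lsoa_to_lad: pd.Series | None = None,
) -> pd.DataFrame:
    """Apply the census correction to stratum rates.

    ``stock`` has columns ``lsoa, property_type, n_census``.  Unsuppressed
    strata with no census stock row are treated as suppressed with a
    warning.  ``suppressed_strategy``:

    - ``"exclude"`` (default): suppressed strata contribute null counts and
      drop out of downstream numerators and denominators;
    - ``"borrow"``: suppressed strata borrow the pooled certificate rate of
      their local authority district for the same property type (requires
      ``lsoa_to_lad``).

    Returns ``lsoa, property_type, n_epc, n_fuel, p_hat, suppressed,
    n_census, est_count``.
    """
    merged = stock.merge(rates, on=["lsoa", "property_type"], how="outer")
    merged["n_epc"] = merged["n_epc"].fillna(0).astype(int)
    merged["n_fuel"] = merged["n_fuel"].fillna(0).astype(int)
    merged["suppressed"] = (
        merged["suppressed"].astype("boolean").fillna(True).astype(bool)
    )

    no_stock = merged["n_census"].isna() & ~merged["suppressed"]
    if no_stock.any():
        logger.warning(
            "corrected_counts: %d unsuppressed strata missing census stock; "
            "treated as suppressed", int(no_stock.sum())
        )
        merged.loc[no_stock, "suppressed"] = True
        merged.loc[no_stock, "p_hat"] = np.nan

    if suppressed_strategy == "borrow":
        if lsoa_to_lad is None:
            raise ValueError("borrow strategy requires an lsoa_to_lad mapping")
        merged["lad"] = merged["lsoa"].map(lsoa_to_lad)
        pooled = (
            merged.groupby(["lad", "property_type"], observed=True)[
                ["n_fuel", "n_epc"]
            ]
            .sum()
            .assign(p_pool=lambda d: d["n_fuel"] / d["n_epc"].replace(0, np.nan))
        )["p_pool"]
        key = pd.MultiIndex.from_frame(merged[["lad", "property_type"]])
        borrow = merged["suppressed"] & merged["n_census"].notna()
        merged.loc[borrow, "p_hat"] = pd.Series(
            key.map(pooled), index=merged.index
        )[borrow]
        merged = merged.drop(columns="lad")
    elif suppressed_strategy != "exclude":
        raise ValueError(f"unknown suppressed_strategy {suppressed_strategy!r}")

    # unsuppressed strata use the ratio form n_fuel * n_census / n_epc,
    # which reduces exactly to n_fuel when the stock equals the register
    # count; borrowed rates fall back to p_hat * n_census
    direct = ~merged["suppressed"] & (merged["n_epc"] > 0)
    with np.errstate(invalid="ignore"):
        merged["est_count"] = np.where(
            direct,
            merged["n_fuel"] * merged["n_census"] / merged["n_epc"],
            merged["p_hat"] * merged["n_census"],
        )
    return merged


def area_estimates(
    counts: pd.DataFrame,
    areas: pd.Series,
    level: str = "lsoa",
) -> pd.DataFrame:
    """Per-LSOA estimates: corrected count, prevalence and concentration.

    ``counts`` is the output of :func:`corrected_counts`; ``areas`` maps
    LSOA code to area in km² (must be positive).  Prevalence uses
    unsuppressed house strata only (percentage of the census house stock);
    concentration uses all property types per km².  Strata still suppressed
    after any borrowing contribute to neither numerator nor denominator.
    """
    if (areas <= 0).any():
        bad = areas[areas <= 0].index.tolist()
        raise ValueError(f"non-positive area for geographies: {bad}")

    usable = counts[counts["est_count"].notna()].copy()
    usable["is_house"] = usable["property_type"].astype(str).isin(HOUSE_TYPES)

    total = usable.groupby("lsoa", observed=True)["est_count"].sum()
    houses = usable[usable["is_house"]]
    house_num = houses.groupby("lsoa", observed=True)["est_count"].sum()
    house_den = houses.groupby("lsoa", observed=True)["n_census"].sum()
    n_suppressed = (
        counts[counts["est_count"].isna()]
        .groupby("lsoa", observed=True)
        .size()
    )

    out = pd.DataFrame(index=counts["lsoa"].drop_duplicates().sort_values())
    out.index.name = "geography"
    out["level"] = level
    out["est_count"] = total.reindex(out.index).fillna(0.0)
    out["est_count_houses"] = house_num.reindex(out.index)
    out["n_census_houses"] = house_den.reindex(out.index)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["prevalence_pct"] = (
            100.0 * out["est_count_houses"] / out["n_census_houses"]
        )
    out.loc[out["n_census_houses"] == 0, "prevalence_pct"] = np.nan
    out["area_km2"] = out.index.map(areas)
    out["concentration_per_km2"] = out["est_count"] / out["area_km2"]
    out["n_strata_suppressed"] = (
        n_suppressed.reindex(out.index).fillna(0).astype(int)
    )
    return out.reset_index()


def aggregate(lsoa_estimates: pd.DataFrame, hierarchy: pd.DataFrame,
              level: str) -> pd.DataFrame:
    """Roll LSOA estimates up to ward / LAD / region.

    ``hierarchy`` has one row per LSOA with columns ``lsoa, ward, lad,
    region``.  Counts, areas, house numerators and denominators are summed;
    prevalence and concentration are recomputed from the sums
    (count-weighted).  LSOAs absent from the hierarchy raise, listing the
    orphan codes.
    """
    est = lsoa_estimates.copy()
    parent = est["geography"].map(hierarchy.set_index("lsoa")[level])
    orphans = est.loc[parent.isna(), "geography"].tolist()
    if orphans:
        raise ValueError(f"LSOAs missing from hierarchy at level {level!r}: "
                         f"{orphans}")
    est["parent"] = parent
    g = est.groupby("parent", observed=True)
    out = g[
        ["est_count", "est_count_houses", "n_census_houses", "area_km2"]
    ].sum(min_count=1)
    out["n_strata_suppressed"] = g["n_strata_suppressed"].sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        out["prevalence_pct"] = (
            100.0 * out["est_count_houses"] / out["n_census_houses"]
        )
    out["concentration_per_km2"] = out["est_count"] / out["area_km2"]
    out = out.reset_index().rename(columns={"parent": "geography"})
    out.insert(1, "level", level)
    cols = [
        "geography", "level", "est_count", "est_count_houses",
        "n_census_houses", "prevalence_pct", "area_km2",
        "concentration_per_km2", "n_strata_suppressed",
    ]
    return out[cols]


def truncate_for_mapping(
    values: pd.Series | np.ndarray,
    lower_pct: float = 5.0,
    upper_pct: float = 95.0,
) -> pd.Series | np.ndarray:
    """Clip extreme values to percentile bounds for choropleth display.

    Percentiles use linear interpolation between order statistics. Nulls
    pass through; an all-null input raises.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        raise ValueError("truncate_for_mapping: no finite values")
    lo, hi = np.percentile(finite, [lower_pct, upper_pct])
    clipped = np.clip(arr, lo, hi)
    clipped[~np.isfinite(arr)] = arr[~np.isfinite(arr)]
    if isinstance(values, pd.Series):
        return pd.Series(clipped, index=values.index, name=values.name)
    return clipped
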