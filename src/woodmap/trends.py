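"""Temporal trends in wood-burner prevalence.

The trend analysis uses ALL certificates (not only the latest per
property), because a property's fuel status can change over time through
renovation; the renovation signal itself is examined through the subset of
properties with multiple certificates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from woodmap.ingest import HOUSE_TYPES


def imd_deciles(covariates: pd.DataFrame, within: str = "urban") -> pd.Series:
    """Deprivation deciles of LSOAs, computed within urban/rural subsets.

    Decile 1 holds the 10 % most deprived LSOAs (highest deprivation
    score) of its urban or rural subset.  Ties are broken by LSOA code
    rank, so the assignment is deterministic.  Returns a Series of deciles
    (1..10) indexed by LSOA code.
    """
    out = pd.Series(np.nan, index=covariates["lsoa"], name="imd_decile")
    for _, grp in covariates.groupby(within):
        ordered = grp.sort_values(
            ["imd_score", "lsoa"], ascending=[False, True], kind="mergesort"
        )
        n = len(ordered)
        ranks = np.arange(n)
        deciles = ranks * 10 // n + 1
        out.loc[ordered["lsoa"].values] = deciles
    return out.astype("Int64")


def annual_prevalence(
    certificates: pd.DataFrame,
    covariates: pd.DataFrame,
    strata: list[str] | None = None,
    flag: str = "wood_fuel",
    date_field: str = "inspection_date",
) -> pd.DataFrame:
    """Percentage of new certificates each year indicating the fuel flag.

    Restricted to houses (detached / semi-detached / terrace).  Default
    stratification is year × property type × urban flag × within-urban/rural
    deprivation decile; pass ``strata`` to change the grouping columns
    (``year`` is always included).  Empty strata are simply absent from the
    output.
    """
    df = certificates[certificates["property_type"].astype(str).isin(HOUSE_TYPES)]
    df = df[df["lsoa"].notna()].copy()
    df["year"] = pd.to_datetime(df[date_field]).dt.year

    cov = covariates.set_index("lsoa")
    if "urban" in cov.columns:
        df["urban"] = df["lsoa"].map(cov["urban"])
    if "imd_score" in cov.columns:
        dec = imd_deciles(covariates)
        df["imd_decile"] = df["lsoa"].map(dec)
    if "region" in cov.columns and "region" not in df.columns:
        df["region"] = df["lsoa"].map(cov["region"])

    if strata is None:
        strata = [c for c in ["property_type", "urban", "imd_decile"]
                  if c in df.columns]
    group_cols = ["year"] + [c for c in strata if c != "year"]
    g = (
        df.groupby(group_cols, observed=True, dropna=True)[flag]
        .agg(n_epcs="size", n_fuel="sum")
        .reset_index()
    )
    g = g[g["n_epcs"] > 0]
    g["prevalence_pct"] = 100.0 * g["n_fuel"] / g["n_epcs"]
    return g


def repeat_epc_prevalence(
    certificates: pd.DataFrame,
    flag: str = "wood_fuel",
    max_certs: int = 4,
) -> pd.DataFrame:
    """Fuel prevalence by certificate order among multi-certificate properties.

    Certificates are ordered by inspection date within property (ties by
    certificate id).  Properties are grouped by their total number of
    certificates (2..``max_certs``); groups with more than ``max_certs``
    certificates are excluded for small sample size.  The property type of
    the latest certificate labels the property.

    Returns ``n_certs_group, epc_order, property_type, n_properties,
    prevalence_pct``.
    """
    df = certificates[certificates["uprn"].astype(str).str.len() > 0].copy()
    df = df.sort_values(
        ["uprn", "inspection_date", "certificate_id"], kind="mergesort"
    )
    grp = df.groupby("uprn", sort=False)
    df["epc_order"] = grp.cumcount() + 1
    df["n_certs_group"] = grp["certificate_id"].transform("size")
    df = df[(df["n_certs_group"] >= 2) & (df["n_certs_group"] <= max_certs)].copy()
    if len(df) == 0:
        return pd.DataFrame(columns=[
            "n_certs_group", "epc_order", "property_type",
            "n_properties", "prevalence_pct",
        ])

    latest_type = (
        df.groupby("uprn", sort=False)["property_type"].last().rename("ptype")
    )
    df["ptype"] = df["uprn"].map(latest_type)

    g = (
        df.groupby(["n_certs_group", "epc_order", "ptype"], observed=True,
                   dropna=False)[flag]
        .agg(n_properties="size", n_fuel="sum")
        .reset_index()
        .rename(columns={"ptype": "property_type"})
    )
    g["prevalence_pct"] = 100.0 * g["n_fuel"] / g["n_properties"]
    return g
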