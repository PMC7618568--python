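"""Certificate ingestion: deduplication, heat-source classification,
category harmonisation and geography linkage.

The register is held as a pandas DataFrame with one row per certificate.
Canonical column names (the open-register headers are mapped onto these by
:func:`read_certificates`):

    certificate_id, uprn, inspection_date, property_type_raw,
    built_form_raw, tenure_raw, transaction_type_raw,
    mainheat_text, secondheat_text

Derived columns added by the ingestion operations:

    solid_fuel, wood_fuel  (bool)      — keyword classification
    property_type, tenure  (category)  — census-aligned harmonised categories
    is_latest              (bool)      — most recent certificate per property
    lsoa, ward, lad, region            — geography codes from the UPRN lookup
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: harmonised property-type categories, aligned with the 2021 Census
PROPERTY_TYPES = ["detached", "semi_detached", "terrace", "flat", "other"]
#: the subset of property types counted as houses (prevalence denominator)
HOUSE_TYPES = ["detached", "semi_detached", "terrace"]
#: harmonised tenure categories
TENURES = ["new_build", "owner_occupied", "rented_private", "rented_social"]

#: default column mapping for the England & Wales open register dialect
REGISTER_COLUMNS = {
    "LMK_KEY": "certificate_id",
    "UPRN": "uprn",
    "INSPECTION_DATE": "inspection_date",
    "PROPERTY_TYPE": "property_type_raw",
    "BUILT_FORM": "built_form_raw",
    "TENURE": "tenure_raw",
    "TRANSACTION_TYPE": "transaction_type_raw",
    "MAINHEAT_DESCRIPTION": "mainheat_text",
    "SECONDHEAT_DESCRIPTION": "secondheat_text",
}

_TEXT_COLUMNS = [
    "certificate_id",
    "uprn",
    "property_type_raw",
    "built_form_raw",
    "tenure_raw",
    "transaction_type_raw",
    "mainheat_text",
    "secondheat_text",
]


@dataclass(frozen=True)
class KeywordRuleset:
    """Case-insensitive substring rules for heat-source classification.

    ``wood_keywords`` must be a subset of patterns that also set the solid
    flag; this is enforced at construction by folding the wood set into
    ``solid_keywords``, so a wood match always implies a solid match.
    """

    wood_keywords: tuple[str, ...] = (
        "wood",
        "log",
        "logs",
        "biomass",
        "pellet",
        "wood chip",
    )
    solid_keywords: tuple[str, ...] = (
        "solid fuel",
        "coal",
        "anthracite",
        "smokeless",
        "multi-fuel",
        "multifuel",
        "peat",
    )
    fields_searched: tuple[str, ...] = ("mainheat_text", "secondheat_text")

    def __post_init__(self):
        object.__setattr__(
            self, "wood_keywords", tuple(k.lower() for k in self.wood_keywords)
        )
        solid = tuple(k.lower() for k in self.solid_keywords)
        # wood is a subset of solid fuel: every wood keyword is a solid keyword
        extra = tuple(k for k in self.wood_keywords if k not in solid)
        object.__setattr__(self, "solid_keywords", solid + extra)

    @classmethod
    def from_dict(cls, d: dict) -> "KeywordRuleset":
        return cls(
            wood_keywords=tuple(d.get("wood_keywords", cls.wood_keywords)),
            solid_keywords=tuple(d.get("solid_keywords", cls.solid_keywords)),
        )


@dataclass
class IngestReport:
    """Row-count bookkeeping across the cleaning steps."""

    n_input: int = 0
    n_missing_id: int = 0
    n_duplicates_removed: int = 0
    n_unparseable_date: int = 0
    n_unmatched_geography: int = 0
    notes: list = field(default_factory=list)


def read_certificates(
    path_or_buffer,
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a certificate CSV and map its headers onto canonical names.

    Columns absent from the file are created empty so downstream
    operations always see the full schema.
    """
    df = pd.read_csv(path_or_buffer, dtype=str, keep_default_na=False)
    column_map = column_map or REGISTER_COLUMNS
    df = df.rename(columns=column_map)
    for col in REGISTER_COLUMNS.values():
        if col not in df.columns:
            df[col] = ""
    df["inspection_date"] = pd.to_datetime(df["inspection_date"], errors="coerce")
    return df[list(REGISTER_COLUMNS.values())]


def _normalise_whitespace(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in _TEXT_COLUMNS:
        if col in out.columns:
            out[col] = (
                out[col]
                .fillna("")
                .astype(str)
                .str.strip()
                .str.replace(r"\s+", " ", regex=True)
            )
    return out


def deduplicate(
    records: pd.DataFrame, report: IngestReport | None = None
) -> pd.DataFrame:
    """Remove duplicated certificate entries.

    Rows identical on every field after whitespace normalisation collapse to
    one representative.  Rows sharing a ``certificate_id`` but differing on
    other fields keep the one with the later ``inspection_date`` (ties: the
    lexicographically last full record, for determinism).  Rows with a
    missing ``certificate_id`` are rejected and counted.
    """
    report = report if report is not None else IngestReport()
    report.n_input = len(records)
    df = _normalise_whitespace(records)

    missing_id = df["certificate_id"] == ""
    report.n_missing_id = int(missing_id.sum())
    if report.n_missing_id:
        logger.warning("rejected %d records with missing certificate_id",
                       report.n_missing_id)
        df = df[~missing_id]

    n_before = len(df)
    # full-field duplicates first, then id collisions keep later inspection
    value_cols = [c for c in df.columns]
    df = df.drop_duplicates(subset=value_cols, keep="first")
    df = df.sort_values(
        ["certificate_id", "inspection_date"] + _TEXT_COLUMNS[1:],
        kind="mergesort",
        na_position="first",
    )
    df = df.drop_duplicates(subset="certificate_id", keep="last")
    report.n_duplicates_removed = n_before - len(df)
    logger.info("deduplicate: removed %d of %d records",
                report.n_duplicates_removed, report.n_input)
    return df.reset_index(drop=True)


def flag_most_recent(records: pd.DataFrame) -> pd.DataFrame:
    """Flag, per property, the certificate with the latest inspection date.

    Date ties are broken by the lexicographically greatest
    ``certificate_id``.  Certificates with an unparseable date never win the
    competition (flag False) and are counted in a warning.  Certificates
    with no UPRN are treated as singleton properties and flagged latest.
    """
    df = records.copy()
    dates = pd.to_datetime(df["inspection_date"], errors="coerce")
    n_bad = int(dates.isna().sum())
    if n_bad:
        logger.warning("%d certificates with unparseable inspection_date "
                       "excluded from latest-flag competition", n_bad)
    df["inspection_date"] = dates

    has_uprn = df["uprn"].astype(str).str.len() > 0
    df["is_latest"] = False

    with_uprn = df[has_uprn & dates.notna()]
    if len(with_uprn):
        order = with_uprn.sort_values(
            ["uprn", "inspection_date", "certificate_id"], kind="mergesort"
        )
        winners = order.groupby("uprn", sort=False).tail(1).index
        df.loc[winners, "is_latest"] = True
    # UPRN-less certificates cannot be grouped into a property
    df.loc[~has_uprn & dates.notna(), "is_latest"] = True
    return df


def classify_heat_source(
    records: pd.DataFrame, ruleset: KeywordRuleset | None = None
) -> pd.DataFrame:
    """Set ``solid_fuel`` / ``wood_fuel`` flags by keyword search.

    A flag is true if any keyword occurs (case-insensitive substring) in
    either the main or the secondary heat description.  Wood fuel is a
    subset of solid fuel by construction of the ruleset.
    """
    ruleset = ruleset or KeywordRuleset()
    df = records.copy()
    text = pd.Series("", index=df.index)
    for col in ruleset.fields_searched:
        text = text + " | " + df[col].fillna("").astype(str).str.lower()

    def _any_match(keywords: tuple[str, ...]) -> pd.Series:
        hit = pd.Series(False, index=df.index)
        for kw in keywords:
            hit |= text.str.contains(kw, regex=False)
        return hit

    wood = _any_match(ruleset.wood_keywords)
    solid = _any_match(ruleset.solid_keywords) | wood
    df["wood_fuel"] = wood
    df["solid_fuel"] = solid
    return df


_BUILT_FORM_MAP = {
    "detached": "detached",
    "semi-detached": "semi_detached",
    "mid-terrace": "terrace",
    "end-terrace": "terrace",
    "enclosed mid-terrace": "terrace",
    "enclosed end-terrace": "terrace",
}


def harmonise_property_type(records: pd.DataFrame) -> pd.DataFrame:
    """Map raw property type and built form onto census-aligned categories.

    Houses and bungalows take their category from the built form; flats and
    maisonettes map to ``flat``; anything unrecognised maps to ``other``.
    A house whose built form is missing or unrecognised keeps a missing
    category (reported separately in summaries, mirroring the register's
    incomplete built-form field).
    """
    df = records.copy()
    ptype = df["property_type_raw"].fillna("").astype(str).str.strip().str.lower()
    bform = df["built_form_raw"].fillna("").astype(str).str.strip().str.lower()

    out = pd.Series(pd.NA, index=df.index, dtype="object")
    is_house = ptype.isin(["house", "bungalow"])
    out[is_house] = bform[is_house].map(_BUILT_FORM_MAP)  # NaN if unknown form
    out[ptype.isin(["flat", "maisonette"])] = "flat"
    unseen = ~is_house & ~ptype.isin(["flat", "maisonette"]) & (ptype != "")
    if unseen.any():
        logger.info("harmonise_property_type: %d unseen raw types -> other",
                    int(unseen.sum()))
    out[unseen] = "other"
    df["property_type"] = pd.Categorical(out, categories=PROPERTY_TYPES)
    return df


def harmonise_tenure(records: pd.DataFrame) -> pd.DataFrame:
    """Map transaction type and raw tenure onto census-aligned tenure.

    A transaction type containing "new dwelling" takes precedence as
    ``new_build``; otherwise the raw tenure string decides; unmapped values
    stay missing.
    """
    df = records.copy()
    tx = df["transaction_type_raw"].fillna("").astype(str).str.lower()
    raw = df["tenure_raw"].fillna("").astype(str).str.strip().str.lower()

    out = pd.Series(pd.NA, index=df.index, dtype="object")
    out[raw.str.contains("owner-occupied", regex=False)] = "owner_occupied"
    out[raw.str.contains("rented (private)", regex=False)
        | raw.str.contains("rental (private)", regex=False)] = "rented_private"
    out[raw.str.contains("rented (social)", regex=False)
        | raw.str.contains("rental (social)", regex=False)] = "rented_social"
    out[tx.str.contains("new dwelling", regex=False)] = "new_build"
    df["tenure"] = pd.Categorical(out, categories=TENURES)
    return df


def link_geography(
    records: pd.DataFrame,
    lookup: pd.DataFrame,
    report: IngestReport | None = None,
) -> pd.DataFrame:
    """Attach LSOA/ward/LAD/region codes via the UPRN lookup.

    The lookup must be a function of UPRN: duplicated UPRNs raise.
    Unmatched records are retained with null codes and counted.
    """
    report = report if report is not None else IngestReport()
    lookup = lookup.rename(
        columns={
            "UPRN": "uprn",
            "LSOA21CD": "lsoa",
            "WD22CD": "ward",
            "LAD22CD": "lad",
            "RGN22CD": "region",
        }
    )
    dup = lookup["uprn"].duplicated()
    if dup.any():
        raise ValueError(
            f"UPRN lookup is not a function: {int(dup.sum())} duplicated UPRNs"
        )
    lookup = lookup.set_index(lookup["uprn"].astype(str))
    df = records.copy()
    keys = df["uprn"].astype(str)
    for col in ["lsoa", "ward", "lad", "region"]:
        df[col] = keys.map(lookup[col])
    unmatched = df["lsoa"].isna()
    report.n_unmatched_geography = int(unmatched.sum())
    if report.n_unmatched_geography:
        logger.info("link_geography: %d of %d records unmatched",
                    report.n_unmatched_geography, len(df))
    return df


def summarise_by_flag(
    properties: pd.DataFrame,
    flag: str = "wood_fuel",
    characteristics: list[str] | None = None,
    weight: str | None = None,
) -> pd.DataFrame:
    """Two-column characteristics table split by presence of the fuel flag.

    For each level of each characteristic, the count of properties and the
    percentage within the flag column, computed over non-missing values of
    that characteristic; missing values are reported as separate ``Missing``
    rows with no percentage.  ``weight`` names an optional column of row
    weights so pre-aggregated count tables can be summarised directly.

    Returns a long DataFrame with columns
    ``characteristic, level, flag_value, count, pct``.
    """
    if characteristics is None:
        characteristics = [
            c for c in ["property_type", "tenure", "sca", "urban"]
            if c in properties.columns
        ]
    rows = []
    if len(properties) == 0:
        return pd.DataFrame(
            columns=["characteristic", "level", "flag_value", "count", "pct"]
        )
    w = (
        properties[weight].astype(float)
        if weight is not None
        else pd.Series(1.0, index=properties.index)
    )
    for char in characteristics:
        values = properties[char]
        for flag_value in (False, True):
            in_col = properties[flag].astype(bool) == flag_value
            nonmiss = in_col & values.notna()
            denom = w[nonmiss].sum()
            counts = w[nonmiss].groupby(values[nonmiss], observed=True).sum()
            for level, count in counts.items():
                rows.append(
                    {
                        "characteristic": char,
                        "level": level,
                        "flag_value": flag_value,
                        "count": count,
                        "pct": 100.0 * count / denom if denom > 0 else np.nan,
                    }
                )
            n_missing = w[in_col & values.isna()].sum()
            if n_missing > 0:
                rows.append(
                    {
                        "characteristic": char,
                        "level": "Missing",
                        "flag_value": flag_value,
                        "count": n_missing,
                        "pct": np.nan,
                    }
                )
    return pd.DataFrame(rows)
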