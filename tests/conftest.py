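"""Shared fixtures: printed characteristics-table counts and a reference
synthetic scenario run once per session through the ingest pipeline."""

import numpy as np
import pandas as pd
import pytest

from woodmap import ingest
from woodmap.synthetic import ScenarioConfig, generate_scenario

# Published England & Wales characteristics table: property counts by
# presence of a wood-burning heat source.  ``None`` keys are values missing
# for that characteristic; "house_form_missing" is a reported level (houses
# whose built form is unrecorded) and carries a percentage in the source.
CHARACTERISTICS_COUNTS = {
    "property_type": {
        False: {
            "detached": 2_890_474, "flat": 5_308_610,
            "house_form_missing": 53_891, "other": 9_772,
            "semi_detached": 4_295_286, "terrace": 4_781_685,
        },
        True: {
            "detached": 679_637, "flat": 26_946,
            "house_form_missing": 2_781, "other": 215,
            "semi_detached": 377_068, "terrace": 282_155,
        },
    },
    "tenure": {
        False: {
            "new_build": 738_240, "owner_occupied": 8_707_524,
            "rented_private": 3_299_967, "rented_social": 3_143_415,
            None: 1_450_572,
        },
        True: {
            "new_build": 18_278, "owner_occupied": 1_105_820,
            "rented_private": 165_375, "rented_social": 18_706,
            None: 60_623,
        },
    },
    "sca": {
        False: {"no": 8_427_370, "yes": 8_912_348},
        True: {"no": 1_159_221, "yes": 209_581},
    },
    "urban": {
        False: {"no": 2_455_205, "yes": 14_093_037, None: 791_476},
        True: {"no": 746_353, "yes": 594_822, None: 27_627},
    },
}

# printed within-column percentages, (value, printed decimals); "<0.1" is
# encoded as None and asserted as pct < 0.1
CHARACTERISTICS_PCTS = {
    "property_type": {
        False: {"detached": (17, 0), "flat": (31, 0),
                "house_form_missing": (0.3, 1), "other": (None, None),
                "semi_detached": (25, 0), "terrace": (28, 0)},
        True: {"detached": (50, 0), "flat": (2.0, 1),
               "house_form_missing": (0.2, 1), "other": (None, None),
               "semi_detached": (28, 0), "terrace": (21, 0)},
    },
    "tenure": {
        False: {"new_build": (4.6, 1), "owner_occupied": (55, 0),
                "rented_private": (21, 0), "rented_social": (20, 0)},
        True: {"new_build": (1.4, 1), "owner_occupied": (85, 0),
               "rented_private": (13, 0), "rented_social": (1.4, 1)},
    },
    "sca": {
        False: {"no": (49, 0), "yes": (51, 0)},
        True: {"no": (85, 0), "yes": (15, 0)},
    },
    "urban": {
        False: {"no": (15, 0), "yes": (85, 0)},
        True: {"no": (56, 0), "yes": (44, 0)},
    },
}


def characteristics_frame(characteristic: str) -> pd.DataFrame:
    """Weighted one-row-per-level frame for one characteristic."""
    rows = []
    for flag_value, counts in CHARACTERISTICS_COUNTS[characteristic].items():
        for level, count in counts.items():
            rows.append(
                {characteristic: level, "wood_fuel": flag_value,
                 "weight": count}
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def scenario():
    """Reference synthetic study (default conditions), generated once."""
    return generate_scenario(ScenarioConfig(seed=101))


def run_ingest(certificates: pd.DataFrame, lookup: pd.DataFrame,
               report: ingest.IngestReport | None = None) -> pd.DataFrame:
    """The full ingest pipeline on an in-memory register."""
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


@pytest.fixture(scope="session")
def ingested(scenario):
    """Scenario register after the full ingest pipeline, with its report."""
    report = ingest.IngestReport()
    df = run_ingest(scenario.certificates, scenario.geography.lookup, report)
    return df, report


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
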