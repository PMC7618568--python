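"""Register cleaning, classification and linkage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from woodmap import ingest
from woodmap.ingest import IngestReport, KeywordRuleset
from woodmap.synthetic import ScenarioConfig, generate_scenario

from conftest import run_ingest


def _record(cid="C1", uprn="1", date="2015-01-01", main="", second="",
            ptype="House", bform="Detached"):
    return {
        "certificate_id": cid, "uprn": uprn, "inspection_date": date,
        "property_type_raw": ptype, "built_form_raw": bform,
        "tenure_raw": "Owner-occupied", "transaction_type_raw": "marketed sale",
        "mainheat_text": main, "secondheat_text": second,
    }


class TestDeduplicate:
    def test_identical_records_collapse(self):
        df = pd.DataFrame([_record(), _record()])
        out = ingest.deduplicate(df)
        assert len(out) == 1

    def test_id_duplicates_with_identical_fields(self):
        rows = [_record(cid=f"C{i}", uprn=str(i)) for i in range(4)]
        rows.append(_record(cid="C0", uprn="0"))  # exact repeat of C0
        out = ingest.deduplicate(pd.DataFrame(rows))
        assert len(out) == 4

    def test_id_collision_keeps_later_inspection(self):
        df = pd.DataFrame([
            _record(cid="C1", date="2010-05-01", main="old text"),
            _record(cid="C1", date="2018-05-01", main="new text"),
        ])
        out = ingest.deduplicate(df)
        assert len(out) == 1
        assert out["mainheat_text"].iloc[0] == "new text"

    def test_missing_id_rejected_and_counted(self):
        report = IngestReport()
        df = pd.DataFrame([_record(), _record(cid="")])
        out = ingest.deduplicate(df, report)
        assert len(out) == 1
        assert report.n_missing_id == 1

    def test_planted_duplication_removed_exactly(self, scenario, ingested):
        _, report = ingested
        assert report.n_duplicates_removed == scenario.truth.n_duplicates_planted


class TestFlagMostRecent:
    def test_singletons_all_latest(self):
        df = pd.DataFrame([_record(cid="C1", uprn="1"),
                           _record(cid="C2", uprn="2")])
        df["inspection_date"] = pd.to_datetime(df["inspection_date"])
        out = ingest.flag_most_recent(df)
        assert out["is_latest"].all()

    def test_latest_date_wins(self):
        df = pd.DataFrame([_record(cid="C1", uprn="1", date="2010-01-01"),
                           _record(cid="C2", uprn="1", date="2019-01-01")])
        out = ingest.flag_most_recent(df)
        assert out.loc[out["certificate_id"] == "C2", "is_latest"].iloc[0]
        assert not out.loc[out["certificate_id"] == "C1", "is_latest"].iloc[0]

    def test_date_tie_broken_by_greatest_id(self):
        df = pd.DataFrame([_record(cid="CA", uprn="1", date="2015-06-01"),
                           _record(cid="CB", uprn="1", date="2015-06-01")])
        out = ingest.flag_most_recent(df)
        assert out.loc[out["certificate_id"] == "CB", "is_latest"].iloc[0]

    def test_unparseable_date_never_wins(self):
        df = pd.DataFrame([_record(cid="C1", uprn="1", date="not a date"),
                           _record(cid="C2", uprn="1", date="2012-01-01")])
        out = ingest.flag_most_recent(df)
        assert out.loc[out["certificate_id"] == "C2", "is_latest"].iloc[0]
        assert not out.loc[out["certificate_id"] == "C1", "is_latest"].iloc[0]

    def test_latest_count_equals_distinct_uprns(self, ingested):
        df, _ = ingested
        dated = df[df["inspection_date"].notna()]
        assert df["is_latest"].sum() == dated["uprn"].nunique()


class TestClassifyHeatSource:
    @pytest.mark.parametrize(
        "main,second,solid,wood",
        [
            ("Boiler and radiators, mains gas", "Room heaters, wood logs",
             True, True),
            ("Boiler, anthracite", "", True, False),
            ("", "", False, False),
            ("ROOM HEATERS, WOOD LOGS", "", True, True),  # case-insensitive
        ],
    )
    def test_keyword_examples(self, main, second, solid, wood):
        df = pd.DataFrame([_record(main=main, second=second)])
        out = ingest.classify_heat_source(df)
        assert bool(out["solid_fuel"].iloc[0]) is solid
        assert bool(out["wood_fuel"].iloc[0]) is wood

    def test_wood_implies_solid_even_for_wood_only_keyword(self):
        rules = KeywordRuleset(wood_keywords=("pellet",),
                               solid_keywords=("coal",))
        df = pd.DataFrame([_record(second="pellet stove")])
        out = ingest.classify_heat_source(df, rules)
        assert out["wood_fuel"].iloc[0] and out["solid_fuel"].iloc[0]

    @given(st.text(alphabet="abcd ", max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_adding_keywords_is_monotone(self, text):
        base = KeywordRuleset(wood_keywords=("ab",), solid_keywords=("cd",))
        wider = KeywordRuleset(wood_keywords=("ab", "da"),
                               solid_keywords=("cd", "bc"))
        df = pd.DataFrame([_record(main=text)])
        small = ingest.classify_heat_source(df, base)
        big = ingest.classify_heat_source(df, wider)
        assert big["wood_fuel"].iloc[0] >= small["wood_fuel"].iloc[0]
        assert big["solid_fuel"].iloc[0] >= small["solid_fuel"].iloc[0]

    def test_recovers_planted_flags_exactly(self, scenario, ingested):
        df, _ = ingested
        truth = scenario.truth.properties.set_index("uprn")
        latest = df[df["is_latest"]].set_index("uprn")
        joined = latest.join(truth[["wood_final"]], how="inner")
        assert len(joined) == len(latest)
        assert (joined["wood_fuel"] == joined["wood_final"]).all()

    def test_noisy_text_mode_still_invertible(self):
        sc = generate_scenario(ScenarioConfig(
            seed=5, grid_rows=4, grid_cols=4, noisy_text=True,
            n_monitors=2, pm_years=(2022,),
            properties_per_lsoa={"detached": 20, "semi_detached": 20,
                                 "terrace": 20, "flat": 10, "other": 2},
        ))
        df = run_ingest(sc.certificates, sc.geography.lookup)
        truth = sc.truth.properties.set_index("uprn")["wood_final"]
        latest = df[df["is_latest"]].set_index("uprn")
        assert (latest["wood_fuel"] == truth[latest.index]).all()


class TestHarmonise:
    @pytest.mark.parametrize(
        "ptype,bform,expected",
        [
            ("House", "Detached", "detached"),
            ("Bungalow", "Semi-Detached", "semi_detached"),
            ("House", "End-Terrace", "terrace"),
            ("House", "Enclosed Mid-Terrace", "terrace"),
            ("Flat", "", "flat"),
            ("Maisonette", "", "flat"),
            ("Park home", "", "other"),
        ],
    )
    def test_property_type_mapping(self, ptype, bform, expected):
        df = pd.DataFrame([_record(ptype=ptype, bform=bform)])
        out = ingest.harmonise_property_type(df)
        assert out["property_type"].iloc[0] == expected

    def test_house_with_unknown_form_is_missing(self):
        df = pd.DataFrame([_record(ptype="House", bform="")])
        out = ingest.harmonise_property_type(df)
        assert pd.isna(out["property_type"].iloc[0])

    @pytest.mark.parametrize(
        "tenure_raw,tx,expected",
        [
            ("Owner-occupied", "marketed sale", "owner_occupied"),
            ("Rented (private)", "rental", "rented_private"),
            ("Rented (social)", "rental", "rented_social"),
            ("Owner-occupied", "new dwelling", "new_build"),
            ("something else", "marketed sale", None),
        ],
    )
    def test_tenure_mapping(self, tenure_raw, tx, expected):
        df = pd.DataFrame([_record()])
        df["tenure_raw"] = tenure_raw
        df["transaction_type_raw"] = tx
        out = ingest.harmonise_tenure(df)
        got = out["tenure"].iloc[0]
        assert (pd.isna(got) and expected is None) or got == expected


class TestLinkGeography:
    def _lookup(self):
        return pd.DataFrame({
            "UPRN": ["1", "2"], "LSOA21CD": ["L1", "L2"],
            "WD22CD": ["W1", "W1"], "LAD22CD": ["D1", "D1"],
            "RGN22CD": ["R1", "R1"],
        })

    def test_matched_records_get_all_codes(self):
        df = pd.DataFrame([_record(uprn="1")])
        out = ingest.link_geography(df, self._lookup())
        assert out[["lsoa", "ward", "lad", "region"]].iloc[0].tolist() == [
            "L1", "W1", "D1", "R1"]

    def test_unmatched_retained_with_null_codes(self):
        report = IngestReport()
        df = pd.DataFrame([_record(uprn="99")])
        out = ingest.link_geography(df, self._lookup(), report)
        assert len(out) == 1 and out["lsoa"].isna().all()
        assert report.n_unmatched_geography == 1

    def test_duplicate_uprn_in_lookup_raises(self):
        lk = self._lookup()
        lk.loc[1, "UPRN"] = "1"
        with pytest.raises(ValueError, match="not a function"):
            ingest.link_geography(pd.DataFrame([_record()]), lk)

    def test_planted_unmatched_rate_recovered(self):
        sc = generate_scenario(ScenarioConfig(
            seed=3, grid_rows=4, grid_cols=4, unmatched_rate=0.10,
            n_monitors=2, pm_years=(2022,),
        ))
        report = IngestReport()
        run_ingest(sc.certificates, sc.geography.lookup, report)
        # every certificate of an unlinked property is unmatched
        df = run_ingest(sc.certificates, sc.geography.lookup)
        unmatched_uprns = df.loc[df["lsoa"].isna(), "uprn"].nunique()
        planted = sc.geography.n_unmatched_planted
        total = len(sc.geography.properties)
        assert planted == round(0.10 * total)
        assert unmatched_uprns <= planted  # only certificated ones observed


class TestSummariseByFlag:
    def test_single_property_is_100pct(self):
        df = pd.DataFrame({"property_type": ["detached"],
                           "wood_fuel": [True]})
        out = ingest.summarise_by_flag(df, characteristics=["property_type"])
        row = out[(out["flag_value"]) & (out["level"] == "detached")]
        assert row["pct"].iloc[0] == 100.0

    def test_empty_input_gives_empty_table(self):
        out = ingest.summarise_by_flag(
            pd.DataFrame(columns=["property_type", "wood_fuel"]))
        assert out.empty

    def test_percentages_sum_to_100_over_nonmissing(self, ingested):
        df, _ = ingested
        latest = df[df["is_latest"]]
        out = ingest.summarise_by_flag(
            latest, characteristics=["property_type", "tenure"])
        sums = (
            out[out["level"] != "Missing"]
            .groupby(["characteristic", "flag_value"])["pct"]
            .sum()
        )
        assert np.allclose(sums, 100.0)

    def test_missing_reported_separately_without_pct(self):
        df = pd.DataFrame({
            "tenure": ["owner_occupied", None, "owner_occupied"],
            "wood_fuel": [True, True, False],
        })
        out = ingest.summarise_by_flag(df, characteristics=["tenure"])
        miss = out[(out["level"] == "Missing") & out["flag_value"]]
        assert miss["count"].iloc[0] == 1 and np.isnan(miss["pct"].iloc[0])
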