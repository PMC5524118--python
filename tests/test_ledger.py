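"""Ledger tests: classification, exclusion cascade, tabulation, combining."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import heartsentinel as hs
from heartsentinel.ledger import SdModel, rollup_categories


def frame(rows):
    base = {"year": 2013, "sex": "men", "age_group": "45-64",
            "code": "410", "flags": "", "weight": 1.0}
    return pd.DataFrame([{**base, **r} for r in rows])


class TestClassification:
    def test_prefix_match_ignores_dots_and_case(self, toy_defs):
        assert hs.classify_event("410.71", "hospitalization", toy_defs) == (
            "ami", "acute myocardial infarction")
        assert hs.classify_event("i21.4", "death", toy_defs)[0] == "ami"

    def test_non_case_code_returns_none(self, toy_defs):
        assert hs.classify_event("486", "ed", toy_defs) is None

    def test_code_systems_are_separate(self, toy_defs):
        # a death record never matches ED/hospitalization code lists
        assert hs.classify_event("410.71", "death", toy_defs) is None
        assert hs.classify_event("I21", "hospitalization", toy_defs) is None

    def test_ambiguous_definition_rejected(self):
        with pytest.raises(ValueError, match="ambiguous"):
            hs.CaseDefinitionSet([
                hs.CaseDefinition("ami", "a", ed_hosp_codes=("410",), death_codes=()),
                hs.CaseDefinition("stroke", "b", ed_hosp_codes=("4107",), death_codes=()),
            ])

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            hs.CaseDefinition("ami", "a", ed_hosp_codes=("",), death_codes=())

    def test_default_definition_loads_and_is_disjoint(self, default_defs):
        assert set(default_defs.categories) == set(hs.CATEGORIES)
        assert hs.classify_event("410.01", "ed", default_defs)[0] == "ami"


class TestExclusions:
    def test_enumerated_toy_ledger(self, toy_defs):
        rows = (
            [{"source": "ed", "flags": "admitted_same_hospital"}] * 2
            + [{"source": "ed", "flags": "died_in_facility"}]
            + [{"source": "ed"}] * 2
            + [{"source": "hospitalization", "flags": "elective"}]
            + [{"source": "hospitalization", "flags": "transferred_out"}]
            + [{"source": "hospitalization"}] * 3
        )
        retained = hs.apply_exclusions(frame(rows))
        assert (retained["source"] == "ed").sum() == 2
        assert (retained["source"] == "hospitalization").sum() == 3

    def test_unflagged_records_all_retained(self):
        f = frame([{"source": "ed"}] * 10)
        assert len(hs.apply_exclusions(f)) == 10

    def test_death_records_exempt_even_with_stray_flag(self):
        f = frame([{"source": "death", "flags": "died_in_facility", "code": "I21"}])
        assert len(hs.apply_exclusions(f)) == 1

    def test_unknown_flag_token_rejected(self):
        with pytest.raises(ValueError, match="unknown disposition flag"):
            hs.apply_exclusions(frame([{"source": "ed", "flags": "left_ama"}]))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.sampled_from([
        "", "elective", "died_in_facility", "transferred_out",
        "admitted_same_hospital", "elective;died_in_facility"]), min_size=1, max_size=30),
        st.sampled_from(["ed", "hospitalization", "death"]))
    def test_exclusion_never_increases_counts(self, flags, source):
        f = frame([{"source": source, "flags": fl} for fl in flags])
        retained = hs.apply_exclusions(f)
        assert len(retained) <= len(f)
        if source == "death":
            assert len(retained) == len(f)


class TestTabulation:
    def test_weighted_sum_and_relative_se(self, toy_defs):
        rows = [{"source": "ed", "weight": w} for w in (10.0, 10.0, 5.0)]
        cases = hs.classify_records(frame(rows), toy_defs)
        counts = hs.tabulate_counts(cases, {"ed": SdModel("relative", 0.03),
                                            "hospitalization": SdModel("zero"),
                                            "death": SdModel("zero")})
        assert counts["count"].iloc[0] == pytest.approx(25.0)
        assert counts["sd"].iloc[0] == pytest.approx(0.75)

    def test_thousand_unit_weights_give_sd_30(self, toy_defs):
        cases = hs.classify_records(frame([{"source": "ed"}] * 1000), toy_defs)
        counts = hs.tabulate_counts(cases, {"ed": SdModel("relative", 0.03),
                                            "hospitalization": SdModel("zero"),
                                            "death": SdModel("zero")})
        assert counts["count"].iloc[0] == 1000
        assert counts["sd"].iloc[0] == pytest.approx(30.0)

    def test_negative_weight_rejected(self, toy_defs):
        cases = hs.classify_records(frame([{"source": "ed"}]), toy_defs)
        cases.loc[0, "weight"] = -1.0
        with pytest.raises(ValueError, match="negative"):
            hs.tabulate_counts(cases)

    def test_matches_brute_force_accumulation_on_small_fixture(self, default_defs):
        cfg = hs.default_sim_config(seed=2, population=2_000)
        records, _ = hs.generate_dataset(cfg, default_defs)
        records = records.head(50)
        cases = hs.classify_records(records, default_defs)
        retained = hs.apply_exclusions(cases)
        counts = hs.tabulate_counts(retained)
        # brute force: accumulate record weights one at a time
        acc: dict[tuple, float] = {}
        for _, r in retained.iterrows():
            key = (r.year, r.sex, r.age_group, r.source, r.category)
            acc[key] = acc.get(key, 0.0) + r.weight
        for _, row in counts.iterrows():
            key = (row.year, row.sex, row.age_group, row.source, row.category)
            assert row["count"] == pytest.approx(acc[key])
        assert len(acc) == len(counts)


class TestCombineSources:
    def test_published_2013_source_totals_sum(self):
        counts = pd.DataFrame({
            "year": 2013, "sex": "all", "age_group": "all",
            "source": ["ed", "hospitalization", "death"],
            "count": [343_214.0, 2_099_874.0, 386_073.0],
            "sd": [0.0, 0.0, 0.0],
        })
        combined = hs.combine_sources(counts)
        assert combined["count"].iloc[0] == 2_829_161

    def test_variances_add_in_quadrature(self):
        counts = pd.DataFrame({
            "year": 2013, "sex": "all", "age_group": "all",
            "source": ["ed", "hospitalization", "death"],
            "count": [1.0, 1.0, 1.0], "sd": [3.0, 4.0, 0.0],
        })
        assert hs.combine_sources(counts)["sd"].iloc[0] == pytest.approx(5.0)

    def test_all_zero_sources(self):
        counts = pd.DataFrame({
            "year": 2013, "sex": "all", "age_group": "all",
            "source": ["ed", "hospitalization", "death"],
            "count": [0.0, 0.0, 0.0], "sd": [0.0, 0.0, 0.0],
        })
        combined = hs.combine_sources(counts)
        assert combined["count"].iloc[0] == 0 and combined["sd"].iloc[0] == 0

    def test_duplicate_source_entries_rejected(self):
        counts = pd.DataFrame({
            "year": 2013, "sex": "all", "age_group": "all",
            "source": ["ed", "ed"], "count": [1.0, 2.0], "sd": [0.0, 0.0],
        })
        with pytest.raises(ValueError, match="duplicate"):
            hs.combine_sources(counts)

    def test_category_partition_and_source_exclusivity(self, default_defs):
        cfg = hs.default_sim_config(seed=7, population=50_000)
        records, _ = hs.generate_dataset(cfg, default_defs)
        retained = hs.apply_exclusions(hs.classify_records(records, default_defs))
        counts = hs.tabulate_counts(retained)
        rolled = rollup_categories(counts)
        # partition: category totals sum to the all-category total per cell
        per_cat = counts.groupby(["year", "sex", "age_group", "source"])["count"].sum()
        pd.testing.assert_series_equal(
            per_cat.sort_index(),
            rolled.set_index(["year", "sex", "age_group", "source"])["count"].sort_index(),
            check_names=False)
        # mutual exclusivity: every retained record lands in exactly one source
        assert counts["count"].sum() == pytest.approx(retained["weight"].sum())
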