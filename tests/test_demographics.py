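"""Characteristic tables, partition conservation and derived ratios."""

import math

import pytest

from faerspv.curation import AEReport
from faerspv.demographics import (
    OutcomeRecord,
    derived_ratios,
    load_published_counts,
    summarize,
    summary_from_counts,
)
from faerspv.faers_io import PartialDate


def _report(pid, sex="M", age=None, weight=None, occ="unknown", country="US"):
    return AEReport(
        primaryid=pid, caseid=pid, fda_dt=PartialDate(2021, 1, 1),
        age_years=age, sex=sex, weight_kg=weight,
        reporter_occupation=occ, country=country,
    )


def _cohort10():
    reports = [_report(str(i), sex="M") for i in range(4)]
    reports += [_report(str(i + 4), sex="F") for i in range(5)]
    reports += [_report("9", sex="unknown")]
    return reports


def test_sex_percentages_and_partition_conservation():
    summary = summarize(_cohort10(), [], {str(i) for i in range(10)})
    sex = summary.bands["sex"]
    assert sex["M"] == (4, 40.0) and sex["F"] == (5, 50.0) and sex["Unknown"] == (1, 10.0)
    for section in ("sex", "age", "weight", "occupation"):
        assert sum(c for c, _ in summary.bands[section].values()) == summary.total


def test_multi_outcome_report_contributes_to_both_bands():
    outcomes = [OutcomeRecord("0", "HO"), OutcomeRecord("0", "DE")]
    summary = summarize(_cohort10(), outcomes, {str(i) for i in range(10)})
    out = summary.bands["outcome"]
    assert out["Hospitalization"][0] == 1 and out["Death"][0] == 1
    assert out["Unknown"][0] == 9  # reports with no outcome row


def test_age_bands_convert_units():
    reports = [_report("0", age=2.0), _report("1", age=70.0),
               _report("2", age=90.0), _report("3")]
    summary = summarize(reports, [], {"0", "1", "2", "3"})
    age = summary.bands["age"]
    assert age["<18"][0] == 1 and age["65-<85"][0] == 1
    assert age[">=85"][0] == 1 and age["Unknown"][0] == 1


def test_occupation_grouping():
    reports = [_report("0", occ="physician"), _report("1", occ="pharmacist"),
               _report("2", occ="consumer"), _report("3", occ="lawyer"),
               _report("4")]
    occ = summarize(reports, [], {str(i) for i in range(5)}).bands["occupation"]
    assert occ["Healthcare professional"][0] == 2
    assert occ["Non-healthcare professional"][0] == 2
    assert occ["Unknown"][0] == 1


def test_empty_cohort_is_an_error():
    with pytest.raises(ValueError):
        summarize(_cohort10(), [], {"nope"})


class TestDerivedRatios:
    def test_equal_sexes_give_ratio_one(self):
        s = summary_from_counts(
            20, {"sex": {"Male": 10, "Female": 10},
                 "age": {"65-<85": 5, ">=85": 1, "Unknown": 4}}
        )
        assert s.derived["male_female_ratio"] == 1.00

    def test_zero_female_count_is_undefined(self):
        s = summary_from_counts(
            5, {"sex": {"Male": 5, "Female": 0},
                "age": {"65-<85": 0, ">=85": 0, "Unknown": 0}}
        )
        assert math.isnan(s.derived["male_female_ratio"])

    def test_published_cohort_counts_reproduce_quoted_ratios(self):
        """94,264/100,658 -> 0.94; (68,625+9,535)/(216,362-67,104) -> 52.37%."""
        summary = load_published_counts()
        assert summary.derived["male_female_ratio"] == 0.94
        assert summary.derived["pct_65plus_known_age"] == 52.37


def test_published_percentages_recompute_from_printed_counts():
    """Every printed percentage follows from its count and the total.

    One printed figure (outcome Unknown) rounds to 3.3 from its own
    counts; the recomputed value is asserted, not the misprint.
    """
    summary = load_published_counts()
    expected = {
        ("sex", "Male"): 43.6, ("sex", "Female"): 46.5, ("sex", "Unknown"): 9.9,
        ("age", "<18"): 2.0, ("age", "18-<65"): 30.8, ("age", "65-<85"): 31.7,
        ("age", ">=85"): 4.4, ("age", "Unknown"): 31.0,
        ("weight", "<50"): 3.2, ("weight", "50-<100"): 20.6,
        ("weight", ">=100"): 5.2, ("weight", "Unknown"): 71.0,
        ("occupation", "Healthcare professional"): 62.3,
        ("occupation", "Non-healthcare professional"): 32.7,
        ("occupation", "Unknown"): 5.0,
        ("country", "United States"): 46.2, ("country", "Japan"): 6.9,
        ("country", "France"): 5.1, ("country", "Canada"): 3.9,
        ("country", "Germany"): 3.8, ("country", "United Kingdom"): 3.2,
        ("country", "Others"): 30.9,
        ("outcome", "Hospitalization"): 40.7, ("outcome", "Death"): 29.3,
        ("outcome", "Other Serious Outcome"): 19.5,
        ("outcome", "Life-threatening"): 6.7, ("outcome", "Disability"): 0.4,
        ("outcome", "Unknown"): 3.3,
    }
    for (section, band), pct in expected.items():
        assert summary.bands[section][band][1] == pct, (section, band)


def test_summary_frame_has_derived_section():
    df = load_published_counts().to_frame()
    assert {"section", "band", "count", "percentage"} <= set(df.columns)
    assert "derived" in set(df.section)
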