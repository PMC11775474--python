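"""ROR disproportionality: 2×2 construction, closed form, signal rule."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.contingency_tables import Table2x2

from faerspv.drug_catalog import AtcMap, DrugRecord
from faerspv.signal_stats import (
    ContingencyTable,
    DisproportionalityModel,
    build_contingency,
    class_signal,
    ror_signal,
)


class TestBuildContingency:
    def test_enumeration(self):
        t = build_contingency({"1", "2"}, {"2", "3"}, {"1", "2", "3", "4"})
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_degenerate_all_equal(self):
        s = {str(i) for i in range(7)}
        t = build_contingency(s, s, s)
        assert (t.a, t.b, t.c, t.d) == (7, 0, 0, 0)

    def test_disjoint(self):
        all_ids = {str(i) for i in range(10)}
        t = build_contingency({"0", "1", "2"}, {"3", "4"}, all_ids)
        assert (t.a, t.b, t.c, t.d) == (0, 3, 2, 5)

    def test_subset_violation_raises(self):
        with pytest.raises(ValueError):
            build_contingency({"9"}, set(), {"1"})


class TestRorSignal:
    def test_symmetric_table_is_null(self):
        r = ror_signal(ContingencyTable(5, 5, 5, 5))
        assert r.ror == pytest.approx(1.0)
        assert r.ci_low < 1 < r.ci_high
        assert not r.is_signal

    def test_hand_evaluated_closed_form(self):
        # (10*9900)/(90*100) = 11; CI = exp(ln 11 ± 1.96*sqrt(1/10+1/90+1/100+1/9900))
        r = ror_signal(ContingencyTable(10, 90, 100, 9900))
        assert r.ror == pytest.approx(11.0)
        assert r.ci_low == pytest.approx(5.5593, abs=2e-3)
        assert r.ci_high == pytest.approx(21.7648, abs=2e-3)
        assert r.is_signal

    def test_fewer_than_three_cases_never_signals(self):
        r = ror_signal(ContingencyTable(2, 8, 10, 980))
        assert not r.is_signal

    @pytest.mark.parametrize("cells", [(0, 5, 5, 5), (5, 0, 5, 5), (5, 5, 0, 5), (5, 5, 5, 0)])
    def test_zero_cell_is_undefined_not_corrected(self, cells):
        r = ror_signal(ContingencyTable(*cells))
        assert r.ror is None and r.ci_low is None and not r.is_signal

    def test_matches_statsmodels_odds_ratio_machinery(self):
        t = ContingencyTable(17, 240, 311, 9432)
        r = ror_signal(t)
        sm = Table2x2(np.array([[t.a, t.b], [t.c, t.d]]))
        assert r.ror == pytest.approx(sm.oddsratio, rel=1e-12)
        lo, hi = sm.oddsratio_confint(0.05)
        assert r.ci_low == pytest.approx(lo, rel=1e-9)
        assert r.ci_high == pytest.approx(hi, rel=1e-9)


def _brute_force(flags):
    """Independent oracle: scan per-report flags and evaluate the formula."""
    a = sum(1 for drug, event in flags if drug and event)
    b = sum(1 for drug, event in flags if drug and not event)
    c = sum(1 for drug, event in flags if not drug and event)
    d = sum(1 for drug, event in flags if not drug and not event)
    if min(a, b, c, d) == 0:
        return (a, None, None, None)
    ror = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(ror) - 1.959963984540054 * se)
    hi = math.exp(math.log(ror) + 1.959963984540054 * se)
    return (a, ror, lo, hi)


def test_oracle_equivalence_on_random_small_databases():
    """500 random databases: set-based pipeline == per-report brute force."""
    rng = np.random.default_rng(20240917)
    for _ in range(500):
        n = int(rng.integers(4, 201))
        flags = list(zip(rng.random(n) < rng.uniform(0.05, 0.6),
                         rng.random(n) < rng.uniform(0.05, 0.6)))
        ids = [str(i) for i in range(n)]
        target = {i for i, (dr, _) in zip(ids, flags) if dr}
        cases = {i for i, (_, ev) in zip(ids, flags) if ev}
        r = ror_signal(build_contingency(target, cases, set(ids)))
        a, ror, lo, hi = _brute_force(flags)
        assert r.n_reports == a
        if ror is None:
            assert r.ror is None
        else:
            assert r.ror == pytest.approx(ror, rel=1e-12)
            assert r.ci_low == pytest.approx(lo, rel=1e-12)
            assert r.ci_high == pytest.approx(hi, rel=1e-12)


@given(st.data())
def test_swapping_drug_and_event_roles_leaves_ror_unchanged(data):
    n = data.draw(st.integers(10, 60))
    ids = [str(i) for i in range(n)]
    target = set(data.draw(st.sets(st.sampled_from(ids))))
    cases = set(data.draw(st.sets(st.sampled_from(ids))))
    r1 = ror_signal(build_contingency(target, cases, set(ids)))
    r2 = ror_signal(build_contingency(cases, target, set(ids)))
    if r1.ror is None:
        assert r2.ror is None
    else:
        assert r1.ror == pytest.approx(r2.ror, rel=1e-12)


def test_marginal_conservation_across_entities():
    ids = {str(i) for i in range(50)}
    cases = {str(i) for i in range(5)}
    model = DisproportionalityModel(
        cases, ids, {"x": {"1", "7"}, "y": {"2", "30", "31"}, "z": set()}
    )
    for r in model.fit():
        assert r.table.n == 50


class TestClassSignal:
    atc = AtcMap({"a": {"L01"}, "b": {"L01"}, "c": {"A10"}})

    def _recs(self, pairs):
        return [DrugRecord(pid, "1", "PS", ing, ing) for pid, ing in pairs]

    def test_two_same_class_drugs_on_one_report_count_once(self):
        recs = self._recs([("1", "a"), ("1", "b"), ("2", "c")])
        all_ids = {"1", "2", "3", "4"}
        r = class_signal("L01", self.atc, recs, {"1"}, all_ids)
        assert r.table.a + r.table.b == 1  # one distinct exposed report

    def test_class_with_no_mapped_drugs_is_empty_and_silent(self):
        r = class_signal("J01", self.atc, self._recs([("1", "a")]), {"1"}, {"1", "2"})
        assert r.table.a == 0 and not r.is_signal

    def test_single_drug_class_reduces_to_the_drug_ror(self):
        pairs = [(str(i), "c") for i in range(6)] + [(str(i + 6), "a") for i in range(4)]
        recs = self._recs(pairs)
        all_ids = {str(i) for i in range(30)}
        cases = {str(i) for i in range(0, 30, 3)}
        target_c = {pid for pid, ing in pairs if ing == "c"}
        direct = ror_signal(build_contingency(target_c, cases, all_ids))
        via_class = class_signal("A10", self.atc, recs, cases, all_ids)
        assert via_class.ror == pytest.approx(direct.ror)


def test_summary_mentions_database_and_signal_counts():
    ids = {str(i) for i in range(40)}
    model = DisproportionalityModel({"1", "2"}, ids, {"x": {"1", "2", "3"}})
    text = model.fit().summary()
    assert "N = 40" in text and "entities = 1" in text
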