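"""Cleaning and CPUE bookkeeping: financial years, length filters,
unknown-gear allocation, CPUE grids and initial-CPUE windows."""

import datetime

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sharkcpue.errors import ConfigError, DataError
from sharkcpue.records import (
    REASON_ABOVE_MAX, REASON_BELOW_MIN, allocate_unknown_gear,
    assign_financial_year, assign_financial_years, compute_cpue,
    count_catches, filter_lengths, initial_cpue, installation_years,
)


class TestFinancialYear:
    @pytest.mark.parametrize("date,expected", [
        ("1962-07-01", 1962),   # first day of the July--June year
        ("1963-06-30", 1962),   # last day still belongs to 1962
        ("1963-07-01", 1963),
        ("2000-01-15", 1999),
        ("2000-12-31", 2000),
    ])
    def test_july_june_rule(self, date, expected):
        assert assign_financial_year(date) == expected

    @given(st.dates(min_value=datetime.date(1900, 1, 1),
                    max_value=datetime.date(2100, 12, 31)))
    @settings(max_examples=200, deadline=None)
    def test_partition(self, date):
        """Every date maps to exactly one label, and the date lies inside
        that label's July--June window."""
        fy = assign_financial_year(date)
        start = datetime.date(fy, 7, 1)
        end = datetime.date(fy + 1, 6, 30)
        assert start <= date <= end

    def test_vectorized_matches_scalar(self):
        dates = pd.Series(["1962-07-01", "1963-06-30", "1999-12-31"])
        assert list(assign_financial_years(dates)) == \
            [assign_financial_year(d) for d in dates]


def _records(rows):
    return pd.DataFrame(rows, columns=["date", "region", "site", "gear",
                                       "group", "species", "total_length_cm",
                                       "sex", "financial_year"])


TL_MAX = {"hammerhead": 610.0, "scalloped_hammerhead": 430.0,
          "tiger": 550.0, "whaler": 360.0}


class TestFilterLengths:
    def test_species_bound_excludes(self):
        rec = _records([
            ("1997-01-01", "a", "s1", "net", "hammerhead",
             "scalloped_hammerhead", 450.0, "F", 1996),
            ("1997-01-01", "a", "s1", "net", "tiger", "", 215.0, "M", 1996),
        ])
        kept, log = filter_lengths(rec, TL_MAX)
        assert len(kept) == 1 and kept.iloc[0]["group"] == "tiger"
        assert log.iloc[0]["reason"] == REASON_ABOVE_MAX
        assert log.iloc[0]["bound"] == 430.0

    def test_group_bound_when_species_missing(self):
        # 450 cm passes the family-level bound (610) used pre-species era
        rec = _records([
            ("1970-01-01", "a", "s1", "net", "hammerhead", "", 450.0,
             "F", 1969),
        ])
        kept, log = filter_lengths(rec, TL_MAX)
        assert len(kept) == 1 and len(log) == 0

    def test_minimum_length_rule(self):
        # a "5" is a suspected feet entry, excluded below the 30 cm floor
        rec = _records([
            ("1970-01-01", "a", "s1", "net", "tiger", "", 5.0, "F", 1969),
        ])
        kept, log = filter_lengths(rec, TL_MAX, min_tl=30.0)
        assert len(kept) == 0
        assert log.iloc[0]["reason"] == REASON_BELOW_MIN

    def test_missing_length_kept(self):
        rec = _records([
            ("1970-01-01", "a", "s1", "net", "tiger", "", np.nan, "F", 1969),
        ])
        kept, log = filter_lengths(rec, TL_MAX)
        assert len(kept) == 1 and len(log) == 0

    def test_unknown_group_raises(self):
        rec = _records([
            ("1970-01-01", "a", "s1", "net", "sawfish", "", 300.0, "F", 1969),
        ])
        with pytest.raises(ConfigError, match="sawfish"):
            filter_lengths(rec, TL_MAX)

    def test_idempotent_on_clean_data(self, small_program):
        from sharkcpue.size_maturity import DEFAULT_TL_MAX
        catch, _ = small_program
        kept, log = filter_lengths(catch, DEFAULT_TL_MAX)
        kept2, log2 = filter_lengths(kept, DEFAULT_TL_MAX)
        assert len(log2) == 0
        pd.testing.assert_frame_equal(kept.reset_index(drop=True),
                                      kept2.reset_index(drop=True))


class TestAllocateUnknownGear:
    def _cell(self, n_net, n_drum, n_unknown):
        rows = []
        for i in range(n_net):
            rows.append((f"1970-01-{i % 28 + 1:02d}", "a", "s1", "net",
                         "tiger", "", 200.0, "F", 1969))
        for i in range(n_drum):
            rows.append((f"1970-02-{i % 28 + 1:02d}", "a", "s1", "drumline",
                         "tiger", "", 200.0, "F", 1969))
        for i in range(n_unknown):
            rows.append((f"1970-03-{i % 28 + 1:02d}", "a", "s1", "unknown",
                         "tiger", "", 200.0, "F", 1969))
        return _records(rows)

    def test_deterministic_proportional_split(self):
        out = allocate_unknown_gear(self._cell(30, 10, 4),
                                    mode="deterministic")
        assert (out["gear"] == "unknown").sum() == 0
        assert (out["gear"] == "net").sum() == 33
        assert (out["gear"] == "drumline").sum() == 11

    def test_noop_without_unknowns(self):
        rec = self._cell(3, 2, 0)
        out = allocate_unknown_gear(rec)
        pd.testing.assert_frame_equal(out, rec)

    def test_error_without_known_catch(self):
        with pytest.raises(DataError, match="tiger"):
            allocate_unknown_gear(self._cell(0, 0, 2))

    def test_conserves_totals_per_cell(self, small_program):
        catch, _ = small_program
        out = allocate_unknown_gear(catch, mode="deterministic")
        assert (out["gear"] == "unknown").sum() == 0
        before = catch.groupby(["group", "region"]).size()
        after = out.groupby(["group", "region"]).size()
        pd.testing.assert_series_equal(before, after)

    def test_stochastic_mean_matches_binomial(self):
        """net=1, drum=1 known, 101 unknowns: over many seeds the mean
        number assigned to net is the binomial mean 50.5 (3 SE check)."""
        rec = self._cell(1, 1, 101)
        n_seeds = 1000
        totals = np.empty(n_seeds)
        for s in range(n_seeds):
            out = allocate_unknown_gear(rec, mode="stochastic", seed=s)
            totals[s] = (out["gear"] == "net").sum() - 1  # minus known net
        se = np.sqrt(101 * 0.25 / n_seeds)
        assert abs(totals.mean() - 50.5) < 3 * se


class TestCPUE:
    def _effort(self, rows):
        return pd.DataFrame(rows, columns=["region", "site", "financial_year",
                                           "gear", "effort"])

    def test_division(self):
        counts = pd.DataFrame([("a", "s1", 1970, "net", "tiger", 19)],
                              columns=["region", "site", "financial_year",
                                       "gear", "group", "catch"])
        effort = self._effort([("a", "s1", 1970, "net", 2.0)])
        grid = compute_cpue(counts, effort)
        assert grid.iloc[0]["cpue"] == pytest.approx(9.5)

    def test_zero_catch_cells_present(self):
        counts = pd.DataFrame([("a", "s1", 1970, "net", "tiger", 3)],
                              columns=["region", "site", "financial_year",
                                       "gear", "group", "catch"])
        effort = self._effort([("a", "s1", 1970, "net", 5.0),
                               ("a", "s1", 1971, "net", 5.0)])
        grid = compute_cpue(counts, effort)
        zero = grid[grid["financial_year"] == 1971]
        assert len(zero) == 1 and zero.iloc[0]["cpue"] == 0.0

    def test_catch_without_effort_raises(self):
        counts = pd.DataFrame([("a", "s1", 1970, "net", "tiger", 3)],
                              columns=["region", "site", "financial_year",
                                       "gear", "group", "catch"])
        effort = self._effort([("a", "s1", 1970, "net", 0.0)])
        with pytest.raises(DataError, match="s1"):
            compute_cpue(counts, effort)

    def test_total_catch_conserved(self, small_program):
        catch, effort = small_program
        allocated = allocate_unknown_gear(catch)
        grid = compute_cpue(count_catches(allocated), effort)
        assert grid["catch"].sum() == len(allocated)


class TestInitialCPUE:
    def _series(self, cpue_by_year, effort=1.0):
        rows = [("a", "s1", "net", "tiger", yr, c * effort, effort, c)
                for yr, c in cpue_by_year.items()]
        return pd.DataFrame(rows, columns=["region", "site", "gear", "group",
                                           "financial_year", "catch",
                                           "effort", "cpue"])

    def test_five_year_mean(self):
        series = self._series({1970 + i: c
                               for i, c in enumerate([10, 8, 6, 4, 2, 99])})
        out = initial_cpue(series, {"s1": 1970})
        assert out.iloc[0]["initial_cpue"] == pytest.approx(6.0)
        assert not out.iloc[0]["short_window"]

    def test_constant_identity(self):
        series = self._series({1970 + i: 3.5 for i in range(7)})
        out = initial_cpue(series, {"s1": 1970})
        assert out.iloc[0]["initial_cpue"] == pytest.approx(3.5)

    def test_truncated_window_flagged(self):
        series = self._series({1970: 3, 1971: 3, 1972: 6})
        out = initial_cpue(series, {"s1": 1970})
        assert out.iloc[0]["initial_cpue"] == pytest.approx(4.0)
        assert out.iloc[0]["short_window"]
        assert out.iloc[0]["n_years"] == 3

    def test_absent_site_raises(self):
        series = self._series({1970: 3})
        with pytest.raises(DataError, match="s1"):
            initial_cpue(series, {"other": 1970})

    def test_installation_years_from_effort(self, small_program):
        _, effort = small_program
        inst = installation_years(effort)
        assert set(inst.columns) == {"region", "site", "gear", "installed"}
        # installation year equals the earliest effort row per site x gear
        one = inst.iloc[0]
        sub = effort[(effort["site"] == one["site"])
                     & (effort["gear"] == one["gear"])]
        assert one["installed"] == sub["financial_year"].min()
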