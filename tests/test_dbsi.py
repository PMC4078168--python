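"""Deer-browsing susceptibility index and its rarity filter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers import make_panel, paired_plots
from phylobrowse import dbsi_per_year, mean_dbsi, rarity_filter


def panel_with(entries, n_sites=4):
    return make_panel(entries, paired_plots(n_sites))


class TestDbsiPerYear:
    def test_exclosure_only_species_scores_one(self):
        panel = panel_with(
            [("s1_ex", 2006, "hemlock", 5.0), ("s2_ex", 2006, "hemlock", 3.0)]
        )
        assert dbsi_per_year(panel, "hemlock", 2006) == 1.0

    def test_control_only_species_scores_zero(self):
        panel = panel_with([("s1_co", 2006, "grass", 4.0)])
        assert dbsi_per_year(panel, "grass", 2006) == 0.0

    def test_equal_cover_scores_half(self):
        panel = panel_with(
            [("s1_ex", 2006, "fern", 2.5), ("s1_co", 2006, "fern", 2.5)]
        )
        assert dbsi_per_year(panel, "fern", 2006) == 0.5

    def test_three_to_one_scores_three_quarters(self):
        panel = panel_with(
            [("s1_ex", 2006, "fern", 3.0), ("s1_co", 2006, "fern", 1.0)]
        )
        assert dbsi_per_year(panel, "fern", 2006) == 0.75

    def test_absent_from_both_treatments_is_undefined(self):
        # fern has cover only in 2006, so 2008 is the 0/0 case for it
        panel = panel_with([("s1_ex", 2006, "fern", 3.0), ("s1_ex", 2008, "oak", 1.0)])
        assert np.isnan(dbsi_per_year(panel, "fern", 2008))

    def test_scale_invariance_within_a_year(self):
        entries = [
            ("s1_ex", 2006, "fern", 3.0),
            ("s2_ex", 2006, "fern", 1.0),
            ("s1_co", 2006, "fern", 2.0),
        ]
        base = dbsi_per_year(panel_with(entries), "fern", 2006)
        scaled = [(p, y, s, c * 7.5) for p, y, s, c in entries]
        assert dbsi_per_year(panel_with(scaled), "fern", 2006) == pytest.approx(base)

    @settings(derandomize=True, max_examples=50)
    @given(
        # line-intercept cover is quantised to 1 cm of 1500, so positive
        # covers are bounded away from zero
        ce=st.one_of(st.just(0.0), st.floats(min_value=100 / 1500, max_value=100.0)),
        cc=st.one_of(st.just(0.0), st.floats(min_value=100 / 1500, max_value=100.0)),
    )
    def test_bounds_and_endpoint_conditions(self, ce, cc):
        entries = []
        if ce > 0:
            entries.append(("s1_ex", 2006, "fern", ce))
        if cc > 0:
            entries.append(("s1_co", 2006, "fern", cc))
        if not entries:
            return
        d = dbsi_per_year(panel_with(entries), "fern", 2006)
        assert 0.0 <= d <= 1.0
        assert (d == 1.0) == (cc == 0.0)
        assert (d == 0.0) == (ce == 0.0)

    def test_complement_symmetry_under_treatment_swap(self):
        rng = np.random.default_rng(21)
        entries = []
        for plot, _, _ in paired_plots(4):
            for year in (2006, 2008):
                for sp in ("fern", "grass", "oak"):
                    c = float(rng.random() * 10)
                    if c > 2:
                        entries.append((plot, year, sp, c))
        panel = panel_with(entries)
        swapped = panel.with_swapped_treatments()
        for sp in ("fern", "grass", "oak"):
            for year in (2006, 2008):
                d = dbsi_per_year(panel, sp, year)
                ds = dbsi_per_year(swapped, sp, year)
                if np.isnan(d):
                    assert np.isnan(ds)
                else:
                    assert ds == pytest.approx(1.0 - d)


class TestRarityFilter:
    def test_three_plots_in_two_years_included(self):
        entries = [
            (p, y, "fern", 1.0)
            for y in (2006, 2008)
            for p in ("s1_ex", "s2_ex", "s3_ex")
        ]
        assert "fern" in rarity_filter(panel_with(entries))

    def test_single_plot_every_year_excluded(self):
        entries = [("s1_ex", y, "fern", 1.0) for y in (2006, 2008, 2009, 2010)]
        assert "fern" not in rarity_filter(panel_with(entries))

    def test_two_plots_single_year_excluded(self):
        entries = [("s1_ex", 2006, "fern", 1.0), ("s2_co", 2006, "fern", 1.0)]
        assert "fern" not in rarity_filter(panel_with(entries))

    def test_treatment_restriction_supports_exclosure_only_reading(self):
        entries = [
            (p, y, "fern", 1.0) for y in (2006, 2008) for p in ("s1_ex", "s2_co")
        ]
        panel = panel_with(entries)
        assert "fern" in rarity_filter(panel)  # either-treatment reading
        assert "fern" not in rarity_filter(panel, treatments=["exclosure"])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_direct_recount_oracle(self, seed):
        rng = np.random.default_rng(seed)
        entries = []
        for plot, _, _ in paired_plots(4):
            for year in (2006, 2008, 2009):
                for sp in ("a", "b", "c", "d"):
                    if rng.random() < 0.35:
                        entries.append((plot, year, sp, float(rng.random() * 5 + 0.1)))
        if not entries:
            return
        panel = panel_with(entries)
        included = rarity_filter(panel, plot_threshold=2, year_threshold=2)
        for sp in "abcd":
            per_year = {}
            for p, y, s, c in entries:
                if s == sp and c > 0:
                    per_year.setdefault(y, set()).add(p)
            good_years = sum(1 for plots in per_year.values() if len(plots) >= 2)
            assert (sp in included) == (good_years >= 2)


class TestMeanDbsi:
    def test_constant_and_averaged_years(self):
        entries = [
            # hemlock: exclosure-only in all three years -> mean 1.0
            *[("s1_ex", y, "hemlock", 2.0) for y in (2006, 2008, 2009)],
            *[("s2_ex", y, "hemlock", 2.0) for y in (2006, 2008, 2009)],
            # fern: 0.2 in 2006 (1:4), 0.6 in 2008 (3:2) -> mean 0.4
            ("s1_ex", 2006, "fern", 1.0),
            ("s1_co", 2006, "fern", 4.0),
            ("s1_ex", 2008, "fern", 3.0),
            ("s1_co", 2008, "fern", 2.0),
        ]
        table = mean_dbsi(panel_with(entries)).set_index("species")
        assert table.loc["hemlock", "mean_dbsi"] == 1.0
        assert table.loc["hemlock", "n_years_defined"] == 3
        assert table.loc["fern", "mean_dbsi"] == pytest.approx(0.4)
        assert np.isnan(table.loc["fern", "dbsi_2009"])

    def test_sorted_ascending_least_to_most_susceptible(self):
        entries = [
            ("s1_co", 2006, "grass", 5.0),
            ("s1_ex", 2006, "hemlock", 5.0),
            ("s1_ex", 2006, "fern", 1.0),
            ("s1_co", 2006, "fern", 1.0),
        ]
        table = mean_dbsi(panel_with(entries))
        assert table["species"].tolist() == ["grass", "fern", "hemlock"]
        assert table["mean_dbsi"].is_monotonic_increasing

    def test_included_flag_reflects_rarity_filter(self):
        entries = [
            *[
                (p, y, "common", 1.0)
                for y in (2006, 2008)
                for p in ("s1_ex", "s2_ex", "s3_co")
            ],
            ("s1_ex", 2006, "rare", 1.0),
        ]
        table = mean_dbsi(panel_with(entries)).set_index("species")
        assert bool(table.loc["common", "included"])
        assert not bool(table.loc["rare", "included"])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_raw_sum_recomputation(self, seed):
        rng = np.random.default_rng(seed + 50)
        entries = []
        for plot, _, treat in paired_plots(4):
            for year in (2006, 2008, 2009):
                for sp in ("a", "b", "c"):
                    if rng.random() < 0.5:
                        entries.append((plot, year, sp, float(rng.random() * 8 + 0.1)))
        panel = panel_with(entries)
        table = mean_dbsi(panel).set_index("species")
        ex_plots = {p for p, _, t in paired_plots(4) if t == "exclosure"}
        for sp in table.index:
            vals = []
            for year in (2006, 2008, 2009):
                ce = sum(c for p, y, s, c in entries if s == sp and y == year and p in ex_plots)
                cc = sum(c for p, y, s, c in entries if s == sp and y == year and p not in ex_plots)
                if ce + cc > 0:
                    vals.append(ce / (ce + cc))
            assert table.loc[sp, "mean_dbsi"] == pytest.approx(float(np.mean(vals)))
            assert table.loc[sp, "n_years_defined"] == len(vals)
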