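import numpy as np
import pandas as pd
import pytest

from helixscan.library import (
    LibraryTable,
    aggregate_potency,
    correlate_lipophilicity,
    fold_change_vs_parent,
    lint_ratios,
    normalize_stability,
    recompute_ratio,
    scan_summary,
    series_helicity_summary,
)
from helixscan.simulate import GeneratorConfig, gen_library


class TestHelicitySummary:
    def test_ala_scan_series_matches_printed_range(self, library_table):
        mean, lo, hi, n = series_helicity_summary(library_table, "table1A")
        assert (lo, hi) == (27.6, 53.3)
        assert n == 9  # two ND rows excluded
        assert mean == pytest.approx(40.8, abs=0.05)

    def test_single_row_series(self):
        t = LibraryTable.from_records(
            [dict(name="x", series="s", notation="Ac-A-amide", helicity_pct=30.0,
                  ec50_uM=1.0, ec50_censored=False, kd_nM=10.0, parent_name="")]
        )
        assert series_helicity_summary(t, "s") == (30.0, 30.0, 30.0, 1)

    def test_empty_series_rejected(self, library_table):
        with pytest.raises(ValueError):
            series_helicity_summary(library_table, "nope")


class TestFoldChange:
    def test_hot_spot_knockouts(self, library_table):
        assert fold_change_vs_parent(library_table, "F3A") == pytest.approx(3600 / 18.6)
        assert fold_change_vs_parent(library_table, "Cba10A") == pytest.approx(176 / 18.6)
        # the alanine hot-spot scan loses 10- to 100-fold and beyond
        assert fold_change_vs_parent(library_table, "W7A") > 100

    def test_parent_vs_itself_is_one(self, library_table):
        assert fold_change_vs_parent(library_table, "MP-292", parent="MP-292") == 1.0

    def test_missing_kd_gives_nan(self):
        t = LibraryTable.from_records(
            [dict(name="p", series="s", notation="Ac-A-amide", helicity_pct=30.0,
                  ec50_uM=1.0, ec50_censored=False, kd_nM=10.0, parent_name=""),
             dict(name="c", series="s", notation="Ac-A-amide", helicity_pct=30.0,
                  ec50_uM=1.0, ec50_censored=False, kd_nM=np.nan, parent_name="p")]
        )
        assert np.isnan(fold_change_vs_parent(t, "c"))


class TestAggregation:
    def test_geometric_for_potencies(self):
        assert aggregate_potency([10, 1000], "binding") == pytest.approx(100.0)
        assert aggregate_potency([30, 30, 30], "cellular") == pytest.approx(30.0)

    def test_arithmetic_for_helicity(self):
        assert aggregate_potency([20, 40, 60], "helicity") == pytest.approx(40.0)

    def test_nonpositive_under_geometric_rejected(self):
        with pytest.raises(ValueError):
            aggregate_potency([10, 0], "binding")


class TestStability:
    def test_flat_timecourse(self):
        tc = normalize_stability([0, 1, 2, 4, 22], [500.0] * 5)
        assert tc.remaining_pct == pytest.approx([100.0] * 5)

    def test_half_life(self):
        tc = normalize_stability([0.0, 22.0], [800.0, 400.0])
        assert tc.remaining_pct[1] == pytest.approx(50.0)

    def test_missing_t0_rejected(self):
        with pytest.raises(ValueError, match="t=0"):
            normalize_stability([1, 2], [10.0, 5.0])


class TestRatioLint:
    def test_audited_rows_match(self, library_table):
        for name, expected in [
            ("MP-292", "29"), ("F3A", "10"), ("S12(D-Ser)", "140"),
            ("Linear Parent (MP-189)", "777"), ("W6(D-Trp) (MP-384)", "20"),
            ("Q8(D-Gln)", "95"), ("L1G, E5G, A8G", "34"), ("F3(D-Phe)", ">8"),
        ]:
            assert str(recompute_ratio(library_table, name)) == expected

    def test_known_discrepant_rows_flagged_not_forced(self, library_table):
        lint = lint_ratios(library_table).set_index("name")
        assert not lint.loc["Cba10A", "match"]  # printed 61, recomputed 63
        assert lint.loc["Cba10A", "ratio_recomputed"] == "63"
        assert lint.loc["MP-292", "match"]
        # the fixture keeps the printed value untouched
        assert library_table.row("Cba10A")["ratio_printed"] == "61"

    def test_lint_covers_all_complete_rows(self, library_table):
        assert len(lint_ratios(library_table)) == 50


class TestCorrelation:
    def _table(self, x, y_ratio):
        recs = [dict(name=f"p{i}", series="s", notation="Ac-A-amide",
                     helicity_pct=40.0, ec50_uM=r * 10.0 / 1000.0, ec50_censored=False,
                     kd_nM=10.0, logd=xi, alogp=xi, parent_name="")
                for i, (xi, r) in enumerate(zip(x, y_ratio))]
        return LibraryTable.from_records(recs)

    def test_exact_line_gives_r2_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t = self._table(x, 10 ** (2 * x + 1))
        res = correlate_lipophilicity(t, x="logd", y_transform="log10_ratio")
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_constant_response_degenerate(self):
        t = self._table(np.array([1.0, 2.0, 3.0]), np.array([10.0, 10.0, 10.0]))
        res = correlate_lipophilicity(t)
        assert res.degenerate and res.r_squared == 0.0

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 4, 12)
        ratio = 10 ** (1.5 - 0.4 * x + rng.normal(0, 0.2, 12))
        t = self._table(x, ratio)
        shuffled = LibraryTable(t.df.sample(frac=1, random_state=1))
        a = correlate_lipophilicity(t)
        b = correlate_lipophilicity(shuffled)
        assert a.r_squared == pytest.approx(b.r_squared)

    def test_censored_rows_excluded_and_counted(self):
        t, _ = gen_library(n_peptides=30, cfg=GeneratorConfig(seed=5))
        n_censored = int(t.df["ec50_censored"].sum())
        res = correlate_lipophilicity(t)
        assert res.n_censored_excluded == n_censored
        assert res.n_points + n_censored == 30 + 1  # + uncensored synthetic parent

    def test_too_few_rows_rejected(self):
        t = self._table(np.array([1.0, 2.0]), np.array([5.0, 10.0]))
        with pytest.raises(ValueError, match="usable rows"):
            correlate_lipophilicity(t)


class TestTableValidation:
    def test_unknown_parent_rejected(self):
        with pytest.raises(ValueError, match="unknown rows"):
            LibraryTable.from_records(
                [dict(name="a", series="s", notation="Ac-A-amide", helicity_pct=1.0,
                      ec50_uM=1.0, ec50_censored=False, kd_nM=1.0, parent_name="ghost")]
            )

    def test_scan_summary_smoke(self, library_table):
        s = scan_summary(library_table, "table1A", "MP-292")
        assert s.helicity_min == 27.6 and s.helicity_max == 53.3
        assert s.fold_changes["F3A"] == pytest.approx(3600 / 18.6)
        assert s.n_censored_ec50 == 0
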