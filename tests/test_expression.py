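"""RPKM arithmetic, dual-threshold DEG calling, Venn consistency, mapping rates."""

import numpy as np
import pandas as pd
import pytest

from anagen.actest import ComparisonContext
from anagen.core import CountTable
from anagen.expression import (
    LibraryStats,
    call_degs,
    compute_rpkm,
    consistent_degs,
    deg_sets,
    mapping_summary,
)


def _table(rows: dict, totals: dict | None = None) -> CountTable:
    df = pd.DataFrame(rows).T
    df.columns = [f"lib{i + 1}" for i in range(df.shape[1])]
    df.index.name = "contig_id"
    t = pd.Series(totals) if totals else None
    return CountTable(df, totals=t)


class TestRpkm:
    def test_formula_arithmetic(self):
        table = _table({"c1": [1000, 1000]}, {"lib1": 10**6, "lib2": 10**6})
        rpkm = compute_rpkm(table, pd.Series({"c1": 1000}))
        assert rpkm.loc["c1", "lib1"] == pytest.approx(1000.0)

    def test_zero_count_zero_rpkm(self):
        table = _table({"c1": [0, 5]}, {"lib1": 10**6, "lib2": 10**6})
        rpkm = compute_rpkm(table, pd.Series({"c1": 500}))
        assert rpkm.loc["c1", "lib1"] == 0.0
        assert rpkm.loc["c1", "lib2"] > 0.0

    def test_doubling_depth_halves_rpkm(self):
        lengths = pd.Series({"c1": 750})
        a = compute_rpkm(_table({"c1": [300, 0]}, {"lib1": 10**6, "lib2": 10**6}), lengths)
        b = compute_rpkm(_table({"c1": [300, 0]}, {"lib1": 2 * 10**6, "lib2": 10**6}), lengths)
        assert b.loc["c1", "lib1"] == pytest.approx(a.loc["c1", "lib1"] / 2)

    def test_missing_or_zero_length_rejected(self):
        table = _table({"c1": [1, 2]})
        with pytest.raises(KeyError):
            compute_rpkm(table, pd.Series({"other": 100}))
        with pytest.raises(ValueError):
            compute_rpkm(table, pd.Series({"c1": 0}))


def _call(rows, totals, **kw):
    table = _table(rows, totals)
    lengths = pd.Series(1000, index=table.counts.index)
    rpkm = compute_rpkm(table, lengths)
    ctx = ComparisonContext(int(table.totals["lib1"]), int(table.totals["lib2"]))
    return call_degs(table, rpkm, ctx, "lib1", "lib2", **kw)


class TestCallDegs:
    def test_both_criteria_met_is_up(self):
        calls = _call({"a": [100, 900], "b": [100, 100]}, {"lib1": 10**6, "lib2": 10**6})
        assert bool(calls.loc["a", "significant"])
        assert calls.loc["a", "direction"] == "up"
        assert not bool(calls.loc["b", "significant"])

    def test_strong_q_but_weak_fold_not_significant(self):
        # 400 vs 600: q is far below 1e-3 but the stabilized ratio is ~1.5
        calls = _call({"a": [400, 600], "b": [5, 5]}, {"lib1": 10**6, "lib2": 10**6})
        assert calls.loc["a", "q_value"] < 1e-4
        assert not bool(calls.loc["a", "significant"])

    def test_exact_twofold_is_inclusive(self):
        # stabilized ratio (199+1)/(99+1) == 2.0 exactly at equal depths
        calls = _call({"a": [99, 199], "b": [100, 100]}, {"lib1": 10**6, "lib2": 10**6})
        assert calls.loc["a", "fold_change"] == pytest.approx(2.0)
        assert calls.loc["a", "q_value"] < 1e-3
        assert bool(calls.loc["a", "significant"])

    def test_all_contigs_reported(self):
        calls = _call({"a": [1, 2], "b": [0, 0], "c": [9, 9]},
                      {"lib1": 10**6, "lib2": 10**6})
        assert set(calls.index) == {"a", "b", "c"}
        assert set(calls.loc[~calls["significant"], "direction"]) == {"none"}

    def test_threshold_monotonicity(self, small_bundle):
        b = small_bundle
        rpkm = compute_rpkm(b.counts, b.lengths)
        ctx = ComparisonContext(
            int(b.counts.totals["BL"]), int(b.counts.totals["BK"]), "BL_vs_BK"
        )
        strict = call_degs(b.counts, rpkm, ctx, "BL", "BK", 1e-3, 2.0)
        looser_q = call_degs(b.counts, rpkm, ctx, "BL", "BK", 1e-2, 2.0)
        looser_fc = call_degs(b.counts, rpkm, ctx, "BL", "BK", 1e-3, 1.5)
        sig = set(strict.index[strict["significant"]])
        assert sig <= set(looser_q.index[looser_q["significant"]])
        assert sig <= set(looser_fc.index[looser_fc["significant"]])

    def test_swap_symmetry_maps_up_to_down(self, small_bundle):
        b = small_bundle
        rpkm = compute_rpkm(b.counts, b.lengths)
        n_bl, n_bk = int(b.counts.totals["BL"]), int(b.counts.totals["BK"])
        fwd = call_degs(b.counts, rpkm, ComparisonContext(n_bl, n_bk), "BL", "BK")
        rev = call_degs(b.counts, rpkm, ComparisonContext(n_bk, n_bl), "BK", "BL")
        up_f, down_f = deg_sets(fwd)
        up_r, down_r = deg_sets(rev)
        # fold changes invert exactly, so direction flips for shared calls;
        # the called set itself may differ by at most a few borderline contigs
        # because the inclusive-tail p-value is only asymptotically symmetric
        sym_diff = (up_f ^ down_r) | (down_f ^ up_r)
        assert len(sym_diff) <= max(2, 0.005 * len(fwd))
        np.testing.assert_allclose(
            rev["fold_change"].to_numpy(), 1.0 / fwd["fold_change"].to_numpy()
        )

    def test_bad_thresholds_rejected(self, small_bundle):
        b = small_bundle
        rpkm = compute_rpkm(b.counts, b.lengths)
        ctx = ComparisonContext(int(b.counts.totals["BL"]), int(b.counts.totals["BK"]))
        with pytest.raises(ValueError):
            call_degs(b.counts, rpkm, ctx, "BL", "BK", fc_threshold=0.5)


class TestConsistency:
    def test_set_intersection(self):
        venn = consistent_degs(({"a", "b", "c"}, set()), ({"b", "c", "d"}, set()))
        assert venn.consistent_up == {"b", "c"}
        assert venn.n_consistent_up == 2

    def test_disjoint_down_sets_empty(self):
        venn = consistent_degs((set(), {"a"}), (set(), {"b"}))
        assert venn.consistent_down == frozenset()
        assert venn.total_consistent == 0

    def test_study_scale_totals(self):
        """Consistent up/down counts of the study sizes total 6,333."""
        up_shared = {f"u{i}" for i in range(1360)}
        down_shared = {f"d{i}" for i in range(4973)}
        up_a = up_shared | {f"ua{i}" for i in range(3532 - 1360)}
        down_a = down_shared | {f"da{i}" for i in range(9927 - 4973)}
        up_b = up_shared | {f"ub{i}" for i in range(3128 - 1360)}
        down_b = down_shared | {f"db{i}" for i in range(6811 - 4973)}
        venn = consistent_degs((up_a, down_a), (up_b, down_b))
        assert venn.n_consistent_up == 1360
        assert venn.n_consistent_down == 4973
        assert venn.total_consistent == 6333

    def test_contradictory_directions_rejected(self):
        with pytest.raises(ValueError):
            consistent_degs(({"a"}, {"a"}), (set(), set()))


class TestMappingSummary:
    def test_study_library_rates(self):
        stats = [
            LibraryStats("BL", 41_232_601, 40_731_588, 35_593_595),
            LibraryStats("BK", 39_363_238, 38_876_298, 34_033_557),
            LibraryStats("BS", 49_962_602, 49_337_308, 42_383_188),
        ]
        rates = mapping_summary(stats)["mapped_pct_of_clean"]
        assert rates["BL"] == 87.4
        assert rates["BK"] == 87.5
        assert rates["BS"] == 85.9

    def test_full_mapping_is_hundred(self):
        rates = mapping_summary([LibraryStats("x", 10, 10, 10)])
        assert rates.loc["x", "mapped_pct_of_clean"] == 100.0

    def test_ordering_invariant_enforced(self):
        with pytest.raises(ValueError):
            LibraryStats("x", 10, 20, 5)
        with pytest.raises(ValueError):
            mapping_summary([LibraryStats("x", 10, 0, 0)])
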