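"""EHH decay, iHH integration, iHS/XP-EHH scans, windowed aggregation."""

import numpy as np
import pandas as pd
import pytest

from xautoscan import (ehh_curve, empirical_window_test, ihh, ihs_scan,
                       make_windows, regionize_scores, top_regions,
                       xpehh_scan)
from xautoscan.ehh import EHHCurve, hap_het_ratio
from xautoscan.panel import PanelError

from conftest import build_panel


def _panel_from_rows(rows, pos_bp=None, anc=0):
    rows = np.asarray(rows, dtype=np.int8)
    n = rows.shape[0]
    assert n % 2 == 0
    return build_panel(rows, ["p"] * (n // 2), ["female"] * (n // 2),
                       pos_bp=pos_bp, anc_state=anc)


class TestEHHCurve:
    def test_offset_zero_is_one_and_hand_enumeration(self):
        # 4 derived-core haplotypes extending as {B,B,C,D}: EHH = 2/(4*3)
        hap = [[1, 0, 0], [1, 0, 0], [1, 1, 0], [1, 0, 1],
               [0, 0, 0], [0, 1, 1]]
        panel = _panel_from_rows(hap)
        c = ehh_curve(panel, None, 0, "derived")
        assert c.n_core == 4
        assert c.right_ehh[0] == pytest.approx(0.5)     # groups {3,1}
        assert c.right_ehh[1] == pytest.approx(1 / 6)   # groups {2,1,1}

    def test_all_distinct_extensions_drop_to_zero(self):
        hap = [[1, 0, 0], [1, 1, 0], [0, 0, 1], [0, 1, 1]]
        panel = _panel_from_rows(hap)
        c = ehh_curve(panel, None, 0, "derived")
        assert c.right_ehh[0] == 0.0
        assert len(c.right_ehh) == 1  # stops once zero

    def test_curves_non_increasing(self, small_sim):
        panel = small_sim.x_panel.subset_population("pop1_1")
        for core in (50, 100, 150):
            c = ehh_curve(panel, None, core, "all")
            for arr in (c.left_ehh, c.right_ehh):
                assert (np.diff(np.concatenate([[1.0], arr])) <= 1e-12).all()

    def test_single_carrier_gives_no_curve(self):
        hap = [[1, 0], [0, 0], [0, 1], [0, 1]]
        panel = _panel_from_rows(hap)
        assert ehh_curve(panel, None, 0, "derived") is None


class TestIHH:
    def _curve(self, right_cm, right_ehh, reached_end=False):
        return EHHCurve(core_index=0, partition="all", n_core=4,
                        left_cm=np.array([0.1]), left_ehh=np.array([0.05]),
                        right_cm=np.asarray(right_cm, float),
                        right_ehh=np.asarray(right_ehh, float),
                        left_reached_end=False,
                        right_reached_end=reached_end)

    def test_trapezoid_arithmetic(self):
        # EHH 1 at 0.1 cM then 0.05 at 0.2 cM: side area 0.1 + 0.0525
        c = self._curve([0.1, 0.2], [1.0, 0.05])
        left = 0.5 * (1 + 0.05) * 0.1          # first-point crossing
        right = 0.1 + 0.5 * (1 + 0.05) * 0.1   # = 0.1525
        assert ihh(c, cutoff=0.1) == pytest.approx(left + right)

    def test_first_flank_below_cutoff_still_defined(self):
        c = self._curve([0.1], [0.05])
        assert ihh(c, cutoff=0.1) == pytest.approx(2 * 0.5 * 1.05 * 0.1)

    def test_absent_when_cutoff_never_reached_before_chromosome_end(self):
        c = self._curve([0.1, 0.2], [0.9, 0.8], reached_end=True)
        assert ihh(c, cutoff=0.1) is None


class TestIHSScan:
    def test_mirror_symmetric_decay_scores_zero(self):
        # derived and ancestral classes with identical haplotype decay:
        # columns are [l1, l2, core, r1, r2]; both classes carry the same
        # four distinct flanking patterns, so EHH hits 0 two markers out
        flanks = [[0, 0], [0, 1], [1, 0], [1, 1]]
        hap = np.array(
            [[f[0], f[1], 1, f[1], f[0]] for f in flanks]
            + [[f[0], f[1], 0, f[1], f[0]] for f in flanks], dtype=np.int8)
        panel = _panel_from_rows(
            hap, pos_bp=[0, 100_000, 200_000, 300_000, 400_000])
        df = ihs_scan(panel)
        core = df[df["marker"] == 2]
        assert len(core) == 1
        assert core["ihs"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_singleton_frequency_group_never_flagged(self, small_sim):
        df = ihs_scan(small_sim.x_panel.subset_population("pop1_1"))
        counts = df["derived_count"].value_counts()
        singletons = df[df["derived_count"].map(counts) == 1]
        assert not singletons["high"].any()

    def test_antisymmetry_under_allele_relabel(self, small_sim):
        panel = small_sim.x_panel.subset_population("pop1_1")
        df = ihs_scan(panel)
        flipped = panel.subset()
        flipped.markers["anc_state"] = 1 - flipped.markers["anc_state"]
        df2 = ihs_scan(flipped)
        merged = df.merge(df2, on="marker", suffixes=("_a", "_b"))
        assert len(merged) > 10
        assert np.allclose(merged["ihs_a"], -merged["ihs_b"], atol=1e-12)


class TestXPEHH:
    def test_identical_panels_score_zero(self, small_sim):
        panel = small_sim.x_panel.subset_population("pop1_1")
        df = xpehh_scan(panel, panel)
        assert len(df) > 0
        assert np.allclose(df["xpehh_raw"], 0.0)

    def test_swapping_panels_negates_raw_scores(self, small_sim):
        a = small_sim.x_panel.subset_population("pop1_1")
        b = small_sim.x_panel.subset_population("pop2_1")
        d1 = xpehh_scan(a, b)
        d2 = xpehh_scan(b, a)
        m = d1.merge(d2, on="marker", suffixes=("_ab", "_ba"))
        assert len(m) == len(d1)
        assert np.allclose(m["xpehh_raw_ab"], -m["xpehh_raw_ba"],
                           atol=1e-12)

    def test_standardised_scores_centred(self, small_sim):
        a = small_sim.x_panel.subset_population("pop1_1")
        b = small_sim.x_panel.subset_population("pop2_1")
        df = xpehh_scan(a, b)
        assert df["xpehh_std"].mean() == pytest.approx(0.0, abs=1e-10)
        assert df["xpehh_std"].std(ddof=0) == pytest.approx(1.0, abs=1e-10)


class TestRegionize:
    def test_ratio_mean_and_zero_fill_rules(self):
        grid = make_windows(0, 1_200_000, 400_000)
        scores = pd.DataFrame({
            "pos_bp": [10, 20, 30, 40, 50, 60, 70, 80, 410_000],
            "score": [1.0] * 8 + [3.0],
            "high": [True, True] + [False] * 7})
        r = regionize_scores(scores, grid, mode="ihs_ratio")
        assert r["score"].iloc[0] == pytest.approx(2 / 8)
        m = regionize_scores(scores, grid, mode="mean")
        assert np.isnan(m["score"].iloc[2])          # empty window missing
        z = regionize_scores(scores, grid, mode="mean_zero_fill")
        assert z["score"].iloc[2] == 0.0             # XP-EHH boundary rule
        assert z["n_snps_scored"].sum() == len(scores)

    @pytest.mark.parametrize("mode", ["mean", "ihs_ratio"])
    def test_matches_brute_force(self, mode):
        rng = np.random.default_rng(5)
        grid = make_windows(0, 2_000_000, 100_000)
        n = 200
        scores = pd.DataFrame({
            "pos_bp": rng.integers(0, 2_000_000, n),
            "score": rng.normal(size=n),
            "high": rng.random(n) < 0.3})
        r = regionize_scores(scores, grid, mode=mode)
        for w in range(grid.n_windows):
            sel = scores[(scores["pos_bp"] >= grid.starts[w])
                         & (scores["pos_bp"] < grid.ends[w])]
            if len(sel) == 0:
                assert np.isnan(r["score"].iloc[w])
                continue
            expect = (sel["high"].mean() if mode == "ihs_ratio"
                      else sel["score"].mean())
            assert r["score"].iloc[w] == pytest.approx(expect)
        assert r["n_snps_scored"].sum() == n


class TestTopRegions:
    def _scores(self, vals):
        grid = make_windows(0, len(vals) * 100, 100)
        return pd.DataFrame({"window": range(len(vals)),
                             "start": grid.starts, "end": grid.ends,
                             "score": vals,
                             "n_snps_scored": 1, "rank": np.nan})

    def test_ordering_and_k(self):
        top = top_regions(self._scores([0.5, 0.9, 0.1]), k=2)
        assert list(top["window"]) == [1, 0]

    def test_ties_broken_by_position(self):
        top = top_regions(self._scores([0.3, 0.3, 0.3, 0.3]), k=2)
        assert list(top["window"]) == [0, 1]

    def test_k_larger_than_scored_returns_all(self):
        vals = [0.1, np.nan, 0.2]
        top = top_regions(self._scores(vals), k=10)
        assert len(top) == 2


class TestEmpiricalWindowTest:
    def test_unique_maximum_is_elevated(self):
        scores = np.array([0.0] * 30 + [5.0, 5.0] + [0.0] * 30)
        pct, elevated = empirical_window_test(scores, 30, 2)
        assert pct == 1.0 and elevated

    def test_constant_track_not_elevated(self):
        pct, elevated = empirical_window_test(np.ones(40), 5, 3)
        assert pct == 0.0 and not elevated

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=50)
        k, start = 4, 17
        pct, _ = empirical_window_test(scores, start, k)
        means = [scores[i:i + k].mean() for i in range(50 - k + 1)]
        target = means.pop(start)
        assert pct == pytest.approx(np.mean([m < target for m in means]))

    def test_k_one_reduces_to_rank_percentile(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=30)
        i = 12
        pct, _ = empirical_window_test(scores, i, 1)
        others = np.delete(scores, i)
        assert pct == pytest.approx((others < scores[i]).mean())

    def test_interval_length_validated(self):
        with pytest.raises(PanelError):
            empirical_window_test(np.ones(5), 0, 5)


class TestHapHetRatio:
    def test_identical_populations_ratio_one(self, small_sim):
        a = small_sim.x_panel.subset_population("pop1_1")
        df = hap_het_ratio(a, a, window_snps=5)
        defined = df.dropna(subset=["ratio"])
        assert np.allclose(defined["ratio"], 1.0)

    def test_monomorphic_window_ratio_zero(self):
        hap_a = np.array([[0, 1, 0], [1, 0, 1], [0, 0, 1], [1, 1, 0]],
                         dtype=np.int8)
        hap_b = np.tile([0, 1, 0], (4, 1)).astype(np.int8)
        pa = _panel_from_rows(hap_a)
        pb = _panel_from_rows(hap_b)
        df = hap_het_ratio(pa, pb, window_snps=3)
        assert df["het_b"].iloc[0] == 0.0
        assert df["ratio"].iloc[0] == 0.0

    def test_equally_frequent_haplotypes_closed_form(self):
        # 4 distinct equally frequent window haplotypes: H = 1 - 1/4
        hap = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.int8)
        panel = _panel_from_rows(hap)
        df = hap_het_ratio(panel, panel, window_snps=2)
        assert df["het_a"].iloc[0] == pytest.approx(0.75)
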