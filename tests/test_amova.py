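"""AMOVA variance components against a brute-force nested ANOVA oracle."""

import numpy as np
import pytest

from xautoscan import (SimConfig, amova, bootstrap_ci,
                       make_pseudofemale_pairs, make_pseudofemales,
                       simulate_dataset)
from xautoscan.panel import PanelError

from conftest import build_panel


def brute_force_amova(units, pops, regs=None):
    """Independent nested sums-of-squares evaluation with explicit loops.

    ``units`` is a list of per-unit integer vectors; distances are squared
    pairwise mismatch counts. Returns variance components (not truncated).
    """
    units = [np.asarray(u) for u in units]
    n = len(units)
    pops = list(pops)
    regs = list(regs) if regs is not None else ["g"] * n

    def d2(i, j):
        return int((units[i] != units[j]).sum())

    def ssd(group_of):
        groups = {}
        for i in range(n):
            groups.setdefault(group_of(i), []).append(i)
        total = 0.0
        for members in groups.values():
            s = 0.0
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    s += d2(members[a], members[b])
            total += s / len(members)
        return total

    ssd_t = ssd(lambda i: 0)
    ssd_wp = ssd(lambda i: pops[i])
    pop_names = sorted(set(pops))
    reg_names = sorted(set(regs))
    n_pop, n_reg = len(pop_names), len(reg_names)
    sizes = {p: pops.count(p) for p in pop_names}

    if n_reg == 1:
        df_ap, df_wp = n_pop - 1, n - n_pop
        sigma_c = ssd_wp / df_wp
        n_prime = (n - sum(v ** 2 for v in sizes.values()) / n) / df_ap
        sigma_b = ((ssd_t - ssd_wp) / df_ap - sigma_c) / n_prime
        return sigma_c, sigma_b, None
    ssd_wg = ssd(lambda i: regs[i])
    df_ag, df_ap, df_wp = n_reg - 1, n_pop - n_reg, n - n_pop
    sigma_c = ssd_wp / df_wp
    reg_of_pop = {p: regs[pops.index(p)] for p in pop_names}
    reg_sizes = {r: regs.count(r) for r in reg_names}
    sq_by_reg = {r: sum(sizes[p] ** 2 for p in pop_names
                        if reg_of_pop[p] == r) / reg_sizes[r]
                 for r in reg_names}
    n1 = (n - sum(sq_by_reg.values())) / df_ap
    n2 = (sum(sq_by_reg.values())
          - sum(v ** 2 for v in sizes.values()) / n) / df_ag
    n3 = (n - sum(v ** 2 for v in reg_sizes.values()) / n) / df_ag
    sigma_b = ((ssd_wg - ssd_wp) / df_ap - sigma_c) / n1
    sigma_a = ((ssd_t - ssd_wg) / df_ag - sigma_c - n2 * sigma_b) / n3
    return sigma_c, sigma_b, sigma_a


def _pct(sigmas):
    vals = [max(s, 0.0) for s in sigmas if s is not None]
    tot = sum(vals)
    return [100 * v / tot for v in vals]


def test_identical_populations_have_zero_among_component():
    hap = np.array([[0, 1, 0, 1], [1, 0, 1, 0]] * 4, dtype=np.int8)
    panel = build_panel(hap, ["A", "A", "B", "B"], ["female"] * 4,
                        chrom="A1")
    res = amova(panel)
    assert res.among_pops == pytest.approx(0.0)
    assert res.within == pytest.approx(100.0)


def test_fixed_differences_put_all_variance_among_populations():
    hap = np.array([[0] * 5] * 4 + [[1] * 5] * 4, dtype=np.int8)
    panel = build_panel(hap, ["A", "A", "B", "B"], ["female"] * 4,
                        chrom="A1")
    res = amova(panel)
    assert res.within == pytest.approx(0.0)
    assert res.among_pops == pytest.approx(100.0)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_two_level_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    hap = rng.integers(0, 2, size=(12, 5)).astype(np.int8)
    pops = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
    panel = build_panel(hap, ["A", "A", "B", "B", "C", "C"],
                        ["female"] * 6, chrom="A1")
    res = amova(panel)
    # oracle works on the same polymorphic loci as the implementation
    poly = np.array([len(np.unique(hap[:, j])) > 1
                     for j in range(hap.shape[1])])
    sig = brute_force_amova(list(hap[:, poly]), pops)
    w, a = _pct(sig[:2])
    assert res.within == pytest.approx(w, abs=1e-9)
    assert res.among_pops == pytest.approx(a, abs=1e-9)


@pytest.mark.parametrize("seed", [3, 4])
def test_three_level_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    hap = rng.integers(0, 2, size=(12, 6)).astype(np.int8)
    pops = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
    regs = ["r1"] * 8 + ["r2"] * 4
    panel = build_panel(hap, ["A", "A", "B", "B", "C", "C"],
                        ["female"] * 6, chrom="A1",
                        regions=["r1", "r1", "r1", "r1", "r2", "r2"])
    res = amova(panel)
    poly = np.array([len(np.unique(hap[:, j])) > 1
                     for j in range(hap.shape[1])])
    sig = brute_force_amova(list(hap[:, poly]), pops, regs)
    w, b, a = _pct(sig)
    assert res.within == pytest.approx(w, abs=1e-9)
    assert res.among_pops == pytest.approx(b, abs=1e-9)
    assert res.among_regions == pytest.approx(a, abs=1e-9)


def test_diploid_matches_brute_force_on_dosages():
    rng = np.random.default_rng(9)
    hap = rng.integers(0, 2, size=(12, 5)).astype(np.int8)
    panel = build_panel(hap, ["A", "A", "B", "B", "C", "C"],
                        ["female"] * 6, chrom="A1")
    res = amova(panel, mode="diploid")
    dos = hap[0::2] + hap[1::2]
    poly = np.array([len(np.unique(dos[:, j])) > 1
                     for j in range(dos.shape[1])])
    sig = brute_force_amova(list(dos[:, poly]), ["A", "A", "B", "B", "C", "C"])
    w, a = _pct(sig[:2])
    assert res.within == pytest.approx(w, abs=1e-9)
    assert res.among_pops == pytest.approx(a, abs=1e-9)


class TestPseudofemales:
    def _male_panel(self, n_males, seed=0):
        rng = np.random.default_rng(seed)
        hap = rng.integers(0, 2, size=(n_males, 4)).astype(np.int8)
        return build_panel(hap, ["A"] * n_males, ["male"] * n_males)

    def test_pair_counts(self):
        assert len(make_pseudofemale_pairs(self._male_panel(10))) == 5
        assert len(make_pseudofemale_pairs(self._male_panel(7))) == 3
        assert len(make_pseudofemale_pairs(self._male_panel(1))) == 0

    def test_large_population_pairing(self):
        pairs = make_pseudofemale_pairs(self._male_panel(615))
        assert len(pairs) == 307  # one male left unused

    def test_seed_determinism_and_no_reuse(self):
        panel = self._male_panel(10)
        p1 = make_pseudofemale_pairs(panel, seed=4)
        p2 = make_pseudofemale_pairs(panel, seed=4)
        assert p1 == p2
        used = [r for pair in p1 for r in pair]
        assert len(used) == len(set(used))

    def test_panel_becomes_fully_diploid(self, small_sim):
        pf = make_pseudofemales(small_sim.x_panel, seed=1)
        assert (pf.ploidy() == 2).all()
        res = amova(pf, mode="diploid")   # smoke: usable downstream
        assert res.within + res.among_pops + (res.among_regions or 0) == \
            pytest.approx(100.0)


class TestBootstrap:
    def _panel(self, seed=0):
        rng = np.random.default_rng(seed)
        hap = (rng.random((8, 30)) < np.linspace(0.2, 0.8, 30)).astype(np.int8)
        return build_panel(hap, ["A", "A", "B", "B"], ["female"] * 4,
                           chrom="A1")

    def test_single_replicate_ci_is_degenerate(self):
        res = bootstrap_ci(self._panel(), B=1, seed=5)
        for lo, hi in res.ci95.values():
            assert lo == pytest.approx(hi)

    def test_seeded_reruns_identical(self):
        r1 = bootstrap_ci(self._panel(), B=200, seed=6)
        r2 = bootstrap_ci(self._panel(), B=200, seed=6)
        assert r1.ci95 == r2.ci95
        for k, (lo, hi) in r1.ci95.items():
            assert lo <= hi

    def test_constant_structure_gives_zero_width_ci(self):
        # every locus carries the identical fixed difference
        hap = np.array([[0] * 20] * 4 + [[1] * 20] * 4, dtype=np.int8)
        panel = build_panel(hap, ["A", "A", "B", "B"], ["female"] * 4,
                            chrom="A1")
        res = bootstrap_ci(panel, B=50, seed=7)
        lo, hi = res.ci95["among_pops"]
        assert lo == pytest.approx(100.0) and hi == pytest.approx(100.0)

    def test_monomorphic_panel_rejected(self):
        hap = np.zeros((8, 5), dtype=np.int8)
        panel = build_panel(hap, ["A", "A", "B", "B"], ["female"] * 4,
                            chrom="A1")
        with pytest.raises(PanelError, match="polymorphic"):
            bootstrap_ci(panel, B=10)


def test_label_permutation_shrinks_among_component(small_sim):
    panel = small_sim.x_panel.subset(marker_mask=np.arange(
        small_sim.x_panel.n_markers) < 120)
    observed = amova(panel, levels=2).among_pops
    rng = np.random.default_rng(11)
    pops = panel.row_population()
    perms = []
    for _ in range(20):
        # permute population labels at the sample level
        samp = panel.samples.copy()
        samp["population"] = rng.permutation(samp["population"].to_numpy())
        samp["region"] = "r"
        shuffled = panel.__class__(panel.haplotypes, panel.markers, samp,
                                   panel.row_sample, panel.row_copy)
        perms.append(amova(shuffled, levels=2).among_pops)
    assert np.mean(perms) < observed
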