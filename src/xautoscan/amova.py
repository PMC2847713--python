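"""Hierarchical analysis of molecular variance (AMOVA) with bootstrap CIs.

Nested Excoffier-Quattro-Smouse sums of squares on pairwise mismatch
distances partition the total molecular variance into within-population,
among-populations-within-regions, and among-regions components, each
reported as a percentage of the total. Haplotypic mode treats every
phased chromosome copy as a unit (so haploid male X chromosomes are used
directly); diploid mode treats individuals as units with genotype-dosage
mismatch distances, and 'pseudofemales' built by pairing random male X
haplotypes within populations let males enter a diploid X analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import (MISSING, SEX_FEMALE, SEX_MALE, HaplotypePanel, PanelError)

log = logging.getLogger(__name__)


@dataclass
class AmovaResult:
    """Variance components as percentages of the total (sum 100).

    ``among_regions`` is None for a 2-level (single-group) analysis.
    ``ci95`` maps component name -> (low, high) percentile bounds when a
    bootstrap was run.
    """

    within: float
    among_pops: float
    among_regions: float | None
    sigma2: dict[str, float]
    n_loci_used: int
    n_units: int
    mode: str
    ci95: dict[str, tuple[float, float]] | None = None


def _unit_matrix(panel: HaplotypePanel, mode: str
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Units x loci matrix plus population and region labels per unit."""
    if mode == "haplotypic":
        mat = panel.haplotypes
        pops = panel.row_population()
        regs = panel.row_region()
    elif mode == "diploid":
        ploidy = panel.ploidy()
        if (ploidy != 2).any():
            bad = list(ploidy[ploidy != 2].index[:3])
            raise PanelError(
                f"diploid AMOVA needs two copies per sample (pair male X "
                f"haplotypes into pseudofemales first); offending: {bad}")
        ids = panel.samples["sample_id"].to_numpy()
        idx = {s: [None, None] for s in ids}
        for r, (s, k) in enumerate(zip(panel.row_sample, panel.row_copy)):
            idx[s][int(k)] = r
        rows0 = np.array([idx[s][0] for s in ids])
        rows1 = np.array([idx[s][1] for s in ids])
        h = panel.haplotypes
        mat = np.where((h[rows0] == MISSING) | (h[rows1] == MISSING),
                       MISSING, h[rows0] + h[rows1])
        attr = panel.samples
        pops = attr["population"].to_numpy()
        regs = attr["region"].to_numpy()
    else:
        raise PanelError(f"unknown AMOVA mode {mode!r}")
    return np.asarray(mat), pops, regs


def _pair_mismatch_sums(mat: np.ndarray, groups: np.ndarray,
                        values: np.ndarray) -> dict:
    """Per-group sums over unit pairs of the mismatch-count distance.

    For units in a set S and one locus with value counts m_v,
    sum_{i<j in S} [v_i != v_j] = C(|S|,2) - sum_v C(m_v,2); summing over
    loci gives sum_{i<j} d2_ij without forming pairwise distances.
    """
    out = {}
    for g in np.unique(groups):
        rows = np.flatnonzero(groups == g)
        block = mat[rows]
        n = len(rows)
        total_pairs = n * (n - 1) / 2
        ss = 0.0
        for v in values:
            m = (block == v).sum(axis=0)
            ss += (m * (m - 1) / 2).sum()
        out[g] = (total_pairs * mat.shape[1] - ss, n)
    return out


def _ssd(mat: np.ndarray, values: np.ndarray,
         groups: np.ndarray | None = None) -> float:
    """SSD for a partition: sum over groups of (1/n_g) * pair-sum of d^2."""
    if groups is None:
        groups = np.zeros(len(mat), dtype=int)
    sums = _pair_mismatch_sums(mat, groups, values)
    return float(sum(s / n for s, n in sums.values()))


def polymorphic_mask(mat: np.ndarray) -> np.ndarray:
    """Loci with at least two observed values among the analysed units."""
    poly = np.zeros(mat.shape[1], dtype=bool)
    obs = mat != MISSING
    for j in range(mat.shape[1]):
        col = mat[obs[:, j], j]
        poly[j] = len(np.unique(col)) > 1
    return poly


def amova(panel: HaplotypePanel, mode: str = "haplotypic",
          levels: int | None = None,
          populations: list[str] | None = None) -> AmovaResult:
    """Nested AMOVA variance components for the panel's region/population
    hierarchy.

    Loci are first filtered to those polymorphic within the analysed group
    (and free of missing calls among its units). ``levels=2`` collapses
    regions and partitions variance within/among populations only;
    ``levels=3`` (the default when more than one region is present) adds
    the among-regions component. Negative variance components are
    truncated to zero before conversion to percentages.
    """
    mat, pops, regs = _unit_matrix(panel, mode)
    if populations is not None:
        keep = np.isin(pops, populations)
        mat, pops, regs = mat[keep], pops[keep], regs[keep]
    pop_names = np.unique(pops)
    if len(pop_names) < 2:
        raise PanelError("AMOVA needs at least two populations")
    if levels is None:
        levels = 3 if len(np.unique(regs)) > 1 else 2
    if levels == 2:
        regs = np.zeros(len(pops), dtype=int)

    complete = ~np.any(mat == MISSING, axis=0)
    poly = polymorphic_mask(mat) & complete
    n_loci = int(poly.sum())
    if n_loci == 0:
        raise PanelError("no polymorphic loci within the analysed group")
    mat = mat[:, poly]
    values = np.unique(mat)

    comp = _components(mat, pops, regs, values)
    return AmovaResult(**comp, n_loci_used=n_loci, n_units=len(mat),
                       mode=mode)


def _components(mat: np.ndarray, pops: np.ndarray, regs: np.ndarray,
                values: np.ndarray) -> dict:
    n = len(mat)
    pop_of = pd.Series(regs).groupby(pops).first()
    n_pop = len(pop_of)
    n_reg = len(np.unique(regs))
    three = n_reg > 1

    ssd_total = _ssd(mat, values)
    ssd_wp = _ssd(mat, values, pops)
    pop_sizes = pd.Series(pops).value_counts()

    if not three:
        df_ap, df_wp = n_pop - 1, n - n_pop
        ssd_ap = ssd_total - ssd_wp
        sigma_c = ssd_wp / df_wp
        n_prime = (n - (pop_sizes ** 2).sum() / n) / df_ap
        sigma_b = (ssd_ap / df_ap - sigma_c) / n_prime
        sigma_a = None
    else:
        ssd_wg = _ssd(mat, values, regs)          # within regions
        ssd_ap = ssd_wg - ssd_wp                  # among pops within regions
        ssd_ag = ssd_total - ssd_wg               # among regions
        df_ag, df_ap, df_wp = n_reg - 1, n_pop - n_reg, n - n_pop
        sigma_c = ssd_wp / df_wp
        reg_sizes = pd.Series(regs).value_counts()
        # sum over regions of (sum_p n_p^2) / N_g
        sq_by_reg = (pd.Series([pop_sizes[p] ** 2 for p in pop_of.index],
                               index=pop_of.values)
                     .groupby(level=0).sum() / reg_sizes)
        n1 = (n - sq_by_reg.sum()) / df_ap
        n2 = (sq_by_reg.sum() - (pop_sizes ** 2).sum() / n) / df_ag
        n3 = (n - (reg_sizes ** 2).sum() / n) / df_ag
        sigma_b = (ssd_ap / df_ap - sigma_c) / n1
        sigma_a = (ssd_ag / df_ag - sigma_c - n2 * sigma_b) / n3

    comps = {"within": sigma_c, "among_pops": sigma_b}
    if sigma_a is not None:
        comps["among_regions"] = sigma_a
    for k, v in comps.items():
        if v < 0:
            log.info("negative %s variance component (%.4g) truncated to 0",
                     k, v)
            comps[k] = 0.0
    total = sum(comps.values())
    pct = {k: 100.0 * v / total if total > 0 else 0.0
           for k, v in comps.items()}
    return {"within": pct["within"], "among_pops": pct["among_pops"],
            "among_regions": pct.get("among_regions"),
            "sigma2": comps}


def make_pseudofemale_pairs(panel: HaplotypePanel,
                            seed: int = 0) -> list[tuple[int, int]]:
    """Random within-population pairs of male X haplotype rows.

    Pairing is without replacement and fully seed-determined; each
    population yields floor(n_males/2) pairs with any leftover male unused
    (a population with fewer than two males yields none, logged).
    """
    rng = np.random.default_rng(seed)
    pairs: list[tuple[int, int]] = []
    for pop in panel.populations():
        rows = panel.hap_rows(population=pop, sex=SEX_MALE)
        if len(rows) < 2:
            log.info("population %s has %d male(s); no pseudofemales",
                     pop, len(rows))
            continue
        perm = rng.permutation(rows)
        for i in range(0, len(perm) - 1, 2):
            pairs.append((int(perm[i]), int(perm[i + 1])))
    return pairs


def make_pseudofemales(panel: HaplotypePanel, seed: int = 0) -> HaplotypePanel:
    """Diploid X panel of females plus pseudofemales.

    Each pseudofemale pairs two random male X haplotypes from the same
    population; leftover males are dropped.
    """
    pairs = make_pseudofemale_pairs(panel, seed=seed)
    female_rows = panel.hap_rows(sex=SEX_FEMALE)
    sample_attr = panel.samples.set_index("sample_id")

    hap_rows = [panel.haplotypes[female_rows]]
    row_sample = list(panel.row_sample[female_rows])
    row_copy = list(panel.row_copy[female_rows])
    new_samples = panel.samples[panel.samples["sex"] == SEX_FEMALE].copy()

    recs = []
    for k, (r0, r1) in enumerate(pairs):
        s0 = panel.row_sample[r0]
        pf_id = f"pf{k + 1}_{s0}"
        pop = sample_attr.loc[s0, "population"]
        reg = sample_attr.loc[s0, "region"]
        recs.append({"sample_id": pf_id, "sex": SEX_FEMALE,
                     "population": pop, "region": reg})
        hap_rows.append(panel.haplotypes[[r0, r1]])
        row_sample.extend([pf_id, pf_id])
        row_copy.extend([0, 1])
    if recs:
        new_samples = pd.concat([new_samples, pd.DataFrame(recs)],
                                ignore_index=True)
    hap = np.vstack(hap_rows)
    return HaplotypePanel(hap, panel.markers.copy(), new_samples,
                          np.array(row_sample, dtype=object),
                          np.array(row_copy, dtype=np.int8))


def bootstrap_ci(panel: HaplotypePanel, mode: str = "haplotypic",
                 B: int = 20000, seed: int = 0,
                 levels: int | None = None,
                 populations: list[str] | None = None,
                 resample: str = "loci") -> AmovaResult:
    """AMOVA with 95% percentile bootstrap confidence intervals.

    Resamples loci with replacement (``resample='units'`` resamples the
    analysed units instead) and reports the 2.5/97.5 percentiles of each
    component over ``B`` replicates.
    """
    if B < 1:
        raise PanelError("B must be >= 1")
    point = amova(panel, mode=mode, levels=levels, populations=populations)

    mat, pops, regs = _unit_matrix(panel, mode)
    if populations is not None:
        keep = np.isin(pops, populations)
        mat, pops, regs = mat[keep], pops[keep], regs[keep]
    if levels is None:
        levels = 3 if len(np.unique(regs)) > 1 else 2
    if levels == 2:
        regs = np.zeros(len(pops), dtype=int)
    complete = ~np.any(mat == MISSING, axis=0)
    poly = polymorphic_mask(mat) & complete
    if not poly.any():
        raise PanelError("no polymorphic loci within the analysed group")
    mat = mat[:, poly]
    values = np.unique(mat)

    rng = np.random.default_rng(seed)
    names = ["within", "among_pops"] + (
        ["among_regions"] if point.among_regions is not None else [])
    draws = {k: np.empty(B) for k in names}
    for b in range(B):
        if resample == "loci":
            idx = rng.integers(0, mat.shape[1], size=mat.shape[1])
            comp = _components(mat[:, idx], pops, regs, values)
        else:
            idx = rng.integers(0, len(mat), size=len(mat))
            comp = _components(mat[idx], pops[idx], regs[idx], values)
        for k in names:
            draws[k][b] = comp[k] if comp[k] is not None else np.nan
    ci = {k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
          for k, v in draws.items()}
    point.ci95 = ci
    return point
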