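"""Per-SNP differentiation scans: delta, pairwise Hudson Fst, high-delta calling.

delta is the absolute allele-frequency difference between two populations
at one SNP; SNPs whose value strictly exceeds a threshold (0.9, or 0.8 for
closely related pairs) are "high-delta" SNPs, and any fixed-width window
holding at least one of them is a high-delta region. Ancestral states come
from an outgroup (fixed outgroup allele = ancestral), and the module
summarises genic/derived/MAF composition of the high-delta set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import ANC_UNKNOWN, MISSING, HaplotypePanel, PanelError, RegionGrid

log = logging.getLogger(__name__)


@dataclass
class FreqTable:
    """Per-(marker, population) allele-1 frequencies and observed copy counts.

    ``p`` and ``n`` have shape (n_markers, n_pops); ``p`` is NaN where no
    non-missing copies were observed. Male X copies count once.
    """

    populations: list[str]
    p: np.ndarray
    n: np.ndarray
    markers: pd.DataFrame

    def freq(self, population: str) -> np.ndarray:
        return self.p[:, self.populations.index(population)]

    def count(self, population: str) -> np.ndarray:
        return self.n[:, self.populations.index(population)]

    def maf(self, population: str) -> np.ndarray:
        f = self.freq(population)
        return np.minimum(f, 1.0 - f)


def population_frequencies(panel: HaplotypePanel,
                           populations: list[str] | None = None) -> FreqTable:
    """Count allele-1 frequencies per population from the haplotype rows.

    p = (# allele-1 copies) / (# non-missing copies); on an X panel males
    contribute one copy because they occupy a single haplotype row. Sites
    with zero non-missing copies get NaN.
    """
    pops = populations or panel.populations()
    missing = [p for p in pops if p not in set(panel.populations())]
    if missing:
        raise PanelError(f"populations not in panel: {missing}")
    p = np.empty((panel.n_markers, len(pops)))
    n = np.empty((panel.n_markers, len(pops)), dtype=np.int64)
    for k, pop in enumerate(pops):
        rows = panel.hap_rows(population=pop)
        block = panel.haplotypes[rows]
        obs = (block != MISSING).sum(axis=0)
        ones = (block == 1).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[:, k] = np.where(obs > 0, ones / np.maximum(obs, 1), np.nan)
        n[:, k] = obs
    return FreqTable(populations=list(pops), p=p, n=n, markers=panel.markers)


def hudson_fst(p1: np.ndarray, n1: np.ndarray,
               p2: np.ndarray, n2: np.ndarray) -> np.ndarray:
    """Hudson's pairwise Fst estimator per site, clipped to [0, 1].

    Numerator (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1), denominator
    p1(1-p2) + p2(1-p1). Sites with fewer than two copies in either
    population, or zero denominator, give NaN.
    """
    p1, p2 = np.asarray(p1, float), np.asarray(p2, float)
    n1, n2 = np.asarray(n1, float), np.asarray(n2, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = ((p1 - p2) ** 2
               - p1 * (1 - p1) / (n1 - 1)
               - p2 * (1 - p2) / (n2 - 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
        fst = num / den
    fst = np.where((n1 < 2) | (n2 < 2) | (den == 0), np.nan, fst)
    return np.clip(fst, 0.0, 1.0)


def delta_scan(panel: HaplotypePanel, pop_a: str, pop_b: str,
               measure: str = "delta") -> pd.Series:
    """Per-marker differentiation between two populations.

    ``measure='delta'`` gives |p_A - p_B|; ``measure='hudson_fst'`` gives
    Hudson's estimator. Sites undefined in either population are NaN.
    """
    freqs = population_frequencies(panel, [pop_a, pop_b])
    pa, pb = freqs.freq(pop_a), freqs.freq(pop_b)
    na, nb = freqs.count(pop_a), freqs.count(pop_b)
    if measure == "delta":
        vals = np.abs(pa - pb)
    elif measure == "hudson_fst":
        vals = hudson_fst(pa, na, pb, nb)
    else:
        raise PanelError(f"unknown measure {measure!r}")
    return pd.Series(vals, index=panel.markers["marker_id"], name=measure)


@dataclass
class HighDeltaResult:
    """High SNP/region tallies over one window grid."""

    n_high_snps: int
    n_high_regions: int
    per_region: pd.DataFrame  # window, start, end, n_snps, n_high

    @property
    def high_windows(self) -> np.ndarray:
        return self.per_region.loc[self.per_region["n_high"] > 0,
                                   "window"].to_numpy()


def call_high_and_regionize(values: np.ndarray, pos_bp: np.ndarray,
                            grid: RegionGrid,
                            threshold: float = 0.9) -> HighDeltaResult:
    """Flag values strictly above ``threshold`` and tally them per window.

    A window holding at least one high SNP is a high region. Values at NaN
    sites are ignored; sites outside the grid span are rejected.
    """
    values = np.asarray(values, dtype=float)
    pos_bp = np.asarray(pos_bp)
    ok = ~np.isnan(values)
    win = grid.assign(pos_bp[ok])
    if np.any(win < 0):
        raise PanelError("marker positions fall outside the window span")
    vals = values[ok]
    high = vals > threshold
    n_snps = np.bincount(win, minlength=grid.n_windows)
    n_high = np.bincount(win[high], minlength=grid.n_windows)
    per_region = pd.DataFrame({
        "window": np.arange(grid.n_windows),
        "start": grid.starts, "end": grid.ends,
        "n_snps": n_snps, "n_high": n_high,
    })
    return HighDeltaResult(n_high_snps=int(high.sum()),
                           n_high_regions=int((n_high > 0).sum()),
                           per_region=per_region)


def assign_ancestral_alleles(markers: pd.DataFrame, outgroup: pd.DataFrame,
                             override: pd.DataFrame | None = None
                             ) -> np.ndarray:
    """Ancestral state per marker from outgroup genotypes.

    An allele fixed across all outgroup chromosome copies is taken as
    ancestral; polymorphic or missing outgroup calls leave the state
    unknown, unless an override table (columns marker_id, ancestral base)
    supplies it. An override base not among the marker's two alleles is an
    error.
    """
    key = outgroup.set_index(["chrom", "pos_bp"])
    gcols = [c for c in outgroup.columns if c.startswith("outgroup")]
    anc = np.full(len(markers), ANC_UNKNOWN, dtype=np.int64)
    for i, m in markers.iterrows():
        try:
            rec = key.loc[(m["chrom"], m["pos_bp"])]
        except KeyError:
            continue
        alleles: set[str] = set()
        missing = False
        for c in gcols:
            call = str(rec[c])
            if call in (".", "./.", "nan", ""):
                missing = True
                break
            alleles.update(call.split("/"))
        if missing or len(alleles) != 1:
            continue
        base = alleles.pop()
        if base == m["ref"]:
            anc[i] = 0
        elif base == m["alt"]:
            anc[i] = 1
        # an outgroup base matching neither allele stays unknown
    if override is not None:
        omap = dict(zip(override["marker_id"], override["ancestral"]))
        for i, m in markers.iterrows():
            if anc[i] != ANC_UNKNOWN or m["marker_id"] not in omap:
                continue
            base = omap[m["marker_id"]]
            if base == m["ref"]:
                anc[i] = 0
            elif base == m["alt"]:
                anc[i] = 1
            else:
                raise PanelError(
                    f"override ancestral allele {base!r} for "
                    f"{m['marker_id']} is not among its alleles "
                    f"({m['ref']}/{m['alt']})")
    return anc


def make_calls(markers: pd.DataFrame, values: pd.Series | np.ndarray,
               grid: RegionGrid, threshold: float = 0.9) -> pd.DataFrame:
    """Per-marker call table: value, high flag, window, genic, ancestral."""
    vals = np.asarray(values, dtype=float)
    win = grid.assign(markers["pos_bp"].to_numpy())
    return pd.DataFrame({
        "marker_id": markers["marker_id"],
        "pos_bp": markers["pos_bp"],
        "value": vals,
        "high": vals > threshold,
        "window": win,
        "genic": markers["genic"].to_numpy(),
        "anc_state": markers["anc_state"].to_numpy(),
    })


def proportion_chi2(k1: int, n1: int, k2: int, n2: int,
                    yates: bool = False) -> tuple[float, float]:
    """Chi-square test comparing two proportions k1/n1 vs k2/n2 (2x2 table)."""
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(stat), float(p)


@dataclass
class HighDeltaSummary:
    """Composition of the high-delta SNP set (Table-3-style summary)."""

    n_high: int
    genic_fraction: float | None
    derived_high: dict[str, tuple[int, int, float | None]]
    decile_enrichment: pd.DataFrame
    crosstab: pd.DataFrame
    chi2_genic: tuple[float, float] | None


def classify_high_delta(calls: pd.DataFrame, freqs: FreqTable,
                        pop_a: str, pop_b: str,
                        derived_high_threshold: float = 0.9,
                        maf_threshold: float = 0.1) -> HighDeltaSummary:
    """Summarise genic/derived/MAF composition of high-delta SNPs.

    For each of the two populations, counts the high-delta SNPs whose
    derived-allele frequency reaches ``derived_high_threshold`` there,
    with SNPs of unknown ancestral state excluded from the denominator.
    Deciles [0, 0.1) ... [0.9, 1.0] report the genic fraction relative to
    the panel-wide genic fraction, and the cross-tabulation splits markers
    by genic x (MAF <= 0.1 in ``pop_a``) x high-delta. An empty high-delta
    set yields fractions of None, not zero.
    """
    high = calls[calls["high"]]
    n_high = len(high)
    genic_fraction = float(high["genic"].mean()) if n_high else None

    derived_high: dict[str, tuple[int, int, float | None]] = {}
    known = high[high["anc_state"] != ANC_UNKNOWN]
    for pop in (pop_a, pop_b):
        f1 = freqs.freq(pop)[known.index.to_numpy()] if len(known) else \
            np.empty(0)
        anc = known["anc_state"].to_numpy()
        derived_freq = np.where(anc == 0, f1, 1.0 - f1)
        k = int((derived_freq >= derived_high_threshold).sum())
        denom = len(known)
        derived_high[pop] = (k, denom, k / denom if denom else None)

    overall_genic = float(calls["genic"].mean()) if len(calls) else np.nan
    vals = calls["value"].to_numpy()
    bins = np.clip((vals * 10).astype(int), 0, 9)  # [0,0.1) ... [0.9,1.0]
    rows = []
    for b in range(10):
        sel = calls[(bins == b) & ~np.isnan(vals)]
        gf = float(sel["genic"].mean()) if len(sel) else np.nan
        rows.append({"bin_low": b / 10, "bin_high": (b + 1) / 10,
                     "n_snps": len(sel), "n_genic": int(sel["genic"].sum()),
                     "genic_fraction": gf,
                     "enrichment": gf / overall_genic if overall_genic else np.nan})
    decile = pd.DataFrame(rows)

    maf = freqs.maf(pop_a)[calls.index.to_numpy()]
    crosstab = (calls.assign(low_maf=maf <= maf_threshold)
                .groupby(["genic", "low_maf", "high"], observed=False)
                .size().rename("n").reset_index())

    chi2 = None
    if n_high:
        # do genic SNPs yield high-delta SNPs more often than non-genic ones?
        g = calls["genic"].to_numpy()
        h = calls["high"].to_numpy()
        chi2 = proportion_chi2(int((g & h).sum()), int(g.sum()),
                               int((~g & h).sum()), int((~g).sum()))
    return HighDeltaSummary(n_high=n_high, genic_fraction=genic_fraction,
                            derived_high=derived_high,
                            decile_enrichment=decile, crosstab=crosstab,
                            chi2_genic=chi2)
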