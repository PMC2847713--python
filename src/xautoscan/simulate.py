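"""Synthetic HGDP-like matched X/autosome datasets with known sex-biased demography.

Populations nested in continental regions are sampled at Balding-Nichols
(beta-binomial island-model) equilibrium: each locus draws an ancestral
frequency, and each population draws its frequency from a Beta centred on
it with spread set by the island-model differentiation F — ``fst_auto`` on
autosomes and its TA/EX image at the configured (N_f/N, m_f/m) on the X.
Haplotypes are then built by founder copying: every chromosome copy is a
mosaic of a small founder pool (switching founders at exponential bp
distances, flipping alleles at a small per-site rate), which gives tunable
extended-haplotype structure on top of the marginal frequencies. Sweeps
are planted, not evolved: carrier haplotypes are regenerated from one or
two founders around a focal marker, producing the long shared haplotypes a
selection scan should flag.

The generator emits the same file set the readers consume (phased VCF,
sample TSV, gene BED, map TSV, outgroup TSV) plus a truth table of the
frequencies actually used, so every downstream stage is testable without
any external data.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import (ANC_UNKNOWN, SEX_FEMALE, SEX_MALE, HaplotypePanel,
                    PanelError)
from .taex import transform_autosomal

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


def expected_x_differentiation(f_auto: float, x: float, y: float) -> float:
    """Expected X-linked differentiation for autosomal ``f_auto`` at (x, y).

    The linearised island-model map: with F' = F/(1-F) and
    M(x, y) = (4/3)(2-x)/(1+y), returns ``F_X = M F'_A / (1 + M F'_A)``.
    F = 1 is a fixed point; the result depends on (x, y) only through the
    combined term (1+y)/(2-x).
    """
    if not (0 <= f_auto <= 1):
        raise PanelError(f"F_A must lie in [0, 1], got {f_auto}")
    return float(transform_autosomal(np.array([f_auto]), x, y)[0])


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate a desk-scale HGDP-like layout: 6 populations nested
    in 2 continental regions, 25 females + 25 males per population, a
    2,000-marker autosomal panel and a 500-marker X panel, island-model
    autosomal differentiation F_A = 0.10, and balanced female demography
    (N_f/N = m_f/m = 0.5, so F_X sits at the classic 4/3 linearised ratio).
    """

    n_regions: int = 2
    pops_per_region: int = 3
    n_auto_loci: int = 2000
    n_x_loci: int = 500
    fst_auto: float = 0.10
    nf_ratio: float = 0.5          # x = N_f/N
    mf_ratio: float = 0.5          # y = m_f/m
    females_per_pop: int = 25
    males_per_pop: int = 25
    founder_count: int = 16
    switch_rate: float = 2.5e-6    # founder switches per bp (~400 kb segments)
    flip_rate: float = 0.002       # per-site copying error / mutation
    outgroup_fixed_prob: float = 0.9
    n_outgroup: int = 1            # diploid outgroup individuals
    genic_fraction_target: float = 0.32
    auto_span_bp: int = 80_000_000
    x_span_bp: int = 20_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fst_auto", "nf_ratio", "mf_ratio"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise PanelError(f"{name} must lie in (0, 1), got {v}")
        for name in ("flip_rate", "outgroup_fixed_prob",
                     "genic_fraction_target"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise PanelError(f"{name} must lie in [0, 1], got {v}")
        if self.founder_count < 1:
            raise PanelError("founder_count must be >= 1")

    def population_names(self) -> list[tuple[str, str]]:
        """(region, population) labels, e.g. ('region1', 'pop1_2')."""
        out = []
        for r in range(self.n_regions):
            for p in range(self.pops_per_region):
                out.append((f"region{r + 1}", f"pop{r + 1}_{p + 1}"))
        return out


@dataclass
class SimOutput:
    """Matched X and autosomal panels plus generative truth."""

    x_panel: HaplotypePanel
    auto_panel: HaplotypePanel
    truth: pd.DataFrame            # per-locus ancestral and per-pop frequencies
    outgroup: pd.DataFrame         # per-marker outgroup diploid genotypes
    f_auto: float
    f_x: float
    config: SimConfig


def _positions(n: int, span: int, rng: np.random.Generator) -> np.ndarray:
    """n strictly increasing integer positions spread over [0, span)."""
    spacing = span / n
    base = (np.arange(n) + 0.5) * spacing
    jitter = rng.uniform(-0.4, 0.4, size=n) * spacing
    pos = np.unique(np.clip((base + jitter).astype(np.int64), 0, span - 1))
    while len(pos) < n:  # rare collisions after rounding
        extra = rng.integers(0, span, size=n - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return pos[:n]


def _pop_frequencies(p_anc: np.ndarray, f: float, n_pops: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols per-population frequencies, shape (n_pops, n_loci)."""
    if f < 1e-12:  # F -> 0 limit: no drift, every population at the ancestral
        return np.tile(p_anc, (n_pops, 1))
    shape = (1.0 - f) / f
    a = np.maximum(p_anc * shape, 1e-12)
    b = np.maximum((1.0 - p_anc) * shape, 1e-12)
    return rng.beta(a, b, size=(n_pops, len(p_anc)))


def _founder_matrix(p: np.ndarray, k: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Founder haplotypes (k x n_loci) whose column means track p.

    The number of founders carrying allele 1 at each locus is the
    randomised rounding of p*k, so the founder-pool frequency equals the
    target up to 1/k — this is the calibration that makes sample
    frequencies match the drawn population frequencies.
    """
    n = len(p)
    carriers = np.floor(p * k).astype(np.int64)
    carriers += rng.random(n) < (p * k - carriers)
    founders = np.zeros((k, n), dtype=np.int8)
    order = np.argsort(rng.random((k, n)), axis=0)
    founders[order < carriers[None, :]] = 1
    return founders


def _mosaic_haplotypes(founders: np.ndarray, pos_bp: np.ndarray, n_hap: int,
                       switch_rate: float, flip_rate: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Haplotypes copied from founders with exponential-distance switches."""
    k, n = founders.shape
    span = int(pos_bp[-1]) + 1
    out = np.empty((n_hap, n), dtype=np.int8)
    for h in range(n_hap):
        if switch_rate <= 0:
            ids = np.full(n, rng.integers(k))
        else:
            # breakpoints of the copying process along the chromosome
            n_bp = rng.poisson(switch_rate * span)
            breaks = np.sort(rng.uniform(0, span, size=n_bp))
            seg = np.searchsorted(breaks, pos_bp, side="right")
            seg_founder = rng.integers(0, k, size=n_bp + 1)
            ids = seg_founder[seg]
        out[h] = founders[ids, np.arange(n)]
    if flip_rate > 0:
        flips = rng.random(out.shape) < flip_rate
        out[flips] = 1 - out[flips]
    return out


def _build_panel(chrom: str, pos_bp: np.ndarray, freqs: np.ndarray,
                 samples: pd.DataFrame, x_chrom: bool, cfg: SimConfig,
                 rng: np.random.Generator) -> HaplotypePanel:
    pops = list(dict.fromkeys(samples["population"]))
    hap_rows, row_sample, row_copy = [], [], []
    for pop in pops:
        sub = samples[samples["population"] == pop]
        n_hap = 0
        for _, s in sub.iterrows():
            copies = 1 if (x_chrom and s["sex"] == SEX_MALE) else 2
            for k in range(copies):
                row_sample.append(s["sample_id"])
                row_copy.append(k)
            n_hap += copies
        p_idx = pops.index(pop)
        founders = _founder_matrix(freqs[p_idx], cfg.founder_count, rng)
        hap_rows.append(_mosaic_haplotypes(founders, pos_bp, n_hap,
                                           cfg.switch_rate, cfg.flip_rate,
                                           rng))
    hap = np.vstack(hap_rows)
    n = len(pos_bp)
    ref = _BASES[rng.integers(0, 4, size=n)]
    alt_shift = rng.integers(1, 4, size=n)
    alt = _BASES[(np.searchsorted(_BASES, ref) + alt_shift) % 4]
    markers = pd.DataFrame({
        "marker_id": [f"{chrom}_snp{i + 1}" for i in range(n)],
        "chrom": chrom, "pos_bp": pos_bp,
        "pos_cm": pos_bp * 1.0e-6,
        "ref": ref, "alt": alt,
        "anc_state": 0,  # allele 1 is the derived allele by construction
        "genic": False,
    })
    return HaplotypePanel(hap, markers, samples,
                          np.array(row_sample, dtype=object),
                          np.array(row_copy, dtype=np.int8))


def _genic_intervals(pos_bp: np.ndarray, target: float, chrom: str,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Random gene intervals sized to flag about ``target`` of the markers."""
    n = len(pos_bp)
    flagged = np.zeros(n, dtype=bool)
    rows = []
    genes_size = max(2, n // 50)  # markers per gene
    while flagged.mean() < target:
        i = int(rng.integers(0, max(1, n - genes_size)))
        j = min(n - 1, i + genes_size - 1)
        rows.append({"chrom": chrom, "start": int(pos_bp[i]),
                     "end": int(pos_bp[j]) + 1})
        flagged[i:j + 1] = True
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _outgroup_calls(markers: pd.DataFrame, fixed_prob: float, n_outgroup: int,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Outgroup diploid genotypes; fixed for the ancestral allele with
    probability ``fixed_prob``, else polymorphic."""
    rows = []
    for _, m in markers.iterrows():
        anc = m["ref"]  # ancestral is allele 0 by construction
        der = m["alt"]
        fixed = rng.random() < fixed_prob
        rec = {"chrom": m["chrom"], "pos_bp": m["pos_bp"]}
        for k in range(n_outgroup):
            rec[f"outgroup{k + 1}"] = (f"{anc}/{anc}" if fixed
                                       else f"{anc}/{der}")
        rows.append(rec)
    return pd.DataFrame(rows)


def simulate_dataset(config: SimConfig | None = None) -> SimOutput:
    """Generate matched X and autosomal panels under the configured demography.

    Fully determined by ``config.seed``: the same configuration yields
    byte-identical outputs.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    f_x = expected_x_differentiation(cfg.fst_auto, cfg.nf_ratio, cfg.mf_ratio)

    pops = cfg.population_names()
    sample_rows = []
    for region, pop in pops:
        for i in range(cfg.females_per_pop):
            sample_rows.append({"sample_id": f"{pop}_F{i + 1}",
                                "sex": SEX_FEMALE,
                                "population": pop, "region": region})
        for i in range(cfg.males_per_pop):
            sample_rows.append({"sample_id": f"{pop}_M{i + 1}",
                                "sex": SEX_MALE,
                                "population": pop, "region": region})
    samples = pd.DataFrame(sample_rows)

    panels = {}
    truth_frames = []
    for chrom, n_loci, span, f, x_chrom in [
            ("A1", cfg.n_auto_loci, cfg.auto_span_bp, cfg.fst_auto, False),
            ("X", cfg.n_x_loci, cfg.x_span_bp, f_x, True)]:
        pos = _positions(n_loci, span, rng)
        p_anc = rng.uniform(0.05, 0.95, size=n_loci)
        freqs = _pop_frequencies(p_anc, f, len(pops), rng)
        panel = _build_panel(chrom, pos, freqs, samples, x_chrom, cfg, rng)
        bed = _genic_intervals(pos, cfg.genic_fraction_target, chrom, rng)
        from .io import genic_flags
        panel.markers["genic"] = genic_flags(
            panel.markers["chrom"].to_numpy(),
            panel.markers["pos_bp"].to_numpy(), bed)
        truth = pd.DataFrame({"chrom": chrom, "pos_bp": pos,
                              "p_ancestral": p_anc, "f_used": f})
        for k, (_, pop) in enumerate(pops):
            truth[f"p_{pop}"] = freqs[k]
        truth_frames.append(truth)
        panels[chrom] = panel

    truth = pd.concat(truth_frames, ignore_index=True)
    all_markers = pd.concat([panels["A1"].markers, panels["X"].markers],
                            ignore_index=True)
    outgroup = _outgroup_calls(all_markers, cfg.outgroup_fixed_prob,
                               cfg.n_outgroup, rng)
    return SimOutput(x_panel=panels["X"], auto_panel=panels["A1"],
                     truth=truth, outgroup=outgroup,
                     f_auto=cfg.fst_auto, f_x=f_x, config=cfg)


def plant_sweep(panel: HaplotypePanel, focal_marker: int | str,
                population: str, carrier_fraction: float = 0.8,
                carrier_founders: int = 2, switch_rate: float = 2.5e-6,
                flip_rate: float = 0.0, tract_bp: int = 2_000_000,
                seed: int = 0) -> HaplotypePanel:
    """Plant a partial selective sweep in one population.

    A ``carrier_fraction`` share of the population's haplotypes is made to
    carry the derived allele at the focal marker and regenerated, over a
    ``tract_bp``-wide tract centred on it, as mosaics of
    ``carrier_founders`` founder haplotypes drawn from existing derived
    carriers (all forced derived at the core). This produces long shared
    haplotypes around the core that recombine back into the background
    outside the tract, the signature of a recent partial sweep.
    Non-carrier haplotypes are set ancestral at the core and otherwise
    untouched.
    """
    if not (0 < carrier_fraction <= 1):
        raise PanelError(
            f"carrier_fraction must lie in (0, 1], got {carrier_fraction}")
    rng = np.random.default_rng(seed)
    markers = panel.markers
    if isinstance(focal_marker, str):
        hits = np.flatnonzero(markers["marker_id"] == focal_marker)
        if not len(hits):
            raise PanelError(f"unknown marker {focal_marker}")
        focal = int(hits[0])
    else:
        focal = int(focal_marker)
    derived = 1 if markers.loc[focal, "anc_state"] in (0, ANC_UNKNOWN) else 0

    rows = panel.hap_rows(population=population)
    core = panel.haplotypes[rows, focal]
    if len(np.unique(core[core >= 0])) < 2:
        raise PanelError(
            f"focal marker {focal} is monomorphic in {population}")

    hap = panel.haplotypes.copy()
    n_carriers = max(1, int(round(carrier_fraction * len(rows))))
    carrier_rows = rng.choice(rows, size=n_carriers, replace=False)
    donor_pool = rows[panel.haplotypes[rows, focal] == derived]
    pos = markers["pos_bp"].to_numpy()
    focal_pos = int(pos[focal])
    in_tract = np.abs(pos - focal_pos) <= tract_bp // 2
    tract_cols = np.flatnonzero(in_tract)
    founders = hap[np.ix_(rng.choice(donor_pool, size=carrier_founders,
                                     replace=len(donor_pool) < carrier_founders),
                          tract_cols)].copy()
    focal_in_tract = int(np.searchsorted(tract_cols, focal))
    founders[:, focal_in_tract] = derived
    new = _mosaic_haplotypes(founders, pos[tract_cols], n_carriers,
                             switch_rate, flip_rate, rng)
    new[:, focal_in_tract] = derived
    hap[np.ix_(carrier_rows, tract_cols)] = new
    non_carriers = np.setdiff1d(rows, carrier_rows)
    hap[non_carriers, focal] = 1 - derived

    out = HaplotypePanel(hap, markers.copy(), panel.samples.copy(),
                         panel.row_sample.copy(), panel.row_copy.copy())
    return out


def write_dataset(sim: SimOutput, outdir: str | os.PathLike) -> dict[str, Path]:
    """Write the full synthetic file set (VCFs, tables, BED, map, truth)."""
    from .io import write_panel
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for prefix, panel in [("x", sim.x_panel), ("auto", sim.auto_panel)]:
        written = write_panel(panel, outdir, prefix=prefix)
        paths.update({f"{prefix}_{k}": v for k, v in written.items()})
    paths["truth"] = outdir / "truth.tsv"
    sim.truth.to_csv(paths["truth"], sep="\t", index=False,
                     float_format="%.8g")
    paths["outgroup"] = outdir / "outgroup.tsv"
    sim.outgroup.to_csv(paths["outgroup"], sep="\t", index=False)
    paths["config"] = outdir / "sim_config.tsv"
    pd.Series(dataclasses.asdict(sim.config)).to_csv(
        paths["config"], sep="\t", header=False)
    return paths
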