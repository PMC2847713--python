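"""File readers and writers: phased VCF, sample/marker TSVs, BED, genetic maps.

VCF parsing goes through :mod:`pysam`; writing emits plain uncompressed
VCF 4.2 text so that panels round-trip exactly. Positions are converted
between VCF's 1-based convention and the package's 0-based half-open one
here and nowhere else.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .panel import (ANC_UNKNOWN, MISSING, SEX_MALE, HaplotypePanel, PanelError,
                    validate_samples)

log = logging.getLogger(__name__)

#: chromosome names treated as the (male-haploid) X by default
X_CHROM_NAMES = {"X", "chrX", "23"}

CM_PER_BP_FALLBACK = 1.0e-6  # 1 cM/Mb when no genetic map is supplied


def read_sample_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TSV with columns sample, sex, population, region."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.rename(columns={"sample": "sample_id"})
    return validate_samples(df)


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BED file (chrom, start, end; 0-based half-open)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"],
                         dtype={"chrom": str, "start": np.int64,
                                "end": np.int64})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end"])
    return df


def read_genetic_map(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genetic map TSV: (pos_bp, cM) or (chrom, pos_bp, cM)."""
    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "chrom" not in cols:
        df["chrom"] = None
    df = df.rename(columns={"cm": "pos_cm"})
    if not {"pos_bp", "pos_cm"} <= set(df.columns):
        raise PanelError("genetic map needs columns pos_bp and cM")
    return df[["chrom", "pos_bp", "pos_cm"]]


def read_score_track(path: str | os.PathLike) -> pd.DataFrame:
    """Read a per-site score track TSV (chrom, pos_bp, score)."""
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "pos_bp", "score"} <= set(df.columns):
        raise PanelError("score track needs columns chrom, pos_bp, score")
    return df


def read_outgroup(path: str | os.PathLike) -> pd.DataFrame:
    """Read outgroup genotypes: chrom, pos_bp, then one 'X/Y' column per
    outgroup individual ('.' or './.' = missing)."""
    return pd.read_csv(path, sep="\t", dtype=str).astype({"pos_bp": np.int64})


def genic_flags(chrom: np.ndarray, pos_bp: np.ndarray,
                bed: pd.DataFrame) -> np.ndarray:
    """True for markers falling inside any (half-open) BED interval."""
    out = np.zeros(len(pos_bp), dtype=bool)
    for c, sub in bed.groupby("chrom"):
        sel = np.asarray(chrom) == c
        if not sel.any():
            continue
        # merge intervals, then a position is genic iff the number of interval
        # starts <= pos exceeds the number of interval ends <= pos
        ivs = sub.sort_values("start")[["start", "end"]].to_numpy()
        merged = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        merged = np.asarray(merged)
        pos = np.asarray(pos_bp)[sel]
        i = np.searchsorted(merged[:, 0], pos, side="right") - 1
        ok = (i >= 0) & (pos < merged[np.clip(i, 0, None), 1])
        out[np.flatnonzero(sel)] = ok
    return out


def interpolate_cm(pos_bp: np.ndarray, chrom: np.ndarray,
                   gmap: pd.DataFrame | None) -> np.ndarray:
    """cM positions by linear interpolation from a map, else 1 cM/Mb."""
    pos_bp = np.asarray(pos_bp, dtype=np.float64)
    if gmap is None:
        return pos_bp * CM_PER_BP_FALLBACK
    out = np.empty(len(pos_bp))
    chrom = np.asarray(chrom)
    for c in np.unique(chrom):
        sel = chrom == c
        sub = gmap if gmap["chrom"].isna().all() else gmap[gmap["chrom"] == c]
        if len(sub) < 2:
            out[sel] = pos_bp[sel] * CM_PER_BP_FALLBACK
            continue
        sub = sub.sort_values("pos_bp")
        out[sel] = np.interp(pos_bp[sel], sub["pos_bp"], sub["pos_cm"])
    return out


def _is_x(chrom: str) -> bool:
    return chrom in X_CHROM_NAMES


def load_panel(vcf_path: str | os.PathLike,
               sample_table_path: str | os.PathLike,
               bed_path: str | os.PathLike | None = None,
               map_path: str | os.PathLike | None = None,
               x_panel: bool | None = None) -> HaplotypePanel:
    """Load a phased biallelic VCF into a :class:`HaplotypePanel`.

    Males contribute a single haplotype row on the X (haploid ``1`` and
    homozygous diploid ``1|1`` encodings are both accepted and normalised);
    everyone contributes two rows on autosomes. Markers overlapping a BED
    interval are flagged genic; cM positions are interpolated from the map
    when given, else set at 1 cM/Mb. Heterozygous male X genotypes,
    unphased heterozygous diploid genotypes, and VCF samples absent from
    the sample table are rejected.

    Parameters
    ----------
    x_panel
        Force X (male-haploid) handling on or off; by default chromosomes
        named X/chrX/23 get X handling.
    """
    samples = read_sample_table(sample_table_path)
    sex = dict(zip(samples["sample_id"], samples["sex"]))

    vcf = pysam.VariantFile(os.fspath(vcf_path))
    vcf_samples = list(vcf.header.samples)
    unknown = [s for s in vcf_samples if s not in sex]
    if unknown:
        raise PanelError(f"VCF samples absent from sample table: {unknown}")

    rows: list[tuple[str, int]] = []
    chrom_seen: str | None = None
    recs = list(vcf)
    if not recs:
        raise PanelError(f"no variant records in {vcf_path}")
    for rec in recs:
        if chrom_seen is None:
            chrom_seen = rec.chrom
    on_x = x_panel if x_panel is not None else any(
        _is_x(r.chrom) for r in recs)

    for s in vcf_samples:
        n_copies = 1 if (on_x and sex[s] == SEX_MALE) else 2
        rows.extend((s, k) for k in range(n_copies))
    row_index = {sr: i for i, sr in enumerate(rows)}

    n_markers = len(recs)
    hap = np.full((len(rows), n_markers), MISSING, dtype=np.int8)
    marker_rows = []
    for j, rec in enumerate(recs):
        if rec.alts is None or len(rec.alts) != 1:
            raise PanelError(
                f"site {rec.chrom}:{rec.pos} is not biallelic")
        aa = rec.info.get("AA") if "AA" in rec.info else None
        if isinstance(aa, tuple):
            aa = aa[0]
        anc = ANC_UNKNOWN
        if aa == rec.ref:
            anc = 0
        elif aa == rec.alts[0]:
            anc = 1
        marker_rows.append({
            "marker_id": rec.id or f"{rec.chrom}:{rec.pos}",
            "chrom": rec.chrom, "pos_bp": rec.pos - 1,
            "ref": rec.ref, "alt": rec.alts[0], "anc_state": anc,
        })
        site_x = _is_x(rec.chrom) if x_panel is None else x_panel
        for s in vcf_samples:
            gt = rec.samples[s]
            alleles = gt["GT"]
            if alleles is None:
                alleles = (None,)
            male = sex[s] == SEX_MALE
            if site_x and male:
                vals = [a for a in alleles if a is not None]
                if len(set(vals)) > 1:
                    raise PanelError(
                        f"heterozygous male X genotype for sample {s} at "
                        f"{rec.chrom}:{rec.pos}")
                hap[row_index[(s, 0)], j] = vals[0] if vals else MISSING
            else:
                if len(alleles) == 1:
                    raise PanelError(
                        f"haploid genotype for {'male autosomal' if male else 'female'} "
                        f"sample {s} at {rec.chrom}:{rec.pos}")
                a0, a1 = alleles
                het = a0 is not None and a1 is not None and a0 != a1
                if het and not gt.phased:
                    raise PanelError(
                        f"unphased heterozygous genotype for sample {s} at "
                        f"{rec.chrom}:{rec.pos}")
                hap[row_index[(s, 0)], j] = MISSING if a0 is None else a0
                hap[row_index[(s, 1)], j] = MISSING if a1 is None else a1

    markers = pd.DataFrame(marker_rows)
    bed = read_bed(bed_path) if bed_path is not None else None
    markers["genic"] = (genic_flags(markers["chrom"].to_numpy(),
                                    markers["pos_bp"].to_numpy(), bed)
                        if bed is not None else False)
    gmap = read_genetic_map(map_path) if map_path is not None else None
    markers["pos_cm"] = interpolate_cm(markers["pos_bp"].to_numpy(),
                                       markers["chrom"].to_numpy(), gmap)

    keep = samples["sample_id"].isin(vcf_samples)
    samples = samples.loc[keep].reset_index(drop=True)
    row_sample = np.array([s for s, _ in rows], dtype=object)
    row_copy = np.array([k for _, k in rows], dtype=np.int8)
    return HaplotypePanel(hap, markers, samples, row_sample, row_copy)


# ---------------------------------------------------------------------------
# writers

def write_vcf(panel: HaplotypePanel, path: str | os.PathLike,
              x_panel: bool | None = None) -> None:
    """Write a panel as uncompressed phased VCF 4.2 (AA INFO for ancestral)."""
    markers = panel.markers
    sample_ids = list(panel.samples["sample_id"])
    sex = dict(zip(panel.samples["sample_id"], panel.samples["sex"]))
    ploidy = panel.ploidy()
    rowmap = {(s, k): i for i, (s, k) in
              enumerate(zip(panel.row_sample, panel.row_copy))}

    def fmt(allele: int) -> str:
        return "." if allele == MISSING else str(int(allele))

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(markers["chrom"]):
            ln = int(markers.loc[markers["chrom"] == chrom, "pos_bp"].max()) + 2
            fh.write(f"##contig=<ID={chrom},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for j, m in markers.iterrows():
            anc = m["anc_state"]
            info = "." if anc == ANC_UNKNOWN else (
                f"AA={m['ref'] if anc == 0 else m['alt']}")
            gts = []
            for s in sample_ids:
                if ploidy[s] == 1:
                    gts.append(fmt(panel.haplotypes[rowmap[(s, 0)], j]))
                else:
                    a0 = panel.haplotypes[rowmap[(s, 0)], j]
                    a1 = panel.haplotypes[rowmap[(s, 1)], j]
                    gts.append(f"{fmt(a0)}|{fmt(a1)}")
            fh.write(f"{m['chrom']}\t{m['pos_bp'] + 1}\t{m['marker_id']}\t"
                     f"{m['ref']}\t{m['alt']}\t.\t.\t{info}\tGT\t"
                     + "\t".join(gts) + "\n")


def write_panel(panel: HaplotypePanel, outdir: str | os.PathLike,
                prefix: str = "panel") -> dict[str, Path]:
    """Write a panel as VCF + sample TSV + genes BED + map TSV.

    The BED holds one 1-bp interval per genic marker and the map pins the
    exact cM value at every marker position, so re-loading with
    :func:`load_panel` reproduces the panel exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / f"{prefix}.vcf",
        "samples": outdir / f"{prefix}.samples.tsv",
        "bed": outdir / f"{prefix}.genes.bed",
        "map": outdir / f"{prefix}.map.tsv",
    }
    write_vcf(panel, paths["vcf"])
    panel.samples.rename(columns={"sample_id": "sample"}).to_csv(
        paths["samples"], sep="\t", index=False)
    genic = panel.markers[panel.markers["genic"]]
    with open(paths["bed"], "w") as fh:
        for _, m in genic.iterrows():
            fh.write(f"{m['chrom']}\t{m['pos_bp']}\t{m['pos_bp'] + 1}\n")
    panel.markers[["chrom", "pos_bp", "pos_cm"]].rename(
        columns={"pos_cm": "cM"}).to_csv(paths["map"], sep="\t", index=False,
                                         float_format="%.10g")
    return paths


def load_written_panel(paths: dict[str, Path],
                       x_panel: bool | None = None) -> HaplotypePanel:
    """Re-load a panel written by :func:`write_panel`."""
    return load_panel(paths["vcf"], paths["samples"], bed_path=paths["bed"],
                      map_path=paths["map"], x_panel=x_panel)
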