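"""Run orchestration: simulate -> diff -> taex -> amova -> selscan -> report.

A single YAML config drives the whole run. One global seed is expanded
into per-stage seeds with ``numpy.random.SeedSequence(seed).spawn`` in a
fixed stage order (simulate, diff, taex, amova, selscan, report), so any
stage re-run in isolation under the same global seed sees the same
stream. All outputs are TSV; the run log echoes the config, the seeds and
the locus counts after each filter. Identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .amova import amova, bootstrap_ci, make_pseudofemales
from .diff import (assign_ancestral_alleles, call_high_and_regionize,
                   classify_high_delta, delta_scan, make_calls,
                   population_frequencies)
from .ehh import (hap_het_ratio, ihs_scan, regionize_scores, top_regions,
                  xpehh_scan)
from .panel import PanelError, make_windows
from .simulate import SimConfig, simulate_dataset, write_dataset
from .taex import grid_scan

log = logging.getLogger(__name__)

STAGES = ["simulate", "diff", "taex", "amova", "selscan", "report"]

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "simulate": {},
    "diff": {"pairs": None, "measure": "delta", "threshold": 0.9,
             "window_bp": 200_000, "derived_high_threshold": 0.9},
    "taex": {"threshold": 0.9, "side": "two_sided"},
    "amova": {"modes": ["haplotypic", "diploid"], "bootstrap": 200},
    "selscan": {"tests": ["ihs", "xpehh"], "window_bp": 400_000,
                "ehh_cutoff": 0.1, "top_k": 10, "hap_window_snps": 5,
                "track": None},
}


class ConfigError(ValueError):
    """Raised for invalid or incomplete run configuration."""


@dataclasses.dataclass
class _LoadedData:
    """File-backed stand-in for a simulation result inside the pipeline."""

    x_panel: Any
    auto_panel: Any
    outgroup: Any
    config: SimConfig

    @property
    def f_auto(self):
        return self.config.fst_auto

    @property
    def f_x(self):
        from .simulate import expected_x_differentiation
        return expected_x_differentiation(self.config.fst_auto,
                                          self.config.nf_ratio,
                                          self.config.mf_ratio)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: dict) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULTS.items()}
    for k, v in (user or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds spawned from the global seed."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(STAGES, children)}


def _tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: dict, outdir: str | Path,
                 stages: list[str] | None = None) -> dict[str, Path]:
    """Execute the requested stages, writing TSV outputs and a run log."""
    cfg = merge_config(config)
    stages = stages or STAGES
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(int(cfg["seed"]))
    outputs: dict[str, Path] = {}
    loglines = [f"xautoscan {__version__}",
                f"global seed: {cfg['seed']}",
                "stage seeds: " + json.dumps(seeds),
                "config:", yaml.safe_dump(cfg, sort_keys=True).rstrip()]

    def fail(stage: str, msg: str) -> ConfigError:
        return ConfigError(f"stage {stage}: {msg}")

    t0 = time.time()
    if cfg.get("data"):
        # panels supplied as files instead of simulated
        from .io import load_panel, read_outgroup
        data = cfg["data"]
        for field in ("x_vcf", "auto_vcf", "samples", "outgroup"):
            if field not in data:
                raise fail("load", f"config data section missing "
                           f"required field {field!r}")
        x_panel = load_panel(data["x_vcf"], data["samples"],
                             bed_path=data.get("bed"),
                             map_path=data.get("map"), x_panel=True)
        auto_panel = load_panel(data["auto_vcf"], data["samples"],
                                bed_path=data.get("bed"),
                                map_path=data.get("map"), x_panel=False)
        sim = _LoadedData(x_panel, auto_panel,
                          read_outgroup(data["outgroup"]),
                          SimConfig(**cfg.get("simulate", {})))
        loglines.append(f"loaded panels: {auto_panel.n_markers} autosomal + "
                        f"{x_panel.n_markers} X loci")
    else:
        sim_cfg = SimConfig(**{**cfg.get("simulate", {}),
                               "seed": seeds["simulate"]})
        sim = simulate_dataset(sim_cfg)
        loglines.append(f"simulate: {sim.config.n_auto_loci} autosomal + "
                        f"{sim.config.n_x_loci} X loci, F_A={sim.f_auto:.4g},"
                        f" F_X={sim.f_x:.4g}")
    if "simulate" in stages and not cfg.get("data"):
        paths = write_dataset(sim, outdir / "simulated")
        outputs.update({f"sim_{k}": v for k, v in paths.items()})

    pops = sim.x_panel.populations()
    dcfg = cfg["diff"]
    pairs = dcfg.get("pairs") or [[pops[0], pops[-1]]]
    anc = {}
    for chrom, panel in [("X", sim.x_panel), ("A1", sim.auto_panel)]:
        sub = sim.outgroup[sim.outgroup["chrom"] == chrom].reset_index(drop=True)
        anc[chrom] = assign_ancestral_alleles(panel.markers, sub)
        panel.markers["anc_state"] = anc[chrom]
        loglines.append(f"ancestral assigned on {chrom}: "
                        f"{(anc[chrom] >= 0).sum()}/{len(anc[chrom])}")

    deltas = {}
    if "diff" in stages or "taex" in stages:
        for pair in pairs:
            pa, pb = pair
            for chrom, panel, span in [
                    ("X", sim.x_panel, sim.config.x_span_bp),
                    ("A1", sim.auto_panel, sim.config.auto_span_bp)]:
                vals = delta_scan(panel, pa, pb, measure=dcfg["measure"])
                grid = make_windows(0, span, dcfg["window_bp"], chrom=chrom)
                deltas[(pa, pb, chrom)] = (vals, panel, grid)
    if "diff" in stages:
        for (pa, pb, chrom), (vals, panel, grid) in deltas.items():
            tag = f"{pa}-{pb}.{chrom}"
            persnp = panel.markers[["marker_id", "chrom", "pos_bp",
                                    "genic"]].copy()
            persnp[dcfg["measure"]] = vals.to_numpy()
            _tsv(persnp, outdir / f"diff.{tag}.persnp.tsv")
            res = call_high_and_regionize(vals.to_numpy(),
                                          panel.markers["pos_bp"].to_numpy(),
                                          grid, dcfg["threshold"])
            _tsv(res.per_region, outdir / f"diff.{tag}.regions.tsv")
            calls = make_calls(panel.markers, vals, grid, dcfg["threshold"])
            freqs = population_frequencies(panel, [pa, pb])
            summary = classify_high_delta(
                calls, freqs, pa, pb,
                derived_high_threshold=dcfg["derived_high_threshold"])
            srows = [{"key": "n_high", "value": summary.n_high},
                     {"key": "n_high_regions", "value": res.n_high_regions},
                     {"key": "genic_fraction", "value": summary.genic_fraction}]
            for pop, (k, d, f) in summary.derived_high.items():
                srows.append({"key": f"derived_high_{pop}",
                              "value": f"{k}/{d}"})
            if summary.chi2_genic:
                srows.append({"key": "chi2_genic",
                              "value": "%.4g,%.4g" % summary.chi2_genic})
            _tsv(pd.DataFrame(srows), outdir / f"diff.{tag}.summary.tsv")
            _tsv(summary.decile_enrichment,
                 outdir / f"diff.{tag}.deciles.tsv")
            loglines.append(f"diff {tag}: {res.n_high_snps} high SNPs in "
                            f"{res.n_high_regions} regions")
            outputs[f"diff_{tag}"] = outdir / f"diff.{tag}.persnp.tsv"

    if "taex" in stages:
        tcfg = cfg["taex"]
        pa, pb = pairs[0]
        a_vals, a_panel, a_grid = deltas[(pa, pb, "A1")]
        x_vals, _, _ = deltas[(pa, pb, "X")]
        res = grid_scan(a_vals.dropna().to_numpy(),
                        a_panel.markers.loc[a_vals.notna().to_numpy(),
                                            "pos_bp"].to_numpy(),
                        x_vals.dropna().to_numpy(), a_grid,
                        threshold=tcfg["threshold"],
                        test_side=tcfg["side"])
        for name, surf in [("snp_count", res.snp_count),
                           ("region_count", res.region_count),
                           ("p_value", res.p_value)]:
            surf.to_frame().to_csv(outdir / f"taex.{pa}-{pb}.{name}.tsv",
                                   sep="\t", float_format="%.6g")
            outputs[f"taex_{name}"] = outdir / f"taex.{pa}-{pb}.{name}.tsv"
        band = res.p_value.cells > 0.05
        loglines.append(f"taex {pa}-{pb}: non-rejection cells "
                        f"{int(band.sum())}/{band.size}")

    if "amova" in stages:
        acfg = cfg["amova"]
        rows = []
        for mode in acfg["modes"]:
            for chrom, panel in [("X", sim.x_panel), ("A1", sim.auto_panel)]:
                p = panel
                if mode == "diploid" and chrom == "X":
                    p = make_pseudofemales(panel, seed=seeds["amova"])
                B = int(acfg["bootstrap"])
                res = (bootstrap_ci(p, mode=mode, B=B, seed=seeds["amova"])
                       if B > 0 else amova(p, mode=mode))
                row = {"chrom": chrom, "mode": mode,
                       "n_loci": res.n_loci_used, "n_units": res.n_units,
                       "within": res.within, "among_pops": res.among_pops,
                       "among_regions": res.among_regions}
                if res.ci95:
                    for k, (lo, hi) in res.ci95.items():
                        row[f"{k}_lo"], row[f"{k}_hi"] = lo, hi
                rows.append(row)
                loglines.append(f"amova {mode} {chrom}: within "
                                f"{res.within:.2f}% over {res.n_loci_used} loci")
        _tsv(pd.DataFrame(rows), outdir / "amova.tsv")
        outputs["amova"] = outdir / "amova.tsv"

    if "selscan" in stages:
        scfg = cfg["selscan"]
        grid = make_windows(0, sim.config.x_span_bp, scfg["window_bp"],
                            chrom="X")
        regions = sim.x_panel.regions()
        pa, pb = pairs[0]
        if "ihs" in scfg["tests"]:
            for region in regions:
                df = ihs_scan(sim.x_panel, None, cutoff=scfg["ehh_cutoff"]) \
                    if region is None else \
                    ihs_scan(sim.x_panel.subset_region(region), None,
                             cutoff=scfg["ehh_cutoff"])
                _tsv(df, outdir / f"selscan.ihs.{region}.persnp.tsv")
                reg = regionize_scores(
                    df.rename(columns={"ihs": "score"}), grid,
                    mode="ihs_ratio")
                _tsv(reg, outdir / f"selscan.ihs.{region}.regions.tsv")
                top = top_regions(reg, k=scfg["top_k"])
                _tsv(top, outdir / f"selscan.ihs.{region}.top.tsv")
                loglines.append(f"selscan ihs {region}: {len(df)} scored")
                outputs[f"ihs_{region}"] = \
                    outdir / f"selscan.ihs.{region}.regions.tsv"
        if "xpehh" in scfg["tests"]:
            pair = scfg.get("xpehh_pair") or [pa, pb]
            df = xpehh_scan(sim.x_panel, sim.x_panel, pair[0], pair[1],
                            cutoff=scfg["ehh_cutoff"])
            _tsv(df, outdir / "selscan.xpehh.persnp.tsv")
            reg = regionize_scores(
                df.rename(columns={"xpehh_std": "score"}), grid,
                mode="mean_zero_fill")
            _tsv(reg, outdir / "selscan.xpehh.regions.tsv")
            _tsv(top_regions(reg, k=scfg["top_k"]),
                 outdir / "selscan.xpehh.top.tsv")
            loglines.append(f"selscan xpehh {pair[0]}-{pair[1]}: "
                            f"{len(df)} scored")
            outputs["xpehh"] = outdir / "selscan.xpehh.regions.tsv"
        if scfg.get("track"):
            from .io import read_score_track
            track = read_score_track(scfg["track"])
            reg = regionize_scores(track, grid, mode="mean")
            _tsv(reg, outdir / "selscan.track.regions.tsv")
            outputs["track"] = outdir / "selscan.track.regions.tsv"
        het = hap_het_ratio(sim.x_panel, sim.x_panel, pa, pb,
                            window_snps=scfg["hap_window_snps"])
        _tsv(het, outdir / "selscan.haphet.tsv")
        outputs["haphet"] = outdir / "selscan.haphet.tsv"

    log.info("pipeline finished in %.1f s", time.time() - t0)
    logpath = outdir / "run.log"
    logpath.write_text("\n".join(str(x) for x in loglines) + "\n")
    outputs["log"] = logpath
    return outputs
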