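"""Haplotype-based selection scans: EHH, iHH, iHS, XP-EHH, window aggregation.

EHH at distance d from a core marker is the probability that two random
haplotypes carrying the core allele are identical at every marker from the
core out to d. Integrating EHH over genetic distance (out to where it
falls below a cutoff, 0.1 here) gives iHH; the unstandardised iHS of a
marker is ln(iHH_ancestral / iHH_derived), and markers whose iHS deviates
by 2 or more from the mean of markers with the same observed derived-allele
count are flagged. XP-EHH contrasts unpartitioned integrated EHH between
two populations, ln(iHH_A / iHH_B), standardised chromosome-wide. Raw
scores are aggregated into fixed-width windows (flagged/scored ratio for
iHS, means for score tracks, zero-filled means for XP-EHH), ranked, and
candidate intervals are tested against the empirical distribution of
same-length consecutive-window averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import ANC_UNKNOWN, HaplotypePanel, PanelError, RegionGrid

log = logging.getLogger(__name__)

EHH_CUTOFF = 0.1


@dataclass
class EHHCurve:
    """EHH decay around one core marker for one allele class.

    Arrays run outward from the core (offset 0, EHH 1) separately for the
    two directions; ``reached_end`` records whether the curve was followed
    to the last marker of the chromosome on that side without dropping
    below the requested stopping value.
    """

    core_index: int
    partition: str                     # derived | ancestral | all
    n_core: int
    left_cm: np.ndarray                # distances from core, increasing
    left_ehh: np.ndarray
    right_cm: np.ndarray
    right_ehh: np.ndarray
    left_reached_end: bool
    right_reached_end: bool


def _ehh_one_side(hap: np.ndarray, cols: np.ndarray, cm: np.ndarray,
                  core_cm: float, stop_below: float | None
                  ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Walk outward over ``cols``, tracking haplotype-group homozygosity.

    Returns (distances, ehh values, reached_end). Stops early once EHH
    drops below ``stop_below`` (the crossing point is included) or hits 0.
    """
    n = hap.shape[0]
    denom = n * (n - 1)
    group = np.zeros(n, dtype=np.int64)
    dists, ehhs = [], []
    reached_end = True
    for col in cols:
        alleles = hap[:, col].astype(np.int64)
        _, group = np.unique(group * 4 + alleles + 1, return_inverse=True)
        counts = np.bincount(group)
        ehh = float((counts * (counts - 1)).sum() / denom)
        dists.append(abs(cm[col] - core_cm))
        ehhs.append(ehh)
        if ehh == 0.0 or (stop_below is not None and ehh < stop_below):
            reached_end = False
            break
    return np.asarray(dists), np.asarray(ehhs), reached_end


def ehh_curve(panel: HaplotypePanel, population: str | None,
              core_marker: int, partition: str = "all",
              stop_below: float | None = None) -> EHHCurve | None:
    """EHH decay curve around ``core_marker`` for one allele class.

    ``partition`` selects the haplotypes carrying the derived or ancestral
    core allele (requiring a known ancestral state) or all haplotypes.
    Returns None when fewer than two haplotypes carry the core allele.
    ``stop_below`` truncates each side at the first point under that value
    (the integration cutoff), saving work during scans.
    """
    rows = (panel.hap_rows(population=population) if population is not None
            else np.arange(panel.n_hap))
    core = int(core_marker)
    anc = int(panel.markers["anc_state"].iloc[core])
    if partition == "all":
        sel = rows
    else:
        if anc == ANC_UNKNOWN:
            return None
        allele = (1 - anc) if partition == "derived" else anc
        sel = rows[panel.haplotypes[rows, core] == allele]
    if len(sel) < 2:
        return None
    hap = panel.haplotypes[sel]
    cm = panel.markers["pos_cm"].to_numpy()
    core_cm = cm[core]
    left_cols = np.arange(core - 1, -1, -1)
    right_cols = np.arange(core + 1, panel.n_markers)
    lcm, lehh, lend = _ehh_one_side(hap, left_cols, cm, core_cm, stop_below)
    rcm, rehh, rend = _ehh_one_side(hap, right_cols, cm, core_cm, stop_below)
    return EHHCurve(core_index=core, partition=partition, n_core=len(sel),
                    left_cm=lcm, left_ehh=lehh,
                    right_cm=rcm, right_ehh=rehh,
                    left_reached_end=lend if len(left_cols) else True,
                    right_reached_end=rend if len(right_cols) else True)


def _side_area(cm: np.ndarray, ehh: np.ndarray, cutoff: float,
               reached_end: bool) -> float | None:
    """Trapezoidal area from the core to the first point below ``cutoff``.

    None (undefined) when the curve never falls below the cutoff before
    the last marker on this side — scores cannot be computed near the
    chromosome ends.
    """
    x = np.concatenate([[0.0], cm])
    y = np.concatenate([[1.0], ehh])
    below = np.flatnonzero(y < cutoff)
    if len(below) == 0:
        if reached_end:
            return None
        # curve was truncated by stop_below yet nothing under the cutoff:
        # treat as reaching the end (caller passed a smaller stop value)
        return None
    stop = below[0]
    return float(np.trapezoid(y[:stop + 1], x[:stop + 1]))


def ihh(curve: EHHCurve, cutoff: float = EHH_CUTOFF) -> float | None:
    """Integrated EHH: two-sided trapezoidal area out to the cutoff.

    Absent (None) when EHH stays at or above the cutoff through the last
    marker on either side.
    """
    left = _side_area(curve.left_cm, curve.left_ehh, cutoff,
                      curve.left_reached_end)
    right = _side_area(curve.right_cm, curve.right_ehh, cutoff,
                       curve.right_reached_end)
    if left is None or right is None:
        return None
    return left + right


def ihs_scan(panel: HaplotypePanel, population: str | None = None,
             cutoff: float = EHH_CUTOFF, flag_deviation: float = 2.0,
             freq_bin_width: float | None = None) -> pd.DataFrame:
    """Raw iHS per marker plus the frequency-centred high-iHS flag.

    raw iHS = ln(iHH_ancestral / iHH_derived). Markers are grouped by the
    observed derived-allele count (or by derived-frequency bins of width
    ``freq_bin_width`` when given) and flagged iff their score differs
    from the group mean by at least ``flag_deviation``. Markers with an
    unknown ancestral state, a monomorphic core, or an undefined or zero
    iHH on either side get no score.
    """
    if population is not None:
        panel = panel.subset_population(population)
    rows = np.arange(panel.n_hap)
    anc_states = panel.markers["anc_state"].to_numpy()
    out = []
    for j in range(panel.n_markers):
        anc = int(anc_states[j])
        if anc == ANC_UNKNOWN:
            continue
        derived = 1 - anc
        dcount = int((panel.haplotypes[rows, j] == derived).sum())
        c_der = ehh_curve(panel, None, j, "derived", stop_below=cutoff)
        c_anc = ehh_curve(panel, None, j, "ancestral", stop_below=cutoff)
        if c_der is None or c_anc is None:
            continue
        ihh_d = ihh(c_der, cutoff)
        ihh_a = ihh(c_anc, cutoff)
        if not ihh_d or not ihh_a:  # absent or zero
            continue
        out.append({"marker": j,
                    "marker_id": panel.markers["marker_id"].iloc[j],
                    "pos_bp": int(panel.markers["pos_bp"].iloc[j]),
                    "derived_count": dcount,
                    "ihs": float(np.log(ihh_a / ihh_d))})
    df = pd.DataFrame(out, columns=["marker", "marker_id", "pos_bp",
                                    "derived_count", "ihs"])
    if df.empty:
        df["group_mean"] = df["high"] = []
        return df
    if freq_bin_width:
        n_rows = len(rows)
        group = np.floor(df["derived_count"] / n_rows / freq_bin_width)
    else:
        group = df["derived_count"]
    df["group_mean"] = df.groupby(group)["ihs"].transform("mean")
    df["high"] = (df["ihs"] - df["group_mean"]).abs() >= flag_deviation
    return df


def xpehh_scan(panel_a: HaplotypePanel, panel_b: HaplotypePanel,
               pop_a: str | None = None, pop_b: str | None = None,
               cutoff: float = EHH_CUTOFF) -> pd.DataFrame:
    """Raw and chromosome-standardised XP-EHH per marker.

    Unpartitioned EHH is integrated per population with the same cutoff
    and boundary rules as iHS; raw = ln(iHH_A / iHH_B), standardised to
    mean 0 and unit variance over the scored markers. Swapping the panels
    negates the raw score.
    """
    if panel_a.n_markers != panel_b.n_markers:
        raise PanelError("panels must share the same marker set")
    if pop_a is not None:
        panel_a = panel_a.subset_population(pop_a)
    if pop_b is not None:
        panel_b = panel_b.subset_population(pop_b)
    out = []
    for j in range(panel_a.n_markers):
        ca = ehh_curve(panel_a, None, j, "all", stop_below=cutoff)
        cb = ehh_curve(panel_b, None, j, "all", stop_below=cutoff)
        if ca is None or cb is None:
            continue
        ia, ib = ihh(ca, cutoff), ihh(cb, cutoff)
        if not ia or not ib:
            continue
        out.append({"marker": j,
                    "marker_id": panel_a.markers["marker_id"].iloc[j],
                    "pos_bp": int(panel_a.markers["pos_bp"].iloc[j]),
                    "xpehh_raw": float(np.log(ia / ib))})
    df = pd.DataFrame(out, columns=["marker", "marker_id", "pos_bp",
                                    "xpehh_raw"])
    if len(df):
        sd = df["xpehh_raw"].std(ddof=0)
        df["xpehh_std"] = ((df["xpehh_raw"] - df["xpehh_raw"].mean())
                           / (sd if sd > 0 else 1.0))
    else:
        df["xpehh_std"] = []
    return df


def regionize_scores(scores: pd.DataFrame, grid: RegionGrid,
                     mode: str = "mean") -> pd.DataFrame:
    """Aggregate per-marker scores into the grid's windows.

    ``scores`` needs columns pos_bp and score (plus a boolean ``high`` for
    mode 'ihs_ratio'). Modes: ``ihs_ratio`` = flagged/scored per window
    (NaN when nothing scored); ``mean`` = average raw score (NaN when
    empty); ``mean_zero_fill`` = mean with empty windows set to 0 (the
    XP-EHH boundary rule). Returns one row per window with n_snps_scored
    and dense ranks (1 = highest score, NaN windows unranked).
    """
    pos = scores["pos_bp"].to_numpy()
    win = grid.assign(pos)
    if np.any(win < 0):
        raise PanelError("scores fall outside the window span")
    n = grid.n_windows
    n_scored = np.bincount(win, minlength=n)
    val = np.full(n, np.nan)
    if mode == "ihs_ratio":
        if "high" not in scores:
            raise PanelError("mode ihs_ratio needs a boolean 'high' column")
        n_high = np.bincount(win, weights=scores["high"].to_numpy(float),
                             minlength=n)
        nz = n_scored > 0
        val[nz] = n_high[nz] / n_scored[nz]
    elif mode in ("mean", "mean_zero_fill"):
        tot = np.bincount(win, weights=scores["score"].to_numpy(float),
                          minlength=n)
        nz = n_scored > 0
        val[nz] = tot[nz] / n_scored[nz]
        if mode == "mean_zero_fill":
            val[~nz] = 0.0
    else:
        raise PanelError(f"unknown aggregation mode {mode!r}")
    df = pd.DataFrame({"window": np.arange(n), "start": grid.starts,
                       "end": grid.ends, "score": val,
                       "n_snps_scored": n_scored})
    order = np.argsort(-df["score"].to_numpy(), kind="stable")
    rank = np.full(n, np.nan)
    scored = ~np.isnan(df["score"].to_numpy())
    rank[order[np.isin(order, np.flatnonzero(scored))]] = \
        np.arange(1, scored.sum() + 1)
    df["rank"] = rank
    return df


def top_regions(region_scores: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """The k highest-scoring windows, rank 1 first; ties broken by the
    smaller start coordinate. Returns all scored windows (logged) when
    fewer than k carry a score."""
    scored = region_scores.dropna(subset=["score"])
    if scored.empty:
        raise PanelError("no scored windows")
    if len(scored) < k:
        log.info("only %d scored windows for top-%d request",
                 len(scored), k)
    top = scored.sort_values(["score", "start"],
                             ascending=[False, True]).head(k)
    return top.reset_index(drop=True)


def empirical_window_test(scores: np.ndarray, start: int,
                          k: int) -> tuple[float, bool]:
    """Percentile of a k-window mean among all other k-window means.

    The mean of ``scores[start:start+k]`` is compared to the means of every
    other length-k consecutive window (sliding, overlapping, the interval
    itself excluded); the percentile is the fraction strictly below, and
    the interval is flagged elevated iff that fraction exceeds 0.95.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if k >= n:
        raise PanelError(f"window length {k} must be below the track "
                         f"length {n}")
    if not (0 <= start <= n - k):
        raise PanelError("interval falls outside the score track")
    means = np.convolve(scores, np.ones(k) / k, mode="valid")
    target = means[start]
    others = np.delete(means, start)
    percentile = float((others < target).mean())
    return percentile, percentile > 0.95


def hap_het_ratio(panel_a: HaplotypePanel, panel_b: HaplotypePanel,
                  pop_a: str | None = None, pop_b: str | None = None,
                  window_snps: int = 5,
                  unbiased: bool = False) -> pd.DataFrame:
    """Ratio of multi-SNP haplotype heterozygosities along the chromosome.

    For every run of ``window_snps`` consecutive markers, haplotype
    heterozygosity H = 1 - sum p_h^2 over observed window-haplotype
    frequencies is computed in each population; the ratio H_B / H_A is
    positioned at the centre SNP and left NaN where H_A = 0.
    ``unbiased`` applies the n/(n-1) small-sample correction.
    """
    if window_snps < 2:
        raise PanelError("window_snps must be >= 2")
    if panel_a.n_markers != panel_b.n_markers:
        raise PanelError("panels must share the same marker set")
    rows_a = (panel_a.hap_rows(population=pop_a) if pop_a is not None
              else np.arange(panel_a.n_hap))
    rows_b = (panel_b.hap_rows(population=pop_b) if pop_b is not None
              else np.arange(panel_b.n_hap))

    def het(block: np.ndarray) -> float:
        _, counts = np.unique(block, axis=0, return_counts=True)
        freqs = counts / counts.sum()
        h = 1.0 - float((freqs ** 2).sum())
        if unbiased:
            nh = counts.sum()
            h *= nh / (nh - 1)
        return h

    m = panel_a.n_markers
    out = []
    for i in range(m - window_snps + 1):
        sl = slice(i, i + window_snps)
        ha = het(panel_a.haplotypes[rows_a, sl])
        hb = het(panel_b.haplotypes[rows_b, sl])
        centre = i + window_snps // 2
        out.append({"center_marker": centre,
                    "pos_bp": int(panel_a.markers["pos_bp"].iloc[centre]),
                    "het_a": ha, "het_b": hb,
                    "ratio": hb / ha if ha > 0 else np.nan})
    return pd.DataFrame(out)
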