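"""Core data model: sample and marker tables, phased haplotype panels, genomic windows.

All coordinates are 0-based half-open internally; VCF (1-based) and BED
(0-based half-open) conventions are converted at the file boundary in
:mod:`xautoscan.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SEX_FEMALE = "female"
SEX_MALE = "male"

#: sentinel for an unknown ancestral state in ``markers["anc_state"]``
ANC_UNKNOWN = -1
#: sentinel for a missing allele in the haplotype matrix
MISSING = -1

SAMPLE_COLUMNS = ["sample_id", "sex", "population", "region"]
MARKER_COLUMNS = ["marker_id", "chrom", "pos_bp", "pos_cm", "ref", "alt",
                  "anc_state", "genic"]


class PanelError(ValueError):
    """Raised when an input violates the data-model invariants."""


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample table (sample_id, sex, population, region).

    sample_ids must be unique, sexes must be female/male, and every
    population must map to exactly one continental region.
    """
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise PanelError(f"sample table missing columns: {missing}")
    samples = samples[SAMPLE_COLUMNS].reset_index(drop=True)
    if samples["sample_id"].duplicated().any():
        dupes = samples.loc[samples["sample_id"].duplicated(), "sample_id"]
        raise PanelError(f"duplicate sample ids: {sorted(set(dupes))}")
    bad_sex = set(samples["sex"]) - {SEX_FEMALE, SEX_MALE}
    if bad_sex:
        raise PanelError(f"sex must be female/male, got: {sorted(bad_sex)}")
    pop_regions = samples.groupby("population")["region"].nunique()
    multi = pop_regions[pop_regions > 1]
    if len(multi):
        raise PanelError(
            f"populations mapped to more than one region: {list(multi.index)}")
    return samples


def validate_markers(markers: pd.DataFrame) -> pd.DataFrame:
    """Validate a marker table: sorted by (chrom, pos_bp), cM non-decreasing."""
    missing = [c for c in MARKER_COLUMNS if c not in markers.columns]
    if missing:
        raise PanelError(f"marker table missing columns: {missing}")
    markers = markers[MARKER_COLUMNS].reset_index(drop=True)
    if (markers["pos_bp"] < 0).any():
        raise PanelError("pos_bp must be >= 0")
    for chrom, sub in markers.groupby("chrom", sort=False):
        if not sub["pos_bp"].is_monotonic_increasing:
            raise PanelError(f"markers on {chrom} not sorted by pos_bp")
        cm = sub["pos_cm"].dropna()
        if len(cm) and not cm.is_monotonic_increasing:
            raise PanelError(f"pos_cm not non-decreasing on {chrom}")
    return markers


@dataclass
class HaplotypePanel:
    """Phased haplotype matrix with per-row sample labels and marker metadata.

    Parameters
    ----------
    haplotypes
        ``(n_hap, n_markers)`` int8 matrix of 0/1 alleles (``MISSING`` = -1),
        one row per chromosome copy.
    markers
        Marker table (see :data:`MARKER_COLUMNS`).
    samples
        Sample table (see :data:`SAMPLE_COLUMNS`).
    row_sample
        sample_id of each haplotype row.
    row_copy
        copy index (0 or 1) of each haplotype row within its sample.

    On an X panel males contribute exactly one row and females two; on an
    autosomal panel everyone contributes two.
    """

    haplotypes: np.ndarray
    markers: pd.DataFrame
    samples: pd.DataFrame
    row_sample: np.ndarray
    row_copy: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.row_sample = np.asarray(self.row_sample, dtype=object)
        self.row_copy = np.asarray(self.row_copy, dtype=np.int8)
        self.samples = validate_samples(self.samples)
        self.markers = validate_markers(self.markers)
        if self.haplotypes.shape != (len(self.row_sample), len(self.markers)):
            raise PanelError(
                f"haplotype matrix shape {self.haplotypes.shape} does not match "
                f"{len(self.row_sample)} rows x {len(self.markers)} markers")
        known = set(self.samples["sample_id"])
        unknown = set(self.row_sample) - known
        if unknown:
            raise PanelError(f"haplotype rows for unlisted samples: {sorted(unknown)}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    def ploidy(self) -> pd.Series:
        """Number of haplotype rows per sample (1 or 2)."""
        return pd.Series(self.row_sample).value_counts().reindex(
            self.samples["sample_id"], fill_value=0)

    # -- row selection --------------------------------------------------
    def _sample_attr(self) -> pd.DataFrame:
        attr = self.samples.set_index("sample_id")
        return attr.loc[self.row_sample].reset_index()

    def hap_rows(self, population: str | None = None,
                 region: str | None = None,
                 sex: str | None = None) -> np.ndarray:
        """Indices of haplotype rows matching the given labels."""
        attr = self._sample_attr()
        mask = np.ones(self.n_hap, dtype=bool)
        if population is not None:
            mask &= (attr["population"] == population).to_numpy()
        if region is not None:
            mask &= (attr["region"] == region).to_numpy()
        if sex is not None:
            mask &= (attr["sex"] == sex).to_numpy()
        return np.flatnonzero(mask)

    def row_population(self) -> np.ndarray:
        return self._sample_attr()["population"].to_numpy()

    def row_region(self) -> np.ndarray:
        return self._sample_attr()["region"].to_numpy()

    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.samples["population"]))

    def regions(self) -> list[str]:
        return list(dict.fromkeys(self.samples["region"]))

    # -- subsetting -----------------------------------------------------
    def subset(self, rows: np.ndarray | None = None,
               marker_mask: np.ndarray | None = None) -> "HaplotypePanel":
        """Return a panel restricted to the given rows and/or markers."""
        if rows is None:
            rows = np.arange(self.n_hap)
        rows = np.asarray(rows)
        hap = self.haplotypes[rows]
        row_sample = self.row_sample[rows]
        row_copy = self.row_copy[rows]
        markers = self.markers
        if marker_mask is not None:
            hap = hap[:, marker_mask]
            markers = self.markers.loc[np.asarray(marker_mask)].reset_index(drop=True)
        keep = self.samples["sample_id"].isin(set(row_sample))
        samples = self.samples.loc[keep].reset_index(drop=True)
        return HaplotypePanel(hap, markers, samples, row_sample, row_copy)

    def subset_population(self, population: str) -> "HaplotypePanel":
        return self.subset(rows=self.hap_rows(population=population))

    def subset_region(self, region: str) -> "HaplotypePanel":
        return self.subset(rows=self.hap_rows(region=region))


@dataclass(frozen=True)
class RegionGrid:
    """Non-overlapping fixed-width windows tiling ``[span_start, span_end)``.

    Windows are half-open ``[start, start + window_bp)`` anchored at the span
    start; the last window may be shorter. A marker sitting exactly on a
    boundary belongs to the right-hand window.
    """

    chrom: str
    span_start: int
    span_end: int
    window_bp: int

    @property
    def n_windows(self) -> int:
        return math.ceil((self.span_end - self.span_start) / self.window_bp)

    @property
    def starts(self) -> np.ndarray:
        return self.span_start + self.window_bp * np.arange(self.n_windows)

    @property
    def ends(self) -> np.ndarray:
        return np.minimum(self.starts + self.window_bp, self.span_end)

    def assign(self, pos_bp: np.ndarray) -> np.ndarray:
        """Window index for each position; -1 for positions outside the span."""
        pos = np.asarray(pos_bp, dtype=np.int64)
        idx = (pos - self.span_start) // self.window_bp
        idx[(pos < self.span_start) | (pos >= self.span_end)] = -1
        return idx


def make_windows(span_start: int, span_end: int, window_bp: int,
                 chrom: str = "X") -> RegionGrid:
    """Tile ``[span_start, span_end)`` into ``ceil(span/window_bp)`` windows.

    Raises :class:`PanelError` for a non-positive window or empty span.
    """
    if window_bp <= 0:
        raise PanelError(f"window_bp must be positive, got {window_bp}")
    if span_end <= span_start:
        raise PanelError(
            f"span_end ({span_end}) must exceed span_start ({span_start})")
    return RegionGrid(chrom=chrom, span_start=int(span_start),
                      span_end=int(span_end), window_bp=int(window_bp))


#: non-pseudoautosomal X layout used for the packaged window counts: a
#: 148.8-Mb span tiles into 744 200-kb or 372 400-kb windows.
X_NONPAR_SPAN_BP = 148_800_000
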