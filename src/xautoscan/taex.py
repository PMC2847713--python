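"""Transformed-autosomal / expected-X (TA/EX) demographic grid inference.

Under an infinite island model at equilibrium, X-linked and autosomal
differentiation are linked through the female share of the effective
population size, x = N_f/N, and of the migration rate, y = m_f/m. The two
parameters act only through the combined term

    c(x, y) = (1 + y) / (2 - x),

and on the linearised scale F' = F/(1-F) the expected X value is

    F'_X = M(x, y) * F'_A,   with   M(x, y) = (4/3) / c(x, y).

At x = y = 0.5 (demographically balanced) M = 4/3, the classic X/autosome
ratio of effective population sizes. Mapping an observed list of autosomal
differentiation values (delta or per-site Fst) through this relation at
every (x, y) on a 99 x 99 grid, and comparing each transformed list to the
observed X-linked list, yields count and rank-sum p-value surfaces whose
non-rejection band locates the demographies consistent with the data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from math import gcd

import numpy as np
from scipy import stats

from .panel import PanelError, RegionGrid

log = logging.getLogger(__name__)

GRID_AXIS = np.round(np.arange(1, 100) / 100, 2)  # 0.01 .. 0.99


def combined_factor(x: float, y: float) -> float:
    """The combined demographic term c = (1 + m_f/m) / (2 - N_f/N)."""
    if not (0 < x < 1 and 0 < y < 1):
        raise PanelError(f"x and y must lie in (0, 1), got ({x}, {y})")
    return (1.0 + y) / (2.0 - x)


def multiplier(x: float, y: float) -> float:
    """Linearised X/autosome multiplier M = (4/3) * (2 - x)/(1 + y)."""
    return (4.0 / 3.0) / combined_factor(x, y)


def transform_autosomal(values: np.ndarray, x: float, y: float) -> np.ndarray:
    """Map autosomal differentiation values to expected X-linked (TA/EX) values.

    Elementwise ``v' = M v/(1-v) / (1 + M v/(1-v))`` with ``M = multiplier(x, y)``;
    0 and 1 are fixed points. Values outside [0, 1] are rejected.
    """
    v = np.asarray(values, dtype=np.float64)
    if np.any((v < 0) | (v > 1)):
        raise PanelError("differentiation values must lie in [0, 1]")
    m = multiplier(x, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        lin = m * v / (1.0 - v)
        out = lin / (1.0 + lin)
    out = np.where(v == 1.0, 1.0, out)
    return out


def inverse_transform_threshold(threshold: float, x: float, y: float) -> float:
    """The autosomal value whose TA/EX image equals ``threshold``.

    Because the transform is strictly increasing, ``v' > threshold`` iff
    ``v`` exceeds this preimage — used to tally high TA/EX values fast.
    """
    m = multiplier(x, y)
    if threshold >= 1.0:
        return 1.0
    lin = threshold / (1.0 - threshold) / m
    return lin / (1.0 + lin)


def wilcoxon_pvalue(a: np.ndarray, b: np.ndarray,
                    side: str = "two_sided") -> float:
    """Rank-sum (Mann-Whitney) p-value comparing lists ``a`` and ``b``.

    Tie-corrected normal approximation with continuity correction; exact
    enumeration when the combined sample size is at most 20 and tie-free.
    ``side='one_sided'`` tests ``a`` stochastically smaller than ``b``.
    All-constant input gives p = 1 with a logged warning.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        log.warning("rank-sum comparison on all-constant input; p set to 1")
        return 1.0
    alternative = {"two_sided": "two-sided", "one_sided": "less"}[side]
    small = len(pooled) <= 20 and len(np.unique(pooled)) == len(pooled)
    method = "exact" if small else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.pvalue)


@dataclass
class DemographySurface:
    """A 99 x 99 matrix over the (N_f/N, m_f/m) grid.

    ``cells[i, j]`` corresponds to x = x_axis[i], y = y_axis[j].
    """

    x_axis: np.ndarray
    y_axis: np.ndarray
    cells: np.ndarray
    cell_kind: str  # snp_count | region_count | p_value

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.cells,
                            index=np.round(self.x_axis, 2),
                            columns=np.round(self.y_axis, 2))


@dataclass
class GridScanResult:
    snp_count: DemographySurface
    region_count: DemographySurface
    p_value: DemographySurface


def _c_key(x: float, y: float) -> tuple[int, int]:
    """Exact rational key for c(x, y) on the percent grid (for caching)."""
    num, den = round(100 * (1 + y)), round(100 * (2 - x))
    g = gcd(num, den)
    return num // g, den // g


def grid_scan(auto_values: np.ndarray,
              auto_pos_bp: np.ndarray,
              observed_x_values: np.ndarray,
              grid: RegionGrid,
              threshold: float = 0.9,
              test_side: str = "two_sided",
              x_axis: np.ndarray = GRID_AXIS,
              y_axis: np.ndarray = GRID_AXIS) -> GridScanResult:
    """Scan the (N_f/N, m_f/m) grid, producing three surfaces.

    For every grid cell: (i) the number of TA/EX values exceeding
    ``threshold`` (strict), (ii) the number of autosomal windows holding at
    least one such value, and (iii) the rank-sum p-value comparing the full
    TA/EX list to the observed X-linked list. Cells sharing the same
    combined term c are computed once and therefore bit-identical.
    """
    auto_values = np.asarray(auto_values, dtype=np.float64)
    observed_x = np.asarray(observed_x_values, dtype=np.float64)
    if len(observed_x) == 0:
        raise PanelError("observed X value list is empty")
    if len(auto_values) != len(auto_pos_bp):
        raise PanelError("auto_values and auto_pos_bp lengths differ")

    win = grid.assign(np.asarray(auto_pos_bp))
    if np.any(win < 0):
        raise PanelError("autosomal markers fall outside the window span")

    # per-window maximum: a window is high iff its max value transforms high
    n_win = grid.n_windows
    win_max = np.full(n_win, -np.inf)
    np.maximum.at(win_max, win, auto_values)
    sorted_vals = np.sort(auto_values)
    sorted_win_max = np.sort(win_max[np.isfinite(win_max)])

    nx, ny = len(x_axis), len(y_axis)
    snp = np.zeros((nx, ny))
    reg = np.zeros((nx, ny))
    pvl = np.zeros((nx, ny))
    cache: dict[tuple[int, int], tuple[float, float, float]] = {}
    for i, x in enumerate(x_axis):
        for j, y in enumerate(y_axis):
            key = _c_key(x, y)
            if key not in cache:
                pre = inverse_transform_threshold(threshold, x, y)
                n_snp = len(sorted_vals) - np.searchsorted(
                    sorted_vals, pre, side="right")
                n_reg = len(sorted_win_max) - np.searchsorted(
                    sorted_win_max, pre, side="right")
                taex = transform_autosomal(auto_values, x, y)
                p = wilcoxon_pvalue(taex, observed_x, side=test_side)
                cache[key] = (float(n_snp), float(n_reg), p)
            snp[i, j], reg[i, j], pvl[i, j] = cache[key]

    return GridScanResult(
        snp_count=DemographySurface(x_axis, y_axis, snp, "snp_count"),
        region_count=DemographySurface(x_axis, y_axis, reg, "region_count"),
        p_value=DemographySurface(x_axis, y_axis, pvl, "p_value"),
    )
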