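"""Shared fixtures: hand-built toy panels and small cached simulations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from xautoscan.panel import HaplotypePanel

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


def build_panel(hap, populations, sexes, chrom="X", pos_bp=None,
                regions=None, anc_state=0, genic=False):
    """Assemble a HaplotypePanel from a raw haplotype matrix.

    ``populations``/``sexes`` are per-sample; each female contributes two
    consecutive rows and (on X) each male one, in sample order.
    """
    hap = np.asarray(hap, dtype=np.int8)
    n_markers = hap.shape[1]
    if pos_bp is None:
        pos_bp = np.arange(n_markers) * 100_000
    if regions is None:
        regions = ["r1"] * len(populations)
    x_chrom = chrom in ("X", "chrX")
    samples, row_sample, row_copy = [], [], []
    for i, (pop, sex, reg) in enumerate(zip(populations, sexes, regions)):
        sid = f"s{i + 1}"
        samples.append({"sample_id": sid, "sex": sex, "population": pop,
                        "region": reg})
        copies = 1 if (x_chrom and sex == "male") else 2
        for k in range(copies):
            row_sample.append(sid)
            row_copy.append(k)
    assert len(row_sample) == hap.shape[0], \
        f"need {len(row_sample)} rows for these samples, got {hap.shape[0]}"
    anc = np.full(n_markers, anc_state) if np.isscalar(anc_state) \
        else np.asarray(anc_state)
    gen = np.full(n_markers, genic) if np.isscalar(genic) \
        else np.asarray(genic)
    markers = pd.DataFrame({
        "marker_id": [f"m{j + 1}" for j in range(n_markers)],
        "chrom": chrom, "pos_bp": np.asarray(pos_bp),
        "pos_cm": np.asarray(pos_bp) * 1e-6,
        "ref": "A", "alt": "G", "anc_state": anc, "genic": gen,
    })
    return HaplotypePanel(hap, markers, pd.DataFrame(samples),
                          np.array(row_sample, dtype=object),
                          np.array(row_copy, dtype=np.int8))


@pytest.fixture
def tiny_x_panel():
    """2 females + 1 male, 3 X SNPs: 5 haplotype rows."""
    hap = [[0, 1, 0],   # s1 copy 0 (female)
           [1, 0, 0],   # s1 copy 1
           [1, 1, 0],   # s2 copy 0 (female)
           [1, 0, 1],   # s2 copy 1
           [1, 1, 1]]   # s3 (male)
    return build_panel(hap, ["p1", "p1", "p1"],
                       ["female", "female", "male"])


@pytest.fixture(scope="session")
def small_sim():
    """Cached 6-population simulation at balanced demography."""
    from xautoscan import SimConfig, simulate_dataset
    return simulate_dataset(SimConfig(n_auto_loci=400, n_x_loci=200,
                                      females_per_pop=10, males_per_pop=10,
                                      seed=7))
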