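"""Shared fixtures: a small two-chromosome genome and simulated data on it.

Session scope keeps the expensive pieces (contact maps, balancing) computed
once; tests that mutate state must copy first.
"""

from __future__ import annotations

import numpy as np
import pytest

from tadmut.genome import BinnedGenome
from tadmut.hic import ContactMap, kr_balance, mask_low_coverage_bins
from tadmut.simulate import SimParams, simulate_contact_map, simulate_truth


@pytest.fixture(scope="session")
def genome_small() -> BinnedGenome:
    """2 x 10 Mb at 50 kb bins: 200 bins per chromosome."""
    return BinnedGenome(("chr1", "chr2"), (10_000_000, 10_000_000), 50_000)


@pytest.fixture(scope="session")
def params_small() -> SimParams:
    return SimParams(seed=7)


@pytest.fixture(scope="session")
def truth_small(genome_small, params_small):
    return simulate_truth(genome_small, params_small)


@pytest.fixture(scope="session")
def cmap_small(genome_small, truth_small, params_small):
    return simulate_contact_map(genome_small, truth_small, params_small)


@pytest.fixture(scope="session")
def balanced_small(cmap_small):
    masked = mask_low_coverage_bins(cmap_small)
    balanced, _ = kr_balance(masked)
    return balanced


def make_balanced_map(matrix: np.ndarray, bin_size: int = 50_000) -> ContactMap:
    """Wrap a hand-built symmetric matrix as an already-balanced single-chrom map.

    Unit weights let tests exercise downstream operations on exact values
    without the balancing transform.
    """
    n = matrix.shape[0]
    genome = BinnedGenome(("chrT",), (n * bin_size,), bin_size)
    cmap = ContactMap(genome, {"chrT": np.asarray(matrix, dtype=float)})
    cmap.weights = {"chrT": np.ones(n)}
    return cmap
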