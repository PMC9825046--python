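"""Binned genome coordinate system shared by all analyses.

Every track, matrix, and interval in the package lives on a fixed-width
binning of a set of chromosomes.  Bin ``i`` of a chromosome covers the
0-based half-open interval ``[i * bin_size, min((i + 1) * bin_size, size))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class BinnedGenome:
    """A set of chromosomes cut into fixed-width bins.

    Parameters
    ----------
    chrom_names
        Chromosome labels, in a stable order.
    chrom_sizes
        Length of each chromosome in bp, parallel to ``chrom_names``.
    bin_size
        Bin width in bp (default 50 kb).
    """

    chrom_names: tuple[str, ...]
    chrom_sizes: tuple[int, ...]
    bin_size: int = 50_000
    _size_of: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        names = tuple(self.chrom_names)
        sizes = tuple(int(s) for s in self.chrom_sizes)
        if len(names) != len(sizes):
            raise ValueError("chrom_names and chrom_sizes length mismatch")
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for n, s in zip(names, sizes):
            if s < self.bin_size:
                raise ValueError(f"chromosome {n} shorter than one bin")
        object.__setattr__(self, "chrom_names", names)
        object.__setattr__(self, "chrom_sizes", sizes)
        object.__setattr__(self, "_size_of", dict(zip(names, sizes)))

    def size(self, chrom: str) -> int:
        return self._size_of[chrom]

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self._size_of[chrom] / self.bin_size)

    def bin_of(self, chrom: str, pos: int) -> int:
        """Bin index containing 0-based position ``pos``."""
        if not 0 <= pos < self._size_of[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return pos // self.bin_size

    def bin_midpoint(self, bin_index: int) -> float:
        """Genomic midpoint (bp) of a bin; used as the boundary coordinate."""
        return (bin_index + 0.5) * self.bin_size

    def bin_midpoints(self, chrom: str):
        import numpy as np

        return (np.arange(self.n_bins(chrom)) + 0.5) * self.bin_size

    def to_chrom_sizes_text(self) -> str:
        return "".join(f"{n}\t{s}\n" for n, s in zip(self.chrom_names, self.chrom_sizes))

    @classmethod
    def from_chrom_sizes_text(cls, text: str, bin_size: int = 50_000) -> "BinnedGenome":
        names, sizes = [], []
        for line in text.strip().splitlines():
            if not line.strip():
                continue
            n, s = line.split()[:2]
            names.append(n)
            sizes.append(int(s))
        return cls(tuple(names), tuple(sizes), bin_size)
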