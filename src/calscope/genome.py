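"""Binned genome coordinate model.

All coordinates are 0-based, half-open (BED convention). A genome is a set
of named chromosomes tiled by fixed-size bins; the last bin of each
chromosome may be short.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BinnedGenome"]


@dataclass(frozen=True)
class BinnedGenome:
    """Fixed-resolution binning of a genome.

    Parameters
    ----------
    chrom_names
        Ordered chromosome identifiers.
    chrom_lengths
        Length in bp of each chromosome, same order as ``chrom_names``.
    bin_size
        Bin width in bp.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int
    _n_bins: dict[str, int] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        object.__setattr__(self, "chrom_names", tuple(self.chrom_names))
        object.__setattr__(self, "chrom_lengths", tuple(int(x) for x in self.chrom_lengths))
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        n = {
            c: int(-(-l // self.bin_size))
            for c, l in zip(self.chrom_names, self.chrom_lengths)
        }
        object.__setattr__(self, "_n_bins", n)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def n_bins(self, chrom: str) -> int:
        return self._n_bins[chrom]

    @property
    def total_bins(self) -> int:
        return sum(self._n_bins.values())

    def chrom_offset(self, chrom: str) -> int:
        """Global (genome-wide) index of a chromosome's first bin."""
        off = 0
        for c in self.chrom_names:
            if c == chrom:
                return off
            off += self._n_bins[c]
        raise KeyError(chrom)

    def bins(self) -> pd.DataFrame:
        """Bin table (chrom, start, end) tiling the genome."""
        rows = []
        for c, l in zip(self.chrom_names, self.chrom_lengths):
            starts = np.arange(0, l, self.bin_size, dtype=np.int64)
            ends = np.minimum(starts + self.bin_size, l)
            rows.append(pd.DataFrame({"chrom": c, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def bin_index(self, chrom: str, pos: int) -> int:
        """Index (within chromosome) of the bin containing ``pos``."""
        if chrom not in self._n_bins:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if pos < 0 or pos >= self.lengths[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return int(pos // self.bin_size)

    def coarsen(self, factor: int) -> "BinnedGenome":
        """Same genome at ``factor``-times-larger bins."""
        if factor < 1 or factor != int(factor):
            raise ValueError("factor must be a positive integer")
        return BinnedGenome(self.chrom_names, self.chrom_lengths, self.bin_size * int(factor))

    def __eq__(self, other):
        return (
            isinstance(other, BinnedGenome)
            and self.chrom_names == other.chrom_names
            and self.chrom_lengths == other.chrom_lengths
            and self.bin_size == other.bin_size
        )

    def __hash__(self):
        return hash((self.chrom_names, self.chrom_lengths, self.bin_size))
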