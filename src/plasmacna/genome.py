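"""Autosomal bin grid: fixed-width genomic bins and blacklist masking.

Shallow-WGS copy-number analysis of cell-free DNA works on a fixed grid of
1 Mb bins tiling the autosomes.  A subset of bins falling in poorly mappable
regions (centromeres, telomeres) is excluded via a BED blacklist; all
downstream statistics are computed over the remaining *usable* bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: GRCh37/hg19 autosome lengths in bp (UCSC chromInfo).
HG19_AUTOSOMES: tuple[tuple[str, int], ...] = (
    ("chr1", 249250621),
    ("chr2", 243199373),
    ("chr3", 198022430),
    ("chr4", 191154276),
    ("chr5", 180915260),
    ("chr6", 171115067),
    ("chr7", 159138663),
    ("chr8", 146364022),
    ("chr9", 141213431),
    ("chr10", 135534747),
    ("chr11", 135006516),
    ("chr12", 133851895),
    ("chr13", 115169878),
    ("chr14", 107349540),
    ("chr15", 102531392),
    ("chr16", 90354753),
    ("chr17", 81195210),
    ("chr18", 78077248),
    ("chr19", 59128983),
    ("chr20", 63025520),
    ("chr21", 48129895),
    ("chr22", 51304566),
)

DEFAULT_BIN_SIZE = 1_000_000


@dataclass(frozen=True)
class GenomeBuild:
    """An ordered set of autosomes (name, length in bp)."""

    name: str
    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome build has no chromosomes")
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in build")
        for chrom, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def length_of(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)


def hg19() -> GenomeBuild:
    """The hg19 autosomal build (chr1..chr22)."""
    return GenomeBuild("hg19", HG19_AUTOSOMES)


def toy_genome(n_chroms: int = 4, chrom_length: int = 50_000_000,
               name: str = "toy") -> GenomeBuild:
    """A small synthetic build for tests and examples (chrT1..chrTn)."""
    return GenomeBuild(
        name, tuple((f"chrT{i + 1}", chrom_length) for i in range(n_chroms))
    )


@dataclass
class BinSet:
    """Ordered, non-overlapping fixed-width bins tiling each autosome.

    Coordinates are 0-based half-open.  Only the last bin of a chromosome
    may be shorter than ``bin_size``.  ``usable`` marks bins that survive
    blacklist exclusion and carry valid GC content.
    """

    chroms: np.ndarray          # object array of chromosome names, per bin
    starts: np.ndarray          # int64
    ends: np.ndarray            # int64
    usable: np.ndarray          # bool
    bin_size: int
    build_name: str = "custom"

    def __post_init__(self) -> None:
        n = len(self.chroms)
        if not (len(self.starts) == len(self.ends) == len(self.usable) == n):
            raise ValueError("bin arrays have mismatched lengths")
        if np.any(self.starts >= self.ends):
            raise ValueError("bins must have start < end")
        if np.any(self.ends - self.starts > self.bin_size):
            raise ValueError("bin wider than bin_size")

    def __len__(self) -> int:
        return len(self.chroms)

    @property
    def n_usable(self) -> int:
        return int(self.usable.sum())

    @property
    def widths(self) -> np.ndarray:
        return self.ends - self.starts

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous index slice per chromosome, in grid order."""
        out: dict[str, slice] = {}
        i = 0
        while i < len(self):
            chrom = self.chroms[i]
            j = i
            while j < len(self) and self.chroms[j] == chrom:
                j += 1
            out[chrom] = slice(i, j)
            i = j
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chroms,
                "start": self.starts,
                "end": self.ends,
                "index": np.arange(len(self)),
                "usable": self.usable.astype(int),
            }
        )

    def copy(self) -> "BinSet":
        return BinSet(
            self.chroms.copy(), self.starts.copy(), self.ends.copy(),
            self.usable.copy(), self.bin_size, self.build_name,
        )


def make_bins(build: GenomeBuild, bin_size: int = DEFAULT_BIN_SIZE) -> BinSet:
    """Tile every autosome of ``build`` with fixed-width bins.

    Each chromosome gets ``ceil(length / bin_size)`` bins; the final bin is
    truncated at the chromosome end.  All bins start out usable.
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for chrom, length in build.chromosomes:
        n_bins = -(-length // bin_size)  # ceil division
        for k in range(n_bins):
            chroms.append(chrom)
            starts.append(k * bin_size)
            ends.append(min((k + 1) * bin_size, length))
    return BinSet(
        chroms=np.array(chroms, dtype=object),
        starts=np.array(starts, dtype=np.int64),
        ends=np.array(ends, dtype=np.int64),
        usable=np.ones(len(chroms), dtype=bool),
        bin_size=bin_size,
        build_name=build.name,
    )


def apply_blacklist(binset: BinSet, regions: list[tuple[str, int, int]]) -> BinSet:
    """Mark bins overlapping any blacklist interval (by >= 1 bp) unusable.

    ``regions`` are BED-style (chrom, start, end) half-open intervals.
    Intervals on chromosomes absent from the grid are skipped with a
    warning.  Returns a new BinSet; existing unusable flags are preserved.
    """
    out = binset.copy()
    slices = binset.chrom_slices()
    for chrom, start, end in regions:
        if chrom not in slices:
            logger.warning("blacklist interval on unknown chromosome %s skipped", chrom)
            continue
        if end <= start:
            continue
        sl = slices[chrom]
        # overlap: bin.start < end and bin.end > start
        hit = (binset.starts[sl] < end) & (binset.ends[sl] > start)
        out.usable[sl] = out.usable[sl] & ~hit
    return out
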