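"""Per-bin read counting from aligned reads, and per-bin GC content.

Reads are assigned to the bin containing their leftmost aligned base.  A
read is retained iff it is mapped, primary (not secondary, not
supplementary), not flagged as a duplicate, and has mapping quality at or
above the threshold (default 60, which with BWA-MEM keeps uniquely mapped
reads).  Duplicate flags are consumed as written by the upstream
deduplicator; no re-deduplication happens here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pysam

from .genome import BinSet

logger = logging.getLogger(__name__)

DEFAULT_MAPQ_MIN = 60

STAGE_RAW = "raw"
STAGE_GC_CORRECTED = "gc_corrected"
STAGE_NORMALIZED = "normalized_percent"


@dataclass
class BinCounts:
    """Per-bin values for one sample at a given pipeline stage.

    ``values`` is aligned to a BinSet; raw counts are integers stored as
    floats, GC-corrected counts are fractional, and at the
    ``normalized_percent`` stage the usable bins sum to 100.  Unusable bins
    hold NaN from the GC-correction stage onward.
    """

    sample_id: str
    values: np.ndarray
    stage: str = STAGE_RAW

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if np.any(finite < 0):
            raise ValueError("bin counts must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    def total(self, usable: np.ndarray | None = None) -> float:
        v = self.values if usable is None else self.values[usable]
        return float(np.nansum(v))


@dataclass
class GcTrack:
    """Per-bin GC fraction (over non-N bases) and fraction of N bases.

    Bins that are entirely N have ``gc`` = NaN; downstream steps demote
    them to unusable.
    """

    gc: np.ndarray
    n_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.gc = np.asarray(self.gc, dtype=float)
        self.n_fraction = np.asarray(self.n_fraction, dtype=float)
        finite = self.gc[np.isfinite(self.gc)]
        if np.any((finite < 0) | (finite > 1)):
            raise ValueError("gc fractions must lie in [0, 1]")


def count_reads(alignments: str, binset: BinSet,
                mapq_min: int = DEFAULT_MAPQ_MIN,
                sample_id: str | None = None) -> BinCounts:
    """Count retained reads per bin from a SAM/BAM file.

    Each retained alignment record is counted once, in the bin containing
    its leftmost aligned base (0-based).  Reads on contigs absent from the
    bin grid are skipped and tallied in a log counter.
    """
    if len(binset) == 0:
        raise ValueError("empty bin set")
    counts = np.zeros(len(binset), dtype=np.int64)
    slices = binset.chrom_slices()
    # per-chromosome offset and bin starts for O(log n) assignment
    chrom_info = {
        chrom: (sl.start, binset.starts[sl], binset.ends[sl])
        for chrom, sl in slices.items()
    }
    off_contig = 0
    mode = "rb" if str(alignments).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(alignments), mode, check_sq=False) as af:
        for read in af.fetch(until_eof=True):
            if (read.is_unmapped or read.is_secondary or read.is_supplementary
                    or read.is_duplicate):
                continue
            if read.mapping_quality < mapq_min:
                continue
            chrom = read.reference_name
            if chrom not in chrom_info:
                off_contig += 1
                continue
            offset, starts, ends = chrom_info[chrom]
            pos = read.reference_start
            k = int(np.searchsorted(starts, pos, side="right")) - 1
            if k < 0 or pos >= ends[k]:
                off_contig += 1
                continue
            counts[offset + k] += 1
    if off_contig:
        logger.info("count_reads: %d reads skipped (contig not in bin grid)",
                    off_contig)
    if sample_id is None:
        sample_id = str(alignments)
    return BinCounts(sample_id=sample_id, values=counts.astype(float),
                     stage=STAGE_RAW)


def compute_gc(reference: str, binset: BinSet) -> GcTrack:
    """GC fraction per bin from a FASTA reference.

    gc = (G+C) / (A+C+G+T) over the bin; bases other than ACGT count toward
    ``n_fraction``.  A bin with no unambiguous bases gets gc = NaN.
    """
    gc = np.full(len(binset), np.nan)
    n_frac = np.zeros(len(binset))
    with pysam.FastaFile(str(reference)) as fa:
        present = set(fa.references)
        missing = set(binset.chrom_slices()) - present
        if missing:
            raise ValueError(f"reference missing chromosomes: {sorted(missing)}")
        for i in range(len(binset)):
            seq = fa.fetch(binset.chroms[i], int(binset.starts[i]),
                           int(binset.ends[i])).upper()
            total = len(seq)
            if total == 0:
                continue
            a = seq.count("A")
            c = seq.count("C")
            g = seq.count("G")
            t = seq.count("T")
            acgt = a + c + g + t
            n_frac[i] = (total - acgt) / total
            if acgt > 0:
                gc[i] = (g + c) / acgt
    return GcTrack(gc=gc, n_fraction=n_frac)
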