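"""Per-bin read counting from a SAM file, with the retention filters.

Builds a 2-chromosome toy genome, renders known bin counts as SAM records
(plus decoy reads: MAPQ 30 and duplicate-flagged, which counting must
drop), and verifies the counts round-trip exactly.
"""

import tempfile
from pathlib import Path

import numpy as np

import plasmacna as pc
from plasmacna.simulate import simulate_sam

build = pc.toy_genome(2, 3_000_000)
binset = pc.make_bins(build)
wanted = pc.BinCounts("demo", np.array([12, 0, 5, 7, 0, 3], dtype=float))

sam_text = simulate_sam(binset, wanted, n_decoy_lowmapq=10,
                        n_decoy_duplicate=10)
with tempfile.TemporaryDirectory() as d:
    sam = Path(d) / "demo.sam"
    sam.write_text(sam_text)
    counts = pc.count_reads(str(sam), binset, mapq_min=60, sample_id="demo")

print("bins (chrom:start):",
      [f"{c}:{s // 1_000_000}Mb" for c, s in zip(binset.chroms, binset.starts)])
print("simulated counts:  ", wanted.values.astype(int).tolist())
print("recovered counts:  ", counts.values.astype(int).tolist())
print("decoy reads written: 20, counted:",
      int(counts.total() - wanted.values.sum()),
      "(low-MAPQ and duplicate-flagged reads are rejected)")
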