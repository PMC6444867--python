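"""Synthetic cohorts with known ground truth for every pipeline stage.

Generates the inputs a cfDNA instability study consumes: a healthy control
panel of noisy bin counts sharing a smooth GC bias, patient samples whose
counts carry arm-level gains and losses diluted by a tumor-fraction
parameter, tiny SAM fixtures for the read counter, duplex droplet counts
under the Poisson partitioning model, and survival times whose hazard
depends on biomarker group with a configurable hazard ratio.

The count model is a diploid-relative admixture: a bin with tumor copy
state ``c`` in a sample with tumor fraction ``tf`` has expected depth
proportional to ``bin_width * gc_bias(gc) * (1 + tf * (c - 2) / 2)``.
Counts are negative-binomial (Gamma-Poisson) so that panel SDs exceed the
Poisson floor, as they do in real shallow-WGS panels.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counting import STAGE_RAW, BinCounts, GcTrack
from .ddpcr import DropletCounts
from .genome import BinSet, GenomeBuild, make_bins, toy_genome

# approximate hg19 centromere midpoints used for arm-level default segments
_HG19_CENTROMERE = {"chr1": 125_000_000, "chr4": 50_400_000, "chr8": 45_600_000}


def default_cna_segments(build: GenomeBuild) -> list[tuple[str, int, int, int]]:
    """Arm-level scenario: gains of 1q and 8q, losses of 1p, 4q and 8p.

    For non-hg19 builds the same pattern is mapped onto the first three
    chromosomes: gain of the second half of chrom 1, loss of the first half
    of chrom 2, loss of the second half of chrom 3 (as available).
    """
    if build.name == "hg19":
        len1 = build.length_of("chr1")
        len4 = build.length_of("chr4")
        len8 = build.length_of("chr8")
        c1, c4, c8 = (_HG19_CENTROMERE[c] for c in ("chr1", "chr4", "chr8"))
        return [
            ("chr1", 0, c1, 1),        # -1p
            ("chr1", c1, len1, 3),     # +1q
            ("chr4", c4, len4, 1),     # -4q
            ("chr8", 0, c8, 1),        # -8p
            ("chr8", c8, len8, 3),     # +8q
        ]
    segs: list[tuple[str, int, int, int]] = []
    states = [3, 1, 1]  # gain, loss, loss
    for (chrom, length), state, second_half in zip(
            build.chromosomes[:3], states, (True, False, True)):
        half = length // 2
        segs.append((chrom, half, length, state) if second_half
                    else (chrom, 0, half, state))
    return segs


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, with study-like defaults.

    The defaults mirror the study design this generator emulates: a panel
    of 14 healthy controls, arm-level gains/losses (+1q, +8q, -1p, -4q,
    -8p), 20,000-droplet ddPCR wells, and survival with a hazard ratio of
    3.5 between biomarker groups (low-group medians 4.1 months for time to
    progression and 14.8 months for overall survival).
    """

    seed: int = 0
    genome: GenomeBuild = field(default_factory=toy_genome)
    bin_size: int = 1_000_000
    n_controls: int = 14
    n_patients: int = 20
    reads_per_sample: float = 3_000_000.0
    # polynomial coefficients of the GC bias on gc in [0,1], low order first;
    # default is a smooth concave curve equal to 1 at gc = 0.45
    gc_bias: tuple[float, ...] = (0.49375, 2.25, -2.5)
    dispersion: float = 0.01
    cna_segments: list[tuple[str, int, int, int]] | None = None
    tumor_fractions: tuple[float, ...] | None = None
    # ddPCR
    n_droplets: int = 20_000
    reference_lambda: float = 0.15
    # survival
    group_hr: float = 3.5
    ttp_median_months: float = 4.1
    os_median_months: float = 14.8
    censoring_rate: float = 0.2
    frailty_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.dispersion:
            raise ValueError("dispersion must be positive")
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")
        if self.tumor_fractions is not None:
            tf = np.asarray(self.tumor_fractions, dtype=float)
            if np.any((tf < 0) | (tf >= 1)):
                raise ValueError("tumor fractions must lie in [0, 1)")
        if self.cna_segments is not None:
            for chrom, start, end, state in self.cna_segments:
                if state == 2:
                    raise ValueError("listed CNA segments must be non-diploid")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")


@dataclass
class GroundTruth:
    """What the generator actually did, for oracle-style assertions."""

    tumor_fractions: np.ndarray            # per patient
    copy_states: np.ndarray                # per bin (shared segment scenario)
    expected_counts: np.ndarray            # (n_controls + n_patients, n_bins)
    group_hr: float | None = None
    droplet_copy_numbers: np.ndarray | None = None


def _simulate_gc(binset: BinSet, rng: np.random.Generator) -> GcTrack:
    """A smooth per-bin GC landscape in roughly [0.32, 0.58]."""
    pos = (binset.starts + binset.ends) / 2
    gc = np.empty(len(binset))
    for chrom, sl in binset.chrom_slices().items():
        frac = pos[sl] / max(binset.ends[sl].max(), 1)
        phase = rng.uniform(0, 2 * np.pi)
        gc[sl] = 0.45 + 0.08 * np.sin(2 * np.pi * 2.5 * frac + phase)
    gc += rng.normal(0, 0.01, size=len(binset))
    gc = np.clip(gc, 0.30, 0.60)
    return GcTrack(gc=gc, n_fraction=np.zeros(len(binset)))


def _copy_states(binset: BinSet,
                 segments: list[tuple[str, int, int, int]]) -> np.ndarray:
    """Per-bin copy state; a bin takes the state of the segment covering
    its midpoint, diploid otherwise."""
    states = np.full(len(binset), 2, dtype=int)
    mid = (binset.starts + binset.ends) // 2
    slices = binset.chrom_slices()
    for chrom, start, end, state in segments:
        if chrom not in slices:
            continue
        sl = slices[chrom]
        hit = (mid[sl] >= start) & (mid[sl] < end)
        states[sl] = np.where(hit, state, states[sl])
    return states


def _nb_counts(mu: np.ndarray, dispersion: float,
               rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2."""
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam).astype(float)


def simulate_bin_counts(config: SimulationConfig
                        ) -> tuple[list[BinCounts], list[BinCounts],
                                   GcTrack, BinSet, GroundTruth]:
    """Generate the control panel and patient bin counts.

    Returns (controls, patients, gc_track, binset, truth).  Controls have
    tumor fraction 0; patients get either the configured tumor fractions or
    an evenly spaced grid over [0, 0.4).  Identical seeds give identical
    outputs.
    """
    rng = np.random.default_rng(config.seed)
    binset = make_bins(config.genome, config.bin_size)
    gc = _simulate_gc(binset, rng)
    segments = (config.cna_segments if config.cna_segments is not None
                else default_cna_segments(config.genome))
    states = _copy_states(binset, segments)
    if config.tumor_fractions is not None:
        tfs = np.asarray(config.tumor_fractions, dtype=float)
        if len(tfs) != config.n_patients:
            raise ValueError("tumor_fractions length != n_patients")
    else:
        tfs = np.linspace(0.0, 0.4, config.n_patients, endpoint=False)

    bias = np.polynomial.polynomial.polyval(gc.gc, config.gc_bias)
    if np.any(bias <= 0):
        raise ValueError("gc_bias polynomial non-positive on simulated GC range")
    width = binset.widths / config.bin_size

    def expected(tf: float) -> np.ndarray:
        w = width * bias * (1.0 + tf * (states - 2) / 2.0)
        if np.any(w <= 0):
            raise ValueError("expected count non-positive "
                             "(tumor fraction too extreme for copy state 0)")
        return config.reads_per_sample * w / w.sum()

    mu_control = expected(0.0)
    controls: list[BinCounts] = []
    expected_all = []
    for i in range(config.n_controls):
        controls.append(BinCounts(
            sample_id=f"control_{i + 1:02d}",
            values=_nb_counts(mu_control, config.dispersion, rng),
            stage=STAGE_RAW,
        ))
        expected_all.append(mu_control)
    patients: list[BinCounts] = []
    for i, tf in enumerate(tfs):
        mu = expected(float(tf))
        patients.append(BinCounts(
            sample_id=f"patient_{i + 1:02d}",
            values=_nb_counts(mu, config.dispersion, rng),
            stage=STAGE_RAW,
        ))
        expected_all.append(mu)
    truth = GroundTruth(
        tumor_fractions=tfs,
        copy_states=states,
        expected_counts=np.vstack(expected_all),
    )
    return controls, patients, gc, binset, truth


def simulate_sam(binset: BinSet, counts: BinCounts, read_length: int = 75,
                 n_decoy_lowmapq: int = 0, n_decoy_duplicate: int = 0) -> str:
    """Render a sample's raw bin counts as SAM text.

    Emits exactly ``counts[i]`` primary MAPQ-60 single-end reads whose
    leftmost base lies inside bin i, plus optional decoy reads (low-MAPQ
    and duplicate-flagged, placed in the first bin) that the counter must
    reject.  Intended for toy genomes; raises if a bin cannot hold its
    reads at the given read length.
    """
    lengths: dict[str, int] = {}
    for chrom, sl in binset.chrom_slices().items():
        lengths[chrom] = int(binset.ends[sl].max())
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for chrom, length in lengths.items():
        lines.append(f"@SQ\tSN:{chrom}\tLN:{length}")
    seq = "A" * read_length
    qual = "I" * read_length
    cigar = f"{read_length}M"
    rid = 0

    def sam_line(name: str, flag: int, chrom: str, pos0: int, mapq: int) -> str:
        return (f"{name}\t{flag}\t{chrom}\t{pos0 + 1}\t{mapq}\t{cigar}"
                f"\t*\t0\t0\t{seq}\t{qual}")

    for i in range(len(binset)):
        n = int(counts.values[i]) if np.isfinite(counts.values[i]) else 0
        if n == 0:
            continue
        start, end = int(binset.starts[i]), int(binset.ends[i])
        capacity = end - start  # leftmost base anywhere in the bin
        if n > capacity:
            raise ValueError(f"bin {i} cannot hold {n} distinct read starts")
        chrom_len = lengths[binset.chroms[i]]
        for j in range(n):
            pos = start + (j % capacity)
            pos = min(pos, chrom_len - 1)
            lines.append(sam_line(f"r{rid}", 0, binset.chroms[i], pos, 60))
            rid += 1
    first_chrom = binset.chroms[0]
    for j in range(n_decoy_lowmapq):
        lines.append(sam_line(f"lowq{j}", 0, first_chrom, j, 30))
    for j in range(n_decoy_duplicate):
        lines.append(sam_line(f"dup{j}", 0x400, first_chrom, j, 60))
    return "\n".join(lines) + "\n"


def simulate_droplets(n_droplets: int, true_copy_number: float,
                      reference_lambda: float,
                      seed: int | np.random.Generator = 0,
                      sample_id: str = "sim") -> DropletCounts:
    """Duplex droplet counts under Poisson partitioning.

    Copies per droplet are Poisson with rate ``reference_lambda`` in the
    reference channel and ``reference_lambda * true_copy_number / 2`` in
    the target channel; a droplet is positive iff it holds >= 1 copy.
    """
    if n_droplets <= 0:
        raise ValueError("n_droplets must be positive")
    if reference_lambda < 0 or true_copy_number < 0:
        raise ValueError("rates must be non-negative")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    lam_target = reference_lambda * true_copy_number / 2.0
    p_target = -np.expm1(-lam_target)
    p_ref = -np.expm1(-reference_lambda)
    return DropletCounts(
        sample_id=sample_id,
        k_target=int(rng.binomial(n_droplets, p_target)),
        n_target=n_droplets,
        k_ref=int(rng.binomial(n_droplets, p_ref)),
        n_ref=n_droplets,
    )


def _solve_censor_horizon(rates: np.ndarray, target: float) -> float:
    """Bisect for the Uniform(0, u) horizon giving the target expected
    censored fraction under exponential event times."""

    def censored_fraction(u: float) -> float:
        lu = rates * u
        return float(np.mean((1.0 - np.exp(-lu)) / lu))

    lo, hi = 1e-9, 1.0
    while censored_fraction(hi) > target:
        hi *= 2
        if hi > 1e9:
            break
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if censored_fraction(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_survival(groups: np.ndarray | list,
                      group_hr: float = 3.5,
                      ttp_median_months: float = 4.1,
                      os_median_months: float = 14.8,
                      censoring_rate: float = 0.2,
                      frailty_sd: float = 0.0,
                      seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Exponential TTP and OS with a group hazard ratio and uniform censoring.

    Subjects labelled "high" get their hazard multiplied by ``group_hr``;
    the stated medians apply to the low group.  A shared lognormal frailty
    (sd ``frailty_sd`` on the log scale) correlates the two endpoints.
    Censoring times are Uniform(0, u) with u solved so the expected
    censored fraction equals ``censoring_rate``.
    """
    if not 0 <= censoring_rate < 1:
        raise ValueError("censoring_rate must lie in [0, 1)")
    groups = np.asarray(groups)
    n = len(groups)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    high = (groups == "high").astype(float)
    frailty = (np.exp(rng.normal(-frailty_sd ** 2 / 2, frailty_sd, n))
               if frailty_sd > 0 else np.ones(n))
    out: dict[str, np.ndarray] = {}
    for endpoint, median in (("ttp", ttp_median_months),
                             ("os", os_median_months)):
        base = np.log(2) / median
        rate = base * group_hr ** high * frailty
        event_time = rng.exponential(1.0 / rate)
        if censoring_rate > 0:
            u = _solve_censor_horizon(rate, censoring_rate)
            censor_time = rng.uniform(0, u, n)
            observed = np.minimum(event_time, censor_time)
            event = (event_time <= censor_time).astype(int)
        else:
            observed = event_time
            event = np.ones(n, dtype=int)
        out[f"{endpoint}_months"] = observed
        out[f"{endpoint}_event"] = event
    return pd.DataFrame(out)
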