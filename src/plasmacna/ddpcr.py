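"""Droplet digital PCR copy-number estimation for VEGFA against EIF2C1.

A ddPCR well partitions the sample into ~20,000 droplets; template molecules
distribute over droplets approximately Poisson, so the mean copies per
droplet in a channel is recovered from the positive-droplet fraction as
lambda = -ln(1 - k/n).  The VEGFA copy number per diploid genome (the
"VEGFA ratio") is 2 * lambda_VEGFA / lambda_EIF2C1, taking the reference
gene as two copies per genome.  Amplification is called when the copy
number strictly exceeds a cutoff derived from healthy controls as
mean + 3 SD (2.60 in the original cohort).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

REFERENCE_COPIES = 2.0


@dataclass
class DropletCounts:
    """Accepted and positive droplet counts for the two channels of a well."""

    sample_id: str
    k_target: int   # positive droplets, VEGFA channel
    n_target: int   # accepted droplets, VEGFA channel
    k_ref: int      # positive droplets, EIF2C1 channel
    n_ref: int      # accepted droplets, EIF2C1 channel

    def __post_init__(self) -> None:
        for k, n, label in ((self.k_target, self.n_target, "target"),
                            (self.k_ref, self.n_ref, "reference")):
            if n <= 0:
                raise ValueError(f"{label} channel has no accepted droplets")
            if not 0 <= k <= n:
                raise ValueError(f"{label} channel: k={k} outside [0, n={n}]")


@dataclass
class CopyNumberCall:
    """Poisson rates, copy number, and (optionally) the amplification call."""

    sample_id: str
    lambda_target: float
    lambda_ref: float
    copy_number: float
    cutoff: float | None = None
    amplified: bool | None = None


def poisson_rate(k: int, n: int) -> float:
    """Mean copies per droplet from k positive of n accepted droplets.

    lambda = -ln(1 - k/n).  Saturated wells (k = n) have an undefined rate.
    """
    if n <= 0:
        raise ValueError("no accepted droplets")
    if k < 0 or k > n:
        raise ValueError(f"positive droplets k={k} outside [0, n={n}]")
    if k == n:
        raise ValueError("all droplets positive: rate undefined (saturation)")
    return -math.log1p(-k / n)


def vegfa_ratio(d: DropletCounts,
                reference_copies: float = REFERENCE_COPIES) -> CopyNumberCall:
    """Copy number per diploid genome from a duplex well's droplet counts."""
    lam_t = poisson_rate(d.k_target, d.n_target)
    lam_r = poisson_rate(d.k_ref, d.n_ref)
    if lam_r == 0:
        raise ValueError(f"{d.sample_id}: no reference-channel signal")
    return CopyNumberCall(
        sample_id=d.sample_id,
        lambda_target=lam_t,
        lambda_ref=lam_r,
        copy_number=reference_copies * lam_t / lam_r,
    )


def amplification_cutoff(control_values: list[float] | np.ndarray,
                         n_sd: float = 3.0) -> float:
    """Control-derived cutoff: mean + n_sd * sample SD of control copy numbers."""
    controls = np.asarray(control_values, dtype=float)
    if controls.size < 2:
        raise ValueError("need >= 2 control copy numbers to derive a cutoff")
    return float(controls.mean() + n_sd * controls.std(ddof=1))


def amplification_call(call: CopyNumberCall,
                       control_values: list[float] | np.ndarray | None = None,
                       fixed_cutoff: float | None = None) -> CopyNumberCall:
    """Call amplification: copy number strictly above the cutoff.

    The cutoff is either supplied directly (``fixed_cutoff``, e.g. a
    previously established 2.60) or derived from control copy numbers as
    mean + 3 SD.
    """
    if fixed_cutoff is not None:
        cutoff = float(fixed_cutoff)
    elif control_values is not None:
        cutoff = amplification_cutoff(control_values)
    else:
        raise ValueError("need control values or a fixed cutoff")
    call.cutoff = cutoff
    call.amplified = call.copy_number > cutoff
    return call
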