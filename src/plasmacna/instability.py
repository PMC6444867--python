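"""Reference panel, per-bin Z-scores, gain/loss calls, I-score and S-score.

A panel of healthy controls defines, per bin, the mean and standard
deviation of the normalized read-count percentage.  A test sample's bin
percentage is converted to a Z-score against the panel; whole-genome
instability is then summarized by the I-score,

    I = sum over usable bins j of |Z_j|, restricted to |Z_j| > t  (t = 2),

and, for comparison, the S-score, the sum of squared Z-scores over all
scorable bins.  A sample drawn from the same population as the panel has
Z ~ 0 in every bin and an I-score of zero; chance excursions past the
threshold give real control samples a small positive sampling baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .counting import STAGE_NORMALIZED, BinCounts

logger = logging.getLogger(__name__)

DEFAULT_Z_THRESHOLD = 2.0


@dataclass
class ReferencePanel:
    """Per-bin mean and SD of control normalized percentages.

    Bins with zero SD cannot be scored (the Z-score is undefined) and are
    flagged unscorable.
    """

    n_controls: int
    mean_pct: np.ndarray
    sd_pct: np.ndarray
    scorable: np.ndarray

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ValueError("reference panel needs >= 2 controls")
        finite_sd = self.sd_pct[np.isfinite(self.sd_pct)]
        if np.any(finite_sd < 0):
            raise ValueError("panel SD must be non-negative")


@dataclass
class CnaProfile:
    """One sample's per-bin Z-scores, calls and instability scores."""

    sample_id: str
    z: np.ndarray
    calls: np.ndarray
    i_score: float
    s_score: float
    threshold: float


def build_panel(controls: list[BinCounts]) -> ReferencePanel:
    """Per-bin mean and sample SD (n-1 denominator) across controls.

    All controls must be at the normalized-percent stage on the same bin
    grid.  Bins where any control is missing, or where the SD is zero, are
    flagged unscorable.
    """
    if len(controls) < 2:
        raise ValueError("need >= 2 controls to build a panel")
    n_bins = len(controls[0])
    for c in controls:
        if c.stage != STAGE_NORMALIZED:
            raise ValueError(f"control {c.sample_id} is at stage {c.stage}, "
                             "expected normalized_percent")
        if len(c) != n_bins:
            raise ValueError("controls are on mismatched bin grids")
    mat = np.vstack([c.values for c in controls])
    complete = np.all(np.isfinite(mat), axis=0)
    mean_pct = np.full(n_bins, np.nan)
    sd_pct = np.full(n_bins, np.nan)
    mean_pct[complete] = mat[:, complete].mean(axis=0)
    sd_pct[complete] = mat[:, complete].std(axis=0, ddof=1)
    scorable = complete & (sd_pct > 0)
    n_zero_sd = int((complete & (sd_pct == 0)).sum())
    if n_zero_sd:
        logger.warning("build_panel: %d zero-SD bins flagged unscorable",
                       n_zero_sd)
    return ReferencePanel(n_controls=len(controls), mean_pct=mean_pct,
                          sd_pct=sd_pct, scorable=scorable)


def zscores(sample: BinCounts, panel: ReferencePanel) -> np.ndarray:
    """Per-bin Z = (sample pct - panel mean) / panel SD on scorable bins.

    Unscorable bins come back as NaN.  A missing sample value on a scorable
    bin is an error: the grids are out of sync.
    """
    if sample.stage != STAGE_NORMALIZED:
        raise ValueError(f"sample is at stage {sample.stage}, "
                         "expected normalized_percent")
    if len(sample) != len(panel.mean_pct):
        raise ValueError("sample and panel are on mismatched bin grids")
    missing = panel.scorable & ~np.isfinite(sample.values)
    if missing.any():
        raise ValueError(
            f"sample {sample.sample_id} missing values on "
            f"{int(missing.sum())} scorable bins"
        )
    z = np.full(len(sample), np.nan)
    s = panel.scorable
    z[s] = (sample.values[s] - panel.mean_pct[s]) / panel.sd_pct[s]
    return z


def i_score(z: np.ndarray, threshold: float = DEFAULT_Z_THRESHOLD) -> float:
    """Sum of |Z| over bins with |Z| strictly above the threshold.

    NaN entries (unscorable bins) are ignored; an empty selection gives 0.
    """
    z = np.asarray(z, dtype=float)
    finite = z[np.isfinite(z)]
    selected = np.abs(finite) > threshold
    return float(np.abs(finite[selected]).sum())


def s_score(z: np.ndarray) -> float:
    """Sum of squared Z over all scorable bins (no thresholding)."""
    z = np.asarray(z, dtype=float)
    finite = z[np.isfinite(z)]
    return float(np.square(finite).sum())


def call_cna(z: np.ndarray, threshold: float = DEFAULT_Z_THRESHOLD) -> np.ndarray:
    """Per-bin call: gain iff Z > t, loss iff Z < -t, else neutral.

    Unscorable (NaN) bins are labelled "na".
    """
    z = np.asarray(z, dtype=float)
    calls = np.full(len(z), "neutral", dtype=object)
    calls[~np.isfinite(z)] = "na"
    with np.errstate(invalid="ignore"):
        calls[z > threshold] = "gain"
        calls[z < -threshold] = "loss"
    return calls


def profile_sample(sample: BinCounts, panel: ReferencePanel,
                   threshold: float = DEFAULT_Z_THRESHOLD) -> CnaProfile:
    """Score one sample against the panel: Z-scores, calls, I- and S-score."""
    z = zscores(sample, panel)
    return CnaProfile(
        sample_id=sample.sample_id,
        z=z,
        calls=call_cna(z, threshold),
        i_score=i_score(z, threshold),
        s_score=s_score(z),
        threshold=threshold,
    )
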