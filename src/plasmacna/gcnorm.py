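"""GC-bias removal by locally weighted regression and percentage scaling.

Sequencing depth in shallow WGS depends smoothly on local GC content.  The
correction fits a LOESS curve of raw bin count on GC fraction over the
usable bins, then rescales each bin multiplicatively by the ratio of the
curve's median level to its fitted value.  Corrected counts are finally
expressed as percentages of the usable-bin total, which is the scale on
which the reference panel and Z-scores are defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .counting import STAGE_GC_CORRECTED, STAGE_NORMALIZED, STAGE_RAW, BinCounts, GcTrack
from .genome import BinSet

logger = logging.getLogger(__name__)

DEFAULT_SPAN = 0.3
MIN_BINS = 50


@dataclass
class GcModel:
    """A fitted count-versus-GC curve.

    ``fitted`` holds the expected raw count given each bin's GC (NaN where
    the model is undefined: unusable bins or missing GC).
    ``reference_level`` is the median of the fitted values; correction
    rescales every bin to this common level.
    """

    span: float
    fitted: np.ndarray
    reference_level: float
    usable: np.ndarray  # bins the model was fit on


def fit_gc_model(counts: BinCounts, gc: GcTrack, binset: BinSet,
                 span: float = DEFAULT_SPAN, iterations: int = 1) -> GcModel:
    """Fit LOESS of raw count on GC fraction over usable bins.

    Local linear (degree 1) smoothing with ``iterations`` robustness
    reweightings.  Fitted values at each bin's GC are recovered from the
    sorted smoother output by interpolation, which handles tied GC values.
    """
    if counts.stage != STAGE_RAW:
        raise ValueError(f"expected raw counts, got stage={counts.stage}")
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    mask = binset.usable & np.isfinite(gc.gc) & np.isfinite(counts.values)
    if mask.sum() < MIN_BINS:
        raise ValueError(
            f"need >= {MIN_BINS} usable bins with GC to fit the model, "
            f"have {int(mask.sum())}"
        )
    x = gc.gc[mask]
    y = counts.values[mask]
    if float(y.sum()) <= 0:
        raise ValueError("total count over usable bins is zero")
    if np.ptp(x) == 0:
        raise ValueError(
            "GC content is constant across bins; skip GC correction"
        )
    smoothed = lowess(y, x, frac=span, it=iterations, return_sorted=True)
    fitted_at = np.interp(x, smoothed[:, 0], smoothed[:, 1])
    fitted = np.full(len(binset), np.nan)
    fitted[mask] = fitted_at
    reference_level = float(np.median(fitted_at))
    if reference_level <= 0:
        raise ValueError("median fitted count is non-positive")
    return GcModel(span=span, fitted=fitted, reference_level=reference_level,
                   usable=mask)


def correct_counts(counts: BinCounts, model: GcModel) -> BinCounts:
    """Multiplicative GC correction: raw * reference_level / fitted.

    Bins outside the model (unusable or missing GC) become NaN.  Bins whose
    fitted value is non-positive are demoted to NaN with a log entry.
    """
    if counts.stage != STAGE_RAW:
        raise ValueError(f"expected raw counts, got stage={counts.stage}")
    if len(counts) != len(model.fitted):
        raise ValueError("counts and model cover different bin grids")
    corrected = np.full(len(counts), np.nan)
    ok = model.usable & np.isfinite(model.fitted)
    bad = ok & (model.fitted <= 0)
    if bad.any():
        logger.warning("correct_counts: %d bins demoted (fitted <= 0)",
                       int(bad.sum()))
        ok = ok & ~bad
    corrected[ok] = counts.values[ok] * model.reference_level / model.fitted[ok]
    return BinCounts(sample_id=counts.sample_id, values=corrected,
                     stage=STAGE_GC_CORRECTED)


def normalize_percent(counts: BinCounts, binset: BinSet) -> BinCounts:
    """Express GC-corrected counts as percentages of the usable-bin total."""
    if counts.stage != STAGE_GC_CORRECTED:
        raise ValueError(f"expected gc_corrected counts, got stage={counts.stage}")
    mask = binset.usable & np.isfinite(counts.values)
    total = float(counts.values[mask].sum())
    if total <= 0:
        raise ValueError("zero total over usable bins; cannot normalize")
    pct = np.full(len(counts), np.nan)
    pct[mask] = 100.0 * counts.values[mask] / total
    return BinCounts(sample_id=counts.sample_id, values=pct,
                     stage=STAGE_NORMALIZED)


def raw_to_percent(counts: BinCounts, gc: GcTrack, binset: BinSet,
                   span: float = DEFAULT_SPAN) -> BinCounts:
    """Convenience: fit the GC model, correct, and normalize in one call."""
    model = fit_gc_model(counts, gc, binset, span=span)
    return normalize_percent(correct_counts(counts, model), binset)
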