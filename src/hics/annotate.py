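"""Peak-track profiles around called boundaries.

Given a BED track of regulatory-factor peaks (CTCF, cohesin, ATAC, ...),
the profile is the average peak count per bin at each offset from a called
boundary, together with a concentration summary: the ratio of the mean
count in the boundary center (offsets |o| <= 1) to the mean count in the
outer half of the flank (|o| >= K/2).  A factor that promotes boundary
formation shows a peaked profile at offset 0 and concentration well above
1; a uniform track is flat with concentration 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .insulation import BoundarySet
from .io import GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class PeakTrack:
    """Per-bin count of peak intervals overlapping each bin."""

    counts: np.ndarray
    name: str = "peaks"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("peak counts must be >= 0")

    @property
    def n_bins(self) -> int:
        return self.counts.size


@dataclass
class BoundaryProfile:
    """Mean peak count per offset around boundaries, plus concentration."""

    offsets: np.ndarray
    means: np.ndarray
    n_boundaries: int
    concentration: float
    track_name: str = "peaks"


def bin_peaks(
    intervals: Sequence[GenomicInterval],
    bin_size: int,
    n_bins: int,
    name: str = "peaks",
) -> PeakTrack:
    """Count intervals overlapping each bin; an interval spanning m bins
    increments all m.  Intervals reaching past the chromosome end are
    clipped with a warning."""
    counts = np.zeros(n_bins, dtype=float)
    chrom_end = n_bins * bin_size
    for iv in intervals:
        start, end = iv.start, iv.end
        if end > chrom_end or start < 0:
            logger.warning("clipping interval [%d, %d) to chromosome", start, end)
            start, end = max(0, start), min(end, chrom_end)
            if start >= end:
                continue
        first = start // bin_size
        last = (end - 1) // bin_size
        counts[first : last + 1] += 1
    return PeakTrack(counts, name=name)


def boundary_profile(
    track: PeakTrack,
    boundaries: BoundarySet | np.ndarray,
    flank_bins: int = 25,
) -> BoundaryProfile:
    """Average track count at each offset -K..+K from a boundary bin.

    Out-of-range positions are skipped (each offset averages over the
    boundaries for which it lies on the chromosome).  Concentration is the
    mean at |offset| <= 1 over the mean at |offset| >= ceil(K/2); infinity
    when the background is empty but the center is not, NaN when both are.
    """
    if flank_bins < 1:
        raise ValueError("flank_bins must be >= 1")
    bins = boundaries.bins if isinstance(boundaries, BoundarySet) else np.asarray(boundaries)
    if bins.size == 0:
        raise ValueError("empty boundary set: profile undefined")
    n = track.n_bins
    offsets = np.arange(-flank_bins, flank_bins + 1)
    sums = np.zeros(offsets.size)
    cnts = np.zeros(offsets.size)
    for k, o in enumerate(offsets):
        pos = bins + o
        ok = (pos >= 0) & (pos < n)
        sums[k] = track.counts[pos[ok]].sum()
        cnts[k] = ok.sum()
    means = np.where(cnts > 0, sums / np.where(cnts > 0, cnts, 1), np.nan)
    center = np.nanmean(means[np.abs(offsets) <= 1])
    bg_cut = math.ceil(flank_bins / 2)
    background = np.nanmean(means[np.abs(offsets) >= bg_cut])
    if background > 0:
        conc = center / background
    elif center > 0:
        conc = float("inf")
    else:
        conc = float("nan")
    return BoundaryProfile(
        offsets=offsets,
        means=means,
        n_boundaries=int(bins.size),
        concentration=float(conc),
        track_name=track.name,
    )


def boundary_ratio_per_bin(
    boundary_sets: Sequence[BoundarySet | np.ndarray], n_bins: int
) -> np.ndarray:
    """Fraction of cells calling each bin a boundary.

    The per-bin ratio underlies cross-cell boundary-preference analyses:
    its cumulative distribution (see :func:`ratio_cumulative`) shows what
    share of genomic positions form a boundary in at least a given
    fraction of cells.
    """
    if len(boundary_sets) < 2:
        raise ValueError("need at least 2 cells")
    indicator = np.zeros(n_bins, dtype=float)
    for bs in boundary_sets:
        bins = bs.bins if isinstance(bs, BoundarySet) else np.asarray(bs, dtype=np.int64)
        if bins.size and (bins.min() < 0 or bins.max() >= n_bins):
            raise ValueError("boundary bin outside the common bin frame")
        indicator[bins] += 1.0
    return indicator / len(boundary_sets)


def ratio_cumulative(ratios: np.ndarray, grid: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of bins with boundary ratio <= each grid value."""
    ratios = np.asarray(ratios, float)
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    frac = np.array([(ratios <= g).mean() for g in grid])
    return grid, frac
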