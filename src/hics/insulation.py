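"""Density-peak metrics on the insulation profile of one chromosome.

For each bin *i* the insulation strength is the normalized contrast between
contacts inside its two flanking windows and contacts crossing the bin:

    I_intra(i) = Ia + Ib,  Ia = sum entries (u, v), i-W <= u < v <= i
                           Ib = sum entries (u, v), i <= u < v <= i+W
    I_inter(i) = Ic      = sum entries (u, v), i-W <= u < i < v <= i+W
    rho(i)     = (I_intra - I_inter) / (I_intra + I_inter)

with windows truncated at the chromosome ends and rho defined as 0 when the
denominator vanishes.  The second density-peak metric delta(i) is the
distance in bins to the nearest bin with strictly higher rho, capped at
MAX.  Bins that are both strong insulators (high rho) and locally dominant
(high delta) — large eta = rho' * delta' — are boundary candidates; the
automatic threshold is set at the reflection point of the ranked eta curve
and scaled by alpha.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

import numpy as np

from .contact_map import BinnedContactMap

logger = logging.getLogger(__name__)


@dataclass
class BoundarySet:
    """Screened boundary bins of one chromosome at one alpha."""

    chrom: str
    alpha: float
    bins: np.ndarray
    eta: np.ndarray
    eta_threshold: float

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=np.int64)
        self.eta = np.asarray(self.eta, dtype=float)
        if self.bins.size and np.any(np.diff(self.bins) <= 0):
            raise ValueError("boundary bins must be strictly increasing")

    def __len__(self) -> int:
        return self.bins.size


@dataclass
class InsulationProfile:
    """Per-bin density-peak metrics for one chromosome of one cell.

    Gap bins carry NaN in every metric and are excluded from ranking,
    reflection-point search and boundary candidacy.
    """

    rho: np.ndarray
    delta: np.ndarray
    rho_norm: np.ndarray
    delta_norm: np.ndarray
    eta: np.ndarray
    gamma: np.ndarray
    gamma_norm: np.ndarray
    reflection_rank: int
    reflection_bin: int
    eta_r: float
    window: int
    max_search: int
    gap_mask: np.ndarray
    chrom: str = "chr1"
    inter_sums: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_bins(self) -> int:
        return self.rho.size


def window_sums(matrix: np.ndarray, W: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin (I_intra, I_inter) flank sums with end truncation."""
    n = matrix.shape[0]
    intra = np.empty(n)
    inter = np.empty(n)
    for i in range(n):
        lo = max(0, i - W)
        hi = min(n - 1, i + W)
        left = matrix[lo : i + 1, lo : i + 1]
        right = matrix[i : hi + 1, i : hi + 1]
        ia = (left.sum() - np.trace(left)) / 2.0
        ib = (right.sum() - np.trace(right)) / 2.0
        ic = matrix[lo:i, i + 1 : hi + 1].sum()
        intra[i] = ia + ib
        inter[i] = ic
    return intra, inter


def insulation_strength(
    cmap: BinnedContactMap | np.ndarray, W: int
) -> np.ndarray:
    """Insulation strength rho per bin; accepts a map or a bare symmetric
    matrix (test/oracle mode).  rho is 0 where I_intra + I_inter = 0."""
    matrix = cmap.matrix if isinstance(cmap, BinnedContactMap) else np.asarray(cmap, float)
    n = matrix.shape[0]
    if W < 1:
        raise ValueError("window half-width W must be >= 1")
    if W >= n:
        raise ValueError(f"window half-width W={W} must be smaller than n_bins={n}")
    intra, inter = window_sums(matrix, W)
    denom = intra + inter
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, (intra - inter) / np.where(denom > 0, denom, 1.0), 0.0)
    return rho


def higher_strength_min_distance(
    rho: np.ndarray, max_search: int, gap_mask: np.ndarray | None = None
) -> np.ndarray:
    """delta(i): distance in bins to the nearest j with rho(j) > rho(i),
    capped at ``max_search``; the profile maximum (and any bin with no
    strictly higher neighbor within range) gets ``max_search``, the
    density-peaks convention for the top point.  Gap bins are excluded from
    both roles and carry NaN.

    Runs in O(n log n): bins are visited in decreasing rho, keeping the
    positions already visited in a sorted list; equal-rho bins are queried
    before any of them is inserted, so the comparison stays strict.
    """
    rho = np.asarray(rho, dtype=float)
    if max_search < 1:
        raise ValueError("max_search must be >= 1")
    n = rho.size
    delta = np.full(n, np.nan)
    if gap_mask is None:
        gap_mask = np.zeros(n, dtype=bool)
    active = np.nonzero(~gap_mask)[0]
    if active.size == 0:
        return delta
    order = active[np.lexsort((active, -rho[active]))]
    seen: list[int] = []
    k = 0
    while k < order.size:
        # tie group [k, m) shares one rho value
        m = k
        while m < order.size and rho[order[m]] == rho[order[k]]:
            m += 1
        for i in order[k:m].tolist():
            best = max_search
            pos = bisect.bisect_left(seen, i)
            if pos < len(seen):
                best = min(best, seen[pos] - i)
            if pos > 0:
                best = min(best, i - seen[pos - 1])
            delta[i] = min(best, max_search)
        for i in order[k:m].tolist():
            bisect.insort(seen, i)
        k = m
    return delta


def normalize_and_rank(
    rho: np.ndarray,
    delta: np.ndarray,
    max_search: int,
    gap_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Min-max scale rho to [0, 1], scale delta by MAX, rank bins by
    eta = rho' * delta' descending (ties -> lower bin index first).

    Returns (rho_norm, delta_norm, eta, gamma, gamma_norm); gap bins are NaN
    throughout and receive no rank.
    """
    rho = np.asarray(rho, float)
    delta = np.asarray(delta, float)
    if rho.shape != delta.shape:
        raise ValueError("rho and delta must have the same length")
    n = rho.size
    if gap_mask is None:
        gap_mask = np.zeros(n, dtype=bool)
    active = np.nonzero(~gap_mask)[0]
    if active.size == 0:
        raise ValueError("no non-gap bins to rank")
    r = rho[active]
    span = r.max() - r.min()
    if span == 0:
        raise ValueError("flat insulation profile: all rho values are equal")
    rho_norm = np.full(n, np.nan)
    delta_norm = np.full(n, np.nan)
    eta = np.full(n, np.nan)
    gamma = np.full(n, np.nan)
    gamma_norm = np.full(n, np.nan)
    rho_norm[active] = (r - r.min()) / span
    delta_norm[active] = delta[active] / max_search
    eta[active] = rho_norm[active] * delta_norm[active]
    order = active[np.lexsort((active, -eta[active]))]
    ranks = np.arange(1, order.size + 1, dtype=float)
    gamma[order] = ranks
    gamma_norm[order] = ranks / order.size
    return rho_norm, delta_norm, eta, gamma, gamma_norm


def reflection_point(
    eta: np.ndarray, gamma_norm: np.ndarray, gap_mask: np.ndarray | None = None
) -> tuple[int, int, float]:
    """Rank position minimizing sqrt(eta^2 + gamma'^2) over ranked bins.

    The ranked eta curve decreases while gamma' increases linearly; the
    point closest to the origin is the elbow separating boundary-like bins
    from the bulk.  Ties resolve to the smallest rank.  Returns
    (rank_position, bin_index, eta_at_r).
    """
    eta = np.asarray(eta, float)
    gamma_norm = np.asarray(gamma_norm, float)
    if gap_mask is None:
        gap_mask = ~np.isfinite(eta)
    active = np.nonzero(~gap_mask)[0]
    if active.size == 0:
        raise ValueError("no ranked bins")
    order = active[np.argsort(gamma_norm[active], kind="stable")]
    objective = np.sqrt(eta[order] ** 2 + gamma_norm[order] ** 2)
    pos = int(np.argmin(objective))  # argmin takes the first = smallest rank
    r_bin = int(order[pos])
    return pos + 1, r_bin, float(eta[r_bin])


def compute_profile(
    cmap: BinnedContactMap, window: int, max_search: int
) -> InsulationProfile:
    """Full per-chromosome profile: rho, delta, normalization, ranks, r.

    The profile gap mask extends the raw mask with bins whose cross-window
    sum I_inter is 0 — such bins insulate trivially and are never
    boundary candidates.
    """
    matrix = cmap.matrix
    n = cmap.n_bins
    if window >= n:
        raise ValueError(f"window half-width {window} must be < n_bins {n}")
    intra, inter = window_sums(matrix, window)
    denom = intra + inter
    rho = np.where(denom > 0, (intra - inter) / np.where(denom > 0, denom, 1.0), 0.0)
    gap = cmap.gap_mask | (inter == 0)
    delta = higher_strength_min_distance(rho, max_search, gap)
    rho_norm, delta_norm, eta, gamma, gamma_norm = normalize_and_rank(
        rho, delta, max_search, gap
    )
    rank, r_bin, eta_r = reflection_point(eta, gamma_norm, gap)
    rho = rho.copy()
    rho[gap] = np.nan
    return InsulationProfile(
        rho=rho,
        delta=delta,
        rho_norm=rho_norm,
        delta_norm=delta_norm,
        eta=eta,
        gamma=gamma,
        gamma_norm=gamma_norm,
        reflection_rank=rank,
        reflection_bin=r_bin,
        eta_r=eta_r,
        window=window,
        max_search=max_search,
        gap_mask=gap,
        chrom=cmap.chrom,
        inter_sums=inter,
    )


def call_boundaries(profile: InsulationProfile, alpha: float = 1.0) -> BoundarySet:
    """Screen bins with eta > alpha * eta(r); gap bins never qualify."""
    if not 0.1 < alpha < 10:
        logger.warning("alpha=%g outside the recommended range (0.1, 10)", alpha)
    if profile.eta_r == 0:
        raise ValueError(
            "degenerate threshold: eta at the reflection point is 0 "
            "(flat or pathological profile)"
        )
    thresh = alpha * profile.eta_r
    keep = ~profile.gap_mask & (profile.eta > thresh)
    bins = np.nonzero(keep)[0]
    return BoundarySet(
        chrom=profile.chrom,
        alpha=float(alpha),
        bins=bins,
        eta=profile.eta[bins],
        eta_threshold=thresh,
    )
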