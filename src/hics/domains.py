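"""Domain intervals and the multi-alpha hierarchy.

Boundary bins partition the non-gap territory of the chromosome into
domains: a boundary bin opens the domain to its right, chromosome ends act
as implicit delimiters, and runs of gap bins split domains and belong to no
domain.  Because the screening threshold alpha * eta(r) is monotone in
alpha over one fixed profile, boundary sets are nested across the alpha
ladder and every lower-level domain lies inside exactly one higher-level
domain (or a gap) — the hierarchy is exact by construction and asserted on
every build.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contact_map import BinnedContactMap
from .insulation import BoundarySet, InsulationProfile, call_boundaries, compute_profile


@dataclass
class HierarchyLevel:
    alpha: float
    boundary_set: BoundarySet
    domains: list[tuple[int, int]]
    # index into the next (higher-alpha) level's domain list, or None
    parents: list[int | None] = field(default_factory=list)


@dataclass
class DomainHierarchy:
    chrom: str
    n_bins: int
    bin_size: int
    levels: list[HierarchyLevel]

    @property
    def alphas(self) -> list[float]:
        return [lv.alpha for lv in self.levels]


def boundaries_to_domains(
    boundary_bins: np.ndarray | BoundarySet,
    n_bins: int,
    gap_mask: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Half-open [start_bin, end_bin) domain intervals from boundary bins.

    Within each contiguous non-gap run [s, e), boundaries b1 < b2 < ... cut
    the run into [s, b1), [b1, b2), ..., [bk, e); empty pieces (a boundary
    at the run start) are dropped so every domain spans >= 1 bin.
    """
    if isinstance(boundary_bins, BoundarySet):
        boundary_bins = boundary_bins.bins
    bounds = np.asarray(boundary_bins, dtype=np.int64)
    if gap_mask is None:
        gap_mask = np.zeros(n_bins, dtype=bool)
    domains: list[tuple[int, int]] = []
    i = 0
    while i < n_bins:
        if gap_mask[i]:
            i += 1
            continue
        s = i
        while i < n_bins and not gap_mask[i]:
            i += 1
        e = i
        cuts = bounds[(bounds > s) & (bounds < e)]
        edges = [s, *cuts.tolist(), e]
        for a, b in zip(edges[:-1], edges[1:]):
            if b > a:
                domains.append((a, b))
    return domains


def build_hierarchy(
    source: BinnedContactMap | InsulationProfile,
    alphas: list[float],
    window: int | None = None,
    max_search: int | None = None,
) -> DomainHierarchy:
    """One hierarchy level per alpha, all reusing a single profile.

    rho, delta, eta and the reflection point are alpha-independent, so the
    profile is computed once; each alpha only re-screens.  Levels are
    ordered by ascending alpha (finest segmentation first).  The nesting
    invariant B(alpha2) subset-of B(alpha1) for alpha2 >= alpha1 is
    asserted, as is containment of every domain in a parent domain of the
    next level.
    """
    if not alphas:
        raise ValueError("need at least one alpha")
    alphas = sorted(float(a) for a in alphas)
    if isinstance(source, InsulationProfile):
        profile = source
        bin_size = 0
    else:
        if window is None or max_search is None:
            raise ValueError("window and max_search are required with a contact map")
        profile = compute_profile(source, window, max_search)
        bin_size = source.bin_size
    n_bins = profile.n_bins

    levels: list[HierarchyLevel] = []
    for alpha in alphas:
        bset = call_boundaries(profile, alpha)
        doms = boundaries_to_domains(bset.bins, n_bins, profile.gap_mask)
        levels.append(HierarchyLevel(alpha=alpha, boundary_set=bset, domains=doms))

    for prev, cur in zip(levels[:-1], levels[1:]):
        missing = np.setdiff1d(cur.boundary_set.bins, prev.boundary_set.bins)
        assert missing.size == 0, (
            f"nesting violated: boundaries {missing.tolist()} at alpha="
            f"{cur.alpha} absent at alpha={prev.alpha}"
        )

    # parent links: enclosing domain at the next (coarser, higher-alpha) level
    for child, parent in zip(levels[:-1], levels[1:]):
        starts = np.array([d[0] for d in parent.domains], dtype=np.int64)
        ends = np.array([d[1] for d in parent.domains], dtype=np.int64)
        links: list[int | None] = []
        for a, b in child.domains:
            hit = np.nonzero((starts <= a) & (ends >= b))[0]
            assert hit.size <= 1, "overlapping parent domains"
            links.append(int(hit[0]) if hit.size else None)
            if hit.size:
                assert starts[hit[0]] <= a and b <= ends[hit[0]]
        child.parents = links
    if levels:
        levels[-1].parents = [None] * len(levels[-1].domains)

    return DomainHierarchy(
        chrom=profile.chrom, n_bins=n_bins, bin_size=bin_size, levels=levels
    )


def domain_size_stats(hierarchy: DomainHierarchy, bin_size: int | None = None) -> list[dict]:
    """Per-level size and boundary-strength summary (counts, median/mean
    domain size in bp, median boundary eta)."""
    bs = bin_size if bin_size is not None else hierarchy.bin_size
    if not bs:
        raise ValueError("bin_size unknown; pass it explicitly")
    out = []
    for lv in hierarchy.levels:
        sizes = np.array([(e - s) * bs for s, e in lv.domains], dtype=float)
        eta = lv.boundary_set.eta
        out.append(
            {
                "alpha": lv.alpha,
                "n_boundaries": int(len(lv.boundary_set)),
                "n_domains": int(sizes.size),
                "median_size_bp": float(np.median(sizes)) if sizes.size else float("nan"),
                "mean_size_bp": float(sizes.mean()) if sizes.size else float("nan"),
                "median_boundary_eta": float(np.median(eta)) if eta.size else float("nan"),
                "boundary_eta": eta.tolist(),
            }
        )
    return out
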