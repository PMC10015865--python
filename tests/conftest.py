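import numpy as np
import pytest

from hics import BinnedContactMap, InsulationProfile, simulate_cell


def make_map(entries, n_bins, bin_size=40_000, chrom="chr1"):
    """Symmetric raw map from {(i, j): count} sparse entries."""
    mat = np.zeros((n_bins, n_bins))
    for (i, j), c in entries.items():
        mat[i, j] += c
        if i != j:
            mat[j, i] += c
    return BinnedContactMap(mat, bin_size=bin_size, chrom=chrom, stage="raw")


def make_profile(eta, eta_r, gap_mask=None, chrom="chr1", max_search=10):
    """Minimal hand-built profile for screening tests: only the fields
    call_boundaries consumes are meaningful."""
    eta = np.asarray(eta, dtype=float)
    n = eta.size
    if gap_mask is None:
        gap_mask = np.zeros(n, dtype=bool)
    dummy = np.zeros(n)
    return InsulationProfile(
        rho=dummy, delta=dummy, rho_norm=dummy, delta_norm=dummy,
        eta=eta, gamma=dummy, gamma_norm=dummy,
        reflection_rank=1, reflection_bin=0, eta_r=eta_r,
        window=1, max_search=max_search, gap_mask=np.asarray(gap_mask, bool),
        chrom=chrom,
    )


def brute_force_delta(rho, max_search, gap_mask=None):
    """Independent O(n * MAX) oracle for the higher-strength min distance."""
    rho = np.asarray(rho, float)
    n = rho.size
    if gap_mask is None:
        gap_mask = np.zeros(n, dtype=bool)
    delta = np.full(n, np.nan)
    for i in range(n):
        if gap_mask[i]:
            continue
        best = max_search
        for j in range(max(0, i - max_search), min(n, i + max_search + 1)):
            if j == i or gap_mask[j]:
                continue
            if rho[j] > rho[i]:
                best = min(best, abs(i - j))
        delta[i] = best
    return delta


def brute_force_rho(matrix, W):
    """Independent per-bin region sums straight from the definitions."""
    n = matrix.shape[0]
    rho = np.zeros(n)
    for i in range(n):
        ia = sum(
            matrix[u, v]
            for u in range(max(0, i - W), i + 1)
            for v in range(u + 1, i + 1)
        )
        ib = sum(
            matrix[u, v]
            for u in range(i, min(n - 1, i + W) + 1)
            for v in range(u + 1, min(n - 1, i + W) + 1)
        )
        ic = sum(
            matrix[u, v]
            for u in range(max(0, i - W), i)
            for v in range(i + 1, min(n - 1, i + W) + 1)
        )
        denom = ia + ib + ic
        rho[i] = ((ia + ib) - ic) / denom if denom > 0 else 0.0
    return rho


@pytest.fixture(scope="session")
def sim_cell():
    """One deterministic synthetic cell shared by read-only tests."""
    cmap, truth = simulate_cell(n_bins=400, depth=20_000, seed=11)
    return cmap, truth
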