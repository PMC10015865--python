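"""Binned per-chromosome contact maps.

A :class:`BinnedContactMap` is the central in-memory container of the
pipeline: a symmetric ``n_bins x n_bins`` matrix of contact counts (raw
stage), smoothed contact probabilities (probability stage), or the
top-fraction sparsified probabilities (sparsified stage), together with a
per-bin gap mask.  Matrices are stored dense; single-cell maps at 40 kb
resolution stay comfortably within memory at chromosome scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

STAGES = ("raw", "probability", "sparsified")


@dataclass
class BinnedContactMap:
    """Symmetric per-chromosome contact matrix at a fixed bin size.

    Parameters
    ----------
    matrix : ndarray of shape (n_bins, n_bins)
        Symmetric, non-negative at raw/sparsified stage.  Probability-stage
        entries are cosine similarities and may be negative.
    bin_size : int
        Bin width in bp.
    chrom : str
        Chromosome name carried through to output files.
    stage : {"raw", "probability", "sparsified"}
    gap_mask : ndarray of bool, optional
        True for bins with no contact to any other bin.  Computed from the
        matrix when omitted; later pipeline stages must propagate the raw
        mask explicitly (an embedded bin can acquire nonzero similarity to
        everything, but a gap stays a gap).
    """

    matrix: np.ndarray
    bin_size: int
    chrom: str = "chr1"
    stage: str = "raw"
    gap_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if sp.issparse(self.matrix):
            self.matrix = np.asarray(self.matrix.todense())
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError(f"contact matrix must be square, got {self.matrix.shape}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("contact matrix must be symmetric")
        if self.stage != "probability" and np.any(self.matrix < 0):
            raise ValueError(f"negative entries not allowed at {self.stage} stage")
        if int(self.bin_size) <= 0:
            raise ValueError("bin_size must be positive")
        self.bin_size = int(self.bin_size)
        if self.gap_mask is None:
            self.gap_mask = self.compute_gap_mask()
        else:
            self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
            if self.gap_mask.shape != (self.n_bins,):
                raise ValueError("gap_mask length must equal n_bins")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def compute_gap_mask(self) -> np.ndarray:
        """Bins whose row has no nonzero off-diagonal entry."""
        off = self.matrix.copy()
        np.fill_diagonal(off, 0.0)
        return ~np.any(off != 0, axis=1)

    def copy_with(self, matrix: np.ndarray, stage: str) -> "BinnedContactMap":
        """New map at a later stage, propagating the current gap mask."""
        return BinnedContactMap(
            matrix=matrix,
            bin_size=self.bin_size,
            chrom=self.chrom,
            stage=stage,
            gap_mask=self.gap_mask.copy(),
        )
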