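"""Scikit-learn-style estimators wrapping the HiCS pipeline.

`BoundaryCaller` is clusterer-shaped: ``fit(X)`` on a symmetric contact
matrix computes the insulation profile and screens boundaries, and
``labels_`` assigns each bin to its domain (gap bins get -1), so the caller
composes with sklearn model selection and pipelines.
`HierarchicalDomainCaller` repeats the screening over an alpha ladder on
one shared profile.  `GraphEmbeddingSmoother` is the transformer form of
the preprocessing stage.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .contact_map import BinnedContactMap
from .domains import boundaries_to_domains, build_hierarchy, domain_size_stats
from .insulation import call_boundaries, compute_profile
from .preprocess import WalkParams, preprocess_map


def _as_map(X, bin_size: int) -> BinnedContactMap:
    if isinstance(X, BinnedContactMap):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != X.shape[1]:
        raise ValueError(f"expected a square contact matrix, got shape {X.shape}")
    return BinnedContactMap(X, bin_size=bin_size, stage="raw")


class GraphEmbeddingSmoother(TransformerMixin, BaseEstimator):
    """Transform a raw contact matrix into the sparsified similarity matrix.

    Parameters mirror the biased-random-walk embedding; ``keep_fraction``
    is the top share of non-gap bin pairs retained (0.05 keeps the top 5%).
    """

    def __init__(
        self,
        dimensions: int = 128,
        walk_length: int = 80,
        walks_per_node: int = 10,
        window: int = 10,
        p: float = 1.0,
        q: float = 1.0,
        keep_fraction: float = 0.05,
        bin_size: int = 40_000,
        random_state: int = 42,
    ):
        self.dimensions = dimensions
        self.walk_length = walk_length
        self.walks_per_node = walks_per_node
        self.window = window
        self.p = p
        self.q = q
        self.keep_fraction = keep_fraction
        self.bin_size = bin_size
        self.random_state = random_state

    def _walk_params(self) -> WalkParams:
        return WalkParams(
            dimensions=self.dimensions,
            walk_length=self.walk_length,
            walks_per_node=self.walks_per_node,
            context_window=self.window,
            return_p=self.p,
            inout_q=self.q,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        cmap = _as_map(X, self.bin_size)
        smoothed = preprocess_map(cmap, self._walk_params(), self.keep_fraction)
        self.n_bins_ = cmap.n_bins
        self.gap_mask_ = cmap.gap_mask
        self.smoothed_map_ = smoothed
        return self

    def transform(self, X=None):
        """Return the smoothed matrix of the map seen at fit time.

        The smoothing is map-specific (walks are simulated on the fitted
        graph), so `X` is accepted for pipeline compatibility but a map
        differing from the fitted one must be refit.
        """
        check_is_fitted(self, "smoothed_map_")
        return self.smoothed_map_.matrix

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


class BoundaryCaller(ClusterMixin, BaseEstimator):
    """Single-level boundary caller (density peaks on the insulation profile).

    Parameters
    ----------
    window_bins : int
        Half-width W of the insulation window in bins (800 kb / 40 kb = 20).
    max_search : int
        Range MAX of the search for a higher-strength bin, in bins.
    alpha : float
        Multiplier on the automatic reflection-point threshold eta(r).
    embed : bool
        When False the insulation profile is computed on raw counts
        directly, bypassing the graph-embedding smoothing (oracle mode for
        hand-made matrices).
    keep_fraction, dimensions, walk_length, walks_per_node, context_window,
    p, q, random_state : embedding stage, see `GraphEmbeddingSmoother`.

    Attributes
    ----------
    profile_ : InsulationProfile
    boundaries_ : BoundarySet
    domains_ : list of (start_bin, end_bin)
    labels_ : ndarray, domain index per bin, -1 for gap bins.
    """

    def __init__(
        self,
        bin_size: int = 40_000,
        window_bins: int = 20,
        max_search: int = 500,
        alpha: float = 1.0,
        embed: bool = True,
        keep_fraction: float = 0.05,
        dimensions: int = 128,
        walk_length: int = 80,
        walks_per_node: int = 10,
        context_window: int = 10,
        p: float = 1.0,
        q: float = 1.0,
        random_state: int = 42,
    ):
        self.bin_size = bin_size
        self.window_bins = window_bins
        self.max_search = max_search
        self.alpha = alpha
        self.embed = embed
        self.keep_fraction = keep_fraction
        self.dimensions = dimensions
        self.walk_length = walk_length
        self.walks_per_node = walks_per_node
        self.context_window = context_window
        self.p = p
        self.q = q
        self.random_state = random_state

    def _preprocessed(self, X) -> BinnedContactMap:
        cmap = _as_map(X, self.bin_size)
        if not self.embed:
            return cmap
        params = WalkParams(
            dimensions=self.dimensions,
            walk_length=self.walk_length,
            walks_per_node=self.walks_per_node,
            context_window=self.context_window,
            return_p=self.p,
            inout_q=self.q,
            seed=self.random_state,
        )
        return preprocess_map(cmap, params, self.keep_fraction)

    def fit(self, X, y=None):
        work = self._preprocessed(X)
        self.map_ = work
        self.profile_ = compute_profile(work, self.window_bins, self.max_search)
        self.boundaries_ = call_boundaries(self.profile_, self.alpha)
        self.domains_ = boundaries_to_domains(
            self.boundaries_.bins, work.n_bins, self.profile_.gap_mask
        )
        labels = np.full(work.n_bins, -1, dtype=np.int64)
        for k, (s, e) in enumerate(self.domains_):
            labels[s:e] = k
        self.labels_ = labels
        self.n_features_in_ = work.n_bins
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class HierarchicalDomainCaller(BaseEstimator):
    """Multi-alpha hierarchy caller over one shared insulation profile.

    Attributes
    ----------
    hierarchy_ : DomainHierarchy
    levels_ : list of HierarchyLevel (ascending alpha)
    stats_ : per-level size/strength summary dicts.
    """

    def __init__(
        self,
        alphas: tuple[float, ...] = (0.2, 1.0, 4.0, 8.0),
        bin_size: int = 40_000,
        window_bins: int = 20,
        max_search: int = 500,
        embed: bool = True,
        keep_fraction: float = 0.05,
        dimensions: int = 128,
        walk_length: int = 80,
        walks_per_node: int = 10,
        context_window: int = 10,
        p: float = 1.0,
        q: float = 1.0,
        random_state: int = 42,
    ):
        self.alphas = alphas
        self.bin_size = bin_size
        self.window_bins = window_bins
        self.max_search = max_search
        self.embed = embed
        self.keep_fraction = keep_fraction
        self.dimensions = dimensions
        self.walk_length = walk_length
        self.walks_per_node = walks_per_node
        self.context_window = context_window
        self.p = p
        self.q = q
        self.random_state = random_state

    def fit(self, X, y=None):
        base = BoundaryCaller(
            bin_size=self.bin_size,
            window_bins=self.window_bins,
            max_search=self.max_search,
            embed=self.embed,
            keep_fraction=self.keep_fraction,
            dimensions=self.dimensions,
            walk_length=self.walk_length,
            walks_per_node=self.walks_per_node,
            context_window=self.context_window,
            p=self.p,
            q=self.q,
            random_state=self.random_state,
        )
        work = base._preprocessed(X)
        self.map_ = work
        self.hierarchy_ = build_hierarchy(
            work, list(self.alphas), self.window_bins, self.max_search
        )
        self.levels_ = self.hierarchy_.levels
        self.stats_ = domain_size_stats(self.hierarchy_, work.bin_size)
        self.n_features_in_ = work.n_bins
        return self
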