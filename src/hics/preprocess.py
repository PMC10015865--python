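"""Smooth a sparse raw single-cell map into a contact-probability matrix.

The chromosome is modeled as an unweighted graph (bins = nodes, any nonzero
contact = an edge).  Nodes are embedded from biased second-order random
walks: walk co-occurrence counts within a context window are turned into a
positive pointwise-mutual-information (PPMI) matrix and factorized by
truncated SVD.  This is the classical closed-form counterpart of training
skip-gram with negative sampling on the same walks, and keeps the whole
pipeline deterministic under a fixed seed.  Contact probability between two
bins is the cosine similarity of their embedding vectors; only the top
fraction of bin pairs (5% by default) is kept, with the diagonal removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .contact_map import BinnedContactMap


@dataclass
class WalkParams:
    """Hyperparameters of the biased-random-walk embedding.

    ``return_p`` and ``inout_q`` follow the node2vec convention: the walk
    revisits its previous node with weight 1/p, moves to a common neighbor
    with weight 1, and moves outward with weight 1/q; p = q = 1 reduces to
    first-order unbiased walks.
    """

    dimensions: int = 128
    walk_length: int = 80
    walks_per_node: int = 10
    context_window: int = 10
    return_p: float = 1.0
    inout_q: float = 1.0
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("dimensions", "walk_length", "walks_per_node", "context_window"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.return_p <= 0 or self.inout_q <= 0:
            raise ValueError("return_p and inout_q must be > 0")


def build_graph(cmap: BinnedContactMap) -> nx.Graph:
    """Unweighted contact graph: every bin is a node, every nonzero
    off-diagonal pair an edge.  Gap bins stay as isolated nodes."""
    if cmap.stage != "raw":
        raise ValueError(f"graph is built from a raw map, got stage {cmap.stage!r}")
    g = nx.Graph()
    g.add_nodes_from(range(cmap.n_bins))
    iu, ju = np.nonzero(np.triu(cmap.matrix, k=1))
    g.add_edges_from(zip(iu.tolist(), ju.tolist()))
    return g


def _simulate_walks(
    indptr: np.ndarray,
    indices: np.ndarray,
    start_nodes: np.ndarray,
    params: WalkParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """All walks as an array of shape (n_walks, walk_length) of node ids.

    Uniform first-order stepping (p = q = 1) is fully vectorized across
    walks; the biased second-order case falls back to rejection sampling
    per step (still vectorized over walks).
    """
    starts = np.tile(start_nodes, params.walks_per_node)
    n_walks = starts.size
    walks = np.empty((n_walks, params.walk_length), dtype=np.int64)
    walks[:, 0] = starts
    degrees = np.diff(indptr)
    unbiased = params.return_p == 1.0 and params.inout_q == 1.0

    for step in range(1, params.walk_length):
        cur = walks[:, step - 1]
        deg = degrees[cur]
        pick = (rng.random(n_walks) * deg).astype(np.int64)
        nxt = indices[indptr[cur] + pick]
        if unbiased or step == 1:
            walks[:, step] = nxt
            continue
        prev = walks[:, step - 2]
        # rejection sampling against max(1, 1/p, 1/q) with node2vec weights
        w_max = max(1.0, 1.0 / params.return_p, 1.0 / params.inout_q)
        pending = np.ones(n_walks, dtype=bool)
        while np.any(pending):
            idx = np.nonzero(pending)[0]
            cand = nxt[idx]
            w = np.full(idx.size, 1.0 / params.inout_q)
            w[cand == prev[idx]] = 1.0 / params.return_p
            # common-neighbor test: is cand adjacent to prev?
            for k, (pv, cd) in enumerate(zip(prev[idx], cand)):
                if cd != pv and _is_edge(indptr, indices, pv, cd):
                    w[k] = 1.0
            accept = rng.random(idx.size) < (w / w_max)
            walks[idx[accept], step] = cand[accept]
            pending[idx[accept]] = False
            still = idx[~accept]
            if still.size:
                pick = (rng.random(still.size) * deg[still]).astype(np.int64)
                nxt[still] = indices[indptr[cur[still]] + pick]
    return walks


def _is_edge(indptr: np.ndarray, indices: np.ndarray, u: int, v: int) -> bool:
    row = indices[indptr[u] : indptr[u + 1]]
    pos = np.searchsorted(row, v)
    return pos < row.size and row[pos] == v


def embed_nodes(graph: nx.Graph, params: WalkParams | None = None) -> dict[int, np.ndarray]:
    """Embed every non-isolated node; isolated (gap) nodes get no vector.

    Walk co-occurrences within ``context_window`` are symmetrized, converted
    to PPMI, and factorized; node vectors are ``U * sqrt(S)`` of the top
    ``dimensions`` singular triplets (capped at the number of embeddable
    nodes).  Deterministic for a fixed seed.
    """
    params = params or WalkParams()
    nodes = np.array([n for n in graph.nodes if graph.degree[n] > 0], dtype=np.int64)
    if nodes.size == 0:
        raise ValueError("no embeddable nodes: the contact graph has no edges")
    relabel = {int(n): k for k, n in enumerate(nodes)}
    n = nodes.size
    adj = sp.lil_matrix((n, n), dtype=np.int8)
    for u, v in graph.edges:
        if u == v:
            continue
        adj[relabel[u], relabel[v]] = 1
        adj[relabel[v], relabel[u]] = 1
    csr = adj.tocsr()
    csr.sort_indices()
    rng = np.random.default_rng(params.seed)
    walks = _simulate_walks(csr.indptr, csr.indices, np.arange(n), params, rng)

    cooc = np.zeros((n, n), dtype=np.float64)
    flat = cooc.ravel()
    for off in range(1, min(params.context_window, params.walk_length - 1) + 1):
        a = walks[:, :-off].ravel()
        b = walks[:, off:].ravel()
        np.add.at(flat, a * n + b, 1.0)
        np.add.at(flat, b * n + a, 1.0)

    total = cooc.sum()
    row = cooc.sum(axis=1, keepdims=True)
    col = cooc.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(cooc * total / (row * col))
    ppmi = np.where(np.isfinite(pmi) & (pmi > 0), pmi, 0.0)

    d = min(params.dimensions, n)
    u, s, _ = np.linalg.svd(ppmi, full_matrices=False)
    vectors = u[:, :d] * np.sqrt(s[:d])
    return {int(node): vectors[k] for k, node in enumerate(nodes)}


def contact_probability(
    vectors: dict[int, np.ndarray], cmap: BinnedContactMap
) -> BinnedContactMap:
    """Cosine-similarity map over embedded bins (probability stage).

    The diagonal is zeroed; gap bins keep all-zero rows; a zero-norm vector
    has similarity 0 to everything.
    """
    if len(vectors) < 2:
        raise ValueError("need at least 2 embedded nodes to form probabilities")
    n = cmap.n_bins
    idx = np.fromiter(vectors.keys(), dtype=np.int64)
    mat_v = np.stack([vectors[int(i)] for i in idx])
    norms = np.linalg.norm(mat_v, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = mat_v / safe[:, None]
    unit[norms == 0] = 0.0
    sims = unit @ unit.T
    out = np.zeros((n, n), dtype=float)
    out[np.ix_(idx, idx)] = sims
    np.fill_diagonal(out, 0.0)
    out[cmap.gap_mask, :] = 0.0
    out[:, cmap.gap_mask] = 0.0
    out = (out + out.T) / 2.0  # exact symmetry against fp round-off
    return cmap.copy_with(out, stage="probability")


def sparsify_top_fraction(cmap: BinnedContactMap, fraction: float = 0.05) -> BinnedContactMap:
    """Keep the ceil(fraction * P) largest off-diagonal pairs, P counted over
    upper-triangle pairs of non-gap bins.  Ties at the cutoff value are all
    kept, so the result can slightly exceed the nominal count but never
    depends on array order."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if cmap.stage != "probability":
        raise ValueError("sparsification applies to a probability-stage map")
    n = cmap.n_bins
    keep_bins = ~cmap.gap_mask
    iu, ju = np.triu_indices(n, k=1)
    cand = keep_bins[iu] & keep_bins[ju]
    iu, ju = iu[cand], ju[cand]
    values = cmap.matrix[iu, ju]
    n_cand = values.size
    if n_cand == 0:
        return cmap.copy_with(np.zeros_like(cmap.matrix), stage="sparsified")
    k = math.ceil(fraction * n_cand)
    if k >= n_cand:
        cutoff = values.min()
    else:
        cutoff = np.partition(values, n_cand - k)[n_cand - k]
    sel = values >= cutoff
    out = np.zeros_like(cmap.matrix)
    out[iu[sel], ju[sel]] = values[sel]
    out[ju[sel], iu[sel]] = values[sel]
    return cmap.copy_with(out, stage="sparsified")


def preprocess_map(
    cmap: BinnedContactMap,
    params: WalkParams | None = None,
    keep_fraction: float = 0.05,
) -> BinnedContactMap:
    """Full smoothing pipeline: graph -> embedding -> cosine -> top fraction."""
    graph = build_graph(cmap)
    vectors = embed_nodes(graph, params)
    prob = contact_probability(vectors, cmap)
    return sparsify_top_fraction(prob, keep_fraction)
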