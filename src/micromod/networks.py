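"""Per-session functional networks and degree-matched surrogate nulls.

A functional network is the significance-thresholded conditional-GC
adjacency for one session: entry ``(i, j)`` is the causality from
source j to target i, zero if not significant.  Chance baselines come
from degree-matched surrogates: directed double-edge swaps that exactly
preserve every node's in- and out-degree while scrambling topology,
with each edge's weight travelling with its source (out-going) stub.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .granger import GCMatrix
from .layout import ArrayLayout

__all__ = [
    "FunctionalNetwork",
    "SurrogateEnsemble",
    "network_from_gc",
    "session_similarity",
    "connection_probability",
    "degree_matched_surrogates",
]


@dataclass
class FunctionalNetwork:
    """Weighted directed adjacency for one session.

    ``adjacency[i, j]`` is the (thresholded) GC from j to i in nats;
    the diagonal is zero.
    """

    adjacency: np.ndarray
    session_id: str = "session-0"
    layout: ArrayLayout | None = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        a = self.adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if np.any(a < 0):
            raise ValueError("adjacency weights must be non-negative")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def connection_probability(self) -> float:
        return connection_probability(self)


@dataclass
class SurrogateEnsemble:
    """Degree-matched rewired surrogates of one functional network."""

    adjacencies: np.ndarray  # (n_surrogates, n, n)
    swap_passes: int
    seed: int
    session_id: str = "session-0"

    @property
    def n_surrogates(self) -> int:
        return self.adjacencies.shape[0]


def network_from_gc(
    gcm: GCMatrix, session_id: str = "session-0", layout: ArrayLayout | None = None
) -> FunctionalNetwork:
    """Wrap a (thresholded) GC matrix as a functional network."""
    a = np.array(gcm.F, dtype=float)
    a[~np.isfinite(a)] = 0.0
    np.fill_diagonal(a, 0.0)
    return FunctionalNetwork(adjacency=a, session_id=session_id, layout=layout)


def session_similarity(nets: list[FunctionalNetwork]):
    """Pearson correlation between session adjacency matrices.

    Correlations are computed between the vectorized off-diagonal
    entries (zeros included: the sparsity pattern is part of network
    identity) for every session pair.  Returns the pairwise matrix and
    the mean over distinct pairs.
    """
    if len(nets) < 2:
        raise ValueError("need at least two sessions")
    n = nets[0].n_nodes
    if any(net.n_nodes != n for net in nets):
        raise ValueError("all sessions must share the same node set")
    off = ~np.eye(n, dtype=bool)
    vecs = np.array([net.adjacency[off] for net in nets])
    r = np.corrcoef(vecs)
    iu = np.triu_indices(len(nets), k=1)
    return r, float(np.mean(r[iu]))


def connection_probability(net: FunctionalNetwork) -> float:
    """Nonzero ordered pairs / N(N-1)."""
    n = net.n_nodes
    off = ~np.eye(n, dtype=bool)
    return float(np.count_nonzero(net.adjacency[off]) / (n * (n - 1)))


def _swap_edges_py(src, dst, has_edge, passes, seed):
    """In-place directed double-edge swaps; one pass attempts |E| swaps.

    Swap (a->b, c->d) => (a->d, c->b), rejected if it would create a
    self-loop or a multi-edge.  Sources never move, so out-degrees (and
    the weights riding the out-stubs) are untouched; destinations are
    exchanged, so in-degrees are preserved too.
    """
    np.random.seed(seed)
    ne = src.size
    for _ in range(passes * ne):
        e1 = np.random.randint(0, ne)
        e2 = np.random.randint(0, ne)
        if e1 == e2:
            continue
        a, b = src[e1], dst[e1]
        c, d = src[e2], dst[e2]
        if a == d or c == b or b == d:
            continue
        if has_edge[a, d] or has_edge[c, b]:
            continue
        has_edge[a, b] = False
        has_edge[c, d] = False
        has_edge[a, d] = True
        has_edge[c, b] = True
        dst[e1] = d
        dst[e2] = b


_swap_edges = None


def _get_swap_edges():
    global _swap_edges
    if _swap_edges is None:
        try:
            import numba

            _swap_edges = numba.njit(cache=True)(_swap_edges_py)
        except ImportError:  # pragma: no cover
            _swap_edges = _swap_edges_py
    return _swap_edges


def degree_matched_surrogates(
    net: FunctionalNetwork, n: int = 500, passes: int = 100, seed: int = 0
) -> SurrogateEnsemble:
    """Build an ensemble of degree-matched rewired surrogate networks.

    Each surrogate starts from the real edge list and applies ``passes``
    rounds of |E| attempted double-edge swaps.  In/out degree sequences
    are asserted equal to the original for every surrogate.  A network
    with fewer than two edges cannot be rewired; the surrogates are then
    copies and a warning is raised.
    """
    a = net.adjacency
    nn = net.n_nodes
    dst0, src0 = np.nonzero(a)  # a[i, j]: source j -> target i
    weights = a[dst0, src0]
    out = []
    if src0.size < 2:
        warnings.warn("fewer than two edges; surrogates are copies", stacklevel=2)
        out = [a.copy() for _ in range(n)]
    else:
        in_deg0 = np.count_nonzero(a, axis=1)
        out_deg0 = np.count_nonzero(a, axis=0)
        swapper = _get_swap_edges()
        root = np.random.SeedSequence(seed)
        sub_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n)]
        for k in range(n):
            src = src0.copy()
            dst = dst0.copy()
            has_edge = np.zeros((nn, nn), dtype=bool)
            has_edge[src, dst] = True
            swapper(src, dst, has_edge, passes, sub_seeds[k])
            s = np.zeros_like(a)
            s[dst, src] = weights
            assert np.array_equal(np.count_nonzero(s, axis=1), in_deg0)
            assert np.array_equal(np.count_nonzero(s, axis=0), out_deg0)
            out.append(s)
    return SurrogateEnsemble(
        adjacencies=np.array(out), swap_passes=passes, seed=seed, session_id=net.session_id
    )
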