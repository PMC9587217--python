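"""Multilayer (temporal) networks and modularity maximization.

Session adjacency matrices are stacked chronologically as layers and
each electrode is linked to itself in the next layer with uniform
weight omega (diagonal-ordinal-uniform coupling), set by default to the
median nonzero intra-layer weight.  The quality of a node-by-layer
partition is

    Q_ml = (1/mu) sum_ijst [ (A_ijs - gamma P_ijs) d_st + d_ij w_jst ]
           d(c_is, c_jt)

with the directed Leicht-Newman null P_ijs = k_i^in(s) k_j^out(s) / m_s
per layer, mu the total weight of all intra- and inter-layer edges, and
gamma the resolution parameter (default 1).  Q_ml <= 1; interlayer
edges enter only the coupling term, never the null.

Maximization uses a generalized Louvain heuristic on node-layer
supernodes (greedy modularity moves in random order, then aggregation,
iterated to convergence), restarted many times because the quality
landscape is nearly degenerate; the best partition and all restart
qualities are returned.  Partition dynamics are summarised by
stationarity (co-classification Jaccard between consecutive layers) and
normalized persistence (fraction of node transitions that keep their
module label).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .networks import FunctionalNetwork, SurrogateEnsemble

__all__ = [
    "MultilayerNetwork",
    "MultilayerPartition",
    "build_multilayer",
    "quality",
    "louvain_optimize",
    "stationarity",
    "normalized_persistence",
    "exhaustive_max_quality",
    "compare_to_surrogates",
]


@dataclass
class MultilayerNetwork:
    """Layer stack with uniform diagonal-ordinal interlayer coupling."""

    layers: list[np.ndarray]
    omega: float
    coupling: str = "diagonal-ordinal-uniform"

    def __post_init__(self) -> None:
        self.layers = [np.asarray(a, dtype=float) for a in self.layers]
        n = self.layers[0].shape[0]
        if any(a.shape != (n, n) for a in self.layers):
            raise ValueError("all layers must be square with identical node sets")
        if self.omega < 0:
            raise ValueError("omega must be non-negative")

    @property
    def n_nodes(self) -> int:
        return self.layers[0].shape[0]

    @property
    def n_layers(self) -> int:
        return len(self.layers)


@dataclass
class MultilayerPartition:
    """Community labels per node per layer plus optimization metadata."""

    labels: np.ndarray  # (n_nodes, n_layers)
    quality: float
    gamma: float
    omega: float
    restart_qualities: np.ndarray = field(default=None)  # type: ignore[assignment]

    def layer_labels(self, s: int) -> np.ndarray:
        return self.labels[:, s]

    @property
    def n_layers(self) -> int:
        return self.labels.shape[1]


def build_multilayer(
    nets: list[FunctionalNetwork], omega: float | None = None
) -> MultilayerNetwork:
    """Stack session networks chronologically into a multilayer network.

    With ``omega=None`` the interlayer weight is the median nonzero
    intra-layer weight pooled over all sessions, keeping across-layer
    links on the scale of the within-layer links.
    """
    if not nets:
        raise ValueError("need at least one session network")
    n = nets[0].n_nodes
    if any(net.n_nodes != n for net in nets):
        raise ValueError("sessions have mismatched node sets")
    layers = [net.adjacency for net in nets]
    if omega is None:
        nz = np.concatenate([a[a > 0] for a in layers]) if layers else np.array([])
        if nz.size == 0:
            warnings.warn("no nonzero weights in any layer; omega set to 0", stacklevel=2)
            omega = 0.0
        else:
            omega = float(np.median(nz))
    return MultilayerNetwork(layers=layers, omega=omega)


def _null_matrix(a: np.ndarray) -> np.ndarray:
    """Directed Leicht-Newman null k_in k_out^T / m for one layer."""
    m = a.sum()
    if m == 0:
        return np.zeros_like(a)
    k_in = a.sum(axis=1)
    k_out = a.sum(axis=0)
    return np.outer(k_in, k_out) / m


def _total_weight(mlnet: MultilayerNetwork) -> float:
    intra = sum(a.sum() for a in mlnet.layers)
    inter = mlnet.n_nodes * (mlnet.n_layers - 1) * mlnet.omega
    return intra + inter


def quality(mlnet: MultilayerNetwork, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Evaluate Q_ml for a node-by-layer partition (direct definition)."""
    labels = np.asarray(labels)
    n, S = mlnet.n_nodes, mlnet.n_layers
    if labels.shape != (n, S):
        raise ValueError(f"labels must have shape ({n}, {S})")
    mu = _total_weight(mlnet)
    if mu == 0:
        return 0.0
    total = 0.0
    for s, a in enumerate(mlnet.layers):
        b = a - gamma * _null_matrix(a)
        same = labels[:, s][:, None] == labels[:, s][None, :]
        total += b[same].sum()
    for s in range(S - 1):
        total += mlnet.omega * np.count_nonzero(labels[:, s] == labels[:, s + 1])
    return float(total / mu)


def _supra_modularity(mlnet: MultilayerNetwork, gamma: float) -> np.ndarray:
    """Symmetrized supra-modularity matrix over node-layer supernodes.

    Supernode u = s * N + i.  Intra-layer blocks hold (A - gamma P)/mu;
    ordinal coupling contributes omega/(2 mu) on each directed
    inter-layer entry so an unordered link totals omega/mu.  The sum of
    entries over co-assigned supernode pairs equals Q_ml exactly.
    """
    n, S = mlnet.n_nodes, mlnet.n_layers
    mu = _total_weight(mlnet)
    B = np.zeros((n * S, n * S))
    if mu == 0:
        return B
    for s, a in enumerate(mlnet.layers):
        B[s * n : (s + 1) * n, s * n : (s + 1) * n] = (a - gamma * _null_matrix(a)) / mu
    for s in range(S - 1):
        idx = np.arange(n)
        B[s * n + idx, (s + 1) * n + idx] += mlnet.omega / (2 * mu)
        B[(s + 1) * n + idx, s * n + idx] += mlnet.omega / (2 * mu)
    return (B + B.T) / 2


def _local_move(
    B: np.ndarray, labels: np.ndarray, rng: np.random.Generator, randmove: bool = True
) -> bool:
    """Greedy passes until no node wants to move; True if any move made.

    With ``randmove`` the destination is drawn uniformly among the
    strictly improving communities rather than the best one; this
    diversifies restarts across the near-degenerate quality landscape.
    """
    n = B.shape[0]
    improved = False
    moved = True
    while moved:
        moved = False
        for u in rng.permutation(n):
            lu = labels[u]
            w = B[u]
            k = labels.max() + 1
            comm_sum = np.bincount(labels, weights=w, minlength=k + 1)
            comm_sum[lu] -= w[u]  # own-community sum excluding self
            # index k is a fresh empty community (sum 0): allows splits
            gains = comm_sum - comm_sum[lu]
            cand = np.nonzero(gains > 1e-14)[0]
            if cand.size:
                target = int(rng.choice(cand)) if randmove else int(cand[np.argmax(gains[cand])])
                labels[u] = target
                moved = True
                improved = True
    return improved


def _relabel(labels: np.ndarray) -> np.ndarray:
    _, inv = np.unique(labels, return_inverse=True)
    return inv


def _aggregate(B: np.ndarray, labels: np.ndarray) -> np.ndarray:
    k = labels.max() + 1
    M = np.zeros((B.shape[0], k))
    M[np.arange(B.shape[0]), labels] = 1.0
    return M.T @ B @ M


def _partition_value(B: np.ndarray, labels: np.ndarray) -> float:
    same = labels[:, None] == labels[None, :]
    return float(B[same].sum())


def _louvain_single(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One Louvain run: alternate node-level moves (starting from the
    current partition, which also repairs aggregation lock-in) with
    moves of whole communities on the aggregated matrix."""
    n0 = B.shape[0]
    assign = np.arange(n0)
    q_best = _partition_value(B, assign)
    while True:
        labels = assign.copy()
        _local_move(B, labels, rng)
        assign = _relabel(labels)
        agg = np.arange(assign.max() + 1)
        _local_move(_aggregate(B, assign), agg, rng)
        assign = _relabel(agg[assign])
        q = _partition_value(B, assign)
        if q <= q_best + 1e-14:
            break
        q_best = q
    return assign


def louvain_optimize(
    mlnet: MultilayerNetwork,
    gamma: float = 1.0,
    n_restarts: int = 500,
    seed: int = 0,
) -> MultilayerPartition:
    """Best-of-restarts generalized Louvain maximization of Q_ml.

    Each restart runs greedy local moves in an independent random node
    order followed by aggregation, iterated to convergence.  Restart r
    uses its own child RNG of ``seed`` so partial re-runs reproduce.
    Returns the best partition (ties: first found) with every restart's
    quality for degeneracy inspection.
    """
    n, S = mlnet.n_nodes, mlnet.n_layers
    if n == 0:
        raise ValueError("empty network")
    B = _supra_modularity(mlnet, gamma)
    qualities = np.empty(n_restarts)
    best_q = -np.inf
    best_labels = None
    children = np.random.SeedSequence(seed).spawn(n_restarts)
    for r in range(n_restarts):
        rng = np.random.default_rng(children[r])
        assign = _louvain_single(B, rng)
        labels = assign.reshape(S, n).T
        q = quality(mlnet, labels, gamma)
        qualities[r] = q
        if q > best_q + 1e-15:
            best_q = q
            best_labels = labels
    return MultilayerPartition(
        labels=best_labels,
        quality=float(best_q),
        gamma=gamma,
        omega=mlnet.omega,
        restart_qualities=qualities,
    )


# ---------------------------------------------------------------------------
# partition dynamics
# ---------------------------------------------------------------------------

def _copair_matrix(layer_labels: np.ndarray) -> np.ndarray:
    same = layer_labels[:, None] == layer_labels[None, :]
    return np.triu(same, k=1)


def stationarity(part: MultilayerPartition, method: str = "jaccard") -> float:
    """Mean similarity of consecutive-layer partitions.

    ``jaccard`` (default): co-assigned node pairs present in both layers
    over pairs co-assigned in either.  ``pearson``: correlation of the
    co-assignment indicator vectors over node pairs.
    """
    if part.n_layers < 2:
        raise ValueError("stationarity undefined for a single layer")
    vals = []
    for s in range(part.n_layers - 1):
        a = _copair_matrix(part.layer_labels(s))
        b = _copair_matrix(part.layer_labels(s + 1))
        if method == "jaccard":
            union = np.count_nonzero(a | b)
            vals.append(np.count_nonzero(a & b) / union if union else 1.0)
        elif method == "pearson":
            iu = np.triu_indices(a.shape[0], k=1)
            va, vb = a[iu].astype(float), b[iu].astype(float)
            if va.std() == 0 or vb.std() == 0:
                vals.append(1.0 if np.array_equal(va, vb) else 0.0)
            else:
                vals.append(float(np.corrcoef(va, vb)[0, 1]))
        else:
            raise ValueError("method must be 'jaccard' or 'pearson'")
    return float(np.mean(vals))


def normalized_persistence(part: MultilayerPartition) -> float:
    """Fraction of node transitions that keep their community label."""
    if part.n_layers < 2:
        raise ValueError("persistence undefined for a single layer")
    same = part.labels[:, :-1] == part.labels[:, 1:]
    return float(np.mean(same))


# ---------------------------------------------------------------------------
# exhaustive oracle (small instances)
# ---------------------------------------------------------------------------

def _enumerate_max_py(B: np.ndarray) -> float:
    n = B.shape[0]
    assign = np.full(n, -1, dtype=np.int64)
    cand = np.zeros(n, dtype=np.int64)
    maxl = np.full(n + 1, -1, dtype=np.int64)
    qacc = np.zeros(n + 1)
    best = -1e300
    k = 0
    while k >= 0:
        if k == n:
            if qacc[n] > best:
                best = qacc[n]
            k -= 1
            continue
        c = cand[k]
        if c > maxl[k] + 1:
            cand[k] = 0
            k -= 1
            continue
        delta = B[k, k]
        for m in range(k):
            if assign[m] == c:
                delta += 2.0 * B[k, m]
        assign[k] = c
        qacc[k + 1] = qacc[k] + delta
        maxl[k + 1] = maxl[k] if maxl[k] >= c else c
        cand[k] = c + 1
        cand[k + 1] = 0
        k += 1
    return best


_enumerate_max = None


def _get_enumerator():
    global _enumerate_max
    if _enumerate_max is None:
        try:
            import numba

            _enumerate_max = numba.njit(cache=True)(_enumerate_max_py)
        except ImportError:  # pragma: no cover
            _enumerate_max = _enumerate_max_py
    return _enumerate_max


def exhaustive_max_quality(mlnet: MultilayerNetwork, gamma: float = 1.0) -> float:
    """Exact maximum of Q_ml over *all* partitions of node-layer pairs.

    Enumerates every set partition of the supernodes (restricted-growth
    strings) with an incremental quality update.  Feasible only for
    small instances (about 12 supernodes, Bell(12) ~ 4.2M partitions).
    """
    n_super = mlnet.n_nodes * mlnet.n_layers
    if n_super > 14:
        raise ValueError(f"{n_super} node-layer pairs is too large for enumeration")
    B = _supra_modularity(mlnet, gamma)
    return float(_get_enumerator()(B))


# ---------------------------------------------------------------------------
# surrogate comparison
# ---------------------------------------------------------------------------

def compare_to_surrogates(
    real_nets: list[FunctionalNetwork],
    ensembles: list[SurrogateEnsemble],
    metric,
    n_surrogates: int | None = None,
) -> dict:
    """Evaluate a partition metric on real vs surrogate multilayer nets.

    ``metric`` maps a list of adjacency layers to a scalar (it should
    run the same optimization settings for real and surrogate data).
    The k-th surrogate network takes layer s from the k-th surrogate of
    session s's ensemble.  Returns the real value and the surrogate
    distribution.
    """
    if not ensembles or any(e.n_surrogates == 0 for e in ensembles):
        raise ValueError("empty surrogate ensemble")
    if len(ensembles) != len(real_nets):
        raise ValueError("need one ensemble per session")
    n_sur = min(e.n_surrogates for e in ensembles)
    if n_surrogates is not None:
        n_sur = min(n_sur, n_surrogates)
    real_value = float(metric([net.adjacency for net in real_nets]))
    sur = np.array(
        [float(metric([e.adjacencies[k] for e in ensembles])) for k in range(n_sur)]
    )
    return {"real": real_value, "surrogates": sur}
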