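"""Binary-network metrics: density, clustering, path length, rewiring nulls,
small-world indices, physical connection lengths and matrix reordering.

Conventions (all logged where they bite):

* nodes with degree < 2 have clustering coefficient 0 and are included in
  the average; callers may restrict averages to an ``active`` node subset
  (the pipeline passes the non-empty parcellation nodes);
* the characteristic path length averages over connected ordered pairs
  only, and the number of excluded (unreachable) pairs is reported;
* null networks are degree-preserving double-edge-swap surrogates, with
  "each edge rewired R times" implemented as R x |E| attempted swaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from ._kernels import bandwidth_search, double_edge_swap

__all__ = [
    "NullEnsemble",
    "edge_density",
    "degrees",
    "clustering_coefficient",
    "characteristic_path_length",
    "rewire_null",
    "scaled_metrics",
    "degree_distribution",
    "edge_lengths",
    "connection_length_histogram",
    "reorder_matrix",
]

log = logging.getLogger(__name__)


def _as_binary(adjacency: np.ndarray) -> np.ndarray:
    adj = np.asarray(adjacency)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError(f"adjacency must be square, got {adj.shape}")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diagonal(adj) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    return (adj != 0).astype(np.float64)


def _active_mask(n: int, active) -> np.ndarray:
    if active is None:
        return np.ones(n, dtype=bool)
    active = np.asarray(active)
    if active.dtype == bool:
        return active
    mask = np.zeros(n, dtype=bool)
    mask[active] = True
    return mask


@dataclass(frozen=True)
class NullEnsemble:
    """Degree-preserving surrogate ensemble and its mean C and L."""

    rewires_per_edge: int
    n_networks: int
    C_rand: float
    L_rand: float
    C_samples: np.ndarray
    L_samples: np.ndarray
    seed: int | None


def degrees(adjacency: np.ndarray) -> np.ndarray:
    return _as_binary(adjacency).sum(axis=1).astype(int)


def edge_density(adjacency: np.ndarray, active=None) -> float:
    """2|E| / (N'(N'-1)) over the active node set (default: all nodes)."""
    a = _as_binary(adjacency)
    mask = _active_mask(a.shape[0], active)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("edge density needs at least 2 active nodes")
    sub = a[np.ix_(mask, mask)]
    return float(sub.sum() / (n * (n - 1)))


def clustering_coefficient(
    adjacency: np.ndarray, active=None
) -> tuple[np.ndarray, float]:
    """Per-node clustering C_i and the average over active nodes.

    C_i = 2 T_i / (k_i (k_i - 1)) with T_i the number of triangles through
    node i; nodes of degree < 2 get C_i = 0 and stay in the average.
    """
    a = _as_binary(adjacency)
    k = a.sum(axis=1)
    tri = ((a @ a) * a).sum(axis=1) / 2.0  # triangles through each node
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c_i = np.where(denom > 0, 2.0 * tri / denom, 0.0)
    mask = _active_mask(a.shape[0], active)
    if not mask.any():
        raise ValueError("no active nodes")
    return c_i, float(c_i[mask].mean())


def characteristic_path_length(
    adjacency: np.ndarray, active=None, return_excluded: bool = False
):
    """Mean shortest-path length over connected ordered pairs of active nodes.

    Unreachable pairs are excluded; their count is logged (and returned if
    ``return_excluded``).  Raises if no pair is connected.
    """
    a = _as_binary(adjacency)
    mask = _active_mask(a.shape[0], active)
    idx = np.flatnonzero(mask)
    if len(idx) < 2:
        raise ValueError("path length needs at least 2 active nodes")
    d = shortest_path(csr_array(a), method="D", directed=False, unweighted=True)
    d = d[np.ix_(idx, idx)]
    off = ~np.eye(len(idx), dtype=bool)
    finite = np.isfinite(d) & off
    n_excluded = int(off.sum() - finite.sum())
    if n_excluded:
        log.info("path length: excluded %d unreachable ordered pairs", n_excluded)
    if not finite.any():
        raise ValueError("no connected pair of active nodes")
    L = float(d[finite].mean())
    if return_excluded:
        return L, n_excluded
    return L


def _edge_list(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    iu, ju = np.nonzero(np.triu(a, 1))
    return iu.astype(np.int64), ju.astype(np.int64)


def rewire_null(
    adjacency: np.ndarray,
    rewires_per_edge: int = 1000,
    n_networks: int = 100,
    seed: int | None = None,
    active=None,
) -> NullEnsemble:
    """Ensemble of degree-preserving randomized surrogates.

    Each surrogate starts from the input and undergoes
    ``rewires_per_edge * |E|`` attempted double-edge swaps (rejections —
    self-loops, multi-edges, shared vertices — count as attempts).  C and L
    of each surrogate use the same conventions as the input metrics;
    ``C_rand`` and ``L_rand`` are ensemble means.
    """
    a = _as_binary(adjacency)
    u0, v0 = _edge_list(a)
    m = len(u0)
    if m < 2:
        raise ValueError("rewiring requires at least 2 edges")
    attempts = int(rewires_per_edge) * m
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    streams = ss.spawn(n_networks)
    c_s = np.empty(n_networks)
    l_s = np.empty(n_networks)
    any_swaps = 0
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        u = u0.copy()
        v = v0.copy()
        adj = a.astype(bool)
        e1 = rng.integers(0, m, size=attempts, dtype=np.int64)
        e2 = rng.integers(0, m, size=attempts, dtype=np.int64)
        flip = rng.integers(0, 2, size=attempts, dtype=np.int64)
        any_swaps += double_edge_swap(u, v, adj, e1, e2, flip)
        surrogate = adj.astype(np.float64)
        _, c_s[r] = clustering_coefficient(surrogate, active)
        l_s[r] = characteristic_path_length(surrogate, active)
    if any_swaps == 0:
        log.warning("no swappable edge pair exists; surrogates equal the input")
    return NullEnsemble(
        rewires_per_edge=int(rewires_per_edge),
        n_networks=int(n_networks),
        C_rand=float(c_s.mean()),
        L_rand=float(l_s.mean()),
        C_samples=c_s,
        L_samples=l_s,
        seed=seed,
    )


def scaled_metrics(
    adjacency: np.ndarray, null: NullEnsemble, active=None
) -> tuple[float, float, float]:
    """gamma = C/C_rand, lambda = L/L_rand, sigma = gamma/lambda."""
    if null.C_rand <= 0:
        raise ValueError(
            f"C_rand = {null.C_rand}: surrogates are triangle-free, "
            "scaled clustering is undefined"
        )
    if null.L_rand <= 0:
        raise ValueError(f"L_rand = {null.L_rand} is not positive")
    _, c = clustering_coefficient(adjacency, active)
    length = characteristic_path_length(adjacency, active)
    gamma = c / null.C_rand
    lam = length / null.L_rand
    return float(gamma), float(lam), float(gamma / lam)


def degree_distribution(
    adjacency: np.ndarray, bins=None
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of node degrees: (counts, bin_edges); unit bins by default."""
    k = degrees(adjacency)
    if bins is None:
        edges = np.arange(k.max() + 2) - 0.5
    else:
        edges = np.asarray(bins, dtype=float)
    counts, edges = np.histogram(k, bins=edges)
    return counts, edges


def edge_lengths(adjacency: np.ndarray, node_centroids_mm: np.ndarray) -> np.ndarray:
    """Euclidean mm distance between the centroids of each connected pair."""
    a = _as_binary(adjacency)
    cent = np.asarray(node_centroids_mm, dtype=float)
    iu, ju = _edge_list(a)
    pts_i, pts_j = cent[iu], cent[ju]
    if np.any(~np.isfinite(pts_i)) or np.any(~np.isfinite(pts_j)):
        raise ValueError("an edge is incident to a node without a centroid")
    return np.linalg.norm(pts_i - pts_j, axis=1)


def connection_length_histogram(
    adjacency: np.ndarray,
    node_centroids_mm: np.ndarray,
    bin_width_mm: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Binned physical connection lengths, one length per edge."""
    lengths = edge_lengths(adjacency, node_centroids_mm)
    if len(lengths) == 0:
        return np.array([], dtype=int), np.array([0.0, bin_width_mm])
    top = np.ceil(lengths.max() / bin_width_mm) * bin_width_mm
    edges = np.arange(0.0, top + bin_width_mm / 2, bin_width_mm)
    counts, edges = np.histogram(lengths, bins=edges)
    return counts, edges


def reorder_matrix(
    adjacency: np.ndarray,
    attempts: int = 1_000_000,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stochastic search for a node order concentrating edges near the diagonal.

    Minimises f(pi) = sum over edges |pi(i) - pi(j)| by proposing random
    transpositions and accepting whenever f does not increase.  Returns the
    permutation ``pi`` (node -> position) and the non-increasing objective
    trace (initial value followed by one entry per attempt).
    """
    if attempts < 1:
        raise ValueError("attempts must be >= 1")
    a = _as_binary(adjacency)
    n = a.shape[0]
    iu, ju = _edge_list(a)
    pos = np.arange(n, dtype=np.int64)
    f0 = int(np.abs(iu - ju).sum())
    rng = np.random.default_rng(seed)
    prop_u = rng.integers(0, n, size=attempts, dtype=np.int64)
    prop_v = rng.integers(0, n, size=attempts, dtype=np.int64)
    csr = csr_array(a)
    trace = np.empty(attempts, dtype=np.int64)
    bandwidth_search(
        pos,
        csr.indptr.astype(np.int64),
        csr.indices.astype(np.int64),
        prop_u,
        prop_v,
        f0,
        trace,
    )
    return pos, np.concatenate([[f0], trace])
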