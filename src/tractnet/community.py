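"""Spectral modularity community detection and cortical module mapping.

Implements Newman's leading-eigenvector method: recursive bisection of the
(generalized) modularity matrix with Kernighan–Lin-style single-node
fine-tuning after every split, stopping when no split increases Q.  A
fixed-K variant constrains the module count by greedy Q-maximising merges
(too many modules) or forced bisections (too few), so every subject can be
segmented into the same number of modules (five, by default, in the
shipped analyses) and compared across development.

Degree-zero nodes receive module label 0 (unassigned) and are excluded
from Q.  Eigenvectors come from a dense symmetric solver, so results are
deterministic; sign ties are broken toward the first module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .parcellation import Parcellation

__all__ = [
    "ModulePartition",
    "modularity_Q",
    "spectral_communities",
    "optimal_module_count",
    "fixed_k_modules",
    "map_modules_to_cortex",
]

log = logging.getLogger(__name__)

_EIG_TOL = 1e-10
_DQ_TOL = 1e-12


@dataclass(frozen=True)
class ModulePartition:
    """Node-to-module labelling (1..K; 0 = unassigned) with its modularity."""

    labels: np.ndarray
    n_modules: int
    Q: float


def _as_binary(adjacency: np.ndarray) -> np.ndarray:
    adj = np.asarray(adjacency)
    if not np.array_equal(adj, adj.T) or np.any(np.diagonal(adj) != 0):
        raise ValueError("adjacency must be symmetric with a zero diagonal")
    return (adj != 0).astype(float)


def modularity_Q(adjacency: np.ndarray, labels: np.ndarray) -> float:
    """Newman–Girvan modularity of a labelling.

    Q = sum_c (e_cc - a_c^2): the fraction of edges inside each module
    minus the expected fraction given the degree sequence.  Label-0
    (unassigned) nodes are ignored.
    """
    a = _as_binary(adjacency)
    labels = np.asarray(labels)
    k = a.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        raise ValueError("modularity is undefined for an edgeless graph")
    q = 0.0
    for c in np.unique(labels):
        if c == 0:
            continue
        sel = labels == c
        e_cc = a[np.ix_(sel, sel)].sum() / two_m
        a_c = k[sel].sum() / two_m
        q += e_cc - a_c * a_c
    return float(q)


def _kl_refine(s: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Kernighan–Lin single-node fine-tuning of a bisection vector.

    Repeatedly moves every node once (in order of best gain in s'Bs, even
    if negative), keeps the best intermediate state, and iterates while
    that best state improves.
    """
    n = len(s)
    diag = np.diagonal(B).copy()
    q_ref = float(s @ B @ s)
    for _ in range(100):  # pass cap; convergence is typically a few passes
        s_work = s.copy()
        bs = B @ s_work
        q_cur = float(s_work @ bs)
        q_best = q_cur
        s_best = s_work.copy()
        moved = np.zeros(n, dtype=bool)
        for _ in range(n):
            gains = -4.0 * s_work * bs + 4.0 * diag
            gains[moved] = -np.inf
            i = int(np.argmax(gains))
            q_cur += gains[i]
            bs = bs - 2.0 * s_work[i] * B[:, i]
            s_work[i] = -s_work[i]
            moved[i] = True
            if q_cur > q_best:
                q_best = q_cur
                s_best = s_work.copy()
        # accept the pass only on a strict, exactly recomputed improvement
        q_new = float(s_best @ B @ s_best)
        if q_new <= q_ref + 1e-9 * max(1.0, abs(q_ref)):
            return s
        s, q_ref = s_best, q_new
    return s


def _bisect_group(B_full: np.ndarray, group: np.ndarray, force: bool = False):
    """Best bisection of ``group`` by the generalized modularity matrix.

    Returns (s, delta) where s is the +/-1 split vector over the group and
    delta = s'B^g s (proportional to 4m * dQ), or None when the group is
    indivisible and ``force`` is False.  With ``force`` a non-trivial split
    is always produced (median split of the eigenvector, index split as a
    last resort).
    """
    bg = B_full[np.ix_(group, group)].copy()
    np.fill_diagonal(bg, np.diagonal(bg) - bg.sum(axis=1))
    vals, vecs = np.linalg.eigh(bg)
    lead = vecs[:, -1]
    if vals[-1] <= _EIG_TOL and not force:
        return None
    s = np.where(lead >= 0, 1.0, -1.0)  # sign ties toward module 1
    s = _kl_refine(s, bg)
    if np.all(s == s[0]):
        if not force:
            return None
        order = np.argsort(lead, kind="stable")
        s = np.ones(len(group))
        s[order[: len(group) // 2]] = -1.0
    delta = float(s @ bg @ s)
    if delta <= _DQ_TOL and not force:
        return None
    return s, delta


def _modularity_matrix(a: np.ndarray) -> np.ndarray:
    k = a.sum(axis=1)
    two_m = k.sum()
    return a - np.outer(k, k) / two_m


def _relabel(groups: list, n: int) -> np.ndarray:
    """1..K labels, modules ordered by their lowest node id."""
    labels = np.zeros(n, dtype=np.int64)
    for new_id, g in enumerate(
        sorted(groups, key=lambda g: int(np.min(g))), start=1
    ):
        labels[g] = new_id
    return labels


def spectral_communities(adjacency: np.ndarray) -> ModulePartition:
    """Leading-eigenvector recursive bisection with KL fine-tuning."""
    a = _as_binary(adjacency)
    k = a.sum(axis=1)
    if k.sum() == 0:
        raise ValueError("community detection needs at least one edge")
    active = np.flatnonzero(k > 0)
    B = _modularity_matrix(a)

    final: list[np.ndarray] = []
    stack = [active]
    while stack:
        group = stack.pop()
        if len(group) < 2:
            final.append(group)
            continue
        res = _bisect_group(B, group)
        if res is None:
            final.append(group)
            continue
        s, _ = res
        g1, g2 = group[s > 0], group[s < 0]
        if len(g1) == 0 or len(g2) == 0:
            final.append(group)
            continue
        stack.extend([g1, g2])

    labels = _relabel(final, a.shape[0])
    return ModulePartition(
        labels=labels,
        n_modules=len(final),
        Q=modularity_Q(a, labels),
    )


def optimal_module_count(adjacency: np.ndarray) -> int:
    """Module count of the Q-maximising subdivision found spectrally."""
    return spectral_communities(adjacency).n_modules


def fixed_k_modules(adjacency: np.ndarray, K: int) -> ModulePartition:
    """Partition with exactly K modules, anchored at the spectral solution.

    More than K modules: greedily merge the pair whose merge maximises Q.
    Fewer than K: bisect the module whose best (possibly Q-decreasing)
    split yields the highest Q, until exactly K remain.
    """
    a = _as_binary(adjacency)
    k = a.sum(axis=1)
    active = np.flatnonzero(k > 0)
    if K < 1 or K > len(active):
        raise ValueError(f"K={K} must be in [1, {len(active)}] (non-empty nodes)")
    base = spectral_communities(a)
    groups = [np.flatnonzero(base.labels == c) for c in range(1, base.n_modules + 1)]

    while len(groups) > K:
        best = None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                trial = groups[: i] + groups[i + 1 : j] + groups[j + 1 :]
                trial.append(np.concatenate([groups[i], groups[j]]))
                q = modularity_Q(a, _relabel(trial, a.shape[0]))
                if best is None or q > best[0] + _DQ_TOL:
                    best = (q, i, j)
        _, i, j = best
        merged = np.concatenate([groups[i], groups[j]])
        groups = [g for idx, g in enumerate(groups) if idx not in (i, j)]
        groups.append(merged)

    B = _modularity_matrix(a)
    while len(groups) < K:
        best = None
        for i, g in enumerate(groups):
            if len(g) < 2:
                continue
            s, _ = _bisect_group(B, g, force=True)
            trial = groups[: i] + groups[i + 1 :] + [g[s > 0], g[s < 0]]
            q = modularity_Q(a, _relabel(trial, a.shape[0]))
            if best is None or q > best[0] + _DQ_TOL:
                best = (q, i, s)
        if best is None:
            raise ValueError("cannot split any module further")
        _, i, s = best
        g = groups[i]
        groups = groups[: i] + groups[i + 1 :] + [g[s > 0], g[s < 0]]

    labels = _relabel(groups, a.shape[0])
    return ModulePartition(labels=labels, n_modules=K, Q=modularity_Q(a, labels))


def map_modules_to_cortex(
    partition: ModulePartition, parcellation: Parcellation
) -> np.ndarray:
    """Volume on the FA grid with each surface voxel's module id (0 elsewhere).

    Every non-empty parcellation node must be present in the partition's
    label array; nodes left unassigned (label 0, i.e. degree-0 nodes) map
    to 0 and are logged.
    """
    labels = np.asarray(partition.labels)
    nonempty = parcellation.nonempty_nodes()
    if len(labels) < parcellation.n_nodes:
        raise ValueError(
            f"partition covers {len(labels)} nodes, parcellation has "
            f"{parcellation.n_nodes}"
        )
    if not np.any(labels > 0):
        raise ValueError("partition assigns no node to any module")
    unassigned = [int(n) for n in nonempty if labels[n - 1] == 0]
    if unassigned:
        log.info("%d non-empty node(s) are unassigned (degree 0): %s",
                 len(unassigned), unassigned[:10])
    vol = np.zeros(parcellation.surface.shape, dtype=np.int32)
    module_of_node = np.concatenate([[0], labels])  # 1-based lookup
    vol[tuple(parcellation.surface.voxels.T)] = module_of_node[parcellation.labels]
    return vol
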