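"""Streamline filtering, track-node intersection and connectivity assembly.

A streamline contributes an edge between every unordered pair of distinct
nodes whose labelled surface voxels it touches ("touched or intersected"
semantics); an endpoint-only mode is available for sensitivity analysis.
Weights are raw streamline counts; the analysed network is the binarized
adjacency (connected iff at least one streamline, by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .parcellation import Parcellation

__all__ = [
    "Tractogram",
    "ConnectivityMatrix",
    "streamline_length",
    "filter_streamlines",
    "resample_polyline",
    "streamline_nodes",
    "build_connectivity",
]

log = logging.getLogger(__name__)


@dataclass
class Tractogram:
    """A set of streamlines; each an ordered (P, 3) polyline in mm."""

    streamlines: list

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]
        for i, s in enumerate(self.streamlines):
            if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
                raise ValueError(
                    f"streamline {i} must be an (>=2, 3) polyline, got {s.shape}"
                )
            if not np.all(np.isfinite(s)):
                raise ValueError(f"streamline {i} has non-finite coordinates")

    def __len__(self) -> int:
        return len(self.streamlines)

    def lengths(self) -> np.ndarray:
        return np.array([streamline_length(s) for s in self.streamlines])


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Streamline-count weights plus the binarized adjacency."""

    weights: np.ndarray  # (N, N) int, symmetric, zero diagonal
    adjacency: np.ndarray  # (N, N) uint8
    n_nodes: int

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def streamline_length(polyline: np.ndarray) -> float:
    """Arc length in mm: sum of Euclidean segment lengths."""
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("a streamline needs at least 2 points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def filter_streamlines(tractogram: Tractogram, min_length_mm: float) -> Tractogram:
    """Keep streamlines with arc length >= ``min_length_mm`` (inclusive)."""
    if min_length_mm < 0:
        raise ValueError("min_length_mm must be non-negative")
    kept = [s for s in tractogram.streamlines
            if streamline_length(s) >= min_length_mm]
    removed = len(tractogram) - len(kept)
    log.info("length filter at %g mm removed %d of %d streamlines",
             min_length_mm, removed, len(tractogram))
    if not kept:
        log.warning("length filter removed every streamline")
    return Tractogram(kept)


def resample_polyline(polyline: np.ndarray, step_mm: float) -> np.ndarray:
    """Resample a polyline at ~``step_mm`` arc-length spacing.

    Both endpoints are preserved exactly; interior samples are linear
    interpolations along the original segments.
    """
    pts = np.asarray(polyline, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    if total == 0 or step_mm <= 0:
        return pts.copy()
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    n_samples = max(int(np.ceil(total / step_mm)) + 1, 2)
    t = np.linspace(0.0, total, n_samples)
    out = np.column_stack([np.interp(t, arc, pts[:, d]) for d in range(3)])
    out[0], out[-1] = pts[0], pts[-1]
    return out


def streamline_nodes(
    polyline: np.ndarray,
    parcellation: Parcellation,
    step_mm: float | None = None,
    endpoints_only: bool = False,
) -> set:
    """Node ids (1..N) whose labelled voxels the streamline touches.

    Points are resampled at half the minimum voxel spacing (unless
    ``step_mm`` overrides) so a thin surface shell cannot be jumped over,
    then mapped to voxels by flooring the continuous grid index
    (half-open voxel boxes).
    """
    surface = parcellation.surface
    spacing = np.linalg.norm(surface.affine[:3, :3], axis=0)
    if step_mm is None:
        step_mm = 0.5 * float(spacing.min())
    pts = np.asarray(polyline, dtype=float)
    if endpoints_only:
        pts = pts[[0, -1]]
    else:
        pts = resample_polyline(pts, step_mm)
    inv = np.linalg.inv(surface.affine)
    idx = np.floor(pts @ inv[:3, :3].T + inv[:3, 3] + 0.5).astype(np.intp)
    shape = surface.shape
    ok = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
    if not ok.any():
        return set()
    vol = parcellation.label_volume()
    labels = vol[tuple(idx[ok].T)]
    return set(int(v) for v in np.unique(labels) if v > 0)


def build_connectivity(
    tractogram: Tractogram,
    parcellation: Parcellation,
    binarize_threshold: int = 1,
    endpoints_only: bool = False,
) -> ConnectivityMatrix:
    """Accumulate streamline counts into a symmetric N x N matrix.

    Every unordered pair of distinct touched nodes gains one count per
    streamline; the diagonal is forced to zero and the adjacency is
    ``weights >= binarize_threshold``.
    """
    if parcellation.n_nodes < 1 or len(parcellation.surface) == 0:
        raise ValueError("parcellation is empty")
    n = parcellation.n_nodes
    weights = np.zeros((n, n), dtype=np.int64)
    for s in tractogram.streamlines:
        nodes = streamline_nodes(s, parcellation, endpoints_only=endpoints_only)
        for a, b in combinations(sorted(nodes), 2):
            weights[a - 1, b - 1] += 1
            weights[b - 1, a - 1] += 1
    np.fill_diagonal(weights, 0)
    adjacency = (weights >= binarize_threshold).astype(np.uint8)
    return ConnectivityMatrix(weights=weights, adjacency=adjacency, n_nodes=n)
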