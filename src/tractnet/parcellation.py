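"""Template-free cortical parcellation from an FA volume.

The node definition used throughout the package: take the non-zero support
of a fractional-anisotropy map as the brain mask, extract a one-voxel
surface shell a few millimetres below the cortex by morphological
operations, and split that shell into N equal-area nodes by radially
projecting each shell voxel onto a sphere partitioned into N regions of
equal area.  The optimal N is the finest parcellation whose binary network
still spans the whole brain in a single connected component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components

from .sphere import SpherePartition, eq_partition

__all__ = [
    "FAVolume",
    "SurfaceVoxelSet",
    "Parcellation",
    "extract_subcortical_surface",
    "label_surface",
    "giant_component",
    "optimal_node_number",
    "DegenerateGeometryError",
    "DepthTooLargeError",
]

log = logging.getLogger(__name__)

# 6-connected (face-neighbour) structuring element
_CROSS = ndimage.generate_binary_structure(3, 1)


class DegenerateGeometryError(ValueError):
    """Geometry too small relative to the voxel grid."""


class DepthTooLargeError(ValueError):
    """Erosion depth consumed the entire brain mask."""


@dataclass(frozen=True)
class FAVolume:
    """A 3-D scalar FA-like volume with its grid-to-mm affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        affine = np.asarray(self.affine, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"FA volume must be 3-D, got shape {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("FA volume contains non-finite voxels")
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)
        if np.any(self.voxel_mm <= 0):
            raise ValueError("voxel spacings must all be positive")

    @property
    def voxel_mm(self) -> np.ndarray:
        """Per-axis voxel spacing in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxels_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def mm_to_voxels(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous grid indices for mm-space points (inverse affine)."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]


@dataclass(frozen=True)
class SurfaceVoxelSet:
    """One-voxel shell of grid indices ``depth_mm`` below the brain surface."""

    voxels: np.ndarray  # (K, 3) int indices, lexicographically sorted
    depth_mm: float
    centroid_mm: np.ndarray
    affine: np.ndarray
    shape: tuple[int, int, int]

    def __len__(self) -> int:
        return len(self.voxels)

    def voxels_mm(self) -> np.ndarray:
        v = self.voxels @ self.affine[:3, :3].T + self.affine[:3, 3]
        return v

    def mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        m[tuple(self.voxels.T)] = True
        return m


@dataclass
class Parcellation:
    """Voxel-to-node labelling of the surface shell.

    ``labels[k]`` is the node id (1..N) of ``surface.voxels[k]``; node
    centroids are the mean mm-position of each node's voxels (NaN for nodes
    that received no voxel — those stay in the matrix with degree 0).
    """

    surface: SurfaceVoxelSet
    labels: np.ndarray  # (K,) ints in 1..N
    node_centroids_mm: np.ndarray  # (N, 3), NaN rows for empty nodes
    n_nodes: int
    _label_volume: np.ndarray | None = field(default=None, repr=False)

    def voxel_counts(self) -> np.ndarray:
        """Number of surface voxels per node (length N)."""
        return np.bincount(self.labels, minlength=self.n_nodes + 1)[1:]

    def nonempty_nodes(self) -> np.ndarray:
        """1-based ids of nodes owning at least one surface voxel."""
        return np.flatnonzero(self.voxel_counts() > 0) + 1

    def label_volume(self) -> np.ndarray:
        """Dense int volume: node id at surface voxels, 0 elsewhere."""
        if self._label_volume is None:
            vol = np.zeros(self.surface.shape, dtype=np.int32)
            vol[tuple(self.surface.voxels.T)] = self.labels
            self._label_volume = vol
        return self._label_volume


def extract_subcortical_surface(fa: FAVolume, depth_mm: float = 5.0) -> SurfaceVoxelSet:
    """Extract the one-voxel shell ``depth_mm`` below the brain surface.

    The binary mask is the non-zero FA support, closed once (dilation then
    erosion, 6-connected) to fill pinholes, then eroded to metric depth via
    the anisotropy-aware Euclidean distance transform — i.e. erosion by a
    Euclidean ball of radius ``depth_mm``, so the shell sits at the same
    physical depth in every direction.  The shell is the eroded mask minus
    one further 6-connected erosion.  Protrusions such as the cerebellum
    are deliberately left in place.
    """
    if depth_mm < 0:
        raise ValueError("depth_mm must be non-negative")
    mask = fa.data > 0
    if not mask.any():
        raise ValueError("FA volume has an empty non-zero mask")
    closed = ndimage.binary_closing(mask, structure=_CROSS)
    # closing clips at the array border; restore any original foreground
    closed |= mask
    dist = ndimage.distance_transform_edt(closed, sampling=fa.voxel_mm)
    eroded = dist > depth_mm
    if not eroded.any():
        raise DepthTooLargeError(
            f"erosion to depth {depth_mm} mm removed the whole mask"
        )
    inner = ndimage.binary_erosion(eroded, structure=_CROSS)
    shell = eroded & ~inner
    voxels = np.argwhere(shell)  # C-order -> lexicographically sorted
    centroid = fa.voxels_to_mm(voxels).mean(axis=0)
    return SurfaceVoxelSet(
        voxels=voxels,
        depth_mm=float(depth_mm),
        centroid_mm=centroid,
        affine=fa.affine.copy(),
        shape=fa.data.shape,
    )


def label_surface(surface: SurfaceVoxelSet, partition: SpherePartition) -> Parcellation:
    """Assign every surface voxel to an equal-area node by radial projection.

    Each voxel's mm-position is referred to the surface centroid and the
    direction vector looked up in the sphere partition (polar axis = the
    volume z-axis).  A voxel exactly at the centroid (zero direction) takes
    the direction of its nearest non-degenerate neighbour.
    """
    if len(surface) == 0:
        raise ValueError("surface voxel set is empty")
    mm = surface.voxels_mm()
    vec = mm - surface.centroid_mm
    norms = np.linalg.norm(vec, axis=1)
    bad = norms == 0
    if bad.any():
        log.warning("%d voxel(s) coincide with the surface centroid; "
                    "borrowing the nearest voxel's direction", int(bad.sum()))
        good_idx = np.flatnonzero(~bad)
        if len(good_idx) == 0:
            raise ValueError("all surface voxels coincide with the centroid")
        for i in np.flatnonzero(bad):
            d = np.linalg.norm(mm[good_idx] - mm[i], axis=1)
            vec[i] = vec[good_idx[np.argmin(d)]]
    labels = partition.assign(vec) + 1  # node ids 1..N

    n = partition.n_regions
    centroids = np.full((n, 3), np.nan)
    for node in range(1, n + 1):
        sel = labels == node
        if sel.any():
            centroids[node - 1] = mm[sel].mean(axis=0)
    return Parcellation(
        surface=surface,
        labels=labels.astype(np.int32),
        node_centroids_mm=centroids,
        n_nodes=n,
    )


def _check_adjacency(adjacency: np.ndarray) -> np.ndarray:
    adj = np.asarray(adjacency)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1] or adj.shape[0] == 0:
        raise ValueError(f"adjacency must be square and non-empty, got {adj.shape}")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diagonal(adj) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    return adj != 0


def giant_component(adjacency: np.ndarray) -> tuple[int, np.ndarray]:
    """Size and (0-based) members of the largest connected component.

    Ties between equal-sized components go to the one containing the
    lowest node id.
    """
    adj = _check_adjacency(adjacency)
    n_comp, comp = connected_components(csr_array(adj), directed=False)
    sizes = np.bincount(comp, minlength=n_comp)
    best = sizes.max()
    # component labels are assigned in order of first appearance, so the
    # first label attaining the max size contains the lowest member id
    label = int(np.flatnonzero(sizes == best)[0])
    members = np.flatnonzero(comp == label)
    return int(best), members


def optimal_node_number(
    fa: FAVolume,
    tractogram,
    candidates,
    depth_mm: float = 5.0,
    binarize_threshold: int = 1,
    require_all_nodes: bool = False,
) -> int:
    """Finest parcellation whose network still spans the whole brain.

    For each candidate N (ascending) the surface is parcellated, the binary
    network built from the (already length-filtered) tractogram, and the
    giant component computed.  Returns the largest N for which the giant
    component contains every non-empty node (every node, if
    ``require_all_nodes``).  If no candidate qualifies, the candidate with
    the largest giant-component fraction is returned and a warning logged.
    """
    from .network import build_connectivity  # deferred: avoids import cycle

    candidates = [int(c) for c in candidates]
    if not candidates:
        raise ValueError("candidate list is empty")
    if len(tractogram.streamlines) == 0:
        raise ValueError("tractogram is empty")

    surface = extract_subcortical_surface(fa, depth_mm)
    best_n, best_frac = candidates[0], -1.0
    answer = None
    for n in candidates:
        parc = label_surface(surface, eq_partition(n))
        conn = build_connectivity(tractogram, parc, binarize_threshold)
        required = (
            np.arange(1, n + 1) if require_all_nodes else parc.nonempty_nodes()
        )
        _, members = giant_component(conn.adjacency)
        member_ids = set((members + 1).tolist())
        covered = sum(1 for node in required if node in member_ids)
        frac = covered / len(required) if len(required) else 0.0
        log.info("candidate N=%d: giant component covers %d/%d nodes",
                 n, covered, len(required))
        if frac == 1.0:
            answer = n
        if frac > best_frac:
            best_n, best_frac = n, frac
    if answer is not None:
        return answer
    log.warning(
        "no candidate fully spanned by the giant component; "
        "falling back to N=%d (fraction %.3f)", best_n, best_frac,
    )
    return best_n
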