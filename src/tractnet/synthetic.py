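"""Phantom data: FA-like ellipsoid volumes, modular tractograms, graph fixtures.

The phantom stands in for a subject scan: a solid ellipsoidal FA volume
supplies the brain mask, and a synthetic tractogram supplies streamlines
whose endpoint nodes follow a planted modular structure.  Planted modules
are angular (longitude) sectors of the phantom surface, so spatially
adjacent nodes share a module by construction.  Streamlines are straight
chords between endpoint surface voxels, bowed slightly inward so that only
their termini lie in the labelled surface shell; a configurable fraction
of short "noise" streamlines falls below the length threshold and must be
removed entirely by the length filter.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx

from .network import Tractogram, resample_polyline
from .parcellation import DegenerateGeometryError, FAVolume, Parcellation

__all__ = [
    "PhantomSpec",
    "GraphFixture",
    "make_phantom_fa",
    "make_phantom_tractogram",
    "make_graph_fixture",
]

# margin (mm, along the tightest semi-axis) by which chord interiors are
# pulled below the endpoint radius, keeping them out of the surface shell
_INWARD_MM = 3.5


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a phantom subject.

    Defaults describe the study conditions used throughout the analyses:
    a brain-sized ellipsoid (semi-axes 55/65/50 mm) on a 1.5 mm grid, five
    planted modules, 5000 streamlines with within/between pair weights
    0.9/0.05, and 10% sub-threshold noise streamlines against the 5 mm
    neonatal length threshold.
    """

    radii_mm: tuple = (55.0, 65.0, 50.0)
    voxel_mm: float = 1.5
    n_modules: int = 5
    n_streamlines: int = 5000
    p_in: float = 0.9
    p_out: float = 0.05
    noise_fraction: float = 0.1
    length_threshold_mm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")
        if np.any(np.asarray(self.radii_mm) <= 0):
            raise ValueError("radii must be positive")
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        for name in ("p_in", "p_out"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValueError("noise_fraction must be in [0, 1]")


@dataclass(frozen=True)
class GraphFixture:
    """A pure-graph test substrate with optional planted block labels."""

    adjacency: np.ndarray
    planted_labels: np.ndarray | None
    kind: str
    seed: int | None


def make_phantom_fa(spec: PhantomSpec, depth_margin_mm: float = 8.0) -> FAVolume:
    """Solid-ellipsoid FA volume, padded so erosion never hits the border.

    Voxel values follow a smooth radial profile in (0, 0.8]; the non-zero
    support is exactly the set of voxel centers inside the ellipsoid.
    Padding is at least ``depth_margin_mm`` (default covers the deepest
    supported surface depth plus two voxels) of background on every side.
    """
    radii = np.asarray(spec.radii_mm, dtype=float)
    v = float(spec.voxel_mm)
    if np.any(radii < 2.0 * v):
        raise DegenerateGeometryError(
            f"radii {tuple(radii)} mm are too small for {v} mm voxels"
        )
    pad = int(np.ceil(depth_margin_mm / v)) + 2
    half = np.ceil(radii / v).astype(int) + pad
    shape = 2 * half + 1
    affine = np.diag([v, v, v, 1.0])
    affine[:3, 3] = -half * v  # mm origin at the ellipsoid center

    ii = [np.arange(s) for s in shape]
    coords = np.meshgrid(*ii, indexing="ij")
    mm = [(c - h) * v for c, h in zip(coords, half)]
    rho2 = sum((x / r) ** 2 for x, r in zip(mm, radii))
    data = np.where(rho2 <= 1.0, 0.1 + 0.7 * (1.0 - rho2), 0.0)
    return FAVolume(data=data, affine=affine)


def planted_node_modules(parcellation: Parcellation, n_modules: int) -> np.ndarray:
    """Planted module id (1..M; 0 for empty nodes) per parcellation node.

    Modules are equal angular sectors of longitude about the surface
    centroid, so each module is a spatially contiguous wedge of nodes.
    """
    n = parcellation.n_nodes
    modules = np.zeros(n, dtype=np.int64)
    cent = parcellation.node_centroids_mm - parcellation.surface.centroid_mm
    for node in parcellation.nonempty_nodes():
        x, y = cent[node - 1, 0], cent[node - 1, 1]
        phi = np.mod(np.arctan2(y, x), 2.0 * np.pi)
        modules[node - 1] = min(int(phi * n_modules / (2.0 * np.pi)), n_modules - 1) + 1
    return modules


def _bow_inward(points: np.ndarray, centroid: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Clamp chord interior points below the endpoint shell.

    Working in ellipsoid-normalized coordinates, interior points are pulled
    to a normalized radius safely below both endpoints, so mid-chord
    samples cannot graze surface voxels of unrelated nodes.
    """
    q = (points - centroid) / radii
    rho = np.linalg.norm(q, axis=1)
    rho_lim = min(rho[0], rho[-1]) - _INWARD_MM / float(np.min(radii))
    if rho_lim <= 0:
        return points
    scale = np.ones(len(points))
    interior = np.arange(1, len(points) - 1)
    over = interior[rho[interior] > rho_lim]
    scale[over] = rho_lim / rho[over]
    return centroid + q * scale[:, None] * radii


def make_phantom_tractogram(
    fa: FAVolume, parcellation: Parcellation, spec: PhantomSpec
) -> tuple[Tractogram, np.ndarray]:
    """Streamlines with planted modular endpoint structure, plus noise.

    Node pairs are sampled with relative weight ``p_in`` (same planted
    module) or ``p_out`` (different modules); each streamline is a 1-mm
    resampled chord between random surface voxels of the sampled pair,
    bowed inward so only the termini touch the shell.  Endpoint voxels are
    re-drawn until they are farther apart than the length threshold, so
    the length filter removes exactly the noise streamlines — short random
    surface segments making up ``noise_fraction`` of the total.
    """
    n_nodes = parcellation.n_nodes
    nonempty = parcellation.nonempty_nodes()
    if len(nonempty) < spec.n_modules:
        raise ValueError(
            f"parcellation has {len(nonempty)} non-empty nodes, "
            f"fewer than {spec.n_modules} planted modules"
        )
    modules = planted_node_modules(parcellation, spec.n_modules)
    rng = np.random.default_rng(spec.seed)
    surface_mm = parcellation.surface.voxels_mm()
    centroid = parcellation.surface.centroid_mm
    radii = np.asarray(spec.radii_mm, dtype=float)
    voxels_of = {int(n): np.flatnonzero(parcellation.labels == n) for n in nonempty}

    # unordered node pairs with modular sampling weights
    pairs = [(int(a), int(b)) for i, a in enumerate(nonempty)
             for b in nonempty[i + 1 :]]
    w = np.array(
        [spec.p_in if modules[a - 1] == modules[b - 1] else spec.p_out
         for a, b in pairs]
    )
    if w.sum() == 0:
        raise ValueError("p_in and p_out are both zero; no pair can be sampled")
    w = w / w.sum()

    n_noise = int(round(spec.n_streamlines * spec.noise_fraction))
    n_real = spec.n_streamlines - n_noise
    choice = rng.choice(len(pairs), size=n_real, p=w)

    min_sep = spec.length_threshold_mm + 1.0
    streamlines: list[np.ndarray] = []
    for c in choice:
        a, b = pairs[c]
        va, vb = voxels_of[a], voxels_of[b]
        best = None
        for _ in range(64):
            pa = surface_mm[va[rng.integers(len(va))]]
            pb = surface_mm[vb[rng.integers(len(vb))]]
            d = float(np.linalg.norm(pa - pb))
            if best is None or d > best[0]:
                best = (d, pa, pb)
            if d >= min_sep:
                break
        _, pa, pb = best
        chord = resample_polyline(np.array([pa, pb]), 1.0)
        streamlines.append(_bow_inward(chord, centroid, radii))

    eps = 0.5
    for _ in range(n_noise):
        p0 = surface_mm[rng.integers(len(surface_mm))]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        length = rng.uniform(1.0, max(spec.length_threshold_mm - eps, 1.0 + 1e-6))
        streamlines.append(
            resample_polyline(np.array([p0, p0 + length * direction]), 1.0)
        )

    return Tractogram(streamlines), modules


def make_graph_fixture(kind: str, seed: int | None = None, **params) -> GraphFixture:
    """Standard graph substrates for metric and community tests.

    Kinds: complete(n), star(n_leaves), ring_lattice(n, k), path(n),
    erdos_renyi(n, p), watts_strogatz(n, k, p),
    planted_partition(n_blocks, block_size, p_in, p_out),
    two_cliques(n1, n2).
    """
    labels = None
    if kind == "complete":
        g = nx.complete_graph(params["n"])
    elif kind == "star":
        g = nx.star_graph(params["n_leaves"])
    elif kind == "ring_lattice":
        g = nx.watts_strogatz_graph(params["n"], params["k"], 0.0)
    elif kind == "path":
        g = nx.path_graph(params["n"])
    elif kind == "erdos_renyi":
        g = nx.gnp_random_graph(params["n"], params["p"], seed=seed)
    elif kind == "watts_strogatz":
        g = nx.watts_strogatz_graph(params["n"], params["k"], params["p"], seed=seed)
    elif kind == "planted_partition":
        g = nx.planted_partition_graph(
            params["n_blocks"], params["block_size"],
            params["p_in"], params["p_out"], seed=seed,
        )
        labels = np.array([g.nodes[i]["block"] + 1 for i in sorted(g)])
    elif kind == "two_cliques":
        n1, n2 = params["n1"], params["n2"]
        g = nx.disjoint_union(nx.complete_graph(n1), nx.complete_graph(n2))
        labels = np.array([1] * n1 + [2] * n2)
    else:
        raise ValueError(f"unknown graph fixture kind: {kind!r}")
    adjacency = nx.to_numpy_array(g, nodelist=sorted(g), dtype=np.uint8)
    return GraphFixture(adjacency=adjacency, planted_labels=labels,
                        kind=kind, seed=seed)
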