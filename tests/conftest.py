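"""Shared fixtures: spherical and study-sized phantoms, built once per session."""

from __future__ import annotations

import numpy as np
import pytest

import tractnet as tn


@pytest.fixture(scope="session")
def sphere_spec() -> tn.PhantomSpec:
    return tn.PhantomSpec(radii_mm=(40.0, 40.0, 40.0), voxel_mm=1.0, seed=11)


@pytest.fixture(scope="session")
def sphere_fa(sphere_spec) -> tn.FAVolume:
    return tn.make_phantom_fa(sphere_spec)


@pytest.fixture(scope="session")
def sphere_surface(sphere_fa) -> tn.SurfaceVoxelSet:
    return tn.extract_subcortical_surface(sphere_fa, depth_mm=5.0)


@pytest.fixture(scope="session")
def sphere_parc100(sphere_surface) -> tn.Parcellation:
    return tn.label_surface(sphere_surface, tn.eq_partition(100))


@pytest.fixture(scope="session")
def study_phantom():
    """The study conditions: default phantom, 100 nodes, full pipeline inputs.

    Returns a dict with the FA volume, surface, parcellation, raw and
    length-filtered tractograms, planted module labels and the binary
    connectivity matrix.
    """
    spec = tn.PhantomSpec()
    fa = tn.make_phantom_fa(spec)
    surface = tn.extract_subcortical_surface(fa, depth_mm=5.0)
    parc = tn.label_surface(surface, tn.eq_partition(100))
    tract, planted = tn.make_phantom_tractogram(fa, parc, spec)
    kept = tn.filter_streamlines(tract, spec.length_threshold_mm)
    conn = tn.build_connectivity(kept, parc)
    return {
        "spec": spec,
        "fa": fa,
        "surface": surface,
        "parc": parc,
        "tract": tract,
        "planted": planted,
        "kept": kept,
        "conn": conn,
    }


@pytest.fixture
def tiny_parcellation():
    """A hand-built 2-node parcellation on an identity-affine grid.

    Nodes 3 and 7 of a 10-node parcellation occupy two separated voxel
    clusters; everything else is background.
    """
    shape = (12, 12, 12)
    voxels = np.array(
        [[2, 2, 2], [2, 2, 3], [9, 9, 9], [9, 9, 8]], dtype=np.intp
    )
    labels = np.array([3, 3, 7, 7], dtype=np.int32)
    affine = np.eye(4)
    surface = tn.SurfaceVoxelSet(
        voxels=voxels,
        depth_mm=0.0,
        centroid_mm=voxels.mean(axis=0),
        affine=affine,
        shape=shape,
    )
    n = 10
    centroids = np.full((n, 3), np.nan)
    centroids[2] = voxels[:2].mean(axis=0)
    centroids[6] = voxels[2:].mean(axis=0)
    return tn.Parcellation(
        surface=surface,
        labels=labels,
        node_centroids_mm=centroids,
        n_nodes=n,
    )
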