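"""Phantom generators: geometry, determinism, planted structure, fixtures."""

import numpy as np
import pytest
from scipy import stats

import tractnet as tn
from tractnet.parcellation import DegenerateGeometryError
from tractnet.synthetic import planted_node_modules


class TestPhantomFA:
    def test_sphere_volume_matches_analytic(self, sphere_fa):
        """Non-zero voxel count within 2% of (4/3) pi 40^3 (1 mm voxels)."""
        count = int((sphere_fa.data > 0).sum())
        analytic = 4 / 3 * np.pi * 40**3
        assert abs(count - analytic) / analytic < 0.02

    def test_voxel_membership_matches_independent_loop(self):
        """Each non-zero voxel center satisfies the ellipsoid inequality."""
        spec = tn.PhantomSpec(radii_mm=(12, 16, 10), voxel_mm=2.0)
        fa = tn.make_phantom_fa(spec)
        radii = np.array(spec.radii_mm)
        nz = fa.data > 0
        for idx in np.ndindex(fa.data.shape):  # independent brute-force check
            mm = fa.voxels_to_mm(np.array([idx]))[0]
            inside = (mm / radii) @ (mm / radii) <= 1.0
            assert nz[idx] == inside

    def test_deterministic(self, sphere_spec, sphere_fa):
        again = tn.make_phantom_fa(sphere_spec)
        assert np.array_equal(sphere_fa.data, again.data)
        assert np.array_equal(sphere_fa.affine, again.affine)

    def test_padding_leaves_background_margin(self, sphere_fa):
        """>= depth+2 voxels of background on every face."""
        nz = np.argwhere(sphere_fa.data > 0)
        lo = nz.min(axis=0)
        hi = np.array(sphere_fa.data.shape) - 1 - nz.max(axis=0)
        assert np.all(lo >= 7) and np.all(hi >= 7)

    def test_degenerate_radii_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            tn.make_phantom_fa(tn.PhantomSpec(radii_mm=(1, 1, 1), voxel_mm=1.0))

    def test_values_are_valid_fa(self, sphere_fa):
        assert sphere_fa.data.min() >= 0.0
        assert sphere_fa.data.max() <= 1.0


class TestPhantomTractogram:
    def test_pure_within_module_sampling(self, sphere_fa, sphere_parc100):
        """p_in=1, p_out=0: endpoint nodes of every real streamline share
        a planted module."""
        spec = tn.PhantomSpec(
            radii_mm=(40, 40, 40), voxel_mm=1.0, p_in=1.0, p_out=0.0,
            noise_fraction=0.0, n_streamlines=300, seed=1,
        )
        tract, planted = tn.make_phantom_tractogram(sphere_fa, sphere_parc100, spec)
        for s in tract.streamlines:
            ends = tn.streamline_nodes(
                s, sphere_parc100, endpoints_only=True
            )
            mods = {planted[n - 1] for n in ends}
            assert len(mods) == 1

    def test_noise_count_exact(self, sphere_fa, sphere_parc100):
        spec = tn.PhantomSpec(
            radii_mm=(40, 40, 40), voxel_mm=1.0, n_streamlines=1000,
            noise_fraction=0.1, seed=2,
        )
        tract, _ = tn.make_phantom_tractogram(sphere_fa, sphere_parc100, spec)
        lengths = tract.lengths()
        assert int((lengths < spec.length_threshold_mm).sum()) == 100
        assert int((lengths >= spec.length_threshold_mm).sum()) == 900

    def test_byte_identical_given_seed(self, sphere_fa, sphere_parc100):
        spec = tn.PhantomSpec(
            radii_mm=(40, 40, 40), voxel_mm=1.0, n_streamlines=200, seed=9
        )
        t1, l1 = tn.make_phantom_tractogram(sphere_fa, sphere_parc100, spec)
        t2, l2 = tn.make_phantom_tractogram(sphere_fa, sphere_parc100, spec)
        assert np.array_equal(l1, l2)
        assert len(t1) == len(t2)
        for a, b in zip(t1.streamlines, t2.streamlines):
            assert a.tobytes() == b.tobytes()

    def test_modular_marginals_chi_squared(self, sphere_fa, sphere_parc100):
        """Within/between module endpoint counts match the sampling weights
        (chi-squared goodness of fit, p > 0.01 at n = 5000)."""
        spec = tn.PhantomSpec(
            radii_mm=(40, 40, 40), voxel_mm=1.0, n_streamlines=5000,
            noise_fraction=0.0, seed=3,
        )
        tract, planted = tn.make_phantom_tractogram(sphere_fa, sphere_parc100, spec)
        nonempty = sphere_parc100.nonempty_nodes()
        mods = planted[nonempty - 1]
        n_within_pairs = sum(
            int((mods == m).sum() * ((mods == m).sum() - 1) / 2)
            for m in np.unique(mods)
        )
        n_pairs = len(nonempty) * (len(nonempty) - 1) // 2
        w_in = n_within_pairs * spec.p_in
        w_out = (n_pairs - n_within_pairs) * spec.p_out
        p_within = w_in / (w_in + w_out)

        observed_within = 0
        for s in tract.streamlines:
            ends = sorted(
                tn.streamline_nodes(s, sphere_parc100, endpoints_only=True)
            )
            if len(ends) == 2 and planted[ends[0] - 1] == planted[ends[1] - 1]:
                observed_within += 1
        n = len(tract)
        chi2 = stats.chisquare(
            [observed_within, n - observed_within],
            [n * p_within, n * (1 - p_within)],
        )
        assert chi2.pvalue > 0.01

    def test_planted_sectors_are_contiguous(self, sphere_parc100):
        """Neighbouring nodes overwhelmingly share a planted module."""
        planted = planted_node_modules(sphere_parc100, 5)
        cents = sphere_parc100.node_centroids_mm
        nonempty = sphere_parc100.nonempty_nodes()
        same = 0
        for node in nonempty:
            d = np.linalg.norm(cents[nonempty - 1] - cents[node - 1], axis=1)
            order = np.argsort(d)[1:4]  # 3 nearest neighbours
            nb_mods = planted[nonempty[order] - 1]
            if (nb_mods == planted[node - 1]).sum() >= 2:
                same += 1
        assert same / len(nonempty) >= 0.8

    def test_too_few_nodes_rejected(self, sphere_fa, sphere_surface):
        parc = tn.label_surface(sphere_surface, tn.eq_partition(3))
        spec = tn.PhantomSpec(radii_mm=(40, 40, 40), voxel_mm=1.0, n_modules=5)
        with pytest.raises(ValueError):
            tn.make_phantom_tractogram(sphere_fa, parc, spec)


class TestGraphFixtures:
    def test_complete_graph(self):
        fix = tn.make_graph_fixture("complete", n=5)
        assert fix.adjacency.sum() // 2 == 10
        assert tn.edge_density(fix.adjacency) == 1.0

    def test_ring_lattice_degrees(self):
        fix = tn.make_graph_fixture("ring_lattice", n=10, k=2)
        assert np.all(fix.adjacency.sum(1) == 2)

    def test_two_cliques_disjoint(self):
        fix = tn.make_graph_fixture("two_cliques", n1=4, n2=5)
        adj = fix.adjacency
        assert adj[:4, 4:].sum() == 0
        assert adj[:4, :4].sum() == 12 and adj[4:, 4:].sum() == 20

    def test_planted_partition_edge_count_within_3_sigma(self):
        """Edge total matches the binomial expectation of the block model."""
        fix = tn.make_graph_fixture(
            "planted_partition", n_blocks=5, block_size=20,
            p_in=0.9, p_out=0.05, seed=0,
        )
        n_within = 5 * (20 * 19 // 2)
        n_between = 100 * 99 // 2 - n_within
        mean = n_within * 0.9 + n_between * 0.05
        var = n_within * 0.9 * 0.1 + n_between * 0.05 * 0.95
        edges = fix.adjacency.sum() // 2
        assert abs(edges - mean) < 3 * np.sqrt(var)
        assert fix.planted_labels is not None
        assert len(np.unique(fix.planted_labels)) == 5

    def test_symmetric_zero_diagonal_all_kinds(self):
        kinds = [
            ("complete", {"n": 6}),
            ("star", {"n_leaves": 4}),
            ("ring_lattice", {"n": 8, "k": 2}),
            ("path", {"n": 5}),
            ("erdos_renyi", {"n": 20, "p": 0.2}),
            ("watts_strogatz", {"n": 20, "k": 4, "p": 0.1}),
            ("planted_partition",
             {"n_blocks": 2, "block_size": 5, "p_in": 0.9, "p_out": 0.1}),
            ("two_cliques", {"n1": 3, "n2": 4}),
        ]
        for kind, params in kinds:
            fix = tn.make_graph_fixture(kind, seed=0, **params)
            assert np.array_equal(fix.adjacency, fix.adjacency.T)
            assert np.all(np.diagonal(fix.adjacency) == 0)

    def test_seeded_fixtures_reproducible(self):
        a = tn.make_graph_fixture("erdos_renyi", n=30, p=0.2, seed=5)
        b = tn.make_graph_fixture("erdos_renyi", n=30, p=0.2, seed=5)
        assert np.array_equal(a.adjacency, b.adjacency)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            tn.make_graph_fixture("hypercube", n=4)
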