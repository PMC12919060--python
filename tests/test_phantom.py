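"""Phantom generator: models, densities, noise, tractogram synthesis."""

import numpy as np
import pytest

import longisift as L
from longisift.phantom import PhantomConfig, _allocate, build_model


class TestBuildModel:
    def test_model1_quarter_count(self, noiseless_config):
        pair = build_model(1, noiseless_config)
        assert pair.bundles[0].fibre_count == (1000, 250)
        # distractors unchanged, at least two of them
        unchanged = [b for b in pair.bundles[1:]
                     if b.fibre_count[0] == b.fibre_count[1]]
        assert len(unchanged) >= 2

    def test_model2_halved_and_doubled(self, noiseless_config):
        pair = build_model(2, noiseless_config)
        fc = [b.fibre_count for b in pair.bundles]
        assert fc[0][1] == fc[0][0] // 2
        assert fc[1][1] == 2 * fc[1][0]
        # the two manipulated bundles cross one another
        assert any({c.bundle_a, c.bundle_b} == {0, 1} for c in pair.crossings)

    def test_model3_lesion_clears_intersecting_bundles(self, noiseless_config):
        pair = build_model(3, noiseless_config)
        centre, radius = pair.lesion
        for b in pair.bundles:
            d = np.linalg.norm(np.cross(b.centreline[-1] - b.centreline[0],
                                        centre - b.centreline[0])) \
                / np.linalg.norm(b.centreline[-1] - b.centreline[0])
            if d <= radius:
                assert b.fibre_count[1] == 0
            else:
                assert b.fibre_count[1] == b.fibre_count[0]
        assert any(b.fibre_count[1] == 0 for b in pair.bundles)
        assert any(b.fibre_count[1] > 0 for b in pair.bundles)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            build_model(4)

    def test_delta_fc_bookkeeping(self, noiseless_config):
        pair = build_model(1, noiseless_config)
        total = pair.delta_fc_connectome().grand_sum()
        assert total == -750  # only the manipulated bundle changes

    def test_bit_reproducible(self, noiseless_config):
        a = build_model(2, noiseless_config)
        b = build_model(2, noiseless_config)
        assert np.array_equal(a.fixels.fd, b.fixels.fd)
        assert np.array_equal(a.fixels.directions, b.fixels.directions)


class TestFibreDensities:
    def test_crossing_voxel_equal_counts_equal_fd(self, noiseless_config):
        pair = build_model(1, noiseless_config)
        # distractors 1 and 2 cross with equal counts: at the crossing
        # voxel the two fixels carry equal density
        cross = next(c for c in pair.crossings
                     if {c.bundle_a, c.bundle_b} == {1, 2})
        voxel = pair.grid.voxel_of(cross.point)
        ids = pair.fixels.fixels_in_voxel(voxel)
        assert len(ids) == 2
        fds = pair.fixels.fd[ids, 0]
        # symmetry up to the disk-quadrature resolution
        assert np.isclose(fds[0], fds[1], rtol=0.05)

    def test_fd_linear_in_fibre_count(self, noiseless_config):
        from dataclasses import replace

        pair = build_model(1, noiseless_config)
        doubled = [replace(b, fibre_count=(2 * b.fibre_count[0],
                                           2 * b.fibre_count[1]))
                   for b in pair.bundles]
        fx2 = L.synthesize_fibre_densities(doubled, pair.grid,
                                           noiseless_config)
        assert np.allclose(fx2.fd, 2.0 * pair.fixels.fd)

    def test_zero_count_zero_fd_in_exclusive_fixels(self):
        pair = L.build_isolated_pair(1000, 0)
        assert np.all(pair.fixels.fd[:, 1] == 0.0)
        assert np.all(pair.fixels.fd[:, 0] > 0.0)


class TestDensityNoise:
    def test_sigma_zero_identity(self, model1_pair):
        out = L.add_density_noise(model1_pair.fixels, 0.0, seed=1)
        assert out is model1_pair.fixels

    def test_reproducible_with_seed(self, model1_pair):
        a = L.add_density_noise(model1_pair.fixels, 0.05, seed=42)
        b = L.add_density_noise(model1_pair.fixels, 0.05, seed=42)
        assert np.array_equal(a.fd, b.fd)
        assert not np.array_equal(a.fd, model1_pair.fixels.fd)

    def test_negative_sigma_rejected(self, model1_pair):
        with pytest.raises(ValueError):
            L.add_density_noise(model1_pair.fixels, -0.1, seed=0)

    def test_empirical_sd_matches_sigma(self):
        """Large-sample noise sd approaches sigma times the mean density."""
        grid = L.VoxelGrid(shape=(50, 20, 20))
        n = 20000
        rng = np.random.default_rng(0)
        vox = np.stack([rng.permutation(n) % 50, (np.arange(n) // 50) % 20,
                        np.arange(n) % 20], axis=1)
        fx = L.FixelSet(grid, vox, np.tile([1.0, 0, 0], (n, 1)),
                        np.ones(n), np.full((n, 1), 5.0),
                        max_per_voxel=60)
        noisy = L.add_density_noise(fx, 0.04, seed=3)
        sd = np.std(noisy.fd[:, 0] - 5.0)
        assert np.isclose(sd, 0.04 * 5.0, rtol=0.05)


class TestAllocation:
    def test_proportional_with_minimum(self):
        alloc = _allocate(100, np.array([50.0, 50.0, 0.0]))
        assert alloc.sum() == 100
        assert alloc.min() >= 1
        assert alloc[2] == 1

    def test_exact_proportions(self):
        assert np.array_equal(_allocate(10, np.array([3.0, 7.0])), [3, 7])


class TestSynthesizeTractogram:
    def test_no_fp_endpoints_in_own_nodes(self, model1_pair):
        t = L.synthesize_tractogram(model1_pair, n_streamlines=100,
                                    fp_fraction=0.0, seed=1)
        a = L.assign_streamlines(t, model1_pair.nodes)
        expected = np.array([model1_pair.bundle_edges()[b]
                             for b in t.bundle_ids])
        assert np.array_equal(a.edges, expected)

    def test_half_false_positives(self, model1_pair):
        t = L.synthesize_tractogram(model1_pair, n_streamlines=1000,
                                    fp_fraction=0.5, seed=1)
        assert int(np.sum(t.bundle_ids == -1)) == 500

    def test_fp_without_crossing_rejected(self):
        pair = L.build_isolated_pair(100, 100)
        with pytest.raises(ValueError):
            L.synthesize_tractogram(pair, n_streamlines=10, fp_fraction=0.5,
                                    seed=0)

    def test_zero_jitter_pure_radial_offset(self, model1_pair):
        t = L.synthesize_tractogram(model1_pair, n_streamlines=20,
                                    fp_fraction=0.0, jitter=0.0, seed=1)
        from longisift.phantom import resample_polyline
        for s, b in zip(t.streamlines, t.bundle_ids):
            bundle = model1_pair.bundles[b]
            path = resample_polyline(bundle.centreline,
                                     model1_pair.config.resample_step)
            offsets = s - path
            # constant perpendicular displacement within the tube radius
            assert np.allclose(offsets, offsets[0], atol=1e-9)
            assert np.linalg.norm(offsets[0]) <= bundle.radius + 1e-9
            assert abs(np.dot(offsets[0], bundle.direction)) < 1e-9

    def test_fp_streamlines_span_two_bundles(self, model1_pair):
        t = L.synthesize_tractogram(model1_pair, n_streamlines=50,
                                    fp_fraction=0.3, seed=2)
        for s, (ba, bb) in t.fp_pairs.items():
            assert ba != bb
            assert t.bundle_ids[s] == -1

    def test_deterministic_given_seed(self, model1_pair):
        a = L.synthesize_tractogram(model1_pair, n_streamlines=60, seed=5)
        b = L.synthesize_tractogram(model1_pair, n_streamlines=60, seed=5)
        assert all(np.array_equal(x, y)
                   for x, y in zip(a.streamlines, b.streamlines))


class TestPerturbSession:
    def test_same_seed_equal_counts_identical(self, noiseless_config):
        pair = build_model(2, noiseless_config)
        from dataclasses import replace
        eq = [replace(b, fibre_count=(b.fibre_count[0], b.fibre_count[0]))
              for b in pair.bundles]
        pair_eq = L.PhantomPair(bundles=eq, fixels=pair.fixels,
                                nodes=pair.nodes, config=pair.config,
                                crossings=pair.crossings)
        a = L.perturb_session_tractogram(pair_eq, 0, seed=7, n_streamlines=50)
        b = L.perturb_session_tractogram(pair_eq, 1, seed=7, n_streamlines=50)
        assert all(np.array_equal(x, y)
                   for x, y in zip(a.streamlines, b.streamlines))

    def test_different_seeds_differ(self, model1_pair):
        a = L.perturb_session_tractogram(model1_pair, 0, seed=1,
                                         n_streamlines=50)
        b = L.perturb_session_tractogram(model1_pair, 0, seed=2,
                                         n_streamlines=50)
        assert not all(np.array_equal(x, y)
                       for x, y in zip(a.streamlines, b.streamlines))

    def test_removed_bundle_gets_minimum_allocation(self, noiseless_config):
        pair = build_model(3, noiseless_config)
        t = L.perturb_session_tractogram(pair, 1, seed=3, n_streamlines=200,
                                         fp_fraction=0.0)
        counts = np.bincount(t.bundle_ids, minlength=len(pair.bundles))
        removed = [b.id for b in pair.bundles if b.fibre_count[1] == 0]
        surviving = pair.counts(1)
        # removed bundles get exactly the minimum; survivors are proportional
        for b in removed:
            assert counts[b] == 1
        alive = surviving > 0
        expected = (200 - len(removed)) * surviving[alive] / surviving[alive].sum()
        # proportional up to rounding and the minimum-allocation transfers
        assert np.all(np.abs(counts[alive] - expected) <= len(removed) + 1)
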