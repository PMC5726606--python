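"""Streamline propagation: stopping rules, conservation, direction sampling."""

import numpy as np
import pytest

from tractterm.phantom import generate_phantom
from tractterm.tracking import (global_profile, propagate_streamline,
                                propagate_streamlines, sample_direction,
                                Streamline, track_seed, TrackingParams)

from conftest import corridor_spec


def _seed_world(phantom, ijk):
    return phantom.grid.voxel_to_world(np.asarray(ijk, dtype=float))


def _end_seed_voxel(phantom):
    """The -x end voxel of the single-row corridor."""
    wm_idx = np.argwhere(phantom.wm_mask)
    return tuple(wm_idx[np.argmin(wm_idx[:, 0])])


class TestSampleDirection:
    def test_dispersion_zero_returns_field_direction(self):
        rng = np.random.default_rng(0)
        d = sample_direction([1.0, 0, 0], [1.0, 0, 0], 0.0, rng)
        assert np.allclose(d, [1, 0, 0])

    def test_sign_aligned_to_previous_direction(self):
        rng = np.random.default_rng(0)
        d = sample_direction([1.0, 0, 0], [-1.0, 0, 0], 0.0, rng)
        assert np.allclose(d, [-1, 0, 0])

    def test_first_step_explores_both_signs(self):
        rng = np.random.default_rng(1)
        signs = [np.sign(sample_direction([1.0, 0, 0], None, 0.0, rng)[0])
                 for _ in range(200)]
        assert 0.3 < np.mean(np.asarray(signs) > 0) < 0.7

    def test_outside_field_errors(self):
        with pytest.raises(ValueError):
            sample_direction([0.0, 0, 0], [1.0, 0, 0], 0.0,
                             np.random.default_rng(0))

    def test_mean_deviation_matches_half_normal(self):
        """10,000 draws at 20 degrees dispersion: the mean angular deviation
        from the fibre axis equals the half-normal mean sigma*sqrt(2/pi)
        within 2 degrees."""
        rng = np.random.default_rng(42)
        axis = np.array([0.0, 0.0, 1.0])
        draws = np.array([sample_direction(axis, axis, 20.0, rng)
                          for _ in range(10_000)])
        ang = np.degrees(np.arccos(np.clip(draws @ axis, -1, 1)))
        expected = 20.0 * np.sqrt(2.0 / np.pi)
        assert abs(ang.mean() - expected) < 2.0
        assert np.allclose(np.linalg.norm(draws, axis=1), 1.0, atol=1e-9)


class TestStoppingRules:
    def test_corridor_exit_retains_exclusion_point(self, corridor_phantom):
        """A 10 mm corridor ahead of the seed yields 21-point streamlines
        (10/0.5 + 1) stopping in the exclusion mask; backward launches stop
        after a single step."""
        params = TrackingParams(n_streamlines=64, step_mm=0.5, rng_seed=0)
        seed = _end_seed_voxel(corridor_phantom)
        start = _seed_world(corridor_phantom, seed)
        res = propagate_streamlines(np.tile(start, (64, 1)), corridor_phantom,
                                    params, np.random.default_rng(3))
        assert set(res.reasons) == {"exclusion_mask"}
        assert set(res.n_points) == {2, 21}
        forward = res.n_points == 21
        assert forward.any() and (~forward).any()

    def test_forward_streamline_geometry(self, corridor_phantom):
        params = TrackingParams(n_streamlines=1, step_mm=0.5, rng_seed=0)
        seed = _end_seed_voxel(corridor_phantom)
        start = _seed_world(corridor_phantom, seed)
        for trial in range(20):
            s = propagate_streamline(start, corridor_phantom, params,
                                     np.random.default_rng(trial))
            steps = np.linalg.norm(np.diff(s.points, axis=0), axis=1)
            assert np.allclose(steps, 0.5, atol=1e-9)
            if len(s.points) == 21:
                assert abs(s.arc_length - 10.0) < 1e-9
                return
        pytest.fail("no forward streamline observed in 20 trials")

    def test_length_cap(self):
        """A straight corridor longer than the cap stops at max_length with
        arc length exactly at the cap."""
        spec = corridor_spec(grid_shape=(60, 5, 5), voxel_size=10.0,
                             half_extent=(280.0, 4.0, 4.0))
        ph = generate_phantom(spec)
        params = TrackingParams(n_streamlines=8, step_mm=0.5,
                                max_length_mm=500.0, rng_seed=0)
        seed = _end_seed_voxel(ph)
        res = propagate_streamlines(
            np.tile(_seed_world(ph, seed), (8, 1)), ph, params,
            np.random.default_rng(0))
        forward = res.n_points == 1001  # 500 mm / 0.5 mm steps + seed point
        assert forward.any()
        assert all(r == "max_length" for r in res.reasons[forward])
        assert all(r == "exclusion_mask" for r in res.reasons[~forward])
        assert np.all((res.n_points - 1) * 0.5 <= 500.0 + 1e-9)

    def test_curvature_stop_on_sharp_bend(self):
        """A field bending 90 degrees within one voxel trips a 45-degree
        curvature limit; the default 180-degree limit lets it pass."""
        spec = corridor_spec(grid_shape=(24, 7, 24), voxel_size=2.0,
                             half_extent=(18.0, 0.9, 18.0))
        ph = generate_phantom(spec)
        gx = ph.grid.world_coordinate_grids()[0]
        bend = ph.wm_mask & (gx >= 4.0)
        ph.orientation_field[bend] = [0.0, 0.0, 1.0]
        seed = _end_seed_voxel(ph)
        start = _seed_world(ph, seed)

        tight = TrackingParams(n_streamlines=8, curvature_limit_deg=45.0,
                               rng_seed=0)
        res = propagate_streamlines(np.tile(start, (8, 1)), ph, tight,
                                    np.random.default_rng(1))
        forward = res.n_points > 10  # backward launches exit within a voxel
        assert forward.any()
        assert all(r == "curvature" for r in res.reasons[forward])

        loose = TrackingParams(n_streamlines=8, curvature_limit_deg=180.0,
                               rng_seed=0)
        res = propagate_streamlines(np.tile(start, (8, 1)), ph, loose,
                                    np.random.default_rng(1))
        assert set(res.reasons) == {"exclusion_mask"}


class TestSeedTracking:
    def test_conservation_and_seed_count(self, corridor_phantom):
        params = TrackingParams(n_streamlines=200, rng_seed=5)
        seed = _end_seed_voxel(corridor_phantom)
        conn, streamlines, _ = track_seed(seed, corridor_phantom, params)
        assert len(streamlines) == 200
        assert conn.counts[seed] == 200          # every streamline starts there
        assert conn.counts.max() <= 200          # one count per streamline

    def test_corridor_counts_split_by_first_step_sign(self, corridor_phantom):
        """Distal corridor voxels are visited by the forward half of the
        launches only (first-step sign is uniform)."""
        params = TrackingParams(n_streamlines=400, rng_seed=5)
        seed = _end_seed_voxel(corridor_phantom)
        conn, _, _ = track_seed(seed, corridor_phantom, params,
                                keep_streamlines=False)
        wm_idx = np.argwhere(corridor_phantom.wm_mask)
        distal = tuple(wm_idx[np.argmax(wm_idx[:, 0])])
        # binomial(400, .5): 5 sigma band
        assert abs(conn.counts[distal] - 200) < 50
        corridor_counts = conn.counts[corridor_phantom.wm_mask]
        assert np.all(corridor_counts[corridor_counts > 0]
                      <= params.n_streamlines)

    def test_no_steps_through_exclusion_interior(self, corridor_phantom):
        """Visited voxels are corridor voxels plus boundary exclusion voxels
        face-adjacent to the white matter."""
        from scipy import ndimage

        params = TrackingParams(n_streamlines=100, rng_seed=2)
        seed = _end_seed_voxel(corridor_phantom)
        conn, _, _ = track_seed(seed, corridor_phantom, params,
                                keep_streamlines=False)
        wm = corridor_phantom.wm_mask
        halo = ndimage.binary_dilation(
            wm, ndimage.generate_binary_structure(3, 1))
        assert not np.any((conn.counts > 0) & ~halo)

    def test_dispersion_cannot_increase_distal_count(self):
        """Raising the angular dispersion never increases the streamline count
        reaching the far end of a straight corridor (checked over 20 seeds)."""
        wide = corridor_spec(grid_shape=(31, 9, 9), voxel_size=2.0,
                             half_extent=(24.0, 6.0, 6.0))
        ph0 = generate_phantom(wide)
        ph20 = generate_phantom(
            corridor_spec(grid_shape=(31, 9, 9), voxel_size=2.0,
                          half_extent=(24.0, 6.0, 6.0), dispersion_deg=20.0))
        wm_idx = np.argwhere(ph0.wm_mask)
        imax = wm_idx[:, 0].max()
        mid = (ph0.grid.shape[1] // 2, ph0.grid.shape[2] // 2)
        seed = (int(wm_idx[:, 0].min()), *mid)
        distal = (int(imax), *mid)
        params = TrackingParams(n_streamlines=100)
        c0 = c20 = 0
        for rep in range(20):
            rng0, rng20 = (np.random.default_rng((rep, d)) for d in (0, 20))
            conn0, _, _ = track_seed(seed, ph0, params, rng=rng0,
                                     keep_streamlines=False)
            conn20, _, _ = track_seed(seed, ph20, params, rng=rng20,
                                      keep_streamlines=False)
            c0 += conn0.counts[distal]
            c20 += conn20.counts[distal]
        assert c20 <= c0

    def test_zero_dispersion_paths_are_reproducible(self, corridor_phantom):
        params = TrackingParams(n_streamlines=16, rng_seed=9)
        seed = _end_seed_voxel(corridor_phantom)
        _, s1, _ = track_seed(seed, corridor_phantom, params)
        _, s2, _ = track_seed(seed, corridor_phantom, params)
        for a, b in zip(s1, s2):
            assert np.array_equal(a.points, b.points)
            assert a.reason == b.reason


class TestGlobalProfile:
    def test_single_profile_identity_and_additivity(self, corridor_phantom):
        params = TrackingParams(n_streamlines=50, rng_seed=1)
        seed = _end_seed_voxel(corridor_phantom)
        conn, _, _ = track_seed(seed, corridor_phantom, params,
                                keep_streamlines=False)
        assert np.array_equal(global_profile([conn]), conn.counts)
        two = global_profile([conn, conn])
        assert np.array_equal(two, 2 * conn.counts)

    def test_permutation_invariance(self, corridor_phantom):
        params = TrackingParams(n_streamlines=30, rng_seed=1)
        wm_idx = np.argwhere(corridor_phantom.wm_mask)
        conns = []
        for ijk in (wm_idx[0], wm_idx[3]):
            c, _, _ = track_seed(tuple(ijk), corridor_phantom, params,
                                 keep_streamlines=False)
            conns.append(c)
        assert np.array_equal(global_profile(conns),
                              global_profile(conns[::-1]))

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError):
            global_profile([np.zeros((3, 3, 3)), np.zeros((4, 4, 4))])
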