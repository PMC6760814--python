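"""Trajectory I/O, cleaning, differentiation and the shuffle control."""

import numpy as np
import pytest

from fishrules import trajectories as tj


def small_ts(T=6, N=2, **kwargs):
    pos = np.cumsum(np.ones((T, N, 2)) * 0.1, axis=0)
    pos[:, 1, 0] += 1.0
    kwargs.setdefault("arena_radius", 10.0)
    return tj.TrajectorySet(positions=pos, **kwargs)


class TestIO:
    @pytest.mark.parametrize("dialect", ["npz", "hdf5", "csv-long"])
    def test_roundtrip_preserves_positions_and_mask(self, tmp_path, dialect):
        ts = small_ts()
        ts.positions[2, 1] = np.nan
        ts.missing_mask[2, 1] = True
        ext = {"npz": "a.npz", "hdf5": "a.h5", "csv-long": "a.csv"}[dialect]
        path = tj.save_trajectories(ts, tmp_path / ext, dialect=dialect)
        back = tj.load_trajectories(path)
        assert back.missing_mask[2, 1]
        np.testing.assert_allclose(
            back.positions[~back.missing_mask], ts.positions[~ts.missing_mask]
        )
        assert back.fps == ts.fps and back.arena_radius == ts.arena_radius

    def test_csv_and_npz_dialects_agree(self, tmp_path):
        ts = small_ts()
        p1 = tj.save_trajectories(ts, tmp_path / "t.npz")
        p2 = tj.save_trajectories(ts, tmp_path / "t.csv")
        np.testing.assert_allclose(
            tj.load_trajectories(p1).positions, tj.load_trajectories(p2).positions
        )

    def test_malformed_shape_names_expected_layout(self, tmp_path):
        np.savez(tmp_path / "bad.npz", trajectories=np.zeros((5, 3)))
        with pytest.raises(ValueError, match=r"T x N x 2"):
            tj.load_trajectories(tmp_path / "bad.npz")

    def test_unknown_dialect_and_empty_file_error(self, tmp_path):
        ts = small_ts()
        path = tj.save_trajectories(ts, tmp_path / "t.npz")
        with pytest.raises(ValueError, match="dialect"):
            tj.load_trajectories(path, dialect="parquet")
        empty = tmp_path / "empty.csv"
        empty.write_text("")
        with pytest.raises(Exception):
            tj.load_trajectories(empty)


class TestInterpolation:
    def test_linear_midpoint(self):
        pos = np.zeros((3, 1, 2))
        pos[0, 0] = (0, 0)
        pos[1, 0] = np.nan
        pos[2, 0] = (2, 0)
        ts = tj.TrajectorySet(positions=pos, arena_radius=5)
        out = tj.interpolate_gaps(ts)
        np.testing.assert_allclose(out.positions[1, 0], (1, 0))
        assert not out.missing_mask.any()

    def test_gap_longer_than_max_gap_left_missing(self):
        pos = np.zeros((8, 1, 2))
        pos[:, 0, 0] = np.arange(8)
        pos[2:6, 0] = np.nan
        ts = tj.TrajectorySet(positions=pos, arena_radius=10)
        out = tj.interpolate_gaps(ts, max_gap=3)
        assert out.missing_mask[2:6, 0].all()
        out2 = tj.interpolate_gaps(ts, max_gap=4)
        assert not out2.missing_mask.any()

    def test_boundary_gap_warns_and_stays_missing(self):
        pos = np.ones((5, 1, 2))
        pos[0, 0] = np.nan
        ts = tj.TrajectorySet(positions=pos, arena_radius=5)
        with pytest.warns(UserWarning, match="boundary"):
            out = tj.interpolate_gaps(ts)
        assert out.missing_mask[0, 0]

    def test_interpolated_fraction_of_points(self):
        # 1 missing point among 500 frames x 2 individuals -> 0.1% of points
        pos = np.cumsum(np.full((500, 2, 2), 0.01), axis=0)
        pos[100, 1] = np.nan
        ts = tj.TrajectorySet(positions=pos, arena_radius=50)
        assert ts.missing_mask.sum() / ts.missing_mask.size == pytest.approx(0.001)
        out = tj.interpolate_gaps(ts)
        assert out.missing_mask.sum() == 0


class TestNormalize:
    def test_centre_maps_to_origin_and_border_mask(self):
        pos = np.zeros((2, 3, 2))
        pos[:, 0] = (5.0, 5.0)  # at centre
        pos[:, 1] = (5.0 + 0.9 * 4.0, 5.0)  # at 0.9 R
        pos[:, 2] = (5.0 + 0.5 * 4.0, 5.0)
        ts = tj.TrajectorySet(
            positions=pos, arena_center=(5.0, 5.0), arena_radius=4.0
        )
        out, border = tj.normalize_and_mask(ts, border_fraction=0.8)
        np.testing.assert_allclose(out.positions[:, 0], 0.0)
        assert border[:, 1].all() and not border[:, 0].any() and not border[:, 2].any()

    def test_masked_fraction_matches_area_ratio(self):
        rng = np.random.default_rng(0)
        n = 40000
        r = np.sqrt(rng.random(n))
        phi = rng.uniform(-np.pi, np.pi, n)
        pos = np.stack([r * np.cos(phi), r * np.sin(phi)], axis=1)[:, None, :]
        ts = tj.TrajectorySet(positions=pos, arena_radius=1.0)
        _, border = tj.normalize_and_mask(ts, border_fraction=0.8)
        assert border.mean() == pytest.approx(1 - 0.8**2, abs=0.01)

    def test_idempotent_on_normalized_data(self):
        ts = small_ts(arena_center=(3.0, 3.0), arena_radius=7.0, body_length=2.0)
        once, mask1 = tj.normalize_and_mask(ts)
        twice, mask2 = tj.normalize_and_mask(once)
        np.testing.assert_allclose(once.positions, twice.positions)
        np.testing.assert_array_equal(mask1, mask2)


class TestSmoothing:
    def test_kernel_positive_and_normalized(self):
        w = tj.half_gaussian_kernel(5, 1.0)
        assert (w > 0).all() and w.sum() == pytest.approx(1.0)
        assert w[0] > w[1] > w[4]  # most weight on the current frame

    def test_constant_trajectory_unchanged(self):
        pos = np.ones((10, 1, 2)) * 3.0
        ts = tj.TrajectorySet(positions=pos, arena_radius=5)
        out = tj.smooth_causal(ts)
        np.testing.assert_allclose(out.positions, pos)

    def test_causality_impulse_response(self):
        pos = np.zeros((12, 1, 2))
        pos[6, 0, 0] = 1.0
        ts = tj.TrajectorySet(positions=pos, arena_radius=5)
        out = tj.smooth_causal(ts)
        assert np.all(out.positions[:6, 0, 0] == 0)
        assert np.all(out.positions[6:11, 0, 0] > 0)

    def test_ramp_delayed_by_kernel_mean_lag(self):
        T, L, sigma = 20, 5, 1.0
        pos = np.zeros((T, 1, 2))
        pos[:, 0, 0] = np.arange(T, dtype=float)
        ts = tj.TrajectorySet(positions=pos, arena_radius=50)
        out = tj.smooth_causal(ts, kernel_len=L, sigma=sigma)
        w = tj.half_gaussian_kernel(L, sigma)
        mean_lag = (w * np.arange(L)).sum()
        t = np.arange(L - 1, T)
        np.testing.assert_allclose(out.positions[L - 1 :, 0, 0], t - mean_lag)


class TestDifferentiate:
    def test_uniform_motion_velocity_and_zero_acceleration(self):
        fps, c = 32.0, 0.25
        pos = np.zeros((10, 1, 2))
        pos[:, 0, 0] = c * np.arange(10)
        ts = tj.TrajectorySet(positions=pos, fps=fps, arena_radius=10)
        kin = tj.differentiate(ts)
        assert not kin.valid_mask[:2].any()
        np.testing.assert_allclose(kin.velocity[2:, 0, 0], c * fps)
        np.testing.assert_allclose(kin.acceleration[2:, 0], 0.0, atol=1e-9)
        np.testing.assert_allclose(kin.speed[2:, 0], c * fps)

    def test_future_perturbation_leaves_past_kinematics(self):
        rng = np.random.default_rng(1)
        pos = np.cumsum(rng.normal(0, 0.1, size=(20, 2, 2)), axis=0)
        ts = tj.TrajectorySet(positions=pos, arena_radius=50)
        kin1 = tj.differentiate(tj.smooth_causal(ts))
        pos2 = pos.copy()
        pos2[11:] += rng.normal(0, 5, size=pos2[11:].shape)
        kin2 = tj.differentiate(
            tj.smooth_causal(tj.TrajectorySet(positions=pos2, arena_radius=50))
        )
        np.testing.assert_allclose(kin1.velocity[:11], kin2.velocity[:11])
        np.testing.assert_allclose(kin1.acceleration[:11], kin2.acceleration[:11])

    def test_circular_motion_centripetal_acceleration(self):
        fps, r, s = 128.0, 2.0, 3.0  # fine discretization
        omega = s / r
        t = np.arange(600) / fps
        pos = np.stack([r * np.cos(omega * t), r * np.sin(omega * t)], axis=1)
        ts = tj.TrajectorySet(positions=pos[:, None, :], fps=fps, arena_radius=5)
        kin = tj.differentiate(ts)
        a = np.linalg.norm(kin.acceleration[2:, 0], axis=1)
        assert np.median(a) == pytest.approx(s**2 / r, rel=0.02)


class TestShuffle:
    def test_published_shift_statistics(self):
        # 10-minute recording at 32 fps, 100 individuals
        min_s, mean_s = tj.circular_shift_stats(600 * 32, 100, fps=32.0)
        assert min_s == pytest.approx(6.0)
        assert mean_s == pytest.approx(150.0)

    def test_marginals_preserved_per_individual(self):
        ts = small_ts(T=50, N=4)
        out = tj.shuffle_shift(ts)
        for i in range(4):
            np.testing.assert_allclose(
                np.sort(out.positions[:, i, 0]), np.sort(ts.positions[:, i, 0])
            )

    def test_n_fold_application_is_identity_when_commensurate(self):
        ts = small_ts(T=40, N=4)
        out = ts
        for _ in range(4):
            out = tj.shuffle_shift(out)
        np.testing.assert_allclose(out.positions, ts.positions)

    def test_more_individuals_than_frames_rejected(self):
        with pytest.raises(ValueError):
            tj.shuffle_offsets(3, 5)


class TestSplit:
    def test_default_fraction_sizes(self):
        idx = tj.split(1000)
        sizes = {
            part: sum(b - a for a, b in ranges)
            for part, ranges in idx.ranges().items()
        }
        assert sizes == {"train": 970, "validation": 20, "test": 10}

    def test_small_recording_split(self):
        idx = tj.split(4, fractions=(0.5, 0.25, 0.25))
        assert idx.validation == (2, 3) and idx.test == (3, 4)
        assert idx.train == [(0, 2)]

    @pytest.mark.parametrize("rotate", [0, 1, 2])
    def test_rotation_keeps_ranges_disjoint_and_covering(self, rotate):
        idx = tj.split(200, rotate=rotate)
        covered = np.zeros(200, dtype=int)
        for ranges in idx.ranges().values():
            for a, b in ranges:
                covered[a:b] += 1
        assert (covered == 1).all()

    def test_rotation_moves_validation_block(self):
        assert tj.split(200, rotate=1).validation != tj.split(200).validation

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            tj.split(20)  # 1% of 20 frames is empty
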