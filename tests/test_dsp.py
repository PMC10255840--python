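"""RT/DT map formation, axis calibration, persistence."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fallradar as fr
from fallradar.dsp import (FeatureMap, load_cubes, load_maps, range_axis,
                           render, save_cubes, save_maps)
from fallradar.radar_sim import DataCube, trajectory_template

from conftest import constant_rate_trajectory, static_trajectory


def nearest_bin(config, d):
    return int(np.abs(range_axis(config, config.samples_per_chirp // 2) - d)
               .argmin())


class TestRangeTimeMap:
    def test_static_target_ridge_at_true_bin(self, small_radar, quiet):
        cube = fr.synthesize_cube(static_trajectory(3.0), small_radar,
                                  quiet, seed=0)
        rt = fr.range_time_map(cube)
        assert np.all(rt.values.argmax(axis=0) == nearest_bin(small_radar,
                                                              3.0))

    def test_all_zero_cube_floors_uniformly(self, small_radar):
        cube = DataCube(samples=np.zeros(
            (small_radar.samples_per_chirp, small_radar.n_chirps),
            dtype=np.complex64), config=small_radar)
        rt = fr.range_time_map(cube)
        assert np.ptp(rt.values) == 0.0

    def test_backward_fall_ridge_reverses(self, radar_config, quiet):
        traj = trajectory_template("backward_fall", "toward_radar",
                                   1.75, 1.0, seed=7)
        cube = fr.synthesize_cube(traj, radar_config, quiet, seed=7)
        rt = fr.range_time_map(cube)
        ridge = rt.ridge()
        onset_col = np.searchsorted(rt.time_axis, traj.fall_onset)
        end_col = np.searchsorted(
            rt.time_axis, traj.fall_onset + traj.fall_duration)
        assert ridge[onset_col] < ridge[0]          # walked toward radar
        assert ridge[end_col] > ridge[onset_col]    # fall reversed the trend

    def test_parseval_total_power_conserved(self, small_radar, quiet):
        cube = fr.synthesize_cube(static_trajectory(2.5), small_radar,
                                  fr.NoiseSpec(snr_db=10.0), seed=1)
        cube128 = DataCube(samples=cube.samples.astype(np.complex128),
                           config=small_radar)
        rt = fr.range_time_map(cube128, decimate=None, db=False,
                               onesided=False)
        n = small_radar.samples_per_chirp
        assert np.sum(rt.values, dtype=np.float64) / n == pytest.approx(
            np.sum(np.abs(cube128.samples) ** 2), rel=1e-6)

    def test_clutter_suppression_removes_static_line(self, small_radar):
        spec = fr.NoiseSpec(snr_db=300.0, clutter_amplitude=0.5,
                            clutter_range_m=1.2)
        cube = fr.synthesize_cube(static_trajectory(4.0), small_radar,
                                  spec, seed=2)
        plain = fr.range_time_map(cube, db=False)
        clean = fr.range_time_map(cube, clutter_suppress=True, db=False)
        cbin = nearest_bin(small_radar, 1.2)
        assert clean.values[cbin].mean() < 1e-3 * plain.values[cbin].mean()


class TestDopplerTimeMap:
    def test_approaching_target_negative_doppler(self, small_radar, quiet):
        cube = fr.synthesize_cube(
            constant_rate_trajectory(4.0, -0.5), small_radar, quiet, seed=0)
        dt = fr.doppler_time_map(cube)
        assert np.all(dt.ridge() < 0)
        # expected Doppler: 2 * fc / c * dd/dt
        expected = 2 * small_radar.start_frequency / 299792458.0 * -0.5
        step = dt.feature_axis[1] - dt.feature_axis[0]
        assert np.abs(dt.ridge() - expected).max() <= step

    def test_static_target_zero_doppler(self, small_radar, quiet):
        cube = fr.synthesize_cube(static_trajectory(3.0), small_radar,
                                  quiet, seed=0)
        dt = fr.doppler_time_map(cube, gate=np.ones(128, dtype=bool))
        assert np.all(dt.ridge() == 0.0)

    def test_right_fall_away_doppler_sign_flips(self, radar_config, quiet):
        traj = trajectory_template("right_fall", "away_from_radar",
                                   1.75, 1.0, seed=5)
        cube = fr.synthesize_cube(traj, radar_config, quiet, seed=5)
        dt = fr.doppler_time_map(cube)
        ridge = dt.ridge()
        walk = ridge[(dt.time_axis > 0.5)
                     & (dt.time_axis < traj.fall_onset - 0.3)]
        mid_fall = traj.fall_onset + 0.5 * traj.fall_duration
        fall = ridge[(dt.time_axis > traj.fall_onset + 0.1)
                     & (dt.time_axis < mid_fall)]
        assert np.median(walk) > 0      # moving away: positive Doppler
        assert np.median(fall) < 0      # fall reverses toward the radar

    def test_conjugate_cube_mirrors_doppler(self, small_radar):
        traj = trajectory_template("forward_fall", "toward_radar", 1.7,
                                   1.0, seed=3, fall_onset=0.5,
                                   fall_duration=0.5)
        cube = fr.synthesize_cube(traj, small_radar, fr.NoiseSpec(), seed=3)
        # conjugate the slow-time phase while keeping beat frequencies
        # positive: conj + fast-time reversal maps X_k -> conj(X_k)
        flipped = np.conj(np.roll(cube.samples[::-1], 1, axis=0))
        conj = DataCube(samples=flipped, config=small_radar)
        gate = np.ones(small_radar.samples_per_chirp // 2, dtype=bool)
        a = fr.doppler_time_map(cube, gate=gate)
        b = fr.doppler_time_map(conj, gate=gate)
        # negative-frequency row 0 has no positive twin on an even-size fft
        assert np.allclose(a.values[1:], b.values[1:][::-1], atol=1e-3)

    def test_window_longer_than_record_rejected(self, small_radar, quiet):
        cube = fr.synthesize_cube(static_trajectory(3.0), small_radar,
                                  quiet, seed=0)
        with pytest.raises(ValueError, match="window"):
            fr.doppler_time_map(cube, fr.StftParams(
                window_length=2 ** 14, hop=2 ** 14, fft_length=2 ** 14))


class TestRangeFromBeat:
    @given(d=st.floats(0.1, 7.0))
    def test_round_trip_is_identity(self, d, radar_config):
        assert fr.range_from_beat(
            fr.beat_frequency(d, radar_config), radar_config) \
            == pytest.approx(d, rel=1e-12)

    def test_zero_and_negative(self, radar_config):
        assert fr.range_from_beat(0.0, radar_config) == 0.0
        with pytest.raises(ValueError):
            fr.range_from_beat(-1.0, radar_config)

    def test_table_geometry_inverse(self, radar_config):
        assert fr.range_from_beat(1.00578e6, radar_config) == pytest.approx(
            3.0, rel=1e-4)


class TestPersistence:
    def test_cube_round_trip(self, small_radar, quiet, tmp_path):
        cube = fr.synthesize_cube(static_trajectory(3.0), small_radar,
                                  quiet, seed=4, trajectory_id="s0")
        save_cubes(tmp_path / "c.h5", [cube])
        loaded = load_cubes(tmp_path / "c.h5")[0]
        assert np.array_equal(loaded.samples, cube.samples)
        assert loaded.config == small_radar
        assert loaded.extras["label"] == "nonmotion_fall"

    def test_map_round_trip_and_render(self, small_radar, quiet, tmp_path):
        cube = fr.synthesize_cube(static_trajectory(3.0), small_radar,
                                  fr.NoiseSpec(), seed=4, trajectory_id="s0")
        maps = {"s0": {"rt": fr.range_time_map(cube),
                       "dt": fr.doppler_time_map(cube)}}
        save_maps(tmp_path / "m.h5", maps)
        loaded = load_maps(tmp_path / "m.h5")
        for key in ("rt", "dt"):
            assert np.array_equal(loaded["s0"][key].values,
                                  maps["s0"][key].values)
            assert loaded["s0"][key].provenance == maps["s0"][key].provenance
        render(maps["s0"]["rt"], tmp_path / "rt.png")
        from PIL import Image
        img = np.asarray(Image.open(tmp_path / "rt.png"))
        assert img.shape == maps["s0"]["rt"].values.shape

    def test_feature_map_validation(self):
        with pytest.raises(ValueError):
            FeatureMap(values=np.zeros((3, 4)), kind="RT",
                       feature_axis=np.arange(3),
                       time_axis=np.arange(5, dtype=float))
        with pytest.raises(ValueError):
            FeatureMap(values=np.full((2, 2), np.nan), kind="DT",
                       feature_axis=np.arange(2),
                       time_axis=np.arange(2, dtype=float))
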