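"""Scene simulator: clock model, calibration sweep, ground-truthed scenes."""

import dataclasses
import hashlib
import json

import numpy as np
import pytest
from scipy import stats

from uwbid.calibration import rmse_1d
from uwbid.mapping import read_detections_csv, read_yolo_txt, read_correspondence_config
from uwbid.ranging import SPEED_OF_LIGHT, compute_all_distances, compute_distance, read_ranging_log
from uwbid.simulate import (
    SimConfig,
    jitter_propagation_constant,
    simulate_calibration_sweep,
    simulate_exchange,
    simulate_scene,
    timestamp_noise_for_range_sd,
)
from uwbid.trilateration import read_anchors, trilaterate


class TestExchange:
    def test_ideal_exchange_is_exact(self, ideal_config):
        ex = simulate_exchange(5.0, ideal_config)
        assert compute_distance(ex, "A1") == pytest.approx(5.0, abs=1e-9)

    def test_skewed_exchange_biased_but_deterministic(self, ideal_config):
        cfg = dataclasses.replace(ideal_config, tag_clock_skew_ppm=20.0)
        d1 = compute_distance(simulate_exchange(8.0, cfg), "A1")
        d2 = compute_distance(simulate_exchange(8.0, cfg), "A1")
        assert d1 == d2
        assert abs(d1 - 8.0) > 0

    def test_jitter_propagation_matches_delta_method(self, ideal_config):
        """Empirical range s.d. within 2x of the linearised prediction."""
        sigma_t = 1e-10
        cfg = dataclasses.replace(ideal_config, timestamp_noise_s=sigma_t)
        rng = np.random.default_rng(0)
        tau = 6.0 / SPEED_OF_LIGHT
        k = jitter_propagation_constant(
            cfg.anchor_reply_delay_s, cfg.tag_reply_delay_s, tau
        )
        samples = np.array(
            [compute_distance(simulate_exchange(6.0, cfg, rng), "A1") for _ in range(1000)]
        )
        predicted_sd = SPEED_OF_LIGHT * sigma_t * k
        assert predicted_sd / 2 < samples.std() < predicted_sd * 2

    def test_noise_helper_inverts_propagation(self, ideal_config):
        sigma_t = timestamp_noise_for_range_sd(0.02, ideal_config)
        k = jitter_propagation_constant(
            ideal_config.anchor_reply_delay_s, ideal_config.tag_reply_delay_s
        )
        assert SPEED_OF_LIGHT * sigma_t * k == pytest.approx(0.02)

    def test_bias_model_shifts_distance(self, ideal_config):
        cfg = dataclasses.replace(
            ideal_config, range_bias_slope=1.002, range_bias_intercept_m=0.15
        )
        d = compute_distance(simulate_exchange(10.0, cfg), "A1")
        assert d == pytest.approx(1.002 * 10.0 + 0.15, abs=1e-9)


class TestCalibrationSweep:
    def test_sweep_shape_and_grid(self, ideal_config):
        ds = simulate_calibration_sweep(ideal_config)
        assert len(ds) == 200
        assert np.array_equal(np.unique(ds.true), np.arange(1.0, 21.0))
        assert np.allclose(ds.measured, ds.true, atol=1e-9)  # no bias, no noise

    def test_constant_offset_gives_matching_rmse(self, ideal_config):
        cfg = dataclasses.replace(ideal_config, range_bias_intercept_m=0.18)
        ds = simulate_calibration_sweep(cfg)
        assert rmse_1d(ds.measured, ds.true) == pytest.approx(0.18, abs=1e-9)

    def test_fixed_seed_reproduces_dataset(self):
        a = simulate_calibration_sweep(SimConfig(seed=3))
        b = simulate_calibration_sweep(SimConfig(seed=3))
        assert np.array_equal(a.measured, b.measured)


class TestScene:
    def test_head_offset_geometry(self):
        scene = simulate_scene(SimConfig(seed=1, n_cows=3))
        for cow in scene.cows:
            d = np.linalg.norm(
                np.array(cow.head_position) - np.array(cow.body_center)
            )
            assert d == pytest.approx(1.2, abs=1e-12)

    def test_pairwise_separation_respected(self):
        cfg = SimConfig(seed=5, n_cows=4, min_separation_m=3.0)
        scene = simulate_scene(cfg)
        centres = np.array([c.body_center for c in scene.cows])
        for i in range(len(centres)):
            for j in range(i + 1, len(centres)):
                assert np.linalg.norm(centres[i] - centres[j]) >= 3.0

    def test_overcrowded_arena_raises(self):
        with pytest.raises(RuntimeError, match="could not place"):
            simulate_scene(SimConfig(arena=(6.0, 6.0), n_cows=10, min_separation_m=3.0))

    def test_single_cow_fix_to_detection_distance_is_head_offset(self, ideal_config):
        """Noise-free scene: tag fix sits one head offset from the box centre."""
        cfg = dataclasses.replace(ideal_config, n_cows=1, seed=2)
        scene = simulate_scene(cfg)
        ex = scene.exchanges[0]
        anchors = cfg.anchor_objects
        res = compute_all_distances(ex)
        fix = trilaterate(anchors, [res.distances[a.anchor_id] for a in anchors])
        # map the detection centre to world through the true homography
        from uwbid.mapping import apply_homography

        det = scene.detections[0]
        x0, y0, x1, y1 = det.box_px
        rect = apply_homography(scene.homography_true, ((x0 + x1) / 2, (y0 + y1) / 2))
        ppcm = cfg.camera["pixels_per_cm"]
        center_world = np.array(rect) / ppcm / 100.0
        d = np.linalg.norm(np.array(fix.position) - center_world)
        # projective distortion of the box centre adds a small geometric residue
        assert d == pytest.approx(1.2, abs=0.15)

    def test_same_seed_writes_byte_identical_files(self, tmp_path):
        def digest(d):
            h = hashlib.sha256()
            for p in sorted(d.iterdir()):
                h.update(p.name.encode() + p.read_bytes())
            return h.hexdigest()

        cfg = SimConfig(seed=9, n_cows=2)
        a, b = tmp_path / "a", tmp_path / "b"
        simulate_scene(cfg).write(a)
        simulate_scene(cfg).write(b)
        assert digest(a) == digest(b)

    def test_written_files_round_trip_through_readers(self, tmp_path):
        cfg = SimConfig(seed=4, n_cows=2, n_frames=2)
        scene = simulate_scene(cfg)
        scene.write(tmp_path)
        exchanges, skipped = read_ranging_log(tmp_path / "ranging.csv")
        assert skipped == 0 and len(exchanges) == len(scene.exchanges)
        dets = read_detections_csv(tmp_path / "detections.csv")
        assert len(dets) == len(scene.detections)
        anchors = read_anchors(tmp_path / "anchors.yaml")
        assert len(anchors) == 3
        corr, scale = read_correspondence_config(tmp_path / "correspondences.yaml")
        assert scale.pixels_per_cm == cfg.camera["pixels_per_cm"]
        yolo = read_yolo_txt(tmp_path / "frame_0000.txt", "frame_0000", cfg.image_size)
        n_frame0 = sum(d.image_id == "frame_0000" for d in scene.detections)
        assert len(yolo) == n_frame0
        truth = json.loads((tmp_path / "ground_truth.json").read_text())
        assert len(truth["cows"]) == 2
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["seed"] == 4

    def test_untagged_cows_get_detections_but_no_exchanges(self):
        scene = simulate_scene(SimConfig(seed=6, n_cows=2, n_tagged=1))
        assert len(scene.exchanges) == 1
        assert len(scene.detections) == 2
        assert sum(c.tagged for c in scene.cows) == 1


class TestStatistics:
    def test_trilateration_error_has_no_mean_bias_under_jitter(self, ideal_config):
        """Timestamp noise only: positional error mean consistent with 0."""
        errors = []
        anchors = ideal_config.anchor_objects
        for seed in range(50):
            cfg = dataclasses.replace(
                ideal_config, timestamp_noise_s=1.1e-10, seed=seed
            )
            rng = np.random.default_rng(seed)
            truth = np.array([5.0, 4.0])
            dists = {
                a.anchor_id: float(np.linalg.norm(truth - a.position)) for a in anchors
            }
            ex = simulate_exchange(dists, cfg, rng)
            res = compute_all_distances(ex)
            fix = trilaterate(anchors, [res.distances[a.anchor_id] for a in anchors])
            errors.append(np.array(fix.position) - truth)
        errors = np.array(errors)
        for axis in range(2):
            t = stats.ttest_1samp(errors[:, axis], 0.0)
            assert t.pvalue > 0.01
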