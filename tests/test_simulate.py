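"""The synthetic thermal-scene generator and its ground truth."""

import collections

import numpy as np
import pytest

import thermofall as tf
from thermofall import pipeline
from thermofall.io import GRID_SHAPE
from thermofall.preprocessing import ForegroundFrame, init_background, subtract_background
from thermofall.segmentation import split_targets
from thermofall.simulate import TRUNCATE_EXCESS_C, MotionScript


class TestRendering:
    def test_empty_scene_is_constant_background(self, clean_scene):
        rec, gt = tf.render_recording(clean_scene, [])
        stack = rec.stack()
        assert stack.shape == (45,) + GRID_SHAPE
        assert np.all(stack == clean_scene.background_c)
        assert gt.n_targets == 0

    def test_static_blob_center_recovered_within_half_pixel(
        self, clean_scene, clean_background
    ):
        rng = np.random.default_rng(0)
        script = tf.make_script("standing", clean_scene, rng, center=(12.0, 16.0))
        rec, gt = tf.render_recording(clean_scene, [script])
        fg = pipeline.recording_foreground(rec, clean_background)
        fgf = ForegroundFrame(delta=fg[10])
        det = tf.detect_human(fgf)
        assert det.detected
        b = tf.refine_barycenter(fgf, det.peak)
        assert np.hypot(*(np.array(b.coords) - gt.centers[0, 10])) < 0.5

    def test_noise_level_matches_config(self):
        scene = tf.SceneConfig(noise_sigma_k=0.25, duration_s=30.0, seed=9)
        rec, _ = tf.render_recording(scene, [])
        pixel = rec.stack()[:, 5, 5]  # 450 samples of one target-free pixel
        assert np.std(pixel) == pytest.approx(0.25, rel=0.10)

    def test_blob_leaving_grid_rejected_unless_clipping(self, clean_scene):
        rng = np.random.default_rng(1)
        script = tf.make_script("walking", clean_scene, rng)
        script.centers[:, 1] += 40.0  # push off-grid
        with pytest.raises(ValueError, match="leaves the grid"):
            tf.render_recording(clean_scene, [script])
        rec, _ = tf.render_recording(clean_scene, [script], allow_clipping=True)
        assert len(rec) == 45


class TestScripts:
    @pytest.mark.parametrize("label", tf.MOTION_LABELS)
    def test_script_invariants(self, label, clean_scene):
        rng = np.random.default_rng(3)
        s = tf.make_script(label, clean_scene, rng)
        assert s.n_frames == clean_scene.n_frames
        assert np.all(s.peak_excess_c >= TRUNCATE_EXCESS_C)  # ≥1 °C above bg
        assert np.all(s.peak_excess_c - TRUNCATE_EXCESS_C <= 5.0)  # ≤5 °C spread
        assert np.all(s.sigma_long >= s.sigma_short)

    def test_spread_invariant_enforced(self, clean_scene):
        rng = np.random.default_rng(0)
        s = tf.make_script("standing", clean_scene, rng)
        with pytest.raises(ValueError, match="5 °C"):
            MotionScript(
                label=s.label, centers=s.centers, sigma_long=s.sigma_long,
                sigma_short=s.sigma_short, theta=s.theta,
                peak_excess_c=np.full(s.n_frames, 7.5),
            )

    def test_fall_signature(self, clean_scene):
        # area and elongation rise during the fall, then the scene is static
        rng = np.random.default_rng(5)
        s = tf.make_script("falling", clean_scene, rng)
        ratio = s.sigma_long / s.sigma_short
        assert ratio[-1] > 2.0 > ratio[0]
        assert np.all(np.diff(ratio) >= -1e-12)
        disp = np.linalg.norm(s.centers[-1] - s.centers[0])
        assert 2.0 <= disp <= 5.0
        late = np.linalg.norm(np.diff(s.centers[-5:], axis=0), axis=1)
        assert np.all(late < 1e-9)  # static after the fall

    def test_exact_area_recovery_noise_free(self, clean_scene):
        # σ=0: render → subtract → threshold-component area equals the
        # scripted support pixel-for-pixel for every class and frame
        rng = np.random.default_rng(11)
        bg = init_background(
            tf.render_recording(clean_scene, [])[0].frames[:1]
        )
        for label in tf.MOTION_LABELS:
            script = tf.make_script(label, clean_scene, rng)
            rec, gt = tf.render_recording(clean_scene, [script])
            for i, frame in enumerate(rec.frames):
                delta = subtract_background(bg, frame).delta
                assert int((delta >= TRUNCATE_EXCESS_C).sum()) == gt.areas[0, i]


class TestDatasets:
    def test_balanced_counts_and_length(self, small_dataset):
        assert len(small_dataset) == 16
        counts = collections.Counter(str(rec.label) for rec, _ in small_dataset)
        assert set(counts.values()) == {2}
        assert all(len(rec) == 45 for rec, _ in small_dataset)

    def test_same_seed_reproduces_identically(self, noisy_scene):
        a = tf.make_dataset(1, noisy_scene, seed=4, n_subjects=2)
        b = tf.make_dataset(1, noisy_scene, seed=4, n_subjects=2)
        for (ra, _), (rb, _) in zip(a, b):
            assert np.array_equal(ra.stack(), rb.stack())
            assert ra.subject_id == rb.subject_id

    def test_different_seed_differs(self, noisy_scene):
        a = tf.make_dataset(1, noisy_scene, seed=4, n_subjects=2)
        b = tf.make_dataset(1, noisy_scene, seed=5, n_subjects=2)
        assert not np.array_equal(a[0][0].stack(), b[0][0].stack())


class TestMultiTarget:
    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_well_separated_targets_counted_exactly(
        self, k, clean_scene, clean_background
    ):
        rec, gt = tf.make_multitarget_scene(k, clean_scene, seed=20 + k)
        assert gt.n_targets == k
        fg = pipeline.recording_foreground(rec, clean_background)
        counts = [len(split_targets(ForegroundFrame(delta=f))) for f in fg]
        assert all(c == k for c in counts)

    def test_adjacent_targets_merge(self, clean_scene, clean_background):
        rec, _ = tf.make_multitarget_scene(
            2, clean_scene, seed=42, spawn_centers=[(12.0, 14.0), (12.0, 18.0)]
        )
        fg = pipeline.recording_foreground(rec, clean_background)
        counts = [len(split_targets(ForegroundFrame(delta=f))) for f in fg]
        mode = collections.Counter(counts).most_common(1)[0][0]
        assert mode == 1  # touching people are seen as one larger target

    def test_one_falls_ground_truth_labels(self, clean_scene):
        _, gt = tf.make_multitarget_scene(3, clean_scene, seed=8, one_falls=True)
        assert [str(l) for l in gt.labels] == ["falling", "walking", "walking"]

    def test_infeasible_placement_raises(self, clean_scene):
        with pytest.raises(ValueError, match="could not place"):
            tf.make_multitarget_scene(3, clean_scene, seed=0, min_separation_px=25.0)
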