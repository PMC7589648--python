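"""Presence decision, barycenter refinement and tracking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import thermofall as tf
from thermofall.detection import associate
from thermofall.preprocessing import ForegroundFrame

from conftest import blob_foreground


def fg_from(delta) -> ForegroundFrame:
    return ForegroundFrame(delta=np.asarray(delta, dtype=float))


def random_fg(seed, p_hot=0.1):
    rng = np.random.default_rng(seed)
    delta = np.maximum(rng.normal(0, 0.3, (24, 32)), 0)
    hot = rng.random((24, 32)) < p_hot
    delta[hot] += rng.uniform(0.5, 4.0, hot.sum())
    return fg_from(delta)


class TestDetectHuman:
    def test_all_zero_not_detected(self):
        det = tf.detect_human(fg_from(np.zeros((24, 32))))
        assert not det.detected and det.marked_count == 0 and not det.marked_mask.any()

    def test_exactly_eight_marked_pixels_is_detected(self):
        delta = np.zeros((24, 32))
        delta[9:12, 11:14] = 1.2  # 9 warm pixels around ...
        delta[10, 12] = 2.0  # ... a unique local peak
        delta[11, 13] = 0.0  # drop one: exactly 8 above threshold
        det = tf.detect_human(fg_from(delta), threshold_c=1.0, N_H=8)
        assert det.marked_count == 8 and det.detected

    def test_seven_marked_pixels_is_not_detected(self):
        delta = np.zeros((24, 32))
        delta[9:12, 11:14] = 1.2
        delta[10, 12] = 2.0
        delta[11, 12:14] = 0.0  # exactly 7 above threshold
        det = tf.detect_human(fg_from(delta), threshold_c=1.0, N_H=8)
        assert det.marked_count == 7 and not det.detected

    def test_below_threshold_never_detected(self):
        delta = np.full((24, 32), 0.9)
        assert not tf.detect_human(fg_from(delta), threshold_c=1.0).detected

    def test_peak_inside_marked_area(self):
        fg = blob_foreground(value=3.0)
        det = tf.detect_human(fg)
        assert det.detected and det.marked_mask[det.peak]

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1),
           t1=st.floats(0.5, 2.0), t2=st.floats(0.5, 2.0))
    def test_monotone_in_threshold(self, seed, t1, t2):
        lo, hi = sorted((t1, t2))
        fg = random_fg(seed)
        assert (tf.detect_human(fg, threshold_c=hi).marked_count
                <= tf.detect_human(fg, threshold_c=lo).marked_count)

    def test_global_count_mode_at_least_largest_area(self):
        fg = random_fg(3)
        per_area = tf.detect_human(fg, count_mode="largest_area").marked_count
        global_ = tf.detect_human(fg, count_mode="global").marked_count
        assert global_ >= per_area


class TestRefineBarycenter:
    def test_symmetric_blob_converges_to_center(self):
        fg = blob_foreground(center=(12, 16), radius=2, value=5.0)
        b = tf.refine_barycenter(fg, start=(12, 16))
        assert b.converged and b.iterations == 1
        assert b.coords == pytest.approx((12.0, 16.0), abs=1e-9)
        # off-center start still lands on the geometric center
        b2 = tf.refine_barycenter(fg, start=(11, 15))
        assert b2.converged and b2.coords == pytest.approx((12.0, 16.0), abs=1e-9)

    def test_two_pixel_weighted_center(self):
        delta = np.zeros((24, 32))
        delta[10, 10] = 1.0
        delta[10, 11] = 3.0
        b = tf.refine_barycenter(fg_from(delta), start=(10, 10), tol=1e-6, max_iter=50)
        assert b.coords[1] == pytest.approx(10.75)  # 3/4 toward the heavier pixel
        assert b.coords[0] == pytest.approx(10.0)

    def test_matches_global_centroid_oracle_when_blob_fits(self, rng):
        # blob confined to a 5x5 box: iterated refinement = plain weighted
        # centroid over the support
        delta = np.zeros((24, 32))
        block = rng.uniform(1.0, 5.0, (4, 4))
        delta[8:12, 14:18] = block
        rr, cc = np.mgrid[8:12, 14:18]
        oracle = ((block * rr).sum() / block.sum(), (block * cc).sum() / block.sum())
        b = tf.refine_barycenter(fg_from(delta), start=(9, 15), tol=1e-9, max_iter=50)
        assert b.coords == pytest.approx(oracle, abs=1e-9)

    def test_no_mass_raises(self):
        with pytest.raises(ValueError, match="no mass"):
            tf.refine_barycenter(fg_from(np.zeros((24, 32))), start=(5, 5))

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_terminates_and_stays_in_mass_bounding_box(self, seed):
        fg = random_fg(seed, p_hot=0.2)
        if fg.delta.max() <= 0:
            return
        start = tuple(int(v) for v in np.unravel_index(np.argmax(fg.delta), (24, 32)))
        b = tf.refine_barycenter(fg, start=start)
        assert b.iterations <= 20
        support = np.argwhere(fg.delta > 0)
        rmin, cmin = support.min(axis=0)
        rmax, cmax = support.max(axis=0)
        assert rmin - 1e-9 <= b.coords[0] <= rmax + 1e-9
        assert cmin - 1e-9 <= b.coords[1] <= cmax + 1e-9


class TestTrack:
    def test_repeated_point_has_zero_motion(self):
        t = tf.Track()
        b = tf.Barycenter((5.0, 5.0), 1, True)
        tf.update_track(t, b)
        tf.update_track(t, b)
        assert t.moving_distance == [0.0, 0.0] and t.speed == [0.0, 0.0]

    def test_three_four_five_step(self):
        t = tf.Track()
        tf.update_track(t, tf.Barycenter((0.0, 0.0), 1, True), frame_rate_hz=15.0)
        tf.update_track(t, tf.Barycenter((3.0, 4.0), 1, True), frame_rate_hz=15.0)
        assert t.moving_distance[-1] == pytest.approx(5.0)
        assert t.speed[-1] == pytest.approx(75.0)

    def test_speed_equals_distance_times_rate(self):
        t = tf.Track()
        rng = np.random.default_rng(0)
        for _ in range(10):
            tf.update_track(t, tf.Barycenter(tuple(rng.uniform(0, 20, 2)), 1, True),
                            frame_rate_hz=15.0)
        assert np.allclose(np.array(t.speed), np.array(t.moving_distance) * 15.0)

    def test_simulated_walk_speed_recovered(self, clean_scene, clean_background):
        from thermofall import pipeline
        from thermofall.segmentation import split_targets

        rng = np.random.default_rng(8)
        script = tf.make_script("walking", clean_scene, rng)
        true_step = np.linalg.norm(np.diff(script.centers, axis=0), axis=1).mean()
        rec, _ = tf.render_recording(clean_scene, [script])
        fg = pipeline.recording_foreground(rec, clean_background)
        track = tf.Track()
        for delta in fg:
            fgf = ForegroundFrame(delta=delta)
            det = tf.detect_human(fgf)
            assert det.detected
            tf.update_track(track, tf.refine_barycenter(fgf, det.peak),
                            frame_rate_hz=15.0)
        measured = np.mean(track.moving_distance[1:])
        assert measured == pytest.approx(true_step, rel=0.10)

    def test_association_gate(self):
        t = tf.Track()
        tf.update_track(t, tf.Barycenter((10.0, 10.0), 1, True))
        near = tf.Barycenter((11.0, 10.0), 1, True)
        far = tf.Barycenter((23.0, 30.0), 1, True)
        assert associate(t, [far, near]) is near
        assert associate(t, [far], max_jump_px=8.0) is None
        assert associate(tf.Track(), [far]) is far
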