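"""Trail rendering core: enhancement, fades, coloring, max projection."""

import numpy as np
import pytest

import wormviz as wv
from wormviz.colormaps import builtin, evaluate
from wormviz.trails import (
    TrailParams,
    colorize,
    enhance,
    fade_weight,
    project_window,
    render_still,
    render_video,
    window_frame_count,
)


def stack_of(frames, fps=1.0):
    return wv.FrameStack.from_frames(np.asarray(frames, dtype=float), fps=fps)


def flat_params(**kw):
    kw.setdefault("fade_fraction", 0.0)
    kw.setdefault("gain", 1.0)
    kw.setdefault("offset", 0.0)
    return TrailParams(**kw)


def brute_force_project(frames, weights):
    """Per-pixel scan, late to early, for the max weighted intensity."""
    n, rows, cols = frames.shape
    win = np.zeros((rows, cols), dtype=int)
    best = np.zeros((rows, cols))
    for r in range(rows):
        for c in range(cols):
            for i in range(n - 1, -1, -1):  # later frames win ties
                s = frames[i, r, c] * weights[i]
                if s > best[r, c]:
                    best[r, c] = s
                    win[r, c] = i
    return best, win


class TestEnhance:
    @pytest.mark.parametrize(
        "v,gain,offset,expected",
        [
            (0.3, 1.0, 0.0, 0.3),  # identity
            (0.05, 2.0, 0.2, 0.0),  # below noise floor
            (0.3, 2.0, 0.2, 0.4),
            (0.9, 5.0, 0.1, 1.0),  # clipped above
        ],
    )
    def test_gain_offset_arithmetic(self, v, gain, offset, expected):
        assert np.isclose(enhance(np.array([[v]]), gain, offset)[0, 0], expected)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            enhance(np.zeros((2, 2)), gain=0.0, offset=0.0)
        with pytest.raises(ValueError):
            enhance(np.zeros((2, 2)), gain=1.0, offset=1.0)


class TestFadeWeight:
    def test_no_fade_all_ones(self):
        assert all(fade_weight(i, 10, 0.0) == 1.0 for i in range(10))

    def test_linear_ramp_n10_fade03(self):
        w = [fade_weight(i, 10, 0.3) for i in range(10)]
        assert np.allclose(w[:3], [0.0, 1 / 3, 2 / 3])
        assert all(x == 1.0 for x in w[3:])

    @pytest.mark.parametrize("n,fade", [(1, 0.5), (2, 0.5), (10, 0.3), (60, 0.2)])
    def test_newest_frame_never_faded(self, n, fade):
        assert fade_weight(n - 1, n, fade) == 1.0

    def test_oldest_frame_invisible_when_ramp_exists(self):
        assert fade_weight(0, 10, 0.3) == 0.0

    def test_non_decreasing_over_ramp(self):
        w = [fade_weight(i, 20, 0.4) for i in range(20)]
        assert all(b >= a for a, b in zip(w, w[1:]))

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ValueError):
            fade_weight(10, 10, 0.2)


class TestColorize:
    def test_zero_weight_annihilates(self, rng):
        out = colorize(rng.random((4, 4)), 0.5, builtin("blue_red"), weight=0.0)
        assert np.all(out.pixels == 0.0)

    def test_early_time_is_blue(self):
        out = colorize(np.ones((2, 2)), 0.0, builtin("blue_red"), weight=1.0)
        assert np.allclose(out.pixels[0, 0], (0, 0, 1))

    def test_constant_white_scales_intensity(self):
        out = colorize(0.5 * np.ones((2, 2)), 0.3, builtin("constant_white"))
        assert np.allclose(out.pixels, 0.5)


class TestProjectWindow:
    def test_all_zero_window_is_black(self):
        s = stack_of(np.zeros((5, 6, 6)))
        tf = project_window(s, range(5), flat_params(colormap=builtin("blue_red")))
        assert np.all(tf.image.pixels == 0.0)

    def test_single_pixel_worm_colors_by_visit_time(self):
        n = 8
        frames = np.zeros((n, 4, n))
        for i in range(n):
            frames[i, 2, i] = 0.7
        s = stack_of(frames)
        cmap = builtin("blue_red")
        tf = project_window(s, range(n), flat_params(colormap=cmap))
        for i in range(n):
            expected = 0.7 * evaluate(cmap, i / (n - 1))
            assert np.allclose(tf.image.pixels[2, i], expected, atol=1e-12)
        lit = tf.image.pixels.sum(axis=2) > 0
        assert lit.sum() == n  # all other pixels black

    def test_tie_breaks_toward_later_frame(self):
        frames = np.zeros((3, 3, 3))
        frames[0, 1, 1] = 0.5
        frames[2, 1, 1] = 0.5  # same intensity, later frame
        s = stack_of(frames)
        cmap = builtin("blue_red")
        tf = project_window(s, range(3), flat_params(colormap=cmap))
        assert np.allclose(tf.image.pixels[1, 1], 0.5 * evaluate(cmap, 1.0))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        frames = rng.random((8, 16, 16))
        s = stack_of(frames)
        tf = project_window(s, range(8), flat_params(colormap=builtin("constant_white")))
        best, _ = brute_force_project(frames, np.ones(8))
        assert np.array_equal(tf.image.pixels[:, :, 0], best)
        assert np.array_equal(tf.image.pixels[:, :, 1], best)

    def test_oracle_with_fade_weights(self, rng):
        frames = rng.random((10, 12, 12))
        s = stack_of(frames)
        params = TrailParams(fade_fraction=0.3, gain=1.0, offset=0.0,
                             colormap=builtin("constant_white"))
        tf = project_window(s, range(10), params)
        weights = np.array([fade_weight(i, 10, 0.3) for i in range(10)])
        best, _ = brute_force_project(frames, weights)
        assert np.allclose(tf.image.pixels[:, :, 0], best, atol=1e-15)

    def test_associativity_over_partitions(self, rng):
        # max projection with fade 0 / white map distributes over any
        # partition of the range into contiguous chunks
        frames = rng.random((9, 8, 8))
        s = stack_of(frames)
        p = flat_params(colormap=builtin("constant_white"))
        whole = project_window(s, range(9), p).image.pixels
        for cut in (1, 4, 8):
            a = project_window(s, range(0, cut), p).image.pixels
            b = project_window(s, range(cut, 9), p).image.pixels
            assert np.array_equal(np.maximum(a, b), whole)

    def test_offset_monotonicity_never_unblackens(self, rng):
        frames = rng.random((6, 10, 10)) * 0.3
        s = stack_of(frames)
        black_lo = project_window(
            s, range(6), flat_params(gain=2.0, offset=0.1,
                                     colormap=builtin("constant_white"))
        ).image.pixels.sum(axis=2) == 0
        black_hi = project_window(
            s, range(6), flat_params(gain=2.0, offset=0.3,
                                     colormap=builtin("constant_white"))
        ).image.pixels.sum(axis=2) == 0
        assert np.all(~black_lo | black_hi)  # black stays black as offset rises

    def test_empty_range_rejected(self):
        s = stack_of(np.zeros((3, 4, 4)))
        with pytest.raises(ValueError, match="empty"):
            project_window(s, range(0), flat_params())


class TestRenderStill:
    def test_static_scene_gives_black_still(self, rng):
        f = rng.random((8, 8))
        sub = wv.average_subtract(stack_of(np.stack([f] * 10)))
        tf = render_still(sub, flat_params(colormap=builtin("blue_red")))
        assert np.all(tf.image.pixels == 0.0)

    def test_time_reversal_equals_reversed_colormap(self, rng):
        frames = rng.random((12, 10, 10))
        fwd = stack_of(frames)
        rev = stack_of(frames[::-1])
        blue_red = builtin("blue_red")
        red_blue = wv.from_control_points([(0.0, (1, 0, 0)), (1.0, (0, 0, 1))])
        a = render_still(fwd, flat_params(colormap=blue_red)).image.pixels
        b = render_still(rev, flat_params(colormap=red_blue)).image.pixels
        assert np.allclose(a, b, atol=1e-12)

    def test_early_blue_late_red_for_moving_point(self):
        frames = np.zeros((10, 3, 10))
        for i in range(10):
            frames[i, 1, i] = 1.0
        tf = render_still(stack_of(frames), flat_params(colormap=builtin("blue_red")))
        first, last = tf.image.pixels[1, 0], tf.image.pixels[1, 9]
        assert first[2] > first[0]  # blue dominant early
        assert last[0] > last[2]  # red dominant late


class TestRenderVideo:
    def test_window_frame_counts(self):
        assert window_frame_count(60.0, 1.0) == 60
        assert window_frame_count(20.0, 1.0) == 20
        assert window_frame_count(0.1, 1.0) == 1

    def test_trailing_window_extents(self):
        s = stack_of(np.zeros((100, 4, 4)))
        out = render_video(s, flat_params(window_s=60.0))
        assert len(out) == 100
        # truncated at the start, full 60 frames once t >= 59
        assert out[0].window == (0.0, 0.0)
        assert out[58].window == (0.0, 58.0)
        assert out[59].window == (0.0, 59.0)
        assert out[99].window == (40.0, 99.0)

    def test_stride_skips_outputs(self):
        s = stack_of(np.zeros((30, 4, 4)))
        out = render_video(s, flat_params(window_s=10.0, stride=5))
        assert len(out) == 6
        assert [tf.t_end for tf in out] == [0.0, 5.0, 10.0, 15.0, 20.0, 25.0]

    def test_nonoverlapping_windows_union_equals_still(self):
        # pixelwise max over stride-n windows == full still (white map, fade 0)
        n = 20
        frames = np.zeros((n, 4, n))
        rng = np.random.default_rng(3)
        for i in range(n):
            frames[i, rng.integers(0, 4), i] = rng.uniform(0.2, 1.0)
        s = stack_of(frames)
        p = flat_params(window_s=5.0, stride=5, colormap=builtin("constant_white"))
        # align windows to cover frames exactly: outputs at t=4,9,14,19
        out = [wv.project_window(s, range(k, k + 5), p) for k in range(0, n, 5)]
        union = np.maximum.reduce([tf.image.pixels for tf in out])
        still = render_still(s, flat_params(colormap=builtin("constant_white")))
        assert np.array_equal(union, still.image.pixels)

    def test_window_longer_than_recording_falls_back(self):
        s = stack_of(np.zeros((10, 4, 4)))
        with pytest.warns(UserWarning, match="single full-recording"):
            out = render_video(s, flat_params(window_s=20.0))
        assert len(out) == 1
        assert out[0].window == (0.0, 9.0)

    def test_fade_zero_matches_no_fade_reference(self, rng):
        # with fade 0 the fade machinery must be a bit-exact no-op: each
        # output equals a plain max projection of the enhanced window
        frames = rng.random((15, 8, 8)) * 0.5
        s = stack_of(frames)
        out = render_video(s, TrailParams(window_s=5.0, fade_fraction=0.0,
                                          gain=2.0, offset=0.05,
                                          colormap=builtin("constant_white")))
        for t, tf in enumerate(out):
            lo = max(0, t - 4)
            enh = enhance(frames[lo:t + 1], 2.0, 0.05)
            best, _ = brute_force_project(enh, np.ones(enh.shape[0]))
            assert np.array_equal(tf.image.pixels[:, :, 0], best)

    def test_newest_frame_dominates_current_position(self):
        # the pixel lit in the newest frame always carries u = 1 color
        n = 10
        frames = np.zeros((n, 3, n))
        for i in range(n):
            frames[i, 1, i] = 0.8
        s = stack_of(frames)
        cmap = builtin("blue_red")
        out = render_video(s, flat_params(window_s=5.0, colormap=cmap))
        for t in range(5, n):
            px = out[t].image.pixels[1, t]
            assert np.allclose(px, 0.8 * evaluate(cmap, 1.0), atol=1e-12)
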