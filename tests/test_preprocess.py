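"""Nightification, grayscale conversion and the optical-flow stream."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cagenet.preprocess import (
    NightReference, compute_flow_stream, compute_night_reference,
    encode_flow_frames, flow_cuboid, nightify_frame, to_grayscale,
)
from cagenet.video_io import FrameSequence


def _uniform_video(rgb, n=2, h=6, w=6):
    return FrameSequence(np.full((n, h, w, 3), rgb, dtype=np.uint8))


class TestNightReference:
    def test_uniform_frame_mean(self):
        frames = np.zeros((1, 4, 4, 3), dtype=np.uint8)
        frames[..., 0], frames[..., 1], frames[..., 2] = 10, 20, 30
        ref = compute_night_reference([FrameSequence(frames)])
        assert ref.mean_rgb == (10.0, 20.0, 30.0)

    def test_mean_across_two_videos(self):
        ref = compute_night_reference([_uniform_video((0, 0, 0)),
                                       _uniform_video((100, 100, 100))])
        assert ref.mean_rgb == (50.0, 50.0, 50.0)

    def test_half_and_half_frame(self):
        frames = np.zeros((1, 2, 2, 3), dtype=np.uint8)
        frames[0, :, 0, 0] = 0
        frames[0, :, 1, 0] = 200
        ref = compute_night_reference([FrameSequence(frames)])
        assert ref.mean_rgb[0] == 100.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_night_reference([])


class TestNightify:
    def test_identity_reference(self):
        rng = np.random.default_rng(0)
        frame = rng.integers(0, 256, (5, 5, 3), dtype=np.uint8)
        np.testing.assert_array_equal(
            nightify_frame(frame, NightReference((255, 255, 255))), frame)

    def test_zero_frame_stays_zero(self):
        frame = np.zeros((4, 4, 3), dtype=np.uint8)
        out = nightify_frame(frame, NightReference((60, 70, 80)))
        assert (out == 0).all()

    def test_saturated_pixel_maps_to_reference(self):
        frame = np.full((2, 2, 3), 255, dtype=np.uint8)
        out = nightify_frame(frame, NightReference((60, 70, 80)))
        assert tuple(out[0, 0]) == (60, 70, 80)

    def test_grayscale_input_rejected(self):
        with pytest.raises(ValueError):
            nightify_frame(np.zeros((4, 4, 1), dtype=np.uint8),
                           NightReference((1, 1, 1)))

    def test_idempotent_compatible(self):
        """nightify(nightify(x, ref), white) == nightify(x, ref)."""
        rng = np.random.default_rng(1)
        frame = rng.integers(0, 256, (6, 6, 3), dtype=np.uint8)
        ref = NightReference((90, 110, 140))
        once = nightify_frame(frame, ref)
        again = nightify_frame(once, NightReference((255, 255, 255)))
        np.testing.assert_array_equal(once, again)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 254), st.integers(1, 255), st.integers(0, 255))
    def test_monotone_per_channel(self, lo, step, refv):
        hi = min(lo + step, 255)
        ref = NightReference((refv, refv, refv))
        f_lo = np.full((1, 1, 3), lo, dtype=np.uint8)
        f_hi = np.full((1, 1, 3), hi, dtype=np.uint8)
        assert (nightify_frame(f_lo, ref) <= nightify_frame(f_hi, ref)).all()


class TestGrayscale:
    def test_pure_gray_preserved(self):
        frame = np.full((3, 3, 3), 123, dtype=np.uint8)
        out = to_grayscale(frame)
        assert out.shape == (3, 3, 1)
        assert (out == 123).all()

    def test_red_maps_to_76(self):
        frame = np.zeros((1, 1, 3), dtype=np.uint8)
        frame[..., 0] = 255
        assert to_grayscale(frame)[0, 0, 0] == 76

    def test_constant_frame_constant_output(self):
        frame = np.tile(np.array([10, 200, 30], dtype=np.uint8), (4, 4, 1))
        out = to_grayscale(frame)
        assert len(np.unique(out)) == 1


def _textured(h=64, w=64, seed=0):
    from scipy.ndimage import gaussian_filter
    base = np.random.default_rng(seed).random((h, w)).astype(np.float32)
    return gaussian_filter(base, 2) * 255


class TestFlow:
    def test_static_scene_has_near_zero_flow(self):
        frame = _textured()
        fields = compute_flow_stream(np.stack([frame, frame]))
        assert fields[0].magnitude.max() < 0.1

    def test_translation_recovered(self):
        """Interior median flow within +-0.5 px of a (+2, 0) px translation."""
        frame = _textured()
        shifted = np.roll(frame, 2, axis=1)   # content moves +2 px in x
        fields = compute_flow_stream(np.stack([frame, shifted]))
        interior = (slice(16, -16), slice(16, -16))
        assert abs(np.median(fields[0].dx[interior]) - 2.0) < 0.5
        assert abs(np.median(fields[0].dy[interior])) < 0.5

    def test_reversed_pair_negates_flow(self):
        frame = _textured(seed=2)
        shifted = np.roll(frame, 2, axis=1)
        fwd = compute_flow_stream(np.stack([frame, shifted]))[0]
        rev = compute_flow_stream(np.stack([shifted, frame]))[0]
        interior = (slice(16, -16), slice(16, -16))
        assert abs(np.median(fwd.dx[interior])
                   + np.median(rev.dx[interior])) < 0.5

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            compute_flow_stream(np.zeros((1, 8, 8)))

    def test_hsv_encoding_matches_rgb_geometry(self):
        frames = np.stack([_textured(32, 32), np.roll(_textured(32, 32), 1, 1)])
        enc = encode_flow_frames(compute_flow_stream(frames))
        assert enc.shape == (1, 32, 32, 3)
        assert 0.0 <= enc.min() and enc.max() <= 1.0

    def test_flow_cuboid_keeps_temporal_length(self):
        rng = np.random.default_rng(0)
        cub = rng.integers(0, 255, (8, 16, 16, 3), dtype=np.uint8)
        out = flow_cuboid(cub, radius=3)
        assert out.shape == (8, 16, 16, 3)
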