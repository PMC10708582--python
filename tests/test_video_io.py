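"""Frame geometry, temporal resampling, cuboid assembly and persistence."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.transform import resize as sk_resize

from cagenet.video_io import (
    Cuboid, DatasetSplit, FrameSequence, assign_label, extract_cuboids,
    read_cuboid_store, resize_and_crop, temporal_downsample, write_cuboid_store,
)


class TestResizeAndCrop:
    def test_default_geometry(self):
        frame = np.random.default_rng(0).integers(0, 256, (480, 640, 3),
                                                  dtype=np.uint8)
        out = resize_and_crop(frame)
        assert out.shape == (96, 128, 3)
        assert out.dtype == np.uint8

    def test_constant_frame_stays_constant(self):
        out = resize_and_crop(np.full((240, 320, 3), 77, dtype=np.uint8))
        assert (out == 77).all()

    def test_matches_two_step_reference(self):
        """Pixel-identical to an independent resize-then-center-crop oracle."""
        rng = np.random.default_rng(1)
        frame = (np.indices((256, 256)).sum(axis=0) % 2 * 255).astype(np.uint8)
        frame = np.repeat(frame[..., None], 3, axis=-1)
        ref = sk_resize(frame, (128, 128), order=1, anti_aliasing=False,
                        preserve_range=True)
        ref = np.rint(ref[16:112]).astype(np.uint8)
        np.testing.assert_array_equal(resize_and_crop(frame), ref)

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError):
            resize_and_crop(np.zeros((0, 0, 3), dtype=np.uint8))


class TestTemporalDownsample:
    @pytest.mark.parametrize("n,interval,expected", [(400, 5, 80), (4, 5, 1)])
    def test_kept_frame_count(self, n, interval, expected):
        seq = FrameSequence(np.zeros((n, 4, 4, 1), dtype=np.uint8))
        assert len(temporal_downsample(seq, interval)) == expected

    def test_interval_one_is_identity(self):
        frames = np.random.default_rng(0).integers(0, 255, (7, 4, 4, 3),
                                                   dtype=np.uint8)
        out = temporal_downsample(FrameSequence(frames), 1)
        np.testing.assert_array_equal(out.frames, frames)

    def test_bad_interval(self):
        with pytest.raises(ValueError):
            temporal_downsample(FrameSequence(np.zeros((3, 4, 4, 1),
                                                       dtype=np.uint8)), 0)


class TestAssignLabel:
    def test_unanimous(self):
        assert assign_label([6] * 8 ) == 6

    def test_majority(self):
        assert assign_label([7, 7, 7, 7, 7, 2, 2, 2]) == 7

    def test_tie_breaks_to_central_frame(self):
        labels = [0, 0, 0, 0, 1, 1, 1, 1]
        assert assign_label(labels) == labels[4]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assign_label([])


class TestExtractCuboids:
    def test_counts_and_normalization(self):
        frames = np.full((80, 8, 8, 3), 255, dtype=np.uint8)
        cubs = extract_cuboids(FrameSequence(frames, source_id="v1"),
                               np.zeros(80, dtype=int), T=8)
        assert len(cubs) == 10
        assert cubs[0].data.shape == (8, 8, 8, 3)
        assert cubs[0].data.max() == 1.0          # /255 at assembly
        assert cubs[3].origin == ("v1", 24)

    def test_short_sequence_gives_empty_list(self):
        frames = np.zeros((7, 4, 4, 1), dtype=np.uint8)
        assert extract_cuboids(FrameSequence(frames), np.zeros(7), T=8) == []

    def test_label_length_mismatch(self):
        with pytest.raises(ValueError):
            extract_cuboids(FrameSequence(np.zeros((8, 4, 4, 1), dtype=np.uint8)),
                            np.zeros(5), T=4)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 200), st.sampled_from([1, 5]),
           st.sampled_from([4, 8, 16]))
    def test_window_count_formula_vs_enumeration(self, n_frames, interval, t_len):
        """floor((floor((F-1)/i)+1)/T) windows, checked by brute enumeration."""
        kept = list(range(0, n_frames, interval))
        expected_windows = 0
        while (expected_windows + 1) * t_len <= len(kept):
            expected_windows += 1
        seq = temporal_downsample(
            FrameSequence(np.zeros((max(n_frames, 1), 2, 2, 1), dtype=np.uint8)
                          [:n_frames] if n_frames else
                          np.zeros((0, 2, 2, 1), dtype=np.uint8)), interval) \
            if n_frames else None
        if n_frames == 0:
            assert expected_windows == 0
            return
        cubs = extract_cuboids(seq, np.zeros(len(seq), dtype=int), T=t_len)
        assert len(cubs) == expected_windows
        if n_frames >= 1:
            assert len(seq) == (n_frames - 1) // interval + 1


class TestStoreRoundTrip:
    def _split(self, rng, n=12):
        split = DatasetSplit(num_classes=4)
        for i in range(n):
            c = Cuboid(rng.random((4, 6, 6, 3), dtype=np.float32), int(i % 4),
                       origin=(f"v{i % 3}", i * 4),
                       flow=rng.random((4, 6, 6, 3), dtype=np.float32))
            split.train.append(c)
        split.validation.append(Cuboid(rng.random((4, 6, 6, 3),
                                                  dtype=np.float32), 1,
                                       origin=("vv", 0),
                                       flow=rng.random((4, 6, 6, 3),
                                                       dtype=np.float32)))
        return split

    def test_bitwise_round_trip(self, tmp_path, rng):
        split = self._split(rng)
        path = tmp_path / "store.h5"
        write_cuboid_store(split, path)
        back = read_cuboid_store(path)
        assert len(back.train) == len(split.train)
        for a, b in zip(split.train, back.train):
            np.testing.assert_array_equal(a.data, b.data)
            np.testing.assert_array_equal(a.flow, b.flow)
            assert a.label == b.label and a.origin == b.origin
        np.testing.assert_array_equal(back.class_counts("train"),
                                      split.class_counts("train"))

    def test_empty_split_round_trips(self, tmp_path):
        path = tmp_path / "empty.h5"
        write_cuboid_store(DatasetSplit(), path)
        back = read_cuboid_store(path)
        assert back.train == [] and back.test == []

    def test_missing_file_raises_with_path(self, tmp_path):
        with pytest.raises(IOError, match="nowhere.h5"):
            read_cuboid_store(tmp_path / "nowhere.h5")

    def test_deterministic_store_bytes(self, tmp_path, rng):
        """Same cuboids serialize to byte-identical files."""
        split = self._split(np.random.default_rng(0))
        p1, p2 = tmp_path / "a.h5", tmp_path / "b.h5"
        write_cuboid_store(split, p1)
        write_cuboid_store(split, p2)
        assert p1.read_bytes() == p2.read_bytes()
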