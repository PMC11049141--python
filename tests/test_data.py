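"""Data pipeline: pairing, class filters, resizing, splitting, patchify."""
import numpy as np
import pytest
from PIL import Image

from pisnet.data import (DatasetSpec, SegmentationSample, load_samples,
                         normalize_image, patchify, resize_sample,
                         scale_factors, split_samples, to_batch)
from pisnet.synthetic import SyntheticSpec, generate_dataset, write_dataset


def _write_pair(root, stem, size=(20, 20), mask_suffix="_mask"):
    root.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(abs(hash(stem)) % 2 ** 31)
    img = (rng.random(size) * 255).astype(np.uint8)
    Image.fromarray(img).save(root / f"{stem}.png")
    mask = np.zeros(size, np.uint8)
    mask[2:8, 3:9] = 255
    Image.fromarray(mask).save(root / f"{stem}{mask_suffix}.png")


class TestLoading:
    def test_enumerates_complete_pairs(self, tmp_path):
        for stem in ("a", "b", "c"):
            _write_pair(tmp_path / "data", stem)
        samples = load_samples(DatasetSpec(root=tmp_path / "data"))
        assert len(samples) == 3
        assert all(set(np.unique(s.mask)) <= {0, 1} for s in samples)

    def test_class_filter_excludes_folder(self, tmp_path):
        _write_pair(tmp_path / "d" / "benign", "b1")
        _write_pair(tmp_path / "d" / "malignant", "m1")
        _write_pair(tmp_path / "d" / "normal", "n1")
        samples = load_samples(DatasetSpec(
            root=tmp_path / "d", class_filter=("benign", "malignant")))
        assert sorted(s.id for s in samples) == ["benign/b1", "malignant/m1"]

    def test_multiple_masks_merge_by_union(self, tmp_path):
        root = tmp_path / "multi"
        root.mkdir()
        Image.fromarray(np.zeros((10, 10), np.uint8)).save(root / "x.png")
        m1 = np.zeros((10, 10), np.uint8)
        m1[:3] = 255
        m2 = np.zeros((10, 10), np.uint8)
        m2[:, :3] = 255
        Image.fromarray(m1).save(root / "x_mask.png")
        Image.fromarray(m2).save(root / "x_mask_1.png")
        (sample,) = load_samples(DatasetSpec(root=root))
        np.testing.assert_array_equal(
            sample.mask, np.maximum(m1 > 0, m2 > 0).astype(np.uint8))

    def test_image_without_mask_skipped_with_warning(self, tmp_path):
        root = tmp_path / "missing"
        root.mkdir()
        Image.fromarray(np.zeros((8, 8), np.uint8)).save(root / "lone.png")
        _write_pair(root, "ok", size=(8, 8))
        with pytest.warns(UserWarning, match="lone"):
            samples = load_samples(DatasetSpec(root=root))
        assert [s.id for s in samples] == ["ok"]

    def test_missing_root_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_samples(DatasetSpec(root=tmp_path / "nope"))

    def test_synthetic_round_trip(self, tmp_path):
        """The generator writes exactly the layout the loader reads."""
        spec = SyntheticSpec(n_images=4, size=32, seed=3)
        originals = generate_dataset(spec)
        write_dataset(originals, tmp_path / "synth")
        loaded = load_samples(DatasetSpec(root=tmp_path / "synth"))
        assert len(loaded) == 4
        by_id = {s.id: s for s in loaded}
        for orig in originals:
            np.testing.assert_array_equal(by_id[orig.id].mask, orig.mask)


class TestResize:
    def _sample(self, h, w):
        rng = np.random.default_rng(h * 1000 + w)
        return SegmentationSample(
            image=rng.random((h, w)).astype(np.float32),
            mask=(rng.random((h, w)) > 0.6).astype(np.uint8),
            native_size=(h, w), id=f"{h}x{w}")

    def test_mask_stays_binary(self):
        out = resize_sample(self._sample(500, 500), 256)
        assert out.image.shape == (256, 256)
        assert set(np.unique(out.mask)) <= {0, 1}

    def test_anisotropic_scale_recorded(self):
        out = resize_sample(self._sample(400, 600), 256)
        assert out.native_size == (400, 600)
        sy, sx = scale_factors(out, 256)
        assert sy == pytest.approx(0.64) and sx == pytest.approx(256 / 600)

    def test_identity_on_target_size(self):
        s = self._sample(256, 256)
        out = resize_sample(s, 256)
        np.testing.assert_array_equal(out.image, s.image)
        np.testing.assert_array_equal(out.mask, s.mask)

    def test_resize_of_resize_is_identity(self):
        once = resize_sample(self._sample(300, 500), 256)
        twice = resize_sample(once, 256)
        np.testing.assert_array_equal(once.image, twice.image)


class TestSplit:
    def _samples(self, n):
        return [SegmentationSample(image=np.zeros((4, 4), np.float32),
                                   mask=np.zeros((4, 4), np.uint8),
                                   native_size=(4, 4), id=f"s{i}")
                for i in range(n)]

    @pytest.mark.parametrize("n,expected", [(10, (8, 2)), (647, (518, 129)),
                                            (5, (4, 1))])
    def test_split_sizes_round_half_up(self, n, expected):
        train, test = split_samples(self._samples(n), 0.8, seed=1)
        assert (len(train), len(test)) == expected

    def test_deterministic_and_exhaustive_partition(self):
        samples = self._samples(20)
        t1, v1 = split_samples(samples, 0.8, seed=9)
        t2, v2 = split_samples(samples, 0.8, seed=9)
        assert [s.id for s in t1] == [s.id for s in t2]
        assert [s.id for s in v1] == [s.id for s in v2]
        assert sorted(s.id for s in t1 + v1) == sorted(s.id for s in samples)
        assert not {s.id for s in t1} & {s.id for s in v1}

    def test_different_seed_changes_partition(self):
        samples = self._samples(40)
        t1, _ = split_samples(samples, 0.8, seed=1)
        t2, _ = split_samples(samples, 0.8, seed=2)
        assert [s.id for s in t1] != [s.id for s in t2]

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            split_samples(self._samples(1))


class TestPatchify:
    def _tile(self, h=1000, w=1000):
        rng = np.random.default_rng(h + w)
        return SegmentationSample(
            image=rng.random((h, w)).astype(np.float32),
            mask=(rng.random((h, w)) > 0.8).astype(np.uint8),
            native_size=(h, w), id="tile")

    def test_grid_count_1000px(self):
        patches = patchify(self._tile(), 256, 128)
        assert len(patches) == 36  # (floor(744/128)+1)^2 = 6^2

    def test_exact_fit_single_patch(self):
        patches = patchify(self._tile(256, 256), 256, 128)
        assert len(patches) == 1

    def test_patch_masks_equal_crops(self):
        tile = self._tile(512, 512)
        for p in patchify(tile, 256, 128):
            r, c = map(int, p.id.split("@")[1].split("+"))
            np.testing.assert_array_equal(
                p.mask, tile.mask[r:r + 256, c:c + 256])
            np.testing.assert_array_equal(
                p.image, tile.image[r:r + 256, c:c + 256])

    def test_window_larger_than_tile_rejected(self):
        with pytest.raises(ValueError):
            patchify(self._tile(200, 200), 256, 128)


class TestBatching:
    def test_normalize_image_range(self, rng):
        img = rng.random((8, 8)).astype(np.float32) * 7 + 3
        out = normalize_image(img)
        assert out.min() == 0.0 and out.max() == 1.0
        np.testing.assert_array_equal(normalize_image(np.full((4, 4), 2.0)), 0)

    def test_to_batch_shapes_and_channel_handling(self, rng):
        gray = SegmentationSample(image=rng.random((16, 16)).astype(np.float32),
                                  mask=np.zeros((16, 16), np.uint8),
                                  native_size=(16, 16), id="g")
        x, y = to_batch([gray, gray], in_channels=1)
        assert x.shape == (2, 1, 16, 16) and y.shape == (2, 1, 16, 16)
        x3, _ = to_batch([gray], in_channels=3)
        assert x3.shape == (1, 3, 16, 16)
        np.testing.assert_array_equal(x3[0, 0], x3[0, 2])
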