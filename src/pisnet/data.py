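"""Paired image/mask loading, preprocessing and dataset splitting.

Datasets follow the breast-ultrasound layout: images under class folders
(or flat), each with one or more mask files named ``<stem>_mask*.png``.
Multiple masks for one image (multi-lesion cases) are merged by pixelwise
union.  Preprocessing resizes images bilinearly and masks by nearest
neighbour to a fixed training resolution (so masks stay binary), recording
the native size so the anisotropic distortion factor remains recoverable.
Large tiles (histology) are instead patchified on a uniform overlapping
grid.  Splitting is a seeded 8:2 partition.
"""
from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg", ".tif", ".tiff")


@dataclass
class SegmentationSample:
    image: np.ndarray            # (H, W) or (H, W, 3), float in [0, 1]
    mask: np.ndarray             # (H, W) uint8 in {0, 1}
    native_size: tuple           # (H, W) before any resizing
    id: str

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask sizes differ")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")


@dataclass(frozen=True)
class DatasetSpec:
    root: Path
    resize_target: int = 256
    split_ratio: float = 0.8
    seed: int = 0
    patch_window: int = 256
    patch_stride: int = 128
    class_filter: tuple = ()

    def __post_init__(self):
        if not (0.0 < self.split_ratio < 1.0):
            raise ValueError("split_ratio must be in (0, 1)")
        if self.patch_stride > self.patch_window:
            raise ValueError("patch_stride must be <= patch_window")


def _read_image(path):
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr.astype(np.float32) / 255.0


def _read_mask(path):
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return (arr > 127).astype(np.uint8)


def _is_mask(path):
    return "_mask" in path.stem


def load_samples(spec: DatasetSpec):
    """Collect image/mask pairs under spec.root.

    Masks are files whose stem is the image stem plus ``_mask`` (optionally
    ``_mask_1`` etc.); several masks merge by union.  With a class_filter,
    only images under the named class sub-folders are kept.  Images lacking
    any mask are skipped with a warning; unreadable files raise.
    """
    root = Path(spec.root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    samples = []
    for path in sorted(root.rglob("*")):
        if path.suffix.lower() not in IMAGE_EXTENSIONS or _is_mask(path):
            continue
        if spec.class_filter:
            rel = path.relative_to(root).parts
            if not (rel and rel[0] in spec.class_filter):
                continue
        masks = sorted(p for p in path.parent.glob(f"{path.stem}_mask*")
                       if p.suffix.lower() in IMAGE_EXTENSIONS)
        if not masks:
            warnings.warn(f"image {path.name} has no mask; skipped")
            continue
        image = _read_image(path)
        mask = _read_mask(masks[0])
        for extra in masks[1:]:
            mask = np.maximum(mask, _read_mask(extra))
        samples.append(SegmentationSample(
            image=image, mask=mask, native_size=mask.shape,
            id=str(path.relative_to(root).with_suffix(""))))
    return samples


def load_manifest(csv_path):
    """Alternative loader: manifest CSV with id, image_path, mask_paths
    (';'-separated), class columns."""
    csv_path = Path(csv_path)
    samples = []
    with open(csv_path) as fh:
        for row in csv.DictReader(fh):
            image = _read_image(csv_path.parent / row["image_path"])
            mask = None
            for mp in row["mask_paths"].split(";"):
                m = _read_mask(csv_path.parent / mp.strip())
                mask = m if mask is None else np.maximum(mask, m)
            samples.append(SegmentationSample(
                image=image, mask=mask, native_size=mask.shape, id=row["id"]))
    return samples


def resize_sample(s: SegmentationSample, target: int):
    """Resize to (target, target): image bilinear, mask nearest neighbour.

    The native size is preserved in metadata, so the anisotropic scale pair
    (target/H_native, target/W_native) stays recoverable.
    """
    if target % 16:
        raise ValueError("target must be divisible by 16")
    if s.image.shape[:2] == (target, target):
        return s
    image = _sk_resize(s.image, (target, target), order=1, mode="edge",
                       anti_aliasing=False, preserve_range=True
                       ).astype(np.float32)
    mask = _sk_resize(s.mask, (target, target), order=0, mode="edge",
                      anti_aliasing=False, preserve_range=True
                      ).astype(np.uint8)
    return SegmentationSample(image=image, mask=mask,
                              native_size=s.native_size, id=s.id)


def scale_factors(s: SegmentationSample, target: int):
    """(row, col) resize factors relative to the native size."""
    return (target / s.native_size[0], target / s.native_size[1])


def split_samples(samples, ratio=0.8, seed=0):
    """Seeded disjoint-and-exhaustive train/test partition.

    Train size is round-half-up(ratio * n); the shuffle is a deterministic
    function of the seed only.
    """
    n = len(samples)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = int(np.floor(ratio * n + 0.5))
    order = np.random.default_rng(seed).permutation(n)
    train = [samples[i] for i in order[:n_train]]
    test = [samples[i] for i in order[n_train:]]
    return train, test


def patchify(s: SegmentationSample, window: int, stride: int):
    """Slice a large tile into a uniform grid of overlapping patches.

    Grid size is (floor((H - window)/stride) + 1) x (same for W); each
    patch carries the matching crop of the mask and an ``@row+col`` suffix
    on the parent id.
    """
    h, w = s.mask.shape
    if window > h or window > w:
        raise ValueError(f"window {window} exceeds image size {(h, w)}")
    out = []
    for i in range((h - window) // stride + 1):
        for j in range((w - window) // stride + 1):
            r, c = i * stride, j * stride
            out.append(SegmentationSample(
                image=s.image[r:r + window, c:c + window].copy(),
                mask=s.mask[r:r + window, c:c + window].copy(),
                native_size=(window, window),
                id=f"{s.id}@{r}+{c}"))
    return out


def normalize_image(image):
    """Per-image min-max normalisation to [0, 1]."""
    lo, hi = float(image.min()), float(image.max())
    if hi - lo < 1e-12:
        return np.zeros_like(image, dtype=np.float32)
    return ((image - lo) / (hi - lo)).astype(np.float32)


def to_batch(samples, in_channels=1):
    """Stack samples into (n, c, H, W) image and (n, 1, H, W) mask arrays."""
    images, masks = [], []
    for s in samples:
        img = s.image
        if in_channels == 1:
            if img.ndim == 3:
                img = img.mean(axis=2)
            images.append(img[None])
        else:
            if img.ndim == 2:
                img = np.stack([img] * 3, axis=2)
            images.append(img.transpose(2, 0, 1))
        masks.append(s.mask[None])
    return (np.stack(images).astype(np.float32),
            np.stack(masks).astype(np.float32))
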