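"""Seeded synthetic image/mask datasets emulating three imaging modalities.

Three presets mirror the statistical character of the benchmark modalities
without any download:

``ultrasound_blob``
    one or two smooth organic blobs (thresholded sums of anisotropic
    Gaussian bumps) on a low-contrast background with multiplicative
    speckle noise — low contrast, uneven grayscale.
``lesion_aspect``
    a single large smooth lesion on a non-square canvas whose aspect ratio
    is drawn from a wide range, so resizing to a square training resolution
    exercises pronounced anisotropic distortion.
``nuclei_field``
    a dense field of 30-200 small ellipses with jittered radii and
    orientations — many tiny objects of varying size.

Masks are the exact rasterised object supports.  Generation is a pure
function of the spec (identical spec, identical dataset, bit for bit).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

PRESETS = ("ultrasound_blob", "lesion_aspect", "nuclei_field")

#: nominal foreground-fraction band per preset (checked by the test-suite)
FOREGROUND_BANDS = {
    "ultrasound_blob": (0.02, 0.15),
    "lesion_aspect": (0.10, 0.40),
    "nuclei_field": (0.05, 0.20),
}


@dataclass(frozen=True)
class SyntheticSpec:
    n_images: int = 16
    size: int = 256
    modality_preset: str = "ultrasound_blob"
    noise_sigma: float = 0.15
    aspect_ratio_range: tuple = (1.3, 2.2)
    seed: int = 0

    def __post_init__(self):
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.modality_preset not in PRESETS:
            raise ValueError(f"invalid preset {self.modality_preset!r}; "
                             f"choose from {PRESETS}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _gauss_blob_mask(rng, h, w, n_bumps, scale, threshold=0.45):
    """Smooth organic region: threshold of summed anisotropic Gaussians."""
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    fieldmap = np.zeros((h, w))
    cy = rng.uniform(0.3 * h, 0.7 * h)
    cx = rng.uniform(0.3 * w, 0.7 * w)
    for _ in range(n_bumps):
        by = cy + rng.normal(0, 0.08 * h)
        bx = cx + rng.normal(0, 0.08 * w)
        sy = rng.uniform(0.75, 1.35) * scale * h
        sx = rng.uniform(0.75, 1.35) * scale * w
        theta = rng.uniform(0, np.pi)
        dy, dx = yy - by, xx - bx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        fieldmap += np.exp(-0.5 * ((u / sy) ** 2 + (v / sx) ** 2))
    m = fieldmap.max()
    return (fieldmap >= threshold * m).astype(np.uint8) if m > 0 else fieldmap.astype(np.uint8)


def _paint_ellipse(mask, cy, cx, ry, rx, theta):
    """Set mask pixels inside a rotated ellipse (bounding-box local work)."""
    h, w = mask.shape
    r = max(ry, rx)
    y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, h)
    x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, w)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    u = dy * np.cos(theta) + dx * np.sin(theta)
    v = -dy * np.sin(theta) + dx * np.cos(theta)
    inside = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
    mask[y0:y1, x0:x1] |= inside.astype(np.uint8)


def _speckle(rng, shape, sigma):
    """Multiplicative speckle factor, unit mean."""
    if sigma == 0:
        return np.ones(shape)
    return np.clip(rng.normal(1.0, sigma, size=shape), 0.0, 2.0)


def _ultrasound_blob(rng, size, noise_sigma):
    h = w = size
    n_lesions = int(rng.integers(1, 3))
    mask = np.zeros((h, w), dtype=np.uint8)
    for _ in range(n_lesions):
        # per-lesion extent shrinks with the count to keep total area in band
        mask |= _gauss_blob_mask(rng, h, w, n_bumps=3,
                                 scale=rng.uniform(0.065, 0.095) / np.sqrt(n_lesions))
    background = 0.45 + 0.1 * rng.standard_normal()
    image = np.full((h, w), background)
    image[mask == 1] = background - rng.uniform(0.2, 0.3)   # hypoechoic lesion
    image *= _speckle(rng, (h, w), noise_sigma)
    return np.clip(image, 0, 1).astype(np.float32), mask


def _lesion_aspect(rng, size, noise_sigma, aspect_range):
    ratio = rng.uniform(*aspect_range)
    if rng.random() < 0.5:
        h, w = size, int(round(size * ratio))
    else:
        h, w = int(round(size * ratio)), size
    mask = _gauss_blob_mask(rng, h, w, n_bumps=4,
                            scale=rng.uniform(0.14, 0.20), threshold=0.35)
    image = np.full((h, w), 0.65)
    image[mask == 1] = 0.3
    image += noise_sigma * 0.5 * rng.standard_normal((h, w))
    return np.clip(image, 0, 1).astype(np.float32), mask


def _nuclei_field(rng, size, noise_sigma):
    h = w = size
    mask = np.zeros((h, w), dtype=np.uint8)
    n_nuclei = int(rng.integers(30, 201))
    # radius co-varies with count so the covered fraction stays in band
    # while sparse fields get large nuclei and dense fields small ones
    r_base = 0.17 * size / np.sqrt(n_nuclei)
    for _ in range(n_nuclei):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        ry = r_base * rng.uniform(0.5, 1.8)
        rx = r_base * rng.uniform(0.5, 1.8)
        _paint_ellipse(mask, cy, cx, ry, rx, rng.uniform(0, np.pi))
    image = np.full((h, w), 0.75)
    image[mask == 1] = 0.35
    image += noise_sigma * 0.4 * rng.standard_normal((h, w))
    return np.clip(image, 0, 1).astype(np.float32), mask


def generate_dataset(spec: SyntheticSpec):
    """Generate ``spec.n_images`` image/mask samples for the preset."""
    from .data import SegmentationSample

    rng = np.random.default_rng(spec.seed)
    samples = []
    for i in range(spec.n_images):
        if spec.modality_preset == "ultrasound_blob":
            image, mask = _ultrasound_blob(rng, spec.size, spec.noise_sigma)
        elif spec.modality_preset == "lesion_aspect":
            image, mask = _lesion_aspect(rng, spec.size, spec.noise_sigma,
                                         spec.aspect_ratio_range)
        else:
            image, mask = _nuclei_field(rng, spec.size, spec.noise_sigma)
        samples.append(SegmentationSample(
            image=image, mask=mask, native_size=mask.shape,
            id=f"{spec.modality_preset}_{i:04d}"))
    return samples


def write_dataset(samples, out_dir):
    """Write samples in the image/mask pairing layout the loader reads."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for s in samples:
        img = Image.fromarray((s.image * 255).astype(np.uint8))
        img.save(out_dir / f"{s.id}.png")
        Image.fromarray((s.mask * 255).astype(np.uint8)).save(
            out_dir / f"{s.id}_mask.png")
    return out_dir
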