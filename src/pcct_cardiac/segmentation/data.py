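"""Synthetic left-ventricle segmentation samples.

Each sample emulates a short-axis slice of a reconstructed cardiac micro-CT
image: a soft-tissue thorax ellipse, a bright iodine-enhanced LV blood pool
of randomized size/position/eccentricity, a darker myocardial rim, mild blur
(reconstruction point spread) and additive noise.  ``input_kind='iodine'``
emulates a decomposed iodine map instead: near-zero background with the
blood pool carrying the concentration signal.  Images are normalized to zero
mean and unit standard deviation; the mask is the noise-free LV indicator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["SegmentationSample", "normalize_image", "make_lv_dataset",
           "split_dataset"]

# fractions mirroring the 186/38/22 split of 246 labeled volumes
DEFAULT_SPLIT = (186 / 246, 38 / 246, 22 / 246)


@dataclass
class SegmentationSample:
    image: np.ndarray  # normalized, zero mean / unit std
    mask: np.ndarray  # binary LV label
    subject_id: str = ""
    phase_label: str = "diastole"
    input_kind: str = "ct"

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(np.uint8)
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-std normalization."""
    image = np.asarray(image, dtype=float)
    std = image.std()
    if std == 0:
        return image - image.mean()
    return (image - image.mean()) / std


def _render_sample(rng, size, input_kind):
    yy, xx = np.mgrid[:size, :size].astype(float)
    cy = size * (0.5 + 0.12 * (rng.random() - 0.5))
    cx = size * (0.5 + 0.12 * (rng.random() - 0.5))
    r = size * rng.uniform(0.10, 0.22)
    ecc = rng.uniform(0.75, 1.3)
    theta = rng.uniform(0, np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    u = (yy - cy) * ct + (xx - cx) * st
    v = -(yy - cy) * st + (xx - cx) * ct
    d2 = (u / r) ** 2 + (v / (r * ecc)) ** 2
    lv = d2 <= 1.0
    myo = (d2 <= (1 + 0.35) ** 2) & ~lv

    body = ((yy - size / 2) / (0.46 * size)) ** 2 + \
        ((xx - size / 2) / (0.42 * size)) ** 2 <= 1.0

    if input_kind == "ct":
        img = np.full((size, size), -800.0)  # airish outside
        img[body] = rng.normal(40.0, 15.0)
        img[myo] = 90.0
        img[lv] = rng.uniform(320.0, 420.0)  # iodine-enhanced blood pool
        noise_sigma = 55.0
    elif input_kind == "iodine":
        img = np.zeros((size, size))
        img[body] = rng.uniform(0.1, 0.4)
        img[lv] = rng.uniform(6.0, 10.0)  # mg/mL
        noise_sigma = 0.8
    else:
        raise ValueError("input_kind must be 'ct' or 'iodine'")
    img = ndimage.gaussian_filter(img, rng.uniform(0.8, 1.4))
    img = img + noise_sigma * rng.standard_normal(img.shape)
    return normalize_image(img), lv


def make_lv_dataset(n: int, size: int = 64, input_kind: str = "ct",
                    seed: int = 0) -> list[SegmentationSample]:
    """Generate ``n`` synthetic LV slices; deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        img, lv = _render_sample(rng, size, input_kind)
        samples.append(SegmentationSample(
            image=img, mask=lv, subject_id=f"synt{i:04d}",
            phase_label="diastole" if i % 2 == 0 else "systole",
            input_kind=input_kind))
    return samples


def split_dataset(samples, fractions=DEFAULT_SPLIT, seed: int = 0):
    """Random shuffle then train/validation/test partition.

    Counts are the floor of n x fraction with the remainder assigned to the
    training set, reproducing a 186/38/22 partition of 246 samples under the
    default proportions.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    n = len(samples)
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_train = n - n_val - n_test
    idx_train = order[:n_train]
    idx_val = order[n_train:n_train + n_val]
    idx_test = order[n_train + n_val:]
    pick = lambda idx: [samples[i] for i in idx]
    return pick(idx_train), pick(idx_val), pick(idx_test)
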