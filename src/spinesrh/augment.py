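"""Stochastic view augmentation for self-supervised training.

The policy mirrors the standard augmentation pool for two-view representation
learning on histology patches: horizontal/vertical flips, sharpness jitter,
Gaussian blur, Gaussian noise, autocontrast, solarization, random erasing,
random affine, and random resized crop.  Every transform has an application
probability and parameter ranges; each sampled view draws all of its
randomness independently.  Transforms preserve the spatial shape and the
stated value range of the input patch.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = ["AugmentationPolicy", "apply_augmentations", "sample_views"]


@dataclass
class AugmentationPolicy:
    """Per-transform application probabilities and parameter ranges.

    Range-valued parameters are uniform sampling intervals.  ``noise_sigma``
    and ``solarize_threshold`` are fractions of the value-range span.
    """

    p_hflip: float = 0.5
    p_vflip: float = 0.5
    p_sharpness: float = 0.2
    sharpness_range: tuple = (0.5, 2.0)
    p_blur: float = 0.3
    blur_sigma: tuple = (0.3, 1.5)
    p_noise: float = 0.25
    noise_sigma: float = 0.02
    p_autocontrast: float = 0.05
    p_solarize: float = 0.05
    solarize_threshold: float = 0.75
    p_erasing: float = 0.10
    erase_scale: tuple = (0.02, 0.10)
    p_affine: float = 0.25
    affine_degrees: float = 15.0
    affine_translate: float = 0.08
    affine_scale: tuple = (0.9, 1.1)
    p_resized_crop: float = 0.5
    crop_scale: tuple = (0.7, 1.0)
    value_range: tuple = (0.0, 1.0)

    @classmethod
    def identity(cls):
        """All application probabilities zero: views equal the input."""
        kwargs = {f: 0.0 for f in (
            "p_hflip", "p_vflip", "p_sharpness", "p_blur", "p_noise",
            "p_autocontrast", "p_solarize", "p_erasing", "p_affine",
            "p_resized_crop")}
        return cls(**kwargs)

    def with_value_range(self, lo: float, hi: float) -> "AugmentationPolicy":
        return replace(self, value_range=(lo, hi))


def _resize(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resize of an (H, W, C) array to (out_h, out_w, C)."""
    h, w = img.shape[:2]
    rows = np.linspace(0, h - 1, out_h)
    cols = np.linspace(0, w - 1, out_w)
    grid = np.meshgrid(rows, cols, indexing="ij")
    out = np.empty((out_h, out_w, img.shape[2]))
    for c in range(img.shape[2]):
        out[..., c] = ndimage.map_coordinates(img[..., c], grid, order=1, mode="nearest")
    return out


def apply_augmentations(patch: np.ndarray, policy: AugmentationPolicy,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw and apply one stochastic augmented view of an (H, W, C) patch."""
    x = np.array(patch, dtype=np.float64, copy=True)
    h, w = x.shape[:2]
    lo, hi = policy.value_range
    span = hi - lo

    if rng.uniform() < policy.p_hflip:
        x = x[:, ::-1]
    if rng.uniform() < policy.p_vflip:
        x = x[::-1]

    if rng.uniform() < policy.p_resized_crop:
        scale = rng.uniform(*policy.crop_scale)
        ch = max(1, int(round(h * np.sqrt(scale))))
        cw = max(1, int(round(w * np.sqrt(scale))))
        r0 = rng.integers(0, h - ch + 1)
        c0 = rng.integers(0, w - cw + 1)
        x = _resize(x[r0:r0 + ch, c0:c0 + cw], h, w)

    if rng.uniform() < policy.p_affine:
        theta = np.deg2rad(rng.uniform(-policy.affine_degrees, policy.affine_degrees))
        s = rng.uniform(*policy.affine_scale)
        ty = rng.uniform(-policy.affine_translate, policy.affine_translate) * h
        tx = rng.uniform(-policy.affine_translate, policy.affine_translate) * w
        c, si = np.cos(theta) / s, np.sin(theta) / s
        mat = np.array([[c, -si], [si, c]])
        center = np.array([(h - 1) / 2, (w - 1) / 2])
        offset = center - mat @ center + np.array([ty, tx])
        for ch_i in range(x.shape[2]):
            x[..., ch_i] = ndimage.affine_transform(
                x[..., ch_i], mat, offset=offset, order=1, mode="nearest")

    if rng.uniform() < policy.p_sharpness:
        factor = rng.uniform(*policy.sharpness_range)
        blur = ndimage.gaussian_filter(x, sigma=(1.0, 1.0, 0))
        x = blur + factor * (x - blur)

    if rng.uniform() < policy.p_blur:
        sigma = rng.uniform(*policy.blur_sigma)
        x = ndimage.gaussian_filter(x, sigma=(sigma, sigma, 0))

    if rng.uniform() < policy.p_noise:
        x = x + rng.normal(0, policy.noise_sigma * span, x.shape)

    if rng.uniform() < policy.p_autocontrast:
        for ch_i in range(x.shape[2]):
            cmin, cmax = x[..., ch_i].min(), x[..., ch_i].max()
            if cmax > cmin:
                x[..., ch_i] = lo + (x[..., ch_i] - cmin) / (cmax - cmin) * span

    if rng.uniform() < policy.p_solarize:
        thresh = lo + policy.solarize_threshold * span
        mask = x > thresh
        x[mask] = hi - (x[mask] - lo)

    if rng.uniform() < policy.p_erasing:
        area = rng.uniform(*policy.erase_scale) * h * w
        eh = max(1, int(round(np.sqrt(area))))
        ew = max(1, int(round(area / eh)))
        eh, ew = min(eh, h), min(ew, w)
        r0 = rng.integers(0, h - eh + 1)
        c0 = rng.integers(0, w - ew + 1)
        x[r0:r0 + eh, c0:c0 + ew] = rng.uniform(lo, hi, (eh, ew, x.shape[2]))

    return np.clip(x, lo, hi)


def sample_views(patch: np.ndarray, policy: AugmentationPolicy,
                 rng: np.random.Generator):
    """Two independently drawn stochastic views of one patch."""
    return (apply_augmentations(patch, policy, rng),
            apply_augmentations(patch, policy, rng))
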