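"""Whole-slide semantic probability heatmaps and overlays.

The heatmap H is a height x width x 4 array; every pixel of a 300x300 patch
block carries that patch's class probability vector.  Non-diagnostic blocks
and unpopulated margins hold NaN sentinels, never fabricated probabilities.
Overlays blend a display rendering I of the slide with the class-colored
heatmap: V = (1 - alpha) * I + alpha * sum_c H[:, :, c] * C_map(c) in the
continuous mode; the default discrete mode paints each block with the color of
its argmax class at full saturation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import CLASSES, N_CLASSES

__all__ = [
    "DEFAULT_COLORMAP",
    "ProbabilityHeatmap",
    "build_heatmap",
    "render_overlay",
    "discrete_class_map",
    "save_overlay_png",
]

BACKGROUND_LABEL = -1

# Only the meningioma color is externally anchored (yellow); the others are
# package defaults chosen for contrast.
DEFAULT_COLORMAP = {
    "meningioma": (255, 220, 40),
    "schwannoma": (60, 200, 90),
    "ependymoma": (70, 120, 255),
    "metastasis": (230, 60, 60),
}


def _colormap_array(colormap: dict | None) -> np.ndarray:
    cm = colormap or DEFAULT_COLORMAP
    return np.array([cm[c] for c in CLASSES], dtype=np.float64)


@dataclass
class ProbabilityHeatmap:
    values: np.ndarray  # (H, W, 4) with NaN sentinel where unpopulated
    alpha: float = 0.4
    colormap: dict = field(default_factory=lambda: dict(DEFAULT_COLORMAP))
    slide_id: str = ""
    patch_size: int = 300

    @property
    def populated_mask(self) -> np.ndarray:
        return ~np.isnan(self.values[..., 0])


def build_heatmap(image_shape, patch_probs, coords, nondiag_mask=None,
                  patch_size: int = 300, slide_id: str = "") -> ProbabilityHeatmap:
    """Populate a heatmap from per-patch probabilities at tiling coordinates.

    ``coords`` are (row, col) top-left offsets from the same tiling geometry
    as preprocessing; ``nondiag_mask`` marks patches whose block keeps the
    sentinel.  Coordinates outside the image raise.
    """
    h, w = image_shape[:2]
    probs = np.atleast_2d(np.asarray(patch_probs, dtype=np.float64))
    coords = np.atleast_2d(np.asarray(coords, dtype=int))
    if probs.shape[0] != coords.shape[0]:
        raise ValueError("one coordinate pair required per patch")
    if probs.shape[1] != N_CLASSES:
        raise ValueError(f"expected {N_CLASSES}-class probabilities")
    if nondiag_mask is None:
        nondiag_mask = np.zeros(probs.shape[0], dtype=bool)
    values = np.full((h, w, N_CLASSES), np.nan)
    for (r, c), p, nd in zip(coords, probs, np.asarray(nondiag_mask, bool)):
        if r < 0 or c < 0 or r + patch_size > h or c + patch_size > w:
            raise ValueError(
                f"patch at ({r}, {c}) exceeds image bounds {h}x{w}")
        if nd:
            continue
        values[r:r + patch_size, c:c + patch_size] = p
    return ProbabilityHeatmap(values=values, slide_id=slide_id,
                              patch_size=patch_size)


def render_overlay(image: np.ndarray, heatmap: ProbabilityHeatmap,
                   alpha: float | None = None, colormap: dict | None = None,
                   mode: str = "discrete") -> np.ndarray:
    """Alpha-blend a display image with the class-colored heatmap.

    ``image`` is an (H, W, 3) RGB rendering (virtual H&E or grayscale stack);
    returns uint8 RGB.  Pixels under the sentinel keep the plain image.
    """
    alpha = heatmap.alpha if alpha is None else alpha
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    img = np.asarray(image, dtype=np.float64)
    if img.shape[:2] != heatmap.values.shape[:2]:
        raise ValueError("image and heatmap shapes differ")
    cmap = _colormap_array(colormap or heatmap.colormap)
    mask = heatmap.populated_mask
    if mode == "discrete":
        labels = discrete_class_map(heatmap)
        color = np.zeros_like(img)
        for c in range(N_CLASSES):
            color[labels == c] = cmap[c]
    elif mode == "continuous":
        vals = np.nan_to_num(heatmap.values, nan=0.0)
        color = vals @ cmap
    else:
        raise ValueError(f"unknown overlay mode {mode!r}")
    out = img.copy()
    out[mask] = (1.0 - alpha) * img[mask] + alpha * color[mask]
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def discrete_class_map(heatmap: ProbabilityHeatmap) -> np.ndarray:
    """Per-pixel argmax class index; sentinel pixels get the background label."""
    vals = heatmap.values
    labels = np.full(vals.shape[:2], BACKGROUND_LABEL, dtype=int)
    mask = heatmap.populated_mask
    labels[mask] = np.argmax(vals[mask], axis=-1)
    return labels


def save_overlay_png(path, overlay: np.ndarray, heatmap: ProbabilityHeatmap,
                     mode: str = "discrete") -> None:
    """Write the overlay PNG plus a JSON sidecar with rendering metadata."""
    import json
    import pathlib

    import imageio.v3 as iio

    path = pathlib.Path(path)
    iio.imwrite(path, overlay)
    sidecar = {
        "slide_id": heatmap.slide_id,
        "alpha": heatmap.alpha,
        "mode": mode,
        "patch_size": heatmap.patch_size,
        "colormap": {k: list(v) for k, v in heatmap.colormap.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
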