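"""Raw two-channel SRH images -> composite -> 300x300 patches -> slide QC.

The imaging convention: CH2 is the 2845 cm^-1 shift (lipid CH2 stretch), CH3
the 2930 cm^-1 shift (protein/DNA-rich regions).  The classifier input is the
three-channel composite (CH3-CH2, CH2, CH3).  Slides are tiled into
non-overlapping 300x300 windows; each patch receives a QC status (tumor /
normal / nondiagnostic) from external labels or a variance/detail heuristic,
and slide-level inclusion rules are applied before any inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import QC_NONDIAG, QC_NORMAL, QC_TUMOR

__all__ = [
    "RamanSlidePair",
    "CompositeImage",
    "PatchSet",
    "QCConfig",
    "compose_three_channel",
    "tile_patches",
    "assign_patch_qc",
    "apply_slide_inclusion_rules",
    "render_virtual_he",
    "read_slide_pair",
    "write_composite",
    "downsample_patches",
]

UINT16_MAX = 65535
PATCH = 300


@dataclass
class RamanSlidePair:
    """One slide's raw pair of 16-bit Raman-shift images."""

    ch2: np.ndarray
    ch3: np.ndarray
    slide_id: str = ""
    patient_id: str = ""

    def __post_init__(self):
        self.ch2 = np.asarray(self.ch2)
        self.ch3 = np.asarray(self.ch3)
        if self.ch2.shape != self.ch3.shape:
            raise ValueError(
                f"CH2 shape {self.ch2.shape} != CH3 shape {self.ch3.shape}"
            )


@dataclass
class CompositeImage:
    """Three-channel composite in order (CH3-CH2, CH2, CH3)."""

    pixels: np.ndarray  # (H, W, 3)
    slide_id: str = ""
    patient_id: str = ""

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class PatchSet:
    """Ordered non-overlapping 300x300x3 patches for one slide.

    ``grid_coords`` holds 0-based (row, col) top-left pixel offsets; patch i
    covers the half-open block [r, r+size) x [c, c+size).
    """

    patches: np.ndarray  # (n, size, size, 3)
    grid_coords: np.ndarray  # (n, 2) int
    slide_id: str = ""
    patient_id: str = ""
    size: int = PATCH
    qc_status: list = field(default_factory=list)

    def __len__(self):
        return len(self.patches)

    def qc_fractions(self):
        n = len(self)
        if n == 0:
            return {QC_TUMOR: 0.0, QC_NORMAL: 0.0, QC_NONDIAG: 0.0}
        counts = {s: self.qc_status.count(s) for s in (QC_TUMOR, QC_NORMAL, QC_NONDIAG)}
        return {s: c / n for s, c in counts.items()}


def compose_three_channel(pair: RamanSlidePair, negative_mode: str = "clip") -> CompositeImage:
    """Stack (CH3-CH2, CH2, CH3) pixelwise.

    Pixels where CH2 exceeds CH3 have no defined contrast in the difference
    channel; by default they are clipped to 0, preserving the 16-bit range
    (``negative_mode='signed'`` keeps the signed difference instead).
    """
    ch2 = pair.ch2.astype(np.float64)
    ch3 = pair.ch3.astype(np.float64)
    diff = ch3 - ch2
    if negative_mode == "clip":
        diff = np.clip(diff, 0.0, None)
    elif negative_mode != "signed":
        raise ValueError(f"unknown negative_mode {negative_mode!r}")
    pixels = np.stack([diff, ch2, ch3], axis=-1)
    return CompositeImage(pixels=pixels, slide_id=pair.slide_id, patient_id=pair.patient_id)


def tile_patches(image: CompositeImage, size: int = PATCH, stride: int | None = None) -> PatchSet:
    """Tile into non-overlapping windows (row-major); trailing margins are dropped."""
    if stride is None:
        stride = size
    if stride != size:
        raise ValueError("only non-overlapping tiling (stride == size) is supported")
    h, w = image.pixels.shape[:2]
    nr, nc = h // size, w // size
    if nr == 0 or nc == 0:
        warnings.warn(
            f"slide {image.slide_id or '<unnamed>'}: image {h}x{w} smaller than one "
            f"{size}x{size} window; empty patch set"
        )
        return PatchSet(
            patches=np.zeros((0, size, size, 3)),
            grid_coords=np.zeros((0, 2), dtype=int),
            slide_id=image.slide_id,
            patient_id=image.patient_id,
            size=size,
        )
    coords = [(r * size, c * size) for r in range(nr) for c in range(nc)]
    patches = np.stack(
        [image.pixels[r:r + size, c:c + size] for r, c in coords]
    )
    return PatchSet(
        patches=patches,
        grid_coords=np.asarray(coords, dtype=int),
        slide_id=image.slide_id,
        patient_id=image.patient_id,
        size=size,
    )


@dataclass
class QCConfig:
    """Thresholds for the heuristic patch QC stand-in.

    A patch whose CH3-channel variance falls below ``nondiag_var_threshold``
    is near-blank and flagged non-diagnostic.  Remaining patches are split by
    high-frequency detail energy (variance of the residual after a Gaussian
    blur of ``blur_sigma`` px): smooth tissue below ``tumor_detail_threshold``
    is called normal, structured tissue tumor.  Constants are co-designed with
    the phantom generator's noise scales; external labels always win.
    """

    nondiag_var_threshold: float = 1.0e5
    tumor_detail_threshold: float = 2.0e5
    blur_sigma: float = 6.0


def _detail_variance(channel: np.ndarray, sigma: float) -> float:
    smooth = ndimage.gaussian_filter(channel, sigma=sigma)
    return float(np.var(channel - smooth))


def assign_patch_qc(patchset: PatchSet, external_labels=None,
                    config: QCConfig | None = None) -> PatchSet:
    """Attach a QC status to every patch.

    ``external_labels`` (one status per patch, in order) takes precedence; the
    heuristic is a stand-in for a dedicated tissue-segmentation model.
    """
    if external_labels is not None:
        labels = list(external_labels)
        if len(labels) != len(patchset):
            raise ValueError(
                f"{len(labels)} external labels for {len(patchset)} patches"
            )
        bad = set(labels) - {QC_TUMOR, QC_NORMAL, QC_NONDIAG}
        if bad:
            raise ValueError(f"unknown QC labels: {sorted(bad)}")
        patchset.qc_status = labels
        return patchset
    config = config or QCConfig()
    labels = []
    for patch in patchset.patches:
        ch3 = patch[..., 2]
        if np.var(ch3) < config.nondiag_var_threshold:
            labels.append(QC_NONDIAG)
        elif _detail_variance(ch3, config.blur_sigma) < config.tumor_detail_threshold:
            labels.append(QC_NORMAL)
        else:
            labels.append(QC_TUMOR)
    patchset.qc_status = labels
    return patchset


def apply_slide_inclusion_rules(patchset: PatchSet) -> tuple[bool, str]:
    """Slide-level QC gate.

    A slide is included iff its non-diagnostic patch fraction is at most 0.90
    (inclusive), it contains at least one tumor patch, and its normal-tissue
    fraction is at most 0.50 (exclusion is strict ``> 0.50``).  Returns
    (include, reason); the reason names the first violated rule.
    """
    if not patchset.qc_status or len(patchset.qc_status) != len(patchset):
        raise ValueError("patch QC must be assigned before inclusion rules")
    frac = patchset.qc_fractions()
    if frac[QC_NONDIAG] > 0.90:
        return False, f"nondiagnostic fraction {frac[QC_NONDIAG]:.3f} > 0.90"
    if patchset.qc_status.count(QC_TUMOR) == 0:
        return False, "no diagnostic patches"
    if frac[QC_NORMAL] > 0.50:
        return False, f"normal fraction {frac[QC_NORMAL]:.3f} > 0.50"
    return True, "included"


# Display-only two-color lookup: the difference channel (protein/DNA contrast)
# drives a hematoxylin-like blue-purple, CH2 (lipid) an eosin-like pink.
_HEMATOX = np.array([0.35, 0.25, 0.65])
_EOSIN = np.array([0.95, 0.55, 0.65])
_BACKGROUND = np.array([1.0, 1.0, 1.0])


def render_virtual_he(image: CompositeImage) -> np.ndarray:
    """Deterministic virtual-H&E-like rendering (uint8 RGB, display only).

    A simple subtractive two-color lookup table: channel 0 (CH3-CH2) darkens
    toward a hematoxylin hue and CH2 toward an eosin hue, starting from a
    white background.  Monotone: more channel-0 signal never lessens the
    hematoxylin contribution.  Never used by the classifier.
    """
    px = image.pixels.astype(np.float64)
    lim = np.percentile(px[..., 2], 99.5) or 1.0
    h = np.clip(px[..., 0] / max(lim, 1.0), 0, 1)[..., None]
    e = np.clip(px[..., 1] / max(lim, 1.0), 0, 1)[..., None]
    rgb = _BACKGROUND * (1 - h) + _HEMATOX * h
    rgb = rgb * (1 - 0.6 * e) + _EOSIN * (0.6 * e)
    return (np.clip(rgb, 0, 1) * 255).astype(np.uint8)


def downsample_patches(patches: np.ndarray, out_size: int) -> np.ndarray:
    """Block-mean downsample (n, H, W, 3) patches to (n, out_size, out_size, 3).

    Used to bring 300x300 patches to the encoder's working resolution; the
    patch edge must be a multiple of ``out_size``.
    """
    n, h, w, c = patches.shape
    if h % out_size or w % out_size:
        raise ValueError(f"patch size {h}x{w} not divisible by {out_size}")
    fh, fw = h // out_size, w // out_size
    return patches.reshape(n, out_size, fh, out_size, fw, c).mean(axis=(2, 4))


# -- I/O ---------------------------------------------------------------------

def read_slide_pair(ch2_path, ch3_path, slide_id: str = "", patient_id: str = "") -> RamanSlidePair:
    import tifffile

    return RamanSlidePair(
        ch2=tifffile.imread(ch2_path),
        ch3=tifffile.imread(ch3_path),
        slide_id=slide_id,
        patient_id=patient_id,
    )


def write_composite(path, image: CompositeImage) -> None:
    import tifffile

    data = np.clip(image.pixels, 0, UINT16_MAX).astype(np.uint16)
    tifffile.imwrite(path, data)


def qc_report_row(patchset: PatchSet, include: bool, reason: str) -> dict:
    frac = patchset.qc_fractions()
    return {
        "slide_id": patchset.slide_id,
        "n_patches": len(patchset),
        "frac_nondiag": frac[QC_NONDIAG],
        "frac_normal": frac[QC_NORMAL],
        "decision": "include" if include else "exclude",
        "reason": reason,
    }


def qc_report(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(
        rows,
        columns=["slide_id", "n_patches", "frac_nondiag", "frac_normal", "decision", "reason"],
    )
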