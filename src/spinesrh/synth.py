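"""Seeded synthetic SRH phantom cohorts.

Generates two-channel 16-bit slide images whose four tumor classes carry
distinct texture motifs echoing named histologic features — circular
high-protein blobs (whorl/psammoma-like bodies) for meningioma, oriented
fascicle-like stripes for schwannoma, ring/rosette motifs for ependymoma, and
coarse pleomorphic speckle for metastasis — plus smooth lipid-rich "normal
tissue" regions and near-blank non-diagnostic background.  These are phantoms
for exercising the pipeline, not simulations of Raman physics.

Regions are allocated on the 300x300 patch grid so that every patch has an
unambiguous ground-truth QC status.  A global cohort seed expands to per-slide
seeds through the documented counter scheme
``default_rng([global_seed, slide_index])`` so any subset of slides is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import CLASSES, QC_NONDIAG, QC_NORMAL, QC_TUMOR
from .preprocess import PATCH, RamanSlidePair

__all__ = [
    "ClassTexture",
    "DEFAULT_TEXTURES",
    "PhantomSpec",
    "CohortSpec",
    "SlidePlan",
    "make_phantom_slide",
    "plan_cohort",
    "make_cohort",
    "ReliabilityProfile",
    "make_probability_fixture",
    "patch_texture_features",
    "write_cohort",
]

UINT16_MAX = 65535


@dataclass
class ClassTexture:
    """Motif parameters for one tissue texture (16-bit intensity units)."""

    motif: str  # blobs | stripes | rings | speckle | smooth | flat
    base_ch2: float
    base_ch3: float
    amp_ch2: float = 0.0
    amp_ch3: float = 0.0
    noise_sigma: float = 800.0
    # motif-specific knobs
    blob_count: int = 28
    blob_radius: tuple = (12.0, 22.0)
    stripe_theta_deg: float = 35.0
    stripe_theta_jitter: float = 6.0
    stripe_wavelength: tuple = (24.0, 40.0)
    ring_count: int = 14
    ring_radius: tuple = (26.0, 40.0)
    ring_thickness: float = 9.0
    speckle_cell: int = 20
    smooth_wavelength: float = 160.0


DEFAULT_TEXTURES = {
    "meningioma": ClassTexture("blobs", base_ch2=9000, base_ch3=16000,
                               amp_ch2=5000, amp_ch3=20000),
    "schwannoma": ClassTexture("stripes", base_ch2=10000, base_ch3=16000,
                               amp_ch2=3500, amp_ch3=12000),
    "ependymoma": ClassTexture("rings", base_ch2=9000, base_ch3=15000,
                               amp_ch2=4000, amp_ch3=18000),
    "metastasis": ClassTexture("speckle", base_ch2=8000, base_ch3=18000,
                               amp_ch2=6000, amp_ch3=26000, noise_sigma=1200),
    "normal": ClassTexture("smooth", base_ch2=17000, base_ch3=14000,
                           amp_ch2=3000, amp_ch3=2500, noise_sigma=200,
                           smooth_wavelength=160.0),
    "background": ClassTexture("flat", base_ch2=2500, base_ch3=2800,
                               noise_sigma=60.0),
}


@dataclass
class PhantomSpec:
    """Specification of one synthetic slide."""

    class_label: str
    image_height: int = 900
    image_width: int = 1200
    texture_params: dict = field(default_factory=dict)  # overrides by region name
    nondiag_fraction: float = 0.25
    normal_fraction: float = 0.15
    intensity_range: tuple = (0, UINT16_MAX)
    seed: int = 0

    def __post_init__(self):
        if self.class_label not in CLASSES:
            raise ValueError(f"unknown class {self.class_label!r}; expected one of {CLASSES}")
        if self.image_height < PATCH or self.image_width < PATCH:
            raise ValueError(
                f"image must be at least {PATCH}x{PATCH}, got "
                f"{self.image_height}x{self.image_width}"
            )
        for name, val in (("nondiag_fraction", self.nondiag_fraction),
                          ("normal_fraction", self.normal_fraction)):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        if self.nondiag_fraction + self.normal_fraction > 1.0 + 1e-12:
            raise ValueError(
                "nondiag_fraction + normal_fraction must not exceed 1 "
                f"({self.nondiag_fraction} + {self.normal_fraction})"
            )
        lo, hi = self.intensity_range
        if not (0 <= lo < hi <= UINT16_MAX):
            raise ValueError(f"intensity_range must be within [0, {UINT16_MAX}]")

    def texture(self, region: str) -> ClassTexture:
        base = DEFAULT_TEXTURES[region]
        override = self.texture_params.get(region)
        if override is None:
            return base
        if isinstance(override, ClassTexture):
            return override
        return replace(base, **override)


# -- motif renderers ---------------------------------------------------------

def _coords(n: int = PATCH):
    return np.meshgrid(np.arange(n), np.arange(n), indexing="ij")


def _motif_field(tex: ClassTexture, rng: np.random.Generator) -> np.ndarray:
    """Render the motif as a field in [0, 1] on a 300x300 block."""
    n = PATCH
    yy, xx = _coords(n)
    m = np.zeros((n, n))
    if tex.motif == "flat":
        return m
    if tex.motif == "smooth":
        theta = rng.uniform(0, np.pi)
        u = xx * np.cos(theta) + yy * np.sin(theta)
        phase = rng.uniform(0, 2 * np.pi)
        return 0.5 * (1 + np.sin(2 * np.pi * u / tex.smooth_wavelength + phase))
    if tex.motif == "blobs":
        for _ in range(tex.blob_count):
            cy, cx = rng.uniform(0, n, 2)
            r = rng.uniform(*tex.blob_radius)
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            np.maximum(m, (d2 <= r * r).astype(float), out=m)
        return m
    if tex.motif == "stripes":
        theta = np.deg2rad(tex.stripe_theta_deg + rng.normal(0, tex.stripe_theta_jitter))
        lam = rng.uniform(*tex.stripe_wavelength)
        phase = rng.uniform(0, 2 * np.pi)
        u = xx * np.cos(theta) + yy * np.sin(theta)
        return 0.5 * (1 + np.sin(2 * np.pi * u / lam + phase))
    if tex.motif == "rings":
        for _ in range(tex.ring_count):
            cy, cx = rng.uniform(0, n, 2)
            r = rng.uniform(*tex.ring_radius)
            d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
            ring = np.abs(d - r) <= tex.ring_thickness / 2
            lumen = d < r - tex.ring_thickness / 2
            np.maximum(m, ring.astype(float), out=m)
            np.maximum(m, 0.2 * lumen, out=m)
        return m
    if tex.motif == "speckle":
        cells = int(np.ceil(n / tex.speckle_cell))
        coarse = rng.uniform(0, 1, (cells, cells))
        up = np.kron(coarse, np.ones((tex.speckle_cell, tex.speckle_cell)))
        return up[:n, :n]
    raise ValueError(f"unknown motif {tex.motif!r}")


def _render_block(tex: ClassTexture, rng: np.random.Generator):
    m = _motif_field(tex, rng)
    ch2 = tex.base_ch2 + tex.amp_ch2 * m + rng.normal(0, tex.noise_sigma, m.shape)
    ch3 = tex.base_ch3 + tex.amp_ch3 * m + rng.normal(0, tex.noise_sigma, m.shape)
    return ch2, ch3


def _allocate_blocks(n_blocks: int, spec: PhantomSpec, rng: np.random.Generator):
    n_nd = int(round(spec.nondiag_fraction * n_blocks))
    n_norm = int(round(spec.normal_fraction * n_blocks))
    n_norm = min(n_norm, n_blocks - n_nd)
    labels = ([QC_NONDIAG] * n_nd + [QC_NORMAL] * n_norm
              + [QC_TUMOR] * (n_blocks - n_nd - n_norm))
    order = rng.permutation(n_blocks)
    return [labels[i] for i in order]


def make_phantom_slide(spec: PhantomSpec, slide_id: str = "", patient_id: str = "",
                       return_truth: bool = False):
    """Generate one two-channel 16-bit phantom slide.

    Regions are allocated per 300x300 block of the patch grid: round(nondiag
    fraction * blocks) blocks of near-blank background, round(normal fraction
    * blocks) of smooth normal-tissue texture, the remainder carrying the
    class motif.  Pixels outside the patch grid (trailing margins) are
    background.  With ``return_truth`` the block-level QC ground truth grid is
    returned alongside the slide.
    """
    rng = np.random.default_rng([spec.seed])
    h, w = spec.image_height, spec.image_width
    nr, nc = h // PATCH, w // PATCH
    block_labels = _allocate_blocks(nr * nc, spec, rng)
    truth = np.array(block_labels, dtype=object).reshape(nr, nc)

    bg = spec.texture("background")
    ch2 = bg.base_ch2 + rng.normal(0, bg.noise_sigma, (h, w))
    ch3 = bg.base_ch3 + rng.normal(0, bg.noise_sigma, (h, w))
    region_for = {
        QC_TUMOR: spec.class_label,
        QC_NORMAL: "normal",
        QC_NONDIAG: "background",
    }
    for bi in range(nr):
        for bj in range(nc):
            region = region_for[truth[bi, bj]]
            if region == "background":
                continue  # already background
            tex = spec.texture(region)
            b2, b3 = _render_block(tex, rng)
            sl = (slice(bi * PATCH, (bi + 1) * PATCH), slice(bj * PATCH, (bj + 1) * PATCH))
            ch2[sl] = b2
            ch3[sl] = b3
    lo, hi = spec.intensity_range
    pair = RamanSlidePair(
        ch2=np.clip(ch2, lo, hi).astype(np.uint16),
        ch3=np.clip(ch3, lo, hi).astype(np.uint16),
        slide_id=slide_id,
        patient_id=patient_id,
    )
    if return_truth:
        return pair, truth
    return pair


# -- cohorts -----------------------------------------------------------------

@dataclass
class CohortSpec:
    """Patient -> slides hierarchy for a synthetic cohort."""

    patients_per_class: dict = field(
        default_factory=lambda: {c: 8 for c in CLASSES}
    )
    slides_per_patient: tuple = (1, 2)  # inclusive range
    slides_per_class: dict | None = None  # optional exact per-class slide totals
    phantom_defaults: dict = field(default_factory=dict)  # PhantomSpec kwargs
    seed: int = 0

    def __post_init__(self):
        for cls, n in self.patients_per_class.items():
            if cls not in CLASSES:
                raise ValueError(f"unknown class {cls!r}")
            if n < 0:
                raise ValueError("patients_per_class must be >= 0")
        lo, hi = self.slides_per_patient
        if lo < 1 or hi < lo:
            raise ValueError("slides_per_patient must be a range with 1 <= lo <= hi")


@dataclass
class SlidePlan:
    spec: PhantomSpec
    slide_id: str
    patient_id: str
    class_label: str


def plan_cohort(cohort: CohortSpec):
    """Expand a cohort spec into a manifest and per-slide phantom plans.

    Per-slide seeds follow ``default_rng([cohort.seed, slide_index])`` with
    ``slide_index`` the row index in the manifest, so any single slide can be
    regenerated independently of the rest of the cohort.
    """
    rng = np.random.default_rng([cohort.seed, 0xC0])
    rows, plans = [], []
    slide_index = 0
    pidx = 0
    for cls in CLASSES:
        n_pat = cohort.patients_per_class.get(cls, 0)
        if n_pat == 0:
            continue
        if cohort.slides_per_class is not None:
            total = cohort.slides_per_class[cls]
            if total < n_pat:
                raise ValueError(f"{cls}: fewer slides ({total}) than patients ({n_pat})")
            base, extra = divmod(total, n_pat)
            slide_counts = [base + (1 if i < extra else 0) for i in range(n_pat)]
        else:
            lo, hi = cohort.slides_per_patient
            slide_counts = rng.integers(lo, hi + 1, n_pat).tolist()
        for k in range(n_pat):
            pidx += 1
            patient_id = f"P{pidx:04d}"
            for s in range(slide_counts[k]):
                slide_id = f"{patient_id}_S{s + 1:02d}"
                # per-slide counter seed, stored in the spec for reproducibility
                spec = PhantomSpec(class_label=cls,
                                   seed=_slide_seed(cohort.seed, slide_index),
                                   **cohort.phantom_defaults)
                plans.append(SlidePlan(spec=spec, slide_id=slide_id,
                                       patient_id=patient_id, class_label=cls))
                rows.append({"patient_id": patient_id, "slide_id": slide_id,
                             "class_label": cls})
                slide_index += 1
    manifest = pd.DataFrame(rows, columns=["patient_id", "slide_id", "class_label"])
    return manifest, plans


def _slide_seed(global_seed: int, slide_index: int) -> int:
    # documented counter scheme: stable, collision-free per cohort
    ss = np.random.SeedSequence([int(global_seed), int(slide_index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def make_cohort(cohort: CohortSpec, return_truth: bool = False):
    """Materialize a full cohort: slides plus (patient, slide, class) table.

    For large cohorts prefer ``plan_cohort`` and generate slides one at a time.
    """
    manifest, plans = plan_cohort(cohort)
    slides, truths = [], {}
    for plan in plans:
        out = make_phantom_slide(plan.spec, slide_id=plan.slide_id,
                                 patient_id=plan.patient_id, return_truth=return_truth)
        if return_truth:
            pair, truth = out
            truths[plan.slide_id] = truth
        else:
            pair = out
        slides.append(pair)
    if return_truth:
        return slides, manifest, truths
    return slides, manifest


# -- probability fixtures for calibration/DCA oracles ------------------------

@dataclass
class ReliabilityProfile:
    """Map from stated top-class confidence to true correctness rate."""

    confidences: np.ndarray
    accuracies: np.ndarray

    def __post_init__(self):
        self.confidences = np.atleast_1d(np.asarray(self.confidences, dtype=float))
        self.accuracies = np.atleast_1d(np.asarray(self.accuracies, dtype=float))
        if self.confidences.shape != self.accuracies.shape:
            raise ValueError("confidences and accuracies must align")
        for name, arr in (("confidences", self.confidences), ("accuracies", self.accuracies)):
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if np.any(self.confidences < 0.25):
            raise ValueError("top-class confidence below 1/4 is not representable")

    @classmethod
    def perfectly_calibrated(cls, levels=(0.4, 0.55, 0.7, 0.85, 0.97)):
        levels = np.asarray(levels, dtype=float)
        return cls(levels, levels)

    @classmethod
    def miscalibrated(cls, delta: float, levels=(0.4, 0.55, 0.7, 0.85)):
        levels = np.asarray(levels, dtype=float)
        return cls(levels, np.clip(levels - delta, 0, 1))

    @classmethod
    def certain_correct(cls):
        return cls(np.array([1.0]), np.array([1.0]))


def make_probability_fixture(n: int, profile: ReliabilityProfile, seed: int = 0):
    """Draw (true labels, 4-class probability vectors) following a profile.

    Each case picks a confidence level uniformly, a predicted class uniformly,
    and is correct with the profile's accuracy at that level.  The emitted
    vector puts the stated confidence on the predicted class and spreads the
    remainder evenly, so stated confidence matches the construction exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    k = len(profile.confidences)
    level = rng.integers(0, k, n)
    conf = profile.confidences[level]
    acc = profile.accuracies[level]
    pred = rng.integers(0, 4, n)
    correct = rng.uniform(0, 1, n) < acc
    offset = rng.integers(1, 4, n)  # wrong class, uniform over the other three
    y_true = np.where(correct, pred, (pred + offset) % 4)
    probs = np.full((n, 4), 0.0)
    rest = (1.0 - conf) / 3.0
    probs[:] = rest[:, None]
    probs[np.arange(n), pred] = conf
    return y_true.astype(int), probs


# -- handcrafted per-patch features (separability guarantee) -----------------

def patch_texture_features(patch: np.ndarray) -> np.ndarray:
    """Simple texture statistics of a composite patch (H, W, 3).

    Returns [log10 var CH3, mean CH3, mean CH2, orientation anisotropy,
    edge density, high-intensity fraction].  The anisotropy is the structure-
    tensor coherence of the CH3 channel; edge density is mean gradient
    magnitude over intensity spread.  These features linearly separate the
    default class motifs, guaranteeing signal for the learning stack.
    """
    ch2 = patch[..., 1].astype(np.float64)
    ch3 = patch[..., 2].astype(np.float64)
    var3 = np.var(ch3)
    gy, gx = np.gradient(ch3)
    jxx, jyy, jxy = (gx * gx).sum(), (gy * gy).sum(), (gx * gy).sum()
    denom = jxx + jyy + 1e-12
    anisotropy = np.sqrt((jxx - jyy) ** 2 + 4 * jxy ** 2) / denom
    grad_mag = np.sqrt(gx ** 2 + gy ** 2)
    edge_density = grad_mag.mean() / (np.std(ch3) + 1e-12)
    high_frac = float(np.mean(ch3 > ch3.mean() + ch3.std()))
    return np.array([
        np.log10(var3 + 1.0),
        ch3.mean() / UINT16_MAX,
        ch2.mean() / UINT16_MAX,
        anisotropy,
        edge_density,
        high_frac,
    ])


# -- I/O ---------------------------------------------------------------------

def write_cohort(out_dir, slides, manifest: pd.DataFrame, cohort: CohortSpec | None = None):
    """Write CH2/CH3 TIFFs, the label table CSV, and a YAML manifest."""
    import pathlib

    import tifffile
    import yaml

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pair in slides:
        tifffile.imwrite(out / f"{pair.slide_id}_ch2.tif", pair.ch2)
        tifffile.imwrite(out / f"{pair.slide_id}_ch3.tif", pair.ch3)
    manifest.to_csv(out / "labels.csv", index=False)
    meta = {
        "n_slides": int(len(manifest)),
        "n_patients": int(manifest["patient_id"].nunique()),
        "classes": list(CLASSES),
    }
    if cohort is not None:
        meta["seed"] = int(cohort.seed)
        meta["patients_per_class"] = {k: int(v) for k, v in cohort.patients_per_class.items()}
    with open(out / "cohort.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)
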