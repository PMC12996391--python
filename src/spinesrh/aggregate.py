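"""Patch -> slide -> patient probability aggregation with Platt calibration.

Patch probability vectors are averaged to slide-level vectors (mean of simplex
vectors, identical to sum-then-renormalize).  Slide-level scores are calibrated
by per-class Platt scaling (a sigmoid on the logit of the raw class score,
fitted one-vs-rest on the training cohort) and renormalized.  Patient-level
vectors are patch-count-weighted means of calibrated slide vectors.  The
per-slide confidence is the maximum calibrated probability; the patient
confidence C_patient = sum_s n_s C_s / sum_s n_s.  An empirical threshold
tau_conf = (C_correct + C_incorrect) / 2 (midpoint of patch-count-weighted
group mean confidences of correctly and incorrectly classified patients)
flags low-confidence predictions for re-sampling or repeat imaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import CLASSES, N_CLASSES

__all__ = [
    "SlideRecord",
    "PatientRecord",
    "PlattCalibrator",
    "ConfidenceThreshold",
    "aggregate_probabilities",
    "fit_platt",
    "apply_platt",
    "patient_confidence",
    "derive_threshold",
    "flag_low_confidence",
    "display_confidence",
    "build_slide_record",
    "build_patient_record",
]

_EPS = 1e-7


def _check_simplex(p: np.ndarray, tol: float = 1e-6):
    p = np.asarray(p, dtype=np.float64)
    if p.shape[-1] != N_CLASSES:
        raise ValueError(f"expected {N_CLASSES}-class probability vectors, got {p.shape}")
    if np.any(p < -tol) or np.any(np.abs(p.sum(axis=-1) - 1.0) > 1e-4):
        raise ValueError("probability vectors must lie on the simplex")
    return p


def aggregate_probabilities(patch_probs: np.ndarray) -> np.ndarray:
    """Mean of N >= 1 patch simplex vectors (= sum followed by renormalization)."""
    probs = np.atleast_2d(np.asarray(patch_probs, dtype=np.float64))
    if probs.shape[0] == 0:
        raise ValueError("no diagnostic patches: slide should have been excluded upstream")
    _check_simplex(probs)
    return probs.mean(axis=0)


@dataclass
class SlideRecord:
    slide_id: str
    patient_id: str
    n_patches: int  # diagnostic patch count n_s
    raw_probs: np.ndarray
    calibrated_probs: np.ndarray | None = None

    @property
    def confidence(self) -> float:
        """C_s: maximum calibrated class probability."""
        return float(np.max(self._active()))

    @property
    def prediction(self) -> int:
        p = self._active()
        top = np.flatnonzero(p == p.max())
        if len(top) > 1:
            warnings.warn(
                f"slide {self.slide_id}: argmax tie broken by canonical class order")
        return int(top[0])

    def _active(self) -> np.ndarray:
        return (self.calibrated_probs if self.calibrated_probs is not None
                else self.raw_probs)


@dataclass
class PatientRecord:
    patient_id: str
    slides: list
    truth: int | None = None
    tau_conf: float | None = None
    strata: dict = field(default_factory=dict)

    @property
    def probs(self) -> np.ndarray:
        """Patch-count-weighted mean of calibrated slide vectors."""
        weights = np.array([s.n_patches for s in self.slides], dtype=float)
        if weights.sum() <= 0:
            raise ValueError(f"patient {self.patient_id}: zero total patch count")
        vecs = np.stack([s._active() for s in self.slides])
        return (weights[:, None] * vecs).sum(axis=0) / weights.sum()

    @property
    def n_patches(self) -> int:
        return int(sum(s.n_patches for s in self.slides))

    @property
    def confidence(self) -> float:
        return patient_confidence(self.slides)

    @property
    def prediction(self) -> int:
        p = self.probs
        top = np.flatnonzero(p == p.max())
        if len(top) > 1:
            warnings.warn(
                f"patient {self.patient_id}: argmax tie broken by canonical class order")
        return int(top[0])

    @property
    def correct(self) -> bool:
        if self.truth is None:
            raise ValueError("truth label not set")
        return self.prediction == int(self.truth)

    @property
    def low_confidence(self) -> bool:
        if self.tau_conf is None:
            raise ValueError("confidence threshold not set")
        return flag_low_confidence(self, self.tau_conf)[0]


@dataclass
class PlattCalibrator:
    """Per-class sigmoid recalibration of raw class scores.

    For class c the calibrated score is sigmoid(a_c * logit(p_c) + b_c);
    the vector is then renormalized to the simplex.  Monotone in each raw
    class score, hence per-class rankings (and per-class AUROC) are preserved.
    """

    slopes: np.ndarray
    intercepts: np.ndarray

    def __post_init__(self):
        self.slopes = np.asarray(self.slopes, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        if self.slopes.shape != (N_CLASSES,) or self.intercepts.shape != (N_CLASSES,):
            raise ValueError("calibrator needs one (slope, intercept) pair per class")

    @classmethod
    def identity(cls):
        return cls(np.ones(N_CLASSES), np.zeros(N_CLASSES))

    def to_dict(self) -> dict:
        return {
            "classes": list(CLASSES),
            "slopes": self.slopes.tolist(),
            "intercepts": self.intercepts.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlattCalibrator":
        return cls(np.asarray(d["slopes"]), np.asarray(d["intercepts"]))

    def save(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "PlattCalibrator":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _EPS, 1 - _EPS)
    return np.log(p / (1 - p))


def fit_platt(raw_probs: np.ndarray, labels: np.ndarray) -> PlattCalibrator:
    """Fit per-class one-vs-rest sigmoids on raw class scores.

    ``raw_probs``: (n, 4) raw probability vectors; ``labels``: integer class
    indices.  Each class needs both positive and negative cases.
    """
    from sklearn.linear_model import LogisticRegression

    probs = _check_simplex(np.atleast_2d(raw_probs))
    y = np.asarray(labels, dtype=int)
    slopes, intercepts = np.empty(N_CLASSES), np.empty(N_CLASSES)
    for c in range(N_CLASSES):
        target = (y == c).astype(int)
        if len(np.unique(target)) < 2:
            raise ValueError(
                f"class {CLASSES[c]!r} has a single outcome label; cannot fit Platt")
        scores = _logit(probs[:, c])[:, None]
        lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=10_000)
        lr.fit(scores, target)
        slopes[c] = lr.coef_[0, 0]
        intercepts[c] = lr.intercept_[0]
    return PlattCalibrator(slopes, intercepts)


def apply_platt(calibrator: PlattCalibrator, probs: np.ndarray,
                renormalize: bool = True) -> np.ndarray:
    """Calibrate raw vectors; by default renormalize onto the simplex.

    The per-class sigmoid is strictly monotone in each raw class score
    (for a positive slope), so per-class rankings — and hence per-class
    AUROC — are preserved in the pre-renormalization scores
    (``renormalize=False``).  Accepts a single 4-vector or an (n, 4) batch;
    the output matches the input's dimensionality.
    """
    arr = np.asarray(probs, dtype=np.float64)
    single = arr.ndim == 1
    p2 = np.atleast_2d(_check_simplex(arr))
    z = calibrator.slopes * _logit(p2) + calibrator.intercepts
    cal = 1.0 / (1.0 + np.exp(-z))
    if renormalize:
        cal = cal / cal.sum(axis=1, keepdims=True)
    return cal[0] if single else cal


def patient_confidence(slides) -> float:
    """C_patient = sum_s n_s C_s / sum_s n_s (exact weighted mean)."""
    if not slides:
        raise ValueError("patient has no slides")
    n = np.array([s.n_patches for s in slides], dtype=float)
    if n.sum() <= 0:
        raise ValueError("total patch count is zero")
    c = np.array([s.confidence for s in slides])
    return float((n * c).sum() / n.sum())


@dataclass
class ConfidenceThreshold:
    tau_conf: float
    c_correct: float
    c_incorrect: float
    cohort_id: str = ""

    def __post_init__(self):
        expected = (self.c_correct + self.c_incorrect) / 2.0
        if abs(self.tau_conf - expected) > 1e-12:
            raise ValueError("tau_conf must equal (C_correct + C_incorrect) / 2")
        if not 0.0 <= self.tau_conf <= 1.0:
            raise ValueError("tau_conf must lie in [0, 1]")


def derive_threshold(patients, cohort_id: str = "") -> ConfidenceThreshold:
    """Empirical threshold tau = (C_correct + C_incorrect) / 2.

    Each group mean is patch-count-weighted across all slides of the group's
    patients.  Requires at least one correct and one incorrect patient;
    otherwise raises with advice to set a manual threshold.
    """
    groups = {True: [], False: []}
    for pat in patients:
        groups[bool(pat.correct)].extend(pat.slides)
    for ok, slides in groups.items():
        if not slides:
            label = "correctly" if ok else "incorrectly"
            raise ValueError(
                f"no {label} classified patients; derive_threshold needs both "
                "groups — set a manual threshold instead")
    c_corr = patient_confidence(groups[True])
    c_inc = patient_confidence(groups[False])
    return ConfidenceThreshold(tau_conf=(c_corr + c_inc) / 2.0,
                               c_correct=c_corr, c_incorrect=c_inc,
                               cohort_id=cohort_id)


def flag_low_confidence(record: PatientRecord, tau_conf: float):
    """Strict comparison C_patient < tau; returns (flag, routing message)."""
    flagged = record.confidence < tau_conf
    if flagged:
        msg = ("low-confidence prediction: recommend additional tissue sampling "
               "or repeat imaging")
    else:
        msg = "confidence above threshold"
    return bool(flagged), msg


def display_confidence(probs: np.ndarray) -> int:
    """Integer 0-100 display score: round(100 * max probability)."""
    p = _check_simplex(np.asarray(probs, dtype=np.float64))
    return int(round(100 * float(np.max(p))))


def build_slide_record(patch_probs: np.ndarray, slide_id: str, patient_id: str,
                       calibrator: PlattCalibrator | None = None) -> SlideRecord:
    probs = np.atleast_2d(np.asarray(patch_probs, dtype=np.float64))
    raw = aggregate_probabilities(probs)
    rec = SlideRecord(slide_id=slide_id, patient_id=patient_id,
                      n_patches=probs.shape[0], raw_probs=raw)
    if calibrator is not None:
        rec.calibrated_probs = np.asarray(apply_platt(calibrator, raw[None, :]))[0]
    return rec


def build_patient_record(patient_id: str, slides, truth=None,
                         tau_conf: float | None = None,
                         strata: dict | None = None) -> PatientRecord:
    truth_idx = CLASSES.index(truth) if isinstance(truth, str) else truth
    return PatientRecord(patient_id=patient_id, slides=list(slides),
                         truth=truth_idx, tau_conf=tau_conf,
                         strata=strata or {})
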