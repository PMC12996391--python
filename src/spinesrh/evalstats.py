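"""Diagnostic evaluation suite: per-class and macro metrics with clustered
bootstrap confidence intervals, calibration diagnostics, decision-curve
analysis, prevalence sensitivity, robustness analyses, and the patch-count
effect analysis.

Percentages are reported on the 0-100 scale; Brier scores and expected
calibration errors on the 0-1 scale.  Patients are the resampling clusters:
a bootstrap replicate draws patients with replacement and every slide of a
drawn patient travels with it.  Metrics with an empty denominator (for
example a class absent from a site) carry the undefined marker NaN and are
excluded from macro averages with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import CLASSES, N_CLASSES

__all__ = [
    "ConfusionSummary",
    "MetricsReport",
    "PrevalenceScenario",
    "confusion_counts",
    "per_class_metrics",
    "balanced_accuracy_from_rates",
    "macro_average",
    "auroc_ovr",
    "cluster_bootstrap_ci",
    "brier_scores",
    "expected_calibration_error",
    "decision_curve",
    "prevalence_adjusted_predictive_values",
    "one_random_slide_eval",
    "patch_count_analysis",
    "ablation_compare",
    "records_to_frame",
    "compute_metrics_report",
    "macro_balanced_accuracy",
]

PROB_COLS = [f"p_{c}" for c in CLASSES]


@dataclass
class ConfusionSummary:
    """One-vs-rest confusion counts for one class at one reporting level."""

    class_label: str
    tp: int
    fp: int
    tn: int
    fn: int
    level: str = "patient"

    @property
    def prevalence_count(self) -> int:
        return self.tp + self.fn


def confusion_counts(y_true, y_pred, level: str = "patient"):
    """Per-class one-vs-rest confusion summaries from integer label arrays."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    out = []
    for c, name in enumerate(CLASSES):
        pos, pred_pos = y_true == c, y_pred == c
        out.append(ConfusionSummary(
            class_label=name,
            tp=int(np.sum(pos & pred_pos)),
            fp=int(np.sum(~pos & pred_pos)),
            tn=int(np.sum(~pos & ~pred_pos)),
            fn=int(np.sum(pos & ~pred_pos)),
            level=level,
        ))
    return out


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); reporting NaN")
        return np.nan
    return 100.0 * num / den


def per_class_metrics(cs: ConfusionSummary) -> dict:
    """Sensitivity, specificity, PPV, NPV and balanced accuracy (percent)."""
    sens = _safe_ratio(cs.tp, cs.tp + cs.fn, f"{cs.class_label} sensitivity")
    spec = _safe_ratio(cs.tn, cs.tn + cs.fp, f"{cs.class_label} specificity")
    ppv = _safe_ratio(cs.tp, cs.tp + cs.fp, f"{cs.class_label} PPV")
    npv = _safe_ratio(cs.tn, cs.tn + cs.fn, f"{cs.class_label} NPV")
    return {
        "class": cs.class_label,
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
        "npv": npv,
        "balanced_accuracy": (sens + spec) / 2.0,
    }


def balanced_accuracy_from_rates(sensitivity: float, specificity: float) -> float:
    """(sensitivity + specificity) / 2, on whatever scale the inputs use."""
    return (sensitivity + specificity) / 2.0


def macro_average(values) -> float:
    """Arithmetic mean over classes; undefined markers excluded with warning."""
    vals = np.asarray(values, dtype=float)
    mask = np.isfinite(vals)
    if not mask.any():
        raise ValueError("all per-class values undefined; no macro average")
    if not mask.all():
        warnings.warn(f"excluding {int((~mask).sum())} undefined value(s) "
                      "from macro average")
    return float(vals[mask].mean())


def _binary_auroc(scores: np.ndarray, outcomes: np.ndarray) -> float:
    pos = outcomes.astype(bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUROC undefined for single-outcome class; reporting NaN")
        return np.nan
    ranks = stats.rankdata(scores)  # average ranks: ties get half credit
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auroc_ovr(scores: np.ndarray, labels: np.ndarray) -> dict:
    """One-vs-rest AUROC per class plus the macro average (percent scale)."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels, dtype=int)
    per_class = {}
    for c, name in enumerate(CLASSES):
        per_class[name] = 100.0 * _binary_auroc(scores[:, c], labels == c)
    vals = np.array(list(per_class.values()))
    per_class["macro"] = macro_average(vals)
    return per_class


def cluster_bootstrap_ci(metric_fn, frame: pd.DataFrame, cluster_col: str = "patient_id",
                         b: int = 1000, level: float = 0.95, seed: int = 0):
    """Percentile CI from cluster(-patient) resampling with replacement.

    ``metric_fn`` maps a DataFrame to a scalar; all rows of a sampled cluster
    travel together (a cluster drawn twice contributes its rows twice).
    Raises when the metric is undefined in more than half of the replicates.
    """
    clusters = frame[cluster_col].unique()
    n_clusters = len(clusters)
    if n_clusters < 2:
        raise ValueError("cluster bootstrap needs at least 2 clusters")
    rng = np.random.default_rng(seed)
    frame = frame.reset_index(drop=True)
    rows_of = frame.groupby(cluster_col, sort=False).indices
    row_lists = [np.asarray(rows_of[c]) for c in clusters]
    vals = np.empty(b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(b):
            draw = rng.integers(0, n_clusters, n_clusters)
            idx = np.concatenate([row_lists[j] for j in draw])
            rep = frame.iloc[idx].reset_index(drop=True)
            try:
                vals[i] = metric_fn(rep)
            except ValueError:
                vals[i] = np.nan
    ok = np.isfinite(vals)
    if ok.sum() < b / 2:
        raise ValueError("metric undefined in more than half of the bootstrap replicates")
    lo, hi = np.percentile(vals[ok], [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return float(lo), float(hi)


def brier_scores(probs: np.ndarray, labels: np.ndarray) -> dict:
    """Overall multiclass Brier score and per-class components (0-1 scale).

    Overall: mean over cases of sum_c (p_c - y_c)^2.  Per class c: mean of
    (p_c - y_c)^2.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    y = np.asarray(labels, dtype=int)
    onehot = np.eye(N_CLASSES)[y]
    sq = (probs - onehot) ** 2
    out = {"overall": float(sq.sum(axis=1).mean())}
    for c, name in enumerate(CLASSES):
        out[name] = float(sq[:, c].mean())
    return out


def expected_calibration_error(scores: np.ndarray, outcomes: np.ndarray,
                               bins: int = 10) -> float:
    """Binned |accuracy - confidence| gap: sum_b (n_b/n) |acc_b - conf_b|.

    Equal-width bins over [0, 1]; ``scores`` are stated probabilities for a
    binary outcome (one-vs-rest class membership or correctness).
    """
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    if np.any(scores < 0) or np.any(scores > 1):
        raise ValueError("scores must lie in [0, 1]")
    edges = np.linspace(0, 1, bins + 1)
    idx = np.clip(np.digitize(scores, edges[1:-1]), 0, bins - 1)
    n = len(scores)
    ece = 0.0
    for b in range(bins):
        mask = idx == b
        if not mask.any():
            continue
        ece += mask.sum() / n * abs(outcomes[mask].mean() - scores[mask].mean())
    return float(ece)


def decision_curve(scores: np.ndarray, outcomes: np.ndarray,
                   thresholds=None) -> pd.DataFrame:
    """Net benefit of acting on scores across threshold probabilities.

    NB(p_t) = TP/n - (FP/n) * p_t / (1 - p_t) where cases with score >= p_t
    are treated; includes treat-all and treat-none reference curves.
    """
    if thresholds is None:
        thresholds = np.arange(0.05, 0.95, 0.05)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds <= 0) or np.any(thresholds >= 1):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    n = len(y)
    prev = y.mean()
    rows = []
    for pt in thresholds:
        treated = scores >= pt
        tp = np.sum(treated & y) / n
        fp = np.sum(treated & ~y) / n
        odds = pt / (1 - pt)
        rows.append({
            "threshold": pt,
            "net_benefit": tp - fp * odds,
            "treat_all": prev - (1 - prev) * odds,
            "treat_none": 0.0,
        })
    return pd.DataFrame(rows)


@dataclass
class PrevalenceScenario:
    """A named per-class prevalence vector on the simplex."""

    name: str
    prevalence: np.ndarray

    def __post_init__(self):
        self.prevalence = np.asarray(self.prevalence, dtype=float)
        if self.prevalence.shape != (N_CLASSES,) or np.any(self.prevalence < 0) \
                or abs(self.prevalence.sum() - 1.0) > 1e-9:
            raise ValueError("prevalence must be a 4-class simplex vector")


def prevalence_adjusted_predictive_values(sens, spec,
                                          scenario: PrevalenceScenario) -> pd.DataFrame:
    """Bayes-adjusted PPV/NPV per class under a prevalence scenario.

    PPV = sens*pi / (sens*pi + (1-spec)(1-pi));
    NPV = spec(1-pi) / (spec(1-pi) + (1-sens)pi).  ``sens``/``spec`` are
    per-class values on the 0-1 scale.
    """
    sens = np.asarray(sens, dtype=float)
    spec = np.asarray(spec, dtype=float)
    if np.any((sens < 0) | (sens > 1)) or np.any((spec < 0) | (spec > 1)):
        raise ValueError("sens/spec must lie in [0, 1]")
    rows = []
    for c, name in enumerate(CLASSES):
        pi = scenario.prevalence[c]
        ppv_den = sens[c] * pi + (1 - spec[c]) * (1 - pi)
        npv_den = spec[c] * (1 - pi) + (1 - sens[c]) * pi
        # no positives can exist at pi = 0 (and no negatives at pi = 1):
        # the corresponding predictive value carries the undefined marker
        ppv = sens[c] * pi / ppv_den if (pi > 0 and ppv_den > 0) else np.nan
        npv = spec[c] * (1 - pi) / npv_den if (pi < 1 and npv_den > 0) else np.nan
        if np.isnan(ppv):
            warnings.warn(f"{name} PPV undefined at prevalence {pi}")
        rows.append({
            "class": name,
            "scenario": scenario.name,
            "prevalence": pi,
            "ppv": ppv,
            "npv": npv,
        })
    return pd.DataFrame(rows)


# -- reporting-level helpers -------------------------------------------------

def records_to_frame(patients, level: str = "patient") -> pd.DataFrame:
    """Flatten patient records into an evaluation DataFrame.

    Columns: patient_id, slide_id (slide level), y_true, y_pred, n_patches,
    p_<class> score columns, plus any strata keys.
    """
    rows = []
    for pat in patients:
        if level == "patient":
            row = {"patient_id": pat.patient_id, "y_true": int(pat.truth),
                   "y_pred": pat.prediction, "n_patches": pat.n_patches,
                   "confidence": pat.confidence}
            row.update(dict(zip(PROB_COLS, pat.probs)))
            row.update(pat.strata)
            rows.append(row)
        elif level == "slide":
            for s in pat.slides:
                row = {"patient_id": pat.patient_id, "slide_id": s.slide_id,
                       "y_true": int(pat.truth), "y_pred": s.prediction,
                       "n_patches": s.n_patches, "confidence": s.confidence}
                row.update(dict(zip(PROB_COLS, s._active())))
                row.update(pat.strata)
                rows.append(row)
        else:
            raise ValueError(f"unknown level {level!r}")
    return pd.DataFrame(rows)


def macro_balanced_accuracy(frame: pd.DataFrame) -> float:
    """Macro-average balanced accuracy (percent) of a y_true/y_pred frame."""
    summaries = confusion_counts(frame["y_true"], frame["y_pred"])
    return macro_average([per_class_metrics(cs)["balanced_accuracy"]
                          for cs in summaries])


@dataclass
class MetricsReport:
    level: str
    n: int
    per_class: pd.DataFrame
    macro: dict
    cis: dict = field(default_factory=dict)
    brier: dict = field(default_factory=dict)
    ece: dict = field(default_factory=dict)
    dca: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "n": self.n,
            "per_class": self.per_class.to_dict(orient="records"),
            "macro": self.macro,
            "cis": {k: list(v) for k, v in self.cis.items()},
            "brier": self.brier,
            "ece": self.ece,
        }


def compute_metrics_report(frame: pd.DataFrame, level: str = "patient",
                           b: int = 1000, seed: int = 0,
                           with_dca: bool = True,
                           ece_bins: int = 10) -> MetricsReport:
    """Full evaluation battery on one reporting level.

    ``frame`` needs y_true, y_pred, patient_id and the p_<class> score
    columns (calibrated).  Confidence intervals use the patient-clustered
    percentile bootstrap with ``b`` replicates.
    """
    summaries = confusion_counts(frame["y_true"], frame["y_pred"], level=level)
    per_class_rows = [per_class_metrics(cs) for cs in summaries]
    per_class = pd.DataFrame(per_class_rows)
    scores = frame[PROB_COLS].to_numpy()
    auroc = auroc_ovr(scores, frame["y_true"].to_numpy())
    per_class["auroc"] = [auroc[c] for c in CLASSES]
    macro = {m: macro_average(per_class[m]) for m in
             ("sensitivity", "specificity", "ppv", "npv", "balanced_accuracy")}
    macro["auroc"] = auroc["macro"]

    cis = {}
    if b > 0:
        cis["macro_balanced_accuracy"] = cluster_bootstrap_ci(
            macro_balanced_accuracy, frame, b=b, seed=seed)
        cis["macro_auroc"] = cluster_bootstrap_ci(
            lambda f: auroc_ovr(f[PROB_COLS].to_numpy(), f["y_true"].to_numpy())["macro"],
            frame, b=b, seed=seed + 1)

    y = frame["y_true"].to_numpy()
    brier = brier_scores(scores, y)
    ece = {name: expected_calibration_error(scores[:, c], y == c, bins=ece_bins)
           for c, name in enumerate(CLASSES)}
    dca = None
    if with_dca:
        dca = pd.concat([
            decision_curve(scores[:, c], y == c).assign(**{"class": name})
            for c, name in enumerate(CLASSES)
        ], ignore_index=True)
    return MetricsReport(level=level, n=len(frame), per_class=per_class,
                         macro=macro, cis=cis, brier=brier, ece=ece, dca=dca)


def stratified_reports(frame: pd.DataFrame, by: str, **kwargs) -> dict:
    """Per-stratum reports for an arbitrary grouping column (site, sex, ...).

    Stratum confusion counts recombine to the pooled counts exactly because
    strata partition the rows.
    """
    return {key: compute_metrics_report(g, **kwargs)
            for key, g in frame.groupby(by)}


# -- robustness analyses -----------------------------------------------------

def one_random_slide_eval(patients, repetitions: int = 100, seed: int = 0) -> dict:
    """Balanced accuracy when only one random slide per patient is available.

    Each repetition samples one slide per patient uniformly, uses that
    slide's prediction as the patient call, and computes the macro balanced
    accuracy; reports mean, standard deviation and a percentile interval.
    """
    rng = np.random.default_rng(seed)
    truths = np.array([int(p.truth) for p in patients])
    slide_preds = [np.array([s.prediction for s in p.slides]) for p in patients]
    vals = np.empty(repetitions)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(repetitions):
            preds = np.array([sp[rng.integers(0, len(sp))] for sp in slide_preds])
            summaries = confusion_counts(truths, preds)
            vals[r] = macro_average([per_class_metrics(cs)["balanced_accuracy"]
                                     for cs in summaries])
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)) if repetitions > 1 else 0.0,
            "ci": (float(lo), float(hi)), "values": vals}


def patch_count_analysis(patients, band_edges=(50, 100, 300)) -> dict:
    """Does a larger diagnostic patch count make patient calls more accurate?

    Reports group means of patch counts for correct vs incorrect patients,
    a two-sided Mann-Whitney U test, a univariate logistic regression of
    correctness on patch count (odds ratio, CI, and percent-per-patch =
    (OR - 1) * 100), and accuracy stratified by patch-count bands.
    """
    counts = np.array([p.n_patches for p in patients], dtype=float)
    correct = np.array([p.correct for p in patients], dtype=bool)
    out = {
        "mean_correct": float(counts[correct].mean()) if correct.any() else np.nan,
        "mean_incorrect": float(counts[~correct].mean()) if (~correct).any() else np.nan,
    }
    if correct.sum() >= 2 and (~correct).sum() >= 2:
        u = stats.mannwhitneyu(counts[correct], counts[~correct],
                               alternative="two-sided")
        out["mannwhitney_p"] = float(u.pvalue)
    else:
        warnings.warn("fewer than 2 patients in a correctness group; "
                      "skipping Mann-Whitney test")
        out["mannwhitney_p"] = np.nan
    # univariate logistic regression of correctness on patch count
    try:
        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(correct.astype(float), sm.add_constant(counts))
            fit = model.fit(disp=0)
        beta = fit.params[1]
        ci = fit.conf_int()[1]
        out["odds_ratio"] = float(np.exp(beta))
        out["or_ci"] = (float(np.exp(ci[0])), float(np.exp(ci[1])))
        out["percent_per_patch"] = odds_ratio_to_percent(out["odds_ratio"])
        out["logit_p"] = float(fit.pvalues[1])
    except Exception as err:  # perfect separation or degenerate outcomes
        warnings.warn(f"logistic regression unavailable ({err}); partial report")
        out.update(odds_ratio=np.nan, or_ci=(np.nan, np.nan),
                   percent_per_patch=np.nan, logit_p=np.nan)
    # accuracy by patch-count band
    edges = [0, *band_edges, np.inf]
    bands = {}
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (counts >= lo) & (counts < hi)
        label = f"{int(lo)}-{int(hi) - 1}" if np.isfinite(hi) else f"{int(lo)}+"
        bands[label] = float(correct[mask].mean()) * 100 if mask.any() else np.nan
    out["accuracy_by_band"] = bands
    return out


def odds_ratio_to_percent(odds_ratio: float) -> float:
    """Per-unit percent change in odds implied by an odds ratio."""
    return (odds_ratio - 1.0) * 100.0


def ablation_compare(transformer_frame: pd.DataFrame, linear_frame: pd.DataFrame,
                     b: int = 1000, seed: int = 0) -> dict:
    """Balanced-accuracy differences (percentage points): attention vs linear head.

    Both frames must cover the same patients (the paired cohort); the paired
    cluster bootstrap resamples patients and recomputes the difference.
    """
    t_ids = set(transformer_frame["patient_id"])
    l_ids = set(linear_frame["patient_id"])
    if t_ids != l_ids:
        raise ValueError("ablation requires identical patient cohorts in both arms")

    def per_class_ba(frame):
        return np.array([per_class_metrics(cs)["balanced_accuracy"]
                         for cs in confusion_counts(frame["y_true"], frame["y_pred"])])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ba_t, ba_l = per_class_ba(transformer_frame), per_class_ba(linear_frame)
    diff = ba_t - ba_l
    out = {
        "per_class_difference": dict(zip(CLASSES, diff)),
        "macro_difference": float(np.nanmean(diff)),
        "macro_transformer": float(np.nanmean(ba_t)),
        "macro_linear": float(np.nanmean(ba_l)),
    }
    if b > 0:
        merged = transformer_frame.merge(
            linear_frame[["patient_id", "y_pred"]].rename(columns={"y_pred": "y_pred_lin"}),
            on="patient_id")

        def paired_diff(f):
            ba1 = macro_balanced_accuracy(f)
            ba2 = macro_balanced_accuracy(f.rename(columns={"y_pred": "_", "y_pred_lin": "y_pred"}))
            return ba1 - ba2

        out["macro_difference_ci"] = cluster_bootstrap_ci(paired_diff, merged,
                                                          b=b, seed=seed)
    return out
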