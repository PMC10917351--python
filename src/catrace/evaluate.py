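"""Classifier evaluation metrics and motility/onset analyses.

Implements the study's per-time-lapse metrics — model efficiency
(reactive-labelled specific cells recovered), overall efficiency (all
specific cells recovered), and the false discovery rate — plus the
weighted performance metric

    pM = 1 / sqrt( w_eff (1 - eff_a)^2 + w_eff (1 - eff_b)^2
                   + w_FDR fdr_a^2 + w_FDR fdr_b^2 )

which scores an operating point by its weighted distance from the
perfect classifier over the two evaluation conditions (strong and weak
agonist), with default weights w_eff = 1, w_FDR = 5. ROC curves, per-FOV
summaries, instantaneous speeds, calcium-onset detection and
onset-aligned speed profiles complete the validation toolbox.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics

from .preprocess import BaselineFit
from .synthetic import CellTrack, GENOTYPE_SPECIFIC

logger = logging.getLogger("catrace")

FDR_VARIANTS = ("predicted", "labeled")


@dataclass(frozen=True)
class PerformanceWeights:
    """Relative importance of efficiency error versus FDR in pM."""

    w_eff: float = 1.0
    w_fdr: float = 5.0

    def __post_init__(self) -> None:
        if self.w_eff < 0 or self.w_fdr < 0 or (self.w_eff == 0 and self.w_fdr == 0):
            raise ValueError("weights must be nonnegative and not both zero")


def _check_aligned(*arrays) -> None:
    lengths = {len(a) for a in arrays}
    if len(lengths) > 1:
        raise ValueError(f"per-cell inputs not aligned: lengths {sorted(lengths)}")


def model_efficiency(calls, reactive_labels, genotypes) -> float:
    """Reactive-labelled specific cells called specific, over all
    reactive-labelled specific cells.

    Comparing predictions to the manual labels decouples the model's
    efficiency from the efficiency of the in vitro activation itself.
    Returns NaN when no specific cell carries a reactive label (the
    denominator is zero); counts stay available via confusion_counts.
    """
    calls = np.asarray(calls, dtype=bool)
    reactive = np.asarray(reactive_labels, dtype=bool)
    specific = np.asarray(genotypes, dtype=bool)
    _check_aligned(calls, reactive, specific)
    denom = int((specific & reactive).sum())
    if denom == 0:
        return float("nan")
    return float((specific & reactive & calls).sum() / denom)


def overall_efficiency(calls, genotypes) -> float:
    """Specific cells called specific / all specific cells (NaN if none)."""
    calls = np.asarray(calls, dtype=bool)
    specific = np.asarray(genotypes, dtype=bool)
    _check_aligned(calls, specific)
    denom = int(specific.sum())
    if denom == 0:
        return float("nan")
    return float((specific & calls).sum() / denom)


def false_discovery_rate(calls, reactive_labels, genotypes,
                         variant: str = "predicted") -> float:
    """Nonspecific cells called specific, over a selectable denominator.

    ``variant="predicted"`` (default) divides by the number of positive
    calls — the fraction of false discoveries among predictions.
    ``variant="labeled"`` divides by the number of reactive-labelled
    cells instead. Zero denominators give NaN.
    """
    if variant not in FDR_VARIANTS:
        raise ValueError(f"unknown FDR variant {variant!r}")
    calls = np.asarray(calls, dtype=bool)
    reactive = np.asarray(reactive_labels, dtype=bool)
    specific = np.asarray(genotypes, dtype=bool)
    _check_aligned(calls, reactive, specific)
    num = int((~specific & calls).sum())
    denom = int(calls.sum()) if variant == "predicted" else int(reactive.sum())
    if denom == 0:
        return float("nan")
    return float(num / denom)


def confusion_counts(calls, reactive_labels, genotypes) -> dict[str, int]:
    calls = np.asarray(calls, dtype=bool)
    reactive = np.asarray(reactive_labels, dtype=bool)
    specific = np.asarray(genotypes, dtype=bool)
    _check_aligned(calls, reactive, specific)
    return {
        "n_cells": int(calls.size),
        "n_specific": int(specific.sum()),
        "n_specific_reactive": int((specific & reactive).sum()),
        "n_reactive": int(reactive.sum()),
        "n_called": int(calls.sum()),
        "n_specific_called": int((specific & calls).sum()),
        "n_nonspecific_called": int((~specific & calls).sum()),
    }


def performance_metric(eff_a: float, eff_b: float, fdr_a: float, fdr_b: float,
                       weights: PerformanceWeights = PerformanceWeights(),
                       literal: bool = False) -> float:
    """Weighted inverse distance from the perfect classifier.

    ``literal=True`` reproduces the formula exactly as printed, where the
    first condition's FDR appears in both FDR terms; the default
    symmetric form uses each condition's own FDR. A perfect classifier
    (zero radicand) returns +infinity.
    """
    for name, v in (("eff_a", eff_a), ("eff_b", eff_b),
                    ("fdr_a", fdr_a), ("fdr_b", fdr_b)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    second_fdr = fdr_a if literal else fdr_b
    radicand = (weights.w_eff * (1.0 - eff_a) ** 2
                + weights.w_eff * (1.0 - eff_b) ** 2
                + weights.w_fdr * fdr_a ** 2
                + weights.w_fdr * second_fdr ** 2)
    if radicand <= 0.0:
        return math.inf
    return 1.0 / math.sqrt(radicand)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_curve(probabilities, binary_labels) -> RocCurve:
    """ROC by threshold sweep over the unique probabilities; trapezoid AUC.

    Ties contribute half a concordant pair, so the AUC equals the
    pairwise concordance probability.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(binary_labels, dtype=bool)
    _check_aligned(p, y)
    if y.all() or not y.any():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = skmetrics.roc_curve(y.astype(int), p)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thr, tpr=tpr, fpr=fpr, auc=auc)


# ---------------------------------------------------------------------------
# per-FOV summaries and aggregation
# ---------------------------------------------------------------------------

@dataclass
class FovMetrics:
    fov_id: str
    condition: str
    model_efficiency: float
    overall_efficiency: float
    fdr: float
    eff_times_one_minus_fdr: float
    counts: dict[str, int] = field(default_factory=dict)


@dataclass
class AggregateReport:
    """Condition means, pM, and the per-FOV table they derive from."""

    condition_efficiency: dict[str, float]
    condition_fdr: dict[str, float]
    pm: float
    weights: PerformanceWeights
    fdr_variant: str
    per_fov: list[FovMetrics]
    n_undefined_skipped: int = 0

    def to_dict(self) -> dict:
        return {
            "condition_efficiency": self.condition_efficiency,
            "condition_fdr": self.condition_fdr,
            "pm": None if math.isinf(self.pm) else self.pm,
            "pm_is_infinite": math.isinf(self.pm),
            "weights": {"w_eff": self.weights.w_eff, "w_fdr": self.weights.w_fdr},
            "fdr_variant": self.fdr_variant,
            "n_undefined_skipped": self.n_undefined_skipped,
        }


def per_fov_summary(calls, reactive_labels, genotypes, fov_ids, conditions,
                    weights: PerformanceWeights = PerformanceWeights(),
                    fdr_variant: str = "predicted",
                    known_conditions: tuple[str, ...] | None = None,
                    ) -> tuple[list[FovMetrics], AggregateReport]:
    """Metrics per field of view, equal-FOV condition means, and pM.

    FOVs with undefined metrics (zero denominators) are skipped in the
    condition means with a logged count; pM applies the performance
    metric to the means of the (up to) two conditions present, reusing a
    single condition for both terms when only one exists.
    """
    calls = np.asarray(calls, dtype=bool)
    reactive = np.asarray(reactive_labels, dtype=bool)
    specific = np.asarray(genotypes, dtype=bool)
    fov_ids = np.asarray(fov_ids, dtype=object)
    conditions = np.asarray(conditions, dtype=object)
    _check_aligned(calls, reactive, specific, fov_ids, conditions)
    if known_conditions is not None:
        unknown = set(conditions) - set(known_conditions)
        if unknown:
            raise ValueError(f"unknown condition tags: {sorted(unknown)}")

    per_fov: list[FovMetrics] = []
    for fov in pd.unique(fov_ids):
        m = fov_ids == fov
        cond = conditions[m][0]
        eff = model_efficiency(calls[m], reactive[m], specific[m])
        oeff = overall_efficiency(calls[m], specific[m])
        fdr = false_discovery_rate(calls[m], reactive[m], specific[m], fdr_variant)
        combo = eff * (1.0 - fdr) if not (math.isnan(eff) or math.isnan(fdr)) \
            else float("nan")
        per_fov.append(FovMetrics(
            fov_id=str(fov), condition=str(cond), model_efficiency=eff,
            overall_efficiency=oeff, fdr=fdr, eff_times_one_minus_fdr=combo,
            counts=confusion_counts(calls[m], reactive[m], specific[m]),
        ))

    cond_eff: dict[str, float] = {}
    cond_fdr: dict[str, float] = {}
    n_skipped = 0
    for cond in pd.unique(conditions):
        rows = [f for f in per_fov if f.condition == cond]
        effs = [f.model_efficiency for f in rows if not math.isnan(f.model_efficiency)]
        fdrs = [f.fdr for f in rows if not math.isnan(f.fdr)]
        n_skipped += sum(1 for f in rows
                         if math.isnan(f.model_efficiency) or math.isnan(f.fdr))
        cond_eff[str(cond)] = float(np.mean(effs)) if effs else float("nan")
        cond_fdr[str(cond)] = float(np.mean(fdrs)) if fdrs else float("nan")
    if n_skipped:
        logger.info("per_fov_summary: %d FOVs had undefined metrics", n_skipped)

    pm = aggregate_pm_from_means(cond_eff, cond_fdr, weights)
    report = AggregateReport(condition_efficiency=cond_eff, condition_fdr=cond_fdr,
                             pm=pm, weights=weights, fdr_variant=fdr_variant,
                             per_fov=per_fov, n_undefined_skipped=n_skipped)
    return per_fov, report


def aggregate_pm_from_means(cond_eff: dict[str, float], cond_fdr: dict[str, float],
                            weights: PerformanceWeights = PerformanceWeights()) -> float:
    """Eq.-style pM from per-condition means (NaN means treated as 0/0)."""
    conds = sorted(cond_eff)
    effs = [0.0 if math.isnan(cond_eff[c]) else cond_eff[c] for c in conds]
    fdrs = [0.0 if math.isnan(cond_fdr[c]) else cond_fdr[c] for c in conds]
    if len(conds) == 1:
        effs, fdrs = effs * 2, fdrs * 2
    elif len(conds) > 2:
        raise ValueError("pM is defined over at most two conditions")
    return performance_metric(effs[0], effs[1], fdrs[0], fdrs[1], weights)


def score_calls(calls, reactive_labels, genotypes, fov_ids, conditions,
                weights: PerformanceWeights = PerformanceWeights(),
                fdr_variant: str = "predicted") -> float:
    """pM of a set of binary calls (the objective of threshold fitting)."""
    _, report = per_fov_summary(calls, reactive_labels, genotypes, fov_ids,
                                conditions, weights, fdr_variant)
    return report.pm


# ---------------------------------------------------------------------------
# motility
# ---------------------------------------------------------------------------

def instantaneous_speed(track: CellTrack) -> np.ndarray:
    """Euclidean step length between consecutive tracked positions."""
    if len(track) < 2:
        return np.empty(0)
    return np.hypot(np.diff(track.x), np.diff(track.y))


def detect_onset(normalized_values: np.ndarray, fit: BaselineFit,
                 min_run_frames: int = 3) -> int | None:
    """First sustained crossing of the lo/hi midpoint, in fold-change units.

    The threshold is (mu_lo + mu_hi) / (2 mu_lo); the crossing must last
    at least ``min_run_frames`` consecutive frames. A degenerate
    (single-mode) fit yields None.
    """
    if fit.degenerate or fit.mu_hi is None:
        logger.info("detect_onset: degenerate baseline fit, no onset")
        return None
    values = np.asarray(normalized_values, dtype=float)
    threshold = (fit.mu_lo + fit.mu_hi) / (2.0 * fit.mu_lo)
    above = values > threshold
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= min_run_frames:
            return i - min_run_frames + 1
    return None


def align_speed_to_onset(tracks: list[CellTrack], onsets: list[int | None],
                         window: int) -> pd.DataFrame:
    """Mean speed at each frame offset relative to calcium onset.

    Offsets span [-window, +window]; each cell contributes its speeds at
    the offsets its track covers, and the per-offset counts reflect the
    truncation at movie edges. Cells without a detected onset are
    ignored; the result is empty if none have one.
    """
    sums = np.zeros(2 * window + 1)
    counts = np.zeros(2 * window + 1, dtype=int)
    for track, onset in zip(tracks, onsets):
        if onset is None:
            continue
        speeds = instantaneous_speed(track)
        if speeds.size == 0:
            continue
        # speed i is the step from frame i to i+1; assign it offset (i - onset)
        offs = track.frames[:-1] - onset
        keep = (offs >= -window) & (offs <= window)
        idx = offs[keep] + window
        np.add.at(sums, idx, speeds[keep])
        np.add.at(counts, idx, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    out = pd.DataFrame({"offset": np.arange(-window, window + 1),
                        "mean_speed": mean, "n_cells": counts})
    return out[out.n_cells > 0].reset_index(drop=True) if counts.any() \
        else out.iloc[0:0]


# ---------------------------------------------------------------------------
# dataset helpers
# ---------------------------------------------------------------------------

def truth_arrays(dataset, cell_ids) -> dict[str, np.ndarray]:
    """Aligned genotype/reactive/fov/condition arrays for given cells.

    'reactive' here is the human majority-vote label (the evaluation
    ground truth for model efficiency), not the simulator's hidden flag.
    """
    from .preprocess import manual_labels

    info: dict[str, tuple] = {}
    for fov in dataset.fovs:
        manual = manual_labels(fov)
        for cell, m in zip(fov.truth, manual):
            info[cell.cell_id] = (cell.genotype == GENOTYPE_SPECIFIC, bool(m),
                                  fov.fov_id, fov.condition)
    rows = [info[c] for c in cell_ids]
    return {
        "genotype": np.array([r[0] for r in rows], dtype=bool),
        "reactive": np.array([r[1] for r in rows], dtype=bool),
        "fov_ids": np.array([r[2] for r in rows], dtype=object),
        "conditions": np.array([r[3] for r in rows], dtype=object),
    }


def write_report(report: AggregateReport, path) -> None:
    """Aggregate metrics as JSON, per-FOV table as CSV next to it."""
    from pathlib import Path

    path = Path(path)
    payload = report.to_dict()
    payload["software"] = "catrace 0.1.0"
    path.write_text(json.dumps(payload, indent=2))
    rows = [{
        "fov_id": f.fov_id, "condition": f.condition,
        "model_efficiency": f.model_efficiency,
        "overall_efficiency": f.overall_efficiency, "fdr": f.fdr,
        "eff_times_one_minus_fdr": f.eff_times_one_minus_fdr, **f.counts,
    } for f in report.per_fov]
    pd.DataFrame(rows).to_csv(path.with_suffix(".per_fov.csv"), index=False)
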