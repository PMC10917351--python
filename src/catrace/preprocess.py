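"""Trace normalization, augmentation, vote aggregation and set assembly.

Inter-experiment variability of the Indo-1 ratio is removed by fitting,
per field of view, a two-component Gaussian mixture to the pooled
per-time-point ratio values; the lower component mean is the resting
calcium state [Ca]lo and every trace is divided by it (fold change over
resting). Training/evaluation sets are split by whole field of view,
class-balanced, and labelled by one of three ground-truth modes: the
human majority-vote label, the genotype, or their combination
(antigen-specific cells labelled reactive versus the rest).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

from .synthetic import (
    CONDITION_OVA,
    GENOTYPE_SPECIFIC,
    CalciumTrace,
    Dataset,
    FieldOfView,
)

logger = logging.getLogger("catrace")

GROUND_TRUTH_MODES = ("manual", "genotype", "combined")
CHANNEL_NAMES = ("ratio", "absdiff", "speed")

#: minimum pooled time points required for a mixture fit
MIN_POOLED_VALUES = 100
#: components closer than this relative separation trigger the fallback
DEGENERATE_SEPARATION = 0.05
#: a component weight below this triggers the fallback
DEGENERATE_WEIGHT = 0.01


@dataclass
class BaselineFit:
    """Two-Gaussian decomposition of a FOV's pooled ratio values.

    ``mu_lo`` is the resting-state mean used for fold-change
    normalization; ``mu_hi`` the elevated state. ``degenerate`` marks a
    single-mode fallback (``mu_hi`` undefined).
    """

    mu_lo: float
    sigma_lo: float
    weight_lo: float
    mu_hi: float | None
    sigma_hi: float | None
    weight_hi: float | None
    fov_id: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate:
            if self.mu_hi is None or self.mu_lo >= self.mu_hi:
                raise ValueError("mu_lo must be below mu_hi")
            if not (0 <= self.weight_lo <= 1 and 0 <= self.weight_hi <= 1):
                raise ValueError("weights must lie in [0, 1]")
            if self.sigma_lo <= 0 or self.sigma_hi <= 0:
                raise ValueError("sigmas must be positive")


def _distribution_mode(values: np.ndarray) -> float:
    """Mode of a 1-D sample via a fine histogram."""
    hist, edges = np.histogram(values, bins=min(256, max(16, values.size // 50)))
    k = int(np.argmax(hist))
    return float(0.5 * (edges[k] + edges[k + 1]))


def fit_baseline_gmm(values: np.ndarray, fov_id: str = "") -> BaselineFit:
    """Fit a two-component Gaussian mixture to pooled ratio values.

    Expectation-maximization with means initialized at the 25th and 90th
    percentiles, equal weights, tolerance 1e-6, up to 500 iterations.
    Components are returned ordered so ``mu_lo < mu_hi``. A degenerate
    fit (component means within 5% of each other, or a component weight
    below 0.01) falls back to a single-mode estimate: ``mu_lo`` is the
    distribution mode, ``mu_hi`` undefined, and the fit is flagged.
    """
    values = np.asarray(values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    if values.size < MIN_POOLED_VALUES:
        raise ValueError(
            f"need at least {MIN_POOLED_VALUES} pooled time points, got {values.size}"
        )
    X = values[:, None]
    means_init = np.array([[np.percentile(values, 25)], [np.percentile(values, 90)]])
    gmm = GaussianMixture(
        n_components=2, covariance_type="full", tol=1e-6, max_iter=500,
        means_init=means_init, weights_init=np.array([0.5, 0.5]),
        reg_covar=1e-9, random_state=0,
    )
    gmm.fit(X)
    means = gmm.means_.ravel()
    sigmas = np.sqrt(gmm.covariances_.ravel())
    weights = gmm.weights_.ravel()
    order = np.argsort(means)
    mu_lo, mu_hi = means[order]
    sigma_lo, sigma_hi = sigmas[order]
    w_lo, w_hi = weights[order]
    scale = max(abs(mu_lo), abs(mu_hi), 1e-12)
    separation = mu_hi - mu_lo
    # degenerate when the components nearly coincide, heavily overlap
    # (a unimodal sample split by EM), or one carries negligible weight
    if (separation / scale < DEGENERATE_SEPARATION
            or separation < 1.5 * max(sigma_lo, sigma_hi)
            or min(w_lo, w_hi) < DEGENERATE_WEIGHT):
        logger.info("baseline fit degenerate for %s; single-mode fallback", fov_id or "fov")
        return BaselineFit(
            mu_lo=_distribution_mode(values), sigma_lo=float(values.std()) or 1e-12,
            weight_lo=1.0, mu_hi=None, sigma_hi=None, weight_hi=None,
            fov_id=fov_id, degenerate=True,
        )
    return BaselineFit(
        mu_lo=float(mu_lo), sigma_lo=float(sigma_lo), weight_lo=float(w_lo),
        mu_hi=float(mu_hi), sigma_hi=float(sigma_hi), weight_hi=float(w_hi),
        fov_id=fov_id,
    )


def normalize_traces(traces: Sequence[CalciumTrace], fit: BaselineFit) -> list[CalciumTrace]:
    """Set each trace's fold change over the resting state (values / mu_lo)."""
    if fit.mu_lo <= 0:
        raise ValueError(f"resting mean must be positive, got {fit.mu_lo}")
    for trace in traces:
        trace.normalized_values = trace.values / fit.mu_lo
    return list(traces)


def normalize_dataset(dataset: Dataset) -> dict[str, BaselineFit]:
    """Fit and apply fold-change normalization per field of view."""
    fits = {}
    for fov in dataset.fovs:
        pooled = np.concatenate([t.values for t in fov.traces])
        fit = fit_baseline_gmm(pooled, fov_id=fov.fov_id)
        normalize_traces(fov.traces, fit)
        fits[fov.fov_id] = fit
    return fits


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentationSpec:
    """Parameters of the trace augmentation (repeat / noise / shift / scale)."""

    n_repeats: int = 1
    noise_sd: float = 0.0
    max_shift_frames: int = 0
    amplitude_scale_range: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_repeats < 0:
            raise ValueError("n_repeats must be >= 0")
        lo, hi = self.amplitude_scale_range
        if not (0 < lo <= hi):
            raise ValueError("amplitude_scale_range must satisfy 0 < lo <= hi")
        if self.max_shift_frames < 0 or self.noise_sd < 0:
            raise ValueError("noise_sd and max_shift_frames must be >= 0")


def baseline_median(values: np.ndarray) -> float:
    """Robust per-trace resting-level estimate.

    Median of the lower half of the sorted values: insensitive to the
    activated plateau even when a cell spends most of the movie elevated.
    """
    values = np.sort(np.asarray(values, dtype=float))
    return float(np.median(values[: max(1, values.size // 2)]))


def augment(trace_values: np.ndarray, spec: AugmentationSpec,
            rng: np.random.Generator) -> list[np.ndarray]:
    """Generate ``n_repeats`` augmented variants of one trace.

    Each variant independently (1) shifts the whole trace by a uniform
    integer in [-max_shift, +max_shift], padding the vacated edge with
    the trace's own baseline median, (2) scales the deviation from that
    baseline by a uniform factor from ``amplitude_scale_range``, and (3)
    adds Gaussian noise of ``noise_sd``.
    """
    values = np.asarray(trace_values, dtype=float)
    base = baseline_median(values)
    out = []
    for _ in range(spec.n_repeats):
        shift = int(rng.integers(-spec.max_shift_frames, spec.max_shift_frames + 1)) \
            if spec.max_shift_frames else 0
        v = np.full_like(values, base)
        if shift >= 0:
            v[shift:] = values[:values.size - shift]
        else:
            v[:shift] = values[-shift:]
        lo, hi = spec.amplitude_scale_range
        scale = float(rng.uniform(lo, hi)) if hi > lo else lo
        v = base + scale * (v - base)
        if spec.noise_sd > 0:
            v = v + rng.normal(0.0, spec.noise_sd, size=v.size)
        out.append(v)
    return out


def augment_training_set(training: "TrainingSet", spec: AugmentationSpec,
                         rng: np.random.Generator) -> "TrainingSet":
    """Append augmented variants of every training trace.

    Only the ratio channel is perturbed; derivative/speed channels of a
    variant are recomputed or copied as appropriate (|first difference|
    recomputed, speed copied unchanged). Labels, FOV assignments and the
    balance report carry over; augmented cells get suffixed ids.
    """
    if spec.n_repeats == 0:
        return training
    mats = [training.trace_matrix]
    labels = [training.labels]
    cell_ids = list(training.cell_ids)
    fov_ids = list(training.fov_ids)
    n = training.trace_matrix.shape[0]
    for i in range(n):
        variants = augment(training.trace_matrix[i, :, 0], spec, rng)
        for j, v in enumerate(variants):
            m = training.trace_matrix[i].copy()
            m[:, 0] = v
            if "absdiff" in training.channels:
                k = training.channels.index("absdiff")
                m[:, k] = np.concatenate([[0.0], np.abs(np.diff(v))])
            mats.append(m[None])
            cell_ids.append(f"{training.cell_ids[i]}_aug{j}")
            fov_ids.append(training.fov_ids[i])
        labels.append(np.repeat(training.labels[i], len(variants)))
    report = dict(training.balance_report)
    report["n_augmented"] = int(n * spec.n_repeats)
    return TrainingSet(
        trace_matrix=np.concatenate(mats), labels=np.concatenate(labels),
        cell_ids=cell_ids, fov_ids=fov_ids,
        ground_truth_mode=training.ground_truth_mode,
        channels=training.channels, balance_report=report)


# ---------------------------------------------------------------------------
# evaluator votes
# ---------------------------------------------------------------------------

@dataclass
class EvaluatorVotes:
    """Binary antigen-reactive calls of independent human evaluators."""

    cell_id: str
    votes: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.votes) < 1:
            raise ValueError("need at least one evaluator vote")


def majority_vote(votes: EvaluatorVotes | Sequence[int]) -> bool:
    """Final reactive label: strictly more than half of votes reactive.

    Exact ties (possible with an even evaluator count) resolve to
    nonreactive — the conservative choice that minimizes false reactive
    ground truth.
    """
    v = votes.votes if isinstance(votes, EvaluatorVotes) else votes
    v = np.asarray(v, dtype=int)
    return bool(v.sum() * 2 > v.size)


def manual_labels(fov: FieldOfView) -> np.ndarray:
    """Majority-vote reactive label per cell of a FOV."""
    return np.array([majority_vote(row) for row in fov.votes], dtype=bool)


# ---------------------------------------------------------------------------
# training-set assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """How FOVs are divided into training and evaluation splits."""

    eval_fraction: float = 0.4          # fraction of OVA-like FOVs held out
    train_conditions: tuple[str, ...] = (CONDITION_OVA,)
    balance_ctfr: bool = True


@dataclass
class TrainingSet:
    """Fixed-length trace matrix with labels and split bookkeeping.

    ``trace_matrix`` is [n_cells, n_frames, n_channels] with channel 0 the
    (normalized) ratio and optional |first difference| and instantaneous
    speed channels.
    """

    trace_matrix: np.ndarray
    labels: np.ndarray
    cell_ids: list[str]
    fov_ids: list[str]
    ground_truth_mode: str
    channels: tuple[str, ...]
    balance_report: dict = field(default_factory=dict)


class StratumError(ValueError):
    """Raised when a balance stratum has no cells to draw from."""


def _label_cells(fov: FieldOfView, mode: str) -> np.ndarray:
    genotype = np.array([c.genotype == GENOTYPE_SPECIFIC for c in fov.truth])
    if mode == "genotype":
        return genotype
    manual = manual_labels(fov)
    if mode == "manual":
        return manual
    if mode == "combined":
        return genotype & manual
    raise ValueError(f"unknown ground_truth_mode {mode!r}")


def pad_to_length(values: np.ndarray, frames: np.ndarray, n_frames: int) -> np.ndarray:
    """Place a (possibly partial) trace on a fixed frame grid.

    Frames outside the tracked span are padded with the trace's own
    baseline median; frames beyond ``n_frames`` are truncated.
    """
    out = np.full(n_frames, baseline_median(values))
    keep = frames < n_frames
    out[frames[keep]] = values[keep]
    return out


def _cell_matrix(fov: FieldOfView, channels: tuple[str, ...], n_frames: int) -> np.ndarray:
    mats = []
    for i, trace in enumerate(fov.traces):
        vals = pad_to_length(trace.working_values, trace.frames, n_frames)
        chans = []
        for ch in channels:
            if ch == "ratio":
                chans.append(vals)
            elif ch == "absdiff":
                d = np.abs(np.diff(vals))
                chans.append(np.concatenate([[0.0], d]))
            elif ch == "speed":
                track = fov.tracks[i] if i < len(fov.tracks) else None
                if track is None or len(track) < 2:
                    chans.append(np.zeros(n_frames))
                else:
                    sp = np.hypot(np.diff(track.x), np.diff(track.y))
                    sp_full = np.zeros(n_frames)
                    frames = track.frames[1:]
                    keep = frames < n_frames
                    sp_full[frames[keep]] = sp[keep]
                    chans.append(sp_full)
            else:
                raise ValueError(f"unknown channel {ch!r}")
        mats.append(np.stack(chans, axis=-1))
    return np.stack(mats) if mats else np.empty((0, n_frames, len(channels)))


def _balanced_indices(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    pos = np.where(labels)[0]
    neg = np.where(~labels)[0]
    if pos.size == 0 or neg.size == 0:
        raise StratumError(
            f"cannot balance classes: {pos.size} positives vs {neg.size} negatives"
        )
    n = min(pos.size, neg.size)
    pos = rng.choice(pos, size=n, replace=False)
    neg = rng.choice(neg, size=n, replace=False)
    return np.sort(np.concatenate([pos, neg]))


def _assemble(fovs: list[FieldOfView], mode: str, channels: tuple[str, ...],
              n_frames: int, rng: np.random.Generator, balance: bool = True) -> TrainingSet:
    mats, labels, cell_ids, fov_ids = [], [], [], []
    for fov in fovs:
        mats.append(_cell_matrix(fov, channels, n_frames))
        labels.append(_label_cells(fov, mode))
        cell_ids.extend(c.cell_id for c in fov.truth)
        fov_ids.extend(fov.fov_id for _ in fov.truth)
    matrix = np.concatenate(mats) if mats else np.empty((0, n_frames, len(channels)))
    labels = np.concatenate(labels) if labels else np.empty(0, dtype=bool)
    cell_ids = np.array(cell_ids, dtype=object)
    fov_ids_arr = np.array(fov_ids, dtype=object)
    if balance and labels.size:
        idx = _balanced_indices(labels, rng)
        matrix, labels = matrix[idx], labels[idx]
        cell_ids, fov_ids_arr = cell_ids[idx], fov_ids_arr[idx]
    orient = {f.fov_id: f.ctfr_orientation for f in fovs}
    report = {
        "n_cells": int(labels.size),
        "n_positive": int(labels.sum()),
        "n_negative": int((~labels).sum()),
        "fovs": [f.fov_id for f in fovs],
        "ctfr_orientations": {
            o: sum(1 for f in fovs if f.ctfr_orientation == o)
            for o in {f.ctfr_orientation for f in fovs}
        },
        "per_orientation_cells": {
            o: int(sum(1 for fid in fov_ids_arr if orient[fid] == o))
            for o in {f.ctfr_orientation for f in fovs}
        },
    }
    return TrainingSet(trace_matrix=matrix, labels=labels,
                       cell_ids=list(cell_ids), fov_ids=list(fov_ids_arr),
                       ground_truth_mode=mode, channels=channels,
                       balance_report=report)


def build_training_set(
    dataset: Dataset,
    ground_truth_mode: str = "manual",
    channels: tuple[str, ...] = ("ratio",),
    split_spec: SplitSpec = SplitSpec(),
    rng: np.random.Generator | None = None,
    balance_eval: bool = True,
) -> tuple[TrainingSet, TrainingSet]:
    """Split a dataset by whole FOV and assemble balanced matrices.

    The training split is restricted to the conditions in
    ``split_spec.train_conditions`` (the strong-agonist "OVA-like"
    condition by default) while the evaluation split receives the held
    out FOVs of every condition — mirroring the generalization test to a
    weaker agonist. Positives and negatives are down-sampled to equal
    counts within each split; CTFR staining orientations are balanced at
    the FOV level in the training split. Cells never straddle splits.
    """
    if ground_truth_mode not in GROUND_TRUTH_MODES:
        raise ValueError(f"unknown ground_truth_mode {ground_truth_mode!r}")
    rng = np.random.default_rng(0) if rng is None else rng
    n_frames = dataset.config.n_frames

    trainable = [f for f in dataset.fovs if f.condition in split_spec.train_conditions]
    other = [f for f in dataset.fovs if f.condition not in split_spec.train_conditions]
    if not trainable:
        raise StratumError("no FOVs in the training conditions")
    order = rng.permutation(len(trainable))
    n_eval = max(1, int(round(split_spec.eval_fraction * len(trainable)))) \
        if len(trainable) > 1 else 0
    eval_fovs = [trainable[i] for i in order[:n_eval]] + other
    train_fovs = [trainable[i] for i in order[n_eval:]]
    if not train_fovs:
        raise StratumError("no FOVs left for the training split")

    if split_spec.balance_ctfr:
        by_orient: dict[str, list[FieldOfView]] = {}
        for f in train_fovs:
            by_orient.setdefault(f.ctfr_orientation, []).append(f)
        if len(by_orient) > 1:
            n_keep = min(len(v) for v in by_orient.values())
            kept = []
            for group in by_orient.values():
                idx = rng.permutation(len(group))[:n_keep]
                kept.extend(group[i] for i in sorted(idx))
            train_fovs = sorted(kept, key=lambda f: f.fov_id)

    train = _assemble(train_fovs, ground_truth_mode, channels, n_frames, rng)
    evaluation = _assemble(eval_fovs, ground_truth_mode, channels, n_frames, rng,
                           balance=balance_eval)
    overlap = set(train.cell_ids) & set(evaluation.cell_ids)
    if overlap:
        raise AssertionError(f"cells in both splits: {sorted(overlap)[:3]}")
    return train, evaluation
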