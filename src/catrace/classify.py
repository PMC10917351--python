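"""Antigen-specificity classifiers: dual-threshold baseline and 1D CNN.

The baseline sets a calcium threshold theta_Ca (fold change over resting)
and a time threshold theta_t (seconds): a cell spending strictly more
than theta_t above theta_Ca is called antigen-specific. Both thresholds
are fitted by exhaustive grid search maximizing the weighted performance
metric pM on the training fields of view.

The CNN consumes fixed-length multichannel traces (normalized ratio,
optionally |first difference| and instantaneous speed), emits a
probability of being antigen-specific per cell, and binarizes it at a
selectable probability threshold (default 0.47). Hyperparameters exposed
to the grid search are the ones that matter at this scale: number of
convolution filters, kernel size, optimizer, and mini-batch size.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._nn import CNN1d, cross_entropy, make_optimizer, softmax
from .evaluate import PerformanceWeights, score_calls
from .preprocess import TrainingSet

logger = logging.getLogger("catrace")

#: default probability cutoff when no selection step is run
DEFAULT_P_THRESHOLD = 0.47


# ---------------------------------------------------------------------------
# dual-threshold baseline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdModel:
    """Calcium threshold (fold change) and dwell-time threshold (seconds)."""

    ca_threshold: float
    time_threshold_s: float

    def __post_init__(self) -> None:
        if self.ca_threshold <= 0:
            raise ValueError("ca_threshold must be > 0")
        if self.time_threshold_s < 0:
            raise ValueError("time_threshold_s must be >= 0")


def time_above(trace_values: np.ndarray, ca_threshold: float,
               frame_interval_s: float) -> float:
    """Seconds spent strictly above the calcium threshold."""
    values = np.asarray(trace_values, dtype=float)
    return float((values > ca_threshold).sum() * frame_interval_s)


def threshold_predict(trace_values: np.ndarray, model: ThresholdModel,
                      frame_interval_s: float) -> bool:
    """Antigen-specific iff dwell time strictly exceeds the time threshold."""
    return time_above(trace_values, model.ca_threshold, frame_interval_s) \
        > model.time_threshold_s


def _times_matrix(values_list, ca_grid: np.ndarray, frame_interval_s: float) -> np.ndarray:
    """[n_cells, n_ca] dwell times above each calcium threshold."""
    out = np.empty((len(values_list), ca_grid.size))
    for i, values in enumerate(values_list):
        v = np.asarray(values, dtype=float)
        # counts of frames above each threshold via a sorted scan
        out[i] = (v[None, :] > ca_grid[:, None]).sum(axis=1) * frame_interval_s
    return out


def threshold_fit(values_list, reactive_labels, genotypes, fov_ids, conditions,
                  ca_grid, time_grid_s, frame_interval_s: float = 30.0,
                  weights: PerformanceWeights = PerformanceWeights(),
                  ) -> tuple[ThresholdModel, float]:
    """Exhaustive search for the (theta_Ca, theta_t) pair maximizing pM.

    Every grid pair is scored on the training FOVs with the weighted
    performance metric; ties are broken by the smaller calcium threshold,
    then the larger time threshold. Undefined per-FOV metrics count as 0
    during fitting so that degenerate inputs still select the documented
    (min theta_Ca, max theta_t) pair. Returns the model and its pM.
    """
    ca_grid = np.asarray(ca_grid, dtype=float)
    time_grid = np.asarray(time_grid_s, dtype=float)
    if ca_grid.size == 0 or time_grid.size == 0:
        raise ValueError("threshold grids must be nonempty")
    times = _times_matrix(values_list, ca_grid, frame_interval_s)

    best: tuple[float, float, float] | None = None   # (pm, ca, t)
    best_pm = -math.inf
    for ci, ca in enumerate(ca_grid):
        for t in time_grid:
            calls = times[:, ci] > t
            pm = score_calls(calls, reactive_labels, genotypes, fov_ids,
                             conditions, weights)
            better = pm > best_pm
            tie = pm == best_pm and best is not None and (
                ca < best[1] or (ca == best[1] and t > best[2]))
            if better or tie:
                best_pm = pm
                best = (pm, float(ca), float(t))
    assert best is not None
    return ThresholdModel(ca_threshold=best[1], time_threshold_s=best[2]), best_pm


# ---------------------------------------------------------------------------
# CNN
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CNNHyperparams:
    """The four searched hyperparameters plus training bookkeeping."""

    n_filters: int = 16
    kernel_size: int = 11
    optimizer_id: str = "adam"
    minibatch_size: int = 64
    epochs: int = 15
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_filters", "kernel_size", "minibatch_size", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer_id not in ("adam", "sgd", "rmsprop"):
            raise ValueError(f"unknown optimizer_id {self.optimizer_id!r}")


#: default grid searched by hyperoptimize
DEFAULT_HYPER_GRID = {
    "n_filters": (8, 16, 32, 64),
    "kernel_size": (5, 11, 21, 41),
    "optimizer_id": ("adam", "sgd", "rmsprop"),
    "minibatch_size": (32, 64, 128),
}


@dataclass
class TrainedClassifier:
    """A trained CNN with its input scaling and probability cutoff."""

    net: CNN1d
    channels: tuple[str, ...]
    channel_mean: np.ndarray
    channel_std: np.ndarray
    p_threshold: float = DEFAULT_P_THRESHOLD
    hyperparams: CNNHyperparams = field(default_factory=CNNHyperparams)
    ground_truth_mode: str = "manual"
    history: list[float] = field(default_factory=list)
    balance_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")


@dataclass
class PredictionResult:
    cell_id: str
    p_antigen_spe: float
    call: bool


def cnn_build(hp: CNNHyperparams, n_channels: int, n_frames: int) -> CNN1d:
    """Build the untrained two-block CNN; logs its parameter count."""
    net = CNN1d(n_channels=n_channels, n_frames=n_frames,
                n_filters=hp.n_filters, kernel_size=hp.kernel_size, seed=hp.seed)
    logger.info("built CNN: %d filters, kernel %d, %d parameters",
                hp.n_filters, hp.kernel_size, net.parameter_count())
    return net


def _to_bct(matrix: np.ndarray) -> np.ndarray:
    """[n_cells, n_frames, n_channels] -> [batch, channel, time]."""
    return np.ascontiguousarray(np.transpose(matrix, (0, 2, 1)))


def cnn_train(net: CNN1d, training: TrainingSet, hp: CNNHyperparams,
              p_threshold: float = DEFAULT_P_THRESHOLD) -> TrainedClassifier:
    """Train by minibatch cross-entropy minimization.

    Inputs are standardized per channel with statistics of the training
    set (stored on the classifier and reapplied at prediction time).
    Seeded shuffling and single-threaded numpy make runs reproducible.
    Aborts with diagnostics if the loss goes non-finite.
    """
    X = _to_bct(training.trace_matrix).astype(float)
    y = training.labels.astype(int)
    mean = X.mean(axis=(0, 2))
    std = X.std(axis=(0, 2))
    std = np.where(std < 1e-9, 1.0, std)
    X = (X - mean[None, :, None]) / std[None, :, None]

    rng = np.random.default_rng(hp.seed)
    opt = make_optimizer(hp.optimizer_id, hp.learning_rate)
    n = X.shape[0]
    history = []
    for epoch in range(hp.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, hp.minibatch_size):
            idx = order[start:start + hp.minibatch_size]
            xb, yb = X[idx], y[idx]
            probs = softmax(net.forward(xb))
            loss = cross_entropy(probs, yb)
            if not math.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {start // hp.minibatch_size}: "
                    f"loss={loss}, lr={hp.learning_rate}, optimizer={hp.optimizer_id}"
                )
            dlogits = probs.copy()
            dlogits[np.arange(yb.size), yb] -= 1.0
            dlogits /= yb.size
            net.backward(dlogits)
            opt.step(net)
            losses.append(loss)
        history.append(float(np.mean(losses)))
        logger.debug("epoch %d: loss %.4f", epoch, history[-1])
    return TrainedClassifier(
        net=net, channels=training.channels, channel_mean=mean, channel_std=std,
        p_threshold=p_threshold, hyperparams=hp,
        ground_truth_mode=training.ground_truth_mode, history=history,
        balance_report=training.balance_report,
    )


def cnn_predict(classifier: TrainedClassifier, trace_matrix: np.ndarray,
                cell_ids=None, batch_size: int = 256) -> list[PredictionResult]:
    """Per-cell probability of being antigen-specific, and the binary call.

    The call uses ``p >= p_threshold`` (a probability exactly at the
    cutoff is positive). Inputs must carry the channels the classifier
    was trained on.
    """
    if trace_matrix.ndim != 3 or trace_matrix.shape[2] != len(classifier.channels):
        raise ValueError(
            f"expected [n, n_frames, {len(classifier.channels)}] input for channels "
            f"{classifier.channels}, got shape {trace_matrix.shape}"
        )
    X = _to_bct(trace_matrix).astype(float)
    X = (X - classifier.channel_mean[None, :, None]) / classifier.channel_std[None, :, None]
    probs = np.concatenate([
        classifier.net.predict_proba(X[i:i + batch_size])[:, 1]
        for i in range(0, X.shape[0], batch_size)
    ]) if X.shape[0] else np.empty(0)
    if cell_ids is None:
        cell_ids = [f"cell{i:05d}" for i in range(X.shape[0])]
    return [
        PredictionResult(cell_id=str(cid), p_antigen_spe=float(p),
                         call=bool(p >= classifier.p_threshold))
        for cid, p in zip(cell_ids, probs)
    ]


def probabilities(predictions: list[PredictionResult]) -> np.ndarray:
    return np.array([p.p_antigen_spe for p in predictions])


def calls(predictions: list[PredictionResult]) -> np.ndarray:
    return np.array([p.call for p in predictions], dtype=bool)


def select_probability_threshold(probs, reactive_labels, genotypes, fov_ids,
                                 conditions, grid,
                                 weights: PerformanceWeights = PerformanceWeights(),
                                 ) -> tuple[float, float]:
    """Grid value maximizing pM of the thresholded calls; ties -> smallest.

    Returns (threshold, pM at that threshold).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid must be nonempty")
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("probability thresholds must lie in (0, 1)")
    probs = np.asarray(probs, dtype=float)
    best_thr, best_pm = None, -math.inf
    for thr in np.sort(grid):
        pm = score_calls(probs >= thr, reactive_labels, genotypes, fov_ids,
                         conditions, weights)
        if pm > best_pm:
            best_pm, best_thr = pm, float(thr)
    return best_thr, best_pm


def hyperoptimize(hyper_grid: list[CNNHyperparams], train_set: TrainingSet,
                  eval_matrix: np.ndarray, eval_truth: dict,
                  weights: PerformanceWeights = PerformanceWeights(),
                  p_threshold: float = DEFAULT_P_THRESHOLD,
                  ) -> tuple[CNNHyperparams, pd.DataFrame]:
    """Train one seeded model per hyperparameter combination; argmax of pM.

    ``eval_truth`` carries aligned genotype / reactive / fov_ids /
    conditions arrays for the evaluation cells. Failed trainings are
    recorded in the leaderboard with NaN pM and excluded from the argmax.
    """
    if not hyper_grid:
        raise ValueError("hyperparameter grid must be nonempty")
    rows = []
    n_frames = train_set.trace_matrix.shape[1]
    for gi, hp in enumerate(hyper_grid):
        row = dataclasses.asdict(hp)
        row["grid_index"] = gi
        try:
            net = cnn_build(hp, len(train_set.channels), n_frames)
            clf = cnn_train(net, train_set, hp, p_threshold=p_threshold)
            preds = cnn_predict(clf, eval_matrix)
            pm = score_calls(calls(preds), eval_truth["reactive"],
                             eval_truth["genotype"], eval_truth["fov_ids"],
                             eval_truth["conditions"], weights)
            row["pm"] = pm
            row["error"] = ""
        except Exception as exc:  # noqa: BLE001 - leaderboard records failures
            logger.warning("hyperopt combination failed: %s", exc)
            row["pm"] = float("nan")
            row["error"] = str(exc)
        rows.append(row)
    leaderboard = pd.DataFrame(rows)
    valid = leaderboard[~leaderboard["pm"].isna()]
    if valid.empty:
        raise RuntimeError("every hyperparameter combination failed")
    best_row = valid.loc[valid["pm"].idxmax()]
    return hyper_grid[int(best_row["grid_index"])], leaderboard


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_classifier(classifier: TrainedClassifier, outdir) -> None:
    """Model bundle: weights npz + metadata JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    weights = classifier.net.get_weights()
    np.savez(outdir / "weights.npz",
             **{f"w{i}": w for i, w in enumerate(weights)},
             channel_mean=classifier.channel_mean,
             channel_std=classifier.channel_std)
    meta = {
        "channels": list(classifier.channels),
        "p_threshold": classifier.p_threshold,
        "hyperparams": dataclasses.asdict(classifier.hyperparams),
        "ground_truth_mode": classifier.ground_truth_mode,
        "n_frames": classifier.net.n_frames,
        "history": classifier.history,
        "balance_report": classifier.balance_report,
        "parameter_count": classifier.net.parameter_count(),
    }
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2))


def load_classifier(indir) -> TrainedClassifier:
    indir = Path(indir)
    meta = json.loads((indir / "metadata.json").read_text())
    hp = CNNHyperparams(**meta["hyperparams"])
    net = CNN1d(n_channels=len(meta["channels"]), n_frames=meta["n_frames"],
                n_filters=hp.n_filters, kernel_size=hp.kernel_size, seed=hp.seed)
    data = np.load(indir / "weights.npz")
    n_weights = len([k for k in data.files if k.startswith("w")])
    net.set_weights([data[f"w{i}"] for i in range(n_weights)])
    return TrainedClassifier(
        net=net, channels=tuple(meta["channels"]),
        channel_mean=data["channel_mean"], channel_std=data["channel_std"],
        p_threshold=meta["p_threshold"], hyperparams=hp,
        ground_truth_mode=meta["ground_truth_mode"], history=meta["history"],
        balance_report=meta["balance_report"],
    )
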