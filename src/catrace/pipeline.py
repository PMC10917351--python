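"""End-to-end runs: simulate -> (extract) -> preprocess -> train -> predict -> evaluate.

One RunConfig drives the whole pipeline with a single seed; every run
writes a manifest (inputs, outputs, content hashes, versions) sufficient
to re-run bit-identically. Each stage is also exposed on its own for
debugging and for the command-line interface.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, evaluate, preprocess, synthetic
from .preprocess import SplitSpec
from .synthetic import Dataset, FieldOfView, SimulationConfig

logger = logging.getLogger("catrace")

PIPELINE_ORDER = ("simulate", "extract", "preprocess", "train", "predict", "evaluate")
#: stages that may be omitted from an otherwise-contiguous run
OPTIONAL_STAGES = ("extract",)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    stages: tuple[str, ...] = ("simulate", "preprocess", "train", "predict", "evaluate")
    seed: int = 0
    outdir: str = "run"
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)     # SimulationConfig overrides
    n_days: int = 2
    conditions: tuple[str, ...] = (synthetic.CONDITION_OVA, synthetic.CONDITION_GP33)
    render: bool = False
    movie_paths: tuple[str, ...] = ()                # external movies for extract
    ground_truth_mode: str = "manual"
    channels: tuple[str, ...] = ("ratio",)
    classifier: str = "cnn"                          # "cnn" or "threshold"
    hyperparams: dict = field(default_factory=dict)  # CNNHyperparams overrides
    split: dict = field(default_factory=dict)        # SplitSpec overrides
    weights: tuple[float, float] = (1.0, 5.0)
    p_threshold: float = classify.DEFAULT_P_THRESHOLD
    augmentation: dict = field(default_factory=dict)   # AugmentationSpec overrides
    select_threshold_grid: tuple[float, ...] = ()      # nonempty -> re-select p_thr

    def __post_init__(self) -> None:
        idx = []
        for s in self.stages:
            if s not in PIPELINE_ORDER:
                raise ValueError(f"unknown stage {s!r}")
            idx.append(PIPELINE_ORDER.index(s))
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ValueError("stages must follow the pipeline order without repeats")
        required = [s for s in PIPELINE_ORDER if s not in OPTIONAL_STAGES]
        chosen = [s for s in self.stages if s not in OPTIONAL_STAGES]
        if chosen and chosen != required[required.index(chosen[0]):
                                         required.index(chosen[0]) + len(chosen)]:
            raise ValueError(
                f"stages must form a contiguous run of {required} (extract optional)"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("stages", "conditions", "channels", "movie_paths"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        if "weights" in raw and isinstance(raw["weights"], list):
            raw["weights"] = tuple(raw["weights"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, dataset: Dataset | None = None) -> dict:
    """Execute the configured stages in order; returns the manifest.

    Inputs referenced by a stage are checked before it runs; a stage
    failure aborts with the stage name while earlier outputs remain on
    disk. The manifest records the seed, per-stage outputs with sha256
    hashes, and library versions. A preloaded ``dataset`` substitutes for
    the simulate stage when working from an existing dataset directory.
    """
    logging.getLogger("catrace").setLevel(config.log_level.upper())
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # no timestamps: identical seeds must reproduce identical manifests
    manifest: dict = {
        "seed": config.seed,
        "stages": list(config.stages),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "versions": {"catrace": "0.1.0", "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    # pre-flight: every referenced external input must exist
    for p in config.movie_paths:
        if not Path(p).exists():
            raise StageError(f"stage 'extract': missing input movie {p}")

    trained = None
    threshold_model = None
    train_set = eval_set = None
    predictions_df = None

    if config.stages and config.stages[0] != "simulate" and dataset is None:
        raise StageError(
            f"stage {config.stages[0]!r} needs a dataset; start at 'simulate' "
            "or pass a preloaded dataset")

    for stage in config.stages:
        t0 = time.time()
        try:
            if stage == "simulate":
                sim = SimulationConfig(seed=config.seed, **config.simulate)
                dataset = synthetic.simulate_dataset(
                    sim, n_days=config.n_days, conditions=config.conditions,
                    separate_cells=config.render)
                stage_dir = outdir / "dataset"
                synthetic.write_dataset(dataset, stage_dir, render=config.render)
            elif stage == "extract":
                stage_dir = outdir / "extracted"
                stage_dir.mkdir(exist_ok=True)
                movie_paths = [Path(p) for p in config.movie_paths] or sorted(
                    (outdir / "dataset").glob("*_indo1.tif"))
                if not movie_paths:
                    raise StageError("stage 'extract': no movies to process")
                from .imaging import MovieStack, process_movie

                for mp in movie_paths:
                    fov_id = mp.stem.replace("_indo1", "")
                    ctfr = mp.with_name(f"{fov_id}_ctfr.tif")
                    idx = mp.with_name(f"{fov_id}_ctfr_frames.csv")
                    movie = MovieStack.from_tiff(
                        mp, ctfr if ctfr.exists() else None,
                        idx if idx.exists() else None)
                    tracks, traces, calls_ = process_movie(movie, fov_id=fov_id)
                    synthetic.tracks_to_frame(tracks).to_csv(
                        stage_dir / f"{fov_id}_tracks.csv", index=False)
                    synthetic.traces_to_frame(traces).to_csv(
                        stage_dir / f"{fov_id}_traces.csv", index=False)
                    pd.DataFrame([
                        {"cell_id": c.cell_id, "call": c.call,
                         "n_positive_samples": c.n_positive_samples,
                         "n_samples": c.n_samples} for c in calls_
                    ]).to_csv(stage_dir / f"{fov_id}_genotype.csv", index=False)
            elif stage == "preprocess":
                assert dataset is not None
                fits = preprocess.normalize_dataset(dataset)
                stage_dir = outdir
                pd.DataFrame([
                    {"fov_id": fid, "mu_lo": f.mu_lo, "mu_hi": f.mu_hi,
                     "sigma_lo": f.sigma_lo, "sigma_hi": f.sigma_hi,
                     "weight_lo": f.weight_lo, "degenerate": f.degenerate}
                    for fid, f in fits.items()
                ]).to_csv(outdir / "baseline_fits.csv", index=False)
                rng = np.random.default_rng(config.seed + 1)
                train_set, eval_set = preprocess.build_training_set(
                    dataset, ground_truth_mode=config.ground_truth_mode,
                    channels=config.channels,
                    split_spec=SplitSpec(**config.split), rng=rng)
                (outdir / "balance_report.json").write_text(
                    json.dumps({"train": train_set.balance_report,
                                "eval": eval_set.balance_report}, indent=2))
            elif stage == "train":
                assert train_set is not None
                hp = classify.CNNHyperparams(seed=config.seed, **config.hyperparams)
                if config.classifier == "cnn":
                    fit_set = train_set
                    if config.augmentation:
                        fit_set = preprocess.augment_training_set(
                            train_set,
                            preprocess.AugmentationSpec(**config.augmentation),
                            np.random.default_rng(config.seed + 2))
                    net = classify.cnn_build(hp, len(config.channels),
                                             dataset.config.n_frames)
                    trained = classify.cnn_train(net, fit_set, hp,
                                                 p_threshold=config.p_threshold)
                    if config.select_threshold_grid:
                        truth = evaluate.truth_arrays(dataset, train_set.cell_ids)
                        probs = classify.probabilities(classify.cnn_predict(
                            trained, train_set.trace_matrix))
                        thr, _ = classify.select_probability_threshold(
                            probs, truth["reactive"], truth["genotype"],
                            truth["fov_ids"], truth["conditions"],
                            config.select_threshold_grid,
                            weights=evaluate.PerformanceWeights(*config.weights))
                        trained.p_threshold = thr
                    classify.save_classifier(trained, outdir / "model")
                elif config.classifier == "threshold":
                    truth = evaluate.truth_arrays(dataset, train_set.cell_ids)
                    values = [train_set.trace_matrix[i, :, 0]
                              for i in range(train_set.trace_matrix.shape[0])]
                    threshold_model, pm = classify.threshold_fit(
                        values, truth["reactive"], truth["genotype"],
                        truth["fov_ids"], truth["conditions"],
                        ca_grid=np.arange(1.0, 3.01, 0.25),
                        time_grid_s=np.arange(0.0, 1801.0, 300.0),
                        frame_interval_s=dataset.config.frame_interval_s,
                        weights=evaluate.PerformanceWeights(*config.weights))
                    (outdir / "model_threshold.json").write_text(json.dumps({
                        "ca_threshold": threshold_model.ca_threshold,
                        "time_threshold_s": threshold_model.time_threshold_s,
                        "training_pm": None if np.isinf(pm) else pm}, indent=2))
                else:
                    raise StageError(f"unknown classifier {config.classifier!r}")
            elif stage == "predict":
                assert eval_set is not None
                if config.classifier == "cnn":
                    preds = classify.cnn_predict(trained, eval_set.trace_matrix,
                                                 cell_ids=eval_set.cell_ids)
                    predictions_df = pd.DataFrame([
                        {"cell_id": p.cell_id, "p_antigen_spe": p.p_antigen_spe,
                         "call": p.call} for p in preds])
                else:
                    calls_ = [classify.threshold_predict(
                        eval_set.trace_matrix[i, :, 0], threshold_model,
                        dataset.config.frame_interval_s)
                        for i in range(eval_set.trace_matrix.shape[0])]
                    predictions_df = pd.DataFrame({
                        "cell_id": eval_set.cell_ids,
                        "p_antigen_spe": [float(c) for c in calls_],
                        "call": calls_})
                predictions_df.to_csv(outdir / "predictions.csv", index=False)
            elif stage == "evaluate":
                assert predictions_df is not None
                truth = evaluate.truth_arrays(dataset, predictions_df.cell_id)
                _, report = evaluate.per_fov_summary(
                    predictions_df.call.to_numpy(dtype=bool), truth["reactive"],
                    truth["genotype"], truth["fov_ids"], truth["conditions"],
                    weights=evaluate.PerformanceWeights(*config.weights))
                evaluate.write_report(report, outdir / "metrics.json")
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s done in %.1fs", stage, time.time() - t0)

    manifest["files"] = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# study-protocol benchmark
# ---------------------------------------------------------------------------

#: probability grid used when re-selecting the CNN cutoff by pM
SELECTION_GRID = tuple(np.round(np.concatenate(
    [np.arange(0.05, 0.9, 0.05), np.arange(0.9, 0.996, 0.01)]), 3))

#: augmentation used for acceptance-scale CNN training: amplitude scaling
#: and onset shifts teach invariance to condition strength and timing
STUDY_AUGMENTATION = preprocess.AugmentationSpec(
    n_repeats=2, noise_sd=0.05, max_shift_frames=30,
    amplitude_scale_range=(0.4, 1.2))


def _train_cnn_for_study(dataset: Dataset, mode: str, seed: int, epochs: int,
                         eval_fraction: float, weights, select: bool = True):
    """One CNN leg of the benchmark: split, augment, train, select cutoff."""
    rng = np.random.default_rng(seed + 10)
    train_set, eval_set = preprocess.build_training_set(
        dataset, ground_truth_mode=mode, channels=("ratio",),
        split_spec=SplitSpec(eval_fraction=eval_fraction), rng=rng,
        balance_eval=False)
    fit_set = preprocess.augment_training_set(
        train_set, STUDY_AUGMENTATION, np.random.default_rng(seed + 20))
    hp = classify.CNNHyperparams(epochs=epochs, seed=seed)
    clf = classify.cnn_train(
        classify.cnn_build(hp, 1, dataset.config.n_frames), fit_set, hp)
    if select:
        t_truth = evaluate.truth_arrays(dataset, train_set.cell_ids)
        probs = classify.probabilities(
            classify.cnn_predict(clf, train_set.trace_matrix))
        thr, _ = classify.select_probability_threshold(
            probs, t_truth["reactive"], t_truth["genotype"],
            t_truth["fov_ids"], t_truth["conditions"], SELECTION_GRID,
            weights=weights)
        clf.p_threshold = thr
    return clf, train_set, eval_set


def _eval_cnn(clf, dataset, eval_set, weights):
    preds = classify.cnn_predict(clf, eval_set.trace_matrix,
                                 cell_ids=eval_set.cell_ids)
    truth = evaluate.truth_arrays(dataset, eval_set.cell_ids)
    probs = classify.probabilities(preds)
    calls = probs >= clf.p_threshold
    _, report = evaluate.per_fov_summary(
        calls, truth["reactive"], truth["genotype"], truth["fov_ids"],
        truth["conditions"], weights=weights)
    roc = evaluate.roc_curve(probs, truth["genotype"] & truth["reactive"])
    return report, roc, calls, probs, truth


def _fit_threshold_for_study(dataset, train_set, eval_set, weights):
    truth_tr = evaluate.truth_arrays(dataset, train_set.cell_ids)
    values = [train_set.trace_matrix[i, :, 0]
              for i in range(train_set.trace_matrix.shape[0])]
    model, _ = classify.threshold_fit(
        values, truth_tr["reactive"], truth_tr["genotype"],
        truth_tr["fov_ids"], truth_tr["conditions"],
        ca_grid=np.arange(1.0, 3.01, 0.1),
        time_grid_s=np.arange(0.0, 3601.0, 120.0),
        frame_interval_s=dataset.config.frame_interval_s, weights=weights)
    calls = np.array([
        classify.threshold_predict(eval_set.trace_matrix[i, :, 0], model,
                                   dataset.config.frame_interval_s)
        for i in range(eval_set.trace_matrix.shape[0])])
    truth_ev = evaluate.truth_arrays(dataset, eval_set.cell_ids)
    _, report = evaluate.per_fov_summary(
        calls, truth_ev["reactive"], truth_ev["genotype"],
        truth_ev["fov_ids"], truth_ev["conditions"], weights=weights)
    return model, report


def run_study(seed: int = 0, n_fov: int = 30, cells_per_fov: int = 200,
              epochs: int = 12, eval_fraction: float = 0.25,
              weights: tuple[float, float] = (1.0, 5.0)) -> dict:
    """The full synthetic benchmark: both classifiers under the study protocol.

    Simulates a multi-day coculture (every fifth FOV weak-agonist), then
    evaluates (a) the CNN on fold-change-normalized traces with
    augmentation and a pM-selected probability cutoff, (b) the same CNN
    protocol without normalization, (c) the dual-threshold baseline on
    raw traces (as that approach is introduced) and on normalized traces,
    and (d) CNNs trained with the three ground-truth modes for the
    call-agreement comparison. Returns a flat dict of the headline
    numbers.
    """
    w = evaluate.PerformanceWeights(*weights)
    conds = tuple(synthetic.CONDITION_OVA if i % 5 else synthetic.CONDITION_GP33
                  for i in range(1, n_fov + 1))
    sim = SimulationConfig(n_fov=n_fov, cells_per_fov=cells_per_fov, seed=seed)

    ds_raw = synthetic.simulate_dataset(sim, n_days=4, conditions=conds)
    ds_norm = synthetic.simulate_dataset(sim, n_days=4, conditions=conds)
    preprocess.normalize_dataset(ds_norm)

    # (a) CNN, normalized (the headline model, manual ground truth)
    clf, train_norm, eval_norm = _train_cnn_for_study(
        ds_norm, "manual", seed, epochs, eval_fraction, w)
    rep_cnn, roc, calls_cnn, probs_cnn, truth_ev = _eval_cnn(
        clf, ds_norm, eval_norm, w)

    # (b) same protocol without normalization
    clf_raw, train_raw, eval_raw = _train_cnn_for_study(
        ds_raw, "manual", seed, epochs, eval_fraction, w)
    rep_cnn_raw, _, _, _, _ = _eval_cnn(clf_raw, ds_raw, eval_raw, w)

    # (c) dual-threshold baseline, raw and normalized
    _, rep_thr_raw = _fit_threshold_for_study(ds_raw, train_raw, eval_raw, w)
    _, rep_thr_norm = _fit_threshold_for_study(ds_norm, train_norm, eval_norm, w)

    # (d) ground-truth-mode agreement on the shared held-out cells
    calls_by_mode = {"manual": dict(zip(eval_norm.cell_ids, calls_cnn))}
    for mode in ("genotype", "combined"):
        clf_m, _, eval_m = _train_cnn_for_study(
            ds_norm, mode, seed, epochs, eval_fraction, w)
        _, _, calls_m, _, _ = _eval_cnn(clf_m, ds_norm, eval_m, w)
        calls_by_mode[mode] = dict(zip(eval_m.cell_ids, calls_m))
    shared = set.intersection(*(set(c) for c in calls_by_mode.values()))
    agreements = {}
    modes = list(calls_by_mode)
    for i in range(len(modes)):
        for j in range(i + 1, len(modes)):
            a, b = calls_by_mode[modes[i]], calls_by_mode[modes[j]]
            agreements[f"{modes[i]}_vs_{modes[j]}"] = float(
                np.mean([a[c] == b[c] for c in shared]))

    gp = synthetic.CONDITION_GP33
    ova = synthetic.CONDITION_OVA
    return {
        "n_train_cells": len(train_norm.cell_ids),
        "n_eval_cells": len(eval_norm.cell_ids),
        "cnn_p_threshold": clf.p_threshold,
        "cnn_efficiency_ova": rep_cnn.condition_efficiency[ova],
        "cnn_efficiency_gp33": rep_cnn.condition_efficiency[gp],
        "cnn_fdr_ova": rep_cnn.condition_fdr[ova],
        "cnn_fdr_gp33": rep_cnn.condition_fdr[gp],
        "cnn_pm": rep_cnn.pm,
        "cnn_auc": roc.auc,
        "cnn_raw_efficiency_gp33": rep_cnn_raw.condition_efficiency[gp],
        "threshold_raw_pm": rep_thr_raw.pm,
        "threshold_raw_efficiency_gp33": rep_thr_raw.condition_efficiency[gp],
        "threshold_norm_efficiency_gp33": rep_thr_norm.condition_efficiency[gp],
        "threshold_norm_pm": rep_thr_norm.pm,
        "mode_agreements": agreements,
        "min_mode_agreement": min(agreements.values()),
    }


def run_imaging_roundtrip(seed: int = 0, n_fov: int = 20, cells_per_fov: int = 50,
                          n_frames: int = 61, image_size: int = 400) -> dict:
    """Render movies, re-analyze them, and score recovery against ground truth.

    For each FOV: render the two-channel movie, run segmentation +
    linking + length filtering + trace extraction, then match recovered
    tracks to ground-truth cells by position. Also links the ground-truth
    detections directly (steps are far below the linking gate) to check
    frame-to-frame assignment in isolation. Returns recovery fractions
    and per-frame trace errors.
    """
    from .imaging import Detection, MovieStack, link_tracks, process_movie

    cfg = SimulationConfig(n_fov=n_fov, cells_per_fov=cells_per_fov,
                           n_frames=n_frames, fov_size_px=image_size, seed=seed)
    ds = synthetic.simulate_dataset(cfg, separate_cells=True)
    render_rng = np.random.default_rng(seed + 1)

    n_truth = n_recovered = 0
    n_links = n_links_correct = 0
    frame_errors: list[np.ndarray] = []
    for fov in ds.fovs:
        arrays = synthetic.render_movie(fov, synthetic.RenderParams(),
                                        image_size=image_size,
                                        ctfr_sample_count=cfg.ctfr_sample_count,
                                        rng=render_rng)
        movie = MovieStack(arrays["frames_405"], arrays["frames_447"],
                           arrays["ctfr_frames"], arrays["ctfr_frame_indices"],
                           frame_interval_s=cfg.frame_interval_s)
        tracks, traces, _ = process_movie(movie, fov_id=fov.fov_id)
        sim = {c.cell_id: t.values for c, t in zip(fov.truth, fov.traces)}
        n_truth += len(fov.truth)
        for track, trace in zip(tracks, traces):
            f0 = track.frames[0]
            dists = {g.cell_id: float(np.hypot(g.x[f0] - track.x[0],
                                               g.y[f0] - track.y[0]))
                     for g in fov.tracks}
            best = min(dists, key=dists.get)
            if dists[best] < 3.0:
                n_recovered += 1
                truth_vals = sim[best][track.frames]
                frame_errors.append(np.abs(trace.values - truth_vals) / truth_vals)

        # linking in isolation: random walks with every step strictly below
        # half the displacement gate, where assignment is unambiguous
        gate = 8.0
        link_rng = np.random.default_rng(seed + 100 + len(frame_errors))
        gx, gy = np.meshgrid(np.linspace(40, image_size - 40, 5),
                             np.linspace(40, image_size - 40, 4))
        starts = np.stack([gx.ravel(), gy.ravel()], axis=1) \
            + link_rng.uniform(-5, 5, (20, 2))
        paths = np.empty((n_frames, 20, 2))
        paths[0] = starts
        for f in range(1, n_frames):
            angles = link_rng.uniform(0, 2 * np.pi, 20)
            steps = link_rng.uniform(0, 0.95 * gate / 2, 20)
            paths[f] = paths[f - 1] + np.stack(
                [steps * np.cos(angles), steps * np.sin(angles)], axis=1)
        dets = [[Detection(x, y, 10.0) for x, y in paths[f]]
                for f in range(n_frames)]
        linked = link_tracks(dets, max_displacement_px=gate)
        for track in linked:
            n_links += len(track) - 1
            d0 = np.hypot(paths[track.frames[0], :, 0] - track.x[0],
                          paths[track.frames[0], :, 1] - track.y[0])
            cell = int(np.argmin(d0))
            ok = np.isclose(track.x, paths[track.frames, cell, 0]) \
                & np.isclose(track.y, paths[track.frames, cell, 1])
            n_links_correct += int(np.all(ok)) * (len(track) - 1)

    errors = np.concatenate(frame_errors) if frame_errors else np.empty(0)
    return {
        "n_ground_truth_cells": n_truth,
        "track_recovery_fraction": n_recovered / n_truth,
        "link_accuracy": n_links_correct / n_links if n_links else float("nan"),
        "trace_error_median": float(np.median(errors)),
        "trace_error_p99": float(np.quantile(errors, 0.99)),
        "trace_frames_within_5pct": float(np.mean(errors <= 0.05)),
    }


# ---------------------------------------------------------------------------
# fixtures and dataset I/O
# ---------------------------------------------------------------------------

def make_fixtures(scale: str, outdir) -> Path:
    """Write the seeded fixture datasets used by the test suite.

    ``tiny``: 2 FOVs x 50 cells, one day, one condition. ``default``:
    20 FOVs x 200 cells over 4 days with both the strong- and
    weak-agonist conditions.
    """
    outdir = Path(outdir)
    if scale == "tiny":
        cfg = SimulationConfig(n_fov=2, cells_per_fov=50, seed=7)
        dataset = synthetic.simulate_dataset(cfg, n_days=1)
    elif scale == "default":
        cfg = SimulationConfig(n_fov=20, cells_per_fov=200, seed=7)
        dataset = synthetic.simulate_dataset(
            cfg, n_days=4,
            conditions=(synthetic.CONDITION_OVA, synthetic.CONDITION_OVA,
                        synthetic.CONDITION_OVA, synthetic.CONDITION_GP33))
    else:
        raise ValueError(f"unknown fixture scale {scale!r}")
    synthetic.write_dataset(dataset, outdir)
    return outdir


def read_dataset(indir, config: SimulationConfig | None = None) -> Dataset:
    """Reconstruct a Dataset from a directory written by write_dataset."""
    indir = Path(indir)
    truth = pd.read_csv(indir / "truth.csv")
    traces = pd.read_csv(indir / "traces.csv")
    tracks = pd.read_csv(indir / "tracks.csv")
    votes = pd.read_csv(indir / "votes.csv")
    fov_table = pd.read_csv(indir / "fovs.csv")
    n_frames = int(traces.frame.max()) + 1
    if config is None:
        config = SimulationConfig(
            n_fov=len(fov_table),
            cells_per_fov=int((truth.fov_id == fov_table.fov_id.iloc[0]).sum()),
            n_frames=n_frames)
    trace_groups = {cid: g for cid, g in traces.groupby("cell_id", sort=False)}
    track_groups = {cid: g for cid, g in tracks.groupby("cell_id", sort=False)}
    vote_cols = [c for c in votes.columns if c.startswith("evaluator_")]
    votes_by_cell = votes.set_index("cell_id")

    fovs = []
    for _, frow in fov_table.iterrows():
        sub = truth[truth.fov_id == frow.fov_id]
        cells, tr_list, tk_list, vote_rows = [], [], [], []
        for _, row in sub.iterrows():
            onset = None if row.onset_frame < 0 else int(row.onset_frame)
            cells.append(synthetic.GroundTruthCell(
                cell_id=row.cell_id, fov_id=row.fov_id, day_id=row.day_id,
                genotype=row.genotype, reactive=bool(row.reactive),
                onset_frame=onset, condition=row.condition,
                ctfr_positive=bool(row.ctfr_positive)))
            g = trace_groups[row.cell_id]
            tr_list.append(synthetic.CalciumTrace(
                cell_id=row.cell_id, values=g.ratio.to_numpy(),
                frames=g.frame.to_numpy()))
            if row.cell_id in track_groups:
                tg = track_groups[row.cell_id]
                tk_list.append(synthetic.CellTrack(
                    cell_id=row.cell_id, fov_id=row.fov_id,
                    frames=tg.frame.to_numpy(), x=tg.x.to_numpy(),
                    y=tg.y.to_numpy()))
            vote_rows.append(votes_by_cell.loc[row.cell_id, vote_cols].to_numpy(int))
        fovs.append(FieldOfView(
            fov_id=frow.fov_id, day_id=frow.day_id, condition=frow.condition,
            ctfr_orientation=frow.ctfr_orientation, day_scale=float(frow.day_scale),
            traces=tr_list, tracks=tk_list, truth=cells,
            votes=np.array(vote_rows)))
    return Dataset(config=config, fovs=fovs)
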