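"""Seeded synthetic cocultures of antigen-specific and nonspecific T cells.

Generates ground-truth calcium traces (background-subtracted Indo-1
405/447 ratios), 2-D motility tracks with TCR-triggered migration arrest,
evaluator votes, and optionally rendered two-channel movies, so that every
downstream stage (imaging, normalization, classification, evaluation) can
be exercised end to end without microscope data.

The statistical structure emulates a 1:1 coculture of TCR-transgenic
antigen-specific and nonspecific CD8+ T cells imaged every 30 s for 2 h:
roughly 68.4% of specific cells show a sustained, oscillating calcium
elevation at some onset time, ~4.1% of nonspecific cells show a shorter
intermediate-amplitude transient, per-day multiplicative baseline drift
mimics inter-experiment variability, and reactive cells slow down at
calcium onset.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("catrace")

#: condition tags for a field of view
CONDITION_OVA = "OVA_like"
CONDITION_GP33 = "gp33_like"
CONDITION_AUTO = "autologous_like"
CONDITIONS = (CONDITION_OVA, CONDITION_GP33, CONDITION_AUTO)

GENOTYPE_SPECIFIC = "specific"
GENOTYPE_NONSPECIFIC = "nonspecific"


class ConfigurationError(ValueError):
    """Raised when a simulation parameter is outside its valid range."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic coculture.

    Amplitudes are fold changes over the resting ratio; times are in
    frames unless suffixed ``_s``. Defaults encode the study conditions:
    50:50 specific:nonspecific mixtures, 68.4% reactive specific cells,
    4.11% nonspecific transients, a 2 h movie at 30 s cadence, and a
    15% coefficient of variation of the per-day baseline scale.
    """

    n_fov: int = 4
    cells_per_fov: int = 50
    frac_specific: float = 0.5
    p_reactive_given_specific: float = 0.684
    p_transient_given_nonspecific: float = 0.0411
    n_frames: int = 241
    frame_interval_s: float = 30.0
    baseline_level: float = 1.0
    day_scale_cv: float = 0.15
    activation_amplitude: float = 3.0       # "OVA-like" sustained plateau
    gp33_amplitude: float = 1.8             # lower-amplitude condition
    transient_amplitude: float = 1.8        # intermediate nonspecific blips
    amplitude_cv: float = 0.15              # per-cell amplitude heterogeneity
    transient_duration_frames: int = 20
    onset_fraction: float = 0.75            # onsets uniform over first 75%
    oscillation_period_frames: int = 40
    oscillation_depth: float = 0.3
    noise_sd: float = 0.08
    speed_free: float = 3.0                 # px/frame before activation
    arrest_factor: float = 0.25
    ctfr_sample_count: int = 12
    n_evaluators: int = 4
    evaluator_error_rate: float = 0.05
    fov_size_px: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "frac_specific": self.frac_specific,
            "p_reactive_given_specific": self.p_reactive_given_specific,
            "p_transient_given_nonspecific": self.p_transient_given_nonspecific,
            "oscillation_depth": self.oscillation_depth,
            "onset_fraction": self.onset_fraction,
            "evaluator_error_rate": self.evaluator_error_rate,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if self.n_frames < 2:
            raise ConfigurationError(f"n_frames must be >= 2, got {self.n_frames}")
        if self.activation_amplitude <= 1.0:
            raise ConfigurationError(
                f"activation_amplitude must be > 1, got {self.activation_amplitude}"
            )
        if not 1.0 <= self.transient_amplitude <= self.activation_amplitude:
            raise ConfigurationError(
                "transient_amplitude must lie between 1 and activation_amplitude, "
                f"got {self.transient_amplitude}"
            )
        if not 0.0 < self.arrest_factor <= 1.0:
            raise ConfigurationError(
                f"arrest_factor must be in (0, 1], got {self.arrest_factor}"
            )
        for name in ("baseline_level", "frame_interval_s", "speed_free"):
            if getattr(self, name) < 0 or (name == "baseline_level" and getattr(self, name) == 0):
                raise ConfigurationError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("n_fov", "cells_per_fov", "transient_duration_frames",
                     "oscillation_period_frames", "ctfr_sample_count", "n_evaluators",
                     "fov_size_px"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.day_scale_cv < 0:
            raise ConfigurationError(f"day_scale_cv must be >= 0, got {self.day_scale_cv}")
        if self.amplitude_cv < 0:
            raise ConfigurationError(f"amplitude_cv must be >= 0, got {self.amplitude_cv}")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def amplitude_for(self, condition: str) -> float:
        """Sustained-activation fold change for a condition tag."""
        if condition == CONDITION_OVA:
            return self.activation_amplitude
        if condition in (CONDITION_GP33, CONDITION_AUTO):
            return self.gp33_amplitude
        raise ConfigurationError(f"unknown condition tag {condition!r}")


@dataclass
class GroundTruthCell:
    """Ground truth for one simulated cell.

    ``reactive`` is true when the trace contains an activation (specific
    cells) or transient (nonspecific cells) event; ``onset_frame`` is
    present iff reactive.
    """

    cell_id: str
    fov_id: str
    day_id: str
    genotype: str
    reactive: bool
    onset_frame: int | None
    condition: str
    ctfr_positive: bool = False

    def __post_init__(self) -> None:
        if self.genotype not in (GENOTYPE_SPECIFIC, GENOTYPE_NONSPECIFIC):
            raise ConfigurationError(f"unknown genotype {self.genotype!r}")
        if self.condition not in CONDITIONS:
            raise ConfigurationError(f"unknown condition {self.condition!r}")
        if self.reactive != (self.onset_frame is not None):
            raise ConfigurationError("onset_frame must be present iff reactive")


@dataclass
class CalciumTrace:
    """Per-cell 405/447 ratio time series (raw, optionally normalized)."""

    cell_id: str
    values: np.ndarray
    frames: np.ndarray | None = None
    normalized_values: np.ndarray | None = None
    usable: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.frames is None:
            self.frames = np.arange(self.values.size)
        else:
            self.frames = np.asarray(self.frames, dtype=int)

    @property
    def working_values(self) -> np.ndarray:
        """Normalized values when present, else raw values."""
        return self.values if self.normalized_values is None else self.normalized_values


@dataclass
class CellTrack:
    """Frame-indexed centroid positions of one tracked cell."""

    cell_id: str
    fov_id: str
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    diameter_px: float = 10.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("track frames must be strictly increasing")

    def __len__(self) -> int:
        return int(self.frames.size)


@dataclass
class FieldOfView:
    """One simulated time lapse: aligned traces, tracks and ground truth."""

    fov_id: str
    day_id: str
    condition: str
    ctfr_orientation: str               # which genotype carries the stain
    day_scale: float
    traces: list[CalciumTrace]
    tracks: list[CellTrack]
    truth: list[GroundTruthCell]
    votes: np.ndarray                   # [n_cells, n_evaluators] binary


@dataclass
class Dataset:
    """A multi-day, multi-condition collection of fields of view."""

    config: SimulationConfig
    fovs: list[FieldOfView]

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for fov in self.fovs:
            for cell in fov.truth:
                rows.append({
                    "cell_id": cell.cell_id, "fov_id": cell.fov_id,
                    "day_id": cell.day_id, "genotype": cell.genotype,
                    "reactive": cell.reactive,
                    "onset_frame": -1 if cell.onset_frame is None else cell.onset_frame,
                    "condition": cell.condition,
                    "ctfr_positive": cell.ctfr_positive,
                })
        return pd.DataFrame(rows)

    def all_traces(self) -> list[CalciumTrace]:
        return [t for fov in self.fovs for t in fov.traces]

    def all_tracks(self) -> list[CellTrack]:
        return [t for fov in self.fovs for t in fov.tracks]


# ---------------------------------------------------------------------------
# trace simulation
# ---------------------------------------------------------------------------

def _activation_profile(config: SimulationConfig, onset: int, amplitude: float) -> np.ndarray:
    """Sustained oscillating plateau from onset to the end of the movie.

    Oscillates between ``amplitude`` and ``amplitude * (1 - depth)`` fold
    change so the post-onset signal never falls below
    ``baseline * amplitude * (1 - depth)``.
    """
    n = config.n_frames
    profile = np.full(n, config.baseline_level)
    t = np.arange(n - onset)
    osc = 1.0 - config.oscillation_depth * 0.5 * (
        1.0 - np.cos(2.0 * np.pi * t / config.oscillation_period_frames)
    )
    profile[onset:] = config.baseline_level * amplitude * osc
    return profile


def simulate_trace(
    config: SimulationConfig,
    truth: GroundTruthCell,
    rng: np.random.Generator,
) -> CalciumTrace:
    """Simulate one cell's 405/447 ratio trace.

    Nonreactive cells fluctuate around the resting baseline. Reactive
    specific cells jump at ``onset_frame`` to a sustained oscillating
    plateau whose amplitude depends on the condition tag. Reactive
    nonspecific cells show a single square transient of intermediate
    amplitude. Gaussian noise of ``noise_sd`` is added throughout and the
    result is clamped to stay positive.
    """
    if truth.onset_frame is not None and not 0 <= truth.onset_frame < config.n_frames:
        raise ConfigurationError(
            f"onset_frame {truth.onset_frame} outside [0, {config.n_frames})"
        )
    base = np.full(config.n_frames, config.baseline_level)
    if truth.reactive:
        onset = int(truth.onset_frame)
        # cell-to-cell amplitude heterogeneity (real calcium responses vary widely)
        jitter = max(float(rng.normal(1.0, config.amplitude_cv)), 0.4) \
            if config.amplitude_cv > 0 else 1.0
        if truth.genotype == GENOTYPE_SPECIFIC:
            amp = max(config.amplitude_for(truth.condition) * jitter, 1.1)
            base = _activation_profile(config, onset, amp)
        else:
            amp = max(config.transient_amplitude * jitter, 1.1)
            end = min(onset + config.transient_duration_frames, config.n_frames)
            base[onset:end] = config.baseline_level * amp
    values = base + rng.normal(0.0, config.noise_sd, size=config.n_frames) \
        if config.noise_sd > 0 else base.copy()
    np.maximum(values, 1e-6, out=values)
    return CalciumTrace(cell_id=truth.cell_id, values=values)


def _simulate_track(
    config: SimulationConfig,
    cell_id: str,
    fov_id: str,
    start: np.ndarray,
    onset: int | None,
    rng: np.random.Generator,
) -> CellTrack:
    """Isotropic random walk with reflecting FOV bounds and arrest at onset."""
    n = config.n_frames
    margin = 8.0
    lo, hi = margin, config.fov_size_px - margin
    angles = rng.uniform(0.0, 2.0 * np.pi, size=n - 1)
    # Rayleigh step lengths (2-D isotropic diffusion) with mean speed_free
    steps = rng.rayleigh(config.speed_free / np.sqrt(np.pi / 2.0), size=n - 1)
    if onset is not None:
        steps[onset:] *= config.arrest_factor
    dx = steps * np.cos(angles)
    dy = steps * np.sin(angles)
    xs = np.empty(n)
    ys = np.empty(n)
    xs[0], ys[0] = start
    for i in range(1, n):
        x = xs[i - 1] + dx[i - 1]
        y = ys[i - 1] + dy[i - 1]
        # reflect at the FOV walls
        if x < lo:
            x = 2 * lo - x
        elif x > hi:
            x = 2 * hi - x
        if y < lo:
            y = 2 * lo - y
        elif y > hi:
            y = 2 * hi - y
        xs[i], ys[i] = x, y
    return CellTrack(cell_id=cell_id, fov_id=fov_id, frames=np.arange(n), x=xs, y=ys)


def _separate_positions(xy: np.ndarray, min_dist: float, lo: float, hi: float,
                        n_iter: int = 40) -> np.ndarray:
    """Push cell centres apart until pairwise distances exceed ``min_dist``.

    Simple excluded-volume relaxation; T cells do not interpenetrate, and
    well-separated cells keep the rendered movies unambiguous for the
    segmentation round trip.
    """
    xy = xy.copy()
    for _ in range(n_iter):
        diff = xy[:, None, :] - xy[None, :, :]
        dist = np.hypot(diff[..., 0], diff[..., 1])
        np.fill_diagonal(dist, np.inf)
        close = dist < min_dist
        if not close.any():
            break
        push = np.zeros_like(xy)
        with np.errstate(invalid="ignore"):
            overlap = np.where(close, (min_dist - dist) / np.maximum(dist, 1e-9), 0.0)
        push[:, 0] = (overlap * diff[..., 0]).sum(axis=1) * 0.6
        push[:, 1] = (overlap * diff[..., 1]).sum(axis=1) * 0.6
        xy += push
        np.clip(xy, lo, hi, out=xy)
    return xy


def _apply_separation(tracks: list[CellTrack], min_dist: float, lo: float, hi: float) -> None:
    """Relax all tracks frame by frame so cells keep an exclusion distance."""
    if not tracks:
        return
    n = len(tracks[0])
    xs = np.stack([t.x for t in tracks])
    ys = np.stack([t.y for t in tracks])
    offset = np.zeros((len(tracks), 2))
    for f in range(n):
        xy = np.stack([xs[:, f], ys[:, f]], axis=1) + offset
        relaxed = _separate_positions(xy, min_dist, lo, hi)
        # carry the displacement forward so trajectories stay smooth
        offset = relaxed - np.stack([xs[:, f], ys[:, f]], axis=1)
        xs[:, f], ys[:, f] = relaxed[:, 0], relaxed[:, 1]
    for i, t in enumerate(tracks):
        t.x = xs[i]
        t.y = ys[i]


def simulate_field_of_view(
    config: SimulationConfig,
    fov_id: str,
    day_id: str,
    rng: np.random.Generator,
    condition: str = CONDITION_OVA,
    ctfr_orientation: str = GENOTYPE_SPECIFIC,
    day_scale: float = 1.0,
    separate_cells: bool = False,
) -> FieldOfView:
    """Simulate one field of view: aligned traces, tracks, truth and votes.

    Genotypes are Bernoulli(``frac_specific``); reactive flags are drawn
    per genotype; evaluator votes flip the true reactive flag with
    ``evaluator_error_rate`` per evaluator. ``day_scale`` multiplies the
    resting baseline (inter-experiment drift). ``separate_cells`` enables
    the excluded-volume relaxation used before rendering movies.
    """
    local = config.replace(baseline_level=config.baseline_level * day_scale)
    n = config.cells_per_fov
    genotypes = np.where(rng.random(n) < config.frac_specific,
                         GENOTYPE_SPECIFIC, GENOTYPE_NONSPECIFIC)
    p_react = np.where(genotypes == GENOTYPE_SPECIFIC,
                       config.p_reactive_given_specific,
                       config.p_transient_given_nonspecific)
    reactive = rng.random(n) < p_react
    onset_hi = max(1, int(config.onset_fraction * config.n_frames))
    onsets = rng.integers(0, onset_hi, size=n)
    margin = 10.0
    starts = rng.uniform(margin, config.fov_size_px - margin, size=(n, 2))

    truth, traces, tracks = [], [], []
    for i in range(n):
        cell_id = f"{fov_id}_c{i:04d}"
        cell = GroundTruthCell(
            cell_id=cell_id, fov_id=fov_id, day_id=day_id,
            genotype=str(genotypes[i]), reactive=bool(reactive[i]),
            onset_frame=int(onsets[i]) if reactive[i] else None,
            condition=condition,
            ctfr_positive=(genotypes[i] == ctfr_orientation),
        )
        truth.append(cell)
        traces.append(simulate_trace(local, cell, rng))
        tracks.append(_simulate_track(config, cell_id, fov_id, starts[i],
                                      cell.onset_frame, rng))
    if separate_cells:
        _apply_separation(tracks, min_dist=12.0, lo=8.0, hi=config.fov_size_px - 8.0)

    flips = rng.random((n, config.n_evaluators)) < config.evaluator_error_rate
    votes = (reactive[:, None] ^ flips).astype(int)
    return FieldOfView(
        fov_id=fov_id, day_id=day_id, condition=condition,
        ctfr_orientation=ctfr_orientation, day_scale=day_scale,
        traces=traces, tracks=tracks, truth=truth, votes=votes,
    )


def simulate_dataset(
    config: SimulationConfig,
    n_days: int = 1,
    conditions: Sequence[str] = (CONDITION_OVA,),
    separate_cells: bool = False,
) -> Dataset:
    """Simulate a multi-day dataset.

    FOVs are spread evenly over ``n_days``; each day draws an independent
    multiplicative baseline scale with coefficient of variation
    ``day_scale_cv`` (this is exactly the drift that fold-change
    normalization should remove). Condition tags cycle across FOVs, and a
    CTFR-orientation tag alternates so that both staining orientations are
    represented.
    """
    if n_days < 1:
        raise ConfigurationError(f"n_days must be >= 1, got {n_days}")
    for c in conditions:
        if c not in CONDITIONS:
            raise ConfigurationError(f"unknown condition {c!r}")
    rng = np.random.default_rng(config.seed)
    day_scales = (
        np.maximum(rng.normal(1.0, config.day_scale_cv, size=n_days), 0.2)
        if config.day_scale_cv > 0 else np.ones(n_days)
    )
    fovs = []
    for k in range(config.n_fov):
        day = k % n_days
        condition = conditions[k % len(conditions)]
        orientation = GENOTYPE_SPECIFIC if k % 2 == 0 else GENOTYPE_NONSPECIFIC
        fovs.append(simulate_field_of_view(
            config, fov_id=f"fov{k:03d}", day_id=f"day{day:02d}", rng=rng,
            condition=condition, ctfr_orientation=orientation,
            day_scale=float(day_scales[day]), separate_cells=separate_cells,
        ))
    return Dataset(config=config, fovs=fovs)


# ---------------------------------------------------------------------------
# movie rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RenderParams:
    """Rendering parameters for synthetic two-channel movies."""

    cell_diameter_px: float = 10.0
    intensity_447: float = 200.0        # per-pixel 447 nm brightness inside a cell
    intensity_447_cv: float = 0.1       # per-cell brightness variation
    background: float = 20.0
    read_noise_sd: float = 2.0
    ctfr_intensity: float = 150.0
    density_warn_fraction: float = 0.02  # warn above this overlapping-pixel fraction


def render_movie(
    fov: FieldOfView,
    params: RenderParams = RenderParams(),
    image_size: int | None = None,
    ctfr_sample_count: int = 12,
    rng: np.random.Generator | None = None,
) -> dict:
    """Render a field of view as a two-channel image stack plus sparse CTFR.

    Each cell is drawn as a uniform disk: the 447 nm channel carries a
    per-cell constant brightness, the 405 nm channel carries that
    brightness multiplied by the trace value (so the background-subtracted
    405/447 ratio of the rendered cell equals the simulated trace). A
    constant additive background and Gaussian read noise complete the
    image. The CTFR channel is nonzero only inside CTFR-positive cells and
    only at ``ctfr_sample_count`` evenly spaced frames.

    Returns a dict with ``frames_405``, ``frames_447`` (float32,
    [n_frames, H, W]), ``ctfr_frames``, ``ctfr_frame_indices``.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    n_frames = len(fov.tracks[0]) if fov.tracks else 0
    size = int(image_size) if image_size else (
        int(max(t.x.max() for t in fov.tracks) + 20) if fov.tracks else 64
    )
    radius = params.cell_diameter_px / 2.0
    n_cells = len(fov.tracks)
    brightness = params.intensity_447 * np.maximum(
        rng.normal(1.0, params.intensity_447_cv, size=n_cells), 0.2
    ) if n_cells else np.empty(0)

    for t in fov.tracks:
        if np.any(t.x < 0) or np.any(t.x >= size) or np.any(t.y < 0) or np.any(t.y >= size):
            raise ValueError(f"track {t.cell_id} leaves the {size}x{size} image bounds")

    ctfr_idx = np.unique(np.linspace(0, n_frames - 1, ctfr_sample_count).round().astype(int)) \
        if n_frames else np.empty(0, dtype=int)
    f405 = np.empty((n_frames, size, size), dtype=np.float32)
    f447 = np.empty((n_frames, size, size), dtype=np.float32)
    ctfr = np.empty((ctfr_idx.size, size, size), dtype=np.float32)
    yy, xx = np.mgrid[0:size, 0:size]

    overlap_frames = 0
    ctfr_pos = [t.ctfr_positive for t in fov.truth] if fov.truth else []
    for f in range(n_frames):
        img405 = np.full((size, size), params.background, dtype=np.float64)
        img447 = np.full((size, size), params.background, dtype=np.float64)
        cover = np.zeros((size, size), dtype=np.int16)
        ctfr_img = None
        in_ctfr = f in ctfr_idx
        if in_ctfr:
            ctfr_img = np.full((size, size), params.background, dtype=np.float64)
        for i, track in enumerate(fov.tracks):
            cx, cy = track.x[f], track.y[f]
            x0, x1 = max(0, int(cx - radius - 2)), min(size, int(cx + radius + 3))
            y0, y1 = max(0, int(cy - radius - 2)), min(size, int(cy + radius + 3))
            mask = ((xx[y0:y1, x0:x1] - cx) ** 2 + (yy[y0:y1, x0:x1] - cy) ** 2) <= radius ** 2
            img447[y0:y1, x0:x1][mask] += brightness[i]
            img405[y0:y1, x0:x1][mask] += brightness[i] * fov.traces[i].values[f]
            cover[y0:y1, x0:x1][mask] += 1
            if in_ctfr and ctfr_pos and ctfr_pos[i]:
                ctfr_img[y0:y1, x0:x1][mask] += params.ctfr_intensity
        n_overlap = int((cover > 1).sum())
        if n_cells and n_overlap > params.density_warn_fraction * np.pi * radius ** 2 * n_cells:
            overlap_frames += 1
        if params.read_noise_sd > 0:
            img405 += rng.normal(0.0, params.read_noise_sd, img405.shape)
            img447 += rng.normal(0.0, params.read_noise_sd, img447.shape)
        f405[f] = img405
        f447[f] = img447
        if in_ctfr:
            if params.read_noise_sd > 0:
                ctfr_img += rng.normal(0.0, params.read_noise_sd, ctfr_img.shape)
            ctfr[np.searchsorted(ctfr_idx, f)] = ctfr_img
    if overlap_frames:
        warnings.warn(
            f"{fov.fov_id}: cell overlap above density limit in {overlap_frames} frames",
            stacklevel=2,
        )
        logger.warning("%s: dense cell overlap in %d frames", fov.fov_id, overlap_frames)
    return {
        "frames_405": f405,
        "frames_447": f447,
        "ctfr_frames": ctfr,
        "ctfr_frame_indices": ctfr_idx,
    }


# ---------------------------------------------------------------------------
# CSV / TIFF export
# ---------------------------------------------------------------------------

def traces_to_frame(traces: Sequence[CalciumTrace]) -> pd.DataFrame:
    """Long-format (cell_id, frame, ratio) table of raw trace values."""
    parts = [
        pd.DataFrame({"cell_id": t.cell_id, "frame": t.frames, "ratio": t.values})
        for t in traces
    ]
    return pd.concat(parts, ignore_index=True) if parts else \
        pd.DataFrame(columns=["cell_id", "frame", "ratio"])


def tracks_to_frame(tracks: Sequence[CellTrack]) -> pd.DataFrame:
    parts = [
        pd.DataFrame({"cell_id": t.cell_id, "frame": t.frames, "x": t.x, "y": t.y})
        for t in tracks
    ]
    return pd.concat(parts, ignore_index=True) if parts else \
        pd.DataFrame(columns=["cell_id", "frame", "x", "y"])


def write_dataset(dataset: Dataset, outdir, render: bool = False,
                  render_params: RenderParams = RenderParams()) -> dict:
    """Write a dataset directory: truth/traces/tracks/votes/fovs CSVs.

    With ``render=True`` each FOV additionally gets a channel-interleaved
    multi-page TIFF (405 then 447 per frame) plus a CTFR TIFF.
    """
    import tifffile
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.truth_frame().to_csv(outdir / "truth.csv", index=False)
    traces_to_frame(dataset.all_traces()).to_csv(outdir / "traces.csv", index=False)
    tracks_to_frame(dataset.all_tracks()).to_csv(outdir / "tracks.csv", index=False)
    vote_rows = []
    for fov in dataset.fovs:
        for cell, votes in zip(fov.truth, fov.votes):
            row = {"cell_id": cell.cell_id}
            row.update({f"evaluator_{j}": int(v) for j, v in enumerate(votes)})
            vote_rows.append(row)
    pd.DataFrame(vote_rows).to_csv(outdir / "votes.csv", index=False)
    pd.DataFrame([
        {"fov_id": f.fov_id, "day_id": f.day_id, "condition": f.condition,
         "ctfr_orientation": f.ctfr_orientation, "day_scale": f.day_scale}
        for f in dataset.fovs
    ]).to_csv(outdir / "fovs.csv", index=False)
    written = {"truth": "truth.csv", "traces": "traces.csv",
               "tracks": "tracks.csv", "votes": "votes.csv", "fovs": "fovs.csv"}
    if render:
        rng = np.random.default_rng(dataset.config.seed + 1)
        for fov in dataset.fovs:
            movie = render_movie(fov, render_params,
                                 image_size=dataset.config.fov_size_px,
                                 ctfr_sample_count=dataset.config.ctfr_sample_count,
                                 rng=rng)
            stack = np.empty((2 * movie["frames_405"].shape[0],) + movie["frames_405"].shape[1:],
                             dtype=np.float32)
            stack[0::2] = movie["frames_405"]
            stack[1::2] = movie["frames_447"]
            tifffile.imwrite(outdir / f"{fov.fov_id}_indo1.tif", stack)
            tifffile.imwrite(outdir / f"{fov.fov_id}_ctfr.tif", movie["ctfr_frames"])
            np.savetxt(outdir / f"{fov.fov_id}_ctfr_frames.csv",
                       movie["ctfr_frame_indices"], fmt="%d")
            written[fov.fov_id] = f"{fov.fov_id}_indo1.tif"
    return written
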