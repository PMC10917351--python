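"""From two-channel ratiometric movies to per-cell calcium traces.

Implements the in silico analysis stages for Indo-1 time lapses:

1. per-frame cell segmentation on the sum of both emission channels
   (edge-aware watershed),
2. frame-to-frame greedy nearest-neighbour particle linking,
3. track-length filtering (at least half the movie),
4. disk-integrated, locally background-subtracted 405/447 ratio
   extraction, and
5. genotype assignment by voting over sparse vital-dye (CTFR) samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian, sobel, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .synthetic import CalciumTrace, CellTrack

logger = logging.getLogger("catrace")

GENOTYPE_POSITIVE = "positive_stain"
GENOTYPE_NEGATIVE = "negative_stain"
GENOTYPE_UNASSIGNED = "unassigned"

#: minimum number of agreeing CTFR samples required for a genotype call
MIN_AGREEING_SAMPLES = 8


@dataclass
class MovieStack:
    """Two-channel Indo-1 movie plus a sparse vital-dye stack.

    ``frames_405``/``frames_447`` are [n_frames, H, W]; ``ctfr_frames``
    holds only the sampled frames, indexed by ``ctfr_frame_indices``.
    """

    frames_405: np.ndarray
    frames_447: np.ndarray
    ctfr_frames: np.ndarray | None = None
    ctfr_frame_indices: np.ndarray | None = None
    frame_interval_s: float = 30.0
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        if self.frames_405.shape != self.frames_447.shape:
            raise ValueError("405 and 447 stacks must share shape")
        if self.ctfr_frame_indices is not None:
            idx = np.asarray(self.ctfr_frame_indices)
            if np.any(np.diff(idx) <= 0):
                raise ValueError("ctfr frame indices must be strictly increasing")
            if idx.size and (idx[0] < 0 or idx[-1] >= self.n_frames):
                raise ValueError("ctfr frame indices out of range")

    @property
    def n_frames(self) -> int:
        return int(self.frames_405.shape[0])

    @classmethod
    def from_tiff(cls, indo1_path, ctfr_path=None, ctfr_index_path=None,
                  frame_interval_s: float = 30.0, channel_order: str = "405_first"):
        """Read a channel-interleaved multi-page TIFF (405/447 per frame)."""
        import tifffile

        stack = tifffile.imread(indo1_path).astype(np.float32)
        if channel_order == "405_first":
            f405, f447 = stack[0::2], stack[1::2]
        elif channel_order == "447_first":
            f447, f405 = stack[0::2], stack[1::2]
        else:
            raise ValueError(f"unknown channel_order {channel_order!r}")
        ctfr = ctfr_idx = None
        if ctfr_path is not None:
            ctfr = tifffile.imread(ctfr_path).astype(np.float32)
            if ctfr.ndim == 2:
                ctfr = ctfr[None]
            if ctfr_index_path is not None:
                ctfr_idx = np.loadtxt(ctfr_index_path, dtype=int, ndmin=1)
        return cls(frames_405=f405, frames_447=f447, ctfr_frames=ctfr,
                   ctfr_frame_indices=ctfr_idx, frame_interval_s=frame_interval_s)


@dataclass
class Detection:
    """One segmented cell in one frame."""

    x: float
    y: float
    diameter_px: float


@dataclass
class GenotypeCall:
    """Dye-based genotype call from sparse CTFR samples."""

    cell_id: str
    call: str
    n_positive_samples: int
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_positive_samples > self.n_samples:
            raise ValueError("n_positive_samples cannot exceed n_samples")


@dataclass(frozen=True)
class SegmentationParams:
    smoothing_sigma: float = 1.5
    min_area_px: int = 20
    max_area_px: int = 400
    min_marker_distance_px: int = 5


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_frame(sum_image: np.ndarray,
                  params: SegmentationParams = SegmentationParams()) -> list[Detection]:
    """Detect cells in the summed (405 + 447) image of one frame.

    Gaussian smoothing, a gradient-magnitude edge map, Otsu foreground
    thresholding, distance-transform markers and a watershed split of
    touching cells; detected objects outside the configured area bounds
    are rejected. A flat or empty image yields an empty list.
    """
    img = np.asarray(sum_image, dtype=float)
    if img.size == 0 or np.ptp(img) <= 1e-12:
        return []
    smooth = gaussian(img, sigma=params.smoothing_sigma, preserve_range=True)
    edges = sobel(smooth)
    try:
        thr = threshold_otsu(smooth)
    except ValueError:
        return []
    foreground = smooth > thr
    if not foreground.any():
        return []
    distance = ndimage.distance_transform_edt(foreground)
    peaks = peak_local_max(distance, min_distance=params.min_marker_distance_px,
                           labels=foreground, exclude_border=False)
    if peaks.size == 0:
        return []
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, peaks.shape[0] + 1)
    labels = watershed(edges, markers=markers, mask=foreground)
    detections = []
    for region in regionprops(labels):
        if not params.min_area_px <= region.area <= params.max_area_px:
            continue
        cy, cx = region.centroid
        detections.append(Detection(x=float(cx), y=float(cy),
                                    diameter_px=float(region.equivalent_diameter_area)))
    return detections


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------

def link_tracks(detections_per_frame: list[list[Detection]],
                max_displacement_px: float,
                fov_id: str = "fov") -> list[CellTrack]:
    """Link per-frame detections into trajectories.

    Greedy mutual-nearest-neighbour assignment between consecutive frames:
    candidate pairs are sorted by distance and accepted while both ends
    are free and the distance is below ``max_displacement_px``; ties are
    broken by the lower track index. Unmatched detections start new
    tracks; tracks end when unmatched (no gap closing).
    """
    open_tracks: list[dict] = []       # {"frames": [...], "x": [...], "y": [...], "d": [...]}
    closed: list[dict] = []

    for frame, detections in enumerate(detections_per_frame):
        if frame == 0 or not open_tracks:
            still_open = []
        else:
            pairs = []
            for ti, track in enumerate(open_tracks):
                tx, ty = track["x"][-1], track["y"][-1]
                for di, det in enumerate(detections):
                    d = math.hypot(det.x - tx, det.y - ty)
                    if d <= max_displacement_px:
                        pairs.append((d, ti, di))
            pairs.sort(key=lambda p: (p[0], p[1], p[2]))
            used_t: set[int] = set()
            used_d: set[int] = set()
            match: dict[int, int] = {}
            for d, ti, di in pairs:
                if ti in used_t or di in used_d:
                    continue
                used_t.add(ti)
                used_d.add(di)
                match[di] = ti
            still_open = []
            for ti, track in enumerate(open_tracks):
                if ti in used_t:
                    still_open.append(track)
                else:
                    closed.append(track)
            for di, det in enumerate(detections):
                if di in match:
                    track = open_tracks[match[di]]
                    track["frames"].append(frame)
                    track["x"].append(det.x)
                    track["y"].append(det.y)
                    track["d"].append(det.diameter_px)
            open_tracks = [open_tracks[ti] for ti in sorted(used_t)]
            detections = [det for di, det in enumerate(detections) if di not in match]
        for det in detections:
            open_tracks.append({"frames": [frame], "x": [det.x], "y": [det.y],
                                "d": [det.diameter_px]})
    closed.extend(open_tracks)
    closed.sort(key=lambda t: (t["frames"][0], t["x"][0], t["y"][0]))
    return [
        CellTrack(cell_id=f"{fov_id}_t{i:04d}", fov_id=fov_id,
                  frames=np.array(t["frames"]), x=np.array(t["x"]), y=np.array(t["y"]),
                  diameter_px=float(np.median(t["d"])))
        for i, t in enumerate(closed)
    ]


def filter_tracks(tracks: list[CellTrack], n_frames: int) -> list[CellTrack]:
    """Keep tracks spanning at least half of the movie duration.

    The cutoff is ``ceil(n_frames / 2)`` tracked frames; dropping shorter
    fragments ensures every retained cell in a time lapse is independent
    (a cell lost and re-found would otherwise appear twice).
    """
    cutoff = math.ceil(n_frames / 2)
    return [t for t in tracks if len(t) >= cutoff]


# ---------------------------------------------------------------------------
# trace extraction
# ---------------------------------------------------------------------------

#: measurement disk diameter as a fraction of the cell diameter
DISK_FRACTION = 0.6
#: local-background annulus, in units of the cell radius
ANNULUS_INNER = 1.1
ANNULUS_OUTER = 1.6
#: floor on the background-subtracted 447 nm denominator
DENOMINATOR_FLOOR = 1e-3
#: traces with more than this fraction of flagged frames are unusable
MAX_FLAGGED_FRACTION = 0.10


def _disk_mask(shape, cx, cy, radius, xx, yy):
    x0, x1 = max(0, int(cx - radius - 2)), min(shape[1], int(cx + radius + 3))
    y0, y1 = max(0, int(cy - radius - 2)), min(shape[0], int(cy + radius + 3))
    sub = ((xx[y0:y1, x0:x1] - cx) ** 2 + (yy[y0:y1, x0:x1] - cy) ** 2) <= radius ** 2
    return (slice(y0, y1), slice(x0, x1)), sub


def extract_trace(movie: MovieStack, track: CellTrack,
                  other_tracks: list[CellTrack] | None = None) -> CalciumTrace:
    """Extract the background-subtracted 405/447 ratio along one track.

    Per tracked frame, both channels are integrated over a disk of 60% of
    the cell's diameter centred on the centroid; a local background — the
    per-channel median over an annulus from 1.1x to 1.6x the cell radius,
    excluding pixels inside other cells' disks — is subtracted from the
    per-pixel mean before forming the ratio. Frames whose denominator
    falls below a small positive floor are flagged and imputed from the
    nearest clean neighbours; a trace with more than 10% flagged frames is
    marked unusable.
    """
    h, w = movie.frames_405.shape[1:]
    yy, xx = np.mgrid[0:h, 0:w]
    disk_r = DISK_FRACTION * track.diameter_px / 2.0
    cell_r = track.diameter_px / 2.0
    values = np.empty(len(track))
    flagged = np.zeros(len(track), dtype=bool)

    others = other_tracks or []
    other_pos = {}
    for ot in others:
        if ot.cell_id == track.cell_id:
            continue
        for f, x, y in zip(ot.frames, ot.x, ot.y):
            other_pos.setdefault(int(f), []).append((x, y, ot.diameter_px / 2.0))

    for i, (f, cx, cy) in enumerate(zip(track.frames, track.x, track.y)):
        if not (0 <= cx < w and 0 <= cy < h):
            raise ValueError(f"track {track.cell_id} outside image at frame {f}")
        sl, disk = _disk_mask((h, w), cx, cy, disk_r, xx, yy)
        img405 = movie.frames_405[f]
        img447 = movie.frames_447[f]
        dx = xx - cx
        dy = yy - cy
        r2 = dx * dx + dy * dy
        annulus = (r2 >= (ANNULUS_INNER * cell_r) ** 2) & (r2 <= (ANNULUS_OUTER * cell_r) ** 2)
        for ox, oy, orad in other_pos.get(int(f), []):
            if (ox - cx) ** 2 + (oy - cy) ** 2 < (ANNULUS_OUTER * cell_r + orad) ** 2:
                annulus &= ((xx - ox) ** 2 + (yy - oy) ** 2) > (orad * 1.2) ** 2
        if not annulus.any():
            annulus = (r2 >= (ANNULUS_INNER * cell_r) ** 2) & \
                      (r2 <= (2.5 * cell_r) ** 2)
        bg405 = float(np.median(img405[annulus]))
        bg447 = float(np.median(img447[annulus]))
        mean405 = float(img405[sl][disk].mean())
        mean447 = float(img447[sl][disk].mean())
        denom = mean447 - bg447
        if denom <= DENOMINATOR_FLOOR:
            flagged[i] = True
            values[i] = np.nan
        else:
            values[i] = (mean405 - bg405) / denom

    if flagged.any() and not flagged.all():
        good = np.where(~flagged)[0]
        bad = np.where(flagged)[0]
        values[bad] = np.interp(bad, good, values[good])
    usable = flagged.mean() <= MAX_FLAGGED_FRACTION and not flagged.all()
    if not usable:
        logger.warning("trace %s unusable: %.0f%% flagged frames",
                       track.cell_id, 100 * flagged.mean())
    values = np.maximum(values, 1e-6)
    return CalciumTrace(cell_id=track.cell_id, values=values,
                        frames=track.frames.copy(), usable=bool(usable))


# ---------------------------------------------------------------------------
# genotype assignment
# ---------------------------------------------------------------------------

def assign_genotype(ctfr_intensities: np.ndarray, positivity_threshold: float,
                    cell_id: str = "cell") -> GenotypeCall:
    """Call a genotype from sparse vital-dye intensity samples.

    A sample is positive when its intensity exceeds the threshold; the
    stain call requires at least eight agreeing samples in either
    direction, otherwise the cell is left unassigned.
    """
    intensities = np.asarray(ctfr_intensities, dtype=float)
    if intensities.size == 0:
        raise ValueError("need at least one CTFR sample")
    n_pos = int((intensities > positivity_threshold).sum())
    n = int(intensities.size)
    if n_pos >= MIN_AGREEING_SAMPLES:
        call = GENOTYPE_POSITIVE
    elif n - n_pos >= MIN_AGREEING_SAMPLES:
        call = GENOTYPE_NEGATIVE
    else:
        call = GENOTYPE_UNASSIGNED
    return GenotypeCall(cell_id=cell_id, call=call, n_positive_samples=n_pos, n_samples=n)


def ctfr_intensities_for_track(movie: MovieStack, track: CellTrack) -> np.ndarray:
    """Mean background-subtracted CTFR intensity in the cell disk per sample."""
    if movie.ctfr_frames is None or movie.ctfr_frame_indices is None:
        raise ValueError("movie carries no CTFR stack")
    h, w = movie.ctfr_frames.shape[1:]
    yy, xx = np.mgrid[0:h, 0:w]
    disk_r = DISK_FRACTION * track.diameter_px / 2.0
    cell_r = track.diameter_px / 2.0
    out = []
    frame_set = {int(f): i for i, f in enumerate(track.frames)}
    for k, f in enumerate(movie.ctfr_frame_indices):
        if int(f) not in frame_set:
            continue
        i = frame_set[int(f)]
        cx, cy = track.x[i], track.y[i]
        sl, disk = _disk_mask((h, w), cx, cy, disk_r, xx, yy)
        img = movie.ctfr_frames[k]
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        annulus = (r2 >= (ANNULUS_INNER * cell_r) ** 2) & (r2 <= (ANNULUS_OUTER * cell_r) ** 2)
        bg = float(np.median(img[annulus])) if annulus.any() else 0.0
        out.append(float(img[sl][disk].mean()) - bg)
    return np.asarray(out)


def otsu_ctfr_threshold(per_cell_intensities: np.ndarray) -> float:
    """Two-class Otsu threshold on pooled per-cell CTFR intensities."""
    values = np.asarray(per_cell_intensities, dtype=float).ravel()
    if values.size < 2 or np.ptp(values) <= 1e-12:
        return float(values.mean()) if values.size else 0.0
    return float(threshold_otsu(values))


def process_movie(movie: MovieStack, fov_id: str = "fov",
                  max_displacement_px: float = 8.0,
                  seg_params: SegmentationParams = SegmentationParams()
                  ) -> tuple[list[CellTrack], list[CalciumTrace], list[GenotypeCall]]:
    """Full imaging pass: segment, link, filter, extract, call genotypes."""
    detections = [
        segment_frame(movie.frames_405[f].astype(float) + movie.frames_447[f].astype(float),
                      seg_params)
        for f in range(movie.n_frames)
    ]
    tracks = filter_tracks(link_tracks(detections, max_displacement_px, fov_id),
                           movie.n_frames)
    traces = [extract_trace(movie, t, other_tracks=tracks) for t in tracks]
    calls: list[GenotypeCall] = []
    if movie.ctfr_frames is not None and movie.ctfr_frames.size:
        per_cell = [ctfr_intensities_for_track(movie, t) for t in tracks]
        pooled = np.concatenate([p for p in per_cell if p.size]) if per_cell else np.empty(0)
        thr = otsu_ctfr_threshold(pooled)
        calls = [assign_genotype(p, thr, cell_id=t.cell_id)
                 for t, p in zip(tracks, per_cell) if p.size]
    return tracks, traces, calls
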