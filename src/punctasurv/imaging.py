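"""Segmentation, tracking, death calling and per-ROI reporter statistics.

Somata are segmented on the constitutive tracking channel (cell fill), so the
ROI pixel set is independent of how the reporter distributes within the cell;
reporter statistics (mean, sd, CV) are then measured on the same pixel set.
Tracks are built by greedy mutual-nearest-neighbour linking between
consecutive timepoints, and death is called from loss (or collapse) of
tracking-channel signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .exceptions import UndefinedCVError

__all__ = [
    "Movie",
    "ROI",
    "Track",
    "SegmentationParams",
    "DeathParams",
    "subtract_background",
    "compute_cv",
    "segment_frame",
    "link_tracks",
    "call_death",
    "process_movie",
    "tracks_to_dataframe",
]

TRACKING, REPORTER = 0, 1


@dataclass
class Movie:
    """A two-channel time-lapse stack.

    ``pixels`` has shape (T, C, H, W) with C = 2: channel 0 is the tracking
    (cell fill) channel, channel 1 the reporter channel. ``times`` holds the
    acquisition time of each frame in hours.
    """

    pixels: np.ndarray
    times: np.ndarray
    channel_names: tuple[str, str] = ("tracking", "reporter")
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.times = np.asarray(self.times, dtype=float)
        if self.pixels.ndim != 4 or self.pixels.shape[1] != 2:
            raise ValueError(
                f"movie pixels must have shape (T, 2, H, W), got {self.pixels.shape}"
            )
        if self.times.shape != (self.pixels.shape[0],):
            raise ValueError("times must have one entry per frame")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.pixels.astype(float))):
            raise ValueError("movie intensities must be finite")
        if np.any(self.pixels.astype(float) < 0):
            raise ValueError("movie intensities must be >= 0")

    @property
    def n_timepoints(self) -> int:
        return self.pixels.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.pixels.shape[2], self.pixels.shape[3]


@dataclass
class ROI:
    """One segmented soma at one timepoint.

    Coordinates are 0-based (row, col) pixel indices. ``mean``/``sd``/``cv``
    are computed from the background-subtracted reporter channel over the ROI
    pixel set; ``cv`` is NaN when undefined (non-positive mean).
    """

    roi_id: int
    timepoint: int  # 0-based frame index
    coords: np.ndarray  # (n_pixels, 2) array of (row, col)
    centroid: tuple[float, float]  # (row, col)
    area: int
    mean: float
    sd: float
    cv: float
    tracking_mean: float


@dataclass
class Track:
    """One neuron's linked ROIs across timepoints.

    ``rois`` is a contiguous run starting at ``first_timepoint`` (0-based
    frame index). After death calling, ``death_interval`` is the 1-based
    timepoint at which the neuron was first scored dead, or None with
    ``censored=True`` if it survived through the last frame.
    """

    neuron_id: int
    rois: list[ROI] = field(default_factory=list)
    first_timepoint: int = 0
    death_interval: int | None = None
    censored: bool = False

    @property
    def last_observed(self) -> int:
        """0-based index of the last frame with an ROI."""
        return self.first_timepoint + len(self.rois) - 1

    def roi_at(self, timepoint: int) -> ROI | None:
        i = timepoint - self.first_timepoint
        if 0 <= i < len(self.rois):
            return self.rois[i]
        return None


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters for per-frame soma segmentation.

    ``min_area``/``max_area`` bound accepted connected components (pixels).
    The global threshold is Otsu's, floored at ``noise_floor_sigma`` robust
    noise standard deviations so blank frames yield no objects.
    """

    min_area: int = 30
    max_area: int = 600
    noise_floor_sigma: float = 4.0


@dataclass(frozen=True)
class DeathParams:
    """Death-calling rule: a neuron is dead at the first timepoint where its
    ROI is absent, or present with mean tracking intensity below
    ``death_fraction`` of its first-timepoint value."""

    death_fraction: float = 0.2


def subtract_background(frame: np.ndarray) -> np.ndarray:
    """Subtract a scalar background estimate (the frame median), clip at 0.

    The median is a robust background estimator for frames dominated by
    background with sparse bright objects.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame must be finite")
    if np.any(frame < 0):
        raise ValueError("frame must be non-negative")
    return np.clip(frame - np.median(frame), 0.0, None)


def compute_cv(values: np.ndarray) -> float:
    """Coefficient of variation: population standard deviation / mean.

    The population (divide-by-N) standard deviation is used; this convention
    must be fixed for the CV = 1.0 aggregate threshold to be reproducible.

    Raises
    ------
    UndefinedCVError
        If fewer than two pixels are given or the mean is not positive.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise UndefinedCVError(f"CV requires >= 2 pixels, got {values.size}")
    m = float(values.mean())
    if m <= 0:
        raise UndefinedCVError(f"CV undefined for non-positive mean ({m})")
    return float(values.std(ddof=0) / m)


def _robust_noise_sigma(frame: np.ndarray) -> float:
    """Noise scale of a background-subtracted frame.

    After median subtraction and clipping at zero, roughly half the
    background pixels are zero; for N(0, sigma) noise the 84.13th percentile
    of the clipped values equals sigma. Valid while objects cover a small
    fraction of the frame.
    """
    return float(np.percentile(frame, 84.134))


def segment_frame(
    tracking_frame: np.ndarray,
    reporter_frame: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    timepoint: int = 0,
) -> list[ROI]:
    """Segment somata on a background-subtracted tracking frame.

    Connected components (8-connectivity) of pixels above
    max(Otsu threshold, noise floor), filtered to
    ``min_area <= area <= max_area``. Reporter statistics are measured on the
    background-subtracted reporter frame over each component's pixel set.
    Two somata closer than one pixel merge into a single component; this is
    documented behaviour, not an error.
    """
    tracking_frame = np.asarray(tracking_frame, dtype=float)
    reporter_frame = np.asarray(reporter_frame, dtype=float)
    if tracking_frame.shape != reporter_frame.shape:
        raise ValueError("tracking and reporter frames must share a shape")
    if tracking_frame.max() <= tracking_frame.min():
        return []  # constant frame: nothing to segment
    try:
        otsu = float(threshold_otsu(tracking_frame))
    except ValueError:
        return []
    thr = max(otsu, params.noise_floor_sigma * _robust_noise_sigma(tracking_frame))
    mask = tracking_frame > thr
    labels = label(mask, connectivity=2)
    rois: list[ROI] = []
    rid = 0
    for prop in regionprops(labels):
        if not params.min_area <= prop.area <= params.max_area:
            continue
        coords = prop.coords
        rep = reporter_frame[coords[:, 0], coords[:, 1]]
        trk = tracking_frame[coords[:, 0], coords[:, 1]]
        mean = float(rep.mean())
        sd = float(rep.std(ddof=0))
        try:
            cv = compute_cv(rep)
        except UndefinedCVError:
            cv = float("nan")
        rois.append(
            ROI(
                roi_id=rid,
                timepoint=timepoint,
                coords=coords,
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                area=int(prop.area),
                mean=mean,
                sd=sd,
                cv=cv,
                tracking_mean=float(trk.mean()),
            )
        )
        rid += 1
    return rois


def _mutual_nearest_pairs(
    a: Sequence[ROI], b: Sequence[ROI], max_displacement: float
) -> list[tuple[int, int]]:
    """Mutual-nearest-neighbour pairs (index_a, index_b) within range.

    Ties in distance are broken toward the smaller roi_id, making linking
    deterministic.
    """
    if not a or not b:
        return []
    ca = np.array([r.centroid for r in a])
    cb = np.array([r.centroid for r in b])
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
    # argmin takes the first index on ties, i.e. the smaller roi_id
    nn_ab = d.argmin(axis=1)
    nn_ba = d.argmin(axis=0)
    pairs = []
    for i, j in enumerate(nn_ab):
        if nn_ba[j] == i and d[i, j] <= max_displacement:
            pairs.append((i, int(j)))
    return pairs


def link_tracks(
    rois_by_timepoint: Sequence[Sequence[ROI]],
    max_displacement: float = 15.0,
) -> list[Track]:
    """Link per-frame ROIs into tracks by greedy mutual nearest neighbours.

    Only ROIs present at the first timepoint seed tracks (neurons appearing
    later are not analyzed); a track ends at the first frame without a
    mutual-nearest match within ``max_displacement`` pixels. Each ROI joins
    at most one track.
    """
    if not rois_by_timepoint:
        return []
    tracks = [
        Track(neuron_id=i, rois=[roi], first_timepoint=0)
        for i, roi in enumerate(rois_by_timepoint[0])
    ]
    # live[j] = index of track currently ending in ROI j of the previous frame
    live = {i: i for i in range(len(tracks))}
    for t in range(1, len(rois_by_timepoint)):
        prev = rois_by_timepoint[t - 1]
        curr = rois_by_timepoint[t]
        pairs = _mutual_nearest_pairs(prev, curr, max_displacement)
        new_live: dict[int, int] = {}
        for i, j in pairs:
            if i in live:
                tracks[live[i]].rois.append(curr[j])
                new_live[j] = live[i]
        live = new_live
    return tracks


def call_death(
    track: Track,
    n_timepoints: int,
    params: DeathParams = DeathParams(),
) -> Track:
    """Annotate a track with its death interval or censoring status.

    The death interval is the first 1-based timepoint at which the neuron's
    ROI is absent, or present with mean tracking intensity below
    ``death_fraction`` of its timepoint-1 value. A neuron observed alive at
    every timepoint is censored at the last one.

    Raises
    ------
    ValueError
        If the track does not start at timepoint 1; such tracks must be
        excluded upstream (flagged, never silently dropped).
    """
    if track.first_timepoint != 0:
        raise ValueError(
            f"track {track.neuron_id} missing its timepoint-1 ROI "
            "(first_timepoint != 0); exclude it from analysis"
        )
    baseline = track.rois[0].tracking_mean
    death: int | None = None
    for t in range(1, n_timepoints):
        roi = track.roi_at(t)
        if roi is None or roi.tracking_mean < params.death_fraction * baseline:
            death = t + 1  # 1-based timepoint of first observed death
            break
    annotated = replace(track)
    if death is None:
        annotated.death_interval = None
        annotated.censored = True
    else:
        annotated.death_interval = death
        annotated.censored = False
        annotated.rois = track.rois[: death - 1]
    return annotated


def process_movie(
    movie: Movie,
    seg_params: SegmentationParams = SegmentationParams(),
    max_displacement: float = 15.0,
    death_params: DeathParams = DeathParams(),
) -> list[Track]:
    """Background-subtract, segment, link and death-call one movie."""
    rois_by_tp: list[list[ROI]] = []
    for t in range(movie.n_timepoints):
        trk = subtract_background(movie.pixels[t, TRACKING])
        rep = subtract_background(movie.pixels[t, REPORTER])
        rois_by_tp.append(segment_frame(trk, rep, seg_params, timepoint=t))
    tracks = link_tracks(rois_by_tp, max_displacement=max_displacement)
    return [call_death(tr, movie.n_timepoints, death_params) for tr in tracks]


def tracks_to_dataframe(tracks: Sequence[Track]):
    """Tidy per-ROI table: one row per (neuron, timepoint) while alive.

    Columns: neuron_id, timepoint (1-based), x, y, area, mean, sd, cv,
    tracking_mean, alive, death_interval (NaN if censored).
    """
    import pandas as pd

    rows = []
    for tr in tracks:
        for roi in tr.rois:
            rows.append(
                {
                    "neuron_id": tr.neuron_id,
                    "timepoint": roi.timepoint + 1,
                    "x": roi.centroid[1],
                    "y": roi.centroid[0],
                    "area": roi.area,
                    "mean": roi.mean,
                    "sd": roi.sd,
                    "cv": roi.cv,
                    "tracking_mean": roi.tracking_mean,
                    "alive": True,
                    "death_interval": (
                        float("nan") if tr.censored else tr.death_interval
                    ),
                }
            )
    columns = [
        "neuron_id", "timepoint", "x", "y", "area", "mean", "sd", "cv",
        "tracking_mean", "alive", "death_interval",
    ]
    return pd.DataFrame(rows, columns=columns)
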