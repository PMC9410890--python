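"""File formats: multi-page TIFF movies, CSV tables, JSON configs/reports.

Movies are stored as multi-page TIFF with pages in timepoint-major order
(page index = timepoint * 2 + channel; channel 0 = tracking, 1 = reporter)
plus a JSON sidecar (``<movie>.json``) recording acquisition times, channel
names and, when available, the generating config and seed. CSV tables carry
documented column schemas that are validated on read with errors naming the
file and the missing columns.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .imaging import Movie

__all__ = [
    "write_movie",
    "read_movie",
    "read_table",
    "write_table",
    "write_json",
    "read_json",
    "TRACKS_COLUMNS",
    "RECORDS_COLUMNS",
    "ROC_COLUMNS",
]

TRACKS_COLUMNS = [
    "neuron_id", "timepoint", "x", "y", "area", "mean", "sd", "cv",
    "tracking_mean", "alive", "death_interval",
]
RECORDS_COLUMNS = ["neuron_id", "time", "event", "group", "aggregate"]
ROC_COLUMNS = ["threshold", "fpr", "tpr"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_movie(movie: Movie, path: str | Path, extra_metadata: dict | None = None) -> None:
    """Write a movie as multi-page TIFF plus a JSON metadata sidecar.

    Integer intensities round-trip losslessly.
    """
    path = Path(path)
    t, c, h, w = movie.pixels.shape
    tifffile.imwrite(path, movie.pixels.reshape(t * c, h, w))
    meta = {
        "schema_version": 1,
        "n_timepoints": t,
        "n_channels": c,
        "times_hours": [float(x) for x in movie.times],
        "channel_names": list(movie.channel_names),
        "page_order": "timepoint-major (page = timepoint * n_channels + channel)",
        "pixel_size_um": movie.pixel_size_um,
    }
    if extra_metadata:
        meta.update(extra_metadata)
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_movie(path: str | Path, interval_hours: float = 24.0) -> Movie:
    """Read a multi-page TIFF movie written by :func:`write_movie`.

    Without a sidecar, pages are assumed timepoint-major two-channel with
    acquisition times 24, 48, ... hours.
    """
    path = Path(path)
    try:
        pages = tifffile.imread(path)
    except Exception as err:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"malformed TIFF {path}: {err}") from err
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"{path}: expected a stack of 2-d pages, got {pages.shape}")
    sidecar = _sidecar(path)
    if sidecar.exists():
        try:
            meta = json.loads(sidecar.read_text())
        except json.JSONDecodeError as err:
            raise ValueError(f"malformed sidecar {sidecar}: {err}") from err
        n_channels = int(meta.get("n_channels", 2))
        times = np.asarray(meta.get("times_hours"), dtype=float)
        channel_names = tuple(meta.get("channel_names", ("tracking", "reporter")))
        pixel_size = meta.get("pixel_size_um")
    else:
        n_channels = 2
        times = None
        channel_names = ("tracking", "reporter")
        pixel_size = None
    if pages.shape[0] % n_channels:
        raise ValueError(
            f"{path}: page count {pages.shape[0]} is not a multiple of "
            f"{n_channels} channels"
        )
    t = pages.shape[0] // n_channels
    if times is None:
        times = interval_hours * (1 + np.arange(t, dtype=float))
    return Movie(
        pixels=pages.reshape(t, n_channels, *pages.shape[1:]),
        times=times,
        channel_names=channel_names,  # type: ignore[arg-type]
        pixel_size_um=pixel_size,
    )


def read_table(path: str | Path, required_columns: Sequence[str]) -> pd.DataFrame:
    """Read a CSV table, validating its column schema.

    Raises a ValueError naming the file and every missing column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as err:  # noqa: BLE001
        raise ValueError(f"malformed CSV {path}: {err}") from err
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_json(obj: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def read_json(path: str | Path) -> dict:
    path = Path(path)
    try:
        return json.loads(path.read_text())
    except json.JSONDecodeError as err:
        raise ValueError(f"malformed JSON {path}: {err}") from err
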