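"""Readers and writers for tracks, localizations, images, and count tables.

Unit handling is strict: track CSVs are either pixel-valued (columns ``x_px,
y_px`` with a required µm/px calibration) or pre-calibrated (``x_um, y_um``);
times come from the frame index times the frame interval.  Localizations are
nm-valued; images carry their pixel size in µm through TIFF metadata.  Every
reader/writer pair round-trips losslessly on synthetic fixtures.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import CellImage, PointPattern, Track, TrackSet
from .errors import ConfigurationError, DataError, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "read_tracks",
    "write_tracks",
    "read_localizations",
    "write_localizations",
    "read_image",
    "write_image",
    "read_counts",
]


def read_tracks(
    path: str | Path,
    frame_interval: float,
    calibration: float = 1.0,
    condition: str = "",
    donor: str = "",
) -> TrackSet:
    """Read a manual-tracking-style CSV into a :class:`TrackSet`.

    Expected columns: ``track_id``, ``frame``, and either ``x_px, y_px``
    (pixel coordinates, multiplied by ``calibration`` µm/px) or ``x_um, y_um``
    (already calibrated; ``calibration`` is recorded but not applied).  Extra
    columns are ignored by name.  Tracks with fewer than 2 points are dropped
    with a warning.

    Raises
    ------
    FormatError
        If a required column is missing.
    DataError
        If frames are non-monotone within a track, or no usable track remains.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if "track_id" not in cols or "frame" not in cols:
        missing = {"track_id", "frame"} - cols
        raise FormatError(f"missing required column(s): {sorted(missing)}")
    if {"x_um", "y_um"} <= cols:
        xcol, ycol, scale = "x_um", "y_um", 1.0
    elif {"x_px", "y_px"} <= cols:
        xcol, ycol, scale = "x_px", "y_px", float(calibration)
        if calibration <= 0:
            raise ConfigurationError("pixel-valued tracks require calibration > 0 (µm/px)")
    else:
        raise FormatError("missing coordinate columns: need x_um/y_um or x_px/y_px")
    if frame_interval <= 0:
        raise ConfigurationError("frame_interval must be > 0 (minutes)")

    tracks: list[Track] = []
    n_dropped = 0
    for tid, sub in df.groupby("track_id", sort=True):
        frames = sub["frame"].to_numpy(dtype=float)
        if not np.all(np.diff(frames) > 0):
            raise DataError(f"track {tid}: frames not strictly increasing")
        if len(sub) < 2:
            n_dropped += 1
            continue
        positions = np.column_stack(
            [sub[xcol].to_numpy(dtype=float) * scale, sub[ycol].to_numpy(dtype=float) * scale]
        )
        tracks.append(Track(str(tid), frames * frame_interval, positions))
    if n_dropped:
        logger.warning("dropped %d track(s) with < 2 points", n_dropped)
    if not tracks:
        raise DataError("no track with >= 2 points in file")
    return TrackSet(tracks, frame_interval, condition=condition, donor=donor,
                    calibration=float(calibration))


def write_tracks(trackset: TrackSet, path: str | Path) -> None:
    """Write a TrackSet as CSV with columns track_id, frame, t_min, x_um, y_um."""
    rows = []
    for t in trackset:
        frames = np.rint(t.times / trackset.frame_interval).astype(int)
        rows.append(
            pd.DataFrame(
                {
                    "track_id": t.track_id,
                    "frame": frames,
                    "t_min": t.times,
                    "x_um": t.positions[:, 0],
                    "y_um": t.positions[:, 1],
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_localizations(
    path: str | Path,
    window: tuple[float, float, float, float],
    cell_id: str = "",
) -> PointPattern:
    """Read a single-molecule localization table (columns x_nm, y_nm).

    Points outside ``window`` (xmin, xmax, ymin, ymax) are dropped with the
    count logged.  Extra columns are ignored.

    Raises
    ------
    FormatError
        Missing coordinate columns.
    DataError
        Empty pattern after window filtering.
    """
    df = pd.read_csv(path)
    missing = {"x_nm", "y_nm"} - set(df.columns)
    if missing:
        raise FormatError(f"missing required column(s): {sorted(missing)}")
    x = df["x_nm"].to_numpy(dtype=float)
    y = df["y_nm"].to_numpy(dtype=float)
    xmin, xmax, ymin, ymax = window
    inside = (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)
    n_out = int((~inside).sum())
    if n_out:
        logger.warning("%d localization(s) dropped outside window", n_out)
    if not inside.any():
        raise DataError("no localizations inside window")
    return PointPattern(np.column_stack([x[inside], y[inside]]), window,
                        cell_id=cell_id or Path(path).stem)


def write_localizations(pattern: PointPattern, path: str | Path) -> None:
    """Write localizations as CSV (x_nm, y_nm); the window goes in a JSON sidecar."""
    pd.DataFrame({"x_nm": pattern.coordinates[:, 0], "y_nm": pattern.coordinates[:, 1]}).to_csv(
        path, index=False
    )
    sidecar = Path(path).with_suffix(".window.json")
    sidecar.write_text(
        json.dumps({"window_nm": list(pattern.window), "cell_id": pattern.cell_id})
    )


def write_image(image: CellImage, path: str | Path) -> None:
    """Write a CellImage as a multi-page TIFF with channel names and pixel size
    in JSON metadata."""
    names = list(image.channels)
    stack = np.stack([image.channels[n] for n in names]).astype(np.float32)
    meta = {
        "axes": "CYX",
        "channel_names": names,
        "pixel_size_um": image.pixel_size,
    }
    gt = image.metadata.get("ground_truth")
    if gt is not None:
        meta["ground_truth"] = json.loads(json.dumps(gt, default=float))
    tifffile.imwrite(path, stack, photometric="minisblack", metadata=meta)


def read_image(path: str | Path, pixel_size: float | None = None) -> CellImage:
    """Read a multi-channel TIFF into a :class:`CellImage`.

    Pixel size is taken from the TIFF metadata; a ``pixel_size`` argument
    overrides it (logged).  If neither is available a
    :class:`ConfigurationError` is raised — physical units are never guessed.
    Channels without recorded names are called ``ch0, ch1, ...``.
    """
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        meta = {}
        if tif.shaped_metadata:
            meta = dict(tif.shaped_metadata[0])
    if stack.ndim == 2:
        stack = stack[None]
    names = meta.get("channel_names") or [f"ch{i}" for i in range(stack.shape[0])]
    if len(names) != stack.shape[0]:
        raise FormatError(
            f"metadata lists {len(names)} channel names for {stack.shape[0]} pages"
        )
    file_px = meta.get("pixel_size_um")
    if pixel_size is not None:
        if file_px is not None and not np.isclose(file_px, pixel_size):
            logger.warning(
                "pixel size override %.4g µm/px replaces file value %.4g", pixel_size, file_px
            )
        px = float(pixel_size)
    elif file_px is not None:
        px = float(file_px)
    else:
        raise ConfigurationError("no pixel size in TIFF metadata and none supplied")
    metadata = {}
    if "ground_truth" in meta:
        metadata["ground_truth"] = meta["ground_truth"]
    return CellImage(
        channels={n: stack[i].astype(float) for i, n in enumerate(names)},
        pixel_size=px,
        metadata=metadata,
    )


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a migration count table.

    Two layouts are accepted: transwell counts (``label, n_input,
    n_migrated``) or homing percentages (``label, pct_farred_tissue,
    pct_violet_tissue, pct_farred_input, pct_violet_input``).  Values are
    validated (counts >= 0, percentages in [0, 100]).
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"n_input", "n_migrated"} <= cols:
        if (df["n_input"] < 0).any() or (df["n_migrated"] < 0).any():
            raise DataError("counts must be >= 0")
        return df
    homing_cols = {
        "pct_farred_tissue", "pct_violet_tissue", "pct_farred_input", "pct_violet_input",
    }
    if homing_cols <= cols:
        vals = df[sorted(homing_cols)].to_numpy(dtype=float)
        if ((vals < 0) | (vals > 100)).any():
            raise DataError("percentages must be in [0, 100]")
        return df
    raise FormatError(
        "count table needs columns (n_input, n_migrated) or the four homing percentages"
    )
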