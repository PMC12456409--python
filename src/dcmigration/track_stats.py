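"""Per-track and per-group kinematics: velocity, MSD, Euclidean displacement.

The mean squared displacement (MSD) follows the per-cell-then-average
convention: MSD(τ) is first computed for each cell over all overlapping start
points, then averaged without weights over the cells whose track supports at
least one interval of lag τ — correcting the group curve for unequal tracking
lengths.  The number of contributing cells and the SEM are reported per lag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import Track, TrackSet
from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "MSDCurve",
    "DisplacementSummary",
    "mean_track_velocity",
    "velocity_table",
    "msd_curve",
    "euclidean_displacement",
    "center_tracks",
]


@dataclass
class MSDCurve:
    """Group MSD as a function of lag.

    ``lags`` in minutes (including τ=0), ``msd`` in µm², ``n_cells`` the
    number of cells contributing at each lag, ``sem`` the standard error of
    the per-cell MSDs.
    """

    lags: np.ndarray
    msd: np.ndarray
    n_cells: np.ndarray
    sem: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag_min": self.lags, "msd_um2": self.msd, "n_cells": self.n_cells,
             "sem_um2": self.sem}
        )


@dataclass
class DisplacementSummary:
    """Per-track Euclidean displacement at a fixed horizon, with group summary."""

    horizon: float
    track_ids: list[str]
    distances: np.ndarray  # µm, one per included track
    n_excluded: int
    relative_to_reference: float | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.distances))

    @property
    def sem(self) -> float:
        if len(self.distances) < 2:
            return float("nan")
        return float(np.std(self.distances, ddof=1) / np.sqrt(len(self.distances)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"track_id": self.track_ids, "euclidean_um": self.distances})


def mean_track_velocity(track: Track) -> float:
    """Mean velocity of one cell: total path length / elapsed time, µm/min."""
    elapsed = track.duration
    if elapsed <= 0:
        raise DataError(f"track {track.track_id}: zero elapsed time")
    steps = np.diff(track.positions, axis=0)
    path = float(np.sum(np.hypot(steps[:, 0], steps[:, 1])))
    return path / elapsed


def velocity_table(trackset: TrackSet) -> pd.DataFrame:
    """Per-track mean velocities as a tidy table."""
    return pd.DataFrame(
        {
            "track_id": [t.track_id for t in trackset],
            "velocity_um_per_min": [mean_track_velocity(t) for t in trackset],
        }
    )


def _single_track_msd(track: Track, max_steps: int) -> np.ndarray:
    """MSD of one track at integer lags 1..max_steps (overlapping intervals);
    NaN where the track is too short."""
    pos = track.positions
    n = len(pos)
    out = np.full(max_steps, np.nan)
    for k in range(1, min(max_steps, n - 1) + 1):
        d = pos[k:] - pos[:-k]
        out[k - 1] = np.mean(d[:, 0] ** 2 + d[:, 1] ** 2)
    return out


def msd_curve(
    trackset: TrackSet, max_lag: float | None = None, weight_by_intervals: bool = False
) -> MSDCurve:
    """Group MSD curve over integer multiples of the frame interval.

    Per cell, MSD(τ) averages |r(t+τ) − r(t)|² over all overlapping start
    points; the group value at each lag is the unweighted mean over cells
    whose track supports that lag (set ``weight_by_intervals=True`` to weight
    cells by their number of intervals instead).  Lag 0 is included with MSD
    exactly 0.

    Raises :class:`ParameterError` if ``max_lag`` is below one frame.
    """
    dt = trackset.frame_interval
    if max_lag is None:
        max_steps = max(t.n_points for t in trackset) - 1
    else:
        max_steps = int(np.floor(max_lag / dt + 1e-9))
        if max_steps < 1:
            raise ParameterError("max_lag must be at least one frame interval")

    per_cell = np.vstack([_single_track_msd(t, max_steps) for t in trackset])
    n_intervals = np.vstack(
        [[max(t.n_points - 1 - k, 0) for k in range(max_steps)] for t in trackset]
    ).astype(float)

    supported = ~np.isnan(per_cell)
    n_cells = supported.sum(axis=0)
    msd = np.full(max_steps, np.nan)
    sem = np.full(max_steps, np.nan)
    for k in range(max_steps):
        vals = per_cell[supported[:, k], k]
        if len(vals) == 0:
            continue
        if weight_by_intervals:
            w = n_intervals[supported[:, k], k]
            msd[k] = np.average(vals, weights=w)
        else:
            msd[k] = np.mean(vals)
        sem[k] = np.std(vals, ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan

    lags = np.concatenate([[0.0], np.arange(1, max_steps + 1) * dt])
    return MSDCurve(
        lags=lags,
        msd=np.concatenate([[0.0], msd]),
        n_cells=np.concatenate([[len(trackset)], n_cells]),
        sem=np.concatenate([[0.0], sem]),
    )


def euclidean_displacement(
    trackset: TrackSet,
    horizon: float = 60.0,
    relative_to: TrackSet | None = None,
) -> DisplacementSummary:
    """Straight-line distance from each cell's start to its position at the horizon.

    For each track the first sample at or after ``horizon`` minutes from the
    track start is used (no interpolation); tracks ending before the horizon
    are excluded with their count logged.  With ``relative_to``, the ratio of
    group means (this set / reference set) is also reported.

    Raises :class:`DataError` when no track reaches the horizon.
    """
    if horizon <= 0:
        raise ParameterError("horizon must be > 0 minutes")
    ids, dists = [], []
    n_excluded = 0
    for t in trackset:
        rel_t = t.times - t.times[0]
        idx = np.searchsorted(rel_t, horizon - 1e-9)
        if idx >= len(rel_t):
            n_excluded += 1
            continue
        d = t.positions[idx] - t.positions[0]
        ids.append(t.track_id)
        dists.append(float(np.hypot(d[0], d[1])))
    if n_excluded:
        logger.warning("%d track(s) shorter than the %.0f-min horizon excluded",
                       n_excluded, horizon)
    if not dists:
        raise DataError(f"no track reaches the {horizon}-min horizon")
    summary = DisplacementSummary(horizon, ids, np.asarray(dists), n_excluded)
    if relative_to is not None:
        ref = euclidean_displacement(relative_to, horizon=horizon)
        summary.relative_to_reference = summary.mean / ref.mean
    return summary


def center_tracks(trackset: TrackSet) -> TrackSet:
    """Translate every track so its first point is the origin (for trajectory
    rose plots); displacement vectors and the MSD are unchanged."""
    return trackset.map_positions(lambda p: p - p[0])
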