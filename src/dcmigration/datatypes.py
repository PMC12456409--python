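"""Core in-memory containers with explicit units.

Conventions used throughout the package:

* Track coordinates are Cartesian, y-up, in micrometres (µm); times in minutes.
* Images are row-major rasters with the origin at the top-left; the row index
  increases downward.  Geometry code that mixes the two conventions converts
  explicitly, never implicitly.
* Localization coordinates are in nanometres (nm) inside an axis-aligned
  rectangular window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class Track:
    """A single cell's time-stamped planar positions.

    Parameters
    ----------
    track_id : str
        Identifier, unique within a :class:`TrackSet`.
    times : ndarray, shape (n,)
        Sample times in minutes, strictly increasing.
    positions : ndarray, shape (n, 2)
        (x, y) positions in µm.
    """

    track_id: str
    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise DataError(f"track {self.track_id}: times must be (n,), positions (n, 2)")
        if len(self.times) != len(self.positions):
            raise DataError(f"track {self.track_id}: times and positions length mismatch")
        if len(self.times) < 2:
            raise DataError(f"track {self.track_id}: needs at least 2 time points")
        if not np.all(np.diff(self.times) > 0):
            raise DataError(f"track {self.track_id}: times must be strictly increasing")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.positions))):
            raise DataError(f"track {self.track_id}: non-finite coordinates")

    @property
    def n_points(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        """Total tracked time in minutes."""
        return float(self.times[-1] - self.times[0])

    def net_displacement(self) -> np.ndarray:
        """Overall displacement vector (end minus start), µm."""
        return self.positions[-1] - self.positions[0]


@dataclass
class TrackSet:
    """A labeled group of tracks sharing acquisition parameters.

    ``frame_interval`` is the acquisition time step in minutes; ``calibration``
    the µm/px factor applied at import (1.0 for data already in µm).
    """

    tracks: list[Track]
    frame_interval: float
    condition: str = ""
    donor: str = ""
    calibration: float = 1.0

    def __post_init__(self) -> None:
        if not self.tracks:
            raise DataError("TrackSet must contain at least one track")
        if self.frame_interval <= 0:
            raise ParameterError("frame_interval must be > 0")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def map_positions(self, func) -> "TrackSet":
        """Return a new TrackSet with ``func`` applied to each (n, 2) position array."""
        new = [
            Track(t.track_id, t.times.copy(), np.asarray(func(t.positions), dtype=float))
            for t in self.tracks
        ]
        return TrackSet(new, self.frame_interval, self.condition, self.donor, self.calibration)


@dataclass
class CellImage:
    """Multi-channel 2D raster with physical pixel size.

    ``channels`` maps channel name -> 2D float array; all channels share one
    shape.  ``pixel_size`` is in µm/px.  ``metadata`` carries free-form
    provenance (e.g. the ground truth of a synthetic image).
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise DataError("CellImage needs at least one channel")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise DataError(f"channels differ in shape: {shapes}")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise DataError(f"no channel {name!r}; available: {sorted(self.channels)}")
        return self.channels[name]


@dataclass
class PointPattern:
    """Per-cell localization coordinates in a rectangular observation window.

    ``coordinates`` is (n, 2) in nm; ``window`` is (xmin, xmax, ymin, ymax) nm.
    """

    coordinates: np.ndarray
    window: tuple[float, float, float, float]
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 2)
        xmin, xmax, ymin, ymax = self.window
        if xmax <= xmin or ymax <= ymin:
            raise ParameterError("window must have positive area")
        x, y = self.coordinates[:, 0], self.coordinates[:, 1]
        inside = (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)
        if not np.all(inside):
            raise DataError(
                f"{int((~inside).sum())} points outside window; filter before constructing"
            )

    @property
    def n_points(self) -> int:
        return len(self.coordinates)

    @property
    def window_area(self) -> float:
        xmin, xmax, ymin, ymax = self.window
        return (xmax - xmin) * (ymax - ymin)

    @property
    def intensity(self) -> float:
        """Empirical point density, points per nm²."""
        return self.n_points / self.window_area
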