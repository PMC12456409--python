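"""Chemotaxis directionality: gradient-frame alignment, displacement angles,
and the bootstrapped group comparison of mean angles.

The directionality statistic is the planar angle between a cell's overall
displacement vector and the gradient axis, in [0°, 180°]: 0° is movement
directly up the gradient, and in the absence of chemotaxis the angles are
uniform with mean 90°.  Angles are compared between groups with a percentile
bootstrap of the difference in arithmetic mean angle (group B − group A).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import Track, TrackSet
from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "GradientFrame",
    "AngleSet",
    "BootstrapResult",
    "align_to_gradient",
    "displacement_angle",
    "angle_set",
    "mean_angle",
    "bootstrap_angle_difference",
]


@dataclass
class GradientFrame:
    """The chemokine-gradient reference frame.

    ``border`` holds two distinct points (raw track coordinates, µm) on the
    boundary of the chemokine-source region.  The gradient direction is the
    unit normal to the border; its sign is fixed either explicitly
    (``gradient_direction``) or by a point on the source side
    (``source_point``).
    """

    border: np.ndarray  # (2, 2): two points on the source border
    source_point: np.ndarray | None = None
    gradient_direction: np.ndarray = field(init=False)

    def __init__(self, border, source_point=None, gradient_direction=None):
        self.border = np.asarray(border, dtype=float).reshape(2, 2)
        d = self.border[1] - self.border[0]
        if np.hypot(*d) < 1e-12:
            raise ParameterError("border points must be distinct")
        d = d / np.hypot(*d)
        normal = np.array([-d[1], d[0]])  # left-hand normal of the border direction
        if gradient_direction is not None:
            g = np.asarray(gradient_direction, dtype=float)
            if np.hypot(*g) == 0:
                raise ParameterError("gradient_direction must be nonzero")
            sign = np.sign(np.dot(normal, g))
            if sign == 0:
                raise ParameterError("gradient_direction is parallel to the border")
        elif source_point is not None:
            self.source_point = np.asarray(source_point, dtype=float)
            sign = np.sign(np.dot(normal, self.source_point - self.border[0]))
            if sign == 0:
                raise ParameterError("source_point lies on the border")
        else:
            sign = 1.0
        self.source_point = None if source_point is None else np.asarray(source_point, float)
        self.gradient_direction = normal * sign


def align_to_gradient(trackset: TrackSet, frame: GradientFrame) -> TrackSet:
    """Rigidly transform all tracks so the border lies on the x axis and the
    gradient points along +y.

    A rotation (no reflection) maps ``frame.gradient_direction`` to (0, 1),
    then a translation takes the first border point to the origin.  Pairwise
    distances — and hence speeds, MSD and path lengths — are preserved.
    """
    g = frame.gradient_direction
    # rotation by (90° − angle(g)) maps g to +y and the border direction to ±x
    c, s = g[1], g[0]  # cos/sin of the rotation angle
    rot = np.array([[c, -s], [s, c]])
    origin = rot @ frame.border[0]
    return trackset.map_positions(lambda p: p @ rot.T - origin)


def displacement_angle(track: Track) -> float:
    """Angle (degrees, in [0, 180]) between the overall displacement vector
    and the gradient axis (+y) of an aligned track.

    0° means movement directly up the gradient; 180° directly down.

    Raises :class:`DataError` for zero net displacement (direction undefined).
    """
    d = track.net_displacement()
    norm = np.hypot(d[0], d[1])
    if norm == 0:
        raise DataError(f"track {track.track_id}: zero net displacement, angle undefined")
    cosang = np.clip(d[1] / norm, -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


@dataclass
class AngleSet:
    """Per-track displacement angles with group/donor labels."""

    angles: np.ndarray  # degrees, each in [0, 180]
    group: str = ""
    donors: list[str] | None = None

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.size and (self.angles.min() < 0 or self.angles.max() > 180):
            raise DataError("angles must lie in [0, 180] degrees")

    def __len__(self) -> int:
        return len(self.angles)


def angle_set(trackset: TrackSet, group: str = "") -> AngleSet:
    """Displacement angles of every track in an aligned TrackSet.

    Tracks with zero net displacement are excluded (not assigned 90°), with
    the exclusion count logged.
    """
    angles, donors = [], []
    n_excluded = 0
    for t in trackset:
        try:
            angles.append(displacement_angle(t))
        except DataError:
            n_excluded += 1
            continue
        donors.append(trackset.donor)
    if n_excluded:
        logger.warning("%d zero-displacement track(s) excluded from angle analysis",
                       n_excluded)
    if not angles:
        raise DataError("no track with nonzero net displacement")
    return AngleSet(np.asarray(angles), group=group or trackset.condition, donors=donors)


def mean_angle(angles: AngleSet) -> float:
    """Arithmetic mean of the per-track angles, degrees.

    The statistic is an unsigned deviation from the gradient axis on
    [0°, 180°], so the plain (non-circular) mean is the relevant summary: it
    is 90° for non-directional migration and decreases with chemotaxis.
    """
    if len(angles) == 0:
        raise DataError("empty angle set")
    return float(np.mean(angles.angles))


def per_donor_means(angles: AngleSet) -> pd.DataFrame:
    """Mean angle per donor label (when donor labels are present)."""
    if not angles.donors:
        raise DataError("angle set carries no donor labels")
    df = pd.DataFrame({"donor": angles.donors, "angle_deg": angles.angles})
    return df.groupby("donor", sort=True)["angle_deg"].agg(["mean", "count"]).reset_index()


@dataclass
class BootstrapResult:
    """Percentile-bootstrap comparison of two groups' mean angles (B − A)."""

    observed_diff: float
    n_resamples: int
    ci_low: float
    ci_high: float
    ci_level: float
    bootstrap_samples: np.ndarray
    seed: int

    @property
    def excludes_zero(self) -> bool:
        """True when the CI does not contain 0 (a directional group difference)."""
        return not (self.ci_low <= 0.0 <= self.ci_high)


def bootstrap_angle_difference(
    group_a: AngleSet,
    group_b: AngleSet,
    n_resamples: int = 10_000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> BootstrapResult:
    """Percentile bootstrap of the difference in mean angle (group B − group A).

    Each of ``n_resamples`` replicates draws with replacement within each
    group (keeping group sizes) and records mean(B*) − mean(A*); the
    confidence interval is the percentile interval at ``ci_level``.

    Raises :class:`DataError` if either group has fewer than 5 angles.
    """
    a, b = group_a.angles, group_b.angles
    if len(a) < 5 or len(b) < 5:
        raise DataError("each group needs at least 5 angles for the bootstrap")
    if n_resamples < 1000:
        raise ParameterError("n_resamples must be >= 1000")
    if not 0.0 < ci_level < 1.0:
        raise ParameterError("ci_level must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    idx_a = rng.integers(0, len(a), size=(n_resamples, len(a)))
    idx_b = rng.integers(0, len(b), size=(n_resamples, len(b)))
    diffs = a[idx_a].mean(axis=1)
    diffs = b[idx_b].mean(axis=1) - diffs
    alpha = 1.0 - ci_level
    lo, hi = np.percentile(diffs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapResult(
        observed_diff=float(b.mean() - a.mean()),
        n_resamples=n_resamples,
        ci_low=float(lo),
        ci_high=float(hi),
        ci_level=ci_level,
        bootstrap_samples=diffs,
        seed=seed,
    )
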