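"""Synthetic ground-truth generators for every analysis stage.

Four generators emulate the statistical structure the downstream analyses
assume:

* a persistent random walk (PRW) with tunable gradient bias, for track
  kinematics and chemotaxis statistics;
* an elliptical polarized cell with an off-center nucleus and a prescribed
  rear:front intensity ratio, for the polarity-imaging pipeline;
* a Thomas cluster process (Poisson parents, Gaussian-dispersed offspring),
  the clustered null of the pair-correlation pipeline;
* binomially sampled transwell/homing migration counts.

All randomness derives from a single integer seed through numpy's
``SeedSequence`` machinery, so outputs are bit-identical across runs for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CellImage, PointPattern, Track, TrackSet
from .errors import GeometryError, ParameterError

__all__ = [
    "PRWParams",
    "PolarizedCellSpec",
    "ThomasParams",
    "generate_prw_tracks",
    "generate_polarized_cell_image",
    "generate_thomas_pattern",
    "generate_migration_counts",
]


@dataclass
class PRWParams:
    """Parameters of the biased persistent random walk.

    The walk's heading angle diffuses with variance ``2*dt/persistence_time``
    per step (Fürth-class persistence); a gradient bias ``bias`` in [0, 1]
    mixes the persistent heading with the gradient direction.  The effective
    2D diffusion coefficient of the unbiased walk is ``D = speed**2 *
    persistence_time / 2``.

    Attributes
    ----------
    n_tracks, n_steps : int
        Number of cells and steps per cell (each track has n_steps+1 points).
    dt : float
        Time step, minutes (acquisition interval; time-lapse assays in this
        domain typically image every 4-5 min).
    speed : float
        Cell speed in µm/min (amoeboid dendritic cells move at a few µm/min).
    persistence_time : float
        Directional persistence time in minutes; ``np.inf`` gives straight
        runs, 0 gives uncorrelated (Brownian-like) steps.
    bias : float
        Gradient bias in [0, 1]; 0 = isotropic walk, 1 = pure drift up the
        gradient.
    gradient_direction : ndarray (2,)
        Unit vector of the chemokine gradient (default +y).
    """

    n_tracks: int
    n_steps: int
    dt: float = 4.0
    speed: float = 4.0
    persistence_time: float = 10.0
    bias: float = 0.0
    gradient_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0]))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tracks < 1:
            raise ParameterError("n_tracks must be >= 1")
        if self.n_steps < 1:
            raise ParameterError("n_steps must be >= 1")
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")
        if self.speed < 0:
            raise ParameterError("speed must be >= 0")
        if self.persistence_time < 0:
            raise ParameterError("persistence_time must be >= 0")
        if not 0.0 <= self.bias <= 1.0:
            raise ParameterError("bias must be in [0, 1]")
        g = np.asarray(self.gradient_direction, dtype=float)
        norm = np.hypot(*g)
        if norm == 0 or not np.all(np.isfinite(g)):
            raise ParameterError("gradient_direction must be a nonzero finite vector")
        self.gradient_direction = g / norm

    @property
    def diffusion_coefficient(self) -> float:
        """D = s²·P/2 for the unbiased 2D walk, µm²/min."""
        return self.speed**2 * self.persistence_time / 2.0


def generate_prw_tracks(params: PRWParams) -> TrackSet:
    """Simulate biased persistent-random-walk tracks.

    Each cell's heading angle performs a wrapped-Gaussian random walk with
    per-step standard deviation ``sqrt(2*dt/P)`` (uniform redraw when P == 0).
    The realized step direction is the renormalized convex combination
    ``(1-b)*heading + b*gradient``, so ``b=0`` is the isotropic PRW and
    ``b=1`` moves every cell straight up the gradient; step length is always
    ``speed*dt``.

    Returns a :class:`TrackSet` of ``n_tracks`` tracks with ``n_steps+1``
    positions each, all starting at the origin.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    n, m = params.n_tracks, params.n_steps
    dt, s, b = params.dt, params.speed, params.bias
    g = params.gradient_direction

    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    if params.persistence_time == 0:
        sd = None  # uncorrelated steps: redraw heading uniformly
    elif np.isinf(params.persistence_time):
        sd = 0.0
    else:
        sd = np.sqrt(2.0 * dt / params.persistence_time)

    pos = np.zeros((n, m + 1, 2))
    for k in range(m):
        if sd is None:
            theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
        elif sd > 0:
            theta = theta + rng.normal(0.0, sd, size=n)
        u = np.column_stack([np.cos(theta), np.sin(theta)])
        v = (1.0 - b) * u + b * g
        norm = np.linalg.norm(v, axis=1, keepdims=True)
        # antipodal heading at b=0.5 is measure-zero; fall back to the gradient
        degenerate = norm[:, 0] < 1e-12
        if degenerate.any():
            v[degenerate] = g
            norm[degenerate] = 1.0
        pos[:, k + 1] = pos[:, k] + s * dt * v / norm

    times = np.arange(m + 1) * dt
    tracks = [Track(f"prw_{i:05d}", times, pos[i]) for i in range(n)]
    return TrackSet(tracks, frame_interval=dt, condition="synthetic_prw")


@dataclass
class PolarizedCellSpec:
    """Specification of a synthetic polarized cell image.

    The cell is an axis-aligned ellipse (major axis horizontal); the nucleus a
    disk offset along the major axis.  ``nucleus_offset`` is signed, in µm;
    negative values shift the nucleus toward the cell rear (by construction
    the rear is the side the nucleus is closer to).  The signal channel takes
    value ``base_intensity * rear_front_ratio`` on the rear half of the cell
    (relative to the nucleus centroid), ``base_intensity`` on the front half,
    plus Gaussian noise inside the cell, and 0 outside.
    """

    image_shape: tuple[int, int] = (256, 512)
    pixel_size: float = 0.2
    cell_axes: tuple[float, float] = (50.0, 20.0)  # (major, minor) full lengths, µm
    nucleus_radius: float = 5.0
    nucleus_offset: float = -5.0
    rear_front_ratio: float = 2.0
    base_intensity: float = 100.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be > 0")
        if self.rear_front_ratio <= 0:
            raise ParameterError("rear_front_ratio must be > 0")
        if self.nucleus_radius <= 0:
            raise ParameterError("nucleus_radius must be > 0")
        a, bm = self.cell_axes
        if a <= 0 or bm <= 0:
            raise ParameterError("cell_axes must be positive")
        # nucleus must sit fully inside the ellipse along the major axis
        if abs(self.nucleus_offset) + self.nucleus_radius >= a / 2.0:
            raise GeometryError("nucleus not fully inside cell ellipse along major axis")
        if self.nucleus_radius >= bm / 2.0:
            raise GeometryError("nucleus radius exceeds cell semi-minor axis")


def generate_polarized_cell_image(spec: PolarizedCellSpec) -> CellImage:
    """Render a synthetic polarized cell.

    Channels: ``signal`` (piecewise rear-bright intensity plus noise),
    ``nucleus`` (disk at ``base_intensity``), ``mask_truth`` (binary cell
    ellipse).  Metadata records the pixel size and the full ground truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    h, w = spec.image_shape
    px = spec.pixel_size
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0  # image center, px

    a = spec.cell_axes[0] / 2.0 / px  # semi-major, px (horizontal)
    bm = spec.cell_axes[1] / 2.0 / px  # semi-minor, px
    cell = ((cols - cx) / a) ** 2 + ((rows - cy) / bm) ** 2 <= 1.0

    # front is the side with the longer nucleus-to-edge distance: opposite the
    # nucleus offset.  Zero offset: rear defaults to -x (left), matching the
    # analysis tie-break.
    front_sign = -1.0 if spec.nucleus_offset > 0 else 1.0
    nuc_cx = cx + spec.nucleus_offset / px  # offset along +x (columns)
    nr = spec.nucleus_radius / px
    nucleus = (cols - nuc_cx) ** 2 + (rows - cy) ** 2 <= nr**2

    axial = (cols - nuc_cx) * front_sign  # >0 toward the front
    signal = np.zeros((h, w))
    rear_half = cell & (axial < 0)
    front_half = cell & (axial >= 0)
    signal[rear_half] = spec.base_intensity * spec.rear_front_ratio
    signal[front_half] = spec.base_intensity
    if spec.noise_sd > 0:
        signal[cell] += rng.normal(0.0, spec.noise_sd, size=int(cell.sum()))
    np.clip(signal, 0.0, None, out=signal)

    nucleus_img = np.where(nucleus, spec.base_intensity, 0.0)

    truth = {
        "rear_front_ratio": spec.rear_front_ratio,
        "nucleus_offset_um": spec.nucleus_offset,
        "nucleus_radius_um": spec.nucleus_radius,
        "cell_axes_um": tuple(spec.cell_axes),
        "front_sign": front_sign,
        "rear_distance_um": spec.cell_axes[0] / 2.0
        - abs(spec.nucleus_offset)
        - spec.nucleus_radius,
        "front_distance_um": spec.cell_axes[0] / 2.0
        + abs(spec.nucleus_offset)
        - spec.nucleus_radius,
        "seed": spec.seed,
    }
    return CellImage(
        channels={
            "signal": signal,
            "nucleus": nucleus_img,
            "mask_truth": cell.astype(float),
        },
        pixel_size=px,
        metadata={"ground_truth": truth},
    )


@dataclass
class ThomasParams:
    """Thomas cluster process parameters.

    Parents form a homogeneous Poisson process of intensity ``kappa``
    (parents/nm²); each parent emits a Poisson(``mu``) number of offspring
    displaced by an isotropic Gaussian of standard deviation ``sigma`` (nm).
    The default window is a 5,000 x 5,000 nm region of interest, the scale at
    which membrane-receptor nanoclusters are imaged by single-molecule
    localization microscopy.
    """

    kappa: float = 8e-6
    sigma: float = 25.0
    mu: float = 20.0
    window: tuple[float, float, float, float] = (0.0, 5000.0, 0.0, 5000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.sigma <= 0 or self.mu <= 0:
            raise ParameterError("kappa, sigma, mu must all be > 0")
        xmin, xmax, ymin, ymax = self.window
        if xmax <= xmin or ymax <= ymin:
            raise ParameterError("window must have positive area")

    @property
    def window_area(self) -> float:
        xmin, xmax, ymin, ymax = self.window
        return (xmax - xmin) * (ymax - ymin)

    @property
    def expected_points(self) -> float:
        """kappa * mu * |window|, the expected retained count for sigma << window."""
        return self.kappa * self.mu * self.window_area

    def theoretical_pcf(self, r: np.ndarray) -> np.ndarray:
        """Closed-form pair correlation g(r) = 1 + exp(-r²/(4σ²)) / (4πκσ²)."""
        r = np.asarray(r, dtype=float)
        return 1.0 + np.exp(-(r**2) / (4.0 * self.sigma**2)) / (
            4.0 * np.pi * self.kappa * self.sigma**2
        )


def generate_thomas_pattern(params: ThomasParams) -> PointPattern:
    """Simulate a Thomas cluster process restricted to the window.

    Parents are simulated on the window dilated by 4σ on every side so that
    edge clusters contribute offspring without boundary bias; offspring
    falling outside the window are discarded.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    xmin, xmax, ymin, ymax = params.window
    pad = 4.0 * params.sigma
    ext_area = (xmax - xmin + 2 * pad) * (ymax - ymin + 2 * pad)
    n_parents = rng.poisson(params.kappa * ext_area)
    px = rng.uniform(xmin - pad, xmax + pad, size=n_parents)
    py = rng.uniform(ymin - pad, ymax + pad, size=n_parents)
    n_off = rng.poisson(params.mu, size=n_parents)
    parent_x = np.repeat(px, n_off)
    parent_y = np.repeat(py, n_off)
    total = int(n_off.sum())
    ox = parent_x + rng.normal(0.0, params.sigma, size=total)
    oy = parent_y + rng.normal(0.0, params.sigma, size=total)
    keep = (ox >= xmin) & (ox <= xmax) & (oy >= ymin) & (oy <= ymax)
    coords = np.column_stack([ox[keep], oy[keep]])
    return PointPattern(coords, params.window, cell_id=f"thomas_seed{params.seed}")


def generate_migration_counts(
    n_input: int,
    p_migrate: float,
    n_replicates: int = 3,
    seed: int = 0,
    label: str = "synthetic",
) -> pd.DataFrame:
    """Binomial transwell counts: each replicate draws Binomial(n_input, p).

    Returns a DataFrame with columns ``label, replicate, n_input, n_migrated,
    p_true`` — the ground-truth migration probability is carried alongside the
    draws.
    """
    if n_input < 0 or n_replicates < 1:
        raise ParameterError("n_input >= 0 and n_replicates >= 1 required")
    if not 0.0 <= p_migrate <= 1.0:
        raise ParameterError("p_migrate must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    migrated = rng.binomial(n_input, p_migrate, size=n_replicates)
    return pd.DataFrame(
        {
            "label": label,
            "replicate": np.arange(1, n_replicates + 1),
            "n_input": n_input,
            "n_migrated": migrated,
            "p_true": p_migrate,
        }
    )
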