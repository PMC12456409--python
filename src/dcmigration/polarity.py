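"""Front–rear polarity quantification on fluorescence images.

A migrating amoeboid cell is polarized along a front–rear axis: the nucleus
sits toward the rear and the contractile uropod forms behind it.  This module
segments the cell, anchors the polarity axis on the nucleus (the rear is by
definition the side with the shorter nucleus-edge-to-cell-edge distance),
and derives

* the rear/front intensity ratio of a marker channel (pixels split by the
  line through the nucleus centroid perpendicular to the axis),
* nucleus-to-edge distances in µm,
* width-averaged intensity line profiles from the rear-most or front-most
  point of the cell, normalized per cell,
* foci and particle counts (spot densities within masks or annuli).

Background pixels are invalid, never zero: every statistic is computed over
cell pixels only, so enlarging the canvas cannot change any measurement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .datatypes import CellImage
from .errors import DataError, GeometryError, ParameterError, SegmentationError

logger = logging.getLogger(__name__)

__all__ = [
    "CellGeometry",
    "LineProfile",
    "segment_cell",
    "compute_geometry",
    "rear_front_ratio",
    "width_averaged_profile",
    "average_profiles",
    "count_foci",
    "count_objects_in_region",
]


@dataclass
class CellGeometry:
    """Cell/nucleus masks with the front–rear axis anchored on the nucleus.

    ``axis`` is the unit front direction in (row, col) pixel coordinates;
    ``rear_point``/``front_point`` are the axis–boundary intersections;
    ``rear_distance``/``front_distance`` measure nucleus edge → cell edge
    along the axis, in µm, with rear ≤ front by definition.  ``tie`` flags a
    symmetric cell whose rear was assigned by the deterministic tie-break.
    """

    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    pixel_size: float
    axis: np.ndarray  # unit (drow, dcol) toward the front
    rear_point: np.ndarray
    front_point: np.ndarray
    rear_distance: float
    front_distance: float
    nucleus_centroid: np.ndarray  # (row, col)
    tie: bool = False


@dataclass
class LineProfile:
    """Width-averaged intensity versus axial offset from a reference end.

    ``offsets`` are µm measured into the cell from the rear-most or
    front-most point; ``intensity`` is the per-offset mean over all valid
    cell pixels in that axial bin, normalized to the per-cell maximum of the
    full-length profile; ``n_pixels`` counts contributing pixels per offset.
    """

    offsets: np.ndarray
    intensity: np.ndarray
    n_pixels: np.ndarray
    from_end: str
    truncated: bool = False


def segment_cell(
    image: CellImage, channel: str = "signal", method: str | float = "otsu"
) -> np.ndarray:
    """Threshold a channel and return the binary cell mask.

    The channel is thresholded globally (Otsu by default, or a fixed value),
    the largest connected component is kept (ties broken by area then lowest
    centroid row, logged), and holes are filled.  Pixels outside the mask are
    treated as invalid by all downstream statistics.

    Raises :class:`SegmentationError` when nothing exceeds the threshold.
    """
    img = image.channel(channel)
    if isinstance(method, str):
        if method != "otsu":
            raise ParameterError(f"unknown threshold method {method!r}")
        if np.all(img == img.flat[0]):
            raise SegmentationError("constant image: no threshold separates cell from background")
        thr = filters.threshold_otsu(img)
    else:
        thr = float(method)
    binary = img > thr
    if not binary.any():
        raise SegmentationError(f"no pixel above threshold {thr:.4g} in channel {channel!r}")
    labels, n = ndimage.label(binary)
    if n > 1:
        props = measure.regionprops(labels)
        best = max(props, key=lambda p: (p.area, -p.centroid[0]))
        areas = sorted((p.area for p in props), reverse=True)
        if len(areas) > 1 and areas[0] == areas[1]:
            logger.warning("area tie between components; kept the one with lowest centroid row")
        mask = labels == best.label
    else:
        mask = binary
    return ndimage.binary_fill_holes(mask)


def _principal_axis(mask: np.ndarray) -> np.ndarray:
    """Unit principal axis of a binary mask in (row, col) coordinates."""
    coords = np.argwhere(mask).astype(float)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, np.argmax(eigvals)]
    return axis / np.linalg.norm(axis)


def _march_extent(mask: np.ndarray, origin: np.ndarray, direction: np.ndarray,
                  step: float = 0.25) -> float:
    """Distance (px) from origin to where the ray leaves the mask."""
    h, w = mask.shape
    t = 0.0
    last_inside = 0.0
    max_t = float(np.hypot(h, w))
    while t <= max_t:
        r = origin + t * direction
        i, j = int(round(r[0])), int(round(r[1]))
        if not (0 <= i < h and 0 <= j < w) or not mask[i, j]:
            break
        last_inside = t
        t += step
    return last_inside


def compute_geometry(
    cell_mask: np.ndarray, nucleus_mask: np.ndarray, pixel_size: float
) -> CellGeometry:
    """Anchor the front–rear axis on the nucleus and measure edge distances.

    The axis is the principal axis of the cell mask passed through the
    nucleus centroid.  On each side the axis is intersected with the cell
    boundary and the nucleus boundary; the side with the shorter
    nucleus-edge-to-cell-edge distance is the rear (ties broken toward the
    negative principal-axis direction and flagged).  Distances are in µm.

    Raises :class:`GeometryError` if the nucleus is not inside the cell; a
    nucleus touching the cell boundary logs a warning but distances are
    still computed.
    """
    if pixel_size <= 0:
        raise ParameterError("pixel_size must be > 0")
    if not cell_mask.any() or not nucleus_mask.any():
        raise GeometryError("empty cell or nucleus mask")
    if np.any(nucleus_mask & ~cell_mask):
        raise GeometryError("nucleus mask extends outside the cell mask")

    axis = _principal_axis(cell_mask)
    nuc_c = np.argwhere(nucleus_mask).mean(axis=0)

    dist: dict[int, float] = {}
    edge: dict[int, float] = {}
    for sign in (+1, -1):
        t_cell = _march_extent(cell_mask, nuc_c, sign * axis)
        t_nuc = _march_extent(nucleus_mask, nuc_c, sign * axis)
        edge[sign] = t_cell
        dist[sign] = max(t_cell - t_nuc, 0.0)
        if t_cell - t_nuc < 0.5:
            logger.warning("nucleus touches the cell boundary on the %+d axis side", sign)

    tie = np.isclose(dist[+1], dist[-1], atol=0.5)
    if tie:
        rear_sign = -1  # deterministic: rear toward the negative principal axis
        logger.warning("symmetric nucleus position; rear assigned to the -axis side")
    else:
        rear_sign = +1 if dist[+1] < dist[-1] else -1
    front_sign = -rear_sign

    rear_point = nuc_c + rear_sign * edge[rear_sign] * axis
    front_point = nuc_c + front_sign * edge[front_sign] * axis
    return CellGeometry(
        cell_mask=cell_mask,
        nucleus_mask=nucleus_mask,
        pixel_size=pixel_size,
        axis=front_sign * axis,
        rear_point=rear_point,
        front_point=front_point,
        rear_distance=dist[rear_sign] * pixel_size,
        front_distance=dist[front_sign] * pixel_size,
        nucleus_centroid=nuc_c,
        tie=bool(tie),
    )


def _axial_coordinate(geometry: CellGeometry) -> np.ndarray:
    """Signed axial coordinate (px) of every pixel relative to the nucleus
    centroid; positive toward the front."""
    h, w = geometry.cell_mask.shape
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    rel = np.stack([rows - geometry.nucleus_centroid[0], cols - geometry.nucleus_centroid[1]])
    return rel[0] * geometry.axis[0] + rel[1] * geometry.axis[1]


def rear_front_ratio(image: CellImage, geometry: CellGeometry,
                     channel: str = "signal") -> float:
    """Mean intensity behind the nucleus over mean intensity in front of it.

    Cell pixels are partitioned by the line through the nucleus centroid
    perpendicular to the polarity axis; the ratio is
    mean(rear partition) / mean(front partition).  Ratios > 1 indicate
    rear-enriched signal (e.g. actomyosin at the uropod).

    Raises :class:`GeometryError` if either partition is empty.
    """
    img = image.channel(channel)
    axial = _axial_coordinate(geometry)
    rear = geometry.cell_mask & (axial < 0)
    front = geometry.cell_mask & (axial >= 0)
    if not rear.any() or not front.any():
        raise GeometryError("empty rear or front partition")
    return float(img[rear].mean() / img[front].mean())


def width_averaged_profile(
    image: CellImage,
    geometry: CellGeometry,
    channel: str = "signal",
    from_end: str = "rear",
    length: float = 25.0,
) -> LineProfile:
    """Width-averaged intensity profile from one end of the cell.

    Each cell pixel is assigned an axial offset (µm) measured into the cell
    from the rear-most or front-most point; pixels are binned at the pixel
    size, and the intensity at each offset is the mean over all cell pixels
    in that bin — the average across the entire width of the cell at that
    axial position.  Values are normalized to the maximum of the cell's
    full-length profile, so every cell's profile peaks at 1.  Profiles
    shorter than ``length`` are truncated with a warning.
    """
    if from_end not in ("rear", "front"):
        raise ParameterError("from_end must be 'rear' or 'front'")
    if length <= 0:
        raise ParameterError("length must be > 0 µm")
    img = image.channel(channel)
    axial = _axial_coordinate(geometry)
    cell = geometry.cell_mask
    a = axial[cell]
    vals = img[cell]
    if from_end == "rear":
        offs_px = a - a.min()
    else:
        offs_px = a.max() - a
    px = geometry.pixel_size

    full_bins = int(np.floor(offs_px.max())) + 1
    bin_idx = np.clip(offs_px.astype(int), 0, full_bins - 1)
    sums = np.bincount(bin_idx, weights=vals, minlength=full_bins)
    counts = np.bincount(bin_idx, minlength=full_bins)
    if counts[0] == 0:
        raise GeometryError("no valid pixels at the reference end of the cell")
    with np.errstate(invalid="ignore"):
        full_profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    peak = np.nanmax(full_profile)
    if peak <= 0:
        raise DataError("profile peak is not positive; cannot normalize")

    n_bins = int(round(length / px))
    truncated = n_bins > full_bins
    if truncated:
        logger.warning(
            "cell extends only %.1f µm along the axis; %g-µm profile truncated",
            full_bins * px, length,
        )
        n_bins = full_bins
    return LineProfile(
        offsets=np.arange(n_bins) * px,
        intensity=full_profile[:n_bins] / peak,
        n_pixels=counts[:n_bins],
        from_end=from_end,
        truncated=truncated,
    )


def average_profiles(profiles: list[LineProfile]) -> dict[str, np.ndarray]:
    """Group mean ± SEM of per-cell normalized profiles, per axial offset.

    Averaging happens after per-cell normalization (never normalization of
    the group mean).  Offsets beyond a shorter cell's extent simply have
    fewer contributing cells.
    """
    if not profiles:
        raise DataError("no profiles to average")
    n_bins = max(len(p.intensity) for p in profiles)
    stack = np.full((len(profiles), n_bins), np.nan)
    for i, p in enumerate(profiles):
        stack[i, : len(p.intensity)] = p.intensity
    n = np.sum(~np.isnan(stack), axis=0)
    mean = np.nanmean(stack, axis=0)
    if len(profiles) > 1:
        with np.errstate(invalid="ignore"):
            sem = np.nanstd(stack, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))
    else:
        sem = np.full(n_bins, np.nan)
    ref = max(profiles, key=lambda p: len(p.intensity))
    return {"offsets": ref.offsets, "mean": mean, "sem": sem, "n_cells": n}


def count_foci(
    image: CellImage,
    cell_mask: np.ndarray,
    channel: str,
    min_area: int = 1,
    threshold: str | float = "otsu",
) -> dict[str, float]:
    """Count fluorescent foci inside the cell and report density per µm².

    The channel is thresholded within the mask (Otsu over cell pixels, or a
    fixed value); connected components of at least ``min_area`` pixels are
    counted.  Returns ``{"count", "cell_area_um2", "density_per_um2"}``.
    """
    if not cell_mask.any():
        raise GeometryError("empty cell mask")
    img = image.channel(channel)
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ParameterError(f"unknown threshold method {threshold!r}")
        inside = img[cell_mask]
        thr = filters.threshold_otsu(inside) if inside.max() > inside.min() else np.inf
    else:
        thr = float(threshold)
    spots = (img > thr) & cell_mask
    labels, n = ndimage.label(spots)
    if n and min_area > 1:
        areas = np.bincount(labels.ravel())[1:]
        n = int(np.sum(areas >= min_area))
    area_um2 = float(cell_mask.sum()) * image.pixel_size**2
    return {"count": float(n), "cell_area_um2": area_um2,
            "density_per_um2": float(n) / area_um2}


def count_objects_in_region(
    image: CellImage,
    region: np.ndarray,
    channel: str,
    min_area: int = 1,
    threshold: str | float = "otsu",
) -> int:
    """Count thresholded connected components within a region mask or annulus.

    Used e.g. to count cells in a fixed-area band around a tumor spheroid.
    Objects are counted when their component overlaps the region.
    """
    if not region.any():
        raise GeometryError("empty region")
    img = image.channel(channel)
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ParameterError(f"unknown threshold method {threshold!r}")
        if img.max() == img.min():
            return 0
        thr = filters.threshold_otsu(img)
    else:
        thr = float(threshold)
    labels, n = ndimage.label(img > thr)
    if n == 0:
        return 0
    areas = np.bincount(labels.ravel())[1:]
    in_region = np.unique(labels[region & (labels > 0)])
    return int(sum(1 for lab in in_region if areas[lab - 1] >= min_area))
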