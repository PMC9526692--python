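"""Concentric-belt quantification of fluorescence distribution in single cells.

Given a single-channel image, a manually drawn cell-edge polygon and the
centrosome (brightest in-cell pixel of the microtubule network), every
interior pixel is assigned a normalized radius

    rho(p) = |p - c| / R(theta)

where ``R(theta)`` is the distance from the centrosome ``c`` to the first
intersection of the cell boundary with the ray through ``p``. Belts are the
equal-width partition of rho into ``n_belts`` zones (belt 0 hugging the
centrosome, the last belt at the cell periphery), so the belts follow the
drawn cell shape rather than a fixed circle. Per belt, the mean intensity
and the area fraction above an Otsu (or fixed) threshold are reported, and
profiles from groups of cells are compared belt-by-belt with Student's t.

Coordinates are (row, col), 0-based, pixel-center convention; a pixel is
interior iff its center lies inside the polygon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from matplotlib.path import Path as _MplPath
from skimage.filters import threshold_otsu

from .assays import student_t

DEFAULT_N_BELTS = 11


class GeometryError(ValueError):
    """Raised when a ray from the centrosome fails to meet the boundary."""


@dataclass
class CellImage:
    """Intensity grid plus cell-edge polygon and optional centrosome.

    ``polygon`` is an ordered (n, 2) array of (row, col) vertices of a simple
    polygon; ``centrosome`` a (row, col) pixel coordinate inside it.
    """

    pixels: np.ndarray
    polygon: np.ndarray
    centrosome: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")
        if (self.pixels < 0).any():
            raise ValueError("pixel intensities must be non-negative")
        if self.polygon.ndim != 2 or self.polygon.shape[0] < 3 or self.polygon.shape[1] != 2:
            raise ValueError("polygon needs >= 3 (row, col) vertices")
        if self.centrosome is not None:
            c = np.asarray(self.centrosome, dtype=float)
            if not point_in_polygon(c, self.polygon):
                raise ValueError("centrosome must lie inside the polygon")

    def interior_mask(self) -> np.ndarray:
        """Boolean mask of pixels whose center lies inside the polygon."""
        return polygon_mask(self.pixels.shape, self.polygon)


def polygon_mask(shape: tuple[int, int], polygon: np.ndarray) -> np.ndarray:
    """Rasterize a polygon: True where the pixel center is inside."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    inside = _MplPath(np.asarray(polygon, float)).contains_points(pts)
    return inside.reshape(shape)


def point_in_polygon(point: np.ndarray, polygon: np.ndarray) -> bool:
    return bool(_MplPath(np.asarray(polygon, float)).contains_point(np.asarray(point, float)))


def locate_centrosome(img: CellImage) -> tuple[int, int]:
    """Brightest pixel strictly inside the polygon.

    Ties are broken by smallest row, then smallest column (row-major argmax).
    The global image maximum is ignored if it falls outside the cell.
    """
    mask = img.interior_mask()
    if not mask.any():
        raise ValueError("polygon encloses no pixel centers")
    masked = np.where(mask, img.pixels, -np.inf)
    idx = int(np.argmax(masked))  # row-major => smallest row, then col
    return np.unravel_index(idx, img.pixels.shape)[0], np.unravel_index(idx, img.pixels.shape)[1]


def _ray_boundary_distances(
    origin: np.ndarray, directions: np.ndarray, polygon: np.ndarray
) -> np.ndarray:
    """Distance from ``origin`` to the first polygon-boundary intersection
    along each unit direction. Vectorised over rays and edges."""
    a = np.asarray(polygon, dtype=float)
    b = np.roll(a, -1, axis=0)
    e = b - a  # edge vectors, (v, 2)
    ao = a - origin  # (v, 2)
    d = directions  # (m, 2), unit
    denom = d[:, 0, None] * e[None, :, 1] - d[:, 1, None] * e[None, :, 0]  # (m, v)
    cross_ao_e = ao[:, 0] * e[:, 1] - ao[:, 1] * e[:, 0]  # (v,)
    cross_ao_d = ao[None, :, 0] * d[:, 1, None] - ao[None, :, 1] * d[:, 0, None]  # (m, v)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cross_ao_e[None, :] / denom
        s = cross_ao_d / denom
    eps = 1e-9
    valid = (np.abs(denom) > 1e-12) & (s >= -eps) & (s <= 1 + eps) & (t > eps)
    t = np.where(valid, t, np.inf)
    dist = t.min(axis=1)
    if not np.all(np.isfinite(dist)):
        raise GeometryError("a ray from the centrosome never meets the boundary")
    return dist


def normalized_radius(
    points: np.ndarray, centrosome: Sequence[float], polygon: np.ndarray
) -> np.ndarray:
    """Normalized radius rho in [0, 1] for each (row, col) point.

    rho = |p - c| / R(theta) with R(theta) the per-ray distance from the
    centrosome to the cell edge; rho(c) = 0 by definition. Accepts a single
    point or an (m, 2) array.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    c = np.asarray(centrosome, dtype=float)
    delta = pts - c
    dist = np.hypot(delta[:, 0], delta[:, 1])
    rho = np.zeros(len(pts))
    nz = dist > 0
    if nz.any():
        dirs = delta[nz] / dist[nz, None]
        rho[nz] = dist[nz] / _ray_boundary_distances(c, dirs, polygon)
    return rho if np.asarray(points).ndim > 1 else rho[0]


def generate_belts(img: CellImage, n_belts: int = DEFAULT_N_BELTS) -> np.ndarray:
    """Per-pixel belt label: interior pixels get 0..n_belts-1, outside -1.

    Belt index is ``min(floor(rho * n_belts), n_belts - 1)``; the labels
    partition the polygon interior.
    """
    if n_belts < 1:
        raise ValueError("n_belts must be >= 1")
    c = img.centrosome if img.centrosome is not None else locate_centrosome(img)
    mask = img.interior_mask()
    labels = np.full(img.pixels.shape, -1, dtype=int)
    pts = np.argwhere(mask).astype(float)
    if len(pts) == 0:
        raise ValueError("polygon encloses no pixel centers")
    rho = normalized_radius(pts, c, img.polygon)
    idx = np.minimum(np.floor(rho * n_belts).astype(int), n_belts - 1)
    labels[mask] = idx
    return labels


@dataclass
class BeltProfile:
    """Per-belt mean intensity and above-threshold area fraction."""

    n_belts: int
    mean_intensity: np.ndarray  # NaN where the belt is empty
    area_fraction: np.ndarray  # NaN where the belt is empty
    pixel_counts: np.ndarray
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "belt": np.arange(self.n_belts),
                "mean_intensity": self.mean_intensity,
                "area_fraction": self.area_fraction,
                "n_pixels": self.pixel_counts,
            }
        )


def _threshold(values: np.ndarray, method: str | float) -> float:
    """Otsu threshold, or a fixed value when ``method`` is a number."""
    if isinstance(method, (int, float)) and not isinstance(method, bool):
        return float(method)
    if method != "otsu":
        raise ValueError(f"unknown threshold method {method!r}")
    if np.ptp(values) == 0:  # constant: nothing exceeds the level
        return float(values.ravel()[0]) if values.size else 0.0
    return float(threshold_otsu(values))


def belt_statistics(
    img: CellImage,
    labels: np.ndarray,
    threshold_method: str | float = "otsu",
    n_belts: int | None = None,
) -> BeltProfile:
    """Mean intensity and area fraction per belt.

    The area fraction is the share of the belt's pixels strictly above a
    single per-cell threshold computed on all interior pixels (Otsu by
    default; pass a number for a fixed threshold). Empty belts get NaN;
    ``n_belts`` defaults to the largest label + 1.
    """
    interior = labels >= 0
    if not interior.any():
        raise ValueError("labels contain no interior pixels")
    if n_belts is None:
        n_belts = int(labels.max()) + 1
    thr = _threshold(img.pixels[interior], threshold_method)
    means = np.full(n_belts, np.nan)
    fracs = np.full(n_belts, np.nan)
    counts = np.zeros(n_belts, dtype=int)
    for b in range(n_belts):
        sel = labels == b
        counts[b] = int(sel.sum())
        if counts[b]:
            vals = img.pixels[sel]
            means[b] = float(vals.mean())
            fracs[b] = float((vals > thr).mean())
    return BeltProfile(
        n_belts=n_belts,
        mean_intensity=means,
        area_fraction=fracs,
        pixel_counts=counts,
        threshold=thr,
    )


def aggregate_cells(
    profiles: Sequence[BeltProfile], groups: Sequence[str], alpha: float = 0.05
) -> pd.DataFrame:
    """Belt-wise group means +- sd and two-sample Student's t per belt.

    ``groups`` assigns each profile to one of exactly two groups (e.g. GC and
    RPM), each with >= 2 cells. Returns one row per belt with per-group mean
    intensity and area fraction, the t statistic and p-value on mean
    intensity, and the significance call at ``alpha``.
    """
    if len(profiles) != len(groups):
        raise ValueError("profiles and groups must align")
    n_belts = {p.n_belts for p in profiles}
    if len(n_belts) != 1:
        raise ValueError(f"mismatched n_belts across profiles: {sorted(n_belts)}")
    (nb,) = n_belts
    names = sorted(set(groups))
    if len(names) != 2:
        raise ValueError("exactly two groups are required")
    by_group = {
        g: [p for p, lab in zip(profiles, groups) if lab == g] for g in names
    }
    for g, ps in by_group.items():
        if len(ps) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 cells")
    rows = []
    for b in range(nb):
        row: dict[str, float] = {"belt": b}
        samples = {}
        for g in names:
            vals = np.array([p.mean_intensity[b] for p in by_group[g]])
            fr = np.array([p.area_fraction[b] for p in by_group[g]])
            row[f"mean_{g}"] = float(np.nanmean(vals))
            row[f"sd_{g}"] = float(np.nanstd(vals, ddof=1))
            row[f"area_fraction_{g}"] = float(np.nanmean(fr))
            row[f"n_{g}"] = len(by_group[g])
            samples[g] = vals[~np.isnan(vals)]
        t, p = student_t(samples[names[0]], samples[names[1]])
        row["t"], row["p"], row["significant"] = t, p, p < alpha
        rows.append(row)
    return pd.DataFrame(rows)


def image_totals(
    pixels: np.ndarray, threshold_method: str | float = "otsu"
) -> tuple[float, int]:
    """Whole-image total intensity and stained area (pixels above threshold).

    Used for extracellular-matrix immunostaining images where no cell-level
    geometry is needed.
    """
    arr = np.asarray(pixels, dtype=float)
    thr = _threshold(arr, threshold_method)
    return float(arr.sum()), int((arr > thr).sum())
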