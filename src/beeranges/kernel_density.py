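"""Quartic (biweight) kernel density surfaces over pooled waypoints.

The utilization surface is built by centering a compact-support quartic
kernel on every fix and summing on a regular grid:

    value(c) = sum_i (1 / r^2) * K(||c - p_i|| / r),
    K(u) = (3/pi) * (1 - u^2)^2   for u < 1, else 0,

with r the fixed kernel radius (default 60 map units). K integrates to 1
over the unit disk, so each point contributes unit mass and the raster
mass approximates the number of points — a conservation law the tests
lean on. A raw-weight variant (``normalize=False``) drops the 1/(pi r^2/3)
scaling for visual parity with desktop-GIS heatmap tools.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError
from .io import write_ascii_grid

__all__ = ["KernelRaster", "quartic_weight", "compute_kde"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class KernelRaster:
    """Gridded density surface; ``values`` row 0 is the northernmost row."""

    origin: tuple[float, float]  # lower-left corner
    cellsize: float
    values: np.ndarray  # shape (nrows, ncols), densities per square map unit
    radius: float

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def mass(self) -> float:
        """Riemann-sum mass: sum(value) * cellsize^2."""
        return float(self.values.sum() * self.cellsize**2)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) 1-D center coordinates; y descends with row index."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = y0 + (np.arange(self.nrows)[::-1] + 0.5) * self.cellsize
        return xs, ys

    def write(self, path) -> None:
        write_ascii_grid(self.values, self.origin, self.cellsize, path)


def quartic_weight(u):
    """Quartic (biweight) kernel K(u) = (3/pi)(1-u^2)^2 on u in [0, 1).

    Accepts scalars or arrays of distance ratios; zero outside the unit
    disk. Negative ratios are a domain error.
    """
    arr = np.asarray(u, dtype=float)
    if (arr < 0).any():
        raise ValueError("distance ratio u must be >= 0")
    out = np.where(arr < 1.0, (3.0 / math.pi) * (1.0 - arr**2) ** 2, 0.0)
    if np.isscalar(u) or arr.ndim == 0:
        return float(out)
    return out


def compute_kde(
    points: np.ndarray,
    radius: float = 60.0,
    cellsize: float | None = None,
    normalize: bool = True,
) -> KernelRaster:
    """Quartic-kernel density raster over a planar point set.

    The grid covers all points padded by one radius; its origin is snapped
    to a multiple of the cell size so equal translations of the input
    produce an identically-valued, shifted raster. ``cellsize`` defaults
    to radius/12; values above radius/4 trigger a resolution warning.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise InsufficientDataError("KDE needs at least one point")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if cellsize is None:
        cellsize = radius / 12.0
    if cellsize <= 0:
        raise ValueError("cellsize must be > 0")
    if cellsize > radius / 4.0:
        log.warning(
            "cellsize %.3g exceeds radius/4 = %.3g; raster mass will be crude",
            cellsize,
            radius / 4.0,
        )

    x0 = math.floor((pts[:, 0].min() - radius) / cellsize) * cellsize
    y0 = math.floor((pts[:, 1].min() - radius) / cellsize) * cellsize
    x1 = math.ceil((pts[:, 0].max() + radius) / cellsize) * cellsize
    y1 = math.ceil((pts[:, 1].max() + radius) / cellsize) * cellsize
    ncols = int(round((x1 - x0) / cellsize))
    nrows = int(round((y1 - y0) / cellsize))

    xs = x0 + (np.arange(ncols) + 0.5) * cellsize
    ys = y0 + (np.arange(nrows) + 0.5) * cellsize  # ascending; flip at the end
    values = np.zeros((nrows, ncols))

    scale = 1.0 / radius**2 if normalize else math.pi / 3.0
    win = int(math.ceil(radius / cellsize)) + 1
    for px, py in pts:
        ci = int((px - x0) / cellsize)
        ri = int((py - y0) / cellsize)
        c_lo, c_hi = max(ci - win, 0), min(ci + win + 1, ncols)
        r_lo, r_hi = max(ri - win, 0), min(ri + win + 1, nrows)
        dx = xs[c_lo:c_hi] - px
        dy = ys[r_lo:r_hi] - py
        u = np.sqrt(dx[None, :] ** 2 + dy[:, None] ** 2) / radius
        values[r_lo:r_hi, c_lo:c_hi] += scale * quartic_weight(u)

    return KernelRaster((x0, y0), cellsize, values[::-1], radius)
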