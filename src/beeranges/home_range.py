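"""Minimum Convex Polygon home ranges with size and shape indices.

The MCP is the classical home-range estimator: the smallest convex polygon
containing all of an animal's relocation fixes. Its shape is summarized by
two dimensionless indices borrowed from map-area morphometry:

* compactness ``Kc = P / (2 * sqrt(pi * A))`` — perimeter relative to the
  perimeter of the equal-area circle; 1 for a circle, larger for elongated
  ranges;
* circularity ratio ``Rci = 4 * pi * A / P**2`` — 1 for a circle, 0.785 for
  a square, below ~0.2 for very elongated or irregular shapes.

The two are algebraically redundant (``Rci = 1 / Kc**2``) but are both
reported because practitioners read them on different scales. The exact
constant ``1/(2*sqrt(pi)) = 0.2820948...`` is used for Kc so the identity
holds to machine precision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Polygon
from shapely.geometry.polygon import orient

from .errors import DegenerateHullError, InsufficientDataError
from .stats_core import describe

__all__ = [
    "HomeRange",
    "compute_mcp",
    "shape_metrics",
    "max_flight_distance",
    "summarize_stage",
]

log = logging.getLogger(__name__)

M2_PER_HA = 10_000.0


@dataclass(frozen=True)
class HomeRange:
    """One bee's Minimum Convex Polygon and its summary metrics."""

    bee_id: str
    hull: Polygon  # counter-clockwise exterior ring
    area_m2: float
    perimeter_m: float
    kc: float
    rci: float
    max_flight_m: float
    n_points: int

    @property
    def area_ha(self) -> float:
        return self.area_m2 / M2_PER_HA

    @property
    def hull_vertices(self) -> np.ndarray:
        """Closed CCW vertex ring, shape (k+1, 2)."""
        return np.asarray(self.hull.exterior.coords)

    def to_record(self) -> dict:
        return {
            "bee_id": self.bee_id,
            "n_points": self.n_points,
            "area_ha": self.area_ha,
            "perimeter_m": self.perimeter_m,
            "kc": self.kc,
            "rci": self.rci,
            "max_flight_m": self.max_flight_m,
        }


def compute_mcp(
    points: np.ndarray, min_points: int = 5, bee_id: str = ""
) -> HomeRange:
    """Convex hull of all fixes, with area, perimeter, shape and diameter.

    ``points`` is an (n, 2) array of planar coordinates in meters. At least
    ``min_points`` fixes are required (the relocation filter; default 5).
    The hull vertices are exactly the "most external" fixes. Collinear
    point sets raise :class:`DegenerateHullError`: the shape indices are
    undefined at zero area.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if not np.isfinite(pts).all():
        raise ValueError("points contain non-finite coordinates")
    if pts.shape[0] < min_points:
        raise InsufficientDataError(
            f"bee {bee_id or '?'}: {pts.shape[0]} fixes < minimum {min_points}"
        )
    hull = MultiPoint(pts).convex_hull
    if hull.geom_type != "Polygon" or hull.area == 0.0:
        raise DegenerateHullError(
            f"bee {bee_id or '?'}: fixes are collinear, hull has no area"
        )
    hull = orient(hull, sign=1.0)  # CCW
    area = hull.area  # shoelace, via shapely
    perimeter = hull.length
    kc, rci = shape_metrics(area, perimeter)
    return HomeRange(
        bee_id=bee_id,
        hull=hull,
        area_m2=float(area),
        perimeter_m=float(perimeter),
        kc=kc,
        rci=rci,
        max_flight_m=max_flight_distance(pts),
        n_points=int(pts.shape[0]),
    )


def shape_metrics(area: float, perimeter: float) -> tuple[float, float]:
    """(Kc, Rci) from area [m^2] and perimeter [m]; both dimensionless."""
    if area <= 0:
        raise DegenerateHullError("shape indices undefined for zero area")
    kc = perimeter / (2.0 * math.sqrt(math.pi * area))
    rci = 4.0 * math.pi * area / perimeter**2
    return float(kc), float(rci)


def max_flight_distance(points: np.ndarray) -> float:
    """Diameter of the fix cloud: the farthest pair of points, in meters.

    Equals the distance between the two most distant hull vertices. The
    all-pairs computation is run on the hull vertices when there are many
    points (the diameter of a set equals the diameter of its hull).
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if pts.shape[0] < 2:
        raise InsufficientDataError("need at least 2 distinct points")
    if pts.shape[0] > 16:
        hull = MultiPoint(pts).convex_hull
        if hull.geom_type == "Polygon":
            pts = np.asarray(hull.exterior.coords)[:-1]
        else:  # collinear: endpoints of the segment suffice, but keep all
            pts = shapely.get_coordinates(hull)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


_METRICS = ("area_ha", "kc", "rci", "max_flight_m")


def summarize_stage(
    homeranges: Sequence[HomeRange],
    stages: Mapping[str, str],
) -> pd.DataFrame:
    """Per-stage mean and sample SD of area, Kc, Rci and flight distance.

    ``stages`` maps bee_id to its lifecycle-stage label. A pooled row
    (stage ``"all"``) carries the across-stage mean/SD of the maximum
    flight distance, the one metric the study pools.
    """
    rows = []
    for hr in homeranges:
        rec = hr.to_record()
        rec["stage"] = stages[hr.bee_id]
        rows.append(rec)
    df = pd.DataFrame(rows)
    return summarize_stage_table(df)


def summarize_stage_table(df: pd.DataFrame) -> pd.DataFrame:
    """Stage summary from a tidy per-bee table.

    Expects columns ``stage`` plus any of ``area_ha, kc, rci,
    max_flight_m``; missing metrics are skipped. Returns one row per stage
    plus a pooled ``"all"`` row for max flight distance.
    """
    out = []
    for stage, grp in df.groupby("stage", sort=False):
        if len(grp) == 0:
            log.warning("stage %s has no home ranges; omitted", stage)
            continue
        row: dict = {"stage": stage, "n_bees": len(grp)}
        for m in _METRICS:
            if m in grp and grp[m].notna().any():
                d = describe(grp[m].dropna())
                row[f"{m}_mean"] = d.mean
                row[f"{m}_sd"] = d.sd
        out.append(row)
    if "max_flight_m" in df and df["max_flight_m"].notna().any():
        d = describe(df["max_flight_m"].dropna())
        out.append(
            {
                "stage": "all",
                "n_bees": int(df["max_flight_m"].notna().sum()),
                "max_flight_m_mean": d.mean,
                "max_flight_m_sd": d.sd,
            }
        )
    return pd.DataFrame(out)
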