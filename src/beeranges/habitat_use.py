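"""Habitat use versus availability inside each bee's home range.

Observed use is the per-bee distribution of fixes over land-use categories
(LUCs). Availability is the null distribution obtained by scattering the
same number of points uniformly at random inside the bee's MCP and
classifying them against the same land-use map — the classical
used-vs-available design. A chi-square goodness-of-fit test compares the
two over the tested categories (by default the four LUCs the bees were
ever observed in; ``developed`` is excluded).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, SamplingError
from .home_range import HomeRange
from .io import LUC_LABELS, LandUseMap
from .stats_core import chi2_sf

__all__ = [
    "DEFAULT_TEST_CATEGORIES",
    "UseProfile",
    "SelectionTest",
    "classify_points",
    "simulate_random_use",
    "selection_chi2",
    "selection_table",
    "nest_substrate_summary",
]

log = logging.getLogger(__name__)

#: categories entering the selection test; the fifth class (developed)
#: is excluded because bees were never observed using it
DEFAULT_TEST_CATEGORIES = ("blueberry", "plantation", "semi_natural", "other_fruits")


@dataclass(frozen=True)
class UseProfile:
    """Per-bee occupancy counts and proportions over LUCs."""

    bee_id: str
    stage: str | None
    counts: dict[str, int]  # LUC -> count, plus "unclassified"
    n_points: int

    @property
    def proportions(self) -> dict[str, float]:
        """Fractions over classified points only."""
        classified = sum(v for k, v in self.counts.items() if k != "unclassified")
        if classified == 0:
            return {k: 0.0 for k in self.counts if k != "unclassified"}
        return {
            k: v / classified for k, v in self.counts.items() if k != "unclassified"
        }


@dataclass(frozen=True)
class SelectionTest:
    """Chi-square comparison of observed use against the availability null."""

    bee_id: str
    observed: dict[str, float]
    expected: dict[str, float]
    chi2: float
    df: int
    p: float
    n_random: int
    seed: int | None
    dropped: tuple[str, ...] = ()


def classify_points(
    points: np.ndarray,
    landuse: LandUseMap,
    bee_id: str = "",
    stage: str | None = None,
) -> UseProfile:
    """Assign each fix the LUC of the polygon containing it.

    Boundary fixes go to the first containing feature in file order;
    fixes in no polygon count as ``unclassified``.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    labels = landuse.classify_xy(pts[:, 0], pts[:, 1])
    counts = {luc: 0 for luc in LUC_LABELS}
    counts["unclassified"] = 0
    for lab in labels:
        counts[lab] += 1
    return UseProfile(bee_id, stage, counts, int(pts.shape[0]))


def _uniform_in_polygon(
    poly: Polygon, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform points inside a polygon by bounding-box rejection."""
    minx, miny, maxx, maxy = poly.bounds
    shapely.prepare(poly)
    out = np.empty((0, 2))
    attempts = 0
    while out.shape[0] < n:
        batch = max(2 * (n - out.shape[0]), 64)
        xs = rng.uniform(minx, maxx, batch)
        ys = rng.uniform(miny, maxy, batch)
        keep = shapely.contains_xy(poly, xs, ys)
        out = np.vstack([out, np.c_[xs[keep], ys[keep]]])
        attempts += batch
        if attempts > 200 * n and out.shape[0] < max(1, attempts // 100):
            raise SamplingError(
                "rejection acceptance below 1%; polygon too thin to sample"
            )
    return out[:n]


def simulate_random_use(
    mcp: HomeRange | Polygon,
    n: int,
    landuse: LandUseMap,
    seed: int | np.random.Generator | None = None,
    replicates: int = 100,
) -> dict[str, float]:
    """Mean availability counts from uniform random points inside the MCP.

    Draws ``replicates`` independent sets of ``n`` uniform points inside
    the MCP polygon (``n`` is conventionally the bee's observed fix
    count), classifies each set, and returns mean counts per LUC plus
    ``unclassified``. ``replicates=1`` reproduces a single-draw null.
    """
    poly = mcp.hull if isinstance(mcp, HomeRange) else mcp
    if poly.area <= 0:
        raise InsufficientDataError("MCP polygon is degenerate")
    if n < 1:
        raise ValueError("n must be >= 1")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    totals = {luc: 0.0 for luc in LUC_LABELS}
    totals["unclassified"] = 0.0
    pts = _uniform_in_polygon(poly, n * replicates, rng)
    labels = landuse.classify_xy(pts[:, 0], pts[:, 1])
    for lab in labels:
        totals[lab] += 1.0
    return {k: v / replicates for k, v in totals.items()}


def selection_chi2(
    observed: dict[str, float],
    expected: dict[str, float],
    categories: tuple[str, ...] = DEFAULT_TEST_CATEGORIES,
    bee_id: str = "",
    n_random: int = 0,
    seed: int | None = None,
) -> SelectionTest:
    """Chi-square goodness of fit of observed counts against the null.

    Expected counts are rescaled so they sum to the observed total over
    the tested categories. Categories with zero expectation are dropped
    (with a warning) and the degrees of freedom reduced accordingly.
    """
    obs = {c: float(observed.get(c, 0.0)) for c in categories}
    exp = {c: float(expected.get(c, 0.0)) for c in categories}
    o_tot = sum(obs.values())
    e_tot = sum(exp.values())
    if o_tot <= 0:
        raise InsufficientDataError("no observed counts in the tested categories")
    if e_tot <= 0:
        raise InsufficientDataError("null produced no mass in the tested categories")

    dropped = tuple(c for c in categories if exp[c] == 0.0)
    if dropped:
        warnings.warn(
            f"bee {bee_id or '?'}: expected count 0 for {dropped}; "
            "categories dropped, df reduced",
            stacklevel=2,
        )
        obs = {c: v for c, v in obs.items() if c not in dropped}
        exp = {c: v for c, v in exp.items() if c not in dropped}
        o_tot = sum(obs.values())
        e_tot = sum(exp.values())
    scale = o_tot / e_tot
    exp = {c: v * scale for c, v in exp.items()}

    chi2 = sum((obs[c] - exp[c]) ** 2 / exp[c] for c in exp)
    df = len(exp) - 1
    p = chi2_sf(chi2, df) if df >= 1 else 1.0
    return SelectionTest(bee_id, obs, exp, float(chi2), df, float(p), n_random, seed, dropped)


def selection_table(tests: list[SelectionTest]) -> pd.DataFrame:
    """Tidy per-bee selection results with a Holm-adjusted p column."""
    df = pd.DataFrame(
        {
            "bee_id": [t.bee_id for t in tests],
            "chi2": [t.chi2 for t in tests],
            "df": [t.df for t in tests],
            "p": [t.p for t in tests],
            "n_random": [t.n_random for t in tests],
            "seed": [t.seed for t in tests],
        }
    )
    if len(df):
        df["p_holm"] = multipletests(df["p"], method="holm")[1]
    return df


# nest substrates as printed group onto LUCs: eucalyptus / casuarina
# plantings and windbreaks are the plantation class
_SUBSTRATE_GROUPS = (
    ("eucalyptus", "plantation"),
    ("casuarina", "plantation"),
    ("windbreak", "plantation"),
    ("pine", "plantation"),
    ("blueberry", "blueberry"),
    ("citrus", "other_fruits"),
    ("savanna", "semi_natural"),
)


def group_substrate(substrate: str) -> str:
    s = substrate.strip().lower()
    for key, luc in _SUBSTRATE_GROUPS:
        if key in s:
            return luc
    return "other"


def nest_substrate_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Nest counts and percentages by substrate group.

    Expects columns ``nest`` (yes/no) and ``nest_substrate``; percentages
    are over confirmed nests only. Substrates are grouped to LUCs (e.g.
    eucalyptus plantations and casuarina windbreaks both count as
    plantation). Returns an empty frame when no nest is confirmed.
    """
    confirmed = table[table["nest"].astype(str).str.lower() == "yes"]
    if confirmed.empty:
        return pd.DataFrame(columns=["substrate_group", "n_nests", "percent"])
    groups = confirmed["nest_substrate"].map(group_substrate)
    counts = groups.value_counts()
    out = pd.DataFrame(
        {
            "substrate_group": counts.index,
            "n_nests": counts.to_numpy(),
            "percent": 100.0 * counts.to_numpy() / len(confirmed),
        }
    )
    return out.reset_index(drop=True)
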