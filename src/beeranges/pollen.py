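"""Pollen-load composition across blueberry flowering stages.

Each sample is the species breakdown of the first 100 pollen grains
counted from one queen's body wash. Samples are binned into three
flowering stages of the blueberry crop by capture date — early flower
(4th week of July and 1st week of August), peak (2nd and 3rd weeks of
August) and post-peak (4th week of August through the 2nd week of
September) — using day-of-month weeks (1-7, 8-14, 15-21, 22-end).
Composition is summarized per stage as mean ± SD percent per species,
with species outside the focal list pooled as "Others", and per-species
stage contrasts use the Kruskal–Wallis rank test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from datetime import date
from fractions import Fraction
from typing import Iterable, Sequence

import pandas as pd

from .errors import StageWindowError
from .stats_core import RankTestResult, kruskal_wallis

__all__ = [
    "FLOWER_STAGES",
    "FOCAL_SPECIES",
    "PollenSample",
    "assign_flower_stage",
    "richness",
    "stage_composition",
    "compare_species_across_stages",
    "read_pollen_csv",
]

log = logging.getLogger(__name__)

FLOWER_STAGES = ("early", "peak", "post_peak")

#: the nine focal species reported individually; everything else pools
#: into "Others"
FOCAL_SPECIES = (
    "Vaccinium corymbosum",
    "Justicia tweediana",
    "Nuttalanthus canadensis",
    "Nothoscordum arenarium",
    "Echium plantagineum",
    "Solanum sisymbriifolium",
    "Conium maculatum",
    "Cuphea glutinosa",
    "Buddleja stachyoides",
)


@dataclass(frozen=True)
class PollenSample:
    """One bee's grain counts (nominally 100 grains) with capture date."""

    bee_id: str
    capture_date: date
    counts: dict[str, int]

    def __post_init__(self) -> None:
        for sp, c in self.counts.items():
            if not sp:
                raise ValueError("empty species label")
            if c < 0:
                raise ValueError(f"negative grain count for {sp}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def stage(self) -> str:
        return assign_flower_stage(self.capture_date)

    def percentages(self) -> dict[str, Fraction]:
        """Exact per-species percent of the load; sums to exactly 100."""
        tot = self.total
        if tot == 0:
            return {sp: Fraction(0) for sp in self.counts}
        return {sp: Fraction(100 * c, tot) for sp, c in self.counts.items()}


def _week_of_month(d: date) -> int:
    """Day-of-month weeks: 1-7 -> 1, 8-14 -> 2, 15-21 -> 3, 22-end -> 4."""
    return min((d.day - 1) // 7 + 1, 4)


def assign_flower_stage(d: date) -> str:
    """Flowering stage for a capture date; errors outside the season."""
    wk = _week_of_month(d)
    key = (d.month, wk)
    if key in ((7, 4), (8, 1)):
        return "early"
    if key in ((8, 2), (8, 3)):
        return "peak"
    if key in ((8, 4), (9, 1), (9, 2)):
        return "post_peak"
    raise StageWindowError(
        f"{d.isoformat()} outside the flowering season window "
        "(4th week of July through 2nd week of September)"
    )


def richness(sample: PollenSample) -> int:
    """Number of species with at least one grain in the load."""
    return sum(1 for c in sample.counts.values() if c > 0)


def _percent_rows(
    samples: Iterable[PollenSample], focal: Sequence[str]
) -> pd.DataFrame:
    """Long table: one row per sample x reported species (focal + Others)."""
    rows = []
    for s in samples:
        pct = {sp: float(p) for sp, p in s.percentages().items()}
        others = sum(p for sp, p in pct.items() if sp not in focal)
        rec = {
            "bee_id": s.bee_id,
            "stage": s.stage,
            "richness": richness(s),
        }
        for sp in focal:
            rec[sp] = pct.get(sp, 0.0)
        rec["Others"] = others
        rows.append(rec)
    return pd.DataFrame(rows)


def stage_composition(
    samples: Sequence[PollenSample],
    focal: Sequence[str] = FOCAL_SPECIES,
) -> pd.DataFrame:
    """Per-stage per-species mean ± SD percent and richness summary.

    Returns a tidy frame with columns ``stage, species, mean_pct, sd_pct,
    n``; richness appears as the pseudo-species ``"N_species"`` (mean ± SD
    of per-sample species counts). Stages with no samples are omitted
    with a warning.
    """
    wide = _percent_rows(samples, focal)
    out = []
    seen = set(wide["stage"]) if len(wide) else set()
    for st in FLOWER_STAGES:
        if st not in seen:
            log.warning("stage %s has no pollen samples; omitted", st)
            continue
        grp = wide[wide["stage"] == st]
        n = len(grp)
        for sp in ("N_species", *focal, "Others"):
            col = "richness" if sp == "N_species" else sp
            vals = grp[col]
            out.append(
                {
                    "stage": st,
                    "species": sp,
                    "mean_pct": float(vals.mean()),
                    "sd_pct": float(vals.std(ddof=1)) if n > 1 else None,
                    "n": n,
                }
            )
    return pd.DataFrame(out)


def compare_species_across_stages(
    samples: Sequence[PollenSample],
    species: str,
    focal: Sequence[str] = FOCAL_SPECIES,
) -> RankTestResult:
    """Kruskal–Wallis on per-sample percentages of one species by stage."""
    wide = _percent_rows(samples, focal)
    col = species if species in wide.columns else None
    if col is None or (wide[col] == 0).all():
        warnings.warn(f"species {species!r} absent from all samples", stacklevel=2)
        k = wide["stage"].nunique() if len(wide) else 2
        return RankTestResult(0.0, max(k - 1, 1), 1.0, (), False)
    groups = [
        wide.loc[wide["stage"] == st, col].to_list()
        for st in FLOWER_STAGES
        if (wide["stage"] == st).any()
    ]
    if len(groups) < 2:
        raise ValueError("need samples from at least two stages")
    return kruskal_wallis(groups)


def read_pollen_csv(path) -> list[PollenSample]:
    """Read long-format pollen counts: ``bee_id,capture_date,species,count``."""
    df = pd.read_csv(path, dtype={"bee_id": str, "species": str})
    samples = []
    for (bee, d), grp in df.groupby(["bee_id", "capture_date"], sort=False):
        counts = dict(zip(grp["species"], grp["count"].astype(int)))
        samples.append(PollenSample(bee, pd.Timestamp(d).date(), counts))
    return samples


def write_pollen_csv(samples: Sequence[PollenSample], path) -> None:
    rows = [
        {
            "bee_id": s.bee_id,
            "capture_date": s.capture_date.isoformat(),
            "species": sp,
            "count": c,
        }
        for s in samples
        for sp, c in s.counts.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
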