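"""Packaged per-bee summary table from the telemetry campaign.

The study's raw GPS fixes were not deposited; the only printed raw-ish
data are the per-bee summaries (17 radio-tracked queens: waypoint counts,
tracking dates, nest presence and substrate, MCP area in hectares, maximum
homing distance in meters). They ship here as a small CSV and drive the
reproducible statistics: stage summaries, rank tests, waypoint bookkeeping
and the nest-substrate breakdown.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_table1"]


def load_table1() -> pd.DataFrame:
    """The 17 printed per-bee rows.

    Columns: ``bee_id, stage, n_waypoints, start_date, end_date, n_days,
    nest, nest_substrate, mcp_ha, max_homing_m``. Stage labels use the
    pipeline's enum values (``before_nest`` / ``after_nest``).
    """
    with resources.files("beeranges.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(
            fh,
            dtype={"bee_id": str, "nest_substrate": str},
            parse_dates=["start_date", "end_date"],
        )
    df["nest_substrate"] = df["nest_substrate"].fillna("")
    return df
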