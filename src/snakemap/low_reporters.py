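"""Within-region low-reporter detection.

A municipality is flagged as a likely "low-reporter" when, among the
municipalities of its environmental region, it sits simultaneously in
the top 40% of the rural-population-percentage ranking and in the
bottom 40% of the reported-incidence ranking: a large rural population
should generate snakebites, so a low reported rate despite one suggests
cases are going unrecorded rather than not occurring.

"Top/bottom 40%" is implemented as rank position <= ceil(q x region
size), so even small regions can flag a municipality; ties in incidence
or rural share are broken by ascending municipality_id. Regions with
fewer than three municipalities are skipped with a warning because a
40% cut is degenerate there.
"""

from __future__ import annotations

import warnings
from math import ceil

import numpy as np
import pandas as pd

from .exceptions import ParameterError, SchemaError
from .regions import RegionAssignment

MIN_REGION_SIZE = 3


def aggregate_case_totals(case_series: pd.DataFrame) -> pd.DataFrame:
    """Collapse a weekly case series to per-municipality totals."""
    _require(case_series, ["municipality_id", "cases"])
    agg = {"cases": "sum"}
    if "deaths" in case_series.columns:
        agg["deaths"] = "sum"
    return case_series.groupby("municipality_id", as_index=False).agg(agg)


def detect_low_reporters(
    case_totals: pd.DataFrame,
    municipalities: pd.DataFrame,
    assignment: RegionAssignment,
    q: float = 0.40,
) -> pd.DataFrame:
    """Flag municipalities with low reported incidence but high rurality.

    Parameters
    ----------
    case_totals : per-municipality total reported cases (see
        :func:`aggregate_case_totals`).
    municipalities : table with municipality_id, population, pct_rural.
    assignment : region membership; ranking happens strictly within
        regions.
    q : quantile of both rankings (default 0.40).

    Returns
    -------
    DataFrame with municipality_id, region, incidence_per_100k,
    incidence_rank (1 = lowest incidence in region), rural_rank
    (1 = most rural in region) and the boolean ``low_reporter`` flag.
    """
    if not 0.0 <= q <= 1.0:
        raise ParameterError(f"q must be in [0, 1], got {q}")
    _require(municipalities, ["municipality_id", "population", "pct_rural"])
    _require(case_totals, ["municipality_id", "cases"])

    merged = municipalities[["municipality_id", "population", "pct_rural"]].merge(
        case_totals[["municipality_id", "cases"]], on="municipality_id", how="left"
    )
    merged["cases"] = merged["cases"].fillna(0).astype(float)
    if (merged["population"] <= 0).any():
        bad = merged.loc[merged["population"] <= 0, "municipality_id"].tolist()
        raise SchemaError(f"non-positive population for municipality_id(s): {bad}")
    if (merged["cases"] < 0).any():
        bad = merged.loc[merged["cases"] < 0, "municipality_id"].tolist()
        raise SchemaError(f"negative case total for municipality_id(s): {bad}")

    region_map = assignment.mapping()
    unassigned = set(merged["municipality_id"]) - set(region_map.index)
    if unassigned:
        raise SchemaError(
            f"municipality_id(s) without a region: {sorted(unassigned)}"
        )
    merged["region"] = merged["municipality_id"].map(region_map)
    merged["incidence_per_100k"] = 1e5 * merged["cases"] / merged["population"]

    out_parts = []
    for region, grp in merged.groupby("region", sort=True):
        grp = grp.copy()
        n_r = len(grp)
        if n_r < MIN_REGION_SIZE:
            warnings.warn(
                f"region {region!r} has only {n_r} municipalities; "
                "low-reporter detection skipped there",
                stacklevel=2,
            )
            grp["incidence_rank"] = np.nan
            grp["rural_rank"] = np.nan
            grp["low_reporter"] = False
            out_parts.append(grp)
            continue
        cut = ceil(q * n_r)
        inc_order = grp.sort_values(
            ["incidence_per_100k", "municipality_id"], kind="mergesort"
        ).index
        rur_order = grp.sort_values(
            ["pct_rural", "municipality_id"],
            ascending=[False, True],
            kind="mergesort",
        ).index
        grp.loc[inc_order, "incidence_rank"] = np.arange(1, n_r + 1)
        grp.loc[rur_order, "rural_rank"] = np.arange(1, n_r + 1)
        grp["low_reporter"] = (grp["incidence_rank"] <= cut) & (
            grp["rural_rank"] <= cut
        )
        out_parts.append(grp)

    out = pd.concat(out_parts).sort_values("municipality_id", kind="mergesort")
    cols = [
        "municipality_id",
        "region",
        "incidence_per_100k",
        "incidence_rank",
        "rural_rank",
        "low_reporter",
    ]
    return out[cols].reset_index(drop=True)


def _require(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"table is missing required column(s): {', '.join(missing)}")
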