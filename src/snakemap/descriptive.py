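"""Descriptive surveillance statistics.

Cumulative and annual incidence per 100,000 inhabitants, mortality per
100,000, case fatality rate, per-region incidence, and weekly seasonal
curves smoothed with a 5-week centered sliding mean (the week, the two
previous and the two following weeks). The seasonal profile is the mean
count per epidemiological week across years, smoothed circularly so
week 1 neighbours week 52; ISO week 53, when present, is folded into
week 52.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ParameterError, SchemaError
from .regions import RegionAssignment


@dataclass
class IncidenceSummary:
    """National descriptive summary over the surveillance period."""

    total_cases: int
    total_deaths: int
    population: int
    years: int
    incidence_per_100k: float  # cumulative over the period
    annual_incidence_per_100k: float
    mortality_per_100k: float  # deaths per 100,000 over the period
    case_fatality_pct: float

    def rounded(self) -> dict:
        """Presentation rounding: incidence to integers, CFR to integer
        percent, mortality to one decimal."""
        return {
            "total_cases": self.total_cases,
            "total_deaths": self.total_deaths,
            "population": self.population,
            "incidence_per_100k": round(self.incidence_per_100k),
            "annual_incidence_per_100k": round(self.annual_incidence_per_100k, 1),
            "mortality_per_100k": round(self.mortality_per_100k, 1),
            "case_fatality_pct": round(self.case_fatality_pct),
        }

    def to_dict(self) -> dict:
        return {
            "total_cases": self.total_cases,
            "total_deaths": self.total_deaths,
            "population": self.population,
            "years": self.years,
            "incidence_per_100k": self.incidence_per_100k,
            "annual_incidence_per_100k": self.annual_incidence_per_100k,
            "mortality_per_100k": self.mortality_per_100k,
            "case_fatality_pct": self.case_fatality_pct,
        }


def incidence_summary(
    case_series: pd.DataFrame, municipalities: pd.DataFrame, years: int
) -> IncidenceSummary:
    """National incidence, mortality and case fatality from a case series.

    ``incidence_per_100k`` is 100,000 x total cases / total population
    over the whole period; the annual figure is that divided by
    ``years`` (so annual x years = cumulative exactly, pre-rounding).
    A series with zero cases yields zero incidence and a CFR defined as
    0 with a warning.
    """
    _require(case_series, ["municipality_id", "cases"])
    _require(municipalities, ["municipality_id", "population"])
    population = int(municipalities["population"].sum())
    if population <= 0:
        raise SchemaError("total population must be positive")
    cases = int(case_series["cases"].sum())
    deaths = int(case_series["deaths"].sum()) if "deaths" in case_series.columns else 0
    if deaths > cases:
        raise SchemaError(f"deaths ({deaths}) exceed cases ({cases})")
    if cases == 0:
        warnings.warn("no cases in series; case fatality rate reported as 0")
        cfr = 0.0
    else:
        cfr = 100.0 * deaths / cases
    cumulative = 1e5 * cases / population
    return IncidenceSummary(
        total_cases=cases,
        total_deaths=deaths,
        population=population,
        years=years,
        incidence_per_100k=cumulative,
        annual_incidence_per_100k=cumulative / years,
        mortality_per_100k=1e5 * deaths / population,
        case_fatality_pct=cfr,
    )


def percent_share(part: float, total: float) -> float:
    """Share of a subgroup among all reports, in percent."""
    if total <= 0:
        raise ParameterError("total must be positive")
    return 100.0 * part / total


def regional_incidence(
    case_series: pd.DataFrame,
    municipalities: pd.DataFrame,
    assignment: RegionAssignment,
) -> pd.DataFrame:
    """Per-region cumulative incidence per 100,000 over the series period."""
    _require(case_series, ["municipality_id", "cases"])
    _require(municipalities, ["municipality_id", "population"])
    totals = case_series.groupby("municipality_id")["cases"].sum()
    merged = municipalities[["municipality_id", "population"]].copy()
    merged["cases"] = merged["municipality_id"].map(totals).fillna(0)
    merged["region"] = merged["municipality_id"].map(assignment.mapping())
    if merged["region"].isna().any():
        bad = merged.loc[merged["region"].isna(), "municipality_id"].tolist()
        raise SchemaError(f"municipality_id(s) without a region: {bad}")
    out = merged.groupby("region", sort=True).agg(
        cases=("cases", "sum"), population=("population", "sum")
    )
    out["incidence_per_100k"] = 1e5 * out["cases"] / out["population"]
    return out.reset_index()


def weekly_profile(
    case_series: pd.DataFrame,
    assignment: RegionAssignment | None = None,
    grouping: Mapping[str, str] | None = None,
    weeks_per_year: int = 52,
) -> pd.DataFrame:
    """Mean weekly count per (super-)region: week x region profile.

    For each region (or the whole country when no assignment is given)
    the profile is the national sum of counts in that week divided by
    the number of years observed; weeks beyond ``weeks_per_year`` fold
    into the last week.
    """
    _require(case_series, ["municipality_id", "year", "week", "cases"])
    df = case_series.copy()
    df["week"] = np.minimum(df["week"].to_numpy(int), weeks_per_year)
    if assignment is not None:
        df["region"] = df["municipality_id"].map(assignment.mapping())
        if df["region"].isna().any():
            raise SchemaError("case series references municipalities without a region")
        if grouping is not None:
            missing = sorted(set(df["region"]) - set(grouping))
            if missing:
                raise SchemaError(f"grouping is missing region label(s): {missing}")
            df["region"] = df["region"].map(dict(grouping))
    else:
        df["region"] = "national"
    n_years = df["year"].nunique()
    prof = (
        df.groupby(["region", "week"], sort=True)["cases"].sum() / n_years
    ).rename("mean_weekly_cases")
    # ensure every week appears even when empty
    full = pd.MultiIndex.from_product(
        [sorted(df["region"].unique()), range(1, weeks_per_year + 1)],
        names=["region", "week"],
    )
    return prof.reindex(full, fill_value=0.0).reset_index()


def seasonal_smooth(values: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered circular moving average of a weekly profile.

    The default 5-week window averages the week itself with the two
    previous and two following weeks; the series wraps (week 1
    neighbours the last week), so the smoothed mean equals the raw mean
    to machine precision.
    """
    x = np.asarray(values, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be odd and >= 1, got {window}")
    if window > len(x):
        raise ParameterError(
            f"window {window} exceeds series length {len(x)}"
        )
    half = window // 2
    out = np.zeros_like(x)
    for shift in range(-half, half + 1):
        out += np.roll(x, -shift)
    return out / window


def seasonal_curves(
    case_series: pd.DataFrame,
    assignment: RegionAssignment | None = None,
    grouping: Mapping[str, str] | None = None,
    window: int = 5,
    weeks_per_year: int = 52,
) -> pd.DataFrame:
    """Raw and smoothed weekly curves per (super-)region."""
    prof = weekly_profile(case_series, assignment, grouping, weeks_per_year)
    parts = []
    for region, grp in prof.groupby("region", sort=True):
        grp = grp.sort_values("week").copy()
        grp["smoothed"] = seasonal_smooth(grp["mean_weekly_cases"].to_numpy(), window)
        parts.append(grp)
    return pd.concat(parts, ignore_index=True)


def plot_seasonal(curves: pd.DataFrame, path: str) -> None:
    """Write a PNG of the smoothed weekly curves, one line per region."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    for region, grp in curves.groupby("region"):
        ax.plot(grp["week"], grp["smoothed"], label=str(region))
    ax.set_xlabel("epidemiological week")
    ax.set_ylabel("mean weekly reported cases (5-week sliding mean)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _require(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"table is missing required column(s): {', '.join(missing)}")
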