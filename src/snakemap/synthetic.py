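"""Synthetic country generator.

Builds a municipality table and a weekly snakebite case series with the
statistical structure the downstream analysis assumes, together with a
ground-truth record of which municipalities underreport:

* true weekly counts are Poisson with rate
  population x baseline x region multiplier x exp(rural_effect x %rural)
  x seasonal sinusoid, rescaled by one national constant so the
  population-weighted national rate equals ``baseline_rate`` exactly;
* observed counts are a binomial thinning of the true counts with a
  reporting probability that is 1 for municipalities below the
  deprivation knee quantile of the six-variable rank-sum index and then
  decays linearly to ``reporting_floor`` for the most deprived;
* deaths are a further binomial thinning of observed counts at the case
  fatality rate.

Randomness comes from one seed consumed in documented order: the
municipality attributes use the stream keyed ``seed`` and the weekly
counts the child stream keyed ``(seed, 1)``, so the municipality table
is reproducible independently of the case series and partial re-runs
give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import DEPRIVATION_VARIABLES, SyntheticConfig
from .exceptions import SchemaError
from .underreporting import (
    compute_index,
    deprivation_quantile,
    rank_variables,
)

#: Columns every downstream stage expects in a municipality table.
MUNICIPALITY_COLUMNS = (
    "municipality_id",
    "sim_region",
    "population",
    "pct_rural",
    "pct_under15",
    "pct_male_surplus",
    *DEPRIVATION_VARIABLES,
    "altitude_m",
    "precipitation_mm_y",
    "x_km",
    "y_km",
)


@dataclass
class SyntheticTruth:
    """Ground truth of the generator, one row per municipality.

    ``table`` columns: municipality_id, true_rate (expected bites per
    inhabitant over the simulated period), reporting_prob, and
    underreporter_flag (reporting_prob < cutoff).
    """

    table: pd.DataFrame
    cutoff: float

    def __post_init__(self) -> None:
        t = self.table
        assert ((t["reporting_prob"] > 0) & (t["reporting_prob"] <= 1)).all()
        assert (t["true_rate"] >= 0).all()
        assert t["underreporter_flag"].equals(t["reporting_prob"] < self.cutoff)


def simulate_municipalities(config: SyntheticConfig) -> pd.DataFrame:
    """Draw the municipality table for one synthetic country.

    Populations are log-normal around 30,000 inhabitants; rural share is
    anticorrelated with population size; the six deprivation variables
    share a latent axis with rurality (rank correlation > 0.3 by
    construction); altitude and precipitation are drawn around region
    means; centroids scatter around well-separated region centres so the
    generated regions are spatially contiguous.
    """
    rng = np.random.default_rng(config.seed)
    regions = config.region_table()
    n = config.n_municipalities

    region_names = np.repeat([r["region"] for r in regions], [r["count"] for r in regions])
    region_index = np.repeat(np.arange(len(regions)), [r["count"] for r in regions])

    population = rng.lognormal(mean=np.log(28_000.0), sigma=0.8, size=n)
    z_pop = _zscore(np.log(population))

    rural_latent = -0.45 * z_pop + 0.9 * rng.standard_normal(n)
    pct_rural = np.clip(55.0 + 18.0 * rural_latent, 2.0, 98.0)
    z_rural = _zscore(pct_rural)

    deprivation = {}
    scales = {
        "dist_hospital_m": lambda lat: np.round(np.exp(8.8 + 0.7 * lat)),
        "pct_households_far_health": lambda lat: 100.0 * expit(0.9 * lat - 0.4),
        "pct_poverty": lambda lat: 100.0 * expit(0.8 * lat + 0.4),
        "pct_illiteracy": lambda lat: 100.0 * expit(0.9 * lat - 0.9),
        "pct_area_far_road": lambda lat: 100.0 * expit(1.0 * lat - 0.2),
        "births_outside_rate": lambda lat: expit(1.1 * lat - 1.2),
    }
    for var in DEPRIVATION_VARIABLES:
        latent = 0.65 * z_rural + 0.76 * rng.standard_normal(n)
        deprivation[var] = scales[var](latent)

    pct_under15 = np.clip(37.0 + 2.5 * z_rural + rng.normal(0.0, 2.5, n), 20.0, 50.0)
    pct_male_surplus = np.clip(0.5 * z_rural + rng.normal(0.0, 1.5, n), -8.0, 8.0)

    alt_means = np.array([r["altitude_m"] for r in regions])[region_index]
    altitude = np.clip(alt_means + rng.normal(0.0, 0.15 * alt_means + 30.0, n), 0.0, None)
    prec_means = np.array([r["precipitation_mm_y"] for r in regions])[region_index]
    precipitation = np.clip(prec_means + rng.normal(0.0, 200.0, n), 300.0, None)

    centres = np.array([r["centre"] for r in regions])[region_index]
    coords = centres + rng.normal(0.0, 9.0, size=(n, 2))

    return pd.DataFrame(
        {
            "municipality_id": np.arange(1, n + 1),
            "sim_region": region_names,
            "population": np.round(population).astype(int),
            "pct_rural": pct_rural,
            "pct_under15": pct_under15,
            "pct_male_surplus": pct_male_surplus,
            **deprivation,
            "altitude_m": altitude,
            "precipitation_mm_y": precipitation,
            "x_km": coords[:, 0],
            "y_km": coords[:, 1],
        }
    )


def expected_case_totals(
    municipalities: pd.DataFrame, config: SyntheticConfig
) -> pd.Series:
    """Closed-form expected true case count per municipality over the period.

    The relative rate of municipality i is
    ``population_i x multiplier(region_i) x exp(rural_effect x pct_rural_i)``;
    one national constant rescales these so the population-weighted mean
    rate equals ``baseline_rate`` per 100,000 over the simulated period.
    Region multipliers and the rural effect therefore act as pure rate
    ratios, which is what the incidence model estimates.
    """
    _require(municipalities, ["municipality_id", "sim_region", "population", "pct_rural"])
    regions = config.region_table()
    mult = {r["region"]: r["multiplier"] for r in regions}
    unknown = set(municipalities["sim_region"]) - set(mult)
    if unknown:
        raise SchemaError(f"unknown sim_region value(s): {sorted(unknown)}")
    pop = municipalities["population"].to_numpy(dtype=float)
    raw = (
        pop
        * municipalities["sim_region"].map(mult).to_numpy(dtype=float)
        * np.exp(config.rural_effect * municipalities["pct_rural"].to_numpy(dtype=float))
    )
    national_total = pop.sum() * config.baseline_rate / 1e5
    lam = raw * national_total / raw.sum()
    return pd.Series(lam, index=municipalities.index, name="expected_cases")


def reporting_probabilities(
    municipalities: pd.DataFrame, config: SyntheticConfig
) -> pd.Series:
    """Per-municipality reporting probability from the deprivation ranking.

    The rank-sum index of the six deprivation variables orders the
    municipalities; below the knee quantile every true case is reported,
    above it the reporting probability falls linearly to the floor for
    the single most deprived municipality.
    """
    index = compute_index(rank_variables(municipalities, DEPRIVATION_VARIABLES))
    d = deprivation_quantile(index).to_numpy()
    knee, floor = config.deprivation_reporting_knee, config.reporting_floor
    p = np.where(
        d <= knee, 1.0, 1.0 - (1.0 - floor) * (d - knee) / (1.0 - knee)
    )
    return pd.Series(p, index=municipalities.index, name="reporting_prob")


def seasonal_multipliers(config: SyntheticConfig) -> np.ndarray:
    """(n_regions, weeks_per_year) sinusoidal forcing with unit weekly mean."""
    weeks = np.arange(1, config.weeks_per_year + 1)
    peaks = np.array([r["peak_week"] for r in config.region_table()])
    phase = 2.0 * np.pi * (weeks[None, :] - peaks[:, None]) / config.weeks_per_year
    return 1.0 + config.seasonal_amplitude * np.cos(phase)


def simulate_cases(
    municipalities: pd.DataFrame, config: SyntheticConfig
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw the weekly case series and the underreporting ground truth.

    Returns
    -------
    cases : long table (municipality_id, year, week, cases, deaths,
        true_cases); ``cases`` is the observed (reported) count, a
        binomial thinning of ``true_cases``.
    truth : :class:`SyntheticTruth` with per-municipality true rate,
        reporting probability and underreporter flag.
    """
    _require(
        municipalities,
        ["municipality_id", "sim_region", "population", "pct_rural", *DEPRIVATION_VARIABLES],
    )
    rng = np.random.default_rng([config.seed, 1])  # child stream: weekly counts

    n = len(municipalities)
    lam_total = expected_case_totals(municipalities, config).to_numpy()
    p_report = reporting_probabilities(municipalities, config).to_numpy()

    regions = config.region_table()
    region_pos = {r["region"]: i for i, r in enumerate(regions)}
    ridx = municipalities["sim_region"].map(region_pos).to_numpy()
    season = seasonal_multipliers(config)[ridx]  # (n, weeks_per_year)

    wpy, years = config.weeks_per_year, config.years
    weekly_lam = (lam_total / (years * wpy))[:, None] * season  # one year
    weekly_lam = np.tile(weekly_lam, (1, years))  # (n, years*wpy)

    true_counts = rng.poisson(weekly_lam)
    observed = rng.binomial(true_counts, p_report[:, None])
    deaths = rng.binomial(observed, config.case_fatality)

    ids = municipalities["municipality_id"].to_numpy()
    year_idx = np.repeat(np.arange(1, years + 1), wpy)
    week_idx = np.tile(np.arange(1, wpy + 1), years)
    cases = pd.DataFrame(
        {
            "municipality_id": np.repeat(ids, years * wpy),
            "year": np.tile(year_idx, n),
            "week": np.tile(week_idx, n),
            "cases": observed.ravel(),
            "deaths": deaths.ravel(),
            "true_cases": true_counts.ravel(),
        }
    )
    truth = SyntheticTruth(
        table=pd.DataFrame(
            {
                "municipality_id": ids,
                "true_rate": lam_total / municipalities["population"].to_numpy(float),
                "reporting_prob": p_report,
                "underreporter_flag": p_report < config.underreporter_cutoff,
            }
        ),
        cutoff=config.underreporter_cutoff,
    )
    return cases, truth


def _require(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(
            f"municipality table is missing required column(s): {', '.join(missing)}"
        )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)
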