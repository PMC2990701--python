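"""Configuration for the synthetic-country generator.

The defaults describe a country of 152 municipalities in seven
environmental regions observed for five 52-week years, with a national
5-year reported incidence of 56 bites per 100,000 — the study conditions
the rest of the package is exercised against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

from .exceptions import ConfigError

#: Canonical seven environmental regions: name, share of municipalities,
#: incidence multiplier relative to the national rate, typical altitude (m),
#: typical annual precipitation (mm), and map centre (km east, km north).
#: Multipliers are the published per-region 5-year incidences divided by the
#: national 56 per 100,000.
CANONICAL_REGIONS = (
    # name,               count, multiplier,  alt, precip, (x, y)
    ("West Coast South", 11, 58.8 / 56.0, 100.0, 1600.0, (20.0, 30.0)),
    ("West Coast Central", 19, 24.1 / 56.0, 150.0, 1400.0, (25.0, 80.0)),
    ("West Coast North", 12, 39.8 / 56.0, 200.0, 1500.0, (35.0, 130.0)),
    ("West Coast High", 14, 26.8 / 56.0, 900.0, 1300.0, (62.0, 110.0)),
    ("Mountains", 56, 59.6 / 56.0, 700.0, 2000.0, (95.0, 140.0)),
    ("East Inland", 22, 46.8 / 56.0, 150.0, 2800.0, (145.0, 100.0)),
    ("East Coast", 18, 187.9 / 56.0, 30.0, 3800.0, (195.0, 90.0)),
)

#: The six municipality deprivation / health-access variables that enter the
#: underreporting index (all oriented so a higher raw value is worse).
DEPRIVATION_VARIABLES = (
    "dist_hospital_m",
    "pct_households_far_health",
    "pct_poverty",
    "pct_illiteracy",
    "pct_area_far_road",
    "births_outside_rate",
)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic municipality/case generator.

    Parameters
    ----------
    n_municipalities : total administrative units (default 152).
    n_regions : environmental regions (default 7; the canonical menu of
        region names, multipliers and climates is used when this is 7).
    years, weeks_per_year : length of the surveillance series.
    seed : seed of the single RNG stream (municipalities drawn first,
        then weekly counts).
    baseline_rate : national expected reported+unreported bites per
        100,000 inhabitants over the whole period (default 56).
    region_multipliers : per-region incidence multipliers (default: the
        canonical menu for 7 regions, otherwise all 1).
    region_peak_weeks : per-region seasonal peak week (default 50,
        i.e. mid-December).
    rural_effect : log-rate increment per percentage point rural
        population (default log 1.017).
    seasonal_amplitude : relative amplitude of the annual sinusoid in
        [0, 1); 0.5 gives a peak/trough ratio of 3.
    reporting_floor : reporting probability of the most deprived
        municipality, in (0, 1].
    deprivation_reporting_knee : deprivation-rank quantile in (0, 1) above
        which reporting decays linearly from 1 to ``reporting_floor``.
    underreporter_cutoff : municipalities with reporting probability below
        this are recorded as true underreporters in the truth table.
    case_fatality : probability a reported case is fatal (default 0.01).
    """

    n_municipalities: int = 152
    n_regions: int = 7
    years: int = 5
    weeks_per_year: int = 52
    seed: int = 0
    baseline_rate: float = 56.0
    region_multipliers: tuple[float, ...] | None = None
    region_peak_weeks: tuple[int, ...] | None = None
    rural_effect: float = 0.016857  # log(1.017)
    seasonal_amplitude: float = 0.5
    reporting_floor: float = 0.5
    deprivation_reporting_knee: float = 0.85
    underreporter_cutoff: float = 0.7
    case_fatality: float = 0.01

    def __post_init__(self) -> None:
        def _positive_int(name: str) -> None:
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 1:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")

        for name in ("n_municipalities", "n_regions", "years", "weeks_per_year"):
            _positive_int(name)
        if self.weeks_per_year < 5:
            raise ConfigError(
                "weeks_per_year must be >= 5 (the 5-week smoothing window "
                f"must fit), got {self.weeks_per_year}"
            )
        if self.n_regions > self.n_municipalities:
            raise ConfigError(
                "n_regions cannot exceed n_municipalities "
                f"({self.n_regions} > {self.n_municipalities})"
            )
        if self.baseline_rate <= 0:
            raise ConfigError(f"baseline_rate must be > 0, got {self.baseline_rate}")
        if self.region_multipliers is not None:
            self.region_multipliers = tuple(float(m) for m in self.region_multipliers)
            if len(self.region_multipliers) != self.n_regions:
                raise ConfigError(
                    "region_multipliers must have one entry per region "
                    f"({self.n_regions}), got {len(self.region_multipliers)}"
                )
            if any(m <= 0 for m in self.region_multipliers):
                raise ConfigError("region_multipliers must all be > 0")
        if self.region_peak_weeks is not None:
            self.region_peak_weeks = tuple(int(w) for w in self.region_peak_weeks)
            if len(self.region_peak_weeks) != self.n_regions:
                raise ConfigError(
                    "region_peak_weeks must have one entry per region "
                    f"({self.n_regions}), got {len(self.region_peak_weeks)}"
                )
        if not 0.0 <= self.seasonal_amplitude < 1.0:
            raise ConfigError(
                f"seasonal_amplitude must be in [0, 1), got {self.seasonal_amplitude}"
            )
        if not 0.0 < self.reporting_floor <= 1.0:
            raise ConfigError(
                f"reporting_floor must be in (0, 1], got {self.reporting_floor}"
            )
        if not 0.0 < self.deprivation_reporting_knee < 1.0:
            raise ConfigError(
                "deprivation_reporting_knee must be in (0, 1), got "
                f"{self.deprivation_reporting_knee}"
            )
        if not 0.0 < self.underreporter_cutoff <= 1.0:
            raise ConfigError(
                f"underreporter_cutoff must be in (0, 1], got {self.underreporter_cutoff}"
            )
        if not 0.0 <= self.case_fatality <= 1.0:
            raise ConfigError(
                f"case_fatality must be in [0, 1], got {self.case_fatality}"
            )

    # -- region layout ----------------------------------------------------

    def region_table(self) -> list[dict]:
        """Resolved per-region layout: name, count, multiplier, climate, centre.

        With seven regions the canonical national layout is used and
        municipality counts are apportioned to its published shares by
        largest remainder; otherwise regions are generic, equal-sized,
        with unit multipliers and a grid of map centres.
        """
        k, n = self.n_regions, self.n_municipalities
        if k == len(CANONICAL_REGIONS):
            names = [r[0] for r in CANONICAL_REGIONS]
            shares = [r[1] for r in CANONICAL_REGIONS]
            mults = [r[2] for r in CANONICAL_REGIONS]
            alts = [r[3] for r in CANONICAL_REGIONS]
            precs = [r[4] for r in CANONICAL_REGIONS]
            centres = [r[5] for r in CANONICAL_REGIONS]
            counts = _largest_remainder(shares, n)
        else:
            names = [f"region_{i + 1:02d}" for i in range(k)]
            mults = [1.0] * k
            alts = [200.0 + 1300.0 * i / max(k - 1, 1) for i in range(k)]
            precs = [1200.0 + 2600.0 * i / max(k - 1, 1) for i in range(k)]
            side = int(np_ceil_sqrt(k))
            centres = [(60.0 * (i % side), 60.0 * (i // side)) for i in range(k)]
            counts = _largest_remainder([1.0] * k, n)
        if self.region_multipliers is not None:
            mults = list(self.region_multipliers)
        peaks = (
            list(self.region_peak_weeks)
            if self.region_peak_weeks is not None
            else [min(50, self.weeks_per_year)] * k
        )
        return [
            {
                "region": names[i],
                "count": counts[i],
                "multiplier": mults[i],
                "altitude_m": alts[i],
                "precipitation_mm_y": precs[i],
                "centre": centres[i],
                "peak_week": peaks[i],
            }
            for i in range(k)
        ]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for key in ("region_multipliers", "region_peak_weeks"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _largest_remainder(shares: Sequence[float], n: int) -> list[int]:
    """Apportion ``n`` items proportionally to ``shares`` (each region >= 1)."""
    total = float(sum(shares))
    quotas = [s / total * n for s in shares]
    counts = [int(q) for q in quotas]
    remainders = sorted(
        range(len(shares)), key=lambda i: (quotas[i] - counts[i], -i), reverse=True
    )
    for i in remainders[: n - sum(counts)]:
        counts[i] += 1
    # guarantee non-empty regions when n >= k
    while min(counts) == 0 and n >= len(shares):
        counts[counts.index(max(counts))] -= 1
        counts[counts.index(0)] += 1
    return counts


def np_ceil_sqrt(k: int) -> int:
    s = int(k**0.5)
    return s if s * s >= k else s + 1
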