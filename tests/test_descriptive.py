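"""Descriptive statistics and seasonal smoothing."""

import numpy as np
import pandas as pd
import pytest

from snakemap import (
    ParameterError,
    RegionAssignment,
    SchemaError,
    incidence_summary,
    regional_incidence,
    seasonal_curves,
    seasonal_smooth,
    weekly_profile,
)


def _series(cases, deaths=0, mid=1):
    return pd.DataFrame(
        {
            "municipality_id": [mid],
            "year": [1],
            "week": [1],
            "cases": [cases],
            "deaths": [deaths],
        }
    )


def _mun(population, mid=1):
    return pd.DataFrame({"municipality_id": [mid], "population": [population]})


class TestIncidenceSummary:
    def test_national_five_year_incidence(self):
        s = incidence_summary(_series(3286, 34), _mun(5_900_000), years=5)
        assert s.incidence_per_100k == pytest.approx(55.7, abs=0.05)
        assert s.rounded()["incidence_per_100k"] == 56
        assert s.annual_incidence_per_100k * 5 == pytest.approx(
            s.incidence_per_100k, rel=1e-12
        )

    def test_case_fatality_and_mortality(self):
        s = incidence_summary(_series(3286, 34), _mun(5_900_000), years=5)
        assert s.rounded()["case_fatality_pct"] == 1
        assert s.rounded()["mortality_per_100k"] == 0.6

    def test_zero_cases_warns_and_reports_zero(self):
        with pytest.warns(UserWarning, match="no cases"):
            s = incidence_summary(_series(0, 0), _mun(1000), years=1)
        assert s.incidence_per_100k == 0.0
        assert s.case_fatality_pct == 0.0

    def test_zero_population_rejected(self):
        with pytest.raises(SchemaError):
            incidence_summary(_series(1), _mun(0), years=1)

    def test_deaths_exceeding_cases_rejected(self):
        with pytest.raises(SchemaError):
            incidence_summary(_series(1, 5), _mun(1000), years=1)


class TestRegionalIncidence:
    @staticmethod
    def _assignment(regions):
        n = len(regions)
        return RegionAssignment(
            table=pd.DataFrame(
                {"municipality_id": range(1, n + 1), "region": regions}
            )
        )

    def test_single_region_equals_national(self):
        cases = pd.concat([_series(10, mid=1), _series(30, mid=2)], ignore_index=True)
        mun = pd.concat([_mun(100_000, 1), _mun(100_000, 2)], ignore_index=True)
        out = regional_incidence(cases, mun, self._assignment(["A", "A"]))
        national = incidence_summary(cases, mun, years=1).incidence_per_100k
        assert out["incidence_per_100k"].iloc[0] == pytest.approx(national)

    def test_incidence_proportional_to_cases(self):
        cases = pd.concat([_series(10, mid=1), _series(30, mid=2)], ignore_index=True)
        mun = pd.concat([_mun(100_000, 1), _mun(100_000, 2)], ignore_index=True)
        out = regional_incidence(cases, mun, self._assignment(["A", "B"])).set_index(
            "region"
        )
        assert out.loc["B", "incidence_per_100k"] == pytest.approx(
            3 * out.loc["A", "incidence_per_100k"]
        )

    def test_region_totals_conserve_national_count(
        self, municipalities, cases_and_truth
    ):
        from snakemap import assign_regions

        cases, _ = cases_and_truth
        out = regional_incidence(cases, municipalities, assign_regions(municipalities))
        assert out["cases"].sum() == cases["cases"].sum()

    def test_highest_multiplier_region_has_highest_incidence(self):
        """The generating region with the largest rate multiplier comes out
        on top of the computed per-region incidence table (10 replicates)."""
        from snakemap import SyntheticConfig, simulate_cases, simulate_municipalities

        wins = 0
        for seed in range(10):
            cfg = SyntheticConfig(seed=400 + seed, reporting_floor=1.0)
            mun = simulate_municipalities(cfg)
            cases, _ = simulate_cases(mun, cfg)
            asg = RegionAssignment(
                table=mun[["municipality_id", "sim_region"]].rename(
                    columns={"sim_region": "region"}
                )
            )
            out = regional_incidence(cases, mun, asg).set_index("region")
            top_true = max(cfg.region_table(), key=lambda r: r["multiplier"])["region"]
            wins += out["incidence_per_100k"].idxmax() == top_true
        assert wins == 10


class TestSeasonalSmooth:
    def test_constant_series_preserved(self):
        x = np.full(52, 3.7)
        assert np.allclose(seasonal_smooth(x), x)

    def test_unit_impulse_spreads_boxcar(self):
        x = np.zeros(52)
        x[9] = 1.0  # week 10
        s = seasonal_smooth(x, window=5)
        assert np.allclose(s[7:12], 0.2)
        assert s.sum() == pytest.approx(1.0)
        assert np.allclose(np.delete(s, range(7, 12)), 0.0)

    def test_circular_mean_preserved(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 10, 52)
        s = seasonal_smooth(x, window=5)
        assert s.mean() == pytest.approx(x.mean(), rel=1e-12)
        # oracle: direct 5-term averaging loop with wraparound
        direct = np.array(
            [np.mean([x[(i + d) % 52] for d in (-2, -1, 0, 1, 2)]) for i in range(52)]
        )
        assert np.allclose(s, direct)

    def test_linearity(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=52), rng.normal(size=52)
        lhs = seasonal_smooth(2.0 * x + 3.0 * y)
        rhs = 2.0 * seasonal_smooth(x) + 3.0 * seasonal_smooth(y)
        assert np.allclose(lhs, rhs)

    @pytest.mark.parametrize("window", [0, 2, 4])
    def test_even_or_zero_window_rejected(self, window):
        with pytest.raises(ParameterError):
            seasonal_smooth(np.zeros(52), window=window)


class TestSeasonalCurves:
    def test_week53_folds_into_52(self):
        cases = pd.DataFrame(
            {
                "municipality_id": [1, 1],
                "year": [1, 1],
                "week": [52, 53],
                "cases": [2, 3],
            }
        )
        prof = weekly_profile(cases)
        assert prof.loc[prof["week"] == 52, "mean_weekly_cases"].iloc[0] == 5.0
        assert prof["week"].max() == 52

    def test_peak_week_recovered_from_synthetic_east(self, municipalities, cases_and_truth):
        cases, _ = cases_and_truth
        asg = RegionAssignment(
            table=municipalities[["municipality_id", "sim_region"]].rename(
                columns={"sim_region": "region"}
            )
        )
        grouping = {
            r: ("East" if r.startswith("East") else "West")
            for r in asg.table["region"].unique()
        }
        curves = seasonal_curves(cases, asg, grouping)
        east = curves[curves["region"] == "East"].set_index("week")
        peak = east["smoothed"].idxmax()
        # generator peak is week 50 (December); Poisson noise plus the
        # 5-week smoother can displace it by a few weeks (circularly)
        dist = min(abs(peak - 50), 52 - abs(peak - 50))
        assert dist <= 6
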