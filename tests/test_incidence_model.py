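"""Poisson rate model: closed forms, grid-search oracle, design bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from snakemap import (
    ModelSpec,
    ParameterError,
    RankDeficiencyError,
    SchemaError,
    build_design,
    fit_poisson_rates,
    model_comparison_report,
    predict_rates,
)


def grid_search_two_param(y, x, pop, passes=9, grid=41):
    """Independent oracle: coarse-to-fine grid maximization of the Poisson
    log-likelihood sum(y * eta - exp(eta)) with eta = b0 + b1 x + log pop.

    The search runs over the decorrelated pair (a, b1) with
    a = b0 + b1 * mean(x), starting at the closed-form pooled rate; each
    pass zooms the grid to twice its previous spacing around the argmax
    (the log-likelihood is concave, so the maximum cannot escape)."""
    logpop = np.log(pop)
    xc = x - x.mean()
    a, b1 = np.log((y.sum() + 0.5) / pop.sum()), 0.0
    wa, wb = 4.0, 0.2
    for _ in range(passes):
        ga = np.linspace(a - wa, a + wa, grid)
        gb = np.linspace(b1 - wb, b1 + wb, grid)
        eta = ga[:, None, None] + gb[None, :, None] * xc + logpop
        ll = (y * eta - np.exp(eta)).sum(axis=2)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        a, b1 = ga[i], gb[j]
        wa *= 4.0 / (grid - 1)
        wb *= 4.0 / (grid - 1)
    return a - b1 * x.mean(), b1


def _random_dataset(rng, n=25):
    pop = rng.integers(5_000, 80_000, n)
    x = rng.uniform(0, 60, n)
    b0, b1 = np.log(rng.uniform(1e-4, 1e-3)), rng.uniform(-0.02, 0.02)
    y = rng.poisson(pop * np.exp(b0 + b1 * x))
    return pd.DataFrame(
        {"municipality_id": range(1, n + 1), "population": pop, "pct_rural": x, "cases": y}
    )


SIMPLE = ModelSpec(include_region=False, include_index=False, continuous=())
RURAL_ONLY = ModelSpec(include_region=False, include_index=False, continuous=("pct_rural",))


def test_intercept_only_recovers_pooled_rate():
    data = pd.DataFrame({"population": [50_000, 150_000], "cases": [10, 40]})
    fit = fit_poisson_rates(data.assign(municipality_id=[1, 2]), SIMPLE)
    assert np.exp(fit.params["intercept"]) == pytest.approx(50 / 200_000, rel=1e-10)
    assert fit.converged


def test_two_group_saturated_ir_is_exact():
    data = pd.DataFrame(
        {
            "municipality_id": [1, 2],
            "population": [100_000, 100_000],
            "cases": [10, 30],
            "region": ["A", "B"],
        }
    )
    spec = ModelSpec(include_index=False, continuous=(), region_reference="A")
    # saturated two-group model: n == p, so relax the row check via 4 rows
    data4 = pd.concat([data, data.assign(municipality_id=[3, 4])], ignore_index=True)
    fit = fit_poisson_rates(data4, spec)
    assert fit.ir["region[B]"] == pytest.approx(3.0, rel=1e-8)


def test_irls_matches_grid_oracle_small_data():
    rng = np.random.default_rng(42)
    data = _random_dataset(rng, n=8)
    fit = fit_poisson_rates(data, RURAL_ONLY)
    b0, b1 = grid_search_two_param(
        data["cases"].to_numpy(float),
        data["pct_rural"].to_numpy(float),
        data["population"].to_numpy(float),
    )
    assert fit.params["intercept"] == pytest.approx(b0, abs=1e-4)
    assert fit.params["pct_rural"] == pytest.approx(b1, abs=1e-4)


def test_irls_matches_statsmodels():
    import statsmodels.api as sm

    rng = np.random.default_rng(7)
    data = _random_dataset(rng, n=40)
    fit = fit_poisson_rates(data, RURAL_ONLY)
    X, _ = build_design(data, RURAL_ONLY)
    ref = sm.GLM(
        data["cases"],
        X,
        family=sm.families.Poisson(),
        offset=np.log(data["population"]),
    ).fit()
    assert np.allclose(fit.params.to_numpy(), ref.params.to_numpy(), atol=1e-8)
    assert np.allclose(fit.se.to_numpy(), ref.bse.to_numpy(), atol=1e-6)


def test_offset_shift_identity():
    rng = np.random.default_rng(3)
    data = _random_dataset(rng, n=30)
    fit = fit_poisson_rates(data, RURAL_ONLY, tol=1e-12)
    scaled = data.assign(population=data["population"] * 10)
    fit10 = fit_poisson_rates(scaled, RURAL_ONLY, tol=1e-12)
    assert fit10.params["intercept"] - fit.params["intercept"] == pytest.approx(
        -np.log(10), abs=1e-8
    )
    assert fit10.params["pct_rural"] == pytest.approx(fit.params["pct_rural"], abs=1e-8)


def test_ci_brackets_ir():
    rng = np.random.default_rng(9)
    data = _random_dataset(rng, n=30)
    fit = fit_poisson_rates(data, RURAL_ONLY)
    ci = fit.conf_int
    assert (ci["ci_low"] <= fit.ir).all() and (fit.ir <= ci["ci_high"]).all()
    assert (fit.ir > 0).all()


class TestBuildDesign:
    @staticmethod
    def _full_table(rng, n=60):
        return pd.DataFrame(
            {
                "municipality_id": range(1, n + 1),
                "population": rng.integers(10_000, 50_000, n),
                "cases": rng.poisson(10, n),
                "region": rng.choice(list("ABCDEFG"), n),
                "category": pd.Categorical(
                    rng.choice(["best", "good", "medium", "bad", "worst"], n),
                    categories=["best", "good", "medium", "bad", "worst"],
                    ordered=True,
                ),
                "pct_rural": rng.uniform(0, 100, n),
                "pct_under15": rng.uniform(20, 50, n),
                "pct_male_surplus": rng.uniform(-5, 5, n),
            }
        )

    def test_full_model_has_14_columns(self):
        data = self._full_table(np.random.default_rng(0))
        X, info = build_design(data, ModelSpec())
        assert X.shape[1] == 1 + 6 + 4 + 3
        assert info.index_reference == "good"
        assert "intercept" in X.columns

    def test_without_index_has_10_columns(self):
        data = self._full_table(np.random.default_rng(0))
        X, _ = build_design(data, ModelSpec(include_index=False))
        assert X.shape[1] == 1 + 6 + 3

    def test_largest_region_is_reference(self):
        data = self._full_table(np.random.default_rng(1))
        _, info = build_design(data, ModelSpec(include_index=False, continuous=()))
        largest = data["region"].value_counts().idxmax()
        assert info.region_reference == largest

    def test_unknown_level_at_predict_time(self):
        rng = np.random.default_rng(2)
        data = self._full_table(rng)
        spec = ModelSpec(include_index=False, continuous=())
        fit = fit_poisson_rates(data, spec)
        new = data.head(3).copy()
        new.loc[new.index[0], "region"] = "Z"
        with pytest.raises(SchemaError, match="Z"):
            predict_rates(fit, new)

    def test_collinear_columns_named(self):
        rng = np.random.default_rng(4)
        data = self._full_table(rng)
        data["pct_under15"] = 2.0 * data["pct_rural"]  # exact collinearity
        with pytest.raises(RankDeficiencyError, match="pct_"):
            build_design(
                data,
                ModelSpec(
                    include_region=False,
                    include_index=False,
                    continuous=("pct_rural", "pct_under15"),
                ),
            )


class TestComparisonReport:
    @staticmethod
    def _fits():
        rng = np.random.default_rng(5)
        data = TestBuildDesign._full_table(rng, n=80)
        full = fit_poisson_rates(data, ModelSpec())
        no_index = fit_poisson_rates(data, ModelSpec(include_index=False))
        return full, no_index

    def test_single_fit_single_column(self):
        full, _ = self._fits()
        table = model_comparison_report([full], names=["only"])
        assert list(table.columns) == ["term", "only"]

    def test_missing_terms_render_not_included(self):
        full, no_index = self._fits()
        table = model_comparison_report([no_index, full], names=["a", "b"])
        row = table.set_index("term").loc["category[medium]"]
        assert row["a"] == "not included"
        assert "(" in row["b"]
        ref = table.set_index("term").loc["category[good]"]
        assert ref["b"] == "Reference category"

    def test_empty_fit_list_rejected(self):
        with pytest.raises(ParameterError):
            model_comparison_report([])


def test_negative_counts_rejected():
    data = pd.DataFrame(
        {"municipality_id": [1, 2], "population": [1000, 1000], "cases": [-1, 3]}
    )
    with pytest.raises(SchemaError):
        fit_poisson_rates(data, SIMPLE)
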