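"""Poisson regression of municipality case counts with a population offset.

The outcome is the total reported snakebite count of a municipality over
the study period; population enters as a rate multiplier (log-population
offset with fixed coefficient 1), so exponentiated coefficients are
incidence ratios (IR): the multiplicative effect of a term on the
reported case rate. Environmental region and underreporting-index
category enter as categorical terms (reference: the largest region and
the "good" index category); rural share, share under 15 and male
surplus enter as untransformed percentages.

Fitting is by iteratively reweighted least squares (IRLS) on the
canonical log link, initialized at the pooled log rate; Wald 95%
confidence intervals use z = 1.96 with standard errors from the inverse
expected information. A sandwich (robust) standard-error option exists
but is off by default — the model is a plain Poisson fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .exceptions import ParameterError, RankDeficiencyError, SchemaError

Z_95 = 1.959963984540054  # normal 97.5% quantile

CONTINUOUS_TERMS = ("pct_rural", "pct_under15", "pct_male_surplus")


@dataclass
class ModelSpec:
    """Which terms enter the model, and the reference-category policy.

    ``region_reference=None`` means "largest region" (ties by label),
    mirroring the choice of the most populous category as reference;
    the index reference defaults to "good", the largest index category.
    """

    include_region: bool = True
    include_index: bool = True
    continuous: tuple[str, ...] = CONTINUOUS_TERMS
    region_col: str = "region"
    index_col: str = "category"
    region_reference: str | None = None
    index_reference: str = "good"
    outcome_col: str = "cases"
    population_col: str = "population"

    def __post_init__(self) -> None:
        self.continuous = tuple(self.continuous)


@dataclass
class DesignInfo:
    """Bookkeeping of a built design matrix."""

    columns: list[str]
    region_levels: list[str] | None
    region_reference: str | None
    index_levels: list[str] | None
    index_reference: str | None


@dataclass
class RateModelFit:
    """A fitted Poisson rate model.

    ``params`` etc. are indexed by design column name; incidence ratios
    are exp(coefficient) with Wald 95% CIs. Reference categories are kept
    in ``info`` and rendered with IR = 1 in term tables.
    """

    params: pd.Series
    se: pd.Series
    loglik: float
    n_iter: int
    converged: bool
    spec: ModelSpec
    info: DesignInfo
    max_delta: float = float("nan")

    @property
    def ir(self) -> pd.Series:
        return np.exp(self.params).rename("IR")

    @property
    def conf_int(self) -> pd.DataFrame:
        lo = np.exp(self.params - Z_95 * self.se)
        hi = np.exp(self.params + Z_95 * self.se)
        return pd.DataFrame({"ci_low": lo, "ci_high": hi})

    def term_table(self) -> pd.DataFrame:
        """One row per model term, reference categories included."""
        rows = []
        ci = self.conf_int
        for name in self.params.index:
            if name == "intercept":
                continue
            rows.append(
                {
                    "term": name,
                    "IR": float(self.ir[name]),
                    "ci_low": float(ci.loc[name, "ci_low"]),
                    "ci_high": float(ci.loc[name, "ci_high"]),
                    "reference": False,
                }
            )
        for levels, ref, col in (
            (self.info.region_levels, self.info.region_reference, self.spec.region_col),
            (self.info.index_levels, self.info.index_reference, self.spec.index_col),
        ):
            if levels is not None:
                rows.append(
                    {
                        "term": f"{col}[{ref}]",
                        "IR": 1.0,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "reference": True,
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        ci = self.conf_int
        return {
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "loglik": float(self.loglik),
            "max_delta": float(self.max_delta),
            "terms": {
                name: {
                    "coef": float(self.params[name]),
                    "se": float(self.se[name]),
                    "IR": float(self.ir[name]),
                    "ci_low": float(ci.loc[name, "ci_low"]),
                    "ci_high": float(ci.loc[name, "ci_high"]),
                }
                for name in self.params.index
            },
            "references": {
                "region": self.info.region_reference,
                "index": self.info.index_reference,
            },
        }


def build_design(
    data: pd.DataFrame,
    spec: ModelSpec,
    info: DesignInfo | None = None,
) -> tuple[pd.DataFrame, DesignInfo]:
    """Build the model matrix: intercept, category indicators, percentages.

    One indicator column per non-reference category level; column order
    is deterministic (intercept, regions, index categories, continuous).
    When ``info`` from a previous build is supplied, its levels are
    enforced and an unknown level in ``data`` is an error. Rank
    deficiency is detected and reported with the offending columns.
    """
    n = len(data)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}

    region_levels = region_ref = None
    if spec.include_region:
        _require(data, [spec.region_col])
        region_levels, region_ref = _category_block(
            data[spec.region_col],
            fixed_levels=None if info is None else info.region_levels,
            reference=(
                spec.region_reference if info is None else info.region_reference
            ),
            largest_as_reference=spec.region_reference is None and info is None,
            cols=cols,
            prefix=spec.region_col,
        )

    index_levels = index_ref = None
    if spec.include_index:
        _require(data, [spec.index_col])
        index_levels, index_ref = _category_block(
            data[spec.index_col],
            fixed_levels=None if info is None else info.index_levels,
            reference=spec.index_reference if info is None else info.index_reference,
            largest_as_reference=False,
            cols=cols,
            prefix=spec.index_col,
        )

    for term in spec.continuous:
        _require(data, [term])
        cols[term] = data[term].to_numpy(dtype=float)

    X = pd.DataFrame(cols, index=data.index)
    _check_rank(X)
    built = DesignInfo(
        columns=list(X.columns),
        region_levels=region_levels,
        region_reference=region_ref,
        index_levels=index_levels,
        index_reference=index_ref,
    )
    return X, built


def fit_poisson_rates(
    data: pd.DataFrame,
    spec: ModelSpec,
    tol: float = 1e-8,
    max_iter: int = 100,
    robust_se: bool = False,
) -> RateModelFit:
    """Maximum-likelihood Poisson fit with log link and log-population offset.

    IRLS iterates weighted least squares on the working response
    ``eta + (y - mu) / mu`` with weights ``mu`` until the largest
    absolute coefficient change drops below ``tol``. Non-convergence is
    returned as a flagged fit (``converged=False``) with diagnostics,
    not raised.
    """
    _require(data, [spec.outcome_col, spec.population_col])
    y = data[spec.outcome_col].to_numpy(dtype=float)
    pop = data[spec.population_col].to_numpy(dtype=float)
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise SchemaError("case counts must be non-negative integers")
    if (pop <= 0).any():
        raise SchemaError("populations must be strictly positive")

    X_df, info = build_design(data, spec)
    X = X_df.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ParameterError(
            f"need more rows than parameters (n={n}, p={p})"
        )
    offset = np.log(pop)

    beta = np.zeros(p)
    beta[0] = np.log(y.sum() / pop.sum()) if y.sum() > 0 else -20.0
    max_delta = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta + offset, -30.0, 30.0)
        mu = np.exp(eta)
        z = (eta - offset) + (y - mu) / mu
        W = mu
        XtWX = X.T @ (X * W[:, None])
        XtWz = X.T @ (W * z)
        try:
            new_beta = np.linalg.solve(XtWX, XtWz)
        except np.linalg.LinAlgError as exc:
            raise RankDeficiencyError(
                f"weighted information matrix singular at iteration {it}: {exc}"
            ) from exc
        max_delta = float(np.max(np.abs(new_beta - beta)))
        beta = new_beta
        if max_delta < tol:
            converged = True
            break

    eta = np.clip(X @ beta + offset, -30.0, 30.0)
    mu = np.exp(eta)
    XtWX = X.T @ (X * mu[:, None])
    cov = np.linalg.inv(XtWX)
    if robust_se:
        score = X * (y - mu)[:, None]
        cov = cov @ (score.T @ score) @ cov
    se = np.sqrt(np.diag(cov))
    loglik = float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))

    return RateModelFit(
        params=pd.Series(beta, index=X_df.columns, name="coef"),
        se=pd.Series(se, index=X_df.columns, name="se"),
        loglik=loglik,
        n_iter=it,
        converged=converged,
        spec=spec,
        info=info,
        max_delta=max_delta,
    )


def predict_rates(fit: RateModelFit, data: pd.DataFrame) -> pd.Series:
    """Expected counts for new municipalities under a fitted model.

    Category levels unseen at fit time raise a SchemaError.
    """
    X, _ = build_design(data, fit.spec, info=fit.info)
    pop = data[fit.spec.population_col].to_numpy(dtype=float)
    eta = X.to_numpy() @ fit.params.to_numpy() + np.log(pop)
    return pd.Series(np.exp(eta), index=data.index, name="expected_cases")


def model_comparison_report(
    fits: Sequence[RateModelFit | Sequence[RateModelFit]],
    names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Side-by-side IR (95% CI) table across models.

    Each entry of ``fits`` is either one fit or a list of fits whose term
    tables are merged into a single column group (used for the
    "terms entered separately" column, where every term comes from its
    own single-term model). Terms absent from a model render as
    "not included"; reference categories as "Reference category".
    Categorical IRs are formatted to 2 decimals, continuous ones to 3.
    """
    if len(fits) == 0:
        raise ParameterError("need at least one fit to report")
    groups: list[list[RateModelFit]] = [
        list(f) if isinstance(f, (list, tuple)) else [f] for f in fits
    ]
    if names is None:
        names = [f"model_{i + 1}" for i in range(len(groups))]
    if len(names) != len(groups):
        raise ParameterError("one name per model (group) required")

    tables = []
    for group in groups:
        parts = [f.term_table() for f in group]
        tables.append(pd.concat(parts, ignore_index=True))

    term_order: list[str] = []
    for t in tables:
        for term in t["term"]:
            if term not in term_order:
                term_order.append(term)

    out = pd.DataFrame({"term": term_order})
    for name, t in zip(names, tables):
        lookup = t.set_index("term")
        rendered = []
        for term in term_order:
            if term not in lookup.index:
                rendered.append("not included")
            elif bool(lookup.loc[term, "reference"]):
                rendered.append("Reference category")
            else:
                d = 3 if not ("[" in term) else 2
                ir = lookup.loc[term, "IR"]
                lo = lookup.loc[term, "ci_low"]
                hi = lookup.loc[term, "ci_high"]
                rendered.append(f"{ir:.{d}f} ({lo:.{d}f}-{hi:.{d}f})")
        out[name] = rendered
    return out


# -- helpers --------------------------------------------------------------


def _category_block(
    series: pd.Series,
    fixed_levels: list[str] | None,
    reference: str | None,
    largest_as_reference: bool,
    cols: dict,
    prefix: str,
) -> tuple[list[str], str]:
    values = series.astype(str)
    observed = sorted(values.unique())
    if fixed_levels is not None:
        unknown = sorted(set(observed) - set(fixed_levels))
        if unknown:
            raise SchemaError(
                f"unknown {prefix} level(s) at predict time: {', '.join(unknown)}"
            )
        levels = list(fixed_levels)
    else:
        levels = observed
        if isinstance(series.dtype, pd.CategoricalDtype):
            levels = [l for l in series.cat.categories.astype(str) if l in observed]
    if largest_as_reference:
        counts = values.value_counts()
        reference = sorted(levels, key=lambda l: (-counts.get(l, 0), l))[0]
    if reference not in levels:
        raise SchemaError(
            f"reference level {reference!r} not among {prefix} levels {levels}"
        )
    for level in levels:
        if level == reference:
            continue
        cols[f"{prefix}[{level}]"] = (values == level).to_numpy(dtype=float)
    return levels, reference


def _check_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # name the columns with (near-)zero pivots in a pivoted QR
        from scipy.linalg import qr

        _, R, piv = qr(A, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        bad = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] < 1e-8 * diag.max()]
        bad += [X.columns[j] for j in piv[len(diag):]]
        raise RankDeficiencyError(
            "design matrix is rank deficient; collinear column(s): "
            + ", ".join(map(str, bad))
        )


def _require(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"table is missing required column(s): {', '.join(missing)}")
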