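"""Rank-sum underreporting index.

Six municipality-level socioeconomic and health-access variables
(distance to hospital, households far from a health centre, poverty,
illiteracy, roadless area, births outside the health system) are each
ranked across the n municipalities, oriented so the most favourable
value receives rank n, and the six ranks are summed with equal weight.
The attainable index range is therefore [6, 6n] — [6, 912] for a
country of 152 municipalities. Low sums mark deprived, remote
municipalities hypothesized to under-ascertain snakebite cases.

Ranks are ordinal (every rank 1..n used exactly once per variable);
ties are broken by ascending municipality_id, which keeps the index
integer-valued and the [6, 6n] bounds exact.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DEPRIVATION_VARIABLES
from .exceptions import ParameterError, SchemaError

#: Index categories ordered best -> worst, and their default share of
#: municipalities (32/152, 45/152, 45/152, 20/152, 10/152). The extreme
#: categories are deliberately small so effects at the ends of the
#: deprivation distribution remain discernible.
CATEGORY_LABELS = ("best", "good", "medium", "bad", "worst")
DEFAULT_CATEGORY_FRACTIONS = (32 / 152, 45 / 152, 45 / 152, 20 / 152, 10 / 152)
REFERENCE_CATEGORY = "good"


def rank_variables(
    municipalities: pd.DataFrame,
    variables: Sequence[str] = DEPRIVATION_VARIABLES,
    higher_is_worse: bool | Mapping[str, bool] = True,
) -> pd.DataFrame:
    """Rank municipalities on each variable; best standing gets rank n.

    Parameters
    ----------
    municipalities : table with ``municipality_id`` and the variables.
    variables : the column names to rank (six by default).
    higher_is_worse : orientation per variable — True means a higher raw
        value (more poverty, longer distance) is a worse standing. A single
        bool applies to all variables.

    Returns
    -------
    DataFrame with ``municipality_id`` and one ``rank_<var>`` column per
    variable; each column is a permutation of 1..n with n = best.
    """
    _require_columns(municipalities, ["municipality_id", *variables])
    if isinstance(higher_is_worse, bool):
        orientation = {v: higher_is_worse for v in variables}
    else:
        orientation = {v: bool(higher_is_worse[v]) for v in variables}

    missing = municipalities.loc[
        municipalities[list(variables)].isna().any(axis=1), "municipality_id"
    ]
    if len(missing):
        raise SchemaError(
            "missing values in index variables for municipality_id(s): "
            + ", ".join(str(m) for m in missing.tolist())
        )

    n = len(municipalities)
    ids = municipalities["municipality_id"].to_numpy()
    out = pd.DataFrame({"municipality_id": ids})
    for var in variables:
        values = municipalities[var].to_numpy(dtype=float)
        badness = values if orientation[var] else -values
        # best (lowest badness) first; ties resolved by ascending id
        order = np.lexsort((ids, badness))
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(n, 0, -1)
        out[f"rank_{var}"] = ranks
    return out


def compute_index(ranks: pd.DataFrame) -> pd.DataFrame:
    """Sum the per-variable ranks into the equal-weight rank index."""
    rank_cols = [c for c in ranks.columns if c.startswith("rank_")]
    if not rank_cols:
        raise SchemaError("ranks table has no rank_<variable> columns")
    out = ranks.copy()
    out["rank_sum"] = ranks[rank_cols].sum(axis=1).astype(int)
    return out


def categorize_index(
    index: pd.DataFrame,
    category_fractions: Sequence[float] = DEFAULT_CATEGORY_FRACTIONS,
    labels: Sequence[str] = CATEGORY_LABELS,
    remainder_label: str = REFERENCE_CATEGORY,
) -> pd.DataFrame:
    """Cut municipalities into ordered index categories of fixed sizes.

    Municipalities are sorted by ``rank_sum`` descending (highest sum =
    best standing, ties by ascending municipality_id) and split into
    categories of size round(fraction x n); rounding remainders go to the
    reference category ("good", the largest). Sizes depend only on n and
    the fractions, never on the data values.
    """
    if len(category_fractions) != len(labels):
        raise ParameterError(
            f"{len(category_fractions)} fractions for {len(labels)} labels"
        )
    if abs(sum(category_fractions) - 1.0) > 1e-9:
        raise ParameterError(
            f"category fractions must sum to 1, got {sum(category_fractions)!r}"
        )
    n = len(index)
    if n < len(labels):
        raise ParameterError(
            f"cannot form {len(labels)} categories from {n} municipalities"
        )
    sizes = [int(np.floor(f * n + 0.5)) for f in category_fractions]
    sizes[list(labels).index(remainder_label)] += n - sum(sizes)
    if min(sizes) < 0:
        raise ParameterError("category fractions produce a negative category size")

    ordered = index.sort_values(
        ["rank_sum", "municipality_id"], ascending=[False, True], kind="mergesort"
    )
    category = np.repeat(list(labels), sizes)
    out = index.copy()
    out["category"] = pd.Series(
        pd.Categorical(category, categories=list(labels), ordered=True),
        index=ordered.index,
    )
    return out


def deprivation_quantile(index: pd.DataFrame) -> pd.Series:
    """Position of each municipality in the deprivation ordering, as i/n.

    The best-standing municipality (highest rank_sum) gets 1/n and the
    most deprived gets 1. Ties broken by ascending municipality_id.
    """
    n = len(index)
    ordered = index.sort_values(
        ["rank_sum", "municipality_id"], ascending=[False, True], kind="mergesort"
    )
    q = pd.Series(np.arange(1, n + 1) / n, index=ordered.index)
    return q.reindex(index.index)


def _require_columns(df: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"table is missing required column(s): {', '.join(missing)}")
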