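"""Environmental region assignment.

Municipalities are grouped into regions of assumed homogeneous snake
prevalence using the three criteria that define such regions — altitude,
annual precipitation and geographical location — via agglomerative
(Ward) clustering on standardized climate variables under a spatial
connectivity constraint built from centroid k-nearest-neighbour
adjacency. The constraint guarantees every region is one connected
component of the adjacency graph, i.e. spatially contiguous.

The procedure is deterministic: cluster labels are canonicalized by the
smallest municipality_id they contain, so permuting the input rows
yields the same partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import AgglomerativeClustering
from sklearn.neighbors import kneighbors_graph

from .exceptions import ParameterError, SchemaError

FEATURE_COLUMNS = ("altitude_m", "precipitation_mm_y")
COORD_COLUMNS = ("x_km", "y_km")
DEFAULT_K_ADJ = 4


@dataclass
class RegionAssignment:
    """A partition of municipalities into labelled regions.

    ``table`` has one row per municipality with columns municipality_id,
    region and (when available) altitude_m / precipitation_mm_y carried
    along so summaries survive relabelling.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table["municipality_id"].duplicated().any():
            raise SchemaError("duplicate municipality_id in region assignment")

    @property
    def labels(self) -> list[str]:
        return sorted(self.table["region"].unique())

    def mapping(self) -> pd.Series:
        return self.table.set_index("municipality_id")["region"]

    def summary(self) -> pd.DataFrame:
        """Per-region size and, if carried, mean altitude and precipitation."""
        agg: dict = {"municipality_id": "size"}
        for col in FEATURE_COLUMNS:
            if col in self.table.columns:
                agg[col] = "mean"
        out = self.table.groupby("region", sort=True).agg(agg)
        return out.rename(
            columns={
                "municipality_id": "n_municipalities",
                "altitude_m": "mean_altitude_m",
                "precipitation_mm_y": "mean_precipitation_mm_y",
            }
        ).reset_index()


def assign_regions(
    municipalities: pd.DataFrame,
    k: int = 7,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    k_adj: int = DEFAULT_K_ADJ,
) -> RegionAssignment:
    """Partition municipalities into ``k`` contiguous environmental regions.

    Parameters
    ----------
    municipalities : table with municipality_id, altitude_m,
        precipitation_mm_y, x_km, y_km.
    k : number of regions (1 <= k <= n).
    weights : scaling of the standardized (altitude, precipitation,
        coordinate) features; the third entry weights both map axes.
    k_adj : neighbours in the contiguity graph (clipped to n - 1).

    The objective is Ward's within-group variance of the weighted,
    z-scored features, minimized greedily under the constraint that only
    adjacent groups may merge — a reproducible restatement of grouping
    by "homogeneity in altitude, precipitation and geographical
    location".
    """
    _require(municipalities, ["municipality_id", *FEATURE_COLUMNS, *COORD_COLUMNS])
    n = len(municipalities)
    if k < 1 or k > n:
        raise ParameterError(f"k must be in [1, {n}], got {k}")
    values = municipalities[[*FEATURE_COLUMNS, *COORD_COLUMNS]].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise SchemaError("altitude, precipitation and coordinates must be finite")

    w_alt, w_prec, w_dist = (float(w) for w in weights)
    features = np.column_stack(
        [
            w_alt * _zscore(values[:, 0]),
            w_prec * _zscore(values[:, 1]),
            w_dist * _zscore(values[:, 2]),
            w_dist * _zscore(values[:, 3]),
        ]
    )

    ids = municipalities["municipality_id"].to_numpy()
    if k == n:
        raw_labels = np.arange(n)
    elif k == 1:
        raw_labels = np.zeros(n, dtype=int)
    else:
        conn = adjacency_graph(municipalities, k_adj)
        model = AgglomerativeClustering(
            n_clusters=k, linkage="ward", connectivity=conn
        )
        import warnings

        with warnings.catch_warnings():
            # sklearn warns when it symmetrizes the kNN graph; ours already is
            warnings.simplefilter("ignore", UserWarning)
            raw_labels = model.fit_predict(features)

    region = _canonical_labels(raw_labels, ids)
    cols = {"municipality_id": ids, "region": region}
    for col in FEATURE_COLUMNS:
        cols[col] = municipalities[col].to_numpy()
    table = pd.DataFrame(cols).sort_values("municipality_id", kind="mergesort")
    return RegionAssignment(table=table.reset_index(drop=True))


def aggregate_regions(
    assignment: RegionAssignment, grouping: Mapping[str, str]
) -> RegionAssignment:
    """Relabel regions into super-regions; membership counts are conserved.

    Every region label present in the assignment must appear in
    ``grouping`` (identity entries included), otherwise a SchemaError
    names the missing labels.
    """
    present = set(assignment.table["region"])
    missing = sorted(present - set(grouping))
    if missing:
        raise SchemaError(f"grouping is missing region label(s): {', '.join(missing)}")
    table = assignment.table.copy()
    table["region"] = table["region"].map(dict(grouping))
    return RegionAssignment(table=table)


def adjacency_graph(municipalities: pd.DataFrame, k_adj: int = DEFAULT_K_ADJ) -> csr_matrix:
    """Symmetrized k-nearest-neighbour adjacency over municipality centroids."""
    coords = municipalities[list(COORD_COLUMNS)].to_numpy(dtype=float)
    n = len(coords)
    if n == 1:
        return csr_matrix((1, 1))
    g = kneighbors_graph(coords, n_neighbors=min(k_adj, n - 1), mode="connectivity")
    return ((g + g.T) > 0).astype(float)


def is_contiguous(
    municipalities: pd.DataFrame,
    assignment: RegionAssignment,
    k_adj: int = DEFAULT_K_ADJ,
) -> bool:
    """True iff every region is one connected component of the kNN graph."""
    graph = adjacency_graph(municipalities, k_adj)
    labels = (
        assignment.mapping()
        .reindex(municipalities["municipality_id"])
        .to_numpy()
    )
    for lab in np.unique(labels):
        mask = labels == lab
        if mask.sum() == 1:
            continue
        sub = graph[mask][:, mask]
        n_comp, _ = connected_components(sub, directed=False)
        if n_comp != 1:
            return False
    return True


def _canonical_labels(raw: np.ndarray, ids: np.ndarray) -> np.ndarray:
    """Name clusters region_01.. by ascending smallest municipality_id."""
    order = sorted(np.unique(raw), key=lambda c: ids[raw == c].min())
    names = {c: f"region_{i + 1:02d}" for i, c in enumerate(order)}
    return np.array([names[c] for c in raw])


def _require(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"table is missing required column(s): {', '.join(missing)}")


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)
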