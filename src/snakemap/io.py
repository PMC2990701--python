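"""Delimited-text and JSON readers/writers.

Every table written by the pipeline is UTF-8 CSV with "." decimals and
a leading comment header recording the tool version, the configuration
hash and the seed, so any output file identifies the run that produced
it; readers skip those comment lines. Headers carry no timestamps, so
re-running with identical inputs reproduces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__


def run_header(config_hash: str | None = None, seed: int | None = None) -> str:
    parts = [f"snakemap v{__version__}"]
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return "# " + " | ".join(parts)


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    config_hash: str | None = None,
    seed: int | None = None,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(run_header(config_hash, seed) + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(obj: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_points_geojson(
    df: pd.DataFrame,
    path: str | Path,
    properties: list[str],
    x_col: str = "x_km",
    y_col: str = "y_km",
) -> None:
    """One point feature per municipality with the listed properties."""
    features = [
        {
            "type": "Feature",
            "geometry": {
                "type": "Point",
                "coordinates": [float(row[x_col]), float(row[y_col])],
            },
            "properties": {p: _jsonable(row[p]) for p in properties},
        }
        for _, row in df.iterrows()
    ]
    write_json({"type": "FeatureCollection", "features": features}, path)


def _jsonable(v):
    try:
        import numpy as np

        if isinstance(v, np.integer):
            return int(v)
        if isinstance(v, np.floating):
            return float(v)
        if isinstance(v, np.bool_):
            return bool(v)
        if isinstance(v, np.ndarray):
            return v.tolist()
    except ImportError:  # pragma: no cover
        pass
    if isinstance(v, (bool, int, float, str)) or v is None:
        return v
    return str(v)
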