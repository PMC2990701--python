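"""End-to-end orchestration.

Runs the full analysis in order: simulate (or load) the municipality
table and weekly case series, validate them, assign environmental
regions, build the underreporting index, flag low-reporters, fit the
three Poisson rate models (terms entered separately; region +
demographics; all terms), compute descriptive statistics and seasonal
curves, and write a consolidated report. In synthetic mode the report
additionally scores both detection approaches against the generator's
ground truth (sensitivity/specificity of the low-reporter flags and of
the worst-index municipalities).

Every output table carries a header comment with tool version, config
hash and seed; a run with identical config and seed reproduces
byte-identical outputs. Stage failures raise :class:`PipelineError`
with the stage name and a machine-readable code; outputs written before
the failure are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SyntheticConfig
from .descriptive import incidence_summary, regional_incidence, seasonal_curves
from .exceptions import PipelineError, SnakemapError
from .incidence_model import (
    ModelSpec,
    fit_poisson_rates,
    model_comparison_report,
)
from .io import config_hash, read_table, write_json, write_table
from .low_reporters import aggregate_case_totals, detect_low_reporters
from .regions import assign_regions
from .synthetic import (
    MUNICIPALITY_COLUMNS,
    simulate_cases,
    simulate_municipalities,
)
from .underreporting import (
    DEFAULT_CATEGORY_FRACTIONS,
    DEPRIVATION_VARIABLES,
    categorize_index,
    compute_index,
    rank_variables,
)

logger = logging.getLogger("snakemap")

REQUIRED_CASE_COLUMNS = ("municipality_id", "year", "week", "cases")
PERCENT_COLUMNS = (
    "pct_rural",
    "pct_under15",
    "pct_households_far_health",
    "pct_poverty",
    "pct_illiteracy",
    "pct_area_far_road",
)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run; round-trips losslessly via dicts."""

    mode: str = "synthetic"  # "synthetic" | "files"
    municipalities_path: str | None = None
    cases_path: str | None = None
    out_dir: str = "snakemap_out"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    k_regions: int = 7
    index_variables: tuple[str, ...] = DEPRIVATION_VARIABLES
    category_fractions: tuple[float, ...] = DEFAULT_CATEGORY_FRACTIONS
    low_reporter_q: float = 0.40
    n_worst: int = 10
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise PipelineError("config", "validation", f"unknown mode {self.mode!r}")
        self.index_variables = tuple(self.index_variables)
        self.category_fractions = tuple(self.category_fractions)
        # one seed drives everything, including the generator
        self.synthetic = (
            SyntheticConfig(**{**self.synthetic.to_dict(), "seed": self.seed})
            if isinstance(self.synthetic, SyntheticConfig)
            else SyntheticConfig(**{**dict(self.synthetic), "seed": self.seed})
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        return cls(**d)


def validate_inputs(
    municipalities: pd.DataFrame, cases: pd.DataFrame
) -> list[dict]:
    """Schema, range and referential-integrity checks.

    Returns a list of issue records (table, row, column, message); an
    empty list means the bundle is clean.
    """
    issues: list[dict] = []

    def issue(table, row, column, message):
        issues.append(
            {"table": table, "row": row, "column": column, "message": message}
        )

    for col in MUNICIPALITY_COLUMNS:
        if col not in municipalities.columns:
            issue("municipalities", None, col, "required column missing")
    for col in REQUIRED_CASE_COLUMNS:
        if col not in cases.columns:
            issue("cases", None, col, "required column missing")
    if issues:
        return issues

    if municipalities["municipality_id"].duplicated().any():
        dup = municipalities.loc[
            municipalities["municipality_id"].duplicated(), "municipality_id"
        ].tolist()
        issue("municipalities", None, "municipality_id", f"duplicate ids {dup}")
    for i, row in municipalities.iterrows():
        if row["population"] <= 0:
            issue("municipalities", int(i), "population", "must be > 0")
        for col in PERCENT_COLUMNS:
            if not 0 <= row[col] <= 100:
                issue("municipalities", int(i), col, "percentage outside [0, 100]")
    count_cols = ["cases"] + (["deaths"] if "deaths" in cases.columns else [])
    for col in count_cols:
        bad = cases.index[cases[col] < 0]
        for i in bad:
            issue("cases", int(i), col, "negative count")
    known = set(municipalities["municipality_id"])
    unknown = cases.loc[~cases["municipality_id"].isin(known), "municipality_id"]
    for i, mid in unknown.items():
        issue("cases", int(i), "municipality_id", f"unknown municipality {mid}")
    return issues


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle to ``out_dir``.

    Returns the consolidated report dictionary (also written as
    report.json).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hashed = {
        k: v
        for k, v in config.to_dict().items()
        if k not in ("out_dir", "log_level")  # where results land never
        # changes what they are
    }
    chash = config_hash(hashed)
    seed = config.seed
    meta = {"config_hash": chash, "seed": seed}

    # -- inputs -----------------------------------------------------------
    truth = None
    if config.mode == "synthetic":
        with _stage("simulate", "internal"):
            municipalities = simulate_municipalities(config.synthetic)
            cases, truth = simulate_cases(municipalities, config.synthetic)
            write_table(municipalities, out / "municipalities.csv", chash, seed)
            write_table(cases, out / "cases.csv", chash, seed)
            write_json(
                {
                    "cutoff": truth.cutoff,
                    "municipalities": truth.table.to_dict(orient="records"),
                },
                out / "truth.json",
            )
    else:
        with _stage("load", "io"):
            if not config.municipalities_path or not config.cases_path:
                raise SnakemapError(
                    "file mode requires municipalities_path and cases_path"
                )
            municipalities = read_table(config.municipalities_path)
            cases = read_table(config.cases_path)

    with _stage("validate", "validation"):
        issues = validate_inputs(municipalities, cases)
        if issues:
            write_json({"issues": issues}, out / "validation.json")
            raise SnakemapError(
                f"{len(issues)} validation issue(s); first: {issues[0]}"
            )

    # -- regions ----------------------------------------------------------
    with _stage("regions", "internal"):
        assignment = assign_regions(municipalities, k=config.k_regions)
        write_table(assignment.table, out / "regions.csv", chash, seed)
        write_table(assignment.summary(), out / "region_summary.csv", chash, seed)

    # -- underreporting index ---------------------------------------------
    with _stage("index", "internal"):
        index = categorize_index(
            compute_index(rank_variables(municipalities, config.index_variables)),
            config.category_fractions,
        )
        write_table(index, out / "index.csv", chash, seed)

    # -- low reporters -----------------------------------------------------
    with _stage("low_reporters", "internal"):
        totals = aggregate_case_totals(cases)
        flags = detect_low_reporters(
            totals, municipalities, assignment, q=config.low_reporter_q
        )
        write_table(flags, out / "low_reporters.csv", chash, seed)

    # -- models ------------------------------------------------------------
    with _stage("models", "convergence"):
        analysis = (
            municipalities.merge(totals, on="municipality_id", how="left")
            .merge(index[["municipality_id", "category"]], on="municipality_id")
            .merge(assignment.table[["municipality_id", "region"]], on="municipality_id")
        )
        analysis["cases"] = analysis["cases"].fillna(0).astype(int)
        analysis["category"] = pd.Categorical(
            analysis["category"],
            categories=index["category"].cat.categories,
            ordered=True,
        )
        separate = [
            fit_poisson_rates(analysis, ModelSpec(include_index=False, continuous=())),
            *[
                fit_poisson_rates(
                    analysis,
                    ModelSpec(include_region=False, include_index=False, continuous=(c,)),
                )
                for c in ("pct_rural", "pct_under15", "pct_male_surplus")
            ],
            fit_poisson_rates(
                analysis, ModelSpec(include_region=False, include_index=True, continuous=())
            ),
        ]
        region_demo = fit_poisson_rates(analysis, ModelSpec(include_index=False))
        full = fit_poisson_rates(analysis, ModelSpec())
        if not (region_demo.converged and full.converged):
            raise SnakemapError("Poisson fit failed to converge")
        report_table = model_comparison_report(
            [separate, region_demo, full],
            names=["terms_separately", "region_demographics", "all_terms"],
        )
        write_table(report_table, out / "model_comparison.csv", chash, seed)
        write_json(
            {
                "terms_separately": [f.to_dict() for f in separate],
                "region_demographics": region_demo.to_dict(),
                "all_terms": full.to_dict(),
            },
            out / "fits.json",
        )

    # -- descriptives ------------------------------------------------------
    with _stage("descriptive", "internal"):
        summary = incidence_summary(cases, municipalities, years=config.synthetic.years)
        per_region = regional_incidence(cases, municipalities, assignment)
        curves = seasonal_curves(cases, assignment)
        write_table(per_region, out / "regional_incidence.csv", chash, seed)
        write_table(curves, out / "seasonal_curves.csv", chash, seed)

    # -- consolidated report ----------------------------------------------
    with _stage("report", "io"):
        worst = (
            index.sort_values(["rank_sum", "municipality_id"], kind="mergesort")
            .head(config.n_worst)["municipality_id"]
            .tolist()
        )
        flagged = flags.loc[flags["low_reporter"], "municipality_id"].tolist()
        report = {
            "version": __version__,
            "config_hash": chash,
            "seed": seed,
            "descriptive": summary.to_dict(),
            "descriptive_rounded": summary.rounded(),
            "regional_incidence": per_region.to_dict(orient="records"),
            "worst_index_municipalities": worst,
            "low_reporters": flagged,
            "n_low_reporters": len(flagged),
        }
        if truth is not None:
            report["detection_vs_truth"] = {
                "low_reporters": _score_detection(flagged, truth.table),
                "worst_index": _score_detection(worst, truth.table),
            }
        write_json(report, out / "report.json")
    return report


def _score_detection(flagged_ids: list, truth_table: pd.DataFrame) -> dict:
    """Sensitivity/specificity of a flag set against the simulated truth.

    With no true underreporters (e.g. reporting_floor = 1) sensitivity is
    undefined and reported as None.
    """
    truth_ids = set(
        truth_table.loc[truth_table["underreporter_flag"], "municipality_id"]
    )
    all_ids = set(truth_table["municipality_id"])
    flagged = set(flagged_ids)
    tp = len(flagged & truth_ids)
    fp = len(flagged - truth_ids)
    tn = len(all_ids - flagged - truth_ids)
    sens = tp / len(truth_ids) if truth_ids else None
    spec = tn / (tn + fp) if (tn + fp) else None
    return {
        "n_true_underreporters": len(truth_ids),
        "n_flagged": len(flagged),
        "true_positives": tp,
        "sensitivity": sens,
        "specificity": spec,
        "note": None if truth_ids else "no true underreporters; sensitivity undefined",
    }


class _stage:
    """Context manager wrapping a pipeline stage into PipelineError."""

    def __init__(self, name: str, code: str):
        self.name, self.code = name, code

    def __enter__(self):
        logger.info("stage %s", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, PipelineError):
            raise PipelineError(self.name, self.code, str(exc)) from exc
        return False
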