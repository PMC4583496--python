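"""End-to-end comparison pipeline.

Orchestrates the full benchmark: obtain a cohort (from CSV or the
synthetic generator), summarise its missingness, run every requested
missing-data strategy, score every requested risk model, evaluate
before and after intercept recalibration, and render the results as a
wide comparison grid (one cell per model x method x calibration state)
plus a per-imputation sub-table for multiple imputation and per-method
cohort characteristic tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    CohortTable,
    MissingnessSummary,
    enumerate_patterns,
    exclude_previously_diagnosed,
    read_cohort,
    summarize_missingness,
    write_cohort,
)
from .impute import (
    METHODS,
    ImputedDataset,
    MultipleImputationResult,
    impute,
)
from .metrics import MetricError, PerformanceReport, evaluate, pool_reports
from .models import (
    CalibrationError,
    RiskModelSpec,
    predict_risk,
    recalibrate_intercept,
)
from .synth import (
    GeneratorConfig,
    MissingnessConfig,
    apply_missingness,
    generate_complete_cohort,
)

STATES = ("original", "adjusted")


@dataclass
class RunConfig:
    """Everything needed to reproduce one benchmark run."""

    models: list[RiskModelSpec]
    methods: list[str] = field(default_factory=lambda: list(METHODS))
    input_path: str | None = None
    schema: list | None = None  # VariableSpec list for input_path
    outcome_name: str | None = None
    generator: GeneratorConfig | None = None
    missingness: MissingnessConfig | None = None
    exclusion_flag: str | None = None
    m: int = 5
    iterations: int = 10
    seed: int = 0

    def __post_init__(self):
        if not self.models or not self.methods:
            raise ValueError("RunConfig needs at least one model and one method")
        unknown = [m for m in self.methods if m not in METHODS]
        if unknown:
            raise ValueError(f"unknown methods {unknown}; expected subset of {METHODS}")
        if self.input_path is None and self.generator is None:
            raise ValueError("RunConfig needs an input path or a generator config")


@dataclass
class RunManifest:
    """Provenance of one run: config echo, stage sizes, warnings, checksums."""

    config: dict
    version: str
    n_input: int = 0
    n_excluded: int = 0
    n_analysis: int = 0
    missingness: MissingnessSummary | None = None
    pattern_count: int = 0
    warnings: list[str] = field(default_factory=list)
    checksums: dict[str, str] = field(default_factory=dict)
    effective_n: dict[str, dict[str, int]] = field(default_factory=dict)


@dataclass
class ComparisonTable:
    """The benchmark grid plus the multiple-imputation sub-table."""

    reports: dict[tuple[str, str, str], PerformanceReport | None]
    errors: dict[tuple[str, str, str], str]
    mi_reports: dict[tuple[str, int, str], PerformanceReport]
    models: list[str]
    methods: list[str]

    def long_frame(self) -> pd.DataFrame:
        rows = []
        for (model, method, state), rep in self.reports.items():
            if rep is None:
                rows.append({"model": model, "method": method, "state": state,
                             "error": self.errors.get((model, method, state), "NA")})
            else:
                rows.append(rep.to_row())
        return pd.DataFrame(rows)

    def mi_frame(self) -> pd.DataFrame:
        rows = []
        for (model, idx, state), rep in sorted(self.mi_reports.items()):
            row = rep.to_row()
            row["dataset"] = idx + 1
            rows.append(row)
        return pd.DataFrame(rows)

    def wide_frame(self) -> pd.DataFrame:
        """Comparison-grid layout: model x measure rows, method columns."""
        measures = ("EO", "brier", "yates", "C", "n_eff")
        rows = []
        for model in self.models:
            for measure in measures:
                row: dict = {"model": model, "measure": measure}
                for method in self.methods:
                    for state in STATES:
                        rep = self.reports.get((model, method, state))
                        key = f"{method}_{state}"
                        row[key] = None if rep is None else _format_measure(rep, measure)
                rows.append(row)
        return pd.DataFrame(rows)


def _format_measure(rep: PerformanceReport, measure: str):
    if measure == "EO":
        return f"{rep.eo_ratio:.2f} ({rep.eo_ci[0]:.2f}-{rep.eo_ci[1]:.2f})"
    if measure == "brier":
        return f"{rep.brier:.3f}"
    if measure == "yates":
        return f"{rep.yates_slope:.3f}"
    if measure == "C":
        return f"{rep.c:.2f} ({rep.c_ci[0]:.2f}-{rep.c_ci[1]:.2f})"
    return rep.n_eff


def derive_seed(master: int, *labels) -> int:
    """Stable sub-seed from the master seed and a label tuple.

    Hash-based so that adding a method or model never perturbs another's
    random stream; result is kept below 2**31.
    """
    digest = hashlib.sha256(("|".join(str(x) for x in labels)).encode()).digest()
    extra = int.from_bytes(digest[:4], "big")
    return int(np.random.SeedSequence([master & 0x7FFFFFFF, extra]).generate_state(1)[0] & 0x7FFFFFFF)


def _table_checksum(table: CohortTable) -> str:
    parts = []
    for v in table.variables:
        col = table.data[v.name]
        if v.kind == "categorical":
            parts.append(col.fillna("<NA>").astype(str).str.cat(sep=","))
        else:
            parts.append(",".join("NA" if pd.isna(x) else repr(float(x)) for x in col))
    return hashlib.sha256("|".join(parts).encode()).hexdigest()


def _obtain_cohort(config: RunConfig) -> tuple[CohortTable, RunManifest]:
    manifest = RunManifest(config=_config_echo(config), version=__version__)
    if config.input_path is not None:
        if config.schema is None:
            raise ValueError("loading a cohort file requires a schema")
        table = read_cohort(config.input_path, config.schema,
                            outcome_name=config.outcome_name)
    else:
        gen = config.generator
        table = generate_complete_cohort(gen)
        if config.missingness is not None:
            table = apply_missingness(
                table, config.missingness, seed=derive_seed(config.seed, "ampute"))
    manifest.n_input = table.n
    if config.exclusion_flag is not None and config.exclusion_flag in table.names:
        table, excluded = exclude_previously_diagnosed(table, config.exclusion_flag)
        manifest.n_excluded = excluded
    manifest.n_analysis = table.n
    manifest.missingness = summarize_missingness(table) if table.n else None
    manifest.pattern_count = len(enumerate_patterns(table)) if table.n else 0
    return table, manifest


def _config_echo(config: RunConfig) -> dict:
    return {
        "models": [m.name for m in config.models],
        "methods": list(config.methods),
        "input_path": config.input_path,
        "generator_n": None if config.generator is None else config.generator.n,
        "m": config.m,
        "iterations": config.iterations,
        "seed": config.seed,
    }


def _evaluate_cell(model: RiskModelSpec, dataset: ImputedDataset
                   ) -> tuple[PerformanceReport, PerformanceReport]:
    """Original and intercept-adjusted reports for one model on one table."""
    table = dataset.table
    outcome = table.data[table.outcome_name].astype(float).to_numpy()
    preds = predict_risk(model, table)
    original = evaluate(preds, outcome, state="original",
                        model_name=model.name, method=dataset.method)
    adjusted_model = recalibrate_intercept(model, table)
    adj_preds = predict_risk(adjusted_model, table)
    adjusted = evaluate(adj_preds, outcome, state="adjusted",
                        model_name=model.name, method=dataset.method)
    return original, adjusted


def run_comparison(config: RunConfig) -> tuple[ComparisonTable, RunManifest]:
    """Execute the full grid: every method, every model, both states.

    Cells that fail (e.g. a single-class outcome after deletion on a
    tiny cohort) are recorded as explicit NA with a reason; the run
    completes for the remaining cells.  With a fixed seed the whole run
    is deterministic.
    """
    table, manifest = _obtain_cohort(config)

    method_data: dict[str, ImputedDataset | MultipleImputationResult] = {}
    for method in config.methods:
        sub_seed = derive_seed(config.seed, "method", method)
        result = impute(table, method, seed=sub_seed,
                        m=config.m, iterations=config.iterations)
        method_data[method] = result
        if isinstance(result, MultipleImputationResult):
            for i, ds in enumerate(result.datasets):
                manifest.checksums[f"{method}[{i}]"] = _table_checksum(ds.table)
                manifest.warnings.extend(f"{method}[{i}]: {w}" for w in set(ds.warnings))
            manifest.effective_n[method] = result.datasets[0].effective_n
        else:
            manifest.checksums[method] = _table_checksum(result.table)
            manifest.warnings.extend(f"{method}: {w}" for w in set(result.warnings))
            manifest.effective_n[method] = result.effective_n

    reports: dict[tuple[str, str, str], PerformanceReport | None] = {}
    errors: dict[tuple[str, str, str], str] = {}
    mi_reports: dict[tuple[str, int, str], PerformanceReport] = {}

    for model in config.models:
        for method in config.methods:
            result = method_data[method]
            try:
                if isinstance(result, MultipleImputationResult):
                    per_state: dict[str, list[PerformanceReport]] = {s: [] for s in STATES}
                    for i, ds in enumerate(result.datasets):
                        orig, adj = _evaluate_cell(model, ds)
                        per_state["original"].append(orig)
                        per_state["adjusted"].append(adj)
                        mi_reports[(model.name, i, "original")] = orig
                        mi_reports[(model.name, i, "adjusted")] = adj
                    for state in STATES:
                        reports[(model.name, method, state)] = pool_reports(
                            per_state[state], result.m)
                else:
                    orig, adj = _evaluate_cell(model, result)
                    reports[(model.name, method, "original")] = orig
                    reports[(model.name, method, "adjusted")] = adj
            except (MetricError, CalibrationError) as exc:
                for state in STATES:
                    reports.setdefault((model.name, method, state), None)
                    errors[(model.name, method, state)] = str(exc)

    comparison = ComparisonTable(
        reports=reports,
        errors=errors,
        mi_reports=mi_reports,
        models=[m.name for m in config.models],
        methods=list(config.methods),
    )
    return comparison, manifest


# ---------------------------------------------------------------------------
# characteristic tables (per-method variable summaries)

def characteristics(dataset: CohortTable | ImputedDataset) -> pd.DataFrame:
    """Per-variable summary: mean (sd) for continuous, level counts otherwise."""
    table = dataset if isinstance(dataset, CohortTable) else dataset.table
    rows = []
    for spec in table.variables:
        col = table.data[spec.name]
        obs = col[~col.isna()]
        if spec.kind == "continuous":
            summary = f"{obs.astype(float).mean():.1f} ({obs.astype(float).std(ddof=1):.1f})" if len(obs) else "NA"
        elif spec.kind == "binary":
            summary = f"{int((obs == 1.0).sum())}/{int((obs == 0.0).sum())}"
        else:
            counts = obs.value_counts()
            summary = "/".join(str(int(counts.get(c, 0))) for c in spec.categories)
        rows.append({"variable": spec.name, "summary": summary, "n_obs": len(obs)})
    return pd.DataFrame(rows)


def characteristics_comparison(
    original: CohortTable,
    method_data: dict[str, ImputedDataset | MultipleImputationResult],
) -> pd.DataFrame:
    """Side-by-side per-method characteristic table (original first)."""
    frames = {"original": characteristics(original).set_index("variable")["summary"]}
    for method, result in method_data.items():
        if isinstance(result, MultipleImputationResult):
            for i, ds in enumerate(result.datasets):
                frames[f"{method}[{i + 1}]"] = characteristics(ds).set_index("variable")["summary"]
        else:
            frames[method] = characteristics(result).set_index("variable")["summary"]
    return pd.DataFrame(frames)


# ---------------------------------------------------------------------------
# rendering

RENDER_FORMATS = ("csv", "json", "markdown")


def render_report(table: ComparisonTable, fmt: str, out_dir: str | Path
                  ) -> list[Path]:
    """Write the comparison grid to disk; returns the files written.

    ``csv`` writes both a tidy long table and the wide grid layout;
    ``json`` a nested structure; ``markdown`` the wide grid.
    """
    if fmt not in RENDER_FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {RENDER_FORMATS}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if fmt == "csv":
        long_path = out_dir / "comparison_long.csv"
        table.long_frame().to_csv(long_path, index=False)
        written.append(long_path)
        wide_path = out_dir / "comparison_wide.csv"
        table.wide_frame().to_csv(wide_path, index=False)
        written.append(wide_path)
        mi = table.mi_frame()
        if len(mi):
            mi_path = out_dir / "mi_datasets.csv"
            mi.to_csv(mi_path, index=False)
            written.append(mi_path)
    elif fmt == "json":
        doc = {
            "cells": [r.to_row() for r in table.reports.values() if r is not None],
            "errors": [
                {"model": k[0], "method": k[1], "state": k[2], "reason": v}
                for k, v in table.errors.items()
            ],
            "mi_datasets": [
                {**rep.to_row(), "dataset": idx + 1}
                for (model, idx, state), rep in sorted(table.mi_reports.items())
            ],
        }
        path = out_dir / "comparison.json"
        path.write_text(json.dumps(doc, indent=2))
        written.append(path)
    else:
        wide = table.wide_frame()
        path = out_dir / "comparison.md"
        path.write_text(wide.to_markdown(index=False) + "\n")
        written.append(path)
    return written


__all__ = [
    "RunConfig",
    "RunManifest",
    "ComparisonTable",
    "run_comparison",
    "render_report",
    "characteristics",
    "characteristics_comparison",
    "derive_seed",
]
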