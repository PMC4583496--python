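"""Cohort data model: typed rectangular tables with explicit missingness.

A cohort is a participants-by-variables table.  Each variable is declared
as continuous, binary (0/1 with an optional label map) or categorical
(ordered label list).  Missing cells are first-class: continuous and
binary columns use NaN, categorical columns use None/NaN.  All I/O is
plain CSV with a configurable missing-value token so fixtures stay
human-readable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

VALID_KINDS = ("continuous", "binary", "categorical")

DEFAULT_MISSING_TOKENS = ("", "NA")


class CohortError(Exception):
    """Base class for cohort-layer errors."""


class SchemaError(CohortError):
    """A variable reference or schema declaration is invalid."""


class ParseError(CohortError):
    """A cell could not be parsed under its declared kind."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        super().__init__(message)
        self.row = row
        self.column = column


class DegenerateInputError(CohortError):
    """An operation was asked to run on an empty or single-class input."""


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one cohort variable.

    Parameters
    ----------
    name
        Column identifier.
    kind
        One of ``continuous``, ``binary``, ``categorical``.
    categories
        Ordered label list; required for categorical variables.
    units
        Free-text units (years, kg/m2, mmHg, cm, ...).
    labels
        Optional meaning of the binary codes, e.g. ``{1: "female", 0: "male"}``.
    """

    name: str
    kind: str
    categories: tuple[str, ...] | None = None
    units: str | None = None
    labels: dict[int, str] | None = None

    def __post_init__(self):
        if self.kind not in VALID_KINDS:
            raise SchemaError(f"variable {self.name!r}: kind {self.kind!r} not in {VALID_KINDS}")
        if self.kind == "categorical":
            if not self.categories or len(set(self.categories)) < 2:
                raise SchemaError(
                    f"categorical variable {self.name!r} needs >= 2 distinct categories"
                )
            object.__setattr__(self, "categories", tuple(self.categories))
        elif self.categories is not None:
            raise SchemaError(f"variable {self.name!r}: categories only allowed for categorical kind")

    def parse(self, token: str, row: int) -> float | str:
        """Parse one non-missing cell string into the variable's value space."""
        if self.kind == "continuous":
            try:
                return float(token)
            except ValueError:
                raise ParseError(
                    f"row {row}, column {self.name!r}: {token!r} is not a number",
                    row=row, column=self.name,
                ) from None
        if self.kind == "binary":
            try:
                value = float(token)
            except ValueError:
                raise ParseError(
                    f"row {row}, column {self.name!r}: {token!r} is not a 0/1 code",
                    row=row, column=self.name,
                ) from None
            if value not in (0.0, 1.0):
                raise ParseError(
                    f"row {row}, column {self.name!r}: binary value must be 0 or 1, got {token!r}",
                    row=row, column=self.name,
                )
            return value
        # categorical
        if token not in self.categories:
            raise ParseError(
                f"row {row}, column {self.name!r}: {token!r} not in categories {self.categories}",
                row=row, column=self.name,
            )
        return token


@dataclass
class CohortTable:
    """A participants-by-variables table with an explicit missingness mask.

    ``data`` holds one column per :class:`VariableSpec`, in schema order:
    continuous and binary columns are float64 with NaN for missing;
    categorical columns are object dtype with NaN for missing.
    """

    variables: list[VariableSpec]
    data: pd.DataFrame
    outcome_name: str | None = None

    def __post_init__(self):
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names in schema")
        if list(self.data.columns) != names:
            self.data = self.data.reindex(columns=names)
        if self.outcome_name is not None:
            spec = self.spec(self.outcome_name)
            if spec.kind != "binary":
                raise SchemaError(f"outcome {self.outcome_name!r} must be binary, is {spec.kind}")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def spec(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise SchemaError(f"no variable named {name!r}")

    def missing_mask(self) -> pd.DataFrame:
        """Boolean frame, True where a cell is missing."""
        return self.data.isna()

    def copy(self) -> "CohortTable":
        return CohortTable(list(self.variables), self.data.copy(), self.outcome_name)

    def drop_variable(self, name: str) -> "CohortTable":
        specs = [v for v in self.variables if v.name != name]
        if len(specs) == len(self.variables):
            raise SchemaError(f"no variable named {name!r}")
        outcome = self.outcome_name if self.outcome_name != name else None
        return CohortTable(specs, self.data.drop(columns=[name]), outcome)

    def equals(self, other: "CohortTable") -> bool:
        """Value-and-mask equality (NaN == NaN)."""
        if self.names != other.names or self.n != other.n:
            return False
        for v in self.variables:
            a, b = self.data[v.name], other.data[v.name]
            if not (a.isna() == b.isna().values).all():
                return False
            obs = ~a.isna()
            if v.kind == "categorical":
                if not (a[obs] == b[obs].values).all():
                    return False
            else:
                if not np.allclose(a[obs].astype(float), b[obs].astype(float), rtol=0, atol=0):
                    return False
        return True


@dataclass
class MissingnessSummary:
    """Per-variable missing counts/percentages plus the any-missing row count."""

    per_variable: pd.DataFrame  # index = variable, columns = missing_count, missing_percent
    n_any_missing: int
    n: int

    @property
    def any_missing_percent(self) -> float:
        return 100.0 * self.n_any_missing / self.n


@dataclass(frozen=True)
class MissingnessPattern:
    """One distinct missingness mask and how many records carry it."""

    mask: tuple[bool, ...]  # per variable, True = missing
    frequency: int


def _ensure_dtypes(data: pd.DataFrame, variables: list[VariableSpec]) -> pd.DataFrame:
    out = {}
    for v in variables:
        col = data[v.name]
        if v.kind == "categorical":
            out[v.name] = col.astype(object).where(col.notna(), np.nan)
        else:
            out[v.name] = col.astype(float)
    return pd.DataFrame(out, index=data.index)


def read_cohort(
    path: str | Path,
    schema: list[VariableSpec],
    outcome_name: str | None = None,
    missing_tokens: tuple[str, ...] = DEFAULT_MISSING_TOKENS,
) -> CohortTable:
    """Read a CSV cohort file against a declared schema.

    The header must contain every schema name (extra columns are an error
    only if a schema column is absent; they are ignored otherwise).  Cells
    equal to any of ``missing_tokens`` (after stripping) are missing.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    names = [v.name for v in schema]
    absent = [n for n in names if n not in raw.columns]
    if absent:
        raise SchemaError(f"{path}: missing required column(s) {absent}")
    tokens = set(missing_tokens)
    columns: dict[str, list] = {}
    for v in schema:
        parsed: list = []
        for i, token in enumerate(raw[v.name].tolist()):
            token = token.strip()
            if token in tokens:
                parsed.append(np.nan)
            else:
                parsed.append(v.parse(token, row=i))
        columns[v.name] = parsed
    data = _ensure_dtypes(pd.DataFrame(columns, columns=names), schema)
    return CohortTable(list(schema), data, outcome_name)


def write_cohort(
    table: CohortTable,
    path: str | Path,
    missing_token: str = "",
) -> Path:
    """Write a cohort to CSV; missing cells become ``missing_token``.

    Continuous values are written with ``repr`` so a read-back round-trip
    is exact; binary values are written as integers.
    """
    path = Path(path)
    out = {}
    for v in table.variables:
        col = table.data[v.name]
        if v.kind == "continuous":
            out[v.name] = [missing_token if pd.isna(x) else repr(float(x)) for x in col]
        elif v.kind == "binary":
            out[v.name] = [missing_token if pd.isna(x) else str(int(x)) for x in col]
        else:
            out[v.name] = [missing_token if pd.isna(x) else str(x) for x in col]
    pd.DataFrame(out, columns=table.names).to_csv(path, index=False)
    return path


def exclude_previously_diagnosed(
    table: CohortTable, flag_name: str
) -> tuple[CohortTable, int]:
    """Drop rows whose exclusion flag equals 1; also drops the flag column.

    Returns the filtered table (row order preserved, original untouched)
    and the number of rows removed.
    """
    spec = table.spec(flag_name)
    if spec.kind != "binary":
        raise SchemaError(f"exclusion flag {flag_name!r} must be binary")
    flag = table.data[flag_name]
    keep = ~(flag == 1.0)
    excluded = int((~keep).sum())
    filtered = table.data.loc[keep].reset_index(drop=True)
    result = CohortTable(list(table.variables), filtered, table.outcome_name)
    return result.drop_variable(flag_name), excluded


def summarize_missingness(table: CohortTable) -> MissingnessSummary:
    """Tabulate per-variable missing counts/percentages and any-missing rows."""
    if table.n == 0:
        raise DegenerateInputError("cannot summarise an empty table")
    mask = table.missing_mask()
    counts = mask.sum(axis=0).astype(int)
    per_var = pd.DataFrame(
        {
            "missing_count": counts,
            "missing_percent": 100.0 * counts / table.n,
        }
    )
    per_var.index.name = "variable"
    return MissingnessSummary(
        per_variable=per_var,
        n_any_missing=int(mask.any(axis=1).sum()),
        n=table.n,
    )


def enumerate_patterns(table: CohortTable) -> list[MissingnessPattern]:
    """Enumerate distinct missingness masks, most frequent first.

    Ties are broken by the mask's lexicographic order so the output is
    deterministic.  Frequencies sum to ``n``.
    """
    if table.n == 0:
        raise DegenerateInputError("cannot enumerate patterns of an empty table")
    mask = table.missing_mask().to_numpy()
    counts: dict[tuple[bool, ...], int] = {}
    for row in mask:
        key = tuple(bool(x) for x in row)
        counts[key] = counts.get(key, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [MissingnessPattern(mask=k, frequency=v) for k, v in ordered]


# ---------------------------------------------------------------------------
# Schema file I/O

def load_schema(path: str | Path) -> tuple[list[VariableSpec], str | None]:
    """Load a YAML schema file: a list of VariableSpec entries plus an
    optional top-level ``outcome`` key."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "variables" not in doc:
        raise SchemaError(f"{path}: expected a mapping with a 'variables' list")
    specs = []
    for entry in doc["variables"]:
        labels = entry.get("labels")
        if labels is not None:
            labels = {int(k): v for k, v in labels.items()}
        specs.append(
            VariableSpec(
                name=entry["name"],
                kind=entry["kind"],
                categories=tuple(entry["categories"]) if entry.get("categories") else None,
                units=entry.get("units"),
                labels=labels,
            )
        )
    return specs, doc.get("outcome")


def save_schema(specs: list[VariableSpec], path: str | Path, outcome: str | None = None) -> Path:
    doc: dict = {"variables": []}
    if outcome is not None:
        doc["outcome"] = outcome
    for v in specs:
        entry: dict = {"name": v.name, "kind": v.kind}
        if v.categories:
            entry["categories"] = list(v.categories)
        if v.units:
            entry["units"] = v.units
        if v.labels:
            entry["labels"] = {int(k): val for k, val in v.labels.items()}
        doc["variables"].append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return Path(path)


def default_schema() -> tuple[list[VariableSpec], str | None]:
    """The shipped 15-variable schema (14 analysis variables + exclusion flag)."""
    from importlib import resources

    res = resources.files(__package__) / "schema" / "bellville.yaml"
    doc = yaml.safe_load(res.read_text())
    specs = []
    for entry in doc["variables"]:
        labels = entry.get("labels")
        if labels is not None:
            labels = {int(k): v for k, v in labels.items()}
        specs.append(
            VariableSpec(
                name=entry["name"],
                kind=entry["kind"],
                categories=tuple(entry["categories"]) if entry.get("categories") else None,
                units=entry.get("units"),
                labels=labels,
            )
        )
    return specs, doc.get("outcome")


def dataclass_fields(obj) -> dict:
    return dataclasses.asdict(obj)
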