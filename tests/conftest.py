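import numpy as np
import pandas as pd
import pytest

from imputebench import CohortTable, VariableSpec


@pytest.fixture
def mixed_schema():
    """Small mixed-kind schema with a binary outcome."""
    return [
        VariableSpec("y", "binary"),
        VariableSpec("age", "continuous", units="years"),
        VariableSpec("bmi", "continuous", units="kg/m2"),
        VariableSpec("treated", "binary"),
        VariableSpec("smoking", "categorical", categories=("current", "past", "no")),
    ]


def build_table(schema, columns, outcome=None):
    """Assemble a CohortTable from per-column python lists (None = missing)."""
    data = {}
    for spec in schema:
        col = columns[spec.name]
        if spec.kind == "categorical":
            data[spec.name] = pd.Series(
                [np.nan if v is None else v for v in col], dtype=object)
        else:
            data[spec.name] = pd.Series(
                [np.nan if v is None else float(v) for v in col], dtype=float)
    return CohortTable(list(schema), pd.DataFrame(data), outcome_name=outcome)


@pytest.fixture
def small_table(mixed_schema):
    """Five rows, two of which have missing cells."""
    return build_table(
        mixed_schema,
        {
            "y": [0, 1, 0, 1, 0],
            "age": [40.0, 55.0, None, 62.0, 48.0],
            "bmi": [22.5, 31.0, 27.2, None, 24.8],
            "treated": [0, 1, 0, 1, 0],
            "smoking": ["no", "current", "past", "current", "no"],
        },
        outcome="y",
    )


def random_mixed_table(rng, n=50, missing_rate=0.1, outcome="y"):
    """Random table over the mixed schema with MCAR holes (outcome kept complete)."""
    schema = [
        VariableSpec("y", "binary"),
        VariableSpec("age", "continuous"),
        VariableSpec("bmi", "continuous"),
        VariableSpec("treated", "binary"),
        VariableSpec("smoking", "categorical", categories=("current", "past", "no")),
    ]
    cols = {
        "y": rng.integers(0, 2, n).astype(float),
        "age": rng.normal(50, 10, n),
        "bmi": rng.normal(28, 5, n),
        "treated": rng.integers(0, 2, n).astype(float),
        "smoking": rng.choice(np.array(["current", "past", "no"], dtype=object), n),
    }
    data = pd.DataFrame(cols)
    for name in ("age", "bmi", "treated", "smoking"):
        holes = rng.random(n) < missing_rate
        data.loc[holes, name] = np.nan
    return CohortTable(schema, data, outcome_name=outcome)
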