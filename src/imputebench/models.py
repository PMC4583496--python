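"""Declarative logistic risk-score engine.

A risk model is an intercept plus additive terms on the logit scale.
Each term is a coefficient times a product of one or more factors, where
a factor applies a transform (identity, category indicator, or banding
into level scores) to one cohort variable.  This covers the published
non-invasive undiagnosed-diabetes scores (Cambridge, Kuwaiti, Omani,
Rotterdam, simplified Finnish), whose coefficients live in editable YAML
spec files rather than code.

Rows missing any predictor a model needs are never scored; they are
counted as unscorable so that downstream metrics report the effective n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import CohortTable, SchemaError

# Linear predictors are clamped to +/- LP_CLAMP before expit so that
# probabilities are representable and strictly inside (0, 1).
LP_CLAMP = 35.0


class ModelSpecError(Exception):
    """A model spec file is malformed or violates a transform invariant."""


class CalibrationError(Exception):
    """Recalibration is impossible (no events or no non-events)."""


@dataclass(frozen=True)
class Transform:
    """A total map from a variable's domain to a real score.

    kind = "identity":   x -> x (continuous or binary variables)
    kind = "indicator":  x -> 1 if x == category else 0
    kind = "band":       x -> scores[i] where breaks[i-1] <= x < breaks[i]
                         (len(scores) == len(breaks) + 1, breaks strictly
                         increasing; the last band is right-open)
    """

    kind: str
    category: object | None = None
    breaks: tuple[float, ...] | None = None
    scores: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.kind not in ("identity", "indicator", "band"):
            raise ModelSpecError(f"unknown transform kind {self.kind!r}")
        if self.kind == "indicator" and self.category is None:
            raise ModelSpecError("indicator transform needs a category")
        if self.kind == "band":
            if not self.breaks or self.scores is None:
                raise ModelSpecError("band transform needs breaks and scores")
            breaks = tuple(float(b) for b in self.breaks)
            if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
                raise ModelSpecError(f"band breaks must be strictly increasing: {breaks}")
            if len(self.scores) != len(breaks) + 1:
                raise ModelSpecError(
                    f"band needs len(scores) == len(breaks) + 1, got "
                    f"{len(self.scores)} scores for {len(breaks)} breaks"
                )
            object.__setattr__(self, "breaks", breaks)
            object.__setattr__(self, "scores", tuple(float(s) for s in self.scores))

    def apply(self, values: pd.Series) -> np.ndarray:
        """Apply to a column; NaN propagates (missing stays missing)."""
        if self.kind == "identity":
            return values.astype(float).to_numpy()
        if self.kind == "indicator":
            missing = values.isna().to_numpy()
            out = (values == self.category).astype(float).to_numpy()
            out[missing] = np.nan
            return out
        x = values.astype(float).to_numpy()
        idx = np.searchsorted(np.asarray(self.breaks), x, side="right")
        out = np.asarray(self.scores, dtype=float)[idx]
        out[np.isnan(x)] = np.nan
        return out


@dataclass(frozen=True)
class TermFactor:
    variable: str
    transform: Transform


@dataclass(frozen=True)
class ModelTerm:
    """coefficient * product of transformed variables (usually one factor)."""

    factors: tuple[TermFactor, ...]
    coefficient: float

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(f.variable for f in self.factors)


@dataclass
class RiskModelSpec:
    """Logistic risk model: p = expit(intercept + sum of terms)."""

    name: str
    intercept: float
    terms: list[ModelTerm] = field(default_factory=list)
    placeholder_coefficients: bool = False

    @property
    def variables(self) -> list[str]:
        seen: list[str] = []
        for t in self.terms:
            for v in t.variables:
                if v not in seen:
                    seen.append(v)
        return seen

    def with_intercept(self, intercept: float) -> "RiskModelSpec":
        return RiskModelSpec(self.name, intercept, list(self.terms),
                             self.placeholder_coefficients)

    def linear_predictor(self, table: CohortTable) -> np.ndarray:
        """Per-row linear predictor; NaN where any required predictor is missing."""
        for v in self.variables:
            table.spec(v)  # raises SchemaError if absent
        lp = np.full(table.n, self.intercept, dtype=float)
        for term in self.terms:
            contrib = np.full(table.n, term.coefficient, dtype=float)
            for factor in term.factors:
                contrib = contrib * factor.transform.apply(table.data[factor.variable])
            lp = lp + contrib
        return lp


@dataclass
class RiskPredictions:
    """Predicted probabilities for one model on one cohort.

    ``probability`` is NaN for unscorable rows (missing predictors).
    """

    model_name: str
    probability: np.ndarray
    n_scored: int
    n_unscorable: int

    @property
    def scored(self) -> np.ndarray:
        return ~np.isnan(self.probability)


def predict_risk(model: RiskModelSpec, table: CohortTable) -> RiskPredictions:
    """Score every row that is complete on the model's predictors."""
    lp = model.linear_predictor(table)
    prob = np.full_like(lp, np.nan)
    ok = ~np.isnan(lp)
    prob[ok] = expit(np.clip(lp[ok], -LP_CLAMP, LP_CLAMP))
    n_scored = int(ok.sum())
    return RiskPredictions(
        model_name=model.name,
        probability=prob,
        n_scored=n_scored,
        n_unscorable=table.n - n_scored,
    )


def recalibrate_intercept(model: RiskModelSpec, table: CohortTable) -> RiskModelSpec:
    """Shift the intercept so expected events equal observed events.

    The shift delta solves sum(expit(lp_i + delta)) = sum(outcome_i) over
    rows that are scorable and have an observed outcome.  The expected
    count is continuous and strictly increasing in delta, so bisection on
    [-20, 20] converges; tolerance is 1e-6 relative to the observed count.
    Being a rank-preserving shift, recalibration leaves discrimination
    (the C-statistic) untouched.
    """
    if table.outcome_name is None:
        raise CalibrationError("table has no outcome variable")
    lp = model.linear_predictor(table)
    outcome = table.data[table.outcome_name].astype(float).to_numpy()
    use = ~np.isnan(lp) & ~np.isnan(outcome)
    lp, outcome = lp[use], outcome[use]
    observed = outcome.sum()
    if observed < 1 or (len(outcome) - observed) < 1:
        raise CalibrationError("recalibration needs at least one event and one non-event")

    def excess(delta: float) -> float:
        return expit(np.clip(lp + delta, -LP_CLAMP, LP_CLAMP)).sum() - observed

    lo, hi = -20.0, 20.0
    if excess(lo) > 0 or excess(hi) < 0:
        raise CalibrationError("recalibration shift outside [-20, 20]")
    delta = brentq(excess, lo, hi, xtol=1e-12, rtol=8.9e-16)
    assert abs(excess(delta)) <= 1e-6 * observed
    return model.with_intercept(model.intercept + delta)


# ---------------------------------------------------------------------------
# Spec file I/O

def _transform_from_doc(doc) -> Transform:
    if doc in (None, "identity"):
        return Transform("identity")
    if isinstance(doc, dict):
        if "indicator" in doc:
            return Transform("indicator", category=doc["indicator"])
        if "band" in doc:
            band = doc["band"]
            return Transform("band", breaks=tuple(band["breaks"]), scores=tuple(band["scores"]))
    raise ModelSpecError(f"unrecognised transform spec: {doc!r}")


def _transform_to_doc(t: Transform):
    if t.kind == "identity":
        return "identity"
    if t.kind == "indicator":
        return {"indicator": t.category}
    return {"band": {"breaks": list(t.breaks), "scores": list(t.scores)}}


def _term_from_doc(doc: dict) -> ModelTerm:
    if "coefficient" not in doc:
        raise ModelSpecError(f"term is missing a coefficient: {doc!r}")
    if "product" in doc:
        factors = tuple(
            TermFactor(f["variable"], _transform_from_doc(f.get("transform")))
            for f in doc["product"]
        )
    elif "variable" in doc:
        factors = (TermFactor(doc["variable"], _transform_from_doc(doc.get("transform"))),)
    else:
        raise ModelSpecError(f"term needs 'variable' or 'product': {doc!r}")
    return ModelTerm(factors=factors, coefficient=float(doc["coefficient"]))


def load_model_spec(path: str | Path) -> RiskModelSpec:
    """Load and validate a YAML risk-model spec."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return model_spec_from_doc(doc, origin=str(path))


def model_spec_from_doc(doc: dict, origin: str = "<doc>") -> RiskModelSpec:
    if not isinstance(doc, dict):
        raise ModelSpecError(f"{origin}: expected a mapping")
    for key in ("name", "intercept"):
        if key not in doc:
            raise ModelSpecError(f"{origin}: missing required field {key!r}")
    link = doc.get("link", "logistic")
    if link != "logistic":
        raise ModelSpecError(f"{origin}: only the logistic link is supported, got {link!r}")
    terms = [_term_from_doc(t) for t in doc.get("terms", [])]
    return RiskModelSpec(
        name=str(doc["name"]),
        intercept=float(doc["intercept"]),
        terms=terms,
        placeholder_coefficients=bool(doc.get("placeholder_coefficients", False)),
    )


def save_model_spec(model: RiskModelSpec, path: str | Path) -> Path:
    doc: dict = {"name": model.name, "intercept": model.intercept, "link": "logistic"}
    if model.placeholder_coefficients:
        doc["placeholder_coefficients"] = True
    doc["terms"] = []
    for term in model.terms:
        if len(term.factors) == 1:
            f = term.factors[0]
            doc["terms"].append(
                {"variable": f.variable, "transform": _transform_to_doc(f.transform),
                 "coefficient": term.coefficient}
            )
        else:
            doc["terms"].append(
                {"product": [
                    {"variable": f.variable, "transform": _transform_to_doc(f.transform)}
                    for f in term.factors
                ], "coefficient": term.coefficient}
            )
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return Path(path)


REGISTRY_NAMES = ("cambridge", "kuwaiti", "omani", "rotterdam", "finnish")


def builtin_registry() -> list[RiskModelSpec]:
    """Load the five shipped undiagnosed-diabetes risk model specs.

    The shipped coefficients are clearly-marked placeholders: the engine
    and predictor sets are fixed, but users validating against the
    original publications should paste the published coefficients into
    the YAML files (they are configuration, not code).
    """
    specs = []
    pkg = resources.files(__package__) / "registry"
    for name in REGISTRY_NAMES:
        res = pkg / f"{name}.yaml"
        if not res.is_file():
            raise ModelSpecError(
                f"registry file {name}.yaml not found; expected one file per "
                f"model in {REGISTRY_NAMES}"
            )
        specs.append(model_spec_from_doc(yaml.safe_load(res.read_text()), origin=name))
    return specs
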