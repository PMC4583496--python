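"""Missing-data handling strategies and Rubin's-rules pooling.

Five strategies are implemented, selectable everywhere by the strings
``deletion``, ``simple``, ``conditional``, ``stochastic`` and ``mice``:

* **deletion** — complete-case analysis: keep only rows with no missing
  cell.  (Some sources label this "pairwise" while reporting a single
  reduced sample size; the single-n behaviour is listwise deletion,
  which is what this module implements under the label ``deletion``.)
* **simple** — unconditional imputation: column mean for continuous
  variables, observed mode for binary/categorical.
* **conditional** — conditional-mean imputation: one regression per
  variable (linear / logistic / multinomial) with *all* other variables
  including the outcome as predictors, fitted on complete cases; only
  cells whose row is complete on every predictor are filled, so residual
  missingness is possible ("varied length").
* **stochastic** — stochastic regression: conditional predictions plus
  residual noise (continuous) or class-probability draws (discrete),
  with residual variance taken from the fit and no parameter-uncertainty
  draw.  Rows incomplete on predictors are completed by one chained
  sweep seeded from unconditional draws, so the output is always a full
  table.
* **mice** — multiple imputation by chained equations (fully conditional
  specification): m independent chains, each initialised with random
  observed-value draws and cycled through the variables for a fixed
  number of sweeps, refitting the type-appropriate stochastic
  conditional model each visit.

Per-imputation estimates are combined with :func:`rubin_pool`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .cohort import CohortTable, VariableSpec

METHODS = ("deletion", "simple", "conditional", "stochastic", "mice")


class ImputationError(Exception):
    """An imputation strategy cannot run on this input."""


@dataclass
class ImputedDataset:
    """One completed (or reduced) table plus provenance of filled cells."""

    table: CohortTable
    method: str
    imputed_mask: pd.DataFrame  # True where a cell was filled by the method
    effective_n: dict[str, int]  # per-variable non-missing count after the method
    warnings: list[str] = field(default_factory=list)
    n_input: int = 0


@dataclass
class MultipleImputationResult:
    """m completed tables from independent chained-equations chains."""

    datasets: list[ImputedDataset]
    m: int
    seed: int
    iterations: int


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of m point estimates and variances.

    q_bar : pooled point estimate (mean of per-dataset estimates)
    w     : within-imputation variance (mean of per-dataset variances)
    b     : between-imputation variance (sample variance of estimates)
    t     : total variance, w + (1 + 1/m) * b
    df    : large-sample degrees of freedom, (m-1)(1 + w/((1+1/m) b))^2
    """

    q_bar: float
    w: float
    b: float
    t: float
    df: float
    m: int

    @property
    def se(self) -> float:
        return math.sqrt(self.t)


def rubin_pool(estimates, variances) -> PooledEstimate:
    """Combine per-imputation estimates and variances by Rubin's rules."""
    q = np.asarray(estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    if q.shape != v.shape or q.ndim != 1:
        raise ValueError("estimates and variances must be equal-length 1-d sequences")
    m = len(q)
    if m < 2:
        raise ValueError(f"pooling needs m >= 2 estimates, got {m}")
    if (v < 0).any():
        raise ValueError("variances must be non-negative")
    q_bar = float(q.mean())
    w = float(v.mean())
    b = float(q.var(ddof=1))
    t = w + (1.0 + 1.0 / m) * b
    if b == 0.0:
        df = math.inf
    else:
        df = (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * b)) ** 2
    return PooledEstimate(q_bar=q_bar, w=w, b=b, t=t, df=df, m=m)


# ---------------------------------------------------------------------------
# deletion and simple imputation

def complete_case(table: CohortTable) -> ImputedDataset:
    """Complete-case (listwise) deletion: keep rows with zero missing cells."""
    mask = table.missing_mask()
    keep = ~mask.any(axis=1)
    kept = table.data.loc[keep].reset_index(drop=True)
    out = CohortTable(list(table.variables), kept, table.outcome_name)
    warns = []
    if len(kept) == 0:
        warns.append("complete-case deletion left zero rows")
    return ImputedDataset(
        table=out,
        method="deletion",
        imputed_mask=pd.DataFrame(False, index=out.data.index, columns=out.names),
        effective_n={name: len(kept) for name in out.names},
        warnings=warns,
        n_input=table.n,
    )


def _column_mode(spec: VariableSpec, observed: pd.Series):
    """Observed mode; ties break toward the earliest code/category."""
    if spec.kind == "binary":
        ones = int((observed == 1.0).sum())
        zeros = int((observed == 0.0).sum())
        return 1.0 if ones > zeros else 0.0
    counts = observed.value_counts()
    best = counts.max()
    for cat in spec.categories:
        if counts.get(cat, 0) == best:
            return cat
    return counts.idxmax()


def simple_impute(table: CohortTable) -> ImputedDataset:
    """Unconditional mean (continuous) / mode (binary, categorical) fill.

    Preserves every continuous column's mean exactly and never increases
    its sample SD.
    """
    mask = table.missing_mask()
    filled = table.data.copy()
    for spec in table.variables:
        col = table.data[spec.name]
        miss = mask[spec.name]
        if not miss.any():
            continue
        observed = col[~miss]
        if observed.empty:
            raise ImputationError(f"column {spec.name!r} has no observed values")
        if spec.kind == "continuous":
            value = float(observed.astype(float).mean())
        else:
            value = _column_mode(spec, observed)
        filled.loc[miss, spec.name] = value
    out = CohortTable(list(table.variables), filled, table.outcome_name)
    return ImputedDataset(
        table=out,
        method="simple",
        imputed_mask=mask.copy(),
        effective_n={name: table.n for name in out.names},
        n_input=table.n,
    )


# ---------------------------------------------------------------------------
# conditional models (shared by conditional / stochastic / mice)

def _design_matrix(data: pd.DataFrame, predictors: list[VariableSpec],
                   rows: np.ndarray) -> np.ndarray:
    """Numeric design matrix (no intercept column) for the given rows.

    Continuous/binary predictors enter as-is; categorical predictors are
    one-hot encoded with the first category as reference.
    """
    cols = []
    for spec in predictors:
        col = data[spec.name]
        if spec.kind == "categorical":
            for cat in spec.categories[1:]:
                cols.append((col.iloc[rows] == cat).astype(float).to_numpy())
        else:
            cols.append(col.iloc[rows].astype(float).to_numpy())
    if not cols:
        return np.empty((len(rows), 0))
    return np.column_stack(cols)


def _fit_fill(
    data: pd.DataFrame,
    specs: list[VariableSpec],
    target: VariableSpec,
    fit_rows: np.ndarray,
    fill_rows: np.ndarray,
    stochastic: bool,
    rng: np.random.Generator | None,
    log: list[str],
    proper: bool = False,
):
    """Fit the type-appropriate conditional model and produce fill values.

    Returns an array of fills aligned with ``fill_rows``.  With
    ``stochastic`` the fills carry residual noise (continuous) or are
    class-probability draws (discrete); with ``proper`` additionally the
    continuous regression parameters are drawn from their posterior
    (sigma^2 from the scaled inverse chi-square, beta from its normal
    conditional), which is what keeps between-imputation variance honest
    in multiple imputation.  On an unfittable model (too few rows,
    single observed class, solver failure) falls back to the
    unconditional mean (continuous), mode (deterministic fill) or an
    observed-distribution draw (stochastic fill), and records the
    fallback in ``log``.
    """
    predictors = [s for s in specs if s.name != target.name]
    y_obs = data[target.name].iloc[fit_rows]

    def fallback():
        log.append(f"fallback to unconditional fill for {target.name!r}")
        if target.kind == "continuous":
            mean = float(y_obs.astype(float).mean())
            if stochastic:
                sd = float(y_obs.astype(float).std(ddof=1)) if len(y_obs) > 1 else 0.0
                return mean + rng.normal(0.0, sd, size=len(fill_rows))
            return np.full(len(fill_rows), mean)
        dtype = object if target.kind == "categorical" else float
        if stochastic:
            return rng.choice(y_obs.to_numpy(), size=len(fill_rows)).astype(dtype)
        return np.full(len(fill_rows), _column_mode(target, y_obs), dtype=dtype)

    n_params = 1 + sum(
        len(s.categories) - 1 if s.kind == "categorical" else 1 for s in predictors
    )
    if len(fit_rows) < n_params + 2:
        return fallback()

    X_fit = _design_matrix(data, predictors, fit_rows)
    X_fill = _design_matrix(data, predictors, fill_rows)

    if target.kind == "continuous":
        y = y_obs.astype(float).to_numpy()
        A = np.column_stack([np.ones(len(X_fit)), X_fit])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        pred_fit = A @ beta
        dof = max(len(y) - A.shape[1], 1)
        sigma2 = float(((y - pred_fit) ** 2).sum() / dof)
        if stochastic and proper and sigma2 > 0:
            # posterior draws: sigma^2* ~ SSR / chi2(dof), beta* ~ N(beta, sigma^2* (A'A)^-1)
            sigma2_star = sigma2 * dof / rng.chisquare(dof)
            gram_inv = np.linalg.pinv(A.T @ A)
            cov = sigma2_star * (gram_inv + gram_inv.T) / 2.0
            try:
                chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(beta)))
                beta = beta + chol @ rng.standard_normal(len(beta))
            except np.linalg.LinAlgError:
                pass
            sigma2 = sigma2_star
        pred = np.column_stack([np.ones(len(X_fill)), X_fill]) @ beta
        if stochastic and sigma2 > 0:
            pred = pred + rng.normal(0.0, math.sqrt(sigma2), size=len(pred))
        return pred

    # discrete target: logistic / multinomial on category codes
    if target.kind == "binary":
        classes = np.array([0.0, 1.0])
        y = y_obs.astype(float).to_numpy()
    else:
        classes = np.asarray(target.categories, dtype=object)
        y = y_obs.to_numpy()
    present = pd.unique(y)
    if len(present) < 2:
        return fallback()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            # C=inf gives the unpenalised maximum-likelihood fit
            clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
            clf.fit(X_fit, y)
        proba = clf.predict_proba(X_fill)
    except Exception:
        return fallback()
    # column order follows clf.classes_; align to the declared class order
    order = {c: i for i, c in enumerate(clf.classes_)}
    full = np.zeros((len(X_fill), len(classes)))
    for j, c in enumerate(classes):
        if c in order:
            full[:, j] = proba[:, order[c]]
    if stochastic:
        cum = full.cumsum(axis=1)
        u = rng.random(len(X_fill))
        idx = (u[:, None] > cum).sum(axis=1).clip(0, len(classes) - 1)
    else:
        idx = full.argmax(axis=1)
    return classes[idx]


def conditional_mean_impute(table: CohortTable) -> ImputedDataset:
    """Conditional-mean imputation with all-other-variables predictors.

    Each variable's model is fitted on rows complete in every variable;
    only missing cells in rows complete on all predictors are filled, so
    the output may retain missing cells (a varied per-variable n).
    """
    mask = table.missing_mask()
    complete_rows = np.flatnonzero(~mask.any(axis=1).to_numpy())
    filled = table.data.copy()
    log: list[str] = []
    for spec in table.variables:
        miss = mask[spec.name].to_numpy()
        if not miss.any():
            continue
        other_complete = ~mask.drop(columns=[spec.name]).any(axis=1).to_numpy()
        fill_rows = np.flatnonzero(miss & other_complete)
        if len(fill_rows) == 0:
            continue
        values = _fit_fill(table.data, table.variables, spec,
                           complete_rows, fill_rows, stochastic=False,
                           rng=None, log=log)
        filled.iloc[fill_rows, filled.columns.get_loc(spec.name)] = values
    out = CohortTable(list(table.variables), filled, table.outcome_name)
    new_mask = out.missing_mask()
    return ImputedDataset(
        table=out,
        method="conditional",
        imputed_mask=mask & ~new_mask,
        effective_n={name: int(table.n - new_mask[name].sum()) for name in out.names},
        warnings=log,
        n_input=table.n,
    )


def _initial_draws(table: CohortTable, work: pd.DataFrame, mask: pd.DataFrame,
                   rng: np.random.Generator) -> None:
    """Fill every missing cell in-place with a random observed-value draw."""
    for spec in table.variables:
        miss = mask[spec.name].to_numpy()
        if not miss.any():
            continue
        observed = table.data[spec.name][~miss]
        if observed.empty:
            raise ImputationError(f"column {spec.name!r} has no observed values")
        draws = rng.choice(observed.to_numpy(), size=int(miss.sum()))
        work.iloc[np.flatnonzero(miss), work.columns.get_loc(spec.name)] = draws


def _chained_sweeps(
    table: CohortTable,
    work: pd.DataFrame,
    mask: pd.DataFrame,
    sweeps: int,
    rng: np.random.Generator,
    log: list[str],
    only_rows: dict[str, np.ndarray] | None = None,
    proper: bool = False,
) -> None:
    """Run FCS sweeps in schema order, redrawing originally-missing cells.

    Models are fitted on rows where the target is originally observed,
    with all other columns taken from the current completed data.  When
    ``only_rows`` is given, only those row indices are redrawn per
    variable (used by the stochastic single-imputation clean-up pass).
    """
    for _ in range(sweeps):
        for spec in table.variables:
            miss = mask[spec.name].to_numpy()
            if not miss.any():
                continue
            fill_rows = (np.flatnonzero(miss) if only_rows is None
                         else only_rows.get(spec.name, np.empty(0, dtype=int)))
            if len(fill_rows) == 0:
                continue
            fit_rows = np.flatnonzero(~miss)
            values = _fit_fill(work, table.variables, spec, fit_rows, fill_rows,
                               stochastic=True, rng=rng, log=log, proper=proper)
            work.iloc[fill_rows, work.columns.get_loc(spec.name)] = values


def stochastic_regression_impute(table: CohortTable, seed: int) -> ImputedDataset:
    """Stochastic regression imputation returning a fully observed table.

    First pass: rows complete on all predictors get a regression fill
    plus residual noise (continuous) or a class-probability draw
    (discrete), with models fitted on complete cases — deterministic-fill
    semantics plus noise, no parameter-uncertainty draw.  Rows still
    incomplete after that pass are completed by one chained sweep seeded
    from unconditional observed-value draws.
    """
    rng = np.random.default_rng(seed)
    mask = table.missing_mask()
    complete_rows = np.flatnonzero(~mask.any(axis=1).to_numpy())
    filled = table.data.copy()
    log: list[str] = []
    for spec in table.variables:
        miss = mask[spec.name].to_numpy()
        if not miss.any():
            continue
        other_complete = ~mask.drop(columns=[spec.name]).any(axis=1).to_numpy()
        fill_rows = np.flatnonzero(miss & other_complete)
        if len(fill_rows) == 0:
            continue
        values = _fit_fill(table.data, table.variables, spec,
                           complete_rows, fill_rows, stochastic=True,
                           rng=rng, log=log)
        filled.iloc[fill_rows, filled.columns.get_loc(spec.name)] = values

    # clean-up pass for rows incomplete on predictors
    leftover_mask = filled.isna()
    if leftover_mask.any().any():
        leftover = {
            name: np.flatnonzero(leftover_mask[name].to_numpy())
            for name in filled.columns
            if leftover_mask[name].any()
        }
        interim = CohortTable(list(table.variables), filled, table.outcome_name)
        _initial_draws(interim, filled, leftover_mask, rng)
        _chained_sweeps(table, filled, mask, sweeps=1, rng=rng, log=log,
                        only_rows=leftover)

    out = CohortTable(list(table.variables), filled, table.outcome_name)
    return ImputedDataset(
        table=out,
        method="stochastic",
        imputed_mask=mask.copy(),
        effective_n={name: table.n for name in out.names},
        warnings=log,
        n_input=table.n,
    )


def mice_impute(
    table: CohortTable,
    m: int = 5,
    iterations: int = 10,
    seed: int = 0,
) -> MultipleImputationResult:
    """Multiple imputation by chained equations (FCS).

    Each of the ``m`` chains starts from independent random
    observed-value draws and cycles the variables in schema order for
    ``iterations`` sweeps; each visit refits the type-appropriate
    stochastic conditional model (all other variables plus the outcome
    as predictors) on rows where the target is originally observed, then
    redraws the target's originally-missing cells.  Continuous
    conditionals draw their regression parameters from the posterior
    before adding residual noise, so between-imputation variability is
    properly propagated; discrete conditionals draw from the fitted
    class probabilities.  Identical
    ``(table, m, iterations, seed)`` give bit-identical results.
    """
    if m < 2:
        raise ValueError(f"multiple imputation needs m >= 2, got {m}")
    mask = table.missing_mask()
    children = np.random.SeedSequence(seed).spawn(m)
    datasets = []
    for k in range(m):
        rng = np.random.default_rng(children[k])
        work = table.data.copy()
        log: list[str] = []
        if mask.any().any():
            _initial_draws(table, work, mask, rng)
            _chained_sweeps(table, work, mask, sweeps=iterations, rng=rng, log=log,
                            proper=True)
        out = CohortTable(list(table.variables), work, table.outcome_name)
        datasets.append(
            ImputedDataset(
                table=out,
                method="mice",
                imputed_mask=mask.copy(),
                effective_n={name: table.n for name in out.names},
                warnings=log,
                n_input=table.n,
            )
        )
    return MultipleImputationResult(datasets=datasets, m=m, seed=seed,
                                    iterations=iterations)


def impute(table: CohortTable, method: str, seed: int = 0,
           m: int = 5, iterations: int = 10):
    """Dispatch by method name; returns an ImputedDataset or, for
    ``mice``, a MultipleImputationResult."""
    if method == "deletion":
        return complete_case(table)
    if method == "simple":
        return simple_impute(table)
    if method == "conditional":
        return conditional_mean_impute(table)
    if method == "stochastic":
        return stochastic_regression_impute(table, seed=seed)
    if method == "mice":
        return mice_impute(table, m=m, iterations=iterations, seed=seed)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
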