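"""Discrimination and calibration metrics for probabilistic predictions.

Implements the external-validation metric set for binary-outcome risk
models: the concordance (C) statistic with a DeLong nonparametric 95% CI
(Hanley–McNeil available behind a flag), the Brier score, the Yates
slope (mean predicted risk in events minus non-events), and the
expected/observed (E/O) ratio with a log-scale Poisson 95% CI.  A
Rubin's-rules pooling routine combines per-imputation reports on each
metric's working scale (logit for C, log for E/O).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit, logit
from scipy.stats import rankdata

from .impute import rubin_pool
from .models import RiskPredictions

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class MetricError(Exception):
    """A metric's preconditions are not met (e.g. single-class outcome)."""


@dataclass
class PerformanceReport:
    """One model x method x calibration-state cell of the comparison grid."""

    model_name: str
    method: str
    calibration_state: str  # "original" | "adjusted"
    e: float
    o: float
    eo_ratio: float
    eo_ci: tuple[float, float]
    brier: float
    yates_slope: float
    c: float
    c_ci: tuple[float, float]
    n_eff: int

    def to_row(self) -> dict:
        return {
            "model": self.model_name,
            "method": self.method,
            "state": self.calibration_state,
            "EO": self.eo_ratio,
            "EO_lo": self.eo_ci[0],
            "EO_hi": self.eo_ci[1],
            "brier": self.brier,
            "yates": self.yates_slope,
            "C": self.c,
            "C_lo": self.c_ci[0],
            "C_hi": self.c_ci[1],
            "n_eff": self.n_eff,
        }


def _as_arrays(predictions, outcomes) -> tuple[np.ndarray, np.ndarray]:
    """Extract aligned (prediction, outcome) arrays over usable rows."""
    if isinstance(predictions, RiskPredictions):
        pred = predictions.probability
    else:
        pred = np.asarray(predictions, dtype=float)
    out = np.asarray(outcomes, dtype=float)
    if pred.shape != out.shape:
        raise ValueError("predictions and outcomes must be aligned")
    use = ~np.isnan(pred) & ~np.isnan(out)
    return pred[use], out[use]


def _split(pred: np.ndarray, out: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    events = pred[out == 1.0]
    non_events = pred[out == 0.0]
    if len(events) == 0 or len(non_events) == 0:
        raise MetricError(
            "c_statistic / yates_slope need at least one event and one non-event"
        )
    return events, non_events


def c_statistic(predictions, outcomes, ci_method: str = "delong"
                ) -> tuple[float, tuple[float, float]]:
    """Concordance statistic with a nonparametric 95% CI.

    C is the probability that a random event outranks a random
    non-event, ties counting one half.  Computed via midranks (exactly
    equal to exhaustive pair enumeration).  The default CI uses the
    DeLong structural-components variance; ``ci_method="hanley"`` gives
    the Hanley–McNeil approximation instead.
    """
    pred, out = _as_arrays(predictions, outcomes)
    pos, neg = _split(pred, out)
    n1, n0 = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    r_all = rankdata(combined)  # midranks handle ties as half-concordances
    c = (r_all[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    if ci_method == "delong":
        v10 = (r_all[:n1] - rankdata(pos)) / n0  # placement values of events
        v01 = 1.0 - (r_all[n1:] - rankdata(neg)) / n1
        s10 = v10.var(ddof=1) if n1 > 1 else 0.0
        s01 = v01.var(ddof=1) if n0 > 1 else 0.0
        var = s10 / n1 + s01 / n0
    elif ci_method == "hanley":
        q1 = c / (2.0 - c)
        q2 = 2.0 * c * c / (1.0 + c)
        var = (c * (1 - c) + (n1 - 1) * (q1 - c * c) + (n0 - 1) * (q2 - c * c)) / (n1 * n0)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    half = Z95 * np.sqrt(max(var, 0.0))
    return float(c), (float(max(c - half, 0.0)), float(min(c + half, 1.0)))


def brier_score(predictions, outcomes) -> float:
    """Mean squared difference between prediction and outcome (0 = perfect)."""
    pred, out = _as_arrays(predictions, outcomes)
    if len(pred) == 0:
        raise MetricError("brier_score needs at least one scored row")
    return float(np.mean((pred - out) ** 2))


def yates_slope(predictions, outcomes) -> float:
    """Mean predicted probability in events minus in non-events."""
    pred, out = _as_arrays(predictions, outcomes)
    pos, neg = _split(pred, out)
    return float(pos.mean() - neg.mean())


def expected_observed(predictions, outcomes) -> tuple[float, tuple[float, float]]:
    """E/O calibration ratio with a log-scale Poisson 95% CI.

    E is the sum of predicted probabilities, O the observed event count.
    Treating O as Poisson, the CI is ratio * exp(±1.96 / sqrt(O)), which
    keeps both bounds positive.
    """
    pred, out = _as_arrays(predictions, outcomes)
    o = float(out.sum())
    if o < 1:
        raise MetricError("expected_observed needs at least one observed event")
    e = float(pred.sum())
    ratio = e / o
    halfwidth = Z95 / np.sqrt(o)
    return ratio, (float(ratio * np.exp(-halfwidth)), float(ratio * np.exp(halfwidth)))


def evaluate(predictions, outcomes, state: str = "original",
             model_name: str = "", method: str = "") -> PerformanceReport:
    """Assemble the full metric set on one scored-row subset."""
    pred, out = _as_arrays(predictions, outcomes)
    if len(pred) == 0:
        raise MetricError("no scorable rows with observed outcomes")
    failing = []
    if (out == 1.0).sum() == 0:
        failing.append("c_statistic, yates_slope, expected_observed (no events)")
    if (out == 0.0).sum() == 0:
        failing.append("c_statistic, yates_slope (no non-events)")
    if failing:
        raise MetricError("degenerate outcome vector; failing metrics: " + "; ".join(failing))
    c, c_ci = c_statistic(pred, out)
    eo, eo_ci = expected_observed(pred, out)
    return PerformanceReport(
        model_name=model_name,
        method=method,
        calibration_state=state,
        e=float(pred.sum()),
        o=float(out.sum()),
        eo_ratio=eo,
        eo_ci=eo_ci,
        brier=brier_score(pred, out),
        yates_slope=yates_slope(pred, out),
        c=c,
        c_ci=c_ci,
        n_eff=int(len(pred)),
    )


def pool_reports(reports: list[PerformanceReport], m: int | None = None
                 ) -> PerformanceReport:
    """Rubin-pool m per-imputation reports into one.

    Point estimates are pooled as arithmetic means.  Interval
    half-widths are pooled via Rubin total variance on each metric's
    working scale — logit for C (per-dataset SEs recovered from the CI
    half-widths by the delta method) and log for E/O (per-dataset
    log-scale SE = 1/sqrt(O)) — then mapped back around the pooled point
    estimate.  Brier score and Yates slope are pooled as plain means.
    """
    if m is None:
        m = len(reports)
    if len(reports) != m or m < 2:
        raise ValueError(f"pooling needs m >= 2 matching reports, got {len(reports)}")
    names = {r.model_name for r in reports}
    if len(names) > 1:
        raise ValueError(f"cannot pool reports from different models: {sorted(names)}")

    first = reports[0]
    if all(
        r.c == first.c and r.c_ci == first.c_ci and r.eo_ratio == first.eo_ratio
        and r.eo_ci == first.eo_ci and r.brier == first.brier
        and r.yates_slope == first.yates_slope and r.e == first.e
        and r.o == first.o and r.n_eff == first.n_eff
        for r in reports[1:]
    ):
        # b = 0 on every metric: the pooled report is any single report
        return replace(first)

    cs = np.array([r.c for r in reports])
    c_se = np.array([(r.c_ci[1] - r.c_ci[0]) / (2 * Z95) for r in reports])
    # delta method: se on the logit scale
    c_se_logit = c_se / np.clip(cs * (1 - cs), 1e-12, None)
    pooled_c = rubin_pool(logit(np.clip(cs, 1e-12, 1 - 1e-12)), c_se_logit**2)
    c_point = float(cs.mean())
    c_half = Z95 * pooled_c.se
    c_center = logit(np.clip(c_point, 1e-12, 1 - 1e-12))
    c_ci = (float(expit(c_center - c_half)), float(expit(c_center + c_half)))

    ratios = np.array([r.eo_ratio for r in reports])
    log_se = np.array([1.0 / np.sqrt(r.o) for r in reports])
    pooled_eo = rubin_pool(np.log(ratios), log_se**2)
    eo_point = float(ratios.mean())
    eo_half = Z95 * pooled_eo.se
    eo_ci = (float(eo_point * np.exp(-eo_half)), float(eo_point * np.exp(eo_half)))

    return PerformanceReport(
        model_name=reports[0].model_name,
        method=reports[0].method,
        calibration_state=reports[0].calibration_state,
        e=float(np.mean([r.e for r in reports])),
        o=float(np.mean([r.o for r in reports])),
        eo_ratio=eo_point,
        eo_ci=eo_ci,
        brier=float(np.mean([r.brier for r in reports])),
        yates_slope=float(np.mean([r.yates_slope for r in reports])),
        c=c_point,
        c_ci=c_ci,
        n_eff=int(round(np.mean([r.n_eff for r in reports]))),
    )
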