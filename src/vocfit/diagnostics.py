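"""Threshold-level diagnostic accuracy: confusion counts, metrics with
interval estimates, threshold sweeps, ROC operating points and trapezoidal AUC.

Conventions
-----------
A subject is test-positive iff its marker value is >= the threshold
(inclusive; the FIT pathway phrases cutoffs this way, with the assay's limit
of detection itself a usable cutoff). Set ``inclusive=False`` for a strict
``>`` rule. Interval estimates default to Wilson score intervals;
Clopper-Pearson is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from ._utils import round_display

__all__ = [
    "ConfusionCounts",
    "TestPerformance",
    "OperatingPoint",
    "confusion_at_threshold",
    "performance",
    "bayes_predictive_values",
    "threshold_sweep",
    "operating_points",
    "roc_auc",
    "sweep_table",
]

Marker = Literal["fit", "voc"]
_MARKER_COLUMNS = {"fit": "fit_ug_g", "voc": "voc_score"}
_CI_METHODS = {"wilson": "wilson", "clopper_pearson": "beta"}


class UndefinedMetricWarning(UserWarning):
    """A metric's denominator is zero; the metric is reported as None."""


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion table at one threshold; the atom of all accuracy metrics."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer; got {v!r}")

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_healthy(self) -> int:
        return self.fp + self.tn

    @property
    def n_total(self) -> int:
        return self.n_diseased + self.n_healthy

    @property
    def prevalence(self) -> float:
        return self.n_diseased / self.n_total


@dataclass(frozen=True)
class TestPerformance:
    """Sensitivity / specificity / PPV / NPV with interval estimates.

    A metric whose denominator is empty (e.g. PPV with no test-positives) is
    ``None`` rather than raising, so a sweep can still report the rest.
    """

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    sensitivity_ci: tuple[float, float] | None
    specificity_ci: tuple[float, float] | None
    ppv_ci: tuple[float, float] | None
    npv_ci: tuple[float, float] | None
    prevalence: float
    n_diseased: int
    n_healthy: int
    threshold: float | None = None
    counts: ConfusionCounts | None = None


@dataclass(frozen=True)
class OperatingPoint:
    """One vertex of the empirical ROC curve: (1 - specificity, sensitivity)."""

    threshold: float
    fpr: float
    tpr: float

    def __post_init__(self) -> None:
        if not (0 <= self.fpr <= 1 and 0 <= self.tpr <= 1):
            raise ValueError(f"operating point ({self.fpr}, {self.tpr}) outside unit square")


def _marker_values(records: pd.DataFrame, marker: Marker) -> np.ndarray:
    try:
        col = _MARKER_COLUMNS[marker]
    except KeyError:
        raise ValueError(f"marker must be one of {sorted(_MARKER_COLUMNS)}; got {marker!r}")
    return records[col].to_numpy(dtype=float)


def confusion_at_threshold(
    records: pd.DataFrame,
    marker: Marker,
    threshold: float,
    *,
    inclusive: bool = True,
) -> ConfusionCounts:
    """Tally the 2x2 table for rule "positive iff marker >= threshold"."""
    if len(records) == 0:
        raise ValueError("cannot tally an empty cohort")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    values = _marker_values(records, marker)
    status = records["diseased"].to_numpy(dtype=int)
    positive = values >= threshold if inclusive else values > threshold
    return ConfusionCounts(
        tp=int(np.sum(positive & (status == 1))),
        fp=int(np.sum(positive & (status == 0))),
        fn=int(np.sum(~positive & (status == 1))),
        tn=int(np.sum(~positive & (status == 0))),
    )


def _ratio_with_ci(
    count: int, nobs: int, method: str, level: float, label: str
) -> tuple[float | None, tuple[float, float] | None]:
    if nobs == 0:
        warnings.warn(f"{label} undefined: zero denominator", UndefinedMetricWarning)
        return None, None
    point = count / nobs
    lo, hi = proportion_confint(count, nobs, alpha=1 - level, method=method)
    return point, (float(lo), float(hi))


def performance(
    counts: ConfusionCounts,
    *,
    ci_method: Literal["wilson", "clopper_pearson"] = "wilson",
    level: float = 0.95,
    threshold: float | None = None,
) -> TestPerformance:
    """All four accuracy metrics with ``level`` interval estimates."""
    try:
        method = _CI_METHODS[ci_method]
    except KeyError:
        raise ValueError(f"ci_method must be one of {sorted(_CI_METHODS)}")
    sens, sens_ci = _ratio_with_ci(counts.tp, counts.n_diseased, method, level, "sensitivity")
    spec, spec_ci = _ratio_with_ci(counts.tn, counts.n_healthy, method, level, "specificity")
    ppv, ppv_ci = _ratio_with_ci(counts.tp, counts.tp + counts.fp, method, level, "PPV")
    npv, npv_ci = _ratio_with_ci(counts.tn, counts.tn + counts.fn, method, level, "NPV")
    return TestPerformance(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        sensitivity_ci=sens_ci,
        specificity_ci=spec_ci,
        ppv_ci=ppv_ci,
        npv_ci=npv_ci,
        prevalence=counts.prevalence,
        n_diseased=counts.n_diseased,
        n_healthy=counts.n_healthy,
        threshold=threshold,
        counts=counts,
    )


def bayes_predictive_values(
    sensitivity: float, specificity: float, prevalence: float
) -> tuple[float, float]:
    """Prevalence-standardised PPV and NPV from the Bayes identities.

    With the cohort's own prevalence and unrounded sensitivity/specificity
    these equal the count ratios exactly; fed two-decimal table values, they
    give the nomogram-style predictive values clinical accuracy tables often
    print instead of the raw ratios.
    """
    pos = sensitivity * prevalence
    ppv = pos / (pos + (1.0 - specificity) * (1.0 - prevalence))
    neg = specificity * (1.0 - prevalence)
    npv = neg / (neg + (1.0 - sensitivity) * prevalence)
    return ppv, npv


def threshold_sweep(
    records: pd.DataFrame,
    marker: Marker,
    thresholds: Sequence[float],
    *,
    inclusive: bool = True,
    ci_method: Literal["wilson", "clopper_pearson"] = "wilson",
    level: float = 0.95,
) -> list[TestPerformance]:
    """One TestPerformance per cutoff, cutoffs strictly increasing."""
    thresholds = [float(t) for t in thresholds]
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    return [
        performance(
            confusion_at_threshold(records, marker, t, inclusive=inclusive),
            ci_method=ci_method,
            level=level,
            threshold=t,
        )
        for t in thresholds
    ]


def operating_points(sweep: Sequence[TestPerformance]) -> list[OperatingPoint]:
    """ROC vertices from a sweep (requires both classes present)."""
    points = []
    for perf in sweep:
        if perf.sensitivity is None or perf.specificity is None:
            raise ValueError("operating point needs both classes present")
        points.append(
            OperatingPoint(
                threshold=perf.threshold if perf.threshold is not None else np.nan,
                fpr=1.0 - perf.specificity,
                tpr=perf.sensitivity,
            )
        )
    return points


def roc_auc(points: Sequence[OperatingPoint], *, anchored: bool = True) -> float:
    """Trapezoidal area under the empirical ROC polygon.

    Points are sorted by fpr (ties by tpr ascending); with ``anchored`` the
    chance endpoints (0,0) and (1,1) are appended before integration.
    """
    if len(points) == 0:
        raise ValueError("at least one operating point required")
    fpr = [p.fpr for p in points]
    tpr = [p.tpr for p in points]
    if anchored:
        fpr += [0.0, 1.0]
        tpr += [0.0, 1.0]
    order = np.lexsort((tpr, fpr))
    x = np.asarray(fpr)[order]
    y = np.asarray(tpr)[order]
    return float(np.trapezoid(y, x))


def _fmt(perf_value, ci) -> str:
    if perf_value is None:
        return "NA"
    s = f"{round_display(perf_value):.2f}"
    if ci is not None:
        s += f" ({round_display(ci[0]):.2f}, {round_display(ci[1]):.2f})"
    return s


def sweep_table(sweep: Sequence[TestPerformance]) -> pd.DataFrame:
    """Machine-readable sweep: one row per cutoff, metrics and CI bounds."""
    rows = []
    for perf in sweep:
        c = perf.counts
        row = {"cutoff": perf.threshold, "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            short = {"sensitivity": "sens", "specificity": "spec"}.get(name, name)
            value = getattr(perf, name)
            ci = getattr(perf, f"{name}_ci")
            row[short] = value
            row[f"{short}_lo"], row[f"{short}_hi"] = ci if ci else (None, None)
        rows.append(row)
    return pd.DataFrame(rows)
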