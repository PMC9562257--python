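"""Seeded synthetic surveillance cohorts with quantile-calibrated biomarkers.

The study population this emulates is a colorectal polyp-surveillance cohort
in which each patient carries a binary "high-risk finding" status (>=2
premalignant polyps including >=1 advanced, or >=5 premalignant polyps), a
quantitative faecal immunochemical test (FIT) result in ug Hb / g faeces, and
a urinary volatile-organic-compound (VOC) classifier score in [0, 1].

No per-subject data are distributed with the study, but its accuracy tables
pin down several exceedance probabilities P(marker >= threshold | class).
This module fits minimal two-parameter class-conditional models to those
anchors — a log-normal for FIT (right-skewed, non-negative) and a Beta for
the VOC score (bounded) — and draws reproducible cohorts from them, so that
every downstream stage of the pipeline is testable end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._utils import check_probability

__all__ = [
    "CalibrationError",
    "CalibrationTargets",
    "LogNormalModel",
    "BetaModel",
    "GeneratorSpec",
    "DEFAULT_TARGETS",
    "calibrate_fit_model",
    "calibrate_voc_model",
    "default_generator_spec",
    "generate_cohort",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
]

#: canonical cohort CSV columns
COHORT_COLUMNS = ["subject_id", "diseased", "fit_ug_g", "voc_score"]


class CalibrationError(ValueError):
    """A pair of (threshold, exceedance) anchors is infeasible or unsolvable."""


Anchors = Sequence[tuple[float, float]]


@dataclass(frozen=True)
class CalibrationTargets:
    """Operating-point anchors the synthetic cohort is calibrated to.

    Each anchor list holds ``(threshold, P(marker >= threshold))`` pairs for
    one class; exceedance must be non-increasing in threshold.
    """

    prevalence: float
    fit_exceedance_diseased: Anchors
    fit_exceedance_healthy: Anchors
    voc_exceedance_diseased: Anchors
    voc_exceedance_healthy: Anchors

    def __post_init__(self) -> None:
        check_probability(self.prevalence, "prevalence")
        for name in (
            "fit_exceedance_diseased",
            "fit_exceedance_healthy",
            "voc_exceedance_diseased",
            "voc_exceedance_healthy",
        ):
            _check_anchor_ordering(getattr(self, name), name)


def _check_anchor_ordering(anchors: Anchors, name: str) -> None:
    last_t, last_p = -np.inf, np.inf
    for t, p in anchors:
        check_probability(p, f"{name} exceedance at {t}")
        if t <= last_t:
            raise CalibrationError(f"{name}: thresholds must be strictly increasing")
        if p > last_p:
            raise CalibrationError(
                f"{name}: exceedance increases with threshold at {t} — infeasible"
            )
        last_t, last_p = t, p


# Anchors read off the study's printed accuracy tables: FIT confusion counts
# (68 diseased / 187 healthy) and VOC sensitivity/specificity rows. Counts
# are preferred over rounded rates where both are printed.
DEFAULT_TARGETS = CalibrationTargets(
    prevalence=0.26,
    fit_exceedance_diseased=((10.0, 37 / 68), (80.0, 17 / 68)),
    fit_exceedance_healthy=((3.0, 64 / 187), (10.0, 39 / 187)),
    voc_exceedance_diseased=((0.88, 0.94), (0.94, 0.66)),
    voc_exceedance_healthy=((0.81, 0.46), (0.88, 0.31)),
)


@dataclass(frozen=True)
class LogNormalModel:
    """log X ~ Normal(mu, sigma); X is a non-negative marker concentration."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise CalibrationError(f"sigma must be positive; got {self.sigma}")

    def sf(self, x):
        return stats.lognorm.sf(x, s=self.sigma, scale=np.exp(self.mu))

    def ppf(self, q):
        return stats.lognorm.ppf(q, s=self.sigma, scale=np.exp(self.mu))


@dataclass(frozen=True)
class BetaModel:
    """Marker score on [0, 1] ~ Beta(a, b)."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise CalibrationError(f"Beta shapes must be positive; got {self.a}, {self.b}")

    def sf(self, x):
        return stats.beta.sf(x, self.a, self.b)

    def ppf(self, q):
        return stats.beta.ppf(q, self.a, self.b)


def calibrate_fit_model(anchors: Anchors) -> LogNormalModel:
    """Fit a log-normal to two FIT exceedance anchors, in closed form.

    With z_i the standard-normal quantile of (1 - p_i), the anchor equations
    P(X >= t_i) = p_i become ln t_i = mu + sigma * z_i — two linear equations
    in (mu, sigma).
    """
    anchors = tuple(anchors)
    if len(anchors) != 2:
        raise CalibrationError("exactly two (threshold, exceedance) anchors required")
    _check_anchor_ordering(anchors, "fit anchors")
    (t1, p1), (t2, p2) = anchors
    if min(t1, t2) <= 0:
        raise CalibrationError("FIT thresholds must be positive")
    for p in (p1, p2):
        check_probability(p, "exceedance", open_interval=True)
    z1, z2 = stats.norm.ppf(1 - p1), stats.norm.ppf(1 - p2)
    if z2 <= z1:
        raise CalibrationError(
            f"anchors ({t1}, {p1}) and ({t2}, {p2}) are infeasible for a log-normal"
        )
    sigma = (np.log(t2) - np.log(t1)) / (z2 - z1)
    mu = np.log(t1) - sigma * z1
    model = LogNormalModel(mu=float(mu), sigma=float(sigma))
    resid = max(abs(model.sf(t1) - p1), abs(model.sf(t2) - p2))
    if resid >= 1e-8:
        raise CalibrationError(f"calibration residual {resid:.2e} exceeds 1e-8")
    return model


def calibrate_voc_model(anchors: Anchors, *, tol: float = 1e-6) -> BetaModel:
    """Fit a Beta(a, b) to two VOC-score exceedance anchors numerically.

    Solves the two survival-function equations for (log a, log b) with a
    damped Newton-type root finder, trying several starting points.
    """
    anchors = tuple(sorted(anchors))
    if len(anchors) != 2:
        raise CalibrationError("exactly two (threshold, exceedance) anchors required")
    _check_anchor_ordering(anchors, "voc anchors")
    (t1, p1), (t2, p2) = anchors
    for t in (t1, t2):
        if not 0 < t < 1:
            raise CalibrationError("VOC thresholds must lie in (0, 1)")
    for p in (p1, p2):
        check_probability(p, "exceedance", open_interval=True)

    def equations(log_shapes):
        a, b = np.exp(log_shapes)
        return [stats.beta.sf(t1, a, b) - p1, stats.beta.sf(t2, a, b) - p2]

    starts = [(0.7, 0.7), (0.0, 0.0), (1.5, 0.0), (0.0, 1.5), (2.3, 2.3), (-1.0, -1.0)]
    for start in starts:
        sol = optimize.root(equations, start, method="hybr")
        if not sol.success:
            continue
        a, b = np.exp(sol.x)
        model = BetaModel(a=float(a), b=float(b))
        resid = max(abs(model.sf(t1) - p1), abs(model.sf(t2) - p2))
        if resid < tol:
            return model
    raise CalibrationError(
        f"no Beta(a, b) found matching anchors ({t1}, {p1}) and ({t2}, {p2})"
    )


@dataclass(frozen=True)
class GeneratorSpec:
    """Everything needed to draw a cohort reproducibly.

    ``copula_rho`` is an optional Gaussian-copula correlation between the two
    markers given disease status (default 0: conditional independence, the
    assumption the serial-testing arithmetic itself makes). ``fixed_counts``
    forces exactly round(n * prevalence) diseased subjects, for table
    reproduction; otherwise status is i.i.d. Bernoulli.
    """

    n_subjects: int
    seed: int
    fit_model_diseased: LogNormalModel
    fit_model_healthy: LogNormalModel
    voc_model_diseased: BetaModel
    voc_model_healthy: BetaModel
    copula_rho: float = 0.0
    fixed_counts: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not -1.0 < self.copula_rho < 1.0:
            raise ValueError("copula_rho must lie in (-1, 1)")


def default_generator_spec(
    n_subjects: int = 255,
    seed: int = 0,
    targets: CalibrationTargets = DEFAULT_TARGETS,
    **overrides,
) -> GeneratorSpec:
    """Calibrate all four marker models to ``targets`` and bundle them.

    The default cohort size (255) and prevalence anchors match the study
    population the generator emulates.
    """
    spec = GeneratorSpec(
        n_subjects=n_subjects,
        seed=seed,
        fit_model_diseased=calibrate_fit_model(targets.fit_exceedance_diseased),
        fit_model_healthy=calibrate_fit_model(targets.fit_exceedance_healthy),
        voc_model_diseased=calibrate_voc_model(targets.voc_exceedance_diseased),
        voc_model_healthy=calibrate_voc_model(targets.voc_exceedance_healthy),
    )
    return replace(spec, **overrides) if overrides else spec


def generate_cohort(spec: GeneratorSpec, prevalence: float) -> pd.DataFrame:
    """Draw a cohort; a pure function of (spec, prevalence).

    Returns a DataFrame with columns ``subject_id, diseased, fit_ug_g,
    voc_score`` sorted by subject_id. Disease status, then the two
    class-conditional marker streams, are derived from independent child
    streams of the single seed, so the draw is bit-reproducible.
    """
    check_probability(prevalence, "prevalence")
    n = spec.n_subjects
    ss = np.random.SeedSequence(spec.seed)
    status_rng, diseased_rng, healthy_rng = (
        np.random.default_rng(child) for child in ss.spawn(3)
    )

    if spec.fixed_counts:
        n_dis = int(np.floor(n * prevalence + 0.5))
        status = np.zeros(n, dtype=np.int64)
        status[status_rng.permutation(n)[:n_dis]] = 1
    else:
        status = (status_rng.random(n) < prevalence).astype(np.int64)

    fit = np.empty(n)
    voc = np.empty(n)
    for flag, rng, fit_model, voc_model in (
        (1, diseased_rng, spec.fit_model_diseased, spec.voc_model_diseased),
        (0, healthy_rng, spec.fit_model_healthy, spec.voc_model_healthy),
    ):
        mask = status == flag
        m = int(mask.sum())
        if m == 0:
            continue
        z = rng.standard_normal((m, 2))
        z2 = spec.copula_rho * z[:, 0] + np.sqrt(1 - spec.copula_rho**2) * z[:, 1]
        fit[mask] = fit_model.ppf(stats.norm.cdf(z[:, 0]))
        voc[mask] = np.clip(voc_model.ppf(stats.norm.cdf(z2)), 0.0, 1.0)

    width = len(str(n))
    ids = [f"S{i + 1:0{width}d}" for i in range(n)]
    df = pd.DataFrame(
        {"subject_id": ids, "diseased": status, "fit_ug_g": fit, "voc_score": voc}
    )
    return df.sort_values("subject_id", ignore_index=True)


def validate_cohort(records: pd.DataFrame) -> pd.DataFrame:
    """Check the cohort invariants; returns the frame for chaining."""
    missing = [c for c in COHORT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"cohort is missing columns: {missing}")
    if len(records) == 0:
        raise ValueError("cohort is empty")
    if not records["diseased"].isin([0, 1]).all():
        raise ValueError("diseased must be 0/1")
    if (records["fit_ug_g"] < 0).any():
        raise ValueError("fit_ug_g must be non-negative")
    if ((records["voc_score"] < 0) | (records["voc_score"] > 1)).any():
        raise ValueError("voc_score must lie in [0, 1]")
    return records


def write_cohort(records: pd.DataFrame, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    """Write the cohort CSV (deterministic row order by subject_id)."""
    records = validate_cohort(records).sort_values("subject_id")
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        records.to_csv(fh, index=False, columns=COHORT_COLUMNS)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    return validate_cohort(df)
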