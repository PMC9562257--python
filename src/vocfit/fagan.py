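"""Likelihood-ratio calculus for single and combined diagnostic tests.

This is the computational content of Fagan's nomogram: a test with
sensitivity *sens* and specificity *spec* multiplies the patient's pre-test
odds by LR+ = sens / (1 - spec) after a positive result, or by
LR- = (1 - sens) / spec after a negative one; converting odds back to a
probability gives the post-test probability. Serial testing chains these
updates along the all-negative path (each test is only given to patients the
previous test called negative — the rule-out triage use case). Parallel
testing treats the pair as one composite test that is negative only when
both components are.

All propagation is in full precision; whole-percent figures are display-only
(``as_percent``, half away from zero). A ``display_rounded_propagation`` flag
on :func:`serial_chain` mimics reading intermediate probabilities off a
printed nomogram to whole percents before the next update.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from ._utils import as_percent, check_probability

__all__ = [
    "TestSpec",
    "LikelihoodRatios",
    "FaganUpdate",
    "SerialChainResult",
    "likelihood_ratios",
    "fagan_update",
    "serial_chain",
    "parallel_combine",
]


@dataclass(frozen=True)
class TestSpec:
    """Assumed performance of a binary diagnostic test (decoupled from data)."""

    name: str
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        check_probability(self.sensitivity, f"{self.name} sensitivity")
        check_probability(self.specificity, f"{self.name} specificity")


@dataclass(frozen=True)
class LikelihoodRatios:
    lr_positive: float
    lr_negative: float


@dataclass(frozen=True)
class FaganUpdate:
    """Pre- and post-test probabilities for one test, both result branches."""

    test: TestSpec
    pre_test_prob: float
    post_test_prob_positive: float
    post_test_prob_negative: float

    @property
    def probability_reduction(self) -> float:
        """How much a negative result lowers the disease probability."""
        return self.pre_test_prob - self.post_test_prob_negative


@dataclass(frozen=True)
class SerialChainResult:
    """All-negative serial path: each update's pre is the previous post-negative."""

    updates: tuple[FaganUpdate, ...]

    @property
    def pre_test_prob(self) -> float:
        return self.updates[0].pre_test_prob

    @property
    def final_post_negative(self) -> float:
        return self.updates[-1].post_test_prob_negative

    @property
    def total_probability_reduction(self) -> float:
        return self.pre_test_prob - self.final_post_negative


def likelihood_ratios(test: TestSpec) -> LikelihoodRatios:
    """LR+ = sens/(1-spec), LR- = (1-sens)/spec; requires spec in (0, 1)."""
    sens, spec = test.sensitivity, test.specificity
    if spec >= 1.0:
        raise ValueError(
            f"{test.name}: specificity 1 makes LR+ infinite; likelihood ratios undefined"
        )
    if spec <= 0.0:
        raise ValueError(
            f"{test.name}: specificity 0 makes LR- undefined (division by zero)"
        )
    if not 0.0 < sens < 1.0:
        raise ValueError(
            f"{test.name}: sensitivity must be in (0, 1) for finite nonzero likelihood ratios"
        )
    return LikelihoodRatios(lr_positive=sens / (1 - spec), lr_negative=(1 - sens) / spec)


def _odds(p: float) -> float:
    return p / (1 - p)


def _prob(odds: float) -> float:
    return odds / (1 + odds)


def fagan_update(pre_test_prob: float, test: TestSpec) -> FaganUpdate:
    """Post-test probabilities via the exact odds update post = pre_odds * LR.

    pre = 0 and pre = 1 are fixed points of the update and are returned
    unchanged (no evidence moves a certainty).
    """
    pre = check_probability(pre_test_prob, "pre_test_prob")
    if pre in (0.0, 1.0):
        return FaganUpdate(test, pre, pre, pre)
    lrs = likelihood_ratios(test)
    pre_odds = _odds(pre)
    return FaganUpdate(
        test=test,
        pre_test_prob=pre,
        post_test_prob_positive=_prob(pre_odds * lrs.lr_positive),
        post_test_prob_negative=_prob(pre_odds * lrs.lr_negative),
    )


def serial_chain(
    pre_test_prob: float,
    tests: Sequence[TestSpec],
    *,
    display_rounded_propagation: bool = False,
) -> SerialChainResult:
    """Chain updates along the all-negative path (rule-out triage).

    Test i+1 is applied only to patients test i called negative, so its
    pre-test probability is update i's post-test-negative probability.
    """
    if len(tests) == 0:
        raise ValueError("serial chain needs at least one test")
    updates = []
    pre = check_probability(pre_test_prob, "pre_test_prob")
    for test in tests:
        update = fagan_update(pre, test)
        updates.append(update)
        pre = update.post_test_prob_negative
        if display_rounded_propagation:
            pre = as_percent(pre) / 100.0
    return SerialChainResult(updates=tuple(updates))


def parallel_combine(
    first: TestSpec,
    second: TestSpec,
    *,
    mode: Literal["independence", "supplied"] = "independence",
    supplied: tuple[float, float] | None = None,
    name: str | None = None,
) -> TestSpec:
    """Composite test that is negative only when both components are.

    ``independence`` derives sens = 1 - (1-s1)(1-s2) and spec = c1*c2 under
    class-conditional independence. ``supplied`` passes through an externally
    measured (sensitivity, specificity) pair — the route for empirical
    combined-test figures that no independence assumption reproduces.
    """
    label = name or f"{first.name}+{second.name} parallel"
    if mode == "independence":
        sens = 1.0 - (1.0 - first.sensitivity) * (1.0 - second.sensitivity)
        spec = first.specificity * second.specificity
        return TestSpec(label, sens, spec)
    if mode == "supplied":
        if supplied is None:
            raise ValueError("mode='supplied' requires a (sensitivity, specificity) pair")
        return TestSpec(label, *supplied)
    raise ValueError(f"mode must be 'independence' or 'supplied'; got {mode!r}")
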