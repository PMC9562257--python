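"""Per-1000-patient accounting of testing strategies.

For a cohort of n surveillance patients with high-risk-finding prevalence pi,
each strategy is an expected-frequency decision tree: how many patients test
positive (and therefore go to colonoscopy, treated as a perfect gold
standard), how many high-risk findings those colonoscopies detect, how many
are missed among test-negatives, and the number needed to scope (NNS) —
colonoscopies performed per finding detected.

Rounding protocol: every reported cell is rounded half-away-from-zero to an
integer, and in the serial strategy the ROUNDED count of diseased patients
among first-stage negatives is what the second stage operates on. The exact
(unrounded) tree is retained on every row for analysis, where
detected + missed = n * pi holds identically.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._utils import check_probability, round_half_away
from .fagan import TestSpec

__all__ = [
    "CohortFlowRow",
    "SerialFlowResult",
    "flow_single_stage",
    "flow_serial",
    "flow_colonoscopy_all",
]


@dataclass(frozen=True)
class CohortFlowRow:
    """One strategy's per-cohort accounting (integer cells; exact tree kept)."""

    strategy: str
    n_cohort: int
    test_positives: int
    test_negatives: int
    detected_in_positives: int
    missed_in_negatives: int
    colonoscopies: int
    number_needed_to_scope: int | None
    unrounded: dict[str, float]

    @property
    def nns_exact(self) -> float | None:
        det = self.unrounded.get("detected")
        if det:
            return self.unrounded["colonoscopies"] / det
        return None


@dataclass(frozen=True)
class SerialFlowResult:
    stage1: CohortFlowRow
    stage2: CohortFlowRow | None
    summary: CohortFlowRow


def _single_stage_tree(n: float, n_diseased: float, test: TestSpec) -> dict[str, float]:
    n_healthy = n - n_diseased
    detected = n_diseased * test.sensitivity
    false_pos = n_healthy * (1.0 - test.specificity)
    positives = detected + false_pos
    return {
        "n": n,
        "diseased": n_diseased,
        "positives": positives,
        "negatives": n - positives,
        "detected": detected,
        "missed": n_diseased - detected,
        "colonoscopies": positives,
    }


def _round_row(strategy: str, tree: dict[str, float]) -> CohortFlowRow:
    positives = round_half_away(tree["positives"])
    n = round_half_away(tree["n"])
    detected = round_half_away(tree["detected"])
    colonoscopies = round_half_away(tree["colonoscopies"])
    nns = round_half_away(colonoscopies / detected) if detected > 0 else None
    return CohortFlowRow(
        strategy=strategy,
        n_cohort=n,
        test_positives=positives,
        test_negatives=n - positives,
        detected_in_positives=detected,
        missed_in_negatives=round_half_away(tree["missed"]),
        colonoscopies=colonoscopies,
        number_needed_to_scope=nns,
        unrounded=tree,
    )


def flow_single_stage(n: int, prevalence: float, test: TestSpec) -> CohortFlowRow:
    """Accounting for 'everyone gets this one test; positives get scoped'."""
    if n < 1:
        raise ValueError("n must be >= 1")
    check_probability(prevalence, "prevalence")
    tree = _single_stage_tree(float(n), n * prevalence, test)
    return _round_row(test.name, tree)


def flow_serial(
    n: int, prevalence: float, first: TestSpec, second: TestSpec
) -> SerialFlowResult:
    """Two-stage serial strategy: second test only for first-test negatives.

    Stage 2 operates on stage 1's rounded negative count, with its diseased
    subset equal to stage 1's rounded missed count; total colonoscopies are
    the positives of both stages.
    """
    stage1 = flow_single_stage(n, prevalence, first)

    if stage1.test_negatives == 0:
        import warnings

        warnings.warn("first stage left no negatives; second stage skipped")
        stage2 = None
        total_col = stage1.colonoscopies
        total_det = stage1.detected_in_positives
        missed = 0
        negatives = 0
    else:
        tree2 = _single_stage_tree(
            float(stage1.test_negatives), float(stage1.missed_in_negatives), second
        )
        stage2 = _round_row(second.name, tree2)
        total_col = stage1.colonoscopies + stage2.colonoscopies
        total_det = stage1.detected_in_positives + stage2.detected_in_positives
        missed = stage2.missed_in_negatives
        negatives = stage2.test_negatives

    exact1 = stage1.unrounded
    exact2 = stage2.unrounded if stage2 else None
    summary_unrounded = {
        "n": float(n),
        "diseased": n * prevalence,
        "positives": exact1["positives"] + (exact2["positives"] if exact2 else 0.0),
        "negatives": exact2["negatives"] if exact2 else 0.0,
        "detected": exact1["detected"] + (exact2["detected"] if exact2 else 0.0),
        "missed": exact2["missed"] if exact2 else 0.0,
        "colonoscopies": exact1["colonoscopies"] + (exact2["colonoscopies"] if exact2 else 0.0),
    }
    summary = CohortFlowRow(
        strategy=f"{first.name} then {second.name} (serial)",
        n_cohort=n,
        test_positives=total_col,
        test_negatives=negatives,
        detected_in_positives=total_det,
        missed_in_negatives=missed,
        colonoscopies=total_col,
        number_needed_to_scope=round_half_away(total_col / total_det) if total_det else None,
        unrounded=summary_unrounded,
    )
    return SerialFlowResult(stage1=stage1, stage2=stage2, summary=summary)


def flow_colonoscopy_all(n: int, prevalence: float) -> CohortFlowRow:
    """Current practice: every patient is scoped; detection is perfect."""
    if n < 1:
        raise ValueError("n must be >= 1")
    check_probability(prevalence, "prevalence")
    if prevalence == 0:
        raise ValueError("NNS undefined at zero prevalence (nothing to detect)")
    detected = round_half_away(n * prevalence)
    return CohortFlowRow(
        strategy="colonoscopy for all (current practice)",
        n_cohort=n,
        test_positives=n,
        test_negatives=0,
        detected_in_positives=detected,
        missed_in_negatives=0,
        colonoscopies=n,
        number_needed_to_scope=round_half_away(n / detected),
        unrounded={
            "n": float(n),
            "diseased": n * prevalence,
            "positives": float(n),
            "negatives": 0.0,
            "detected": n * prevalence,
            "missed": 0.0,
            "colonoscopies": float(n),
        },
    )
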