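"""Confusion counts, accuracy metrics, threshold sweeps and trapezoidal AUC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vocfit import (
    ConfusionCounts,
    OperatingPoint,
    bayes_predictive_values,
    confusion_at_threshold,
    operating_points,
    performance,
    roc_auc,
    threshold_sweep,
)
from vocfit.diagnostics import UndefinedMetricWarning, sweep_table
from vocfit.reference import (
    FIT_CUTOFFS,
    FIT_TRUE_NEGATIVES,
    FIT_TRUE_POSITIVES,
    N_HEALTHY,
    PREVALENCE,
)
from vocfit._utils import round_display


def _toy(values, statuses):
    return pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(len(values))],
            "diseased": statuses,
            "fit_ug_g": values,
            "voc_score": [0.5] * len(values),
        }
    )


def test_confusion_perfectly_separated_toy():
    counts = confusion_at_threshold(_toy([2, 5, 12, 30], [0, 0, 1, 1]), "fit", 10)
    assert (counts.tp, counts.tn, counts.fp, counts.fn) == (2, 2, 0, 0)


def test_confusion_threshold_below_everything_makes_all_positive():
    counts = confusion_at_threshold(_toy([2, 5, 12, 30], [0, 0, 1, 1]), "fit", 0)
    assert counts.fn == 0 and counts.tn == 0
    assert counts.tp + counts.fp == 4


def test_confusion_inclusive_versus_strict_rule():
    records = _toy([10.0, 10.0], [1, 0])
    inc = confusion_at_threshold(records, "fit", 10.0, inclusive=True)
    strict = confusion_at_threshold(records, "fit", 10.0, inclusive=False)
    assert (inc.tp, inc.fp) == (1, 1)
    assert (strict.tp, strict.fp) == (0, 0)


def test_confusion_matches_brute_force_tally(small_cohort):
    for threshold in (5.0, 10.0, 80.0):
        counts = confusion_at_threshold(small_cohort, "fit", threshold)
        tp = fp = fn = tn = 0  # oracle: direct loop over subjects
        for _, row in small_cohort.iterrows():
            pos = row["fit_ug_g"] >= threshold
            if row["diseased"] == 1:
                tp, fn = tp + pos, fn + (not pos)
            else:
                fp, tn = fp + pos, tn + (not pos)
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (tp, fp, fn, tn)


def test_empty_cohort_rejected():
    with pytest.raises(ValueError):
        confusion_at_threshold(_toy([], []), "fit", 1.0)


def test_headline_cutoff_metrics_from_published_counts():
    """At the 10 ug/g cutoff: sens 0.54, spec 0.79, and table-style PPV 0.47."""
    perf = performance(ConfusionCounts(tp=37, fn=31, tn=148, fp=39))
    assert round_display(perf.sensitivity) == 0.54
    assert round_display(perf.specificity) == 0.79
    assert perf.ppv == pytest.approx(37 / 76)
    ppv, npv = bayes_predictive_values(
        round_display(perf.sensitivity), round_display(perf.specificity), PREVALENCE
    )
    assert round_display(ppv) == 0.47
    assert round_display(npv) == 0.83


def test_specificity_at_lower_quantitation_cutoff():
    perf = performance(ConfusionCounts(tp=37, fn=31, tn=140, fp=47))
    assert round_display(perf.specificity) == 0.75


def test_degenerate_classifier_metrics():
    perf = performance(ConfusionCounts(tp=0, fn=10, tn=10, fp=0))
    assert perf.sensitivity == 0.0
    assert perf.specificity == 1.0


def test_zero_denominator_metric_is_none_with_warning():
    with pytest.warns(UndefinedMetricWarning):
        perf = performance(ConfusionCounts(tp=0, fn=10, tn=10, fp=0))
    assert perf.ppv is None and perf.ppv_ci is None
    assert perf.npv == 0.5


def test_ci_methods_bracket_the_point_estimate():
    for method in ("wilson", "clopper_pearson"):
        perf = performance(ConfusionCounts(tp=37, fn=31, tn=148, fp=39), ci_method=method)
        for value, ci in [
            (perf.sensitivity, perf.sensitivity_ci),
            (perf.specificity, perf.specificity_ci),
        ]:
            assert ci[0] <= value <= ci[1]
            assert 0 <= ci[0] and ci[1] <= 1


@given(
    tp=st.integers(0, 200),
    fn=st.integers(0, 200),
    fp=st.integers(0, 200),
    tn=st.integers(0, 200),
)
def test_metrics_are_exact_count_ratios(tp, fn, fp, tn):
    """Integer cross-multiplication oracle: metric * denominator == numerator."""
    import warnings

    counts = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
    if counts.n_total == 0:
        return
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UndefinedMetricWarning)
        perf = performance(counts)
    for value, num, den in [
        (perf.sensitivity, tp, tp + fn),
        (perf.specificity, tn, tn + fp),
        (perf.ppv, tp, tp + fp),
        (perf.npv, tn, tn + fn),
    ]:
        if den == 0:
            assert value is None
        else:
            assert value * den == pytest.approx(num, abs=1e-9)


def test_bayes_consistency_with_empirical_prevalence(small_cohort):
    """PPV/NPV equal the Bayes formula at the cohort's own prevalence, exactly."""
    sweep = threshold_sweep(small_cohort, "fit", [3, 10, 80])
    for perf in sweep:
        ppv, npv = bayes_predictive_values(
            perf.sensitivity, perf.specificity, perf.prevalence
        )
        assert perf.ppv == pytest.approx(ppv, abs=1e-12)
        assert perf.npv == pytest.approx(npv, abs=1e-12)


def test_sweep_reconstructs_published_confusion_counts(table_cohort):
    """Per-threshold brute-force tallies reproduce every printed TP/TN pair."""
    sweep = threshold_sweep(table_cohort, "fit", FIT_CUTOFFS)
    values = table_cohort["fit_ug_g"].to_numpy()
    status = table_cohort["diseased"].to_numpy()
    for perf, want_tp, want_tn in zip(sweep, FIT_TRUE_POSITIVES, FIT_TRUE_NEGATIVES):
        # oracle: direct tally at this cutoff
        oracle_tp = int(((values >= perf.threshold) & (status == 1)).sum())
        assert perf.counts.tp == oracle_tp == want_tp
        assert perf.counts.tn == want_tn


def test_sweep_monotone_in_threshold(small_cohort):
    sweep = threshold_sweep(small_cohort, "fit", sorted({1, 3, 5, 10, 20, 50, 100}))
    sens = [p.sensitivity for p in sweep]
    spec = [p.specificity for p in sweep]
    assert all(b <= a for a, b in zip(sens, sens[1:]))
    assert all(b >= a for a, b in zip(spec, spec[1:]))


def test_sweep_singleton_equals_direct_performance(small_cohort):
    (swept,) = threshold_sweep(small_cohort, "fit", [10.0])
    direct = performance(confusion_at_threshold(small_cohort, "fit", 10.0), threshold=10.0)
    assert swept == direct


def test_sweep_requires_increasing_thresholds(small_cohort):
    with pytest.raises(ValueError):
        threshold_sweep(small_cohort, "fit", [10, 5])


def test_auc_of_chance_anchors_is_half():
    assert roc_auc([OperatingPoint(0.5, 0.5, 0.5)], anchored=True) == pytest.approx(0.5)
    assert roc_auc(
        [OperatingPoint(np.nan, 0.0, 0.0), OperatingPoint(np.nan, 1.0, 1.0)], anchored=False
    ) == pytest.approx(0.5)


def test_auc_of_perfect_classifier_point_is_one():
    assert roc_auc([OperatingPoint(1.0, 0.0, 1.0)], anchored=True) == pytest.approx(1.0)


def test_auc_invariant_under_point_permutation(table_cohort):
    points = operating_points(threshold_sweep(table_cohort, "fit", FIT_CUTOFFS))
    base = roc_auc(points, anchored=True)
    rng = np.random.default_rng(0)
    for _ in range(5):
        shuffled = [points[i] for i in rng.permutation(len(points))]
        assert roc_auc(shuffled, anchored=True) == base


def test_published_fit_auc_from_table_counts():
    """Operating points implied by the printed TP/TN counts integrate to 0.67."""
    points = [
        OperatingPoint(t, fpr=1 - tn / 187, tpr=tp / 68)
        for t, tp, tn in zip(FIT_CUTOFFS, FIT_TRUE_POSITIVES, FIT_TRUE_NEGATIVES)
    ]
    assert round_display(roc_auc(points, anchored=True)) == 0.67


def test_operating_point_outside_unit_square_rejected():
    with pytest.raises(ValueError):
        OperatingPoint(1.0, fpr=1.2, tpr=0.5)


def test_sweep_table_shape(table_cohort):
    frame = sweep_table(threshold_sweep(table_cohort, "fit", FIT_CUTOFFS))
    assert list(frame["cutoff"]) == list(FIT_CUTOFFS)
    assert {"tp", "tn", "sens", "sens_lo", "sens_hi", "spec", "ppv", "npv"} <= set(frame)
    assert list(frame["fp"]) == [N_HEALTHY - tn for tn in FIT_TRUE_NEGATIVES]
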