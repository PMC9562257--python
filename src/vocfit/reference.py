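"""Published operating characteristics of the study the pipeline reproduces.

The multi-centre polyp-surveillance study (n = 255; 68 with a high-risk
finding, 187 without; prevalence 0.26) printed, for FIT, the true-positive /
true-negative counts at eight cutoffs, and for the VOC score, sensitivity /
specificity at five thresholds. Those printed values are the *inputs* to the
desk-scale reproduction: the confusion counts pin the FIT analysis down
exactly, so a cohort whose marker values are placed at the implied ranks
reproduces every cell of the accuracy table by direct tallying.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import DEFAULT_TARGETS, calibrate_voc_model
from .fagan import TestSpec

__all__ = [
    "PREVALENCE",
    "N_STUDY",
    "N_DISEASED",
    "N_HEALTHY",
    "FIT_CUTOFFS",
    "FIT_TRUE_POSITIVES",
    "FIT_TRUE_NEGATIVES",
    "VOC_OPERATING_TABLE",
    "VOC_TEST",
    "FIT_TEST",
    "PARALLEL_TEST",
    "rank_matched_cohort",
]

PREVALENCE = 0.26
N_STUDY = 255
N_DISEASED = 68
N_HEALTHY = 187

#: FIT cutoffs (ug Hb / g faeces) with printed TP / TN counts
FIT_CUTOFFS = (3.0, 5.0, 7.0, 10.0, 20.0, 80.0, 100.0, 120.0)
FIT_TRUE_POSITIVES = (42, 38, 37, 37, 33, 17, 16, 14)
FIT_TRUE_NEGATIVES = (123, 136, 140, 148, 159, 170, 172, 172)

#: VOC score thresholds with printed (sensitivity, specificity)
VOC_OPERATING_TABLE = (
    (0.78, 0.99, 0.48),
    (0.81, 0.98, 0.54),
    (0.88, 0.94, 0.69),
    (0.94, 0.66, 0.76),
    (0.95, 0.43, 0.77),
)

#: headline single-test operating points (VOC at 0.88, FIT at 10 ug/g)
VOC_TEST = TestSpec("VOC", 0.94, 0.69)
FIT_TEST = TestSpec("FIT", 0.54, 0.79)
#: empirical parallel-combination performance (supplied, not an independence product)
PARALLEL_TEST = TestSpec("VOC+FIT parallel", 0.97, 0.11)


def _fill_values(n: int, exceed_counts: list[int], cutoffs: tuple[float, ...]) -> np.ndarray:
    """Place n marker values so that exactly exceed_counts[i] are >= cutoffs[i].

    Values inside each inter-cutoff bin sit at the bin's geometric interior;
    only their ranks relative to the cutoffs matter.
    """
    edges = [0.0, *cutoffs]
    # counts strictly below each cutoff boundary, bin occupancy from differences
    at_least = [n, *exceed_counts]
    values: list[float] = []
    for i in range(len(cutoffs)):
        lo, hi = edges[i], edges[i + 1]
        values.extend([lo + 0.25 * (hi - lo)] * (at_least[i] - at_least[i + 1]))
    values.extend([cutoffs[-1] + 30.0] * at_least[-1])
    out = np.array(values)
    assert len(out) == n
    return out


def rank_matched_cohort() -> pd.DataFrame:
    """A 255-subject cohort reproducing every printed FIT confusion count.

    FIT values are placed deterministically at the ranks the printed TP/TN
    counts imply, so an inclusive >=-threshold tally at the eight cutoffs
    returns the table exactly. VOC scores are deterministic class-conditional
    quantiles of the calibrated score model at mid-ranks (plotting positions),
    giving realistic — but not count-exact — score exceedances.
    """
    tp = list(FIT_TRUE_POSITIVES)
    fp = [N_HEALTHY - tn for tn in FIT_TRUE_NEGATIVES]
    fit_dis = _fill_values(N_DISEASED, tp, FIT_CUTOFFS)
    fit_hea = _fill_values(N_HEALTHY, fp, FIT_CUTOFFS)

    voc_dis_model = calibrate_voc_model(DEFAULT_TARGETS.voc_exceedance_diseased)
    voc_hea_model = calibrate_voc_model(DEFAULT_TARGETS.voc_exceedance_healthy)
    voc_dis = voc_dis_model.ppf((np.arange(N_DISEASED) + 0.5) / N_DISEASED)
    voc_hea = voc_hea_model.ppf((np.arange(N_HEALTHY) + 0.5) / N_HEALTHY)

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:03d}" for i in range(N_STUDY)],
            "diseased": [1] * N_DISEASED + [0] * N_HEALTHY,
            "fit_ug_g": np.concatenate([fit_dis, fit_hea]),
            "voc_score": np.concatenate([voc_dis, voc_hea]),
        }
    )
    return df.sort_values("subject_id", ignore_index=True)
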