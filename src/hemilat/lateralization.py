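"""Hemispheric asymmetry (lateralization) scores.

For a nonnegative network measure X evaluated in each hemisphere, the
asymmetry score is

    AS = 100 * (X(L) - X(R)) / (X(L) + X(R))

which is bounded in [-100, +100], scale-invariant, and antisymmetric under
hemisphere swap. Positive AS means leftward dominance of X. (For the path
length Lp a larger value means poorer integration, so a positive AS(Lp)
indicates a *rightward* integration advantage; no sign flip is applied —
interpretation is left to reporting.) When X is zero in both hemispheres the
score is undefined and recorded as NaN with ``defined=False``; downstream
statistics drop such records per outcome with a logged count.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping

import numpy as np
import pandas as pd

from .atlas import ROI_NAMES
from .errors import InputError
from .metrics import GLOBAL_METRICS, NetworkMetricSet

log = logging.getLogger(__name__)

ALL_METRICS = tuple(GLOBAL_METRICS) + tuple(ROI_NAMES)

AS_COLUMNS = ["subject_id", "metric", "x_left", "x_right", "AS", "defined"]


def asymmetry_score(x_left: float, x_right: float) -> float:
    """AS = 100 (L - R)/(L + R); NaN (undefined marker) when L + R = 0."""
    if x_left < 0 or x_right < 0:
        raise InputError(
            f"asymmetry score requires nonnegative values, got "
            f"({x_left}, {x_right})"
        )
    total = x_left + x_right
    if total == 0:
        return math.nan
    # ratio first, then scale, clamped: |L - R| <= L + R holds exactly in
    # real arithmetic and must survive rounding
    return float(np.clip(100.0 * ((x_left - x_right) / total), -100.0, 100.0))


def lateralize_cohort(
    left_metrics: Mapping[str, NetworkMetricSet],
    right_metrics: Mapping[str, NetworkMetricSet],
    roi_left: Mapping[str, Mapping[str, float]] | None = None,
    roi_right: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Asymmetry records for a cohort, one row per subject x metric.

    ``left_metrics`` / ``right_metrics`` map subject id to that hemisphere's
    :class:`NetworkMetricSet`; ``roi_left`` / ``roi_right`` optionally map
    subject id to the four fronto-limbic ROI betweenness values. Subjects
    must be present on both sides.
    """
    only_left = set(left_metrics) - set(right_metrics)
    only_right = set(right_metrics) - set(left_metrics)
    if only_left or only_right:
        raise InputError(
            "subjects present on one side only: "
            f"left-only={sorted(only_left)}, right-only={sorted(only_right)}"
        )
    with_roi = roi_left is not None and roi_right is not None
    rows = []
    n_undefined = 0
    for sid in left_metrics:
        pairs = [(m, left_metrics[sid].value(m), right_metrics[sid].value(m))
                 for m in GLOBAL_METRICS]
        if with_roi:
            pairs += [(r, roi_left[sid][r], roi_right[sid][r])
                      for r in ROI_NAMES]
        for metric, xl, xr in pairs:
            score = asymmetry_score(xl, xr)
            defined = not math.isnan(score)
            n_undefined += not defined
            rows.append(
                {"subject_id": sid, "metric": metric, "x_left": xl,
                 "x_right": xr, "AS": score, "defined": defined}
            )
    if n_undefined:
        log.info("lateralize_cohort: %d undefined asymmetry records", n_undefined)
    return pd.DataFrame(rows, columns=AS_COLUMNS)
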