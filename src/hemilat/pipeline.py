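"""End-to-end orchestration: connectomes -> hemispheric metrics ->
asymmetry scores -> adjusted group statistics."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import ROI_NAMES
from .connectome import Connectome, split_hemispheres
from .errors import InputError
from .lateralization import lateralize_cohort
from .metrics import GLOBAL_METRICS, compute_metrics, extract_roi_betweenness
from .simulate import SyntheticCohort
from .stats import (
    DEFAULT_COVARIATES,
    compare_lateralization,
    correlate_with_age,
    subgroup_compare,
)

log = logging.getLogger(__name__)

_STREAM_METRICS = 3  # seed stream id for per-subject metric randomness


@dataclass
class AnalysisResult:
    """Result bundle of one cohort analysis."""

    metrics_table: pd.DataFrame       # subject, hemisphere, metric, value
    node_betweenness: pd.DataFrame    # subject, hemisphere, label, value
    as_table: pd.DataFrame            # subject, metric, x_left, x_right, AS
    comparisons: pd.DataFrame         # adjusted group comparisons, FDR by family
    age_correlations: pd.DataFrame
    subgroup: pd.DataFrame | None = None
    notes: dict = field(default_factory=dict)


def _metric_seed(master_seed: int, subject_index: int, side_index: int) -> int:
    ss = np.random.SeedSequence(
        master_seed, spawn_key=(_STREAM_METRICS, subject_index, side_index)
    )
    return int(ss.generate_state(1)[0] % (2**31))


def subject_hemisphere_metrics(
    connectome: Connectome,
    atlas: pd.DataFrame,
    n_random: int,
    master_seed: int,
    subject_index: int,
    swap_factor: int = 10,
    orientation: str = "standard",
):
    """Split one connectome and compute both hemispheres' metric sets plus
    fronto-limbic ROI betweenness."""
    left_net, right_net = split_hemispheres(connectome, atlas)
    out = {}
    for side_index, net in enumerate((left_net, right_net)):
        mset = compute_metrics(
            net,
            n_random=n_random,
            seed=_metric_seed(master_seed, subject_index, side_index),
            swap_factor=swap_factor,
            orientation=orientation,
        )
        roi = extract_roi_betweenness(mset, atlas, net.side)
        out[net.side] = (mset, roi)
    return out


def analyze_cohort(
    cohort: SyntheticCohort,
    n_random: int = 100,
    seed: int = 0,
    swap_factor: int = 10,
    orientation: str = "standard",
    covariates=DEFAULT_COVARIATES,
    with_subgroup: bool = True,
) -> AnalysisResult:
    """Run the full analysis on an in-memory cohort.

    Computes per-hemisphere metrics for every subject, the asymmetry table,
    the covariate-adjusted preterm-vs-term comparisons (FDR within the
    global and fronto-limbic families), the age-at-MRI correlations, and —
    when both social-emotional subgroups are populated — the preterm
    subgroup comparison.
    """
    table = cohort.cohort_table
    if len(table) != len(cohort.connectomes):
        raise InputError(
            f"cohort table has {len(table)} rows but "
            f"{len(cohort.connectomes)} connectomes"
        )
    left_m, right_m, roi_l, roi_r = {}, {}, {}, {}
    metric_rows, node_rows = [], []
    for i, conn in enumerate(cohort.connectomes):
        sid = conn.subject_id
        per_side = subject_hemisphere_metrics(
            conn, cohort.atlas, n_random, seed, i,
            swap_factor=swap_factor, orientation=orientation,
        )
        left_m[sid], roi_l[sid] = per_side["left"]
        right_m[sid], roi_r[sid] = per_side["right"]
        for side, (mset, _roi) in per_side.items():
            for metric in GLOBAL_METRICS:
                metric_rows.append(
                    {"subject_id": sid, "hemisphere": side,
                     "metric": metric, "value": mset.value(metric)}
                )
            labels = mset.node_profiles["label"].to_numpy()
            bvals = mset.node_profiles["betweenness"].to_numpy()
            node_rows.extend(
                {"subject_id": sid, "hemisphere": side,
                 "label": int(lab), "value": float(v)}
                for lab, v in zip(labels, bvals)
            )
    as_table = lateralize_cohort(left_m, right_m, roi_l, roi_r)
    comparisons = compare_lateralization(
        as_table, table, covariates=covariates
    )
    correlations = correlate_with_age(as_table, table)
    subgroup = None
    notes = {}
    if with_subgroup:
        assessed = table[(table["group"] == "preterm")
                         & table["assessed_flag"].astype(bool)]
        n_abn = int(assessed["se_abnormal"].astype(bool).sum())
        n_norm = len(assessed) - n_abn
        if n_abn >= 2 and n_norm >= 2:
            subgroup = subgroup_compare(as_table, table)
        else:
            notes["subgroup_skipped"] = (
                f"subgroups too small (abnormal={n_abn}, normal={n_norm})"
            )
    n_undef = int((~as_table["defined"]).sum())
    if n_undef:
        notes["undefined_asymmetry_records"] = n_undef
    return AnalysisResult(
        metrics_table=pd.DataFrame(metric_rows),
        node_betweenness=pd.DataFrame(node_rows),
        as_table=as_table,
        comparisons=comparisons,
        age_correlations=correlations,
        subgroup=subgroup,
        notes=notes,
    )
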