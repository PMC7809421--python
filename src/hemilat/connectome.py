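"""Connectome construction from streamline summaries.

A streamline summary lists, per reconstructed fiber, its two endpoint labels
and the fractional-anisotropy (FA) values of the voxels it traverses. Edge
strength follows the two-stage average used in FA-weighted connectomics:
FA is first averaged over the voxels of each fiber, then averaged (unweighted)
over the fibers of a region pair, so long fibers get no extra weight. The
unweighted (binary) view declares an edge present when the pair is connected
by at least ``min_fibers`` streamlines; all graph metrics downstream operate
on binary intra-hemispheric networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import hemisphere_labels, validate_atlas
from .errors import InputError

log = logging.getLogger(__name__)

# type alias: one fiber = (endpoint_label_a, endpoint_label_b, voxel FA values)
Fiber = tuple[int, int, np.ndarray]


@dataclass
class StreamlineSet:
    """Per-subject streamline summary: endpoint labels + voxel FA samples."""

    subject_id: str
    fibers: list[Fiber] = field(default_factory=list)


@dataclass
class Connectome:
    """Symmetric region-by-region connectivity matrices for one subject.

    ``fa_weight`` holds tract-mean FA (0 where no fibers), ``fiber_count``
    the streamline counts, ``binary`` the unweighted view. ``labels`` gives
    the atlas label id of each row/column.
    """

    subject_id: str
    labels: list[int]
    fa_weight: np.ndarray
    fiber_count: np.ndarray
    binary: np.ndarray

    def index_of(self, label_id: int) -> int:
        index = getattr(self, "_label_index", None)
        if index is None:
            index = {lab: i for i, lab in enumerate(self.labels)}
            object.__setattr__(self, "_label_index", index)
        try:
            return index[label_id]
        except KeyError:
            raise InputError(
                f"label {label_id} not present in connectome "
                f"of subject {self.subject_id!r}"
            ) from None


@dataclass
class HemisphereNetwork:
    """Binary intra-hemispheric network: the graph G on node set N."""

    side: str
    node_labels: list[int]
    adjacency: np.ndarray  # symmetric 0/1, zero diagonal

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())


def fiber_mean_fa(voxel_fa_values) -> float:
    """Arithmetic mean FA over the voxels of one fiber."""
    values = np.asarray(voxel_fa_values, dtype=float)
    if values.size == 0:
        raise InputError("fiber has no voxel FA values")
    if np.any(values < 0) or np.any(values > 1):
        raise InputError("voxel FA values must lie in [0, 1]")
    return float(values.mean())


def tract_mean_fa(fibers) -> float:
    """Unweighted mean of per-fiber mean FA over the fibers of one tract.

    Fibers with many voxels do not get extra weight. An empty fiber list is
    an absent edge and returns NaN (the absent-edge marker), not an error.
    """
    fibers = list(fibers)
    if not fibers:
        return float("nan")
    return float(np.mean([fiber_mean_fa(f) for f in fibers]))


def build_matrix(streamlines: StreamlineSet, atlas: pd.DataFrame) -> Connectome:
    """Aggregate a streamline summary into symmetric count and FA matrices.

    Self-loops (both endpoints in the same label) are dropped with a logged
    count; unknown endpoint labels raise :class:`InputError` naming the label.
    """
    validate_atlas(atlas)
    labels = atlas["label_id"].tolist()
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    counts = np.zeros((n, n), dtype=int)
    # per-pair running sums of fiber means; tract FA is their unweighted mean
    fa_sums = np.zeros((n, n), dtype=float)
    n_self_loops = 0
    for a, b, voxels in streamlines.fibers:
        for lab in (a, b):
            if lab not in index:
                raise InputError(
                    f"streamline endpoint label {lab} not in atlas "
                    f"(subject {streamlines.subject_id!r})"
                )
        if a == b:
            n_self_loops += 1
            continue
        i, j = index[a], index[b]
        m = fiber_mean_fa(voxels)
        counts[i, j] += 1
        counts[j, i] += 1
        fa_sums[i, j] += m
        fa_sums[j, i] += m
    if n_self_loops:
        log.info(
            "subject %s: dropped %d self-loop fibers",
            streamlines.subject_id,
            n_self_loops,
        )
    with np.errstate(invalid="ignore"):
        fa = np.where(counts > 0, fa_sums / np.maximum(counts, 1), 0.0)
    binary = (counts >= 1).astype(np.uint8)
    return Connectome(
        subject_id=streamlines.subject_id,
        labels=labels,
        fa_weight=fa,
        fiber_count=counts,
        binary=binary,
    )


def binarize(connectome: Connectome, min_fibers: int = 1) -> Connectome:
    """Re-threshold the unweighted view: edge present iff
    ``fiber_count >= min_fibers``. Idempotent for a fixed threshold."""
    if min_fibers < 1:
        raise InputError(f"min_fibers must be >= 1, got {min_fibers}")
    binary = (connectome.fiber_count >= min_fibers).astype(np.uint8)
    return Connectome(
        subject_id=connectome.subject_id,
        labels=list(connectome.labels),
        fa_weight=connectome.fa_weight.copy(),
        fiber_count=connectome.fiber_count.copy(),
        binary=binary,
    )


def split_hemispheres(
    connectome: Connectome, atlas: pd.DataFrame
) -> tuple[HemisphereNetwork, HemisphereNetwork]:
    """Induced left and right intra-hemispheric binary networks.

    Midline labels and interhemispheric edges are excluded; their counts are
    logged. Hemispheric metrics are computed on these induced subgraphs.
    """
    validate_atlas(atlas)
    out = []
    n_total_edges = int(np.triu(connectome.binary, 1).sum())
    n_intra = 0
    for side in ("left", "right"):
        labs = hemisphere_labels(atlas, side)
        if len(labs) < 2:
            raise InputError(
                f"{side} hemisphere has {len(labs)} labels; need at least 2"
            )
        idx = [connectome.index_of(lab) for lab in labs]
        sub = connectome.binary[np.ix_(idx, idx)].astype(np.uint8)
        np.fill_diagonal(sub, 0)
        n_intra += int(np.triu(sub, 1).sum())
        out.append(HemisphereNetwork(side=side, node_labels=labs, adjacency=sub))
    n_midline = (atlas["hemisphere"] == "midline").sum()
    log.info(
        "subject %s: excluded %d interhemispheric edges and %d midline labels",
        connectome.subject_id,
        n_total_edges - n_intra,
        n_midline,
    )
    return out[0], out[1]
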