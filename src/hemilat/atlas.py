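"""Atlas-label tables.

An atlas table assigns every network node (parcellation label) a hemisphere,
a homotopic partner, and optionally a fronto-limbic region-of-interest flag.
The default table emulates the structure of a 64-label neonatal parcellation:
32 homotopic left/right pairs, four of which carry the fronto-limbic ROI flags
(medial fronto-orbital gyrus, superior temporal gyrus, amygdala, hippocampus).

The table is a plain :class:`pandas.DataFrame` with columns
``label_id, name, hemisphere, pair_id, roi_flag``; :func:`validate_atlas`
enforces the invariants.
"""

from __future__ import annotations

import pandas as pd

from .errors import InputError

ATLAS_COLUMNS = ["label_id", "name", "hemisphere", "pair_id", "roi_flag"]
HEMISPHERES = ("left", "right", "midline")
ROI_NAMES = ("mFOG", "STG", "amygdala", "hippocampus")
_SIDE_SUFFIX = {"left": "L", "right": "R"}


def default_atlas(nodes_per_hemisphere: int = 32) -> pd.DataFrame:
    """Build the synthetic default atlas: ``nodes_per_hemisphere`` homotopic
    pairs, no midline labels, ROI flags on the first four pairs.

    Left labels get ids ``1..n``, right labels ``n+1..2n``; homotopic pairs
    share a ``pair_id``.
    """
    if nodes_per_hemisphere < len(ROI_NAMES):
        raise InputError(
            f"need at least {len(ROI_NAMES)} nodes per hemisphere "
            f"to place the fronto-limbic ROIs, got {nodes_per_hemisphere}"
        )
    rows = []
    for side in ("left", "right"):
        offset = 0 if side == "left" else nodes_per_hemisphere
        for i in range(nodes_per_hemisphere):
            roi = ROI_NAMES[i] if i < len(ROI_NAMES) else "none"
            base = ROI_NAMES[i] if roi != "none" else f"ctx{i + 1:02d}"
            rows.append(
                {
                    "label_id": offset + i + 1,
                    "name": f"{base}_{_SIDE_SUFFIX[side]}",
                    "hemisphere": side,
                    "pair_id": f"P{i + 1:02d}",
                    "roi_flag": roi,
                }
            )
    atlas = pd.DataFrame(rows, columns=ATLAS_COLUMNS)
    validate_atlas(atlas)
    return atlas


def validate_atlas(atlas: pd.DataFrame) -> None:
    """Check the atlas-table invariants; raise :class:`InputError` on failure.

    Invariants: unique label ids; hemisphere in {left, right, midline}; every
    paired left label has exactly one right partner with the same pair_id;
    each ROI flag appears at most once per hemisphere and, when present,
    on both sides (the default 64-label table carries all four).

    A successfully validated table is marked in ``DataFrame.attrs`` so that
    repeated per-subject calls skip the re-check.
    """
    if atlas.attrs.get("_hemilat_validated"):
        return
    missing = set(ATLAS_COLUMNS) - set(atlas.columns)
    if missing:
        raise InputError(f"atlas table missing columns: {sorted(missing)}")
    if atlas["label_id"].duplicated().any():
        dupes = atlas.loc[atlas["label_id"].duplicated(), "label_id"].tolist()
        raise InputError(f"duplicate atlas label ids: {dupes}")
    bad_hemi = set(atlas["hemisphere"]) - set(HEMISPHERES)
    if bad_hemi:
        raise InputError(f"unknown hemisphere values: {sorted(bad_hemi)}")
    paired = atlas[atlas["pair_id"].notna() & (atlas["pair_id"] != "")]
    for pair_id, grp in paired.groupby("pair_id"):
        sides = sorted(grp["hemisphere"])
        if sides != ["left", "right"]:
            raise InputError(
                f"pair {pair_id!r} must have exactly one left and one right "
                f"label, found hemispheres {sides}"
            )
    for roi in ROI_NAMES:
        flagged = atlas[atlas["roi_flag"] == roi]
        n_left = (flagged["hemisphere"] == "left").sum()
        n_right = (flagged["hemisphere"] == "right").sum()
        if n_left > 1 or n_right > 1 or n_left != n_right:
            raise InputError(
                f"ROI flag {roi!r} must appear at most once per hemisphere "
                f"and on both sides or neither (found left={n_left}, "
                f"right={n_right})"
            )
    bad_roi = set(atlas["roi_flag"]) - set(ROI_NAMES) - {"none"}
    if bad_roi:
        raise InputError(f"unknown roi_flag values: {sorted(bad_roi)}")
    atlas.attrs["_hemilat_validated"] = True


def hemisphere_labels(atlas: pd.DataFrame, side: str) -> list[int]:
    """Label ids of one hemisphere, in atlas order."""
    if side not in HEMISPHERES:
        raise InputError(f"unknown hemisphere {side!r}")
    return atlas.loc[atlas["hemisphere"] == side, "label_id"].tolist()


def roi_label(atlas: pd.DataFrame, roi: str, side: str) -> int:
    """Label id of one fronto-limbic ROI in one hemisphere."""
    if roi not in ROI_NAMES:
        raise InputError(f"unknown ROI {roi!r}; expected one of {ROI_NAMES}")
    sel = atlas[(atlas["roi_flag"] == roi) & (atlas["hemisphere"] == side)]
    if len(sel) != 1:
        raise InputError(f"ROI {roi!r} not uniquely present in {side} hemisphere")
    return int(sel["label_id"].iloc[0])
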