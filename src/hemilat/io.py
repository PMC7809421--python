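"""Delimited-text readers and writers.

Everything is TSV (UTF-8, '.' decimal separator) with '#'-prefixed metadata
header lines, so files diff cleanly and round-trip bit-exactly. Every writer
stamps the run's config hash and master seed into the header when provided.

Schemas
-------
* atlas:       label_id, name, hemisphere, pair_id, roi_flag
* cohort:      the covariate table produced by :mod:`hemilat.simulate`
* matrix:      square table; first row and first column carry label ids
* streamlines: subject_id, label_a, label_b, voxel_fa (comma-joined floats)
* asymmetry:   subject_id, metric, x_left, x_right, AS, defined
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atlas import validate_atlas
from .connectome import Connectome, StreamlineSet
from .errors import InputError

COHORT_BOOL_COLUMNS = ("assessed_flag", "se_abnormal")


def config_hash(config) -> str:
    """Short stable hash of a configuration object."""
    if dataclasses.is_dataclass(config):
        config = dataclasses.asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def _header_lines(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def read_metadata(path) -> dict:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
    return meta


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])


def write_atlas(atlas: pd.DataFrame, path, meta: dict | None = None) -> None:
    validate_atlas(atlas)
    write_table(atlas, path, meta)


def read_atlas(path) -> pd.DataFrame:
    atlas = read_table(path)
    validate_atlas(atlas)
    return atlas


def write_cohort(table: pd.DataFrame, path, meta: dict | None = None) -> None:
    write_table(table, path, meta)


def read_cohort(path) -> pd.DataFrame:
    table = read_table(path)
    for col in COHORT_BOOL_COLUMNS:
        if col in table.columns:
            table[col] = table[col].astype(bool)
    return table


def write_matrix(matrix: np.ndarray, labels, path,
                 meta: dict | None = None, fmt: str = "%.6g") -> None:
    """Square matrix with a label-id header row and column."""
    matrix = np.asarray(matrix)
    n = len(labels)
    if matrix.shape != (n, n):
        raise InputError(
            f"matrix shape {matrix.shape} does not match {n} labels"
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_lines(meta))
        fh.write("label_id\t" + "\t".join(str(l) for l in labels) + "\n")
        for i, lab in enumerate(labels):
            row = "\t".join(fmt % v for v in matrix[i])
            fh.write(f"{lab}\t{row}\n")


def read_matrix(path, atlas: pd.DataFrame | None = None,
                atol: float = 1e-8) -> tuple[np.ndarray, list[int]]:
    """Read a square matrix; validate symmetry and (optionally) that its
    labels match the atlas."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    labels = [int(c) for c in df.columns]
    row_labels = [int(r) for r in df.index]
    if labels != row_labels:
        raise InputError(
            f"{path}: row labels differ from column labels"
        )
    matrix = df.to_numpy(dtype=float)
    if not np.allclose(matrix, matrix.T, atol=atol):
        i, j = np.unravel_index(
            np.argmax(np.abs(matrix - matrix.T)), matrix.shape
        )
        raise InputError(
            f"{path}: matrix is asymmetric at labels "
            f"({labels[i]}, {labels[j]})"
        )
    if atlas is not None:
        expected = atlas["label_id"].tolist()
        if labels != expected:
            extra = sorted(set(labels) - set(expected))
            missing = sorted(set(expected) - set(labels))
            raise InputError(
                f"{path}: labels do not match atlas "
                f"(unexpected {extra}, missing {missing})"
            )
    return matrix, labels


def write_connectome(conn: Connectome, out_dir, meta: dict | None = None) -> None:
    """Per-subject matrices as ``{subject_id}_{view}.tsv``."""
    out_dir = Path(out_dir)
    views = {
        "count": (conn.fiber_count, "%d"),
        "fa": (conn.fa_weight, "%.6g"),
        "binary": (conn.binary, "%d"),
    }
    for view, (mat, fmt) in views.items():
        write_matrix(mat, conn.labels, out_dir / f"{conn.subject_id}_{view}.tsv",
                     meta=meta, fmt=fmt)


def read_connectome(subject_id: str, matrices_dir,
                    atlas: pd.DataFrame) -> Connectome:
    """Rebuild a connectome from its per-view matrix files; the binary view
    is derived from counts if absent."""
    matrices_dir = Path(matrices_dir)
    count_path = matrices_dir / f"{subject_id}_count.tsv"
    if not count_path.exists():
        raise InputError(
            f"subject {subject_id!r}: missing matrix file {count_path.name}"
        )
    counts, labels = read_matrix(count_path, atlas)
    fa_path = matrices_dir / f"{subject_id}_fa.tsv"
    fa = (read_matrix(fa_path, atlas)[0] if fa_path.exists()
          else np.zeros_like(counts))
    bin_path = matrices_dir / f"{subject_id}_binary.tsv"
    binary = (read_matrix(bin_path, atlas)[0].astype(np.uint8)
              if bin_path.exists() else (counts >= 1).astype(np.uint8))
    return Connectome(
        subject_id=subject_id,
        labels=labels,
        fa_weight=fa,
        fiber_count=counts.astype(int),
        binary=binary,
    )


def write_streamlines(streamlines: StreamlineSet, path,
                      meta: dict | None = None) -> None:
    rows = [
        {"subject_id": streamlines.subject_id, "label_a": a, "label_b": b,
         "voxel_fa": ",".join(f"{v:.6g}" for v in np.asarray(fa))}
        for a, b, fa in streamlines.fibers
    ]
    write_table(pd.DataFrame(rows, columns=["subject_id", "label_a",
                                            "label_b", "voxel_fa"]),
                path, meta)


def read_streamlines(path) -> list[StreamlineSet]:
    df = read_table(path)
    out = []
    for sid, grp in df.groupby("subject_id", sort=False):
        fibers = [
            (int(r["label_a"]), int(r["label_b"]),
             np.array([float(v) for v in str(r["voxel_fa"]).split(",")]))
            for _, r in grp.iterrows()
        ]
        out.append(StreamlineSet(subject_id=str(sid), fibers=fibers))
    return out


def write_run_config(config: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def read_run_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)
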