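"""Readers, writers and the run manifest.

All CSV output uses '.' decimals, comma separators, UTF-8 and LF endings
with a fixed column order, so two runs with the same configuration and
seed produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._fcs import read_fcs
from .preprocess import CellMatrix
from .recursion import BranchHierarchy, TreeTopConfig
from .scoring import BRANCH_POINT_LABEL, BranchingResult

__all__ = ["read_matrix", "write_results", "write_manifest"]

_FLOAT_FMT = "%.10g"


def read_matrix(
    path: str | Path,
    format: Optional[str] = None,
    channels: Optional[Sequence[str]] = None,
    label_column: Optional[str] = None,
    id_column: Optional[str] = None,
) -> CellMatrix:
    """Load a cells x species matrix from FCS, CSV or TSV.

    ``channels`` restricts (and orders) the species columns — cytometry
    panels usually analyse a marker subset. For delimited files the header
    row supplies species names and each subsequent row is one cell; cell
    identifiers default to 0-based row indices unless ``id_column`` is
    given.
    """
    path = Path(path)
    if format is None:
        format = {".fcs": "fcs", ".csv": "csv", ".tsv": "tsv", ".txt": "tsv"}.get(
            path.suffix.lower(), "csv"
        )
    if format == "fcs":
        values, names = read_fcs(path)
        df = pd.DataFrame(values, columns=names)
        labels = None
        ids = None
    else:
        sep = "," if format == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep)
        except Exception as exc:
            raise ValueError(f"{path}: cannot parse as {format}: {exc}") from exc
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValueError(f"{path}: no data rows found")
        labels = None
        if label_column is not None:
            if label_column not in df.columns:
                raise ValueError(f"{path}: label column {label_column!r} not found")
            labels = df.pop(label_column).to_numpy()
        ids = None
        if id_column is not None:
            if id_column not in df.columns:
                raise ValueError(f"{path}: id column {id_column!r} not found")
            ids = df.pop(id_column).tolist()
    if channels is not None:
        missing = [c for c in channels if c not in df.columns]
        if missing:
            raise ValueError(
                f"{path}: channels {missing} not found; available: {list(df.columns)}"
            )
        df = df[list(channels)]
    if df.isna().any().any():
        raise ValueError(f"{path}: matrix contains missing values")
    return CellMatrix(
        values=df.to_numpy(dtype=float),
        species_names=[str(c) for c in df.columns],
        cell_ids=ids if ids is not None else list(range(len(df))),
        labels=labels,
    )


def _branch_label_str(label: int) -> str:
    return "branch_point" if label == BRANCH_POINT_LABEL else str(int(label))


def _write_result_files(result: BranchingResult, matrix_ids: list, outdir: Path) -> list[Path]:
    files = []
    b_ref = result.b_ref
    scores = pd.DataFrame(
        {
            "node": np.arange(len(result.raw_scores)),
            "raw_score": result.raw_scores,
            "relative_score": (
                result.raw_scores / b_ref if b_ref else np.full(len(result.raw_scores), np.nan)
            ),
        }
    )
    p = outdir / "scores.csv"
    scores.to_csv(p, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    files.append(p)
    branches = pd.DataFrame(
        {
            "cell_id": [matrix_ids[i] for i in result.retained_indices],
            "branch_label": [_branch_label_str(b) for b in result.cell_branches],
        }
    )
    p = outdir / "branches.csv"
    branches.to_csv(p, index=False, lineterminator="\n")
    files.append(p)
    summary = {
        "branch_node": int(result.branch_node),
        "best_pcut": float(result.best_pcut),
        "b_max": float(result.b_max),
        "b_ref": None if b_ref is None else float(b_ref),
        "relative_score": None
        if result.relative_score is None
        else float(result.relative_score),
        "n_branches": int(result.n_branches),
        "reference_params": result.reference_params,
    }
    p = outdir / "summary.json"
    p.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    files.append(p)
    return files


def _hierarchy_flat(h: BranchHierarchy, matrix_ids: list, prefix: str = "") -> list[tuple]:
    rows = []
    res = h.result
    for i, row in enumerate(res.retained_indices):
        label = res.cell_branches[i]
        rows.append((matrix_ids[row], prefix + _branch_label_str(label)))
    return rows


def write_results(
    result: Union[BranchingResult, BranchHierarchy],
    outdir: str | Path,
    matrix: Optional[CellMatrix] = None,
    config: Optional[TreeTopConfig] = None,
) -> dict[str, str]:
    """Write scores, branch assignments, hierarchy JSON and a manifest.

    Returns the file registry (name -> sha256) also stored in the
    manifest. Overwrites idempotently.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = matrix.cell_ids if matrix is not None else None
    files: list[Path] = []
    if isinstance(result, BranchHierarchy):
        root = result.result
        if ids is None:
            ids = list(range(int(root.retained_indices.max()) + 1))
        files += _write_result_files(root, ids, outdir)
        p = outdir / "hierarchy.json"
        p.write_text(json.dumps(result.to_dict(), indent=2, sort_keys=True) + "\n")
        files.append(p)
        # per-cell path through the hierarchy
        paths = {cid: lab for cid, lab in _hierarchy_flat(result, ids)}
        stack = [(result, "")]
        while stack:
            node, prefix = stack.pop()
            for label, child in sorted(node.children.items()):
                child_prefix = f"{prefix}{label}/"
                for cid, lab in _hierarchy_flat(child, ids, prefix=child_prefix):
                    paths[cid] = lab
                stack.append((child, child_prefix))
        flat = pd.DataFrame(
            {"cell_id": list(paths.keys()), "branch_path": list(paths.values())}
        )
        p = outdir / "hierarchy_flat.csv"
        flat.to_csv(p, index=False, lineterminator="\n")
        files.append(p)
    else:
        if ids is None:
            ids = list(range(int(result.retained_indices.max()) + 1))
        files += _write_result_files(result, ids, outdir)
    registry = write_manifest(outdir, files, config=config)
    return registry


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(
    outdir: Path, files: list[Path], config: Optional[TreeTopConfig] = None
) -> dict[str, str]:
    """Store the config snapshot, seed and output checksums next to the outputs."""
    registry = {f.name: _sha256(f) for f in files}
    snapshot = None
    if config is not None:
        snapshot = asdict(config)
        snapshot["thresholds"] = [float(t) for t in snapshot["thresholds"]]
        if not isinstance(snapshot.get("reference_table"), (str, type(None))):
            snapshot["reference_table"] = "<in-memory table>"
    manifest = {
        "config": snapshot,
        "outputs": registry,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return registry
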