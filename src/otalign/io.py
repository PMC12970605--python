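"""Reading and writing matrices, labels, and run artifacts.

Input matrices are cells x features after loading, regardless of the
on-disk orientation (use ``transpose=True`` for features-as-rows files).
All floating-point text output uses 17 significant digits so that a
write -> read round trip is bit exact.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmread

from ._exceptions import ValidationError

__all__ = ["DataMatrix", "read_matrix", "read_labels", "write_results", "zscore"]

_FLOAT_FMT = "%.17g"

#: warn above this many cells: the method builds dense n x n kernels.
DENSE_CELL_WARN = 20_000


@dataclasses.dataclass
class DataMatrix:
    """One modality's cells x features matrix with optional annotations.

    Parameters
    ----------
    values
        Dense real matrix, cells as rows.
    cell_names, feature_names
        Optional axis names (lengths n and d).
    labels
        Optional per-cell categorical labels, length n.  Labels are never
        consumed by the alignment itself; they exist for semi-supervised
        hyperparameter selection and for evaluation.
    """

    values: np.ndarray
    cell_names: list[str] | None = None
    feature_names: list[str] | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError(f"expected a 2-D matrix, got ndim={self.values.ndim}")
        n, d = self.values.shape
        if n < 2 or d < 1:
            raise ValidationError(f"need at least 2 cells and 1 feature, got {n} x {d}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite entry at row {bad[0]}, column {bad[1]}"
            )
        if self.cell_names is not None and len(self.cell_names) != n:
            raise ValidationError("cell_names length does not match row count")
        if self.feature_names is not None and len(self.feature_names) != d:
            raise ValidationError("feature_names length does not match column count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != n:
                raise ValidationError(
                    f"labels have length {len(self.labels)}, expected {n}"
                )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def zscore(values: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Column-wise z-score normalization (constant columns map to zero)."""
    values = np.asarray(values, dtype=np.float64)
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    sd = np.where(sd < eps, 1.0, sd)
    return (values - mu) / sd


def _read_delimited(path: Path, sep: str, has_feature_names: bool, has_cell_names: bool) -> pd.DataFrame:
    try:
        return pd.read_csv(
            path,
            sep=sep,
            header=0 if has_feature_names else None,
            index_col=0 if has_cell_names else None,
            float_precision="round_trip",
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValidationError(f"could not parse {path}: {exc}") from exc


def read_matrix(
    path: str | Path,
    format: str | None = None,
    transpose: bool = False,
    has_feature_names: bool = False,
    has_cell_names: bool = False,
) -> DataMatrix:
    """Load a cells x features matrix from CSV, TSV, or MatrixMarket.

    ``format`` is inferred from the file suffix when omitted.  For MTX
    files, optional sidecar name files ``<stem>_rows.txt`` and
    ``<stem>_cols.txt`` are picked up automatically (one name per line).
    ``transpose`` flips the on-disk orientation so that the returned
    matrix always has cells as rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".txt": "tsv", ".mtx": "mtx"}.get(
            path.suffix.lower(), "csv"
        )
    if format not in {"csv", "tsv", "mtx"}:
        raise ValidationError(f"unknown format {format!r}")

    cell_names = feature_names = None
    if format == "mtx":
        try:
            raw = mmread(path)
        except Exception as exc:  # scipy raises bare ValueError on bad headers
            raise ValidationError(f"could not parse {path}: {exc}") from exc
        values = np.asarray(raw.todense() if hasattr(raw, "todense") else raw, dtype=np.float64)
        rows_file = path.with_name(path.stem + "_rows.txt")
        cols_file = path.with_name(path.stem + "_cols.txt")
        row_names = read_labels(rows_file).tolist() if rows_file.exists() else None
        col_names = read_labels(cols_file).tolist() if cols_file.exists() else None
        cell_names, feature_names = row_names, col_names
        if transpose:
            cell_names, feature_names = col_names, row_names
    else:
        frame = _read_delimited(
            path, "," if format == "csv" else "\t", has_feature_names, has_cell_names
        )
        values = frame.to_numpy(dtype=np.float64, na_value=np.nan)
        cell_names = [str(i) for i in frame.index] if has_cell_names else None
        feature_names = [str(c) for c in frame.columns] if has_feature_names else None
        if transpose:
            cell_names, feature_names = feature_names, cell_names
    if transpose:
        values = values.T
    if values.shape[0] > DENSE_CELL_WARN:
        warnings.warn(
            f"{values.shape[0]} cells: the method builds dense n x n kernel and "
            "transport matrices (O(n^2) memory); consider subsampling",
            stacklevel=2,
        )
    return DataMatrix(values, cell_names=cell_names, feature_names=feature_names)


def read_labels(path: str | Path) -> np.ndarray:
    """Read one label token per line; empty lines are ignored."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    labels = [ln for ln in lines if ln]
    if not labels:
        raise ValidationError(f"label file {path} contains no labels")
    return np.asarray(labels, dtype=object)


def _save_array(path: Path, arr: np.ndarray) -> dict:
    arr = np.atleast_2d(np.asarray(arr, dtype=np.float64))
    np.savetxt(path, arr, fmt=_FLOAT_FMT, delimiter=",")
    return {"file": path.name, "shape": list(arr.shape)}


def write_results(
    outdir: str | Path,
    embeddings_x: np.ndarray,
    embeddings_y: np.ndarray,
    plan: np.ndarray | None = None,
    importance_x: np.ndarray | None = None,
    importance_y: np.ndarray | None = None,
    config: Mapping | None = None,
    metrics: Mapping | None = None,
    coclusters: pd.DataFrame | None = None,
) -> dict:
    """Write the standard run layout and return (and save) a manifest.

    The layout is deterministic: ``embeddings_x.csv``, ``embeddings_y.csv``
    and optionally ``plan.csv``, ``importance_x.csv``, ``importance_y.csv``,
    ``coclusters.csv``, ``metrics.json``, ``config.yaml``, ``manifest.json``.
    """
    outdir = Path(outdir)
    if not outdir.parent.exists():
        raise IOError(f"parent directory of {outdir} does not exist")
    outdir.mkdir(exist_ok=True)
    manifest: dict = {"files": {}}
    manifest["files"]["embeddings_x.csv"] = _save_array(outdir / "embeddings_x.csv", embeddings_x)
    manifest["files"]["embeddings_y.csv"] = _save_array(outdir / "embeddings_y.csv", embeddings_y)
    if plan is not None:
        manifest["files"]["plan.csv"] = _save_array(outdir / "plan.csv", plan)
    if importance_x is not None:
        manifest["files"]["importance_x.csv"] = _save_array(outdir / "importance_x.csv", importance_x)
    if importance_y is not None:
        manifest["files"]["importance_y.csv"] = _save_array(outdir / "importance_y.csv", importance_y)
    if coclusters is not None:
        coclusters.to_csv(outdir / "coclusters.csv", index=False)
        manifest["files"]["coclusters.csv"] = {
            "file": "coclusters.csv",
            "shape": list(coclusters.shape),
        }
    if metrics is not None:
        (outdir / "metrics.json").write_text(json.dumps(dict(metrics), indent=2, sort_keys=True))
        manifest["files"]["metrics.json"] = {"file": "metrics.json"}
    if config is not None:
        (outdir / "config.yaml").write_text(yaml.safe_dump(dict(config), sort_keys=True))
        manifest["files"]["config.yaml"] = {"file": "config.yaml"}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def write_labels(path: str | Path, labels: Sequence) -> None:
    Path(path).write_text("\n".join(str(l) for l in labels) + "\n")
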