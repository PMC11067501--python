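"""Core data model and I/O for cells × markers ADT matrices.

An ADT (antibody-derived tag) matrix holds per-cell counts of DNA-barcoded
antibodies against surface proteins — the CITE-seq analogue of fluorophore
intensities. :class:`CellDataset` couples the matrix with per-cell metadata
(ground-truth label, sample and group identifiers) and a normalization tag
so downstream code can tell raw counts from transformed values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "CitegateError",
    "CitegateWarning",
    "NormalizationTag",
    "CellDataset",
    "load_dataset",
    "clr_normalize",
    "arcsinh_normalize",
    "write_table",
]

MISSING = "unlabelled"


class CitegateError(Exception):
    """Base class for data and configuration errors in this package."""


class CitegateWarning(UserWarning):
    """Base class for warnings emitted by this package."""


@dataclass(frozen=True)
class NormalizationTag:
    """Records which transform produced the values of a :class:`CellDataset`.

    method is one of ``raw``, ``clr`` (centred log-ratio across markers
    within each cell) or ``arcsinh``; parameters hold the pseudocount or
    cofactor used.
    """

    method: str = "raw"
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in {"raw", "clr", "arcsinh"}:
            raise CitegateError(f"unknown normalization method {self.method!r}")


@dataclass
class CellDataset:
    """Cells × markers ADT values plus per-cell annotations.

    Parameters
    ----------
    values
        Dense float matrix, one row per cell, one column per marker.
    marker_names, cell_ids
        Ordered, duplicate-free axis labels.
    truth_label, sample_id, group
        Optional per-cell annotations; missing entries are the sentinel
        ``"unlabelled"`` (exposed as :data:`MISSING`).
    normalization
        Tag describing the transform applied to ``values``.
    """

    values: np.ndarray
    marker_names: list[str]
    cell_ids: list[str]
    truth_label: Optional[np.ndarray] = None
    sample_id: Optional[np.ndarray] = None
    group: Optional[np.ndarray] = None
    normalization: NormalizationTag = field(default_factory=NormalizationTag)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise CitegateError("values must be a 2-D cells × markers matrix")
        n, m = self.values.shape
        self.marker_names = [str(x) for x in self.marker_names]
        self.cell_ids = [str(x) for x in self.cell_ids]
        if len(self.cell_ids) != n:
            raise CitegateError(
                f"{len(self.cell_ids)} cell ids for {n} matrix rows"
            )
        if len(self.marker_names) != m:
            raise CitegateError(
                f"{len(self.marker_names)} marker names for {m} matrix columns"
            )
        if len(set(self.cell_ids)) != n:
            raise CitegateError("duplicate cell ids")
        if len(set(self.marker_names)) != m:
            raise CitegateError("duplicate marker names")
        if not np.all(np.isfinite(self.values)):
            raise CitegateError("matrix contains non-finite values")
        if self.normalization.method == "raw" and np.any(self.values < 0):
            raise CitegateError("raw counts must be non-negative")
        for name in ("truth_label", "sample_id", "group"):
            col = getattr(self, name)
            if col is not None:
                col = np.asarray(col, dtype=object)
                if col.shape != (n,):
                    raise CitegateError(f"{name} must have one entry per cell")
                col = np.where(pd.isna(col), MISSING, col).astype(object)
                setattr(self, name, col)

    # -- convenience -------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def is_raw(self) -> bool:
        return self.normalization.method == "raw"

    def marker_index(self, marker: str) -> int:
        try:
            return self.marker_names.index(marker)
        except ValueError:
            raise CitegateError(
                f"marker {marker!r} not in dataset (has: {self.marker_names})"
            ) from None

    def marker_values(self, marker: str) -> np.ndarray:
        return self.values[:, self.marker_index(marker)]

    def labelled_mask(self) -> np.ndarray:
        """Boolean mask of cells carrying a real (non-missing) truth label."""
        if self.truth_label is None:
            return np.zeros(self.n_cells, dtype=bool)
        return self.truth_label != MISSING

    def subset(self, mask: np.ndarray) -> "CellDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CellDataset(
            values=self.values[idx],
            marker_names=list(self.marker_names),
            cell_ids=[self.cell_ids[i] for i in idx],
            truth_label=None if self.truth_label is None else self.truth_label[idx],
            sample_id=None if self.sample_id is None else self.sample_id[idx],
            group=None if self.group is None else self.group[idx],
            normalization=self.normalization,
        )

    def with_values(self, values: np.ndarray, tag: NormalizationTag) -> "CellDataset":
        return CellDataset(
            values=values,
            marker_names=list(self.marker_names),
            cell_ids=list(self.cell_ids),
            truth_label=self.truth_label,
            sample_id=self.sample_id,
            group=self.group,
            normalization=tag,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.marker_names)

    def metadata_frame(self) -> pd.DataFrame:
        cols = {"cell_id": self.cell_ids}
        for name in ("truth_label", "sample_id", "group"):
            col = getattr(self, name)
            if col is not None:
                cols[name] = col
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# loading


def _read_lines(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _find_sidecar(directory: Path, names: Sequence[str]) -> Path:
    for name in names:
        p = directory / name
        if p.exists():
            return p
    raise CitegateError(
        f"no sidecar file among {list(names)} found next to the MTX matrix in {directory}"
    )


def _load_mtx(matrix_path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    directory = matrix_path.parent
    features_path = _find_sidecar(directory, ("features.tsv", "genes.tsv", "markers.tsv"))
    barcodes_path = _find_sidecar(directory, ("barcodes.tsv", "cells.tsv"))
    features = _read_lines(features_path)
    barcodes = _read_lines(barcodes_path)
    try:
        mat = scipy.io.mmread(matrix_path)
    except Exception as exc:  # malformed header / out-of-range 1-based indices
        raise CitegateError(f"invalid Matrix Market file {matrix_path}: {exc}") from exc
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    nr, nc = mat.shape
    # Orientation: features may be rows (CellRanger convention) or columns.
    if nr == len(features) and nc == len(barcodes):
        values = mat.T
    elif nr == len(barcodes) and nc == len(features):
        values = mat
    else:
        raise CitegateError(
            f"matrix shape {mat.shape} matches neither |features|={len(features)} "
            f"× |barcodes|={len(barcodes)} nor its transpose"
        )
    return values, features, barcodes


def _load_dense(matrix_path: Path, sep: str) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(matrix_path, sep=sep, index_col=0)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.any().any():
        i, j = np.argwhere(bad.values)[0]
        raise CitegateError(
            f"non-numeric matrix entry {df.iat[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    if numeric.isna().any().any():
        i, j = np.argwhere(numeric.isna().values)[0]
        raise CitegateError(
            f"missing matrix entry at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return numeric.values.astype(float), list(df.columns), [str(x) for x in df.index]


def load_dataset(
    matrix_path,
    metadata_path=None,
    format: Optional[str] = None,
) -> CellDataset:
    """Load an ADT matrix (MTX triplet or dense CSV/TSV) with optional metadata.

    MTX input expects ``features.tsv`` and ``barcodes.tsv`` sidecars in the
    same directory; orientation is auto-detected from the sidecar lengths.
    Dense input has cells as rows, a header of marker names and cell ids in
    the first column. Metadata is a TSV with a ``cell_id`` column and any of
    ``truth_label``, ``sample_id``, ``group``; matrix cells absent from the
    metadata keep missing labels, metadata rows absent from the matrix are
    dropped with a warning. The matrix cell order is preserved.
    """
    matrix_path = Path(matrix_path)
    if not matrix_path.exists():
        raise FileNotFoundError(f"matrix file not found: {matrix_path}")
    if format is None:
        format = matrix_path.suffix.lstrip(".").lower() or "csv"
    if format == "mtx":
        values, markers, cells = _load_mtx(matrix_path)
    elif format in {"csv", "tsv"}:
        values, markers, cells = _load_dense(
            matrix_path, "," if format == "csv" else "\t"
        )
    else:
        raise CitegateError(f"unknown matrix format {format!r}")
    if len(set(cells)) != len(cells):
        raise CitegateError("duplicate cell ids in matrix")

    truth = sample = group = None
    if metadata_path is not None:
        metadata_path = Path(metadata_path)
        if not metadata_path.exists():
            raise FileNotFoundError(f"metadata file not found: {metadata_path}")
        meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
        if "cell_id" not in meta.columns:
            raise CitegateError("metadata must have a cell_id column")
        if meta["cell_id"].duplicated().any():
            raise CitegateError("duplicate cell ids in metadata")
        known = set(cells)
        missing = ~meta["cell_id"].isin(known)
        if missing.any():
            warnings.warn(
                f"{int(missing.sum())} metadata rows reference cells absent from "
                "the matrix; dropped",
                CitegateWarning,
                stacklevel=2,
            )
            meta = meta.loc[~missing]
        meta = meta.set_index("cell_id").reindex(cells)
        truth = meta["truth_label"].to_numpy(object) if "truth_label" in meta else None
        sample = meta["sample_id"].to_numpy(object) if "sample_id" in meta else None
        group = meta["group"].to_numpy(object) if "group" in meta else None

    return CellDataset(
        values=values,
        marker_names=markers,
        cell_ids=cells,
        truth_label=truth,
        sample_id=sample,
        group=group,
    )


# ---------------------------------------------------------------------------
# normalization


def clr_normalize(dataset: CellDataset, pseudocount: float = 1.0) -> CellDataset:
    """Centred log-ratio transform across markers within each cell.

    out[i, m] = ln((x[i, m] + pseudocount) / g_i) with g_i the geometric mean
    of (x[i, ·] + pseudocount) over markers of cell i. Per-cell CLR values
    therefore sum to zero, which downstream code may rely on.
    """
    if not dataset.is_raw:
        raise CitegateError(
            f"clr_normalize expects raw counts, got {dataset.normalization.method!r}"
        )
    if pseudocount <= 0:
        raise CitegateError("pseudocount must be positive")
    logged = np.log(dataset.values + pseudocount)
    out = logged - logged.mean(axis=1, keepdims=True)
    return dataset.with_values(
        out, NormalizationTag("clr", {"pseudocount": pseudocount})
    )


def arcsinh_normalize(dataset: CellDataset, cofactor: float = 5.0) -> CellDataset:
    """Inverse-hyperbolic-sine transform arcsinh(x / cofactor), per entry."""
    if not dataset.is_raw:
        raise CitegateError(
            f"arcsinh_normalize expects raw counts, got {dataset.normalization.method!r}"
        )
    if cofactor <= 0:
        raise CitegateError("cofactor must be positive")
    return dataset.with_values(
        np.arcsinh(dataset.values / cofactor),
        NormalizationTag("arcsinh", {"cofactor": cofactor}),
    )


# ---------------------------------------------------------------------------
# table output


def write_table(table: pd.DataFrame, path, format: str = "tsv") -> None:
    """Write a labelled table as TSV/CSV with a deterministic layout.

    Floats are written with 6 significant digits; a header row is always
    present; the index is written when it carries labels.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(table)
    if table.empty:
        raise CitegateError("refusing to write an empty table")
    if format not in {"tsv", "csv"}:
        raise CitegateError(f"unknown table format {format!r}")
    sep = "\t" if format == "tsv" else ","
    write_index = table.index.name is not None or not isinstance(
        table.index, pd.RangeIndex
    )
    table.to_csv(path, sep=sep, float_format="%.6g", index=write_index)
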