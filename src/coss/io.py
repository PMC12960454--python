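"""Readers and writers for spatial feature matrices and score tables.

Supported matrix dialects: wide tables (features x wells), long
(feature, well, value) tables, MatrixMarket sparse triplets with companion
feature/barcode/position files, and Visium-style directories whose
tissue-positions file carries array indices directly. All text readers are
gzip-transparent (pandas compression inference).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import DataError, UsageError
from .lattice import WellLattice, align_to_lattice, lattice_from_axial

logger = logging.getLogger(__name__)

FORMATS = ("wide_table", "long_table", "triplet_matrix", "visium_dir")

VISIUM_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


@dataclass
class SampleData:
    """One sample: a lattice plus a features x wells nonnegative matrix."""

    lattice: WellLattice
    matrix: np.ndarray
    feature_ids: np.ndarray
    normalization: str = "raw"

    def __post_init__(self):
        if sp.issparse(self.matrix):
            self.matrix = np.asarray(self.matrix.todense(), dtype=float)
        else:
            self.matrix = np.asarray(self.matrix, dtype=float)
        self.feature_ids = np.asarray(self.feature_ids)
        if self.matrix.shape != (len(self.feature_ids), self.lattice.n_wells):
            raise DataError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.feature_ids)} features x {self.lattice.n_wells} wells"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise DataError("matrix contains non-finite values")
        if np.any(self.matrix < 0):
            raise DataError("matrix contains negative values")
        if len(set(map(str, self.feature_ids))) != len(self.feature_ids):
            raise DataError("duplicate feature ids")


def _check_duplicates(ids, what: str) -> None:
    counts = pd.Series(list(map(str, ids))).value_counts()
    dups = counts[counts > 1].index.tolist()
    if dups:
        raise DataError(f"duplicate {what}: {dups[:5]}")


def read_positions(path, lattice_type: Optional[str] = None) -> WellLattice:
    """Read a (well_id, x, y) table (header optional) and align it."""
    df = _read_table_flex(path, min_cols=3)
    well_ids = df.iloc[:, 0].astype(str).to_numpy()
    coords = df.iloc[:, 1:3].astype(float).to_numpy()
    _check_duplicates(well_ids, "well ids")
    return align_to_lattice(coords, well_ids=well_ids, lattice_type=lattice_type)


def read_visium_positions(path) -> WellLattice:
    """Visium tissue-positions dialect: in_tissue==0 rows are dropped and
    array_row/array_col are used directly as hexagonal lattice indices
    (column parity encodes the row offset), bypassing geometric alignment.
    """
    df = pd.read_csv(path)
    if not set(VISIUM_COLUMNS[:4]).issubset(df.columns):
        # headerless legacy dialect
        df = pd.read_csv(path, header=None)
        df.columns = VISIUM_COLUMNS[: len(df.columns)]
    df = df[df["in_tissue"].astype(int) == 1].reset_index(drop=True)
    if len(df) < 3:
        raise DataError("fewer than 3 in-tissue wells")
    row = df["array_row"].astype(int).to_numpy()
    col = df["array_col"].astype(int).to_numpy()
    if np.any((row + col) % 2 != 0):
        raise DataError("array_row/array_col parity violates the Visium hex dialect")
    axial = np.column_stack([(col - row) // 2, row])
    return lattice_from_axial(
        axial, "hexagonal", spacing=1.0, well_ids=df["barcode"].astype(str).to_numpy()
    )


def _read_table_flex(path, min_cols: int) -> pd.DataFrame:
    sep = "\t" if str(path).replace(".gz", "").endswith((".tsv", ".txt")) else ","
    head = pd.read_csv(path, sep=sep, header=None, nrows=1)
    has_header = any(
        isinstance(v, str) and not _floatable(v) for v in head.iloc[0, 1:]
    )
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
    if df.shape[1] < min_cols:
        raise DataError(f"{path}: expected >= {min_cols} columns, got {df.shape[1]}")
    return df


def _floatable(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def read_wide_matrix(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Wide table: first column feature ids, remaining columns one per well."""
    sep = "\t" if str(path).replace(".gz", "").endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    feats = df.index.astype(str).to_numpy()
    _check_duplicates(feats, "feature ids")
    return df.to_numpy(dtype=float), feats, df.columns.astype(str).to_numpy()


def read_long_matrix(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Long table with columns (feature, well, value); absent pairs are 0."""
    df = _read_table_flex(path, min_cols=3)
    df.columns = list(df.columns[:3]) + list(df.columns[3:])
    f = df.iloc[:, 0].astype(str)
    w = df.iloc[:, 1].astype(str)
    v = df.iloc[:, 2].astype(float)
    feats = pd.unique(f)
    wells = pd.unique(w)
    if df.iloc[:, :2].duplicated().any():
        raise DataError("duplicate (feature, well) pairs in long table")
    X = np.zeros((len(feats), len(wells)))
    X[
        pd.Categorical(f, categories=feats).codes,
        pd.Categorical(w, categories=wells).codes,
    ] = v.to_numpy()
    return X, feats.astype(str), wells.astype(str)


def read_sample(
    matrix_path=None,
    positions_path=None,
    format: str = "wide_table",
    features_path=None,
    barcodes_path=None,
    lattice_type: Optional[str] = None,
) -> SampleData:
    """Assemble a :class:`SampleData` from files in one of the supported
    dialects. Wells listed in the positions file but missing from the matrix
    get zero counts; matrix wells missing positions raise an error naming
    the barcode.
    """
    if format not in FORMATS:
        raise UsageError(f"format must be one of {FORMATS}, got {format!r}")

    if format == "visium_dir":
        d = Path(matrix_path)
        lattice = read_visium_positions(_first_existing(
            d, ["tissue_positions.csv", "tissue_positions_list.csv"]
        ))
        mat = scipy.io.mmread(_first_existing(d, ["matrix.mtx", "matrix.mtx.gz"]))
        feats = pd.read_csv(
            _first_existing(d, ["features.tsv", "features.tsv.gz", "genes.tsv"]),
            sep="\t", header=None,
        ).iloc[:, 0].astype(str).to_numpy()
        wells = pd.read_csv(
            _first_existing(d, ["barcodes.tsv", "barcodes.tsv.gz"]),
            sep="\t", header=None,
        ).iloc[:, 0].astype(str).to_numpy()
        X = np.asarray(sp.csr_matrix(mat).todense(), dtype=float)
        return _assemble(X, feats, wells, lattice)

    if format == "triplet_matrix":
        lattice = (
            read_visium_positions(positions_path)
            if _looks_visium(positions_path)
            else read_positions(positions_path, lattice_type)
        )
        mat = scipy.io.mmread(matrix_path)
        feats = pd.read_csv(features_path, sep="\t", header=None).iloc[:, 0].astype(str).to_numpy()
        wells = pd.read_csv(barcodes_path, sep="\t", header=None).iloc[:, 0].astype(str).to_numpy()
        X = np.asarray(sp.csr_matrix(mat).todense(), dtype=float)
        if X.shape != (len(feats), len(wells)):
            raise DataError(
                f"matrix shape {X.shape} does not match features/barcodes files"
            )
        return _assemble(X, feats, wells, lattice)

    if format == "wide_table":
        X, feats, wells = read_wide_matrix(matrix_path)
    else:
        X, feats, wells = read_long_matrix(matrix_path)
    lattice = read_positions(positions_path, lattice_type)
    return _assemble(X, feats, wells, lattice)


def _looks_visium(path) -> bool:
    try:
        head = pd.read_csv(path, nrows=1)
    except Exception:
        return False
    return {"in_tissue", "array_row", "array_col"}.issubset(head.columns)


def _first_existing(d: Path, names) -> Path:
    for name in names:
        p = d / name
        if p.exists():
            return p
    raise DataError(f"none of {names} found in {d}")


def _assemble(X, feats, wells, lattice: WellLattice) -> SampleData:
    _check_duplicates(feats, "feature ids")
    pos_ids = list(map(str, lattice.well_ids))
    col = {w: i for i, w in enumerate(map(str, wells))}
    unknown = [w for w in col if w not in set(pos_ids)]
    if unknown:
        raise DataError(f"matrix wells missing positions: {unknown[:5]}")
    out = np.zeros((len(feats), lattice.n_wells))
    for j, w in enumerate(pos_ids):
        if w in col:
            out[:, j] = X[:, col[w]]
    return SampleData(lattice=lattice, matrix=out, feature_ids=feats)


def cpm_normalize(sample: SampleData) -> SampleData:
    """Scale each well's column to total 1e6 (counts per million)."""
    if sample.normalization != "raw":
        raise UsageError(f"sample already normalized ({sample.normalization})")
    totals = sample.matrix.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.warning("%d wells have zero total counts; left at zero", int(zero.sum()))
    scale = np.where(zero, 0.0, 1e6 / np.where(zero, 1.0, totals))
    return replace(sample, matrix=sample.matrix * scale, normalization="cpm")


def write_scores(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_long_matrix(sample: SampleData, path) -> None:
    """Long-format (feature, well, value) export of nonzero entries."""
    rows, cols = np.nonzero(sample.matrix)
    df = pd.DataFrame(
        {
            "feature": sample.feature_ids[rows],
            "well": np.asarray(sample.lattice.well_ids)[cols],
            "value": sample.matrix[rows, cols],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def write_positions(lattice: WellLattice, path) -> None:
    df = pd.DataFrame(
        {
            "well_id": lattice.well_ids,
            "x": lattice.coords[:, 0],
            "y": lattice.coords[:, 1],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")
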