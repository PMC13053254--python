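"""Count matrices, cell annotations, and library-size log normalization.

Cells are rows internally (matrices are transposed on load from the
MatrixMarket genes x cells convention). Normalization is library-size
scaling to ``scale`` counts per cell followed by log2(x + 1), the scale on
which the downstream "highly expressed" threshold of 0.5 is defined. The log
base is configurable.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "ExpressionDataset",
    "NormalizedMatrix",
    "load_counts",
    "attach_annotations",
    "normalize",
    "write_counts",
    "ANNOTATION_COLUMNS",
]

ANNOTATION_COLUMNS = ("cell_type", "condition", "sample_id")


@dataclass
class ExpressionDataset:
    """Sparse cells x genes UMI counts with optional per-cell annotations."""

    counts: sp.csr_matrix
    cell_ids: pd.Index
    gene_ids: pd.Index
    annotations: pd.DataFrame | None = None

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = pd.Index(self.cell_ids, name="barcode")
        self.gene_ids = pd.Index(self.gene_ids, name="gene")
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        _check_unique(self.cell_ids, "cell barcodes")
        _check_unique(self.gene_ids, "gene symbols")
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.rint(data))):
            raise ValueError("counts must be nonnegative integers")
        if self.annotations is not None:
            missing = self.cell_ids.difference(self.annotations.index)
            if len(missing) > 0:
                raise ValueError(f"cells without annotation: {list(missing[:10])}")
            self.annotations = self.annotations.loc[self.cell_ids]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class NormalizedMatrix:
    """log(count / cell_total * scale + 1) values; zeros stay exactly zero."""

    values: sp.csr_matrix
    cell_ids: pd.Index
    gene_ids: pd.Index
    annotations: pd.DataFrame | None
    scale: float = 1e4
    log_base: float = 2.0

    def gene_column(self, gene: str) -> np.ndarray:
        """Dense vector of one gene's normalized values across all cells."""
        j = self.gene_index(gene)
        return np.asarray(self.values[:, j].todense()).ravel()

    def gene_index(self, gene: str) -> int:
        idx = self.gene_ids.get_indexer([gene])
        if idx[0] < 0:
            raise KeyError(f"gene {gene!r} absent from matrix")
        return int(idx[0])

    def cells_of(self, cell_type: str, condition: str | None = None) -> np.ndarray:
        """Row indices of cells of one annotated type (optionally one condition)."""
        if self.annotations is None:
            raise ValueError("matrix carries no annotations")
        mask = self.annotations["cell_type"].to_numpy() == cell_type
        if condition is not None:
            mask &= self.annotations["condition"].to_numpy() == condition
        return np.flatnonzero(mask)


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:10]}")


def _read_lines(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _find_sidecar(directory: Path, stem: str) -> Path:
    for name in (f"{stem}.tsv", f"{stem}.tsv.gz", f"{stem}.txt"):
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"no {stem} sidecar found in {directory}")


def load_counts(path: str | Path) -> ExpressionDataset:
    """Load a count matrix from an MTX triplet directory or a delimited table.

    MTX triplets follow the genes x cells on-disk convention and are
    transposed to cells x genes on load. Delimited tables are cells in rows
    (first column = barcode) and genes in columns.
    """
    path = Path(path)
    if path.is_dir():
        mtx = None
        for name in ("matrix.mtx", "matrix.mtx.gz"):
            if (path / name).exists():
                mtx = path / name
                break
        if mtx is None:
            raise FileNotFoundError(f"no matrix.mtx[.gz] in {path}")
        mat = mmread(str(mtx))  # genes x cells on disk
        counts = sp.csr_matrix(mat).T
        barcodes = [l.split("\t")[0] for l in _read_lines(_find_sidecar(path, "barcodes"))]
        feat_lines = [l.split("\t") for l in _read_lines(_find_sidecar(path, "features"))]
        # 10x-style features files carry (id, symbol[, type]); use the symbol
        genes = [f[1] if len(f) > 1 else f[0] for f in feat_lines]
        return ExpressionDataset(counts=counts, cell_ids=barcodes, gene_ids=genes)
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{path}: non-numeric entries in count table")
    return ExpressionDataset(
        counts=sp.csr_matrix(values), cell_ids=df.index, gene_ids=df.columns
    )


def write_counts(ds: ExpressionDataset, directory: str | Path) -> None:
    """Write an MTX triplet (genes x cells on disk) plus annotations.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(ds.counts.T.astype(np.int64))
    mmwrite(str(directory / "matrix.mtx"), mat, field="integer")
    (directory / "barcodes.tsv").write_text("\n".join(ds.cell_ids) + "\n")
    (directory / "features.tsv").write_text(
        "\n".join(f"{g}\t{g}" for g in ds.gene_ids) + "\n"
    )
    if ds.annotations is not None:
        ds.annotations.to_csv(directory / "annotations.tsv", sep="\t")


def attach_annotations(
    ds: ExpressionDataset, table: str | Path | pd.DataFrame
) -> ExpressionDataset:
    """Attach the per-cell annotation table (barcode-keyed, cell_type/condition/sample_id).

    Every matrix cell must be present in the table; extra table rows are
    ignored (their count is reported via the returned dataset's annotations
    attrs). Cells missing from the table raise instead of being dropped.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t", index_col=0, dtype=str)
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"annotation table missing column(s): {missing_cols}")
    missing = ds.cell_ids.difference(table.index)
    if len(missing) > 0:
        raise ValueError(
            f"{len(missing)} cell(s) absent from annotation table, "
            f"e.g. {list(missing[:5])}"
        )
    extra = table.index.difference(ds.cell_ids)
    ann = table.loc[ds.cell_ids, list(ANNOTATION_COLUMNS)].copy()
    ann.attrs["ignored_rows"] = int(len(extra))
    return replace(ds, annotations=ann)


def normalize(
    ds: ExpressionDataset, scale: float = 1e4, log_base: float = 2.0
) -> NormalizedMatrix:
    """Library-size normalization: value = log_b(count / cell_total * scale + 1).

    Zero counts map to exactly 0 (the sparsity pattern is preserved), so the
    result is invariant to per-cell multiplicative rescaling of counts.
    Cells with zero total count are rejected.
    """
    totals = np.asarray(ds.counts.sum(axis=1)).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        bad = [ds.cell_ids[i] for i in zero[:10]]
        raise ValueError(f"{zero.size} cell(s) with zero total count, e.g. {bad}")
    mat = sp.csr_matrix(ds.counts, dtype=float)
    # scale each row by scale/total, then log(1 + x) on stored entries only
    row_scale = scale / totals
    mat.data *= np.repeat(row_scale, np.diff(mat.indptr))
    mat.data = np.log1p(mat.data) / np.log(log_base)
    return NormalizedMatrix(
        values=mat,
        cell_ids=ds.cell_ids,
        gene_ids=ds.gene_ids,
        annotations=ds.annotations,
        scale=scale,
        log_base=log_base,
    )
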