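"""Expression-matrix and annotation containers plus the readers/writers.

The internal orientation is genes as rows, cells as columns, with counts held
in a scipy CSR matrix.  Matrix-Market triplets with the usual
``matrix.mtx`` / ``features.tsv`` / ``barcodes.tsv`` sidecar convention are
supported (plain or gzip), as are dense TSVs with gene symbols in the first
column.  All numeric outputs are TSV with a fixed column order and floats at
six significant digits, so that written tables round-trip and byte-compare
across reruns.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

CONDITIONS = ("healthy", "disease")

_FLOAT_FMT = "%.6g"


def _check_unique(names: Sequence[str], what: str) -> None:
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate {what} in matrix index")


@dataclass
class ExpressionMatrix:
    """Sparse non-negative integer counts, genes x cells, with name indices."""

    counts: sp.csr_matrix
    gene_symbols: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_symbols), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_symbols)} genes x {len(self.cell_ids)} cells"
            )
        _check_unique(self.gene_symbols, "gene symbols")
        _check_unique(self.cell_ids, "cell ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts are not allowed")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, rows: Sequence[int]) -> "ExpressionMatrix":
        rows = list(rows)
        return ExpressionMatrix(
            counts=self.counts[rows, :],
            gene_symbols=[self.gene_symbols[i] for i in rows],
            cell_ids=list(self.cell_ids),
        )

    def subset_cells(self, cols: Sequence[int]) -> "ExpressionMatrix":
        cols = list(cols)
        return ExpressionMatrix(
            counts=self.counts[:, cols],
            gene_symbols=list(self.gene_symbols),
            cell_ids=[self.cell_ids[i] for i in cols],
        )

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_symbols)}

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


@dataclass
class CellAnnotation:
    """Per-cell metadata: donor, condition, optional sex / cell type / subcluster."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("cell_id", "donor_id", "condition")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation missing required columns: {missing}")
        if self.table["condition"].isna().any():
            raise ValueError("annotation has cells with null condition")
        bad = set(self.table["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")
        _check_unique(list(self.table["cell_id"]), "cell ids")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def aligned_to(self, cell_ids: Sequence[str]) -> "CellAnnotation":
        """Reorder rows to match ``cell_ids``; every id must be annotated."""
        indexed = self.table.set_index("cell_id")
        missing = [c for c in cell_ids if c not in indexed.index]
        if missing:
            raise ValueError(f"{len(missing)} cells lack annotation, e.g. {missing[:3]}")
        out = indexed.loc[list(cell_ids)].reset_index()
        return CellAnnotation(out)

    def column(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy()


# ---------------------------------------------------------------------------
# readers


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _read_sidecar(path: Path) -> list[str]:
    with _open_maybe_gzip(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _find_sidecar(directory: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = directory / f"{stem}{suffix}"
            if p.exists():
                return p
    raise FileNotFoundError(f"no sidecar matching {stems} in {directory}")


def read_matrix_market(source: str | Path) -> ExpressionMatrix:
    """Read a Matrix-Market triplet directory (or a bare ``.mtx`` path).

    Expects ``matrix.mtx``, ``features.tsv`` (or ``genes.tsv``) and
    ``barcodes.tsv`` next to each other, optionally gzipped.  Inputs whose
    header dimensions place barcodes on rows (rows match the barcode sidecar
    length and not the feature sidecar) are transposed on load, since both
    dialects circulate.
    """
    source = Path(source)
    if source.is_dir():
        mtx_path = _find_sidecar(source, ["matrix.mtx"])
        directory = source
    else:
        mtx_path = source
        directory = source.parent
    features = _read_sidecar(_find_sidecar(directory, ["features.tsv", "genes.tsv"]))
    barcodes = _read_sidecar(_find_sidecar(directory, ["barcodes.tsv"]))

    with _open_maybe_gzip(mtx_path) as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.coo_matrix(mat)
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise ValueError(f"{mtx_path}: non-integer count values")
    if mat.nnz and mat.data.min() < 0:
        raise ValueError(f"{mtx_path}: negative count values")
    mat = mat.astype(np.int64)

    shape = mat.shape
    if shape == (len(features), len(barcodes)):
        pass
    elif shape == (len(barcodes), len(features)):
        logger.info("%s: barcodes on rows; transposing to genes x cells", mtx_path.name)
        mat = mat.T
    else:
        raise ValueError(
            f"{mtx_path}: matrix shape {shape} matches neither "
            f"(features={len(features)}, barcodes={len(barcodes)}) orientation"
        )
    return ExpressionMatrix(sp.csr_matrix(mat), features, barcodes)


def write_matrix_market(matrix: ExpressionMatrix, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(directory / "matrix.mtx"), sp.coo_matrix(matrix.counts), field="integer"
    )
    (directory / "features.tsv").write_text("\n".join(matrix.gene_symbols) + "\n")
    (directory / "barcodes.tsv").write_text("\n".join(matrix.cell_ids) + "\n")


def read_dense_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a dense counts TSV: header row of cell ids, gene symbol first column."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty and df.columns.empty:
        raise ValueError(f"{path}: no data rows")
    if df.isna().any().any():
        raise ValueError(f"{path}: ragged rows or missing values")
    values = df.to_numpy()
    if values.size and not np.allclose(values, np.round(values)):
        raise ValueError(f"{path}: non-integer count values")
    values = values.astype(np.int64)
    if values.size and values.min() < 0:
        raise ValueError(f"{path}: negative count values")
    return ExpressionMatrix(
        sp.csr_matrix(values), [str(g) for g in df.index], [str(c) for c in df.columns]
    )


def write_dense_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        matrix.to_dense(), index=matrix.gene_symbols, columns=matrix.cell_ids
    )
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_annotation(path: str | Path) -> CellAnnotation:
    return CellAnnotation(pd.read_csv(path, sep="\t", dtype={"cell_id": str, "donor_id": str}))


def write_annotation(annotation: CellAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# result-table writers (fixed column order, 6 significant digits)

TABLE_COLUMNS = {
    "labels": ["cell_id", "label"],
    "typed_labels": ["cell_id", "cell_type", "subcluster"],
    "markers": ["gene", "cluster", "p_value", "fraction_in", "mean_in", "mean_out", "fold", "log2fc"],
    "composition": ["cell_type", "subcluster", "condition", "n_cells", "percent"],
    "enrichment": ["term", "k", "K", "n", "N", "p_value", "p_adjusted", "enrichment_score"],
}


def write_table(df: pd.DataFrame, path: str | Path, kind: str | None = None) -> None:
    """Write a result table as TSV with a documented fixed column order."""
    if kind is not None:
        cols = TABLE_COLUMNS[kind]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{kind} table missing columns {missing}")
        df = df[cols]
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
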