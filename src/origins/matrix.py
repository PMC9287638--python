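"""Gene-expression matrix container and single-cell file IO.

The canonical internal layout is genes-as-rows x cells-as-columns, which
mirrors how the activity quadratic form indexes genes i, j. Readers that
receive a cells-as-rows table must be told explicitly (``cells_as_rows=True``);
orientation is never guessed.

Matrices are kept sparse whenever they arrive sparse; only operations that
are mathematically dense (the offset log-normalization) densify, and those
enforce a configurable element-count ceiling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, ValidationError

__all__ = [
    "GeneExpressionMatrix",
    "read_mtx_triplet",
    "read_dense_table",
    "write_mtx_triplet",
    "write_scores",
    "read_scores",
]


def _is_sparse(values) -> bool:
    return sp.issparse(values)


@dataclass
class GeneExpressionMatrix:
    """Non-negative genes x cells expression matrix with identifiers.

    Parameters
    ----------
    values : ndarray or scipy sparse matrix, shape (n_genes, n_cells)
        Non-negative expression values (raw counts or normalized).
    gene_ids : sequence of str
        Unique gene symbols, one per row.
    cell_ids : sequence of str
        Unique cell barcodes, one per column.
    layer_tag : {"counts", "normalized"}
        Which processing layer the values represent.
    """

    values: np.ndarray | sp.spmatrix
    gene_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)
    layer_tag: str = "counts"

    def __post_init__(self):
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.layer_tag not in ("counts", "normalized"):
            raise ValidationError(f"unknown layer_tag {self.layer_tag!r}")
        if not _is_sparse(self.values):
            self.values = np.asarray(self.values, dtype=np.float64)
            if self.values.ndim != 2:
                raise ValidationError("expression values must be 2-dimensional")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _first_duplicate(self.gene_ids)
            raise ValidationError(f"duplicate gene identifier {dupes!r}")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            dupes = _first_duplicate(self.cell_ids)
            raise ValidationError(f"duplicate cell barcode {dupes!r}")
        data = self.values.data if _is_sparse(self.values) else self.values
        if data.size and np.min(data) < 0:
            raise ValidationError("expression matrix contains negative entries")

    # -- shape helpers -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_genes, self.n_cells)

    def toarray(self) -> np.ndarray:
        if _is_sparse(self.values):
            return np.asarray(self.values.todense(), dtype=np.float64)
        return np.asarray(self.values, dtype=np.float64)

    def subset_genes(self, index) -> "GeneExpressionMatrix":
        """Row subset by integer index array or boolean mask (order preserved)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        vals = self.values.tocsr()[index] if _is_sparse(self.values) else self.values[index]
        return replace(
            self,
            values=vals,
            gene_ids=[self.gene_ids[i] for i in index],
            cell_ids=list(self.cell_ids),
        )

    def subset_cells(self, index) -> "GeneExpressionMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        vals = (
            self.values.tocsc()[:, index] if _is_sparse(self.values) else self.values[:, index]
        )
        return replace(
            self,
            values=vals,
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in index],
        )

    def with_values(self, values, layer_tag: str | None = None) -> "GeneExpressionMatrix":
        return replace(self, values=values, layer_tag=layer_tag or self.layer_tag)

    # -- interop -------------------------------------------------------
    def to_anndata(self):
        """Export as an :class:`anndata.AnnData` (cells x genes, scanpy layout)."""
        import anndata as ad

        X = self.values.T.tocsr() if _is_sparse(self.values) else self.values.T.copy()
        adata = ad.AnnData(
            X=X,
            obs=pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )
        adata.uns["layer_tag"] = self.layer_tag
        return adata

    @classmethod
    def from_anndata(cls, adata, layer_tag: str = "counts") -> "GeneExpressionMatrix":
        """Build from an AnnData (cells x genes); transposes to genes x cells."""
        X = adata.X
        vals = X.T.tocsr() if sp.issparse(X) else np.asarray(X).T
        return cls(
            values=vals,
            gene_ids=list(map(str, adata.var_names)),
            cell_ids=list(map(str, adata.obs_names)),
            layer_tag=layer_tag,
        )


def _first_duplicate(items: Sequence[str]) -> str:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_sidecar(path: Path) -> list[str]:
    """One identifier per line; for 10x-style two-column gene files the
    second column (the symbol) is used."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            out.append(fields[1] if len(fields) >= 2 else fields[0])
    return out


def read_mtx_triplet(
    matrix_path, genes_path, barcodes_path, *, cells_as_rows: bool = False
) -> GeneExpressionMatrix:
    """Read a MatrixMarket coordinate file plus gene/barcode sidecars.

    Genes are rows unless ``cells_as_rows`` says otherwise. Entries are
    coerced to non-negative reals; a negative entry raises
    :class:`ValidationError`, a sidecar/dimension mismatch raises
    :class:`FormatError`.
    """
    matrix_path = Path(matrix_path)
    try:
        m = scipy.io.mmread(matrix_path)
    except ValueError as exc:
        raise FormatError(f"cannot parse MatrixMarket file: {exc}", path=str(matrix_path))
    m = sp.csr_matrix(m, dtype=np.float64)
    if cells_as_rows:
        m = m.T.tocsr()
    genes = _read_sidecar(Path(genes_path))
    cells = _read_sidecar(Path(barcodes_path))
    if m.shape[0] != len(genes):
        raise FormatError(
            f"matrix declares {m.shape[0]} rows but gene sidecar has {len(genes)} entries",
            path=str(genes_path),
        )
    if m.shape[1] != len(cells):
        raise FormatError(
            f"matrix declares {m.shape[1]} columns but barcode sidecar has {len(cells)} entries",
            path=str(barcodes_path),
        )
    return GeneExpressionMatrix(values=m, gene_ids=genes, cell_ids=cells, layer_tag="counts")


def write_mtx_triplet(matrix: GeneExpressionMatrix, out_dir) -> dict[str, Path]:
    """Write matrix.mtx + genes.tsv + barcodes.tsv under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "genes": out_dir / "genes.tsv",
        "barcodes": out_dir / "barcodes.tsv",
    }
    vals = matrix.values if _is_sparse(matrix.values) else sp.coo_matrix(matrix.values)
    scipy.io.mmwrite(str(paths["matrix"]), vals)
    paths["genes"].write_text("".join(g + "\n" for g in matrix.gene_ids))
    paths["barcodes"].write_text("".join(c + "\n" for c in matrix.cell_ids))
    return paths


def read_dense_table(
    path, *, delimiter: str | None = None, cells_as_rows: bool = False
) -> GeneExpressionMatrix:
    """Read a dense CSV/TSV with gene symbols in the first column and a
    header row of cell barcodes. Delimiter is sniffed from the extension
    (".csv" -> comma, otherwise tab) unless given explicitly."""
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse table: {exc}", path=str(path))
    if cells_as_rows:
        df = df.T
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate gene symbol {dup!r} in {path}")
    if df.shape[1] == 0:
        warnings.warn(f"{path}: table has genes but zero cells", UserWarning)
    values = df.to_numpy(dtype=np.float64, na_value=np.nan)
    if np.isnan(values).any():
        raise ValidationError(f"non-numeric or missing entries in {path}")
    return GeneExpressionMatrix(
        values=values,
        gene_ids=[str(g) for g in df.index],
        cell_ids=[str(c) for c in df.columns],
        layer_tag="counts",
    )


def write_scores(scores, path) -> None:
    """Write per-cell activity scores as a three-column TSV.

    Columns: cell_id, activity_raw, activity_scaled; row order follows the
    input cell order; floats are written with ``repr`` precision so the file
    round-trips exactly.
    """
    from .activity import ActivityScores  # local import to avoid a cycle

    if not isinstance(scores, ActivityScores):
        raise ValidationError("write_scores expects an ActivityScores instance")
    df = pd.DataFrame(
        {
            "cell_id": scores.cell_ids,
            "activity_raw": scores.raw,
            "activity_scaled": scores.scaled,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_scores(path):
    """Read a scores TSV written by :func:`write_scores`."""
    from .activity import ActivityScores

    df = pd.read_csv(path, sep="\t")
    required = {"cell_id", "activity_raw", "activity_scaled"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"scores table missing column(s) {sorted(missing)}", path=str(path))
    return ActivityScores(
        cell_ids=[str(c) for c in df["cell_id"]],
        raw=df["activity_raw"].to_numpy(dtype=np.float64),
        scaled=df["activity_scaled"].to_numpy(dtype=np.float64),
    )
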