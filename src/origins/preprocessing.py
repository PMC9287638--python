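"""Quality filtering, normalization and HVF selection on genes x cells matrices.

Filtering operates on raw counts and follows the usual droplet QC recipe:
cells are trimmed on detected-feature count (debris / empty droplets below,
doublets above), on total counts and on mitochondrial fraction; genes are
then trimmed on the number of cells in which they are detected. The pipeline
order is cells-then-genes (the two do not commute).

Normalization and HVF selection are thin genes x cells wrappers over the
sklearn estimators in :mod:`origins.estimators`, which expect cells x genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import ValidationError
from .estimators import (
    LogNormalizer,
    OffsetLogNormalizer,
    VSTSelector,
)
from .matrix import GeneExpressionMatrix

__all__ = [
    "FilterConfig",
    "CellFilterReport",
    "HVFSelection",
    "filter_cells",
    "filter_genes",
    "lognormalize",
    "offset_lognormalize",
    "select_hvf",
]


@dataclass
class FilterConfig:
    """Quality-control thresholds for droplet scRNA-seq.

    Defaults follow common practice for 10x data: keep cells with
    200..3000 detected features, at most 12000 total counts and at most 5%
    mitochondrial content; keep genes detected in at least 3 cells.
    """

    min_features_per_cell: int = 200
    max_features_per_cell: int = 3000
    max_counts_per_cell: int = 12000
    max_mito_fraction: float = 0.05
    min_cells_per_gene: int = 3
    mito_prefix: str = "MT-"

    def __post_init__(self):
        if self.min_features_per_cell >= self.max_features_per_cell:
            raise ValidationError("min_features_per_cell must be < max_features_per_cell")
        for name in ("min_features_per_cell", "max_features_per_cell",
                     "max_counts_per_cell", "min_cells_per_gene"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValidationError("max_mito_fraction must lie in [0, 1]")

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class CellFilterReport:
    """Removal counts per QC criterion (a cell can fail several)."""

    n_in: int = 0
    n_kept: int = 0
    removed_low_features: int = 0
    removed_high_features: int = 0
    removed_high_counts: int = 0
    removed_high_mito: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _require_counts(matrix: GeneExpressionMatrix, op: str) -> None:
    if matrix.layer_tag != "counts":
        raise ValidationError(f"{op} expects a counts-layer matrix, got {matrix.layer_tag!r}")


def filter_cells(
    matrix: GeneExpressionMatrix, config: FilterConfig | None = None
) -> tuple[GeneExpressionMatrix, CellFilterReport]:
    """Drop low-quality cells; returns the reduced matrix and a report.

    Retains a cell iff min_features <= detected features <= max_features,
    total counts <= max_counts, and mitochondrial fraction (genes whose
    symbol starts with ``mito_prefix``, case-insensitive) <= max_mito_fraction.
    Removing every cell raises :class:`ValidationError`.
    """
    config = config or FilterConfig()
    _require_counts(matrix, "filter_cells")
    V = matrix.values
    if sp.issparse(V):
        V = V.tocsc()
        detected = np.asarray((V > 0).sum(axis=0)).ravel()
        totals = np.asarray(V.sum(axis=0)).ravel()
    else:
        detected = (V > 0).sum(axis=0)
        totals = V.sum(axis=0)
    mito_mask = np.array(
        [g.upper().startswith(config.mito_prefix.upper()) for g in matrix.gene_ids]
    )
    if mito_mask.any():
        sub = V[mito_mask] if not sp.issparse(V) else V.tocsr()[np.flatnonzero(mito_mask)]
        mito_counts = np.asarray(sub.sum(axis=0)).ravel()
    else:
        mito_counts = np.zeros(matrix.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1e-300), 0.0)

    low = detected < config.min_features_per_cell
    high = detected > config.max_features_per_cell
    counts_high = totals > config.max_counts_per_cell
    mito_high = mito_frac > config.max_mito_fraction
    keep = ~(low | high | counts_high | mito_high)
    report = CellFilterReport(
        n_in=matrix.n_cells,
        n_kept=int(keep.sum()),
        removed_low_features=int(low.sum()),
        removed_high_features=int(high.sum()),
        removed_high_counts=int(counts_high.sum()),
        removed_high_mito=int(mito_high.sum()),
    )
    if report.n_kept == 0:
        raise ValidationError("cell filtering removed every cell; relax the thresholds")
    return matrix.subset_cells(keep), report


def filter_genes(
    matrix: GeneExpressionMatrix, config: FilterConfig | None = None
) -> GeneExpressionMatrix:
    """Keep genes detected (count > 0) in at least ``min_cells_per_gene`` cells."""
    config = config or FilterConfig()
    _require_counts(matrix, "filter_genes")
    V = matrix.values
    if sp.issparse(V):
        detected = np.asarray((V > 0).sum(axis=1)).ravel()
    else:
        detected = (V > 0).sum(axis=1)
    keep = detected >= config.min_cells_per_gene
    return matrix.subset_genes(keep)


def lognormalize(
    matrix: GeneExpressionMatrix, scale_factor: float = 1e4
) -> GeneExpressionMatrix:
    """Library-size log normalization: x' = ln(1 + count / cell_total * scale_factor)."""
    _require_counts(matrix, "lognormalize")
    norm = LogNormalizer(scale_factor=scale_factor)
    out = norm.fit_transform(matrix.values.T)
    return matrix.with_values(out.T, layer_tag="normalized")


def offset_lognormalize(
    matrix: GeneExpressionMatrix,
    offset: float = 1.1,
    scale_factor: float = 1e4,
    max_dense_elements: int = 200_000_000,
) -> GeneExpressionMatrix:
    """Zero-free normalization: x' = log2(offset + count / cell_total * scale_factor).

    With the default offset 1.1 every entry is strictly positive, which
    suits consumers that cannot handle zeros. Output is dense.
    """
    _require_counts(matrix, "offset_lognormalize")
    norm = OffsetLogNormalizer(
        offset=offset, scale_factor=scale_factor, max_dense_elements=max_dense_elements
    )
    out = norm.fit_transform(matrix.values.T)
    return matrix.with_values(out.T, layer_tag="normalized")


@dataclass
class HVFSelection:
    """Result of vst highly-variable-feature selection.

    ``ranked_genes`` holds every gene sorted by decreasing standardized
    variance (ties keep matrix order); ``selected`` is the top ``n_selected``.
    ``standardized_variance`` is aligned with ``ranked_genes``.
    """

    ranked_genes: list[str]
    standardized_variance: np.ndarray
    n_selected: int
    means: np.ndarray = field(default=None, repr=False)
    variances: np.ndarray = field(default=None, repr=False)

    @property
    def selected(self) -> list[str]:
        return self.ranked_genes[: self.n_selected]


def select_hvf(
    matrix: GeneExpressionMatrix,
    n: int = 2000,
    loess_span: float = 0.3,
    clip: float | None = None,
) -> HVFSelection:
    """Rank genes by vst standardized variance and keep the top ``n``.

    The vst procedure: per-gene mean/variance of raw counts; local quadratic
    regression of log10 variance on log10 mean (span ``loess_span``) over
    genes with positive variance; counts standardized by the fitted standard
    deviation and clipped from above at ``clip`` (default sqrt(n_cells));
    genes ranked by the variance of the clipped standardized values.
    """
    _require_counts(matrix, "select_hvf")
    sel = VSTSelector(n_top=n, span=loess_span, clip=clip)
    sel.fit(matrix.values.T)
    order = sel.ranked_indices_
    return HVFSelection(
        ranked_genes=[matrix.gene_ids[i] for i in order],
        standardized_variance=sel.standardized_variance_[order],
        n_selected=sel.n_selected_,
        means=sel.means_[order],
        variances=sel.variances_[order],
    )
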