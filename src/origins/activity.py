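"""Differentiation activity: the per-cell network score and the pipeline.

For a cell with expression profile {x_i} and the undirected differentiation
PPI adjacency A, the mass-action weight of edge {i, j} is W_ij = A_ij x_i x_j
and the activity is the sum of all edge weights,

    P_k = sum over edges {i,j} of x_ik * x_jk,

interpreted as how active the differentiation interaction network is in cell
k; min-max scaling across cells maps it to [0, 1]. The sum streams over the
edge list — the weighted edge matrix W is never materialized — so memory
stays at one score vector.

Writing P as a double sum over a symmetric adjacency counts every undirected
edge twice; that global factor 2 cancels in the min-max scaling, so the
default convention sums each unordered edge once and a ``symmetric_double``
flag is kept for raw-value comparability with the literal double sum.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from . import __version__
from .errors import ValidationError
from .estimators import ActivityScorer, edge_activity, minmax_scale_scores
from .matrix import GeneExpressionMatrix, read_dense_table, read_mtx_triplet, write_scores
from .network import PPIEdgeList, read_edge_list
from .preprocessing import (
    FilterConfig,
    filter_cells,
    filter_genes,
    lognormalize,
    offset_lognormalize,
    select_hvf,
)

__all__ = [
    "ActivityScores",
    "CoverageReport",
    "match_genes",
    "compute_activity",
    "scale_activity",
    "compute_activity_scores",
    "compute_activity_hvf",
    "run_pipeline",
    "PipelineConfig",
]


@dataclass
class ActivityScores:
    """Per-cell activity scores.

    ``raw`` is P_k; ``scaled`` is the min-max rescaling of ``raw`` to [0, 1]
    across the cells of the run. ``n_edges_used`` and ``gene_coverage``
    document network attrition against the scored matrix.
    """

    cell_ids: list[str]
    raw: np.ndarray
    scaled: np.ndarray
    n_edges_used: int = 0
    gene_coverage: float = float("nan")

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=np.float64)
        self.scaled = np.asarray(self.scaled, dtype=np.float64)
        if not (len(self.cell_ids) == self.raw.size == self.scaled.size):
            raise ValidationError("cell_ids, raw and scaled must have equal length")


@dataclass
class CoverageReport:
    network_genes: int
    network_genes_found: int
    network_edges: int
    edges_retained: int

    @property
    def gene_coverage(self) -> float:
        return self.network_genes_found / self.network_genes if self.network_genes else 0.0

    @property
    def edge_coverage(self) -> float:
        return self.edges_retained / self.network_edges if self.network_edges else 0.0

    def as_dict(self) -> dict:
        return {
            "network_genes": self.network_genes,
            "network_genes_found": self.network_genes_found,
            "network_edges": self.network_edges,
            "edges_retained": self.edges_retained,
            "gene_coverage": self.gene_coverage,
            "edge_coverage": self.edge_coverage,
        }


def _fit_scorer(
    matrix: GeneExpressionMatrix, edges: PPIEdgeList, convention: str = "edge_once"
) -> ActivityScorer:
    scorer = ActivityScorer(edges=edges, gene_names=matrix.gene_ids, convention=convention)
    scorer.fit(matrix.values.T)
    return scorer


def match_genes(
    matrix: GeneExpressionMatrix, edges: PPIEdgeList
) -> tuple[np.ndarray, CoverageReport]:
    """Match network edges onto matrix gene rows (case-insensitive).

    Returns a (2, n_matched) index array into the matrix's gene order for
    every edge with both endpoints present, plus a coverage report. Zero
    retained edges raise :class:`ValidationError`.
    """
    scorer = _fit_scorer(matrix, edges)
    n_edges = len(edges)
    universe = edges.gene_universe
    report = CoverageReport(
        network_genes=len(universe),
        network_genes_found=round(scorer.gene_coverage_ * len(universe)),
        network_edges=n_edges,
        edges_retained=scorer.n_edges_used_,
    )
    return scorer.edge_index_, report


def compute_activity(
    matrix: GeneExpressionMatrix,
    edges: PPIEdgeList | np.ndarray,
    convention: str = "edge_once",
) -> np.ndarray:
    """Raw activity vector P (length n_cells) over matched edges.

    ``edges`` may be a :class:`PPIEdgeList` (matched here) or a (2, E) index
    array from :func:`match_genes`. The matrix may contain zeros; entries
    must be non-negative and finite.
    """
    if isinstance(edges, PPIEdgeList):
        scorer = _fit_scorer(matrix, edges, convention)
        return scorer.raw_activity(matrix.values.T)
    idx = np.asarray(edges)
    if idx.ndim != 2 or idx.shape[0] != 2:
        raise ValidationError("edge index array must have shape (2, n_edges)")
    return edge_activity(matrix.values.T, idx[0], idx[1], convention)


def scale_activity(raw: np.ndarray) -> np.ndarray:
    """Min-max scale raw activities to [0, 1] (constant input -> zeros + warning)."""
    return minmax_scale_scores(raw)


def compute_activity_scores(
    matrix: GeneExpressionMatrix,
    edges: PPIEdgeList,
    convention: str = "edge_once",
) -> ActivityScores:
    """Match, score and scale in one call."""
    scorer = _fit_scorer(matrix, edges, convention)
    raw = scorer.raw_activity(matrix.values.T)
    return ActivityScores(
        cell_ids=list(matrix.cell_ids),
        raw=raw,
        scaled=minmax_scale_scores(raw),
        n_edges_used=scorer.n_edges_used_,
        gene_coverage=scorer.gene_coverage_,
    )


def compute_activity_hvf(
    counts: GeneExpressionMatrix,
    edges: PPIEdgeList,
    n_hvf: int = 2000,
    *,
    normalization: str = "lognorm",
    scale_factor: float = 1e4,
    offset: float = 1.1,
    loess_span: float = 0.3,
    clip: float | None = None,
    convention: str = "edge_once",
) -> ActivityScores:
    """Fast activity approximation on the top highly-variable features.

    HVFs are selected on the raw counts (vst ranking); the *full* matrix is
    normalized and its rows are then subset to the selection — normalization
    is never recomputed from reduced totals — and the activity is computed on
    the reduced matrix against the same edge list.
    """
    selection = select_hvf(counts, n=n_hvf, loess_span=loess_span, clip=clip)
    if normalization == "lognorm":
        normalized = lognormalize(counts, scale_factor=scale_factor)
    elif normalization == "offset":
        normalized = offset_lognormalize(counts, offset=offset, scale_factor=scale_factor)
    else:
        raise ValidationError(f"unknown normalization {normalization!r}")
    chosen = set(selection.selected)
    keep = [i for i, g in enumerate(counts.gene_ids) if g in chosen]
    reduced = normalized.subset_genes(np.asarray(keep, dtype=np.intp))
    return compute_activity_scores(reduced, edges, convention=convention)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Resolved parameters for an end-to-end run (read -> QC -> normalize ->
    score -> write)."""

    filters: FilterConfig = field(default_factory=FilterConfig)
    normalization: str = "lognorm"  # "lognorm" | "offset"
    scale_factor: float = 1e4
    offset: float = 1.1
    n_hvf: int | None = None  # None = full matrix
    convention: str = "edge_once"
    skip_filtering: bool = False

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["filters"] = self.filters.as_dict()
        return d


def _load_matrix(matrix_path) -> GeneExpressionMatrix:
    p = Path(matrix_path)
    if p.is_dir():
        def _first(*names):
            for n in names:
                c = p / n
                if c.exists():
                    return c
            raise ValidationError(f"no {names[0]} found under {p}")
        return read_mtx_triplet(
            _first("matrix.mtx"), _first("genes.tsv", "features.tsv"), _first("barcodes.tsv")
        )
    if p.suffix.lower() == ".mtx":
        return read_mtx_triplet(p, p.parent / "genes.tsv", p.parent / "barcodes.tsv")
    return read_dense_table(p)


def run_pipeline(
    matrix_path,
    edge_path,
    config: PipelineConfig | None = None,
    *,
    out_scores=None,
    out_report=None,
) -> tuple[ActivityScores, dict]:
    """Run read -> filter cells -> filter genes -> normalize -> score -> write.

    Deterministic given inputs and config. The report captures every
    parameter that affects the output, per-stage counts, and network
    coverage. Any stage failure is re-raised with the stage name prefixed.
    """
    config = config or PipelineConfig()
    report: dict = {
        "tool_version": __version__,
        "started_unix": time.time(),
        "parameters": config.as_dict(),
        "inputs": {"matrix": str(matrix_path), "edges": str(edge_path)},
        "stages": {},
        "warnings": [],
    }

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc

    matrix = stage("read", _load_matrix, matrix_path)
    edges = stage("read", read_edge_list, edge_path)
    report["stages"]["read"] = {
        "n_genes": matrix.n_genes,
        "n_cells": matrix.n_cells,
        "n_edges": len(edges),
    }

    if not config.skip_filtering:
        matrix, cell_report = stage("filter_cells", filter_cells, matrix, config.filters)
        report["stages"]["filter_cells"] = cell_report.as_dict()
        n_before = matrix.n_genes
        matrix = stage("filter_genes", filter_genes, matrix, config.filters)
        report["stages"]["filter_genes"] = {
            "n_in": n_before,
            "n_kept": matrix.n_genes,
        }

    counts = matrix
    if config.n_hvf is not None:
        scores = stage(
            "activity_hvf",
            compute_activity_hvf,
            counts,
            edges,
            config.n_hvf,
            normalization=config.normalization,
            scale_factor=config.scale_factor,
            offset=config.offset,
            convention=config.convention,
        )
    else:
        if config.normalization == "lognorm":
            normalized = stage("normalize", lognormalize, counts, config.scale_factor)
        elif config.normalization == "offset":
            normalized = stage(
                "normalize", offset_lognormalize, counts, config.offset, config.scale_factor
            )
        else:
            raise ValidationError(f"unknown normalization {config.normalization!r}")
        scores = stage(
            "activity", compute_activity_scores, normalized, edges, config.convention
        )
    report["stages"]["activity"] = {
        "n_cells_scored": len(scores.cell_ids),
        "n_edges_used": scores.n_edges_used,
        "gene_coverage": scores.gene_coverage,
    }

    if out_scores is not None:
        stage("write", write_scores, scores, out_scores)
        report["outputs"] = {"scores": str(out_scores)}
    if out_report is not None:
        Path(out_report).write_text(json.dumps(report, indent=2, default=str) + "\n")
    return scores, report
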