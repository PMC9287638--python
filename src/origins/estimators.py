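"""scikit-learn estimators for the activity workflow.

These classes follow the sklearn contract (``fit``/``transform``,
``get_params``/``set_params``, trailing-underscore fitted attributes) and
operate on the sklearn layout: X is cells x genes. They compose with
:class:`sklearn.pipeline.Pipeline`; with ``set_output(transform="pandas")``
gene names propagate through a VST selection into the scorer.

The functional API in :mod:`origins.preprocessing` and
:mod:`origins.activity` (genes x cells layout) wraps these estimators.

Estimators
----------
``LogNormalizer``
    Seurat-style per-cell log normalization ln(1 + x / total * scale_factor).
``OffsetLogNormalizer``
    Zero-free variant log2(offset + x / total * scale_factor), offset > 1,
    used when a downstream consumer cannot handle zeros.
``VSTSelector``
    Highly-variable-gene selection by variance-stabilizing-transform ranking
    (local regression of log10 variance on log10 mean; clipped standardized
    variance), equivalent to Seurat's ``FindVariableFeatures(vst)``.
``ActivityScorer``
    The differentiation-activity score: for each cell k,
    P_k = sum over network edges {i,j} of x_ik * x_jk, optionally min-max
    scaled across the cells of the batch.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import DegenerateRangeWarning, ValidationError
from .network import PPIEdgeList, canonical_edge

__all__ = [
    "LogNormalizer",
    "OffsetLogNormalizer",
    "VSTSelector",
    "ActivityScorer",
]


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------


def _as_float_matrix(X, *, accept_sparse=True):
    if sp.issparse(X):
        if not accept_sparse:
            X = np.asarray(X.todense(), dtype=np.float64)
        else:
            X = X.tocsr().astype(np.float64)
    else:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValidationError("X must be a 2-d cells x genes matrix")
    data = X.data if sp.issparse(X) else X
    if data.size and not np.isfinite(data).all():
        raise ValidationError("X contains NaN or infinite entries")
    if data.size and data.min() < 0:
        raise ValidationError("X contains negative entries")
    return X

def _feature_names(X):
    names = getattr(X, "columns", None)
    if names is not None:
        return [str(c) for c in names]
    return None


def _cell_totals(X) -> np.ndarray:
    if sp.issparse(X):
        return np.asarray(X.sum(axis=1)).ravel()
    return X.sum(axis=1)


# ---------------------------------------------------------------------------
# normalizers
# ---------------------------------------------------------------------------


class LogNormalizer(TransformerMixin, BaseEstimator):
    """Per-cell library-size log normalization.

    x' = ln(1 + x / cell_total * scale_factor). Zeros stay zero, so sparse
    input yields sparse output. Stateless: ``fit`` only validates.

    Parameters
    ----------
    scale_factor : float, default 10_000
        Pseudo-library size every cell is rescaled to before log1p.
    """

    def __init__(self, scale_factor: float = 1e4):
        self.scale_factor = scale_factor

    def fit(self, X, y=None):
        if self.scale_factor <= 0:
            raise ValidationError("scale_factor must be > 0")
        X = _as_float_matrix(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = _as_float_matrix(X)
        totals = _cell_totals(X)
        if (totals == 0).any():
            raise ValidationError(
                "cell with zero total counts; filter empty cells before normalizing"
            )
        if sp.issparse(X):
            out = X.tocsr(copy=True)
            scale = self.scale_factor / totals
            out = sp.diags(scale) @ out
            out.data = np.log1p(out.data)
            return out.tocsr()
        out = X * (self.scale_factor / totals)[:, None]
        return np.log1p(out)


class OffsetLogNormalizer(TransformerMixin, BaseEstimator):
    """Zero-free log normalization: x' = log2(offset + x / total * scale_factor).

    With offset > 1 every output entry is strictly positive, which makes the
    result acceptable to methods that reject zeros. The output is inherently
    dense; ``max_dense_elements`` guards against accidentally materializing a
    huge matrix.
    """

    def __init__(self, offset: float = 1.1, scale_factor: float = 1e4,
                 max_dense_elements: int = 200_000_000):
        self.offset = offset
        self.scale_factor = scale_factor
        self.max_dense_elements = max_dense_elements

    def fit(self, X, y=None):
        X = _as_float_matrix(X)
        if self.scale_factor <= 0:
            raise ValidationError("scale_factor must be > 0")
        data = X.data if sp.issparse(X) else X
        has_zero = (sp.issparse(X) and X.nnz < X.shape[0] * X.shape[1]) or (
            not sp.issparse(X) and bool((data == 0).any())
        )
        if self.offset <= 1 and has_zero:
            raise ValidationError(
                f"offset {self.offset} <= 1 would leave non-positive values "
                "for zero counts; use offset > 1"
            )
        if self.offset <= 0:
            raise ValidationError("offset must be positive")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = _as_float_matrix(X)
        if X.shape[0] * X.shape[1] > self.max_dense_elements:
            raise ValidationError(
                "offset normalization would densify beyond max_dense_elements "
                f"({self.max_dense_elements}); raise the threshold explicitly"
            )
        totals = _cell_totals(X)
        if (totals == 0).any():
            raise ValidationError(
                "cell with zero total counts; filter empty cells before normalizing"
            )
        dense = np.asarray(X.todense()) if sp.issparse(X) else X
        out = dense * (self.scale_factor / totals)[:, None]
        return np.log2(self.offset + out)


# ---------------------------------------------------------------------------
# vst highly-variable-gene selection
# ---------------------------------------------------------------------------


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - u ** 3, 0.0, None)
    return w ** 3


def loess_quadratic(x: np.ndarray, y: np.ndarray, span: float = 0.3) -> np.ndarray:
    """Local quadratic regression (tricube weights), evaluated at the data.

    For each point the nearest ceil(span*n) neighbours get tricube weights
    scaled by the span radius, and a degree-2 weighted least-squares fit is
    evaluated at the point. Matches R's loess(degree=2, family="gaussian")
    up to its interpolation surface.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = x.size
    if n < 3:
        raise ValidationError("loess needs at least 3 points")
    q = int(np.ceil(span * n))
    q = min(max(q, 3), n)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    fitted_sorted = np.empty(n)
    lo = 0
    for idx in range(n):
        xi = xs[idx]
        # slide the window of q consecutive points minimizing max distance
        hi = lo + q
        while hi < n and (xs[hi] - xi) < (xi - xs[lo]):
            lo += 1
            hi += 1
        d = np.abs(xs[lo:hi] - xi)
        h = d.max()
        if h <= 0:
            fitted_sorted[idx] = ys[lo:hi].mean()
            continue
        w = _tricube(d / h)
        xc = xs[lo:hi] - xi
        basis = np.column_stack([np.ones_like(xc), xc, xc ** 2])
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(basis * sw[:, None], ys[lo:hi] * sw, rcond=None)
        fitted_sorted[idx] = coef[0]
    fitted = np.empty(n)
    fitted[order] = fitted_sorted
    return fitted


def vst_standardized_variance(
    X, *, span: float = 0.3, clip: float | None = None
) -> np.ndarray:
    """Per-gene clipped standardized variance of raw counts (vst ranking).

    X is cells x genes raw counts. Steps: per-gene mean and variance; local
    quadratic regression of log10(variance) on log10(mean) over genes with
    positive variance gives an expected standard deviation sigma_hat; counts
    are standardized z = (x - mean)/sigma_hat and clipped from above at
    ``clip`` (default sqrt(n_cells)); the statistic is sum(z_clipped**2)/(n-1)
    per gene (no re-centering, matching the reference implementation).
    Genes with zero variance score 0.
    """
    X = _as_float_matrix(X)
    n_cells, n_genes = X.shape
    if n_cells < 2:
        raise ValidationError("vst selection needs at least 2 cells")
    if clip is None:
        clip = float(np.sqrt(n_cells))
    if sp.issparse(X):
        Xc = X.tocsc()
        mu = np.asarray(Xc.mean(axis=0)).ravel()
        sq = np.asarray(Xc.multiply(Xc).mean(axis=0)).ravel()
        var = (sq - mu ** 2) * n_cells / (n_cells - 1)
    else:
        mu = X.mean(axis=0)
        var = X.var(axis=0, ddof=1)
    var = np.maximum(var, 0.0)
    variable = var > 0
    if variable.sum() < 3:
        raise ValidationError(
            "fewer than 3 genes with positive variance; local regression is underdetermined"
        )
    fitted = loess_quadratic(np.log10(mu[variable]), np.log10(var[variable]), span=span)
    sd_hat = np.zeros(n_genes)
    sd_hat[variable] = np.sqrt(10.0 ** fitted)

    out = np.zeros(n_genes)
    idx = np.flatnonzero(variable)
    if sp.issparse(X):
        Xc = X.tocsc()
        for g in idx:
            col = Xc.data[Xc.indptr[g]:Xc.indptr[g + 1]]
            z_nz = np.minimum((col - mu[g]) / sd_hat[g], clip)
            z_zero = min((0.0 - mu[g]) / sd_hat[g], clip)
            n_zero = n_cells - col.size
            out[g] = (np.sum(z_nz ** 2) + n_zero * z_zero ** 2) / (n_cells - 1)
    else:
        Z = np.minimum((X[:, idx] - mu[idx]) / sd_hat[idx], clip)
        out[idx] = np.sum(Z ** 2, axis=0) / (n_cells - 1)
    return out


class VSTSelector(SelectorMixin, BaseEstimator):
    """Select the top highly-variable genes by vst standardized variance.

    Fit on raw counts (cells x genes). Ranks genes by the clipped
    standardized variance described in :func:`vst_standardized_variance`
    and keeps the top ``n_top`` (ties broken by input order).

    Parameters
    ----------
    n_top : int, default 2000
        Number of genes to keep; clamped (with a warning) to the number of
        genes seen at fit time.
    span : float, default 0.3
        Local-regression span for the mean-variance trend.
    clip : float or None
        Upper clip for standardized counts; None means sqrt(n_cells).

    Attributes
    ----------
    means_, variances_ : per-gene raw-count moments
    standardized_variance_ : the ranking statistic
    ranked_indices_ : gene indices sorted by decreasing statistic
    """

    def __init__(self, n_top: int = 2000, span: float = 0.3, clip: float | None = None):
        self.n_top = n_top
        self.span = span
        self.clip = clip

    def fit(self, X, y=None):
        if self.n_top < 1:
            raise ValidationError("n_top must be >= 1")
        self.feature_names_in_ = np.asarray(_feature_names(X), dtype=object) if _feature_names(X) else None
        if self.feature_names_in_ is None:
            del self.feature_names_in_
        Xv = X.to_numpy(dtype=np.float64) if hasattr(X, "to_numpy") else X
        Xv = _as_float_matrix(Xv)
        n_genes = Xv.shape[1]
        n_top = self.n_top
        if n_top > n_genes:
            warnings.warn(
                f"n_top={n_top} exceeds the {n_genes} available genes; clamping",
                UserWarning,
            )
            n_top = n_genes
        if sp.issparse(Xv):
            Xc = Xv.tocsc()
            self.means_ = np.asarray(Xc.mean(axis=0)).ravel()
            sq = np.asarray(Xc.multiply(Xc).mean(axis=0)).ravel()
            n = Xv.shape[0]
            self.variances_ = np.maximum((sq - self.means_ ** 2) * n / (n - 1), 0.0)
        else:
            self.means_ = Xv.mean(axis=0)
            self.variances_ = Xv.var(axis=0, ddof=1)
        self.standardized_variance_ = vst_standardized_variance(
            Xv, span=self.span, clip=self.clip
        )
        # stable mergesort => ties keep input order
        self.ranked_indices_ = np.argsort(-self.standardized_variance_, kind="stable")
        self.n_selected_ = n_top
        self.n_features_in_ = n_genes
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranked_indices_[: self.n_selected_]] = True
        return mask


# ---------------------------------------------------------------------------
# the activity score
# ---------------------------------------------------------------------------


def edge_activity(
    X, i_idx: np.ndarray, j_idx: np.ndarray, convention: str = "edge_once"
) -> np.ndarray:
    """Raw activity P_k = sum over edges of x_ik * x_jk for each cell (row) k.

    Streams over the edge index arrays and the sparse structure; the weighted
    edge matrix W is never materialized. Under ``symmetric_double`` each
    off-diagonal edge counts twice (the literal double sum over a symmetric
    adjacency); self-loops contribute x**2 once under either convention.
    """
    if convention not in ("edge_once", "symmetric_double"):
        raise ValidationError(f"unknown convention {convention!r}")
    X = _as_float_matrix(X)
    i_idx = np.asarray(i_idx, dtype=np.intp)
    j_idx = np.asarray(j_idx, dtype=np.intp)
    if i_idx.shape != j_idx.shape:
        raise ValidationError("edge index arrays must have equal length")
    if i_idx.size == 0:
        return np.zeros(X.shape[0])
    self_mask = i_idx == j_idx
    factor = 1.0 if convention == "edge_once" else 2.0
    if sp.issparse(X):
        Xc = X.tocsc()
        A = Xc[:, i_idx]
        B = Xc[:, j_idx]
        per_edge = A.multiply(B)  # cells x edges
        if self_mask.any():
            off = np.asarray(per_edge[:, ~self_mask].sum(axis=1)).ravel()
            diag = np.asarray(per_edge[:, self_mask].sum(axis=1)).ravel()
        else:
            off = np.asarray(per_edge.sum(axis=1)).ravel()
            diag = 0.0
    else:
        per_edge = X[:, i_idx] * X[:, j_idx]
        off = per_edge[:, ~self_mask].sum(axis=1)
        diag = per_edge[:, self_mask].sum(axis=1) if self_mask.any() else 0.0
    return factor * off + diag


def minmax_scale_scores(raw: np.ndarray) -> np.ndarray:
    """Min-max scale a raw activity vector to [0, 1].

    A constant vector (including a single cell) scales to all zeros with a
    :class:`DegenerateRangeWarning`.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.size == 0:
        raise ValidationError("cannot scale an empty score vector")
    if not np.isfinite(raw).all():
        raise ValidationError("raw scores contain NaN or infinite values")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        warnings.warn(
            "raw activity is constant across cells; scaled scores set to 0",
            DegenerateRangeWarning,
        )
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


class ActivityScorer(TransformerMixin, BaseEstimator):
    """Differentiation activity of a PPI network, per cell.

    Given an undirected edge list over gene symbols and a non-negative
    expression matrix X (cells x genes), computes for every cell the
    mass-action activity P_k = sum over matched edges {i, j} of
    x_ik * x_jk, and (by default) min-max scales it across the batch to
    [0, 1]. Gene symbols are matched case-insensitively; edges with an
    endpoint absent from the matrix are dropped (equivalent to zero
    expression) and the attrition is reported via ``gene_coverage_`` and
    ``edge_coverage_``.

    Parameters
    ----------
    edges : PPIEdgeList or iterable of (str, str) pairs
        The network adjacency (unordered, deduplicated).
    gene_names : sequence of str, optional
        Column names for array input; ignored when X is a DataFrame.
    convention : {"edge_once", "symmetric_double"}
        Whether each undirected edge is summed once or twice. The scaled
        score is identical under both; the raw score differs by the factor 2.
    output : {"scaled", "raw"}
        What ``transform`` returns (shape (n_cells, 1)).

    Attributes
    ----------
    edge_index_ : (2, n_matched) int array of column indices per matched edge
    n_edges_used_ : number of matched edges
    gene_coverage_ : fraction of network genes present in the matrix
    edge_coverage_ : fraction of network edges with both endpoints present
    """

    def __init__(
        self,
        edges=None,
        gene_names=None,
        convention: str = "edge_once",
        output: str = "scaled",
    ):
        self.edges = edges
        self.gene_names = gene_names
        self.convention = convention
        self.output = output

    # -- helpers -------------------------------------------------------
    def _edge_pairs(self) -> list[tuple[str, str]]:
        if self.edges is None:
            raise ValidationError("ActivityScorer requires an edge list")
        if isinstance(self.edges, PPIEdgeList):
            return sorted(self.edges.edges)
        return sorted({canonical_edge(a, b) for a, b in self.edges})

    def _resolve_names(self, X) -> list[str]:
        names = _feature_names(X)
        if names is None and self.gene_names is not None:
            names = [str(g) for g in self.gene_names]
        if names is None:
            raise ValidationError(
                "gene names unavailable: pass a DataFrame or set gene_names"
            )
        return names

    def fit(self, X, y=None):
        if self.output not in ("scaled", "raw"):
            raise ValidationError(f"unknown output {self.output!r}")
        if self.convention not in ("edge_once", "symmetric_double"):
            raise ValidationError(f"unknown convention {self.convention!r}")
        names = self._resolve_names(X)
        Xv = X.to_numpy(dtype=np.float64) if hasattr(X, "to_numpy") else X
        Xv = _as_float_matrix(Xv)
        if Xv.shape[1] != len(names):
            raise ValidationError(
                f"X has {Xv.shape[1]} columns but {len(names)} gene names given"
            )
        lookup: dict[str, int] = {}
        for i, g in enumerate(names):
            key = g.strip().upper()
            if key not in lookup:  # first occurrence wins on case collisions
                lookup[key] = i
        pairs = self._edge_pairs()
        if not pairs:
            raise ValidationError("edge list is empty")
        ii, jj = [], []
        network_genes: set[str] = set()
        found_genes: set[str] = set()
        for a, b in pairs:
            network_genes.update((a, b))
            ia, ib = lookup.get(a), lookup.get(b)
            if ia is not None:
                found_genes.add(a)
            if ib is not None:
                found_genes.add(b)
            if ia is not None and ib is not None:
                ii.append(ia)
                jj.append(ib)
        if not ii:
            raise ValidationError("network and matrix share no interacting genes")
        self.edge_index_ = np.array([ii, jj], dtype=np.intp)
        self.n_edges_used_ = len(ii)
        self.gene_coverage_ = len(found_genes) / len(network_genes)
        self.edge_coverage_ = len(ii) / len(pairs)
        self.n_features_in_ = Xv.shape[1]
        if _feature_names(X) is not None:
            self.feature_names_in_ = np.asarray(names, dtype=object)
        return self

    def raw_activity(self, X) -> np.ndarray:
        """Raw per-cell activity P_k (1-d vector, length n_cells)."""
        check_is_fitted(self)
        Xv = X.to_numpy(dtype=np.float64) if hasattr(X, "to_numpy") else X
        return edge_activity(Xv, self.edge_index_[0], self.edge_index_[1], self.convention)

    def transform(self, X) -> np.ndarray:
        raw = self.raw_activity(X)
        if self.output == "raw":
            return raw[:, None]
        return minmax_scale_scores(raw)[:, None]

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y).transform(X)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self)
        return np.asarray(
            ["activity_scaled" if self.output == "scaled" else "activity_raw"], dtype=object
        )
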