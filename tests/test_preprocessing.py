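"""QC filtering, both normalizations, and vst highly-variable-feature
selection (including the frozen R Seurat cross-check)."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from origins import (
    FilterConfig,
    GeneExpressionMatrix,
    ValidationError,
    filter_cells,
    filter_genes,
    lognormalize,
    offset_lognormalize,
    select_hvf,
)
from origins.simulate import SimulationConfig, simulate_counts

from _seurat_vst_oracle import SEURAT_VST_STANDARDIZED_VARIANCE


def counts_matrix(values, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{i}" for i in range(values.shape[1])]
    return GeneExpressionMatrix(values=values, gene_ids=genes, cell_ids=cells)


class TestFilterCells:
    def test_low_feature_cell_removed_at_default_threshold(self):
        # 300 genes; cell 0 detects 150 (< 200), cell 1 detects 250
        values = np.zeros((300, 2))
        values[:150, 0] = 1
        values[:250, 1] = 1
        filtered, report = filter_cells(counts_matrix(values))
        assert filtered.cell_ids == ["c1"]
        assert report.removed_low_features == 1

    def test_cell_within_all_bounds_retained(self):
        values = np.zeros((300, 1))
        values[:250, 0] = 20  # 250 features, 5000 counts, 0% mito
        filtered, report = filter_cells(counts_matrix(values))
        assert report.n_kept == 1

    def test_one_removal_per_criterion(self):
        # 4 cells: too-few features / too-many features / too-many counts / high mito
        n_genes = 3100
        genes = ["MT-ND1"] + [f"G{i}" for i in range(n_genes - 1)]
        values = np.zeros((n_genes, 4))
        values[1:51, 0] = 1            # 50 features: below 200
        values[1:3002, 1] = 1          # 3001 features: above 3000
        values[1:301, 2] = 50          # 300 features, 15000 counts: above 12000
        values[1:301, 3] = 1           # 300 features ...
        values[0, 3] = 100             # ... mito fraction 100/400 = 25%
        with pytest.raises(ValidationError):
            filter_cells(counts_matrix(values, genes=genes))  # everything fails
        # add one clean cell so the call succeeds and the report is inspectable
        values = np.hstack([values, np.zeros((n_genes, 1))])
        values[1:301, 4] = 2
        filtered, report = filter_cells(counts_matrix(values, genes=genes))
        assert filtered.n_cells == 1
        assert report.removed_low_features == 1
        assert report.removed_high_features == 1
        assert report.removed_high_counts == 1
        assert report.removed_high_mito == 1

    def test_mito_prefix_case_insensitive(self):
        genes = ["mt-co1", "G1", "G2"]
        values = np.array([[10.0, 0.0], [5.0, 5.0], [5.0, 5.0]])
        cfg = FilterConfig(min_features_per_cell=1, max_mito_fraction=0.2)
        filtered, report = filter_cells(counts_matrix(values, genes=genes), cfg)
        assert report.removed_high_mito == 1 and filtered.cell_ids == ["c1"]


class TestFilterGenes:
    @pytest.mark.parametrize("n_cells_detected,kept", [(2, False), (3, True), (4, True)])
    def test_min_cells_boundary_is_inclusive(self, n_cells_detected, kept):
        values = np.zeros((2, 4))
        values[0, :n_cells_detected] = 1
        values[1, :] = 1
        out = filter_genes(counts_matrix(values))
        assert ("G0" in out.gene_ids) is kept

    def test_zero_threshold_is_identity(self):
        values = np.zeros((3, 4))
        cfg = FilterConfig(min_cells_per_gene=0)
        out = filter_genes(counts_matrix(values), cfg)
        assert out.gene_ids == ["G0", "G1", "G2"]

    def test_pipeline_order_cells_then_genes_differs_from_reverse(self):
        # gene detected in 3 cells, one of which fails cell QC afterwards
        values = np.zeros((400, 4))
        values[:250, :] = 1          # all 4 cells pass features... except:
        values[250:, 0] = 1          # cell 0 detects 400 genes but only 400 counts
        values[399, 1:] = 0
        values[398, :] = [1, 0, 0, 0]  # gene 398 detected only in cell 0
        cfg = FilterConfig(min_features_per_cell=200, max_features_per_cell=300,
                           min_cells_per_gene=1)
        cells_first, _ = filter_cells(counts_matrix(values), cfg)
        cells_then_genes = filter_genes(cells_first, cfg)
        genes_first = filter_genes(counts_matrix(values), cfg)
        assert set(genes_first.gene_ids) != set(cells_then_genes.gene_ids)


class TestLogNormalize:
    def test_closed_form_values(self):
        # cell totals [10, 10], counts [5, 10], scale 10 -> ln(6), ln(11)
        values = np.array([[5.0, 10.0], [5.0, 0.0]])
        out = lognormalize(counts_matrix(values), scale_factor=10)
        assert out.layer_tag == "normalized"
        np.testing.assert_allclose(
            out.toarray()[0], [np.log(6.0), np.log(11.0)], rtol=1e-12
        )

    def test_zeros_stay_zero_and_sparsity_preserved(self):
        values = sp.csr_matrix(np.array([[0.0, 2.0], [3.0, 0.0]]))
        m = GeneExpressionMatrix(values=values, gene_ids=["G0", "G1"], cell_ids=["a", "b"])
        out = lognormalize(m)
        assert sp.issparse(out.values) and out.values.nnz == 2

    def test_zero_total_cell_is_error(self):
        with pytest.raises(ValidationError, match="zero total"):
            lognormalize(counts_matrix(np.array([[1.0, 0.0], [1.0, 0.0]])))

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_per_cell_count_rescaling(self, scale):
        rng = np.random.default_rng(5)
        values = rng.integers(0, 20, size=(30, 8)).astype(float) + 1
        base = lognormalize(counts_matrix(values)).toarray()
        scaled = lognormalize(counts_matrix(values * scale)).toarray()
        np.testing.assert_allclose(base, scaled, rtol=1e-9, atol=1e-12)


class TestOffsetLogNormalize:
    def test_zero_count_maps_to_log2_offset(self):
        values = np.array([[0.0], [10.0]])
        out = offset_lognormalize(counts_matrix(values), offset=1.1)
        np.testing.assert_allclose(out.toarray()[0, 0], np.log2(1.1), rtol=1e-12)

    def test_equal_counts_give_equal_values_and_strict_positivity(self):
        values = np.full((4, 3), 7.0)
        out = offset_lognormalize(counts_matrix(values))
        arr = out.toarray()
        assert np.allclose(arr, arr[0, 0])
        assert arr.min() > 0

    def test_output_strictly_positive_on_sparse_input(self):
        values = sp.random(30, 10, density=0.2, random_state=0, format="csr")
        values.data = np.ceil(values.data * 5)
        values[0, :] = 1  # avoid zero-total cells
        m = GeneExpressionMatrix(values=sp.csr_matrix(values),
                                 gene_ids=[f"G{i}" for i in range(30)],
                                 cell_ids=[f"c{i}" for i in range(10)])
        assert offset_lognormalize(m).toarray().min() > 0

    def test_offset_at_most_one_with_zeros_is_error(self):
        with pytest.raises(ValidationError, match="offset"):
            offset_lognormalize(counts_matrix(np.array([[0.0], [5.0]])), offset=1.0)


class TestSelectHvf:
    def test_zero_variance_gene_scores_zero_and_ranks_last(self):
        rng = np.random.default_rng(0)
        values = rng.poisson(5, size=(10, 20)).astype(float)
        values[3, :] = 4.0  # constant gene
        sel = select_hvf(counts_matrix(values), n=5)
        idx = sel.ranked_genes.index("G3")
        assert sel.standardized_variance[idx] == 0.0
        assert "G3" not in sel.selected

    def test_tenfold_variance_at_equal_mean_ranks_first(self):
        # genes A and B share mean 5; A's variance is ~10x B's; anchors pin the trend
        rng = np.random.default_rng(1)
        n = 40
        a = np.array([0.0, 10.0] * (n // 2))            # var 25.6 at mean 5
        b = np.array([4.0, 6.0] * (n // 2))             # var 1.03 at mean 5
        anchors = rng.poisson(5.0, size=(6, n)).astype(float)
        values = np.vstack([a, b, anchors])
        genes = ["A", "B"] + [f"N{i}" for i in range(6)]
        sel = select_hvf(counts_matrix(values, genes=genes), n=2)
        assert sel.ranked_genes.index("A") < sel.ranked_genes.index("B")
        assert sel.ranked_genes[0] == "A"

    def test_n_equal_to_gene_count_selects_everything(self):
        rng = np.random.default_rng(2)
        values = rng.poisson(3, size=(8, 15)).astype(float)
        sel = select_hvf(counts_matrix(values), n=8)
        assert sorted(sel.selected) == [f"G{i}" for i in range(8)]

    def test_n_above_gene_count_clamps_with_warning(self):
        rng = np.random.default_rng(3)
        values = rng.poisson(3, size=(5, 12)).astype(float)
        with pytest.warns(UserWarning, match="clamp"):
            sel = select_hvf(counts_matrix(values), n=50)
        assert sel.n_selected == 5

    def test_too_few_variable_genes_is_error(self):
        values = np.ones((4, 6))
        values[0, 0] = 2
        with pytest.raises(ValidationError, match="positive variance"):
            select_hvf(counts_matrix(values), n=2)

    def test_sparse_and_dense_agree(self):
        rng = np.random.default_rng(4)
        values = rng.poisson(2, size=(30, 25)).astype(float)
        dense = select_hvf(counts_matrix(values), n=10)
        m_sparse = GeneExpressionMatrix(
            values=sp.csr_matrix(values),
            gene_ids=[f"G{i}" for i in range(30)],
            cell_ids=[f"c{i}" for i in range(25)],
        )
        sparse = select_hvf(m_sparse, n=10)
        np.testing.assert_allclose(
            dense.standardized_variance, sparse.standardized_variance, rtol=1e-10
        )
        assert dense.ranked_genes == sparse.ranked_genes


@pytest.fixture(scope="module")
def fixture_matrix():
    cfg = SimulationConfig(
        n_genes=60, n_network_genes=20, n_cells=40,
        nb_mean=2.0, nb_dispersion=2.0, potency_effect=2.0, seed=42,
    )
    matrix, _ = simulate_counts(cfg)
    # checksum guards against generator drift invalidating the oracle
    assert matrix.toarray().sum() == 6444.0
    return matrix


class TestSeuratCrossCheck:
    """Frozen oracle: R Seurat 5.3.0 FindVariableFeatures(vst) on the
    deterministic negative-binomial fixture (see _seurat_vst_oracle)."""

    def test_standardized_variances_match_seurat(self, fixture_matrix):
        sel = select_hvf(fixture_matrix, n=10)
        ours = dict(zip(sel.ranked_genes, sel.standardized_variance))
        theirs = SEURAT_VST_STANDARDIZED_VARIANCE
        rel = np.array(
            [abs(ours[g] - v) / v for g, v in theirs.items() if v > 0]
        )
        assert rel.max() < 0.1          # worst gene (interpolation-surface diff)
        assert (rel < 1e-6).sum() >= 35  # the bulk agrees to numerical precision
        common = list(theirs)
        rho = spearmanr([ours[g] for g in common], [theirs[g] for g in common]).statistic
        assert rho > 0.995

    def test_top10_set_matches_seurat(self, fixture_matrix):
        sel = select_hvf(fixture_matrix, n=10)
        seurat_top10 = sorted(
            SEURAT_VST_STANDARDIZED_VARIANCE,
            key=SEURAT_VST_STANDARDIZED_VARIANCE.get,
            reverse=True,
        )[:10]
        assert set(sel.selected) == set(seurat_top10)


class TestFilterConfigValidation:
    def test_min_not_below_max_rejected(self):
        with pytest.raises(ValidationError):
            FilterConfig(min_features_per_cell=500, max_features_per_cell=100)

    def test_mito_fraction_range(self):
        with pytest.raises(ValidationError):
            FilterConfig(max_mito_fraction=1.5)
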