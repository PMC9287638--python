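"""Synthetic networks, count matrices and potency-labelled populations.

Everything here is a pure function of its configuration (seed included), so
tests and the acceptance checks run fully offline. The count generator draws
negative-binomial baselines — the standard overdispersed model for UMI
counts — and injects a ground-truth "potency" signal by multiplying the
expected counts of network genes by (1 + potency_effect * p_k) for cell k.
This is the minimal mechanism realizing the premise behind the activity
score: more pluripotent cells keep the differentiation network more broadly
active, hence higher expression across its genes and higher mass-action edge
weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .errors import ValidationError
from .matrix import GeneExpressionMatrix
from .network import PPIEdgeList, edges_from_pairs

__all__ = ["SimulationConfig", "simulate_network", "simulate_counts", "toy_fixture"]


def _gene_name(i: int) -> str:
    return f"G{i + 1:04d}"


@dataclass
class SimulationConfig:
    """Knobs for the synthetic generators.

    n_network_genes leading genes (G0001...) carry the network; the rest are
    background. nb_mean / nb_dispersion parameterize the negative binomial
    (dispersion = shape r; variance = mean + mean^2 / r). potency_model
    "uniform" draws p_k ~ U(0,1); "two_population" splits cells into a
    low-potency (p=0) and a high-potency (p=1) half.
    """

    n_genes: int = 500
    n_network_genes: int = 100
    n_cells: int = 300
    edge_density: float = 0.1
    nb_mean: float = 2.0
    nb_dispersion: float = 2.0
    potency_model: Literal["uniform", "two_population"] = "uniform"
    potency_effect: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.n_network_genes <= self.n_genes):
            raise ValidationError("need 1 <= n_network_genes <= n_genes")
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        if not 0 < self.edge_density <= 1:
            raise ValidationError("edge_density must lie in (0, 1]")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValidationError("nb_mean and nb_dispersion must be > 0")
        if self.potency_effect < 0:
            raise ValidationError("potency_effect must be >= 0")
        n_pairs = self.n_network_genes * (self.n_network_genes - 1) / 2
        if n_pairs * self.edge_density < 1:
            raise ValidationError("edge_density too small: fewer than one expected edge")


def simulate_network(config: SimulationConfig) -> PPIEdgeList:
    """Erdős–Rényi G(n, p) graph over the first n_network_genes symbols.

    No self-loops, deduplicated, deterministic per seed. Raises if zero
    edges are drawn (possible only at tiny n·p).
    """
    g = nx.gnp_random_graph(config.n_network_genes, config.edge_density, seed=config.seed)
    edges = edges_from_pairs(
        (_gene_name(a), _gene_name(b)) for a, b in g.edges()
    )
    if len(edges) == 0:
        raise ValidationError(
            "simulated network has zero edges; increase edge_density or n_network_genes"
        )
    return edges


def _potency(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.potency_model == "uniform":
        return rng.uniform(0.0, 1.0, size=config.n_cells)
    if config.potency_model == "two_population":
        p = np.zeros(config.n_cells)
        p[config.n_cells // 2:] = 1.0
        return rng.permutation(p)
    raise ValidationError(f"unknown potency_model {config.potency_model!r}")


def simulate_counts(
    config: SimulationConfig,
) -> tuple[GeneExpressionMatrix, np.ndarray]:
    """Draw a genes x cells count matrix plus per-cell potency labels.

    Counts are NB(mean, dispersion) per gene/cell; the expected counts of
    the n_network_genes network genes are multiplied by
    (1 + potency_effect * p_k) before drawing. Deterministic per seed.
    """
    rng = np.random.default_rng(config.seed)
    potency = _potency(config, rng)
    r = config.nb_dispersion
    mean = np.full((config.n_genes, config.n_cells), float(config.nb_mean))
    boost = 1.0 + config.potency_effect * potency
    mean[: config.n_network_genes, :] *= boost[None, :]
    # NB as gamma-poisson keeps the parameterization explicit
    lam = rng.gamma(shape=r, scale=mean / r)
    counts = rng.poisson(lam).astype(np.float64)
    matrix = GeneExpressionMatrix(
        values=sp.csr_matrix(counts),
        gene_ids=[_gene_name(i) for i in range(config.n_genes)],
        cell_ids=[f"CELL{k + 1:05d}" for k in range(config.n_cells)],
        layer_tag="counts",
    )
    return matrix, potency


def toy_fixture():
    """Frozen 5-gene x 4-cell matrix, 3-edge network and hand-computed scores.

    Edges {G1,G2}, {G2,G3}, {G4,G5}; cell profiles and edge-once raw scores:

        c1 = (1, 2, 3, 0, 0) -> 1*2 + 2*3 + 0*0 = 8
        c2 = (0, 0, 0, 0, 0) -> 0
        c3 = (1, 1, 1, 1, 1) -> 1 + 1 + 1     = 3
        c4 = (2, 2, 1, 3, 1) -> 4 + 2 + 3     = 9

    raw = (8, 0, 3, 9); scaled = ((8-0)/9, 0, 3/9, 1) = (8/9, 0, 1/3, 1).
    """
    from .activity import ActivityScores  # deferred: avoids import cycle

    values = np.array(
        [
            [1.0, 0.0, 1.0, 2.0],
            [2.0, 0.0, 1.0, 2.0],
            [3.0, 0.0, 1.0, 1.0],
            [0.0, 0.0, 1.0, 3.0],
            [0.0, 0.0, 1.0, 1.0],
        ]
    )
    matrix = GeneExpressionMatrix(
        values=values,
        gene_ids=["G1", "G2", "G3", "G4", "G5"],
        cell_ids=["c1", "c2", "c3", "c4"],
        layer_tag="normalized",
    )
    edges = edges_from_pairs([("G1", "G2"), ("G2", "G3"), ("G4", "G5")])
    raw = np.array([8.0, 0.0, 3.0, 9.0])
    scaled = np.array([8.0 / 9.0, 0.0, 3.0 / 9.0, 1.0])
    expected = ActivityScores(
        cell_ids=list(matrix.cell_ids),
        raw=raw,
        scaled=scaled,
        n_edges_used=3,
        gene_coverage=1.0,
    )
    return matrix, edges, expected
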