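# origins-activity

Per-cell **differentiation activity** scores for single-cell RNA-seq: a
network-based measure of pluripotency that helps locate stem and progenitor
cells — for example to pick the root cell before trajectory inference — 
without relying on tissue-specific stemness markers.

## The score

The method uses the protein–protein interaction (PPI) network associated with
the *cell differentiation* biological process (GO:0030154, descendants
included) as a scaffold of putative biochemical reactions. By the law of mass
action, the propensity of the reaction behind an edge between proteins *i*
and *j* is approximated by the product of the reactant concentrations, read
off the expression profile:

```
W_ij = A_ij · x_i · x_j
```

where `A` is the (undirected, unweighted) adjacency matrix of the network and
`x_i` the expression of gene *i*. The differentiation activity of cell *k* is
the sum of all edge weights,

```
P_k = Σ_{i,j} W_ij(k)
```

and scores are min-max scaled across cells, `P̂_k = (P_k − min P)/(max P − min P)`,
so each dataset spans [0, 1]. Cells that keep the differentiation network
broadly active — stem and progenitor cells — score high; committed cells with
a few specific pathways active score low. The sum streams over the edge list,
so memory stays at one score vector, and matrices with zeros are perfectly
acceptable input.

The package also implements:

* **network construction** from a GO-annotation export (QuickGO-style TSV)
  and a Pathway-Commons-style SIF interaction dump — keeping interactions
  whose two participants are both catalog proteins and discarding chemical
  compounds (`CHEBI:` by default);
* **preprocessing**: droplet QC filters (detected-feature bounds, total-count
  bound, mitochondrial fraction, cells-per-gene), library-size log
  normalization `ln(1 + x/total·10⁴)` and the zero-free variant
  `log2(1.1 + x/total·10⁴)`;
* a **fast approximation** that scores only the top highly-variable features
  (vst-style selection, default 2000), typically ~50× faster on large data;
* a **synthetic-data generator** (negative-binomial counts with a
  ground-truth potency signal on the network genes) so every claim is
  testable offline.

## Worked example

Simulate a potency-labelled dataset and score it:

```sh
$ origins simulate --out-dir demo --seed 3 --n-genes 300 --n-network-genes 80 --n-cells 120
simulated 300x120 counts and 301 edges in demo
$ origins compute --matrix demo --edges demo/edges.tsv --no-filter --out demo/scores.tsv
scored 120 cells over 301 edges -> demo/scores.tsv
$ head -4 demo/scores.tsv
cell_id	activity_raw	activity_scaled
CELL00001	1943.082762256013	0.20990341445958313
CELL00002	3200.2360292475223	0.6281547240260942
CELL00003	3341.527289267445	0.6751619236136639
```

`activity_raw` is P_k (the edge-weight sum for that cell), `activity_scaled`
its min-max rescaling across the 120 cells. Cells generated with higher
potency labels receive systematically higher activity (Spearman ≈ 0.8 on this
small example; ≥ 0.95 at the default simulation scale). A JSON run report
(`demo/scores.tsv.report.json`) records every parameter, per-stage counts and
network coverage.

The same computation as a library, sklearn style:

```python
import pandas as pd
from origins import LogNormalizer, ActivityScorer, read_edge_list
from sklearn.pipeline import Pipeline

counts = pd.read_csv("counts.csv", index_col=0).T   # cells x genes
edges = read_edge_list("edges.tsv")
pipe = Pipeline([
    ("norm", LogNormalizer()),
    ("score", ActivityScorer(edges=edges, gene_names=list(counts.columns))),
])
scaled = pipe.fit_transform(counts)                  # (n_cells, 1) in [0, 1]
```

or functionally on genes × cells matrices:

```python
from origins import read_mtx_triplet, lognormalize, compute_activity_scores
m = read_mtx_triplet("matrix.mtx", "genes.tsv", "barcodes.tsv")
scores = compute_activity_scores(lognormalize(m), edges)
```

Building the differentiation network from public exports:

```sh
origins build-network --annotations goa_export.tsv --interactions pc.sif \
    --go-term GO:0030154 --taxon 9606 --descendants children.txt --out edges.tsv
```

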