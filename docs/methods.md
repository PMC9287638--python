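# Methods

## The activity model

The score treats the PPI network of the cell-differentiation biological
process (GO:0030154 plus descendant terms) as a set of putative elementary
reactions. Under mass action, the rate of the reaction behind edge {i, j} is
proportional to the product of reactant concentrations; using expression as
a proxy for protein concentration gives the edge weight W_ij = A_ij·x_i·x_j
and the per-cell activity P_k = Σ W_ij(k). Assumptions worth stating
explicitly:

* **expression ≈ concentration** — no protein-level measurement, no
  stoichiometry, no distinction between activating and inhibiting
  interactions;
* the network is **undirected and unweighted**: curation quality and
  interaction type are ignored once an edge passes the build filters;
* **min-max scaling is dataset-relative**: a scaled score of 1 means "most
  active cell in this dataset", never an absolute potency; scores are not
  comparable across datasets without re-scaling.

### Summation convention

The double sum P = Σ_{i,j} A_ij x_i x_j over a symmetric adjacency counts
every undirected edge twice. The implementation sums each unordered edge
once by default (`edge_once`); the literal symmetric double sum
(`symmetric_double`) is exactly 2× that, and the factor cancels in min-max
scaling — the equality of scaled scores under both conventions is asserted
to 1e-12 in the test suite. Raw values published under one convention can be
matched by choosing the flag. Self-interactions are excluded at network
build time by default (an x_i² term rewards abundance of a single product
rather than an interaction) but are honoured if present: they contribute
x_i² once under either convention.

### Numerical notes

Per-cell sums stream over the edge-index arrays in fixed (sorted) edge
order with double-precision accumulation, so results are deterministic and
the dense weighted edge matrix W is never materialized; the sparse path
multiplies two column-sliced sparse matrices elementwise. A constant raw
vector (including the single-cell case) min-max scales to all zeros with an
explicit warning rather than dividing by zero.

## Network construction

Nodes come from a QuickGO-style annotation export filtered to one taxon and
to the target GO term plus a caller-supplied descendant list — the package
deliberately does not traverse the ontology, which keeps the builder
offline-testable and makes the descendant closure an explicit, versionable
input. Edges come from a SIF interaction dump; a row survives iff neither
participant has a chemical-compound prefix (`CHEBI:` by default) and both
participants are catalog members. Survivors are deduplicated as unordered
pairs; every dropped row is attributed to exactly one reason (chemical,
out-of-catalog, self-loop, duplicate), so input rows = final edges + drops —
an invariant the tests assert. Identifier matching is exact string equality
after uppercasing; no alias resolution is attempted (a documented
limitation: symbol drift between annotation and interaction sources loses
edges silently, visible only through the coverage report).

Public snapshots of GO and Pathway Commons drift over time, so the package
makes no attempt to reproduce any particular published node/edge census; the
builder is validated on constructed fixtures with known accounting instead.

## Preprocessing

QC defaults follow common droplet practice: cells keep 200–3000 detected
features, ≤ 12000 total counts (doublet guard) and ≤ 5% mitochondrial
content (`MT-` prefix); genes must be detected in ≥ 3 cells (inclusive
boundary). The 12000-count threshold is applied as an upper bound,
consistent with its doublet-filtering purpose; every threshold is
configurable. The pipeline order is cells-then-genes; the two filters do not
commute and the order is asserted in tests.

Two normalizations are provided. Standard log normalization,
x' = ln(1 + 10⁴·x/total), preserves zeros and sparsity. The offset variant,
x' = log2(1.1 + 10⁴·x/total), produces strictly positive matrices for
consumers that cannot tolerate zeros; it is inherently dense, so it refuses
to materialize matrices beyond a configurable element budget. The activity
computation itself accepts zeros — the offset variant exists purely for
interoperability and for matching results computed under that convention.
The log base (2 for the offset variant, e for the standard one) follows the
conventions the variants are drawn from and is recorded in the run report.

## Highly-variable-feature approximation

Scoring only the most variable genes approximates the full activity at a
fraction of the cost, because low-variance genes contribute a nearly
constant term to every cell's P_k that min-max scaling removes. Selection
follows the vst recipe: per-gene mean μ and variance σ² of *raw counts*; a
local **quadratic** regression (tricube weights, span 0.3) of log10 σ² on
log10 μ over genes with σ² > 0 predicts σ̂ per gene; counts are standardized
as z = (x − μ)/σ̂, clipped from above at √n_cells, and genes are ranked by
Σz²/(n−1) (no re-centering, matching the reference implementation of this
selector). The local regression is implemented in-package because the
installed lowess routines are degree-1 only; it reproduces R Seurat 5.3.0's
`FindVariableFeatures(selection.method = "vst")` standardized variances to
numerical precision for two thirds of genes on the frozen cross-check
fixture, within 8% on the worst gene (the reference fits an interpolated
loess surface rather than an exact local fit), with identical top-10
selections; the frozen oracle values live in the test suite.

Two contract details matter for reproducibility: selection always runs on
the counts layer, and the reduced matrix is obtained by subsetting rows of
the *fully normalized* matrix — per-cell totals are never recomputed from
the reduced gene set. With n_hvf = n_genes the approximation is exactly the
full computation (asserted to 1e-12 on scaled scores).

## Synthetic data

The generator exists to make every pipeline stage testable offline, not to
emulate any particular tissue. Baseline counts are negative-binomial
(gamma–Poisson), the standard overdispersed model for UMI counts, with
per-gene mean 2.0 and dispersion r = 2.0 by default — variance = μ + μ²/r,
i.e. about twice Poisson, typical of QC-filtered, moderately expressed
genes; the defaults are chosen so that the generator's own potency mechanism
is comfortably detectable at the scale the validation properties use
(300 cells, 100 network genes in a G(n, p = 0.1) graph). Ground truth enters
multiplicatively: cell k's network-gene expected counts are scaled by
(1 + effect·p_k), with potency p_k either uniform on (0, 1) or a
two-population split — the minimal mechanism realizing the premise that more
pluripotent cells keep the differentiation network more broadly active. At
the default effect of 3, Spearman(potency, raw activity on the generated
counts) ≥ 0.95 across seeds; with effect 0 the correlation is null.

What the generator does *not* emulate — and what passing tests therefore do
not establish about real data: dropout beyond NB sparsity, per-cell library
size variation, correlated gene modules, batch effects, or cell-type
structure. Note also that library-size normalization partially divides out a
broad multiplicative potency signal (boosted network genes inflate the
cell's total), so potency recovery on normalized synthetic data is
systematically weaker than on the generated counts; on real data the network
genes are a small fraction of the transcriptome and the effect is minor.

The frozen 5-gene × 4-cell toy fixture with hand-computed scores
(raw (8, 0, 3, 9) → scaled (8/9, 0, 1/3, 1)) is the package's canonical
regression anchor.

## Problem sizes

Test and acceptance computations run at desk scale, chosen to exercise every
code path with comfortable statistical margins: 100 random oracle instances
at ≤ 50 genes × ≤ 20 cells, potency recovery at 500 genes × 300 cells, HVF
fidelity at 3000 genes × 200 cells. The implementation itself is sparse
end-to-end (except the deliberately dense offset normalization) and scales
to typical 10x matrices.

## Known limitations

* No identifier mapping: symbol mismatches between network and matrix
  silently reduce coverage (always reported, never repaired).
* Scaled scores are dataset-relative; cross-dataset comparison requires
  joint scaling.
* The score is blind to interaction sign: a highly expressed inhibitor
  raises activity as much as an activator.
* vst agreement with the reference selector is exact for most genes but not
  all (interpolation-surface differences); rankings near the selection
  boundary can differ by a few genes.
* Quiescent stem cells with globally low transcription (e.g. HSCs) score
  low by construction — a limitation shared by expression-based potency
  measures generally.
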