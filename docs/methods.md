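# Methods

## Scope and pipeline order

`salinet` compares two condition groups of bulk expression data through
signed weighted co-expression networks.  The stage order is fixed:

1. probe averaging (arithmetic mean of probe rows per gene),
2. dataset merging by gene intersection (first input's gene order, samples
   concatenated with a dataset prefix),
3. per-sample linear rescaling to [0, 100],
4. low-expression filtering (keep a gene iff its value exceeds 1 in at
   least 50 % of samples; the boundary is inclusive),
5. outlier-sample removal by average-linkage hierarchical clustering,
6. per-group network construction (signed similarity → soft-threshold
   power → signed TOM → 0.4 edge cutoff),
7. centralities and cross-network screens,
8. all-pairs differential correlation between the groups,
9. annotation: GO over-representation, marker-interval mapping,
   TF-centred differential modules.

Rescaling precedes merging-dependent filtering because the expression
floor (1) is defined on the 0–100 scale.  The filter is applied before
outlier removal; outlier removal precedes correlation, so the sample
counts entering Fisher's z-test are the post-removal counts.

## Network mathematics

Similarity is `s = (1 + r)/2`; no additional hard threshold is applied
below 0.5 — the power β already suppresses weak similarities, and r = −1
maps to exactly 0.  Adjacency is `s^β` with a zero diagonal.  The signed
topological overlap is

    TOM_ij = (a_ij + Σ_{u≠i,j} a_iu a_uj) / (min(k_i, k_j) + 1 − a_ij),

computed as a matrix product (the zero diagonal removes the u = i, j self
terms); the diagonal is set to 1 by convention and a denominator below
1e−12 yields 0.  Edges are pairs with TOM ≥ cutoff (default 0.4); a gene
is in the network iff it keeps at least one edge, so node counts are below
the filtered gene counts.

**Soft-threshold selection.**  For each candidate power (default grid
1–30, which contains the classic signed-network choice 22) the soft
connectivities `k_i = Σ_u a_ui` are binned into 10 equal-width bins (empty
bins dropped) and log10(frequency) is regressed on log10(mean k per bin).
The fit R² is negated when the slope is positive (scale-free topology
requires a decreasing relation); degenerate single-bin distributions
report 0 with a warning.  The selected β is the smallest candidate with
signed R² ≥ 0.5; if none qualifies, the maximizer is taken and a warning
logged.  A fixed β bypasses selection entirely — useful because the
smallest qualifying power on small simulated data (β ≈ 6–9) leaves a
heavier background adjacency (0.5^β per null pair) in the TOM denominators
than a large power does, producing a core-only network; β = 22 suppresses
the background to ≈ 2e−7 and exports the planted structure.

## Centrality conventions

All four measures are computed on the unweighted thresholded graph (the
convention of the standard interactive network analyzer): DG is the edge
count; BW is Brandes betweenness normalized by (N−1)(N−2)/2 over the whole
graph, also in disconnected graphs; CN is the inverse mean shortest-path
distance to *reachable* nodes (so the member of an isolated adjacent pair
has CN = 1), 0 for isolated nodes in cross-network tables; CC is
2·triangles/(DG·(DG−1)), 0 when DG < 2.  Diameter and radius are the
max/min eccentricity over connected pairs; the average shortest path is
the mean over connected pairs; heterogeneity is the coefficient of
variation of the degree sequence (population sd).  High-degree and
high-closeness screens are inclusive at DG ≥ 0.5·(N−1) and CN ≥ 0.75; the
cross-network table reports a gene absent from the other network with
value 0 and flags "weak" presence at ≤ 10 % connectivity.

## Differential correlation

Fisher's transform is `atanh(r)` with |r| clamped to 1 − 1e−7; the test
statistic divides the transform difference by
`sqrt(1/(n₁−3) + 1/(n₂−3))` with a two-sided normal p-value.  All shared
gene pairs are tested (not only network edges); genes constant in either
group are dropped with a warning.  Multiple testing uses
Benjamini–Hochberg by default.  An Efron-style local false-discovery rate
is available (`fdr_method="local"`): the marginal z density is a
polynomial fit to the log histogram, the empirical null N(μ₀, σ₀) comes
from a quadratic fit of log f around its central peak, π₀ matches the
densities at the mode, and fdr(z) = min(1, π₀ f₀(z)/f(z)).  BH is the
default because it is deterministic and conservative at these scales; the
local estimator needs thousands of tests to stabilize.  Selection requires
|Δr| ≥ 0.7 (inclusive) *and* FDR ≤ 0.05; the magnitude gate encodes the
design decision that a change between two weak correlations (0 vs 0.6) is
not biologically interpretable as rewiring, however significant.

## Annotation

GO enrichment is a one-sided hypergeometric upper-tail test per term with
at least one study gene, BH-corrected across tested terms; the background
defaults to all annotated genes and is overridable.  The annotation table
is consumed flat — no propagation up the ontology DAG is performed, so
parent terms are only tested if explicitly annotated (a documented
limitation).  Interval mapping is locus-level: a gene, represented by its
single start coordinate (1-based), hits an interval when it lies inside
the inclusive [start, end] range on the same chromosome.  TF candidates
are high-centrality genes annotated to any of the four
transcription-activity GO terms (configurable); a TF module exists for
every TF with ≥ 1 selected differential pair, each partner labelled
positive (correlation higher in the sensitive group) or negative.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, at
desk scale, via a Gaussian latent factor model mapped to nonnegative
expression by the affine transform `50 + 10·z` (clipped at 0, a ≈ 5σ
event) — affine rather than exponential because exponentiation attenuates
Pearson correlations and would blur the planted differential-correlation
truth.

* **Samples**: 72 and 96 per group by default (the post-outlier-removal
  scale of a multi-dataset two-cultivar design); `corrupt` appends 5
  outlier samples per group, restoring the 77/101 pre-cleaning scale.
* **Modules**: six 30-gene blocks.  Gene loadings on the module factor
  grade from a core (squared loading `within_module_cor + 0.045`, default
  core correlation ≈ 0.95, matching the edge-weight scale a β = 22 export
  implies) down to a periphery floor (0.35), the convention of the
  canonical WGCNA expression simulator.  Background genes carry weak
  diffuse membership (squared loading ~ U(0, 0.30)) to a round-robin
  factor.  This continuum of membership is what gives the simulated
  networks the heavy-tailed connectivity distribution real co-expression
  data shows; with uniform loadings the degree distribution is bimodal and
  no power attains a scale-free fit.
* **noise_sd** multiplies the residual (uniqueness) term, so `noise_sd=1`
  reproduces the target correlations exactly and `noise_sd → 0` drives
  within-module correlations to 1.
* **Hubs** load on a global factor (squared loading 0.95) that each module
  factor shares (ρ = 0.3), correlating them moderately (r ≈ 0.5) with all
  module genes.  A gene cannot be strongly correlated with many mutually
  weakly-correlated genes (positive-definiteness), so hub "high degree" is
  a soft property at this scale; tests of the degree screen use explicit
  graph fixtures with unambiguous truth.
* **Planted differential pairs** live outside module blocks and hubs: each
  pair is a fresh bivariate draw with correlation `r_A = 0.45 + Δ/2` in
  the sensitive group and `r_A − Δ` in the tolerant group (both clamped to
  ±0.99), Δ = 0.9 by default.  Structural loadings are drawn once and
  shared by the groups, so every non-planted pair is an exact null.
* **Outlier samples** are per-gene sign-flipped shifts (±8 latent SDs,
  independent random pattern per outlier).  A plain mean shift would be
  erased by the per-sample 0–100 rescaling; the sign-flip pattern survives
  any per-sample affine transform, which is what makes downstream
  detection meaningful.
* **Fixture annotations** plant one GO term enriched in the hubs, attach
  the four transcription GO IDs to a known subset (alternate hubs, module
  cores, and the first gene of every planted pair, whose surviving network
  dyads are high-closeness), and lay genes on 12 chromosomes at 10-kb
  spacing with intervals spanning known gene runs.

What the generator does **not** emulate: count-based mean–variance
relationships (negative binomial dispersion), batch effects, platform
differences between microarray and RNA-seq, and correlated outliers.
Passing tests therefore demonstrate correctness of the algorithms under
the factor-model assumptions, not robustness to those real-data artifacts.

## Numerical and design choices

* Automatic outlier cut height: a robust upper fence on the dendrogram
  merge heights, `median + 7·(p80 − median)`.  The 80th percentile stays
  inside the normal bulk even when a handful of outliers occupy the top
  merges, so the fence lands in the gap between ordinary and outlier joins
  on both raw and rescaled data (validated across seeds, outlier counts
  and both scales); an explicit `cut_height` overrides it.  If the cut
  removes more than half the samples a warning is issued and the run
  proceeds.
* Exact symmetry of correlation/TOM matrices is enforced by averaging with
  the transpose and clipping to the valid range.
* Ties in the largest-cluster rule (outlier removal) break toward the
  lowest cluster label; writers sort all outputs lexicographically, so
  reruns are byte-identical.
* `planted_delta` may reach 2.0; the ±0.99 clamp then compresses the
  realized difference to 1.98 (recorded in the truth table as clamped
  values, so tests compare against what was actually planted).
* Problem sizes in the shipped tests and acceptance checks: 300-gene
  fixtures, ≤ 50-node oracle graphs, 5000-pair null calibration and
  10 × 2020-pair recovery simulations — sizes at which every check runs in
  seconds while the statistical assertions retain power.

## Known limitations

The local-fdr estimator is a compact central-matching implementation, not
a re-implementation of any specific published package's internals; with
few tests or a sparse z histogram it falls back toward a standard-normal
null.  Betweenness normalization in disconnected graphs follows the
whole-graph convention, which understates within-component brokerage.  GO
analysis ignores ontology structure.  The pipeline assumes both groups
share a gene universe after preprocessing; genes present in only one group
are silently excluded from the differential screen.
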