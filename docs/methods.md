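# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions that were genuinely open.

## Preprocessing

The pipeline starts from a numeric intensity table (probes or genes ×
samples); scanner-level feature extraction and background correction are
upstream and out of scope. Stage order is fixed: log2 → quantile
normalization → probe averaging. Quantile normalization forces every
column onto the per-rank mean of the column-sorted values; within-column
ties receive the mean of the reference values over the rank span they
occupy, making the operation invariant to tie order and idempotent (both
properties are tested to 1e-12). Probe summarization is the arithmetic
mean of a gene's probes per sample, with genes emitted in lexicographic
order for deterministic output bytes.

## Moderated t-test

Gene-wise fits are ordinary two-group least squares: logfc = mean(treated)
− mean(control), pooled variance s²_g on d = n_T + n_C − 2 df. The
empirical-Bayes layer assumes s²_g | σ²_g ~ σ²_g·χ²_d/d with σ²_g drawn
from a scaled inverse-χ²(d₀, s₀²) prior. The prior is estimated by moment
matching on z = log s²: the excess of var(z) over trigamma(d/2) identifies
trigamma(d₀/2) (solved by bracketed root-finding on the strictly
decreasing trigamma), and mean(z) with the digamma bias corrections
identifies s₀². When the empirical spread does not exceed the χ² sampling
spread the estimator returns d₀ = ∞ (full shrinkage; the moderated t is
then referred to a normal). d₀ = 0 is admitted as the no-moderation limit
and reproduces the classical pooled t exactly — this is the main
correctness oracle for the stage. Zero-variance genes are excluded from
prior estimation with a warning; zero posterior variance yields a signed
infinite statistic with the p-value floored at 1e-300 so that downstream
logarithms stay finite.

Multiplicity: Benjamini–Hochberg step-up, chosen as the default of the
linear-modeling toolchain this stage mirrors. DE counts are stratified on
adjusted p by default (raw p by flag), because the exported cumulative
distribution tables are defined on adjusted p.

## Rank-based set enrichment with overlap discarding

Genes are ranked by ascending raw p (ties broken lexicographically so the
ranking is a deterministic permutation). The set statistic is a one-sided
rank-sum (Wilcoxon/Mann–Whitney) on member ranks: it uses only the
ranking and needs no significance cutoff, which are the two properties the
method is defined by. The full published machinery of the SetRank package
(set-network construction and PageRank-style rescoring) is deliberately
not reproduced; only the ranking statistic and the discarding principle
are implemented. Exact enumeration of the rank-sum null is used when
|members| ≤ 8 and |universe| ≤ 25, the normal approximation with
continuity correction otherwise; the two agree within |Δp| ≤ 0.02 on
borderline 25-gene instances (tested). Sets with fewer than 2 members
after universe intersection are untestable and dropped with a warning.

Correction is one pooled BH family across all collections (per-database
membership is reported as a column). Pooling is the conservative single
choice when several databases are searched simultaneously; it is also
order-free, which makes results invariant to the GMT file order.

Pruning processes initially significant sets (adjusted p ≤ α) in ascending
raw-p order — the stronger set explains the weaker, with ties broken by
set id. A later set B overlapping a retained set A is re-tested on B \ A;
if that difference set is untestable or not significant at α, B is
discarded with `explained_by = A`. Non-significant sets are reported
unpruned. A set disjoint from every other significant set can never be
discarded (tested as an invariant).

## Edge costs and weighted betweenness

Every interactome edge is annotated with the log₁₀ geometric mean of its
endpoints' adjusted p-values, (log₁₀ p_u + log₁₀ p_v)/2. As a
shortest-path weight this quantity is unusable — it is ≤ 0 — so the
default traversal cost is the geometric mean itself, √(p_u·p_v): strictly
positive and order-isomorphic to the log score, so minimum-cost paths are
attracted to significant genes, which is the analytic intent. A
"shifted_log" alternative (log score minus the network-wide minimum plus
ε = 1e-6) gives additive rather than multiplicative path costs; the
literal log score is always exported as an annotation regardless of
transform. The log base is 10 for reporting; it cancels in the gm
transform and is a monotone rescaling in shifted_log. Genes absent from
the DE table receive p_adj = 1 (maximal cost, logged) so unmeasured genes
never attract paths. The STRING combined-score cutoff defaults to 400
(medium confidence) and is configurable.

Betweenness is computed by Brandes single-source accumulation over a
Dijkstra traversal with fractional counting over all minimum-cost paths.
Floating-point path sums make exact tie detection fragile, so equal-cost
alternatives are recognised with a relative tolerance of 1e-9 (scaled by
max(1, |distance|)); the tolerance assumes edge costs are not themselves
smaller than the tie band, which holds after the 1e-300 p-value floor for
any network whose path costs are dominated by a few significant edges.
Endpoints are excluded from their own pairs, disconnected pairs contribute
nothing, and undirected double-counting is halved. Values are
unnormalized raw pair counts (a star center over k leaves scores C(k,2)).
The implementation is verified against exhaustive all-simple-paths
enumeration on small random graphs and against a textbook unweighted
betweenness computation in the unit-cost special case.

Two scopes are reported per pathway node: betweenness within the full
cost-weighted interactome ("global"; node width in the figure-attribute
export) and within the induced pathway subnetwork ("pathway"; node
height). Neither bounds the other — removing the rest of the graph can
either starve a node of paths or remove the detours around it — so both
are computed independently. "Global" means the full loaded interactome,
not the union of tested pathways.

## Synthetic data generator

The generator emulates the statistical shape of a small two-arm microarray
comparison: log2-scale baselines N(8, 1.5²) (typical log-intensity range),
gene-wise true variances s₀²·d₀/χ²(d₀) with defaults (d₀=4, s₀²=0.05) so
the prior-recovery target of the moderated-t stage is well posed, two arms
of n=5 (the animal-per-arm count of the study design it mirrors; a
stand-in, not a claim about the deposited data), 10% of genes shifted by
±2 log2 units (half up, half down), optional probe-level replication with
independent N(0, 0.25²) probe noise, and values exported on the raw
intensity scale 2^x so the pipeline's log2 step applies. True drawn
variances, DE genes with signed effects, and signal/decoy set identities
are recorded in a truth JSON.

Gene sets: signal sets take 80% of their members from the DE pool by
default (`signal_de_fraction`, the detection-power condition), the rest
uniform non-DE filler; sizes are uniform on [10, 50]. A decoy takes
`overlap_fraction` of its parent signal set's members plus
max(2, ⌈overlap/2⌉) non-DE fillers — proportional dilution, so a decoy is
always a genuinely diluted copy: strong enough to be flagged significant
through the shared genes, never an exact duplicate (which would make
attribution between parent and decoy arbitrary), and always weaker than
its parent in a head-to-head ranking. Background sets are uniform draws
from the non-DE pool. The interactome is a preferential-attachment
(Barabási–Albert) graph with m = round(edges_per_node) = 3 by default,
producing hubs so betweenness rankings are non-degenerate, with uniform
integer confidence scores on [150, 999] spanning the STRING range so
cutoff filtering is exercised.

What the generator does **not** emulate: probe sequences and scanner
artifacts, intensity-dependent variance (its variance prior is
exchangeable by construction), correlated co-expression blocks,
annotation noise, or the degree-significance coupling of real disease
networks (DE genes land on hubs only by chance). Passing tests therefore
demonstrate algorithmic correctness and calibration under the assumed
model, not robustness to the full messiness of real array data.

All generators are driven by independent named substreams of one seed, so
identical configs give byte-identical output files (tested); changing the
seed changes the data.

## Problem sizes and defaults

Defaults are desk-scale by design: 2000 genes, 20 sets, a 2000-node
interactome. The whole-interactome weighted betweenness is the dominant
cost (O(V·E log V) per scope, ~20 s at the default size in pure Python);
pathway subnetworks are tiny. Calibration checks run at 2000 genes / 400
sets (binomial SE ≈ 0.011 on the 5% rate, so the ±0.02 acceptance band is
a ~2σ check), prior recovery at 10000 genes × 20 seeds, and power/pruning
at 20 seeded replicates of the signal+decoy scenario.

## Known limitations

- Two-group designs only; no general design matrices, array weights, or
  duplicate-correlation modeling.
- The rank-sum set statistic ignores inter-gene correlation; its null
  calibration is exact only under independent rankings, which the
  generator satisfies but real arrays do not.
- Induced pathway subgraphs of a sparse interactome are often nearly
  edgeless at desk scale, so within-pathway betweenness can be uniformly
  zero while the global scope remains informative (visible in the demo
  run).
- The shifted_log cost depends on the network-wide minimum log score and
  is therefore not stable under edge subsetting; gm is the default for
  exactly this reason.
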