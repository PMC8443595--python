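# Methods

`seednet` re-implements, as a tested library, a common systems-biology
workflow for relating disease gene sets to each other and to
tissue-compartment gene sets through the protein–protein interaction
(PPI) network: build seed-gene *interactomes*, test their pairwise
overlaps and their regional-expression enrichment with hypergeometric
statistics, and summarize the resulting significance matrix by PCA and
hierarchical clustering. Every stage can be driven by a synthetic-data
generator that plants known structure, so the whole pipeline is testable
without any database downloads.

## Interactome construction

The global PPI universe is an undirected simple graph over gene symbols
(self-loops and duplicate edges are dropped at load time and counted).
The interactome of a labelled seed list is the *distance-1 neighborhood
as an induced subgraph*: seeds found in the network, all of their direct
interactors, and every global interaction with both endpoints inside
that node set. Because the subgraph is induced, any gene that links two
seed genes is included automatically as an intermediate interactor — no
separate path search is performed. Seeds absent from the network are
recorded and reported rather than raised as errors (disease-association
databases routinely list genes without curated interactions); only a
seed list with *no* network member is an error. Seed tables are
`(gene, label, score)` rows filtered at an association score ≥ 0.01,
the conventional "at least one supporting publication" cutoff.
Compartment gene lists may pass through a user-supplied ortholog table
(one-to-many mappings allowed; unmapped symbols are reported, never
silently discarded).

Overlap bookkeeping reports the shared gene set of two interactomes
together with both totals, and percentages as `100·k/total` rounded
half-up at a caller-chosen precision.

## Over-representation statistics

All enrichment tests are upper-tail hypergeometric: for an overlap of
`k` genes between a query of size `n` and an annotated set of size `K`
in a universe of `N` genes,

    P(X ≥ k) = Σ_{x=k}^{min(n,K)} C(K,x) C(N−K, n−x) / C(N,n),

computed from an exact big-integer anchor term P(X = k) extended by the
stable term-ratio recurrence with compensated summation (absolute error
near machine precision at genome-scale universes); tails below the
double-precision range, and universes beyond 1e5 genes, fall back to
log-space summation of log-gamma binomials so nothing underflows.
P-values are floored at 1e-300 before any −log10 transform. The enrichment ratio is `(k/n)/(K/N)`.
One-sided Fisher's exact mode (identical tail, computed by scipy) is
provided for pathway-style tests. Benjamini–Hochberg step-up adjustment
(via statsmodels) treats all tests of one invocation — one query against
one collection, or one batch of overlap tests — as a single family.

Universe choices, which the databases behind such analyses rarely make
explicit, are pinned down as follows and are configurable:
interactome–interactome overlap tests use all genes of the loaded PPI
network; region-expression tests use the union of the region gene sets
(i.e. genes expressed above threshold in at least one region after
housekeeping exclusion). The latter choice makes the test exactly
hypergeometric under the generator's null, where expression is i.i.d.
across genes (gene exchangeability).

## Region gene sets

An expression matrix (genes × regions; TPM or log-RPKM units) is
thresholded into one gene set per region. The boundary operator is part
of the configuration because the two common conventions differ: TPM
matrices use `≥ 9` ("medium or high expression"), log-RPKM matrices use
`> 2`. Housekeeping genes — expressed at TPM ≥ 1 in *every* region — are
excluded from all region sets, since they carry no regional information.
Missing values never satisfy a threshold. Region sets are written and
read as GMT.

## Significance matrix, PCA, clustering

Per-condition enrichment batteries are assembled into a regions ×
conditions matrix of −log10 p with missing cells where a test was not
run. Rows, then columns, with ≥ 70% missing cells are removed (the
boundary is exclusive: "less than 70% missing" is kept). Each row
variable is centered and scaled to unit variance (sample SD, ddof = 1);
constant rows are dropped with a warning.

PCA uses SVD with imputation: missing cells start at zero (the row mean
after centering) and are repeatedly replaced by the rank-r SVD
reconstruction until their relative change falls below `tol = 1e-6` (in
Frobenius norm over the imputed cells) or `max_iter = 100` passes, the
standard iterative SVD-impute scheme; a complete matrix exits after one
pass and equals direct SVD PCA to machine precision. Scores are the
projections of the condition columns; loadings are Pearson correlations
of each region variable with each score vector; variance percentages
come from the squared singular values of the completed matrix.

Conditions (or regions) are clustered by UPGMA on the Pearson
correlation distance `d = 1 − r`, computed on pairwise-complete cells.
The cluster-to-cluster distance is the arithmetic mean of all cross-pair
leaf distances (maintained by the Lance–Williams size-weighted update);
ties are broken deterministically by the lexicographically smallest
member label. UPGMA was written in-house because this tie-break contract
is not available in `scipy.cluster.hierarchy.linkage`; scipy serves as
an independent cross-check in the test suite. Dendrograms serialize to
ultrametric Newick (leaf-to-root depth = half the root merge height).
Z-score heatmap matrices are computed per row by default (per region
across conditions) with sample SD; constant vectors become zeros with a
warning so the matrix shape is preserved.

## Synthetic data and study conditions

The generator emits every pipeline input from one integer seed, with a
named random stream per artifact, and records a ground-truth manifest.
Defaults are genome-scale: 20,000 genes; an Erdős–Rényi interaction
graph of mean degree 16, matching the neighborhood expansion observed in
curated human PPI compilations where a seed list grows by roughly 12–19
interactors per seed (so a 49-gene compartment list yields a ~800-gene
interactome); six disorders with 25-gene seed lists plus sub-threshold
decoy rows (score < 0.01) so the filter is always exercised; 49/19-gene
compartment lists; a 13-region expression matrix with log-normal
baseline (µ = 0.5, σ = 2 on the log scale, giving ~20% of genes above
9 TPM per region) and ~45% housekeeping genes floored at TPM 1; and a
20-set pathway collection. A preferential-attachment graph model is
available as an alternative.

Two kinds of signal can be planted. A disorder→compartment *affiliation*
of strength `s` draws a fraction `s` of that disorder's seeds from
within distance 1 of the compartment's gene list; at strength 1 the two
interactomes share genes far beyond chance. A (compartment, region)
*expression enrichment* multiplies the expression of the compartment's
distance-1 neighborhood in that region by a boost factor (default 50),
pushing those genes over the region-set threshold.

What the generator does *not* emulate: the heavy-tailed degree
distribution of real PPI networks (beyond the optional
preferential-attachment model), correlated expression across regions,
study-specific ascertainment of seed genes, and literature-curation
biases. Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted structure under a clean null —
not that any particular biological conclusion is robust.

## Calibration of the overlap test — a known limitation

Under the no-signal null (uniform seeds on a random graph), the
hypergeometric overlap test between two distance-1 interactomes is
exactly calibrated in the bulk but anti-conservative in the far tail:
both neighborhoods preferentially contain high-degree genes, and every
direct adjacency between the two seed lists contributes ~2 shared genes
at once. The induced shift scales as √(s_a·s_b/N) for seed-list sizes
s_a, s_b in an N-gene universe and is therefore irreducible at
genome-scale list sizes; at the default conditions the tail beyond
p ≈ 0.004 is inflated roughly three-fold. Two consequences for
Monte-Carlo expectations are worth stating plainly. First, even a
perfectly calibrated null would yield at least one BH-significant
overlap among 12 tests in ~5% of runs (under the global null, BH rejects
with probability exactly α for independent p-values), so "no significant
overlap in ≥95% of runs" sits on the boundary before any network
dependence; the tail inflation pushes the observed clean-run rate below
it. Second, BH controls the false-discovery rate, not family-wise error:
with several strength-1 planted pairs driving the step-up threshold for
the remaining pairs toward α, an occasional spurious pair is expected by
design, capping the frequency of *exact* planted-pair recovery below
~90% even under a calibrated null. The test suite asserts the idealized
bars and these two assertions fail honestly at their measured rates;
the same numbers are reported by `scripts/acceptance.py`. Practically,
the same mechanism means that small printed p-values for
interactome–interactome overlaps in real analyses of this kind should
be read as anti-conservative.

The KS uniformity check of null region-enrichment p-values pools one
13-region battery per replicate across 50 replicates. Pooling every
battery (thousands of p-values) would reject the *exact* hypergeometric
test purely for its discreteness — upper-tail p-values of a discrete
statistic are super-uniform at the resolution of the attained levels —
which is an artifact of sample size, not miscalibration.

## Numerical and degenerate-input choices

TSV outputs carry 6 significant digits (Newick branch lengths 10);
reports are full-precision JSON with stable key order. The pipeline
re-reads its own written intermediates before the PCA/clustering stage
so that re-running those stages from files reproduces the end-to-end
outputs bit-for-bit. Empty region sets are kept (with a warning) so
region labels survive into matrices; an all-empty collection is an
error. Constant vectors are an error where a correlation is required
(clustering), dropped where scaling is optional (unit-variance), and
zeroed where shape must be preserved (z-scores). Edge lists only carry
interacting genes, so isolated genes drop out of a written-then-reloaded
network; seeds among them are reported as dropped.
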