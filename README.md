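# seednet

Disease gene lists rarely explain a disorder on their own; much of the
signal lives in the protein–protein interaction (PPI) neighborhood around
them. `seednet` is a Python library and CLI for the workflow that makes
that idea testable: build the *interactome* of each disorder — its seed
genes plus their distance-1 interactors as an induced subgraph of a
global PPI network — test how strongly interactomes overlap each other
and how strongly they are enriched for genes expressed in specific brain
regions, and cluster the disorders from the resulting significance
matrix. It is aimed at computational biologists who want this pipeline
as tested, scriptable code rather than a chain of web tools.

## The statistics in brief

Every overlap and enrichment question is an upper-tail hypergeometric
test. For an overlap of `k` genes between a query of size `n` and an
annotated set of size `K` in a universe of `N` genes,

    P(X ≥ k) = Σ_{x=k}^{min(n,K)} C(K,x) C(N−K,n−x) / C(N,n)

with enrichment ratio `(k/n)/(K/N)` and Benjamini–Hochberg adjustment
across each test family (one-sided Fisher mode, the identical tail, is
available for pathway tests). Regions × conditions matrices of −log10 p
are analysed by PCA using SVD with iterative imputation of missing cells
after unit-variance scaling, and by UPGMA (average-linkage) clustering
on the Pearson correlation distance d = 1 − r. A synthetic-data module
generates every input — PPI graph, seed tables, compartment gene lists,
expression matrix, pathway GMT, ortholog table — from one seed, with
planted disorder→compartment affiliations and regional expression
boosts recorded in a ground-truth manifest. See `docs/methods.md` for
assumptions, defaults and known limitations.

## Worked example

Run the full pipeline on synthetic data with two disorders planted onto
the two striatal-style compartments:

```python
from seednet import PipelineConfig, SimulationConfig, run_pipeline

sim = SimulationConfig(
    n_disorders=4,
    affiliations={
        "D1": ("striosome", 1.0), "D2": ("striosome", 1.0),
        "D3": ("matrix", 1.0), "D4": ("matrix", 1.0),
    },
    planted_region_enrichments=[
        ("striosome", "region_01"), ("striosome", "region_02"),
        ("matrix", "region_07"), ("matrix", "region_08"),
    ],
)
report = run_pipeline(PipelineConfig(outdir="out", rng_seed=7, simulation=sim))
for s in report.significant_overlaps:
    print(s["disorder"], s["compartment"], s["k"], f"{s['q_value']:.3g}")
print([round(float(v), 1) for v in report.pca.variance_explained])
print(report.dendrogram.to_newick())
```

which prints

```
D1 striosome 68 4.24e-22
D2 striosome 97 9.67e-44
D3 matrix 47 9.62e-25
D4 matrix 110 5.37e-109
[63.1, 20.4]
((D1-striosome:0.0004658628664,D2-striosome:0.0004658628664):0.5917190615,(D3-matrix:0.001862826161,D4-matrix:0.001862826161):0.5903220982);
```

Exactly the four planted disorder–compartment pairs are significant:
each shares 47–110 genes with its compartment interactome against a
chance expectation of roughly 10–20, so the BH-adjusted q-values are
astronomically small. PC1 carries 63.1% of the variance in region-wise
enrichment, and the dendrogram splits the disorders into their planted
compartment groups: the two striosome-affiliated conditions and the two
matrix-affiliated conditions merge at tiny heights (their regional
enrichment profiles are nearly identical) before joining at a large
height.

The same stages are available individually from the shell:

```bash
seednet simulate --outdir data --seed 7
seednet build-interactome --network data/ppi_edges.tsv \
    --seeds data/associations.tsv --label D1 --min-score 0.01 --outdir out
seednet region-sets --expr data/expression.tsv --threshold 9 --op ge \
    --out out/regions.gmt
seednet cluster --matrix out/shared_matrix.tsv --axis columns --out out/tree.nwk
seednet run --config pipeline.yaml
```

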