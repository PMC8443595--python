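"""End-to-end orchestration: inputs -> interactomes -> overlaps -> regional
enrichment -> significance matrices -> PCA + clustering -> pathways -> report.

The pipeline either simulates its inputs (with planted ground truth) or
loads them from files; simulated inputs are first written to disk and read
back through the same readers used for real data, so running the stages
individually on the intermediate files reproduces the end-to-end outputs.

Disorder-compartment shared gene sets ("AD-SMI"-style sets) are formed
only for interactome overlaps that are significant after BH adjustment
(q below the configured alpha); downstream regional-expression analyses
run both on the full disorder interactomes and on those shared sets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

from . import matrixops
from .enrichment import (
    EnrichmentResult,
    bh_adjust,
    overlap_test,
    set_enrichment,
    write_results_tsv,
)
from .expression import (
    ThresholdConfig,
    housekeeping_genes,
    read_expression_table,
    region_gene_sets,
)
from .genesets import read_gmt, write_gmt
from .network import (
    Interactome,
    build_interactome,
    interactome_overlap,
    map_orthologs,
    read_edge_list,
    read_ortholog_table,
    read_seed_table,
    seeds_by_label,
    write_interactome,
)
from .simulate import SimulationConfig, SyntheticTruth, simulate_inputs


@dataclass
class PipelineConfig:
    """Everything needed for one reproducible run."""

    outdir: str
    rng_seed: int = 0
    simulation: Optional[SimulationConfig] = None
    inputs: Dict[str, str] = field(default_factory=dict)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    overlap_universe: Optional[int] = None  # None -> all genes in the network
    pca_components: int = 2
    pca_tol: float = 1e-6
    pca_max_iter: int = 100
    cluster_axis: str = "columns"
    pathway_mode: str = "fisher_greater"

    def __post_init__(self) -> None:
        has_sim = self.simulation is not None
        has_inputs = bool(self.inputs)
        if has_sim and has_inputs:
            raise ValueError("config must carry exactly one of simulation block / input paths")
        if not has_sim and not has_inputs:
            raise ValueError("config needs either a simulation block or input paths")

    @classmethod
    def from_dict(cls, raw: Dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulation", None)
        if sim is not None:
            if "affiliations" in sim:
                sim["affiliations"] = {
                    k: tuple(v) for k, v in sim["affiliations"].items()
                }
            for key in ("compartment_sizes", "compartment_labels", "baseline",
                        "pathway_size_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "planted_region_enrichments" in sim:
                sim["planted_region_enrichments"] = [
                    tuple(t) for t in sim["planted_region_enrichments"]
                ]
            sim = SimulationConfig(**sim)
        thresholds = raw.pop("thresholds", None)
        if thresholds is not None:
            thresholds = ThresholdConfig(**thresholds)
        else:
            thresholds = ThresholdConfig()
        return cls(simulation=sim, thresholds=thresholds, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunReport:
    """Summaries, in-memory results and output files of one pipeline run."""

    config_fingerprint: str = ""
    alpha: float = 0.05
    stages: Dict[str, Dict] = field(default_factory=dict)
    interactome_sizes: Dict[str, Dict[str, int]] = field(default_factory=dict)
    significant_overlaps: List[Dict] = field(default_factory=list)
    files: Dict[str, str] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)
    fingerprint: str = ""
    # in-memory results (not serialized)
    truth: Optional[SyntheticTruth] = field(default=None, repr=False)
    overlap_results: List[EnrichmentResult] = field(default_factory=list, repr=False)
    shared_sets: Dict[str, List[str]] = field(default_factory=dict, repr=False)
    adi_region_results: Dict[str, List[EnrichmentResult]] = field(
        default_factory=dict, repr=False
    )
    shared_region_results: Dict[str, List[EnrichmentResult]] = field(
        default_factory=dict, repr=False
    )
    adi_matrix: Optional[object] = field(default=None, repr=False)
    shared_matrix: Optional[object] = field(default=None, repr=False)
    pca: Optional[matrixops.PCAResult] = field(default=None, repr=False)
    dendrogram: Optional[matrixops.Dendrogram] = field(default=None, repr=False)
    pathway_results: Dict[str, List[EnrichmentResult]] = field(
        default_factory=dict, repr=False
    )

    def to_json_dict(self) -> Dict:
        return {
            "config_fingerprint": self.config_fingerprint,
            "alpha": self.alpha,
            "stages": self.stages,
            "interactome_sizes": self.interactome_sizes,
            "significant_overlaps": self.significant_overlaps,
            "files": self.files,
            "warnings": self.warnings,
            "fingerprint": self.fingerprint,
        }


def _config_fingerprint(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(type(o))

    raw = dataclasses.asdict(config)
    raw.pop("outdir", None)  # identical analyses in different folders fingerprint alike
    blob = json.dumps(raw, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _files_fingerprint(files: Dict[str, str]) -> str:
    h = hashlib.sha256()
    for name in sorted(files):
        h.update(name.encode())
        h.update(hashlib.sha256(Path(files[name]).read_bytes()).digest())
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage in order; any stage error aborts with context."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        config_fingerprint=_config_fingerprint(config), alpha=config.thresholds.alpha
    )
    stage = "setup"
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")

            # -- stage: inputs -------------------------------------------------
            stage = "inputs"
            if config.simulation is not None:
                truth = simulate_inputs(
                    config.simulation, outdir / "inputs", config.rng_seed
                )
                report.truth = truth
                input_files = dict(truth.files)
            else:
                input_files = dict(config.inputs)
            report.stages["inputs"] = {"files": sorted(input_files)}

            network = read_edge_list(input_files["network"])
            seed_table = read_seed_table(
                input_files["associations"], min_score=config.thresholds.min_score
            )
            disorder_seeds = seeds_by_label(seed_table)
            if not disorder_seeds:
                raise ValueError("no disorder seeds survive the score filter")

            comp_coll = read_gmt(input_files["compartments"])
            if "orthologs" in input_files:
                mapping = read_ortholog_table(input_files["orthologs"])
            else:
                mapping = None
            compartment_seeds: Dict[str, set] = {}
            unmapped_report: Dict[str, List[str]] = {}
            for label in comp_coll:
                genes = comp_coll.genes(label)
                if mapping is not None:
                    mapped, unmapped = map_orthologs(genes, mapping)
                    compartment_seeds[label] = mapped
                    unmapped_report[label] = sorted(unmapped)
                else:
                    compartment_seeds[label] = {g.upper() for g in genes}
            report.stages["ortholog_mapping"] = {"unmapped": unmapped_report}

            # -- stage: interactomes ------------------------------------------
            stage = "interactomes"
            interactomes: Dict[str, Interactome] = {}
            for label, seeds in sorted(disorder_seeds.items()):
                interactomes[label] = build_interactome(network, seeds, label)
            compartment_interactomes: Dict[str, Interactome] = {}
            for label, seeds in sorted(compartment_seeds.items()):
                compartment_interactomes[label] = build_interactome(network, seeds, label)
            inter_dir = outdir / "interactomes"
            for it in list(interactomes.values()) + list(compartment_interactomes.values()):
                paths = write_interactome(it, inter_dir)
                report.files.update(
                    {f"interactome_{it.label}_{k}": v for k, v in paths.items()}
                )
                report.interactome_sizes[it.label] = {
                    "n_genes": it.n_genes,
                    "n_ppis": it.n_edges,
                    "n_seeds": len(it.seed_genes),
                    "n_dropped_seeds": len(it.dropped_seeds),
                }

            # -- stage: overlaps ----------------------------------------------
            stage = "overlaps"
            universe_n = config.overlap_universe or network.n_nodes
            universe = set(network.nodes)
            results: List[EnrichmentResult] = []
            for d_label, d_it in sorted(interactomes.items()):
                for c_label, c_it in sorted(compartment_interactomes.items()):
                    shared = interactome_overlap(d_it, c_it)
                    res = overlap_test(
                        d_it.genes,
                        c_it.genes,
                        universe,
                        query_label=d_label,
                        set_label=c_label,
                    )
                    assert res.counts.k == shared.k
                    results.append(res)
            qvals = bh_adjust([r.p_value for r in results])
            for r, q in zip(results, qvals):
                r.q_value = float(q)
            report.overlap_results = results
            overlaps_path = outdir / "overlaps.tsv"
            write_results_tsv(
                sorted(results, key=lambda r: (r.p_value, r.query_label, r.set_label)),
                overlaps_path,
            )
            report.files["overlaps"] = str(overlaps_path)
            alpha = config.thresholds.alpha
            for r in results:
                if r.q_value < alpha:
                    report.significant_overlaps.append(
                        {
                            "disorder": r.query_label,
                            "compartment": r.set_label,
                            "k": r.counts.k,
                            "n": r.counts.n,
                            "K": r.counts.K,
                            "N": universe_n,
                            "p_value": r.p_value,
                            "q_value": r.q_value,
                        }
                    )
                    report.shared_sets[f"{r.query_label}-{r.set_label}"] = r.overlap_genes
            report.stages["overlaps"] = {
                "n_tests": len(results),
                "n_significant": len(report.significant_overlaps),
                "universe_size": universe_n,
            }

            # -- stage: region sets -------------------------------------------
            stage = "region_sets"
            expr = read_expression_table(input_files["expression"])
            hk = housekeeping_genes(expr, config.thresholds.housekeeping_min)
            regions = region_gene_sets(expr, config.thresholds, exclude=hk)
            region_universe = regions.all_genes()
            if not region_universe:
                raise ValueError("every region gene set is empty")
            regions_path = outdir / "region_sets.gmt"
            write_gmt(regions, regions_path)
            report.files["region_sets"] = str(regions_path)
            report.stages["region_sets"] = {
                "n_regions": len(regions),
                "n_housekeeping": len(hk),
                "universe_size": len(region_universe),
            }

            # -- stage: regional enrichment -----------------------------------
            stage = "regional_enrichment"
            for label, it in sorted(interactomes.items()):
                report.adi_region_results[label] = set_enrichment(
                    it.genes, regions, region_universe, query_label=label
                )
            for label, genes in sorted(report.shared_sets.items()):
                inside = set(genes) & region_universe
                if not inside:
                    report.warnings.append(
                        f"shared set {label}: no genes inside the expression universe"
                    )
                    continue
                report.shared_region_results[label] = set_enrichment(
                    genes, regions, region_universe, query_label=label
                )
            enrich_path = outdir / "region_enrichment.tsv"
            all_res = [
                r
                for batch in list(report.adi_region_results.values())
                + list(report.shared_region_results.values())
                for r in batch
            ]
            write_results_tsv(all_res, enrich_path)
            report.files["region_enrichment"] = str(enrich_path)

            # -- stage: matrix analysis ---------------------------------------
            stage = "matrix_analysis"
            report.adi_matrix = matrixops.build_significance_matrix(
                report.adi_region_results
            )
            matrixops.write_matrix_tsv(
                report.adi_matrix, outdir / "adi_significance_matrix.tsv", "region"
            )
            report.files["adi_significance_matrix"] = str(
                outdir / "adi_significance_matrix.tsv"
            )
            analysis_results = report.shared_region_results or report.adi_region_results
            analysis_tag = "shared" if report.shared_region_results else "adi"
            matrix = matrixops.build_significance_matrix(analysis_results)
            report.shared_matrix = matrix
            matrixops.write_matrix_tsv(
                matrix, outdir / f"{analysis_tag}_matrix.tsv", "region"
            )
            report.files[f"{analysis_tag}_matrix"] = str(outdir / f"{analysis_tag}_matrix.tsv")
            # re-read the fixed-precision TSV so that rerunning the PCA and
            # clustering stages from this intermediate reproduces the outputs
            # bit-for-bit
            matrix = matrixops.read_matrix_tsv(outdir / f"{analysis_tag}_matrix.tsv")
            report.shared_matrix = matrix
            if matrix.shape[1] >= 2:
                filtered = matrixops.filter_missing(
                    matrix, config.thresholds.missing_frac
                )
                scaled = matrixops.scale_unit_variance(filtered, axis="rows")
                n_comp = min(config.pca_components, min(scaled.shape))
                pca = matrixops.pca_svd_impute(
                    scaled,
                    n_components=n_comp,
                    tol=config.pca_tol,
                    max_iter=config.pca_max_iter,
                )
                report.pca = pca
                matrixops.write_matrix_tsv(pca.scores, outdir / "pca_scores.tsv", "condition")
                matrixops.write_matrix_tsv(pca.loadings, outdir / "pca_loadings.tsv", "region")
                (outdir / "pca_variance.json").write_text(
                    json.dumps(
                        {
                            f"PC{i + 1}": float(v)
                            for i, v in enumerate(pca.variance_explained)
                        },
                        indent=2,
                        sort_keys=True,
                    )
                    + "\n"
                )
                report.files["pca_scores"] = str(outdir / "pca_scores.tsv")
                report.files["pca_loadings"] = str(outdir / "pca_loadings.tsv")
                report.files["pca_variance"] = str(outdir / "pca_variance.json")
                zmat = matrixops.zscore_matrix(filtered, axis="rows")
                matrixops.write_matrix_tsv(zmat, outdir / "zscore_matrix.tsv", "region")
                report.files["zscore_matrix"] = str(outdir / "zscore_matrix.tsv")
                dend = matrixops.cluster_upgma_pearson(filtered, axis=config.cluster_axis)
                report.dendrogram = dend
                (outdir / "conditions.nwk").write_text(dend.to_newick() + "\n")
                report.files["dendrogram"] = str(outdir / "conditions.nwk")
                report.stages["matrix_analysis"] = {
                    "conditions": list(matrix.columns),
                    "variance_explained": [float(v) for v in pca.variance_explained],
                    "pca_iterations": pca.n_iterations,
                }
            else:
                report.stages["matrix_analysis"] = {
                    "conditions": list(matrix.columns),
                    "note": "fewer than 2 conditions; PCA and clustering skipped",
                }

            # -- stage: pathways ----------------------------------------------
            stage = "pathways"
            if "pathways" in input_files and report.shared_sets:
                pathways = read_gmt(input_files["pathways"])
                pathway_universe = pathways.all_genes()
                for label, genes in sorted(report.shared_sets.items()):
                    if not set(genes) & pathway_universe:
                        continue
                    report.pathway_results[label] = set_enrichment(
                        genes,
                        pathways,
                        pathway_universe,
                        mode=config.pathway_mode,
                        query_label=label,
                    )
                if report.pathway_results:
                    path = outdir / "pathway_enrichment.tsv"
                    write_results_tsv(
                        [r for b in report.pathway_results.values() for r in b], path
                    )
                    report.files["pathway_enrichment"] = str(path)
                report.stages["pathways"] = {
                    "n_queries": len(report.pathway_results)
                }

            report.warnings.extend(str(w.message) for w in caught)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report.fingerprint = _files_fingerprint(report.files)
    return report


def write_report(report: RunReport, path: str | Path) -> None:
    """Write the JSON report plus a human-readable text summary beside it."""
    path = Path(path)
    for name, fpath in report.files.items():
        if not Path(fpath).exists():
            raise ValueError(f"report lists missing output file {name}: {fpath}")
    path.write_text(json.dumps(report.to_json_dict(), indent=2, sort_keys=True) + "\n")
    lines = [
        "seednet pipeline run",
        f"  config fingerprint : {report.config_fingerprint}",
        f"  output fingerprint : {report.fingerprint}",
        f"  alpha              : {report.alpha}",
        "  interactomes:",
    ]
    for label, sizes in sorted(report.interactome_sizes.items()):
        lines.append(
            f"    {label}: {sizes['n_genes']} genes, {sizes['n_ppis']} PPIs "
            f"({sizes['n_seeds']} seeds, {sizes['n_dropped_seeds']} dropped)"
        )
    lines.append(f"  significant overlaps (q < {report.alpha}):")
    if report.significant_overlaps:
        for s in report.significant_overlaps:
            lines.append(
                f"    {s['disorder']} ~ {s['compartment']}: k={s['k']} "
                f"(n={s['n']}, K={s['K']}, N={s['N']}), q={s['q_value']:.3g}"
            )
    else:
        lines.append("    none")
    if report.warnings:
        lines.append(f"  warnings: {len(report.warnings)}")
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n")
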