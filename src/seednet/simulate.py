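"""Synthetic inputs with planted, recoverable structure.

Every pipeline input — the PPI universe, per-disorder seed tables,
striatal-compartment gene lists, a gene x region expression matrix,
pathway gene sets and an ortholog mapping table — is generated from a
single integer seed, together with a ground-truth manifest recording
what was planted.  The generator controls two kinds of signal:

* disorder -> compartment *affiliation*: a fraction ``strength`` of a
  disorder's seed genes is drawn from within distance 1 of the
  compartment's gene list, so the two interactomes share genes far in
  excess of chance;
* (gene set, region) *expression enrichment*: the expression of a chosen
  gene set is multiplicatively boosted in a chosen region, pushing it
  over the region-set threshold.

With zero planted signal, seeds are uniform over the graph and expression
is i.i.d. log-normal across genes, so downstream hypergeometric p-values
are calibrated against their null.  Baseline expression is log-normal
(heavy-tailed, positive, TPM-like); a designated housekeeping fraction of
genes is floored at 1 in every region.  All symbols are fixed-width
synthetic IDs ("G000001", aliases "X000001").
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .genesets import GeneSetCollection, write_gmt
from .network import PPINetwork

GENE_FMT = "G{:06d}"
ALIAS_FMT = "X{:06d}"


@dataclass
class SyntheticTruth:
    """Manifest of everything planted into one simulated data set."""

    rng_seed: int
    network_params: Dict = field(default_factory=dict)
    planted_affiliations: Dict[str, Tuple[str, float]] = field(default_factory=dict)
    planted_region_enrichments: List[Tuple[str, str, float]] = field(default_factory=list)
    housekeeping_fraction: float = 0.0
    housekeeping_genes: List[str] = field(default_factory=list)
    disorder_seeds: Dict[str, List[str]] = field(default_factory=dict)
    compartment_genes: Dict[str, List[str]] = field(default_factory=dict)
    files: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.housekeeping_fraction <= 1.0:
            raise ValueError("housekeeping_fraction must lie in [0, 1]")
        for disorder, (comp, strength) in self.planted_affiliations.items():
            if not 0.0 <= strength <= 1.0:
                raise ValueError(
                    f"affiliation strength for {disorder!r}->{comp!r} must lie in [0, 1]"
                )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        raw = json.loads(Path(path).read_text())
        raw["planted_affiliations"] = {
            k: tuple(v) for k, v in raw.get("planted_affiliations", {}).items()
        }
        raw["planted_region_enrichments"] = [
            tuple(t) for t in raw.get("planted_region_enrichments", [])
        ]
        return cls(**raw)


def _gene_ids(n: int) -> List[str]:
    return [GENE_FMT.format(i + 1) for i in range(n)]


def generate_network(
    n_genes: int, model: str = "erdos_renyi", param: float = 0.0004, rng_seed: int = 0
) -> Tuple[PPINetwork, SyntheticTruth]:
    """Random simple undirected PPI universe with synthetic gene IDs.

    ``model`` is ``erdos_renyi`` (param = edge probability) or
    ``preferential_attachment`` (param = integer edges per new node).
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    if model == "erdos_renyi":
        if not 0.0 <= param <= 1.0:
            raise ValueError("erdos_renyi edge probability must lie in [0, 1]")
        g = nx.fast_gnp_random_graph(n_genes, param, seed=int(rng_seed))
    elif model == "preferential_attachment":
        m = int(param)
        if m < 1 or m >= n_genes:
            raise ValueError("preferential_attachment parameter must satisfy 1 <= m < n_genes")
        g = nx.barabasi_albert_graph(n_genes, m, seed=int(rng_seed))
    else:
        raise ValueError(f"unknown network model {model!r}")
    ids = _gene_ids(n_genes)
    g = nx.relabel_nodes(g, dict(zip(range(n_genes), ids)))
    truth = SyntheticTruth(
        rng_seed=int(rng_seed),
        network_params={"n_genes": n_genes, "model": model, "param": param},
    )
    return PPINetwork(graph=g, provenance=f"synthetic:{model}"), truth


def generate_compartment_genes(
    network: PPINetwork,
    size_a: int = 49,
    size_b: int = 19,
    rng_seed: int = 0,
    labels: Tuple[str, str] = ("striosome", "matrix"),
) -> Dict[str, List[str]]:
    """Two disjoint gene lists sampled uniformly from the network.

    The default sizes mirror the 49/19 differential-expression lists that
    seed the striosome and matrix interactomes.
    """
    nodes = sorted(network.nodes)
    if size_a + size_b > len(nodes):
        raise ValueError("compartment sizes exceed the number of network genes")
    rng = np.random.default_rng(int(rng_seed))
    pick = rng.choice(len(nodes), size=size_a + size_b, replace=False)
    genes = [nodes[i] for i in pick]
    return {labels[0]: sorted(genes[:size_a]), labels[1]: sorted(genes[size_a:])}


def closed_neighborhood(network: PPINetwork, genes: Sequence[str]) -> Set[str]:
    """Genes plus all their direct interactors (distance <= 1)."""
    out: Set[str] = set()
    for g in genes:
        if g in network.graph:
            out.add(g)
            out.update(network.graph.neighbors(g))
    return out


def generate_disorder_associations(
    network: PPINetwork,
    n_disorders: int = 6,
    seeds_per: int = 25,
    affiliations: Mapping[str, Tuple[str, float]] | None = None,
    compartments: Mapping[str, Sequence[str]] | None = None,
    rng_seed: int = 0,
    decoys_per: int | None = None,
) -> Tuple[pd.DataFrame, Dict[str, List[str]]]:
    """Per-disorder seed tables with optional planted compartment affiliation.

    For a disorder affiliated to a compartment with strength ``s``, a
    fraction ``s`` of its ``seeds_per`` seed genes is drawn from within
    distance 1 of that compartment's gene list and the rest uniformly
    from the remaining graph.  Intended seeds get association scores
    >= 0.01; ``decoys_per`` decoy rows per disorder (default
    ``seeds_per // 2``) carry scores < 0.01 so the score filter is
    always exercised.  Returns the association table and the true seed
    lists per disorder.
    """
    affiliations = dict(affiliations or {})
    compartments = dict(compartments or {})
    for disorder, (comp, strength) in affiliations.items():
        if comp not in compartments:
            raise ValueError(
                f"affiliation for {disorder!r} references unknown compartment {comp!r}"
            )
        if not 0.0 <= strength <= 1.0:
            raise ValueError("affiliation strength must lie in [0, 1]")
    nodes = sorted(network.nodes)
    if seeds_per > len(nodes):
        raise ValueError("seeds_per exceeds the number of network genes")
    labels = list(affiliations)
    i = 1
    while len(labels) < n_disorders:
        cand = f"D{i}"
        if cand not in labels:
            labels.append(cand)
        i += 1
    if decoys_per is None:
        decoys_per = seeds_per // 2
    rng = np.random.default_rng(int(rng_seed))
    rows: List[Tuple[str, str, float]] = []
    seed_lists: Dict[str, List[str]] = {}
    node_index = {g: i for i, g in enumerate(nodes)}
    for disorder in labels:
        chosen: List[str] = []
        if seeds_per > 0:
            if disorder in affiliations:
                comp, strength = affiliations[disorder]
                pool = sorted(closed_neighborhood(network, compartments[comp]))
                n_local = min(int(round(strength * seeds_per)), len(pool))
                if n_local:
                    idx = rng.choice(len(pool), size=n_local, replace=False)
                    chosen.extend(pool[i] for i in idx)
            remaining = [g for g in nodes if g not in set(chosen)]
            n_rest = seeds_per - len(chosen)
            if n_rest > 0:
                idx = rng.choice(len(remaining), size=n_rest, replace=False)
                chosen.extend(remaining[i] for i in idx)
        seed_lists[disorder] = sorted(chosen)
        for g in chosen:
            rows.append((g, disorder, float(rng.uniform(0.01, 1.0))))
        # decoy rows below the score filter
        if decoys_per > 0 and seeds_per > 0:
            pool = [g for g in nodes if g not in set(chosen)]
            idx = rng.choice(len(pool), size=min(decoys_per, len(pool)), replace=False)
            for i in idx:
                rows.append((pool[i], disorder, float(rng.uniform(1e-4, 0.0099))))
        _ = node_index  # symbol order is fixed by the sorted node list
    table = pd.DataFrame(rows, columns=["gene", "label", "score"])
    return table, seed_lists


def generate_expression(
    genes: Sequence[str],
    regions: Sequence[str],
    baseline: Tuple[float, float] = (0.5, 2.0),
    planted: Sequence[Tuple[Set[str] | Sequence[str], str, float]] = (),
    housekeeping_fraction: float = 0.45,
    rng_seed: int = 0,
) -> Tuple[pd.DataFrame, SyntheticTruth]:
    """Log-normal TPM-like matrix with planted regional enrichments.

    ``baseline`` is (mu, sigma) of the log-normal; each planted
    ``(gene_set, region, boost)`` multiplies those genes' expression in
    that region by ``boost`` (> 1).  A ``housekeeping_fraction`` of genes
    is floored at 1 in every region.
    """
    if not regions:
        raise ValueError("regions must be non-empty")
    if len(set(regions)) != len(regions):
        raise ValueError("duplicate region labels")
    gene_list = list(genes)
    gene_pos = {g: i for i, g in enumerate(gene_list)}
    region_pos = {r: j for j, r in enumerate(regions)}
    for gene_set, region, boost in planted:
        if boost <= 1.0:
            raise ValueError("boost factors must be > 1")
        if region not in region_pos:
            raise ValueError(f"planted region {region!r} not among regions")
        missing = set(gene_set) - set(gene_list)
        if missing:
            raise ValueError(
                f"planted gene set is not a subset of genes ({len(missing)} unknown)"
            )
    rng = np.random.default_rng(int(rng_seed))
    mu, sigma = baseline
    values = rng.lognormal(mean=mu, sigma=sigma, size=(len(gene_list), len(regions)))
    for gene_set, region, boost in planted:
        rows = [gene_pos[g] for g in sorted(set(gene_set))]
        values[rows, region_pos[region]] *= boost
    n_hk = int(round(housekeeping_fraction * len(gene_list)))
    hk_idx = rng.choice(len(gene_list), size=n_hk, replace=False) if n_hk else np.array([], int)
    values[hk_idx] = np.maximum(values[hk_idx], 1.0)
    expr = pd.DataFrame(values, index=gene_list, columns=list(regions))
    expr.attrs["units"] = "TPM"
    truth = SyntheticTruth(
        rng_seed=int(rng_seed),
        housekeeping_fraction=housekeeping_fraction,
        housekeeping_genes=sorted(gene_list[i] for i in hk_idx),
        planted_region_enrichments=[
            ("planted", region, float(boost)) for _, region, boost in planted
        ],
    )
    return expr, truth


def generate_pathway_sets(
    genes: Sequence[str],
    n_sets: int = 20,
    size_range: Tuple[int, int] = (10, 50),
    rng_seed: int = 0,
) -> GeneSetCollection:
    """Random named gene sets (a stand-in pathway GMT)."""
    lo, hi = size_range
    if lo > hi:
        raise ValueError("size_range minimum exceeds maximum")
    if hi > len(genes):
        raise ValueError("maximum set size exceeds the number of genes")
    rng = np.random.default_rng(int(rng_seed))
    gene_list = sorted(genes)
    coll = GeneSetCollection()
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(gene_list), size=size, replace=False)
        coll.add(
            f"PWY{i + 1:03d}",
            sorted(gene_list[j] for j in idx),
            description="synthetic pathway",
        )
    return coll


def make_ortholog_mapping(
    genes: Sequence[str], n_renames: int = 5, rng_seed: int = 0
) -> Tuple[Dict[str, str], Dict[str, Set[str]]]:
    """Identity ortholog table with some genes hidden behind alias symbols.

    Returns ``(alias_of, mapping)``: ``alias_of`` maps each input gene to
    the symbol under which it should be *written* in input files (itself,
    or an alias), and ``mapping`` is the full source -> target table that
    resolves every written symbol back to the network symbol.
    """
    gene_list = list(genes)
    rng = np.random.default_rng(int(rng_seed))
    n_renames = min(n_renames, len(gene_list))
    renamed_idx = set(
        rng.choice(len(gene_list), size=n_renames, replace=False).tolist()
    )
    alias_of: Dict[str, str] = {}
    mapping: Dict[str, Set[str]] = {}
    for i, g in enumerate(gene_list):
        if i in renamed_idx:
            alias = ALIAS_FMT.format(i + 1)
            alias_of[g] = alias
            mapping[alias] = {g}
        else:
            alias_of[g] = g
            mapping[g] = {g}
    return alias_of, mapping


def write_association_table(table: pd.DataFrame, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene\tdisorder\tscore\n")
        for _, row in table.iterrows():
            fh.write(f"{row['gene']}\t{row['label']}\t{row['score']:.6g}\n")


def write_ortholog_table(mapping: Mapping[str, Set[str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for src in sorted(mapping):
            for dst in sorted(mapping[src]):
                fh.write(f"{src}\t{dst}\n")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic data set.

    Defaults emulate a genome-scale analysis: a 20,000-gene interaction
    universe of mean degree 16 (HPRD+BioGRID-scale neighborhoods of
    roughly 12-19 interactors per seed gene), six disorders with 25-gene
    seed lists (association-score filtered), 49/19-gene compartment
    lists, a 13-region TPM-like expression matrix with ~45% housekeeping
    genes, and a 20-set pathway collection.
    """

    n_genes: int = 20000
    model: str = "erdos_renyi"
    mean_degree: float = 16.0
    n_disorders: int = 6
    seeds_per: int = 25
    compartment_sizes: Tuple[int, int] = (49, 19)
    compartment_labels: Tuple[str, str] = ("striosome", "matrix")
    affiliations: Dict[str, Tuple[str, float]] = field(default_factory=dict)
    regions: List[str] = field(
        default_factory=lambda: [f"region_{i:02d}" for i in range(1, 14)]
    )
    baseline: Tuple[float, float] = (0.5, 2.0)
    boost: float = 50.0
    planted_region_enrichments: List[Tuple[str, str]] = field(default_factory=list)
    housekeeping_fraction: float = 0.45
    n_pathways: int = 20
    pathway_size_range: Tuple[int, int] = (10, 50)
    n_ortholog_renames: int = 5

    @property
    def edge_param(self) -> float:
        if self.model == "erdos_renyi":
            return self.mean_degree / (self.n_genes - 1)
        return max(1, int(round(self.mean_degree / 2)))


def simulate_inputs(
    cfg: SimulationConfig, outdir: str | Path, rng_seed: int
) -> SyntheticTruth:
    """Generate one full input bundle and write it as plain-text files.

    Files: ``ppi_edges.tsv``, ``associations.tsv``, ``compartments.gmt``
    (written under alias symbols), ``orthologs.tsv``, ``expression.tsv``,
    ``pathways.gmt`` and ``truth.json``.  Each artifact draws from its own
    named stream of the master seed, so regenerating any one of them with
    the same seed is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(int(rng_seed))
    sub = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ["network", "compartments", "seeds", "expression", "pathways", "orthologs"],
            ss.spawn(6),
        )
    }
    network, truth = generate_network(
        cfg.n_genes, cfg.model, cfg.edge_param, rng_seed=sub["network"]
    )
    compartments = generate_compartment_genes(
        network,
        cfg.compartment_sizes[0],
        cfg.compartment_sizes[1],
        rng_seed=sub["compartments"],
        labels=cfg.compartment_labels,
    )
    table, seed_lists = generate_disorder_associations(
        network,
        n_disorders=cfg.n_disorders,
        seeds_per=cfg.seeds_per,
        affiliations=cfg.affiliations,
        compartments=compartments,
        rng_seed=sub["seeds"],
    )
    planted_expr = [
        (closed_neighborhood(network, compartments[comp]), region, cfg.boost)
        for comp, region in cfg.planted_region_enrichments
    ]
    expr, expr_truth = generate_expression(
        sorted(network.nodes),
        cfg.regions,
        baseline=cfg.baseline,
        planted=planted_expr,
        housekeeping_fraction=cfg.housekeeping_fraction,
        rng_seed=sub["expression"],
    )
    pathways = generate_pathway_sets(
        sorted(network.nodes),
        n_sets=cfg.n_pathways,
        size_range=cfg.pathway_size_range,
        rng_seed=sub["pathways"],
    )
    all_comp_genes = sorted({g for gl in compartments.values() for g in gl})
    alias_of, mapping = make_ortholog_mapping(
        all_comp_genes, n_renames=cfg.n_ortholog_renames, rng_seed=sub["orthologs"]
    )

    from .network import write_edge_list

    files = {
        "network": str(outdir / "ppi_edges.tsv"),
        "associations": str(outdir / "associations.tsv"),
        "compartments": str(outdir / "compartments.gmt"),
        "orthologs": str(outdir / "orthologs.tsv"),
        "expression": str(outdir / "expression.tsv"),
        "pathways": str(outdir / "pathways.gmt"),
        "truth": str(outdir / "truth.json"),
    }
    write_edge_list(network, files["network"])
    write_association_table(table, files["associations"])
    comp_coll = GeneSetCollection()
    for label, genes in compartments.items():
        comp_coll.add(label, [alias_of[g] for g in genes], description="synthetic compartment")
    write_gmt(comp_coll, files["compartments"])
    write_ortholog_table(mapping, files["orthologs"])
    from .expression import write_expression_table

    write_expression_table(expr, files["expression"])
    write_gmt(pathways, files["pathways"])

    truth = SyntheticTruth(
        rng_seed=int(rng_seed),
        network_params=truth.network_params,
        planted_affiliations=dict(cfg.affiliations),
        planted_region_enrichments=[
            (comp, region, cfg.boost) for comp, region in cfg.planted_region_enrichments
        ],
        housekeeping_fraction=cfg.housekeeping_fraction,
        housekeeping_genes=expr_truth.housekeeping_genes,
        disorder_seeds=seed_lists,
        compartment_genes={k: list(v) for k, v in compartments.items()},
        files=files,
    )
    truth.to_json(files["truth"])
    return truth
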