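"""Protein-protein interaction networks and seed-gene interactomes.

The global PPI universe is an undirected, simple graph over gene symbols.
A disease (or striatal-compartment) *interactome* is the distance-1
neighborhood of its seed genes: the seeds found in the network, all of
their direct interactors, and every interaction of the global network
whose two endpoints both fall inside that node set.  Because the subgraph
is induced, any gene linking two seed genes is automatically included as
an intermediate interactor; no separate path search is needed.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class LoadReport:
    """Bookkeeping from parsing an edge list."""

    n_lines: int = 0
    n_self_loops: int = 0
    n_duplicate_edges: int = 0


@dataclass
class PPINetwork:
    """Undirected gene-symbol graph: the global interaction universe."""

    graph: nx.Graph
    provenance: str = ""
    load_report: LoadReport = field(default_factory=LoadReport)

    @property
    def nodes(self) -> Set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> Set[frozenset]:
        return {frozenset((a, b)) for a, b in self.graph.edges}

    def neighbors(self, gene: str) -> Set[str]:
        return set(self.graph.neighbors(gene))


@dataclass
class Interactome:
    """Seed genes plus their distance-1 neighborhood as an induced subgraph."""

    label: str
    seed_genes: Set[str]
    interactor_genes: Set[str]
    edges: Set[frozenset]
    dropped_seeds: Set[str] = field(default_factory=set)

    @property
    def genes(self) -> Set[str]:
        return self.seed_genes | self.interactor_genes

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class SharedGeneSet:
    """Genes common to two interactomes."""

    label_a: str
    label_b: str
    genes: Set[str]
    size_a: int
    size_b: int

    @property
    def k(self) -> int:
        return len(self.genes)


def _normalize_symbol(raw: str) -> str:
    return raw.strip().upper()


def read_edge_list(path: str | Path, provenance: str | None = None) -> PPINetwork:
    """Load a two-column gene-symbol TSV as an undirected simple graph.

    Symbols are whitespace-trimmed and upper-cased; self-loops and duplicate
    edges (in either orientation) are dropped and counted in the load
    report.  An optional single header line is tolerated when its first
    field is not repeated as an interactor elsewhere; in practice headers
    like ``geneA\tgeneB`` simply become an isolated edge, so files written
    by this package carry no header.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1], names=["a", "b"], dtype=str
        )
    except (pd.errors.EmptyDataError, pd.errors.ParserError, ValueError):
        df = None
    if df is None or df.empty or df.isna().any().any():
        # slow path: per-line parse for exact error locations and
        # whitespace-separated files
        return _read_edge_list_slow(path, provenance)
    report = LoadReport(n_lines=len(df))
    a = df["a"].str.strip().str.upper().to_numpy()
    b = df["b"].str.strip().str.upper().to_numpy()
    if (a == "").any() or (b == "").any():
        return _read_edge_list_slow(path, provenance)
    pairs = np.sort(np.stack([a, b], axis=1), axis=1)
    loops = pairs[:, 0] == pairs[:, 1]
    report.n_self_loops = int(loops.sum())
    kept = pd.DataFrame(pairs[~loops], columns=["a", "b"])
    dup = kept.duplicated()
    report.n_duplicate_edges = int(dup.sum())
    kept = kept[~dup]
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(pairs[loops, 0])
    graph.add_edges_from(kept.itertuples(index=False, name=None))
    return PPINetwork(graph=graph, provenance=provenance or str(path), load_report=report)


def _read_edge_list_slow(path: Path, provenance: str | None) -> PPINetwork:
    graph: nx.Graph = nx.Graph()
    report = LoadReport()
    any_line = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            any_line = True
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=2 fields, got {len(fields)}"
                )
            a = _normalize_symbol(fields[0])
            b = _normalize_symbol(fields[1])
            if not a or not b:
                raise ValueError(f"{path}: line {lineno}: empty gene symbol")
            report.n_lines += 1
            if a == b:
                report.n_self_loops += 1
                graph.add_node(a)
                continue
            if graph.has_edge(a, b):
                report.n_duplicate_edges += 1
                continue
            graph.add_edge(a, b)
    if not any_line:
        raise ValueError(f"{path}: empty edge-list file")
    return PPINetwork(graph=graph, provenance=provenance or str(path), load_report=report)


def write_edge_list(network: PPINetwork, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in network.graph.edges):
            fh.write(f"{a}\t{b}\n")


def read_seed_table(
    path: str | Path, min_score: float = 0.01
) -> pd.DataFrame:
    """Read a (gene, label, score) association TSV and apply the score filter.

    Rows below ``min_score`` are dropped; the default 0.01 keeps only
    associations backed by at least one publication in DisGeNET-style
    scoring.  Returns a DataFrame with columns gene/label/score, symbols
    upper-cased, and duplicate (gene, label) pairs rejected.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["gene", "label", "score"],
        comment="#",
        skip_blank_lines=True,
        dtype={"gene": str, "label": str},
    )
    if df.empty:
        return df
    # tolerate a header row
    first = df.iloc[0]
    try:
        float(first["score"])
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    df["score"] = df["score"].astype(float)
    if ((df["score"] < 0) | (df["score"] > 1)).any():
        bad = df[(df["score"] < 0) | (df["score"] > 1)].iloc[0]
        raise ValueError(
            f"{path}: association score out of [0, 1] for gene {bad['gene']!r}"
        )
    df["gene"] = df["gene"].map(_normalize_symbol)
    df["label"] = df["label"].str.strip()
    dup = df.duplicated(subset=["gene", "label"])
    if dup.any():
        g, l = df[dup].iloc[0][["gene", "label"]]
        raise ValueError(f"{path}: duplicate (gene, label) pair ({g}, {l})")
    return df[df["score"] >= min_score].reset_index(drop=True)


def seeds_by_label(table: pd.DataFrame) -> Dict[str, Set[str]]:
    """Group a filtered seed table into label -> seed-gene set."""
    if table.empty:
        return {}
    return {
        label: set(sub["gene"]) for label, sub in table.groupby("label", sort=True)
    }


def read_ortholog_table(path: str | Path) -> Dict[str, Set[str]]:
    """Read a two-column source->target symbol mapping (one-to-many allowed)."""
    path = Path(path)
    mapping: Dict[str, Set[str]] = {}
    any_row = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 fields, got {len(fields)}"
                )
            src = _normalize_symbol(fields[0])
            dst = _normalize_symbol(fields[1])
            mapping.setdefault(src, set()).add(dst)
            any_row = True
    if not any_row:
        raise ValueError(f"{path}: empty ortholog mapping table")
    return mapping


def map_orthologs(
    genes: Iterable[str], mapping: Mapping[str, Set[str]]
) -> Tuple[Set[str], Set[str]]:
    """Map symbols through an ortholog table.

    Returns ``(mapped, unmapped)``: the union of the images of all mapped
    genes, and the genes absent from the table (reported, never silently
    dropped).
    """
    if not mapping:
        raise ValueError("empty ortholog mapping table")
    mapped: Set[str] = set()
    unmapped: Set[str] = set()
    for g in genes:
        g = _normalize_symbol(g)
        if g in mapping:
            mapped.update(mapping[g])
        else:
            unmapped.add(g)
    return mapped, unmapped


def build_interactome(
    network: PPINetwork, seeds: Iterable[str], label: str
) -> Interactome:
    """Construct the distance-1 interactome of ``seeds`` in ``network``.

    Node set: seeds present in the network plus all of their direct
    neighbors.  Edge set: the induced subgraph on those nodes.  Seeds
    absent from the network are recorded in ``dropped_seeds``; it is an
    error only when no seed at all is present.
    """
    seed_set = {_normalize_symbol(s) for s in seeds}
    if not seed_set:
        raise ValueError(f"interactome {label!r}: no seeds given")
    present = seed_set & set(network.graph.nodes)
    dropped = seed_set - present
    if not present:
        raise ValueError(
            f"interactome {label!r}: none of the {len(seed_set)} seeds are in the network"
        )
    interactors: Set[str] = set()
    for s in present:
        interactors.update(network.graph.neighbors(s))
    interactors -= present
    node_set = present | interactors
    sub = network.graph.subgraph(node_set)
    edges = {frozenset((a, b)) for a, b in sub.edges}
    return Interactome(
        label=label,
        seed_genes=present,
        interactor_genes=interactors,
        edges=edges,
        dropped_seeds=dropped,
    )


def interactome_overlap(a: Interactome, b: Interactome) -> SharedGeneSet:
    """Genes common to two interactomes (symmetric)."""
    if not a.genes or not b.genes:
        raise ValueError("interactome overlap requires two non-empty interactomes")
    return SharedGeneSet(
        label_a=a.label,
        label_b=b.label,
        genes=a.genes & b.genes,
        size_a=a.n_genes,
        size_b=b.n_genes,
    )


def shared_core(interactomes: Sequence[Interactome]) -> Set[str]:
    """Genes present in every given interactome."""
    if len(interactomes) < 2:
        raise ValueError("shared_core needs at least 2 interactomes")
    out = set(interactomes[0].genes)
    for i in interactomes[1:]:
        out &= i.genes
    return out


def exclusive_to(target: Interactome, others: Sequence[Interactome]) -> Set[str]:
    """Genes of ``target`` not found in any of ``others``."""
    if not others:
        raise ValueError("exclusive_to needs a non-empty list of other interactomes")
    union: Set[str] = set()
    for o in others:
        union |= o.genes
    return target.genes - union


def overlap_fraction(k: int, total: int, decimals: int = 0) -> float:
    """Percentage 100*k/total, half-up rounded to ``decimals`` places."""
    if total <= 0:
        raise ValueError("overlap_fraction: total must be positive")
    if not 0 <= k <= total:
        raise ValueError("overlap_fraction: need 0 <= k <= total")
    pct = decimal.Decimal(100 * k) / decimal.Decimal(total)
    quantum = decimal.Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=decimal.ROUND_HALF_UP))


def write_interactome(interactome: Interactome, outdir: str | Path) -> Dict[str, str]:
    """Write node/edge TSVs and a JSON-able summary; returns file paths."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = interactome.label.replace(" ", "_")
    nodes_path = outdir / f"{tag}.nodes.tsv"
    edges_path = outdir / f"{tag}.edges.tsv"
    summary_path = outdir / f"{tag}.summary.json"
    with nodes_path.open("w") as fh:
        fh.write("gene\trole\n")
        for g in sorted(interactome.seed_genes):
            fh.write(f"{g}\tseed\n")
        for g in sorted(interactome.interactor_genes):
            fh.write(f"{g}\tinteractor\n")
    with edges_path.open("w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in interactome.edges):
            fh.write(f"{a}\t{b}\n")
    summary = {
        "label": interactome.label,
        "n_genes": interactome.n_genes,
        "n_ppis": interactome.n_edges,
        "n_seeds": len(interactome.seed_genes),
        "dropped_seeds": sorted(interactome.dropped_seeds),
    }
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return {
        "nodes": str(nodes_path),
        "edges": str(edges_path),
        "summary": str(summary_path),
    }
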