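"""Named gene-set collections and GMT (gene matrix transpose) file I/O.

A GMT file is line-oriented: set name, description, then member genes, all
tab-separated.  Collections preserve insertion order of sets and member
order within a set (after de-duplication), so a write/read round trip is
the identity on canonical files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Tuple


@dataclass
class GeneSetCollection:
    """Ordered mapping of set name -> (description, member gene list)."""

    sets: Dict[str, Tuple[str, List[str]]] = field(default_factory=dict)

    def add(self, name: str, genes: Iterable[str], description: str = "") -> None:
        if name in self.sets:
            raise ValueError(f"duplicate gene-set name: {name!r}")
        deduped: List[str] = []
        seen = set()
        n_dup = 0
        for g in genes:
            if g in seen:
                n_dup += 1
                continue
            seen.add(g)
            deduped.append(g)
        if n_dup:
            warnings.warn(f"gene set {name!r}: removed {n_dup} duplicate gene(s)")
        self.sets[name] = (description, deduped)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets

    def names(self) -> List[str]:
        return list(self.sets)

    def genes(self, name: str) -> List[str]:
        return list(self.sets[name][1])

    def description(self, name: str) -> str:
        return self.sets[name][0]

    def all_genes(self) -> set:
        out: set = set()
        for _, members in self.sets.values():
            out.update(members)
        return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file.

    Each line must carry at least a set name and a description; lines with
    fewer than two fields are an error.  Duplicate genes within a line are
    dropped with a warning.
    """
    path = Path(path)
    coll = GeneSetCollection()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need >=2 tab-separated "
                    f"fields (name, description), got {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g.strip() for g in genes if g.strip()]
            if not genes:
                warnings.warn(f"{path}: line {lineno}: gene set {name!r} is empty")
            coll.add(name, genes, desc)
    return coll


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT; empty sets are written with a warning."""
    path = Path(path)
    with path.open("w") as fh:
        for name in collection:
            desc = collection.description(name)
            genes = collection.genes(name)
            if not genes:
                warnings.warn(f"writing empty gene set {name!r} to {path}")
            fh.write("\t".join([name, desc, *genes]) + "\n")
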