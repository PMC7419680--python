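"""Gene sets and multi-gene signatures (GMT parsing and universe handling)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

ROLES = {"erk_axis", "akt_axis", "immune_celltype", "signature", "generic"}


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols with a pipeline role tag."""

    name: str
    genes: frozenset
    role: str = "generic"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        clean = frozenset(str(g).strip().upper() for g in self.genes)
        object.__setattr__(self, "genes", clean)

    def __len__(self) -> int:
        return len(self.genes)


class GeneSetCollection:
    """An ordered mapping of unique set names to :class:`GeneSet`."""

    def __init__(self, sets: Iterable[GeneSet] = ()) -> None:
        self._sets: Dict[str, GeneSet] = {}
        for s in sets:
            self.add(s)

    def add(self, s: GeneSet) -> None:
        if s.name in self._sets:
            raise ValueError(f"duplicate gene set name {s.name!r}")
        self._sets[s.name] = s

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def with_role(self, role: str) -> "GeneSetCollection":
        return GeneSetCollection(s for s in self if s.role == role)


def read_gmt(path, role: str = "generic") -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene...`` per line.

    Duplicate genes within a line are de-duplicated; a line with fewer than
    three fields or a repeated set name is an error.
    """
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected >=3 tab-separated fields")
            name, description, *genes = fields
            genes = [g for g in genes if g.strip()]
            if not genes:
                raise ValueError(f"line {lineno}: gene set {name!r} has no genes")
            set_role = role
            if description.startswith("role:") and description[5:] in ROLES:
                set_role = description[5:]  # role tag round-tripped by write_gmt
            collection.add(GeneSet(name, frozenset(genes), role=set_role, description=description))
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            genes = "\t".join(sorted(s.genes))
            description = s.description or f"role:{s.role}"
            fh.write(f"{s.name}\t{description}\t{genes}\n")


def read_gene_list(path) -> list[str]:
    """Read a one-symbol-per-line signature list."""
    with open(path) as fh:
        return [ln.strip().upper() for ln in fh if ln.strip()]


def restrict_to_universe(
    collection: GeneSetCollection,
    universe: Sequence[str],
    min_size: int = 5,
) -> GeneSetCollection:
    """Intersect every set with the measured-gene universe.

    Sets falling below ``min_size`` surviving genes are dropped and logged;
    the operation is idempotent.
    """
    uni = frozenset(str(g).strip().upper() for g in universe)
    kept = GeneSetCollection()
    for s in collection:
        surviving = s.genes & uni
        if len(surviving) < min_size:
            logger.warning(
                "dropping gene set %r: %d of %d genes in universe (min %d)",
                s.name, len(surviving), len(s.genes), min_size,
            )
            continue
        kept.add(GeneSet(s.name, surviving, role=s.role, description=s.description))
    return kept
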