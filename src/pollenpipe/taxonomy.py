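"""NCBI-style taxonomy: taxdump parsing and lineage queries.

Assignments are made at five ranks — species, genus, tribe, family, order —
plus a target-kingdom test (is the taxon within Viridiplantae, the green
plants).  The tree is loaded from ``nodes.dmp`` / ``names.dmp`` dialect files
(pipe-delimited, scientific-name class) and validated: exactly one root
(parent == self), no cycles, every node reachable from the root.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

logger = logging.getLogger(__name__)

ASSIGNMENT_RANKS = ("species", "genus", "tribe", "family", "order")
TARGET_KINGDOM_NAME = "Viridiplantae"


class TaxonomyError(ValueError):
    pass


@dataclass(frozen=True)
class RankVector:
    """(taxid, name) per assignment rank; None where the lineage lacks the
    rank (e.g. many lineages have no tribe node)."""

    species: tuple[int, str] | None = None
    genus: tuple[int, str] | None = None
    tribe: tuple[int, str] | None = None
    family: tuple[int, str] | None = None
    order: tuple[int, str] | None = None

    def at(self, rank: str) -> tuple[int, str] | None:
        return getattr(self, rank)


def _parse_dmp_line(line: str) -> list[str]:
    return [f.strip("\t") for f in line.rstrip("\t|\n").split("|")]


class TaxonomyTree:
    """In-memory taxonomy with memoized lineage walks."""

    def __init__(self, nodes: dict[int, tuple[int, str]],
                 names: dict[int, str],
                 target_root: int | None = None,
                 merged: dict[int, int] | None = None):
        self.nodes = nodes
        self.names = names
        self.merged = merged or {}
        self._lineage_cache: dict[int, tuple[int, ...]] = {}
        self._validate()
        if target_root is None:
            target_root = next(
                (t for t, n in names.items() if n == TARGET_KINGDOM_NAME),
                self.root)
        self.target_root = target_root

    # -- construction and validation

    def _validate(self) -> None:
        roots = [t for t, (p, _) in self.nodes.items() if p == t]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {roots}")
        self.root = roots[0]
        for taxid, (parent, _) in self.nodes.items():
            if parent not in self.nodes:
                raise TaxonomyError(
                    f"taxid {taxid} has unknown parent {parent}")
        for taxid in self.nodes:
            self._walk(taxid)  # raises on cycles / unreachable nodes

    def _walk(self, taxid: int) -> tuple[int, ...]:
        cached = self._lineage_cache.get(taxid)
        if cached is not None:
            return cached
        chain, seen, t = [], set(), taxid
        while True:
            if t in seen:
                raise TaxonomyError(f"cycle detected at taxid {t}")
            seen.add(t)
            chain.append(t)
            parent = self.nodes[t][0]
            if parent == t:
                break
            t = parent
        result = tuple(chain)
        self._lineage_cache[taxid] = result
        return result

    # -- queries

    def resolve(self, taxid: int) -> int:
        """Follow merged-taxid redirections, if any."""
        return self.merged.get(taxid, taxid)

    def lineage(self, taxid: int) -> tuple[int, ...]:
        """Ancestor-or-self chain from ``taxid`` up to the root."""
        taxid = self.resolve(taxid)
        if taxid not in self.nodes:
            raise TaxonomyError(f"unknown taxid {taxid}")
        return self._walk(taxid)

    def rank(self, taxid: int) -> str:
        return self.nodes[self.resolve(taxid)][1]

    def name(self, taxid: int) -> str:
        return self.names.get(self.resolve(taxid), f"taxid:{taxid}")

    def rank_vector(self, taxid: int) -> RankVector:
        """First ancestor-or-self node labeled with each assignment rank."""
        slots: dict[str, tuple[int, str]] = {}
        for t in self.lineage(taxid):
            r = self.nodes[t][1]
            if r in ASSIGNMENT_RANKS and r not in slots:
                slots[r] = (t, self.name(t))
        return RankVector(**slots)

    def in_target(self, taxid: int) -> bool:
        """True iff the target kingdom root is an ancestor-or-self."""
        return self.target_root in self.lineage(taxid)

    def lineage_names(self, taxid: int) -> list[str]:
        return [self.name(t) for t in self.lineage(taxid)]


def load_taxdump(nodes_file, names_file,
                 merged_file=None, target_root: int | None = None
                 ) -> TaxonomyTree:
    """Parse nodes.dmp / names.dmp (and optionally merged.dmp)."""
    nodes: dict[int, tuple[int, str]] = {}
    with open(nodes_file) as fh:
        for line in fh:
            fields = _parse_dmp_line(line)
            if len(fields) < 3:
                raise TaxonomyError(f"malformed nodes line: {line!r}")
            nodes[int(fields[0])] = (int(fields[1]), fields[2])

    names: dict[int, str] = {}
    with open(names_file) as fh:
        for line in fh:
            fields = _parse_dmp_line(line)
            if len(fields) < 4:
                raise TaxonomyError(f"malformed names line: {line!r}")
            taxid, name, _, name_class = fields[:4]
            if name_class != "scientific name":
                continue
            taxid = int(taxid)
            if taxid in names:
                logger.warning(
                    "duplicate scientific name for taxid %d: %r replaces %r",
                    taxid, name, names[taxid])
            names[taxid] = name

    merged: dict[int, int] = {}
    if merged_file is not None:
        with open(merged_file) as fh:
            for line in fh:
                fields = _parse_dmp_line(line)
                merged[int(fields[0])] = int(fields[1])

    return TaxonomyTree(nodes, names, target_root=target_root, merged=merged)


def load_accession_map(path) -> dict[str, int]:
    """Two-column TSV: accession <tab> taxid."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            acc, taxid = line.split("\t")[:2]
            out[acc.strip()] = int(taxid)
    return out


def write_accession_map(acc2taxid: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for acc in sorted(acc2taxid):
            fh.write(f"{acc}\t{acc2taxid[acc]}\n")
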