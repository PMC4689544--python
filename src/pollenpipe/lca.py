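"""Paired-read naive lowest-common-ancestor (LCA) taxonomic assignment.

Each OTU is represented by its two component reads.  For every candidate
taxon at a given rank, the combined score is the best bit score that taxon
achieves with mate 1 plus the best it achieves with mate 2.  Working from
species upward through genus, tribe, family and order, the OTU is assigned
at the first rank where exactly one taxon has a combined score > 600 that
is also within 3% of the best combined score; otherwise that rank is
undetermined and the next coarser rank is tried.  Requiring support from
*both* mates makes single-read matches insufficient by construction and
turns taxonomic discordance between mates into a strong chimera filter.

At the 600-bit acceptance threshold the 3% relative window corresponds to a
minimum absolute bit-score margin of 18 bits.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .taxonomy import ASSIGNMENT_RANKS, TaxonomyTree

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HspRecord:
    """One BLAST-style high-scoring pair for a mate-qualified read."""

    read_id: str
    accession: str
    bit_score: float
    percent_identity: float
    taxid: int

    def __post_init__(self):
        if self.bit_score <= 0:
            raise ValueError("bit_score must be positive")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent_identity must be in [0, 100]")


@dataclass(frozen=True)
class LcaParams:
    top_accessions: int = 25
    min_combined_score: float = 600.0
    rel_window: float = 0.03
    conflict_min_bit: float = 200.0
    ranks: tuple[str, ...] = ASSIGNMENT_RANKS

    def __post_init__(self):
        if not 0 < self.rel_window < 1:
            raise ValueError("rel_window must be in (0, 1)")
        if self.top_accessions < 1:
            raise ValueError("top_accessions must be >= 1")

    @property
    def min_margin_at_threshold(self) -> float:
        """Implied minimum absolute bit-score margin for a candidate at the
        acceptance threshold (600 * 0.03 = 18 bits under the defaults)."""
        return self.min_combined_score * self.rel_window


@dataclass
class Assignment:
    otu_id: str
    assigned_rank: str | None = None
    taxid: int | None = None
    taxon_name: str | None = None
    combined_score: float = 0.0
    mean_percent_identity: float = 0.0
    mean_bit_score: float = 0.0
    in_target: bool = False
    conflict_flag: bool = False

    @property
    def assigned(self) -> bool:
        return self.assigned_rank is not None


@dataclass(frozen=True)
class CurationRule:
    """Post-hoc curation: HSP exclusions and assignment rewrites.

    kinds:
      exclude_accession(accessions)           — drop HSPs to these accessions
      exclude_name_substring(substring)       — drop HSPs whose lineage names
                                                contain the substring
      reassign_taxon(match_name, target_name, target_rank)
      merge_species(names, target_name)
    """

    kind: str
    accessions: tuple[str, ...] = ()
    substring: str = ""
    match_name: str = ""
    target_name: str = ""
    target_rank: str = ""
    names: tuple[str, ...] = ()

    _KINDS = ("exclude_accession", "exclude_name_substring",
              "reassign_taxon", "merge_species")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown curation rule kind {self.kind!r}")


# ---------------------------------------------------------------------------
# HSP table parsing


def parse_hsp_table(path, acc2taxid: Mapping[str, int] | None = None,
                    params: LcaParams = LcaParams()) -> list[HspRecord]:
    """Parse a BLAST outfmt-6 style tabular file.

    Expected columns: qseqid sseqid pident length mismatch gapopen qstart
    qend sstart send evalue bitscore [staxids].  Per (read, accession) only
    the best-scoring HSP is kept; per read, only HSPs to the top
    ``top_accessions`` distinct accessions by bit score are retained.
    """
    best: dict[tuple[str, str], HspRecord] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 12 tab-separated columns")
            try:
                read_id, accession = fields[0], fields[1]
                pident = float(fields[2])
                bit = float(fields[11])
                if len(fields) > 12 and fields[12]:
                    taxid = int(fields[12].split(";")[0])
                elif acc2taxid is not None:
                    taxid = acc2taxid[accession]
                else:
                    raise KeyError(
                        "no staxids column and no accession map given")
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            key = (read_id, accession)
            if key not in best or bit > best[key].bit_score:
                best[key] = HspRecord(read_id, accession, bit, pident, taxid)

    return keep_top_accessions(best.values(), params.top_accessions)


def keep_top_accessions(hsps: Iterable[HspRecord], top: int
                        ) -> list[HspRecord]:
    """Per read, retain HSPs of the top-N distinct accessions by bit score
    (deterministic: accession id breaks score ties)."""
    by_read: dict[str, list[HspRecord]] = defaultdict(list)
    for h in hsps:
        by_read[h.read_id].append(h)
    out: list[HspRecord] = []
    for read_id in sorted(by_read):
        ranked = sorted(by_read[read_id],
                        key=lambda h: (-h.bit_score, h.accession))
        out.extend(ranked[:top])
    return out


def filter_accessions(hsps: Sequence[HspRecord],
                      rules: Sequence[CurationRule],
                      tree: TaxonomyTree) -> list[HspRecord]:
    """Drop HSPs excluded by accession or by lineage-name substring (e.g.
    accessions whose taxonomy contains "environmental sample")."""
    excluded_accs: set[str] = set()
    substrings: list[str] = []
    for rule in rules:
        if rule.kind == "exclude_accession":
            excluded_accs.update(rule.accessions)
        elif rule.kind == "exclude_name_substring":
            substrings.append(rule.substring.lower())
    out = []
    lineage_cache: dict[int, str] = {}
    for h in hsps:
        if h.accession in excluded_accs:
            continue
        if substrings:
            blob = lineage_cache.get(h.taxid)
            if blob is None:
                blob = "; ".join(tree.lineage_names(h.taxid)).lower()
                lineage_cache[h.taxid] = blob
            if any(s in blob for s in substrings):
                continue
        out.append(h)
    return out


# ---------------------------------------------------------------------------
# The paired-read LCA


def paired_lca(hsps_mate1: Sequence[HspRecord],
               hsps_mate2: Sequence[HspRecord],
               tree: TaxonomyTree,
               params: LcaParams = LcaParams(),
               otu_id: str = "") -> Assignment:
    """Assign one OTU from its two mates' HSP lists.

    See the module docstring for the algorithm.  A mate with no HSP for a
    taxon contributes nothing to that taxon's combined score; an OTU with an
    empty HSP list on either mate is unassigned outright.
    """
    assignment = Assignment(otu_id=otu_id)
    assignment.conflict_flag = _conflict(hsps_mate1, hsps_mate2, tree, params)
    if not hsps_mate1 or not hsps_mate2:
        return assignment

    for rank in params.ranks:
        combined: dict[int, float] = {}
        names: dict[int, str] = {}
        per_mate_best: list[dict[int, float]] = []
        for mate_hsps in (hsps_mate1, hsps_mate2):
            best: dict[int, float] = {}
            for h in mate_hsps:
                slot = tree.rank_vector(h.taxid).at(rank)
                if slot is None:
                    continue
                taxid, name = slot
                names[taxid] = name
                if h.bit_score > best.get(taxid, 0.0):
                    best[taxid] = h.bit_score
            per_mate_best.append(best)
        for taxid in set(per_mate_best[0]) | set(per_mate_best[1]):
            combined[taxid] = (per_mate_best[0].get(taxid, 0.0)
                               + per_mate_best[1].get(taxid, 0.0))
        if not combined:
            continue
        top = max(combined.values())
        qualifying = [t for t, c in combined.items()
                      if c > params.min_combined_score
                      and c >= (1.0 - params.rel_window) * top]
        if len(qualifying) == 1:
            winner = qualifying[0]
            winner_hsps = [
                h for h in list(hsps_mate1) + list(hsps_mate2)
                if (tree.rank_vector(h.taxid).at(rank) or (None,))[0] == winner
            ]
            assignment.assigned_rank = rank
            assignment.taxid = winner
            assignment.taxon_name = names[winner]
            assignment.combined_score = combined[winner]
            assignment.mean_percent_identity = (
                sum(h.percent_identity for h in winner_hsps)
                / len(winner_hsps))
            assignment.mean_bit_score = (
                sum(h.bit_score for h in winner_hsps) / len(winner_hsps))
            assignment.in_target = tree.in_target(winner)
            return assignment
    return assignment


def _conflict(hsps1, hsps2, tree, params) -> bool:
    """Strong but incompatible family-level best matches between mates —
    instrumentation for likely chimeras; never used in assignment logic."""
    tops = []
    for hsps in (hsps1, hsps2):
        if not hsps:
            return False
        best = max(hsps, key=lambda h: h.bit_score)
        if best.bit_score < params.conflict_min_bit:
            return False
        fam = tree.rank_vector(best.taxid).at("family")
        tops.append(fam[0] if fam else None)
    return tops[0] is not None and tops[1] is not None and tops[0] != tops[1]


# ---------------------------------------------------------------------------
# Post-hoc curation and summaries


def apply_curation(assignments: Sequence[Assignment],
                   rules: Sequence[CurationRule],
                   tree: TaxonomyTree) -> list[Assignment]:
    """Apply reassign_taxon / merge_species rules, in declared order."""
    name_to_taxid = {name: taxid for taxid, name in tree.names.items()}
    out = list(assignments)
    for rule in rules:
        if rule.kind in ("exclude_accession", "exclude_name_substring"):
            continue  # HSP-level rules, handled by filter_accessions
        if rule.kind == "reassign_taxon":
            if rule.target_name not in name_to_taxid:
                raise ValueError(
                    f"curation rule targets unknown taxon {rule.target_name!r}")
            taxid = name_to_taxid[rule.target_name]
            for a in out:
                if a.taxon_name == rule.match_name:
                    a.assigned_rank = rule.target_rank
                    a.taxid = taxid
                    a.taxon_name = rule.target_name
                    a.in_target = tree.in_target(taxid)
        elif rule.kind == "merge_species":
            if rule.target_name not in name_to_taxid:
                raise ValueError(
                    f"curation rule targets unknown taxon {rule.target_name!r}")
            taxid = name_to_taxid[rule.target_name]
            for a in out:
                if a.assigned_rank == "species" and a.taxon_name in rule.names:
                    a.taxid = taxid
                    a.taxon_name = rule.target_name
                    a.in_target = tree.in_target(taxid)
    return out


def assignment_rank_summary(assignments: Sequence[Assignment],
                            counts: Mapping[str, int]):
    """Fractions of OTUs and of mapped read pairs per assigned rank, with
    non-target and unassigned bins; each basis sums to 1."""
    import pandas as pd

    bins = list(ASSIGNMENT_RANKS) + ["non_target", "unassigned"]
    otu_n = {b: 0 for b in bins}
    read_n = {b: 0 for b in bins}
    for a in assignments:
        if not a.assigned:
            b = "unassigned"
        elif not a.in_target:
            b = "non_target"
        else:
            b = a.assigned_rank
        otu_n[b] += 1
        read_n[b] += counts.get(a.otu_id, 0)
    total_otus = sum(otu_n.values())
    total_reads = sum(read_n.values())
    return pd.DataFrame({
        "bin": bins,
        "n_otus": [otu_n[b] for b in bins],
        "fraction_otus": [otu_n[b] / total_otus if total_otus else 0.0
                          for b in bins],
        "n_read_pairs": [read_n[b] for b in bins],
        "fraction_read_pairs": [read_n[b] / total_reads if total_reads
                                else 0.0 for b in bins],
    })


def write_assignments_tsv(assignments: Sequence[Assignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("otu_id\trank\ttaxid\tname\tcombined_score\t"
                 "mean_pid\tmean_bit\tin_target\tconflict\n")
        for a in assignments:
            fh.write("\t".join([
                a.otu_id, a.assigned_rank or "NA",
                str(a.taxid) if a.taxid is not None else "NA",
                a.taxon_name or "NA",
                f"{a.combined_score:.1f}", f"{a.mean_percent_identity:.2f}",
                f"{a.mean_bit_score:.1f}", str(int(a.in_target)),
                str(int(a.conflict_flag)),
            ]) + "\n")
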