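"""OTU picking: reference-seeded binning, greedy 97% clustering with a
recapture pass, pair-to-OTU mapping, consensus building, and chimera-score
filtering.

The clustering unit is the masked scaffold (read1 + 30-N linker +
revcomp(read2)).  Identity between two scaffolds is computed piecewise on
the read-1 and read-2 segments with global (Needleman-Wunsch) alignment via
edlib; linker and masked N positions are excluded from both numerator and
denominator, and the denominator is the informative length of the *shorter*
scaffold (CD-HIT convention).

Binning emulates a concordant paired-end mapping against a pre-clustered
reference database: candidate references are pre-filtered by shared 12-mers,
each segment is aligned in infix mode, and a pair is binned only when both
mates hit the same accession in the proper orientation with an implied
insert <= 1100 bp.  The binning alignment itself is discarded — it only
partitions the clustering work.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib

from ._seq import kmer_set
from .scaffold import LINKER_LEN, Scaffold

logger = logging.getLogger(__name__)

KMER_K = 12
KMER_QUERY_STEP = 3


@dataclass(frozen=True)
class RefSeq:
    accession: str
    sequence: str
    taxid: int


@dataclass
class ReferenceDb:
    accessions: list[RefSeq]

    def __post_init__(self):
        ids = [r.accession for r in self.accessions]
        if len(ids) != len(set(ids)):
            raise ValueError("reference accession ids must be unique")
        self._by_acc = {r.accession: r for r in self.accessions}

    def __len__(self) -> int:
        return len(self.accessions)

    def get(self, accession: str) -> RefSeq:
        return self._by_acc[accession]

    @classmethod
    def from_fasta(cls, path, acc2taxid: dict[str, int]) -> "ReferenceDb":
        from Bio import SeqIO
        refs = []
        for rec in SeqIO.parse(str(path), "fasta"):
            acc = rec.id
            if acc not in acc2taxid:
                logger.warning("accession %s has no taxid; dropped", acc)
                continue
            refs.append(RefSeq(acc, str(rec.seq).upper(), acc2taxid[acc]))
        return cls(refs)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.accessions:
                fh.write(f">{r.accession} taxid={r.taxid}\n{r.sequence}\n")


@dataclass
class Otu:
    otu_id: str
    representative: Scaffold
    member_ids: list[str] = field(default_factory=list)
    consensus: str | None = None
    chimera_score: float | None = None

    @property
    def consensus_or_rep(self) -> str:
        return self.consensus if self.consensus is not None \
            else self.representative.sequence

    def consensus_scaffold(self) -> Scaffold:
        """The consensus in scaffold coordinates (falls back to the
        representative when no consensus has been built)."""
        rep = self.representative
        if self.consensus is None:
            return rep
        return Scaffold(self.otu_id, self.consensus, rep.len1, rep.len2,
                        rep.sample_id)


@dataclass(frozen=True)
class MapParams:
    min_identity: float = 0.97
    max_indel_positions: int = 5
    max_insert: int = 1100
    min_bin_identity: float = 0.85
    per_mate_identity: bool = False

    def __post_init__(self):
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")


@dataclass(frozen=True)
class AlnStats:
    matches: int
    mismatches: int
    indels: int
    tstart: int
    tend: int  # exclusive

    @property
    def columns(self) -> int:
        return self.matches + self.mismatches + self.indels

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def align_segments(query: str, target: str, mode: str = "NW",
                   project: bool = False) -> tuple[AlnStats, str | None]:
    """edlib alignment of two segments with N-aware column accounting.

    Columns where either side is N are skipped entirely (masked or linker
    positions carry no information).  With ``project=True`` also returns the
    query projected onto target coordinates ('.' = uncovered, '-' = deletion
    relative to the target).
    """
    if not query or not target:
        return AlnStats(0, 0, 0, 0, 0), None
    res = edlib.align(query, target, mode=mode, task="path")
    if res["editDistance"] < 0 or res["cigar"] is None:
        return AlnStats(0, 0, 0, 0, 0), None
    tstart, tend = res["locations"][0]
    tend += 1

    if not project and "N" not in query and "N" not in target:
        # aggregate directly from the cigar run lengths
        matches = mismatches = indels = 0
        for length, op in _parse_cigar(res["cigar"]):
            if op == "=":
                matches += length
            elif op == "X":
                mismatches += length
            else:
                indels += length
        return AlnStats(matches, mismatches, indels, tstart, tend), None

    proj = ["."] * len(target) if project else None
    qi, ti = 0, tstart
    matches = mismatches = indels = 0
    for length, op in _parse_cigar(res["cigar"]):
        if op == "=":
            qchunk = query[qi:qi + length]
            tchunk = target[ti:ti + length]
            if "N" in qchunk or "N" in tchunk:
                for k in range(length):
                    if qchunk[k] != "N" and tchunk[k] != "N":
                        matches += 1
            else:
                matches += length
            if proj is not None:
                proj[ti:ti + length] = qchunk
            qi += length
            ti += length
        elif op == "X":
            qchunk = query[qi:qi + length]
            tchunk = target[ti:ti + length]
            for k in range(length):
                if qchunk[k] != "N" and tchunk[k] != "N":
                    mismatches += 1
            if proj is not None:
                proj[ti:ti + length] = qchunk
            qi += length
        elif op == "I":  # present in query, absent from target
            chunk = query[qi:qi + length]
            indels += length - chunk.count("N")
            qi += length
        elif op == "D":  # gap in query relative to target
            chunk = target[ti:ti + length]
            if proj is not None:
                proj[ti:ti + length] = "-" * length
            indels += length - chunk.count("N")
            ti += length
        else:  # pragma: no cover - edlib emits only =/X/I/D
            raise ValueError(f"unexpected cigar op {op!r}")
    stats = AlnStats(matches, mismatches, indels, tstart, ti)
    return stats, ("".join(proj) if proj is not None else None)


def informative_length(scaffold: Scaffold) -> int:
    return sum(1 for b in scaffold.seg1 if b != "N") + \
        sum(1 for b in scaffold.seg2 if b != "N")


def scaffold_identity(a: Scaffold, b: Scaffold) -> float:
    """Piecewise identity: matches on seg1 + seg2 over the informative
    length of the shorter scaffold."""
    s1, _ = align_segments(a.seg1, b.seg1, mode="NW")
    s2, _ = align_segments(a.seg2, b.seg2, mode="NW")
    denom = min(informative_length(a), informative_length(b))
    if denom == 0:
        return 0.0
    return (s1.matches + s2.matches) / denom


# ---------------------------------------------------------------------------
# Reference pre-clustering and binning


def precluster_reference(db: ReferenceDb, threshold: float = 0.95
                         ) -> tuple[ReferenceDb, dict[str, str]]:
    """Greedy length-sorted clustering of reference sequences; returns the
    representative-only database and accession -> cluster-representative map."""
    order = sorted(db.accessions, key=lambda r: (-len(r.sequence), r.accession))
    reps: list[RefSeq] = []
    membership: dict[str, str] = {}
    for ref in order:
        joined = False
        for rep in reps:
            res = edlib.align(ref.sequence, rep.sequence, mode="NW",
                              task="distance")
            shorter = min(len(ref.sequence), len(rep.sequence))
            ident = 1.0 - res["editDistance"] / shorter if shorter else 0.0
            if ident >= threshold:
                membership[ref.accession] = rep.accession
                joined = True
                break
        if not joined:
            reps.append(ref)
            membership[ref.accession] = ref.accession
    return ReferenceDb(reps), membership


def _ref_kmer_index(db: ReferenceDb) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i, ref in enumerate(db.accessions):
        for km in kmer_set(ref.sequence, KMER_K):
            index[km].append(i)
    return dict(index)


def bin_pairs(scaffolds: Sequence[Scaffold], ref: ReferenceDb,
              params: MapParams = MapParams(),
              clusters: dict[str, str] | None = None,
              max_candidates: int = 3
              ) -> tuple[dict[str, list[str]], list[str]]:
    """Assign each pair (scaffold) to the reference cluster of its best
    concordant mapping; pairs with no qualifying mapping are unbinned.

    A mapping qualifies when both segments align to the same accession, in
    proper relative orientation, each at >= ``min_bin_identity``, with an
    implied insert in (0, ``max_insert``].
    """
    if len(ref) == 0:
        raise ValueError("reference database is empty")
    index = _ref_kmer_index(ref)
    bins: dict[str, list[str]] = defaultdict(list)
    unbinned: list[str] = []
    for sc in scaffolds:
        counts: Counter[int] = Counter()
        for seg in (sc.seg1, sc.seg2):
            for km in kmer_set(seg, KMER_K, step=KMER_QUERY_STEP):
                for i in index.get(km, ()):
                    counts[i] += 1
        candidates = [i for i, _ in counts.most_common(max_candidates)]
        best_acc, best_ed = None, None
        for i in candidates:
            refseq = ref.accessions[i]
            r1 = edlib.align(sc.seg1, refseq.sequence, mode="HW",
                             task="locations")
            r2 = edlib.align(sc.seg2, refseq.sequence, mode="HW",
                             task="locations")
            if r1["editDistance"] < 0 or r2["editDistance"] < 0:
                continue
            id1 = 1.0 - r1["editDistance"] / max(len(sc.seg1), 1)
            id2 = 1.0 - r2["editDistance"] / max(len(sc.seg2), 1)
            if min(id1, id2) < params.min_bin_identity:
                continue
            t1s = r1["locations"][0][0]
            t2s, t2e = r2["locations"][0]
            insert = t2e + 1 - t1s
            if t1s > t2s or not 0 < insert <= params.max_insert:
                continue
            ed = r1["editDistance"] + r2["editDistance"]
            if best_ed is None or ed < best_ed:
                best_ed, best_acc = ed, refseq.accession
        if best_acc is None:
            unbinned.append(sc.id)
        else:
            key = clusters.get(best_acc, best_acc) if clusters else best_acc
            bins[key].append(sc.id)
    return dict(bins), unbinned


# ---------------------------------------------------------------------------
# Greedy clustering


def _scaffold_kmers(sc: Scaffold) -> set[str]:
    return kmer_set(sc.seg1, KMER_K) | kmer_set(sc.seg2, KMER_K)


def greedy_cluster(scaffolds: Sequence[Scaffold], threshold: float = 0.97,
                   id_prefix: str = "OTU", start_index: int = 1) -> list[Otu]:
    """Length-sorted greedy clustering at the given identity threshold.

    Scaffolds are visited in order of descending combined length (id as
    tie-break); each joins the first existing cluster whose representative
    it matches at >= threshold, else founds a new cluster.  Deterministic
    given the input set.
    """
    order = sorted(scaffolds, key=lambda s: (-s.combined_length, s.id))
    otus: list[Otu] = []
    rep_kmers: list[set[str]] = []
    for sc in order:
        sc_kmers = None
        joined = False
        for otu, kms in zip(otus, rep_kmers):
            if sc_kmers is None:
                sc_kmers = _scaffold_kmers(sc)
            if kms and sc_kmers and not (kms & sc_kmers):
                continue
            if scaffold_identity(sc, otu.representative) >= threshold:
                otu.member_ids.append(sc.id)
                joined = True
                break
        if not joined:
            otu_id = f"{id_prefix}{start_index + len(otus):06d}"
            otus.append(Otu(otu_id, sc, [sc.id]))
            rep_kmers.append(sc_kmers if sc_kmers is not None
                             else _scaffold_kmers(sc))
    return otus


def recapture_unclustered(scaffolds: Sequence[Scaffold],
                          otus: Sequence[Otu],
                          params: MapParams = MapParams(),
                          threshold: float = 0.97,
                          id_prefix: str = "OTU") -> list[Otu]:
    """Pool scaffolds that fail to match any existing representative at the
    clustering threshold and cluster them as one pool; returns the new OTUs
    (with ids continuing after the existing set)."""
    rep_kmers = [_scaffold_kmers(o.representative) for o in otus]
    pool: list[Scaffold] = []
    for sc in scaffolds:
        if not sc.clustering_eligible:
            continue
        sc_kmers = _scaffold_kmers(sc)
        captured = False
        for otu, kms in zip(otus, rep_kmers):
            if kms and sc_kmers and not (kms & sc_kmers):
                continue
            if scaffold_identity(sc, otu.representative) >= threshold:
                captured = True
                break
        if not captured:
            pool.append(sc)
    return greedy_cluster(pool, threshold, id_prefix=id_prefix,
                          start_index=len(otus) + 1)


# ---------------------------------------------------------------------------
# Mapping pairs back to OTUs


@dataclass
class PairMapping:
    pair_id: str
    sample_id: str
    otu_id: str | None
    status: str  # mapped | discordant | unmapped
    identity: float = 0.0
    indel_positions: int = 0
    aligned1: str | None = None
    aligned2: str | None = None


def map_pairs_to_otus(scaffolds: Sequence[Scaffold], otus: Sequence[Otu],
                      params: MapParams = MapParams(),
                      use_consensus: bool = False,
                      want_projection: bool = True) -> list[PairMapping]:
    """Map every pair to the OTU whose representative (or consensus) both
    mates match, preferring concordant placements.

    An OTU is a *concordant* candidate for a pair when both mates align to
    it with pooled identity >= ``min_identity``, at most
    ``max_indel_positions`` gapped columns in total, and an implied insert
    <= ``max_insert``; the pair maps to the best such OTU (highest pooled
    identity, ties to the lexicographically smallest otu_id).  When no OTU
    satisfies the pair as a whole but each mate individually aligns at
    >= ``min_identity`` to a *different* OTU, the pair is *discordant* —
    the paired-read chimera filter.  Everything else is unmapped.
    """
    targets = [o.consensus_scaffold() if use_consensus else o.representative
               for o in otus]
    otu_kmers = [_scaffold_kmers(t) for t in targets]
    order = sorted(range(len(otus)), key=lambda i: otus[i].otu_id)
    n_count = [t.sequence.count("N") - LINKER_LEN for t in targets]

    out: list[PairMapping] = []
    for sc in scaffolds:
        sc_kmers = _scaffold_kmers(sc)
        sc_n = sc.sequence.count("N") - LINKER_LEN
        # cheap edit-distance bounds per candidate, for ordering + pruning
        bounds = []
        for i in order:
            if otu_kmers[i] and sc_kmers and not (otu_kmers[i] & sc_kmers):
                continue
            tgt = targets[i]
            ed1 = edlib.align(sc.seg1, tgt.seg1, mode="NW",
                              task="distance")["editDistance"]
            ed2 = edlib.align(sc.seg2, tgt.seg2, mode="NW",
                              task="distance")["editDistance"]
            total_len = (len(sc.seg1) + len(sc.seg2)
                         + len(tgt.seg1) + len(tgt.seg2))
            slack = max(ed1 + ed2 - sc_n - n_count[i], 0)
            bound = 1.0 - slack / total_len if total_len else 0.0
            bounds.append((bound, i))
        bounds.sort(key=lambda t: (-t[0], otus[t[1]].otu_id))

        best = None          # (pooled_identity, index) of best concordant
        best_stats = None
        best1 = best2 = None  # per-mate best exact (identity, index)
        for n_eval, (bound, i) in enumerate(bounds):
            # the bound dominates the true pooled identity, so once it
            # falls below the current best (or the gate) nothing later in
            # the ordering can win; keep a floor of 3 exact evaluations so
            # discordance has per-mate evidence
            if n_eval >= 3 and best is not None and bound < best[0]:
                break
            if n_eval >= 3 and bound < params.min_identity:
                break
            tgt = targets[i]
            s1, _ = align_segments(sc.seg1, tgt.seg1, mode="NW")
            s2, _ = align_segments(sc.seg2, tgt.seg2, mode="NW")
            if best1 is None or s1.identity > best1[0]:
                best1 = (s1.identity, i)
            if best2 is None or s2.identity > best2[0]:
                best2 = (s2.identity, i)
            cols = s1.columns + s2.columns
            pooled = (s1.matches + s2.matches) / cols if cols else 0.0
            indels = s1.indels + s2.indels
            if params.per_mate_identity:
                ok_identity = (min(s1.identity, s2.identity)
                               >= params.min_identity)
            else:
                ok_identity = pooled >= params.min_identity
            implied_insert = tgt.combined_length + LINKER_LEN
            if (ok_identity and indels <= params.max_indel_positions
                    and implied_insert <= params.max_insert):
                if best is None or pooled > best[0]:
                    best = (pooled, i)
                    best_stats = (pooled, indels)
        if best is not None:
            pooled, indels = best_stats
            p1 = p2 = None
            if want_projection:
                tgt = targets[best[1]]
                _, p1 = align_segments(sc.seg1, tgt.seg1, mode="NW",
                                       project=True)
                _, p2 = align_segments(sc.seg2, tgt.seg2, mode="NW",
                                       project=True)
            out.append(PairMapping(sc.id, sc.sample_id,
                                   otus[best[1]].otu_id, "mapped",
                                   pooled, indels, p1, p2))
        elif (best1 is not None and best2 is not None
                and best1[1] != best2[1]
                and min(best1[0], best2[0]) >= params.min_identity):
            out.append(PairMapping(sc.id, sc.sample_id, None, "discordant"))
        else:
            out.append(PairMapping(sc.id, sc.sample_id, None, "unmapped"))
    return out


# ---------------------------------------------------------------------------
# Consensus and chimera filtering


def build_consensus(otu: Otu, alignments: Sequence[PairMapping]) -> str:
    """Per-column majority base over the mapped pairs of this OTU.

    Ties fall back to the representative's base; columns with zero read
    coverage keep the representative's base; linker-only columns remain N.
    Columns where most covering reads carry a gap (e.g. a residual-primer
    insertion private to the representative) become N, so they no longer
    penalize downstream identity computations.
    """
    rep = otu.representative
    counts1 = [Counter() for _ in range(rep.len1)]
    counts2 = [Counter() for _ in range(rep.len2)]
    for pm in alignments:
        if pm.otu_id != otu.otu_id or pm.status != "mapped":
            continue
        for proj, counts in ((pm.aligned1, counts1), (pm.aligned2, counts2)):
            if proj is None:
                continue
            for j, ch in enumerate(proj):
                if ch in "ACGT" or ch == "-":
                    counts[j][ch] += 1

    def resolve(counts, ref_seg):
        out = []
        for j, ctr in enumerate(counts):
            gaps = ctr.pop("-", 0)
            if not ctr and not gaps:
                out.append(ref_seg[j])
                continue
            if gaps > sum(ctr.values()):
                out.append("N")
                continue
            if not ctr:
                out.append(ref_seg[j])
                continue
            top = max(ctr.values())
            winners = sorted(b for b, c in ctr.items() if c == top)
            if ref_seg[j] in winners:
                out.append(ref_seg[j])
            else:
                out.append(winners[0])
        return "".join(out)

    return (resolve(counts1, rep.seg1) + "N" * LINKER_LEN
            + resolve(counts2, rep.seg2))


def apply_chimera_scores(otus: Sequence[Otu],
                         scores: dict[str, float],
                         threshold: float = 30.0
                         ) -> tuple[list[Otu], list[Otu]]:
    """Remove OTUs whose (externally computed) chimera score is >= the
    threshold; OTUs with no score entry are kept (score treated as 0)."""
    kept, removed = [], []
    for otu in otus:
        score = scores.get(otu.otu_id, 0.0)
        otu.chimera_score = score if otu.otu_id in scores else None
        (removed if score >= threshold else kept).append(otu)
    return kept, removed


def load_chimera_scores(path) -> dict[str, float]:
    """Two-column TSV: otu_id <tab> score."""
    scores: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            otu_id, score = line.split("\t")[:2]
            scores[otu_id.strip()] = float(score)
    return scores


def write_otus_fasta(otus: Iterable[Otu], path,
                     consensus: bool = False) -> None:
    with open(path, "w") as fh:
        for otu in otus:
            seq = otu.consensus_or_rep if consensus \
                else otu.representative.sequence
            fh.write(f">{otu.otu_id} members={len(otu.member_ids)}\n{seq}\n")


def write_membership_tsv(otus: Iterable[Otu], path) -> None:
    with open(path, "w") as fh:
        fh.write("otu_id\tmember_id\n")
        for otu in otus:
            for mid in otu.member_ids:
                fh.write(f"{otu.otu_id}\t{mid}\n")
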