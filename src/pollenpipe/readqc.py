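"""Read-pair quality control.

Trims fusion primers and low-quality ends from raw paired reads, enforces
length/ambiguity gates, and rejects pairs whose mates overlap (improper short
fragments).  The amplicon strategy produces ~900-bp fragments sequenced
2 x 300 bp, so proper pairs must *not* overlap: a detectable overlap means the
template was an artifactually short fragment.

Primer trimming uses local alignment of each explicit primer variant
(degenerate positions expanded combinatorially) against the 5' window of the
read under a +1 match / -2 mismatch / -2 indel scheme; a hit scoring >= 10
removes the aligned span and everything 5' of it.  Quality trimming follows
the Mott running-sum rule with per-base weight ``limit - p_err`` and
``limit = 0.05``: the retained read is the maximal-sum contiguous subread, so
bases with error probability above the limit are shed from the ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from Bio import Align, SeqIO

from ._seq import count_ambiguous, expand_degenerate, reverse_complement

logger = logging.getLogger(__name__)

# Amplicon primers (degenerate), 5'->3' as they appear at the start of each
# mate: read 1 is initiated by the modified ITS4 primer, read 2 by the
# modified ITS5a primer.
DEFAULT_PRIMER_READ1 = "TTCCTCCGCTTATTGATATGCTTAARYTCAGC"
DEFAULT_PRIMER_READ2 = "ACCTTATCATTTAGAGGAAGKARAARTCGTAACAAGGT"


@dataclass(frozen=True)
class RawRead:
    """A single read with per-base Phred qualities.  ``mate`` is 1 or 2."""

    id: str
    sequence: str
    qualities: tuple[int, ...]
    mate: int = 1

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"{self.id}: sequence and qualities differ in length"
            )
        if self.mate not in (1, 2):
            raise ValueError(f"{self.id}: mate must be 1 or 2")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadPair:
    id: str
    read1: RawRead
    read2: RawRead
    sample_id: str = ""

    def __post_init__(self):
        if self.read1.mate != 1 or self.read2.mate != 2:
            raise ValueError(f"{self.id}: mates mislabeled")


@dataclass(frozen=True)
class TrimParams:
    """Numeric knobs of the QC stage.

    The primer scheme is +1/-2/-2 (match/mismatch/indel) with acceptance
    score 10; the merge (overlap) scheme is +1/-2/-3 with acceptance score
    25.  ``max_base_error_prob`` is the Mott trimming limit.
    """

    max_base_error_prob: float = 0.05
    primer_match_score: int = 1
    primer_mismatch_penalty: int = -2
    primer_indel_penalty: int = -2
    primer_min_score: int = 10
    min_read_len: int = 150
    max_ambiguous: int = 3
    merge_match: int = 1
    merge_mismatch: int = -2
    merge_indel: int = -3
    merge_min_score: int = 25
    min_overlap: int = 10

    def __post_init__(self):
        if self.min_read_len <= 0:
            raise ValueError("min_read_len must be positive")
        for name in ("primer_mismatch_penalty", "primer_indel_penalty",
                     "merge_mismatch", "merge_indel"):
            if getattr(self, name) >= 0:
                raise ValueError(f"{name} must be negative")


def _primer_aligner(params: TrimParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.primer_match_score
    aligner.mismatch_score = params.primer_mismatch_penalty
    aligner.open_gap_score = params.primer_indel_penalty
    aligner.extend_gap_score = params.primer_indel_penalty
    return aligner


def trim_primer(read: RawRead, primer_variants: Sequence[str],
                params: TrimParams = TrimParams()) -> RawRead:
    """Remove a 5' fusion-primer hit and everything upstream of it.

    Each explicit (non-degenerate) variant is aligned locally against the 5'
    window of the read (1.5x the primer length — fusion primers can only
    occur at the read start).  If the best variant scores at least
    ``primer_min_score``, the read is cut just 3' of the aligned span;
    otherwise it is returned unchanged.  Qualities are trimmed in lockstep.
    """
    if not primer_variants:
        raise ValueError("primer_variants must be non-empty")
    if len(read) == 0:
        return read

    window_len = int(1.5 * max(len(v) for v in primer_variants))
    window = read.sequence[:window_len]

    # Fast path: an exact variant at the very start of the read.
    for variant in primer_variants:
        if window.startswith(variant):
            return _cut_5prime(read, len(variant))

    aligner = _primer_aligner(params)
    best_score, best_end = -1.0, 0
    for variant in primer_variants:
        score = aligner.score(window, variant)
        if score > best_score:
            best_score = score
            if score >= params.primer_min_score:
                alignment = aligner.align(window, variant)[0]
                start = int(alignment.aligned[0][0][0])
                end = int(alignment.aligned[0][-1][1])
                # a local alignment can stop short of the primer 3' end on
                # a score tie; the primer still occupies that span, so cut
                # its full length from where the hit starts
                best_end = min(max(end, start + len(variant)), len(read))
    if best_score >= params.primer_min_score:
        return _cut_5prime(read, best_end)
    return read


def _cut_5prime(read: RawRead, start: int) -> RawRead:
    return replace(read, sequence=read.sequence[start:],
                   qualities=read.qualities[start:])


def quality_trim(read: RawRead,
                 params: TrimParams = TrimParams()) -> RawRead:
    """Mott running-sum trimming.

    Each base gets weight ``limit - 10**(-Q/10)``; the retained subread is
    the contiguous interval with maximal weight sum (empty if every interval
    is negative).  Bases with error probability above the limit therefore
    contribute negatively and are shed from the ends.
    """
    if len(read) == 0:
        return read
    q = np.asarray(read.qualities, dtype=float)
    w = params.max_base_error_prob - np.power(10.0, -q / 10.0)
    if w.min() > 0.0:
        return read

    # Maximal-sum interval via prefix sums: for each end position j the
    # best interval ending at j starts after the running prefix minimum.
    prefix = np.concatenate(([0.0], np.cumsum(w)))
    run_min = np.minimum.accumulate(prefix)
    gains = prefix[1:] - run_min[:-1]
    j = int(np.argmax(gains))
    best = float(gains[j])
    if best <= 0.0:
        return replace(read, sequence="", qualities=())
    lo = int(np.argmin(prefix[:j + 1]))
    hi = j + 1
    return replace(read, sequence=read.sequence[lo:hi],
                   qualities=read.qualities[lo:hi])


def filter_pair(pair: ReadPair, params: TrimParams = TrimParams()) -> bool:
    """Keep a (trimmed) pair iff both mates pass the length and ambiguity
    gates; failure of either mate drops the pair."""
    return filter_reason(pair, params) is None


def filter_reason(pair: ReadPair,
                  params: TrimParams = TrimParams()) -> str | None:
    """None if the pair passes, else a drop-reason code."""
    for read in (pair.read1, pair.read2):
        if len(read) < params.min_read_len:
            return "short_read"
        if count_ambiguous(read.sequence) > params.max_ambiguous:
            return "ambiguous_bases"
    return None


def _byte_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _suffix_prefix_score(a: np.ndarray, b: np.ndarray,
                         params: TrimParams) -> int:
    la, lb = len(a), len(b)
    best = -(10 ** 9)
    match = params.merge_match
    mismatch = params.merge_mismatch
    for k in range(params.min_overlap, min(la, lb) + 1):
        m = int(np.count_nonzero(a[la - k:] == b[:k]))
        score = m * match + (k - m) * mismatch
        if score > best:
            best = score
    return best


def overlap_score(pair: ReadPair, params: TrimParams = TrimParams()) -> int:
    """Best gapless overlap score of read1 against revcomp(read2) under the
    merge scheme (+1 match / -2 mismatch), scanning all offsets in both the
    innie (suffix/prefix) and outie (prefix/suffix, read-through)
    configurations.  Overlaps shorter than ``min_overlap`` are not scanned
    (they cannot reach the acceptance score anyway)."""
    a = _byte_array(pair.read1.sequence)
    b = _byte_array(reverse_complement(pair.read2.sequence))
    return max(_suffix_prefix_score(a, b, params),
               _suffix_prefix_score(b, a, params))


_SEED_K = 11


def detect_overlap(pair: ReadPair,
                   params: TrimParams = TrimParams()) -> bool:
    """True (-> discard as an improper short fragment) iff the best overlap
    alignment of read1 against revcomp(read2) scores >= ``merge_min_score``.

    A shared-11-mer seed check gates the exhaustive offset scan: any overlap
    strong enough to reach the acceptance score contains a long exact run,
    while unrelated mates almost never share an 11-mer.
    """
    if min(len(pair.read1), len(pair.read2)) < params.min_overlap:
        return False
    rc2 = reverse_complement(pair.read2.sequence)
    s1 = pair.read1.sequence
    k = _SEED_K
    if len(s1) >= k and len(rc2) >= k:
        seeds = {s1[i:i + k] for i in range(len(s1) - k + 1)}
        if not any(rc2[i:i + k] in seeds
                   for i in range(len(rc2) - k + 1)):
            return False
    return overlap_score(pair, params) >= params.merge_min_score


def qc_pair(pair: ReadPair,
            primers1: Sequence[str],
            primers2: Sequence[str],
            params: TrimParams = TrimParams()) -> tuple[ReadPair | None, str]:
    """Full QC of one pair: primer trim, quality trim, gates, overlap check.

    Returns ``(trimmed_pair, "pass")`` or ``(None, reason)``.
    """
    r1 = quality_trim(trim_primer(pair.read1, primers1, params), params)
    r2 = quality_trim(trim_primer(pair.read2, primers2, params), params)
    trimmed = ReadPair(pair.id, r1, r2, pair.sample_id)
    reason = filter_reason(trimmed, params)
    if reason is not None:
        return None, reason
    if detect_overlap(trimmed, params):
        return None, "overlapping_mates"
    return trimmed, "pass"


def expand_primers(primer: str) -> list[str]:
    """Expand a degenerate primer into explicit search variants."""
    return expand_degenerate(primer)


# ---------------------------------------------------------------------------
# FASTQ I/O


def read_fastq_pairs(path1, path2, sample_id: str = "") -> list[ReadPair]:
    """Load intact pairs from a pair of Sanger-Phred FASTQ files."""
    pairs = []
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    for rec1, rec2 in zip(it1, it2):
        pid = rec1.id.split("/")[0].split()[0]
        r1 = RawRead(pid, str(rec1.seq).upper(),
                     tuple(rec1.letter_annotations["phred_quality"]), mate=1)
        r2 = RawRead(pid, str(rec2.seq).upper(),
                     tuple(rec2.letter_annotations["phred_quality"]), mate=2)
        pairs.append(ReadPair(pid, r1, r2, sample_id))
    return pairs


def write_fastq_pairs(pairs: Iterable[ReadPair], path1, path2) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    recs1, recs2 = [], []
    for pair in pairs:
        for read, recs in ((pair.read1, recs1), (pair.read2, recs2)):
            rec = SeqRecord(Seq(read.sequence), id=f"{pair.id}/{read.mate}",
                            description="")
            rec.letter_annotations["phred_quality"] = list(read.qualities)
            recs.append(rec)
    SeqIO.write(recs1, str(path1), "fastq")
    SeqIO.write(recs2, str(path2), "fastq")
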