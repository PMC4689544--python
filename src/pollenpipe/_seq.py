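"""Small shared sequence utilities (reverse complement, IUPAC expansion, k-mers)."""

from __future__ import annotations

from itertools import product

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHSWNacgtrykmbvdhswn",
                            "TGCAYRMKVBHDSWNtgcayrmkvbhdswn")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def expand_degenerate(seq: str) -> list[str]:
    """Expand an IUPAC-degenerate sequence into all explicit ACGT variants."""
    pools = []
    for base in seq.upper():
        try:
            pools.append(IUPAC[base])
        except KeyError:
            raise ValueError(f"not an IUPAC nucleotide code: {base!r}")
    return ["".join(p) for p in product(*pools)]


def kmer_set(seq: str, k: int, step: int = 1) -> set[str]:
    """Set of k-mers of ``seq`` sampled every ``step`` positions; k-mers
    containing N are skipped (masked/linker positions never seed matches)."""
    out = set()
    for i in range(0, len(seq) - k + 1, step):
        km = seq[i:i + k]
        if "N" not in km:
            out.add(km)
    return out


def count_ambiguous(seq: str) -> int:
    return sum(1 for b in seq if b not in "ACGT")
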