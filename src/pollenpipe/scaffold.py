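"""Scaffold construction and low-complexity masking.

A non-overlapping pair is represented as a single *scaffold*:
``read1 + 30*N + reverse_complement(read2)``.  The 30-N linker is long enough
that single reads cannot align across the gap, so the scaffold behaves like
one sequence for clustering while keeping the two informative segments
separate.  Scaffolds with a combined informative length >= 520 bp are
eligible to seed OTU clustering (shorter pairs carry no extra information
once a longer representative exists).

Low-complexity masking is DUST-style, aimed at the 3' G-homopolymer
sequencing artifact: windows whose triplet-coincidence score exceeds a
threshold have their repeated-triplet core replaced by N, and G homopolymers
of >= 12 bp are always masked regardless of the window score.  Masked
positions are written as N so downstream identity computations skip them
automatically.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np

from ._seq import reverse_complement

LINKER_LEN = 30
LINKER = "N" * LINKER_LEN
MIN_COMBINED_LEN = 520

# DUST-style parameters.  The window score is the classic normalized triplet
# statistic 10 * sum_t c_t*(c_t-1)/2 / (n_triplets - 1); ~5 on uniform-random
# sequence, >300 on a homopolymer window.
DUST_WINDOW = 64
DUST_THRESHOLD = 20.0
DUST_CORE_MIN = 5
HOMOPOLYMER_BASE = "G"
HOMOPOLYMER_MIN = 12


@dataclass(frozen=True)
class Scaffold:
    id: str
    sequence: str
    len1: int
    len2: int
    sample_id: str = ""

    def __post_init__(self):
        if len(self.sequence) != self.len1 + LINKER_LEN + self.len2:
            raise ValueError(f"{self.id}: scaffold length inconsistent")

    @property
    def clustering_eligible(self) -> bool:
        return self.len1 + self.len2 >= MIN_COMBINED_LEN

    @property
    def combined_length(self) -> int:
        return self.len1 + self.len2

    @property
    def seg1(self) -> str:
        """The read-1 segment (5' of the linker)."""
        return self.sequence[:self.len1]

    @property
    def seg2(self) -> str:
        """The reverse-complemented read-2 segment (3' of the linker)."""
        return self.sequence[self.len1 + LINKER_LEN:]


def build_scaffold(pair) -> Scaffold:
    """read1 + 30-N linker + reverse-complement(read2)."""
    seg1 = pair.read1.sequence
    seg2 = reverse_complement(pair.read2.sequence)
    return Scaffold(id=pair.id, sequence=seg1 + LINKER + seg2,
                    len1=len(seg1), len2=len(seg2),
                    sample_id=pair.sample_id)


_TRIPLET_ENC = np.full(256, -1, dtype=np.int16)
for _i, _b in enumerate(b"ACGT"):
    _TRIPLET_ENC[_b] = _i


def _triplet_codes(seq: str) -> np.ndarray:
    """Per-position triplet codes in [0, 64); -1 where the triplet touches
    a non-ACGT base."""
    enc = _TRIPLET_ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    codes = enc[:-2] * 16 + enc[1:-1] * 4 + enc[2:]
    codes[(enc[:-2] < 0) | (enc[1:-1] < 0) | (enc[2:] < 0)] = -1
    return codes


def mask_low_complexity(seq: str,
                        window: int = DUST_WINDOW,
                        threshold: float = DUST_THRESHOLD,
                        core_min: int = DUST_CORE_MIN,
                        homopolymer_min: int = HOMOPOLYMER_MIN) -> str:
    """Replace low-complexity cores with N.

    Sliding windows (half-overlapping) are scored by triplet coincidences;
    in a flagged window every occurrence of a triplet type seen >= ``core_min``
    times is masked.  Independently, runs of >= ``homopolymer_min`` G are
    always masked — the explicit rule guarantees the 3'-G artifact is removed
    under any window parameterization.  Masking is idempotent.
    """
    masked = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n_code = ord("N")

    for m in re.finditer(f"{HOMOPOLYMER_BASE}{{{homopolymer_min},}}", seq):
        masked[m.start():m.end()] = n_code

    n = len(seq)
    if n < 3:
        return masked.tobytes().decode("ascii")
    step = max(window // 2, 1)
    starts = list(range(0, max(n - window, 0) + 1, step))
    if starts[-1] + window < n:
        starts.append(n - window)
    codes = _triplet_codes(masked.tobytes().decode("ascii"))
    for s in starts:
        wcodes = codes[s:s + max(window - 2, 1)]
        valid = wcodes[wcodes >= 0]
        if len(valid) < 2:
            continue
        counts = np.bincount(valid, minlength=64)
        raw = int((counts * (counts - 1) // 2).sum())
        score = 10.0 * raw / (len(valid) - 1)
        if score > threshold:
            hot = set(np.nonzero(counts >= core_min)[0].tolist())
            if not hot:
                continue
            for i, code in enumerate(wcodes.tolist()):
                if code in hot:
                    masked[s + i:s + i + 3] = n_code
            codes = _triplet_codes(masked.tobytes().decode("ascii"))
    return masked.tobytes().decode("ascii")


def mask_scaffold(scaffold: Scaffold, **kwargs) -> Scaffold:
    return replace(scaffold,
                   sequence=mask_low_complexity(scaffold.sequence, **kwargs))


def write_scaffolds_fasta(scaffolds, path) -> None:
    with open(path, "w") as fh:
        for sc in scaffolds:
            fh.write(f">{sc.id} len1={sc.len1} len2={sc.len2} "
                     f"sample={sc.sample_id}\n{sc.sequence}\n")
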