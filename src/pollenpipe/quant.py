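"""Per-sample quantification: counting under the concordant-pair rule, cpm
normalization, low-count filtering, diversity, dissimilarity, rarefaction,
and flora-checklist concordance.

Counting rule: a read pair contributes one count to (sample, taxon) only if
it mapped concordantly to a single OTU (97% pooled identity, <= 5 indel
positions) and that OTU carries a taxonomic assignment; discordant pairs
and pairs on unassigned OTUs enter the library size only.  Counts for OTUs
sharing a taxon are summed.  Counts-per-million (cpm) normalize by library
size; taxa with fewer than 50 counts summed over all samples are dropped as
mapping noise.

Diversity is the effective number of equally abundant species from the
Chao-Shen coverage-adjusted Shannon entropy (order q = 1), computed on raw
counts.  Rarefaction uses the exact hypergeometric expectation, evaluated
in log space.  Bray-Curtis dissimilarity (via scipy) compares samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _scipy_braycurtis
from scipy.special import gammaln

logger = logging.getLogger(__name__)

TaxonKey = tuple[int, str, str]  # (taxid, name, rank)


@dataclass(frozen=True)
class QuantParams:
    min_total_count: int = 50
    cpm_scale: float = 1e6
    diversity_order: int = 1

    def __post_init__(self):
        if self.min_total_count < 0:
            raise ValueError("min_total_count must be >= 0")


@dataclass
class CountMatrix:
    """Taxon x sample integer counts plus per-sample library sizes
    (mapped pairs, including discordant and unassigned ones)."""

    counts: pd.DataFrame  # index: TaxonKey tuples, columns: sample ids
    library_sizes: pd.Series

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        short = self.counts.sum(axis=0) > self.library_sizes.reindex(
            self.counts.columns).fillna(0)
        if short.any():
            raise ValueError("library sizes smaller than assigned counts")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def taxa(self) -> list[TaxonKey]:
        return list(self.counts.index)


def tally_counts(mappings: Sequence, assignments: Sequence,
                 samples: Sequence[str]) -> CountMatrix:
    """Build the count matrix from pair->OTU mappings and OTU assignments.

    ``mappings`` are PairMapping records (status mapped/discordant/unmapped);
    ``assignments`` are Assignment records keyed by otu_id.
    """
    by_otu = {a.otu_id: a for a in assignments}
    taxon_of: dict[str, TaxonKey] = {}
    for a in assignments:
        if a.assigned:
            taxon_of[a.otu_id] = (a.taxid, a.taxon_name, a.assigned_rank)

    counts: dict[TaxonKey, dict[str, int]] = {}
    library: dict[str, int] = {s: 0 for s in samples}
    for pm in mappings:
        if pm.status == "unmapped":
            continue
        library[pm.sample_id] = library.get(pm.sample_id, 0) + 1
        if pm.status != "mapped":
            continue  # discordant pairs are library-size only
        key = taxon_of.get(pm.otu_id)
        if key is None:
            continue  # unassigned OTU: library-size only
        counts.setdefault(key, {}).setdefault(pm.sample_id, 0)
        counts[key][pm.sample_id] += 1

    all_samples = sorted(set(samples) | set(library))
    index = sorted(counts.keys())
    data = np.zeros((len(index), len(all_samples)), dtype=int)
    for i, key in enumerate(index):
        for j, s in enumerate(all_samples):
            data[i, j] = counts[key].get(s, 0)
    frame = pd.DataFrame(data, columns=all_samples)
    frame.index = pd.Index(index, tupleize_cols=False)
    lib = pd.Series({s: library.get(s, 0) for s in all_samples})
    return CountMatrix(frame, lib)


def filter_min_total(m: CountMatrix,
                     params: QuantParams = QuantParams()) -> CountMatrix:
    """Drop taxa whose counts summed across all samples are below the
    floor; a total of exactly the floor is kept."""
    keep = m.counts.sum(axis=1) >= params.min_total_count
    return CountMatrix(m.counts.loc[keep], m.library_sizes)


def to_cpm(m: CountMatrix,
           params: QuantParams = QuantParams()) -> pd.DataFrame:
    """counts-per-million by library size; zero-size samples are excluded
    with a warning."""
    keep = []
    for s in m.samples:
        if m.library_sizes[s] > 0:
            keep.append(s)
        else:
            logger.warning("sample %s has zero library size; excluded", s)
    sub = m.counts[keep]
    return sub * params.cpm_scale / m.library_sizes[keep]


def chao_shen_diversity(counts: Sequence[float] | np.ndarray,
                        q: int = 1) -> float:
    """Effective species number exp(H) where H is the Chao-Shen
    coverage-adjusted Shannon entropy on raw counts.

    With n reads and f1 singletons, estimated coverage C = 1 - f1/n
    (C = 1 - (n-1)/n when every taxon is a singleton), adjusted abundances
    p_i = C * x_i / n, and H = sum -p_i ln p_i / (1 - (1 - p_i)^n).
    """
    if q != 1:
        raise NotImplementedError("only order q = 1 is implemented")
    x = np.asarray(counts, dtype=float)
    x = x[x > 0]
    n = x.sum()
    if n <= 0:
        raise ValueError("sample has no counts")
    f1 = int((x == 1).sum())
    if f1 == n:
        coverage = 1.0 - (n - 1.0) / n
    else:
        coverage = 1.0 - f1 / n
    p = coverage * x / n
    h = float(np.sum(-p * np.log(p) / (1.0 - np.power(1.0 - p, n))))
    return math.exp(h)


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min)/sum(total) on shared taxon
    ordering (scipy implementation)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("vectors must share taxon ordering and length")
    if (xa < 0).any() or (ya < 0).any():
        raise ValueError("abundances must be non-negative")
    if xa.sum() == 0 and ya.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two empty samples")
    return float(_scipy_braycurtis(xa, ya))


def bray_curtis_matrix(abundances: pd.DataFrame) -> pd.DataFrame:
    """All pairwise sample dissimilarities; columns are samples."""
    samples = list(abundances.columns)
    out = pd.DataFrame(0.0, index=samples, columns=samples)
    for i, a in enumerate(samples):
        for b in samples[i + 1:]:
            d = bray_curtis(abundances[a], abundances[b])
            out.loc[a, b] = out.loc[b, a] = d
    return out


def rarefaction_curve(counts: Sequence[float],
                      depths: Sequence[int]) -> list[float]:
    """Exact expected richness E[S_m] = S - sum_i C(n - x_i, m)/C(n, m)
    at each subsampling depth m, computed with log-gamma for stability."""
    x = np.asarray(counts, dtype=int)
    x = x[x > 0]
    n = int(x.sum())
    s = len(x)
    out = []
    for m in depths:
        if not 1 <= m <= n:
            raise ValueError(f"depth {m} outside [1, {n}]")
        # log C(n - x_i, m) - log C(n, m); C(a, m) = 0 when a < m
        keep = (n - x) >= m
        a = (n - x)[keep].astype(float)
        log_frac = (gammaln(a + 1) - gammaln(a - m + 1)
                    - gammaln(n + 1) + gammaln(n - m + 1))
        out.append(float(s - np.exp(log_frac).sum()))
    return out


# ---------------------------------------------------------------------------
# Flora checklist concordance


@dataclass(frozen=True)
class ChecklistRow:
    species_name: str
    genus_name: str
    species_listed: bool
    genus_listed: bool
    is_bryophyte: bool


@dataclass
class FloraChecklist:
    rows: list[ChecklistRow]

    def __post_init__(self):
        self._by_species = {r.species_name: r for r in self.rows}

    def lookup(self, species_name: str) -> ChecklistRow:
        row = self._by_species.get(species_name)
        if row is None:
            genus = species_name.split()[0] if species_name else ""
            row = ChecklistRow(species_name, genus, False, False, False)
        return row

    @classmethod
    def from_csv(cls, path) -> "FloraChecklist":
        df = pd.read_csv(path)
        rows = [
            ChecklistRow(r.species, str(r.species).split()[0],
                         bool(r.species_listed), bool(r.genus_listed),
                         bool(r.is_bryophyte))
            for r in df.itertuples()
        ]
        return cls(rows)


@dataclass(frozen=True)
class ConcordanceResult:
    species_fraction: float | None
    genus_fraction: float | None
    species_listed: int
    genus_listed: int
    n_flowering: int


def flora_concordance(species_assignments: Iterable[str],
                      checklist: FloraChecklist) -> ConcordanceResult:
    """Fractions of non-bryophyte species-level assignments whose species
    (resp. genus) appears on the state flora checklist."""
    sp_hits = gen_hits = denom = 0
    for name in species_assignments:
        row = checklist.lookup(name)
        if row.is_bryophyte:
            continue
        denom += 1
        sp_hits += int(row.species_listed)
        gen_hits += int(row.genus_listed)
    if denom == 0:
        return ConcordanceResult(None, None, 0, 0, 0)
    return ConcordanceResult(sp_hits / denom, gen_hits / denom,
                             sp_hits, gen_hits, denom)


def default_checklist() -> FloraChecklist:
    """The packaged state-flora checklist of the study's species-level
    plant assignments (60 rows, 4 bryophytes)."""
    from importlib.resources import files
    path = files("pollenpipe.data").joinpath("state_flora_checklist.csv")
    return FloraChecklist.from_csv(path)


def write_count_matrix(m: CountMatrix, path) -> None:
    out = m.counts.copy()
    out.index = [f"{t}\t{n}\t{r}" for t, n, r in out.index]
    with open(path, "w") as fh:
        fh.write("taxid\tname\trank\t" + "\t".join(m.samples) + "\n")
        for idx, row in zip(out.index, out.to_numpy()):
            fh.write(idx + "\t" + "\t".join(str(v) for v in row) + "\n")
        fh.write("#library_size\t\t\t"
                 + "\t".join(str(int(m.library_sizes[s]))
                             for s in m.samples) + "\n")
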