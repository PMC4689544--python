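"""Synthetic data: taxonomy trees, ITS-like references, mixed-sample read
pairs with sequencing error and chimeras, and matching HSP tables.

The generator emulates the study's amplicon geometry: a ~900-bp template
whose 5' end starts with the read-1 (ITS4-type) primer and whose 3' end is
the reverse complement of the read-2 (ITS5a-type) primer, sequenced as
non-overlapping 2 x 300 bp pairs.  Reference sequences evolve down a
balanced rank-labeled tree by per-branch substitution fractions, so sequence
divergence tracks taxonomic distance.  Chimeras are template switches at the
mate boundary: mate 2 is drawn from a different species — the kind of
artifact the paired-read concordance filter is designed to catch.

Every generator is deterministic under its seed, and every emitted pair has
exactly one ground-truth row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._seq import expand_degenerate, reverse_complement
from .lca import HspRecord
from .otu import ReferenceDb, RefSeq, align_segments
from .readqc import (DEFAULT_PRIMER_READ1, DEFAULT_PRIMER_READ2, RawRead,
                     ReadPair)
from .taxonomy import TaxonomyTree

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    mixture: dict[str, float]  # species name -> proportion (sums to 1)
    n_pairs: int


@dataclass(frozen=True)
class SimConfig:
    seed: int = 1
    n_orders: int = 1
    n_families: int = 2
    n_genera: int = 3
    n_species: int = 5
    ref_length: int = 900
    divergence_order: float = 0.15
    divergence_family: float = 0.10
    divergence_genus: float = 0.06
    divergence_species: float = 0.04
    read_length: int = 300
    per_base_error: float = 0.001
    chimera_rate: float = 0.02
    with_primers: bool = True
    samples: tuple[SampleSpec, ...] = ()

    def __post_init__(self):
        for d in (self.divergence_order, self.divergence_family,
                  self.divergence_genus, self.divergence_species):
            if d >= 0.75:
                raise ValueError(
                    "per-branch divergence >= 0.75 is saturated")
        for spec in self.samples:
            total = sum(spec.mixture.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(
                    f"sample {spec.sample_id}: mixture sums to {total}")


@dataclass
class SynthWorld:
    """Everything the pipeline consumes: taxonomy, references, templates."""

    cfg: SimConfig
    tree: TaxonomyTree
    refs: ReferenceDb
    acc2taxid: dict[str, int]
    templates: dict[str, str]        # species name -> full template
    species_taxids: dict[str, int]   # species name -> taxid
    primer1: str                     # concrete read-1 primer expansion
    primer2: str

    @property
    def species_names(self) -> list[str]:
        return sorted(self.species_taxids)


def _mutate(seq_arr: np.ndarray, divergence: float,
            rng: np.random.Generator) -> np.ndarray:
    out = seq_arr.copy()
    n_sub = int(round(divergence * len(out)))
    if n_sub == 0:
        return out
    pos = rng.choice(len(out), size=n_sub, replace=False)
    shift = rng.integers(1, 4, size=n_sub)
    idx = np.searchsorted(_BASES, out[pos])
    out[pos] = _BASES[(idx + shift) % 4]
    return out


def _round_robin(n_children: int, n_parents: int) -> list[int]:
    return [i % n_parents for i in range(n_children)]


def make_taxonomy_and_refs(cfg: SimConfig) -> SynthWorld:
    """Balanced rank-labeled tree plus one reference per species, evolved
    from a common root sequence by per-level divergences."""
    rng = np.random.default_rng(cfg.seed)

    nodes: dict[int, tuple[int, str]] = {1: (1, "no rank")}
    names: dict[int, str] = {1: "root"}
    next_id = 2

    kingdom = next_id
    nodes[kingdom] = (1, "kingdom")
    names[kingdom] = "Viridiplantae"
    next_id += 1

    primer1 = expand_degenerate(DEFAULT_PRIMER_READ1)[0] \
        if cfg.with_primers else ""
    primer2 = expand_degenerate(DEFAULT_PRIMER_READ2)[0] \
        if cfg.with_primers else ""
    core_len = cfg.ref_length - len(primer1) - len(primer2)
    if core_len <= 0:
        raise ValueError("ref_length too short for the primer sites")
    root_core = _BASES[rng.integers(0, 4, size=core_len)]

    def add(parent: int, rank: str, name: str, parent_core: np.ndarray,
            divergence: float):
        nonlocal next_id
        taxid = next_id
        next_id += 1
        nodes[taxid] = (parent, rank)
        names[taxid] = name
        return taxid, _mutate(parent_core, divergence, rng)

    orders = [add(kingdom, "order", f"Order{i + 1}", root_core,
                  cfg.divergence_order) for i in range(cfg.n_orders)]
    fam_parents = _round_robin(cfg.n_families, cfg.n_orders)
    families = [add(orders[p][0], "family", f"Family{i + 1}", orders[p][1],
                    cfg.divergence_family)
                for i, p in enumerate(fam_parents)]
    gen_parents = _round_robin(cfg.n_genera, cfg.n_families)
    genera = [add(families[p][0], "genus", f"Genus{i + 1}", families[p][1],
                  cfg.divergence_genus)
              for i, p in enumerate(gen_parents)]
    sp_parents = _round_robin(cfg.n_species, cfg.n_genera)
    species = []
    for i, p in enumerate(sp_parents):
        name = f"{names[genera[p][0]]} species{i + 1}"
        species.append(add(genera[p][0], "species", name, genera[p][1],
                           cfg.divergence_species))

    tree = TaxonomyTree(nodes, names)
    refs, acc2taxid, templates, species_taxids = [], {}, {}, {}
    for taxid, core in species:
        name = names[taxid]
        template = primer1 + core.tobytes().decode("ascii") \
            + reverse_complement(primer2)
        acc = f"ACC{taxid:05d}.1"
        refs.append(RefSeq(acc, template, taxid))
        acc2taxid[acc] = taxid
        templates[name] = template
        species_taxids[name] = taxid

    return SynthWorld(cfg, tree, ReferenceDb(refs), acc2taxid, templates,
                      species_taxids, primer1, primer2)


# ---------------------------------------------------------------------------
# Read simulation


def _apply_errors(seq: str, per_base_error: float,
                  rng: np.random.Generator) -> str:
    if per_base_error <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < per_base_error)[0]
    if len(hits):
        idx = np.searchsorted(_BASES, arr[hits])
        arr[hits] = _BASES[(idx + rng.integers(1, 4, size=len(hits))) % 4]
    return arr.tobytes().decode("ascii")


def simulate_sample(world: SynthWorld, mixture: dict[str, float],
                    n_pairs: int, sample_id: str,
                    rng: np.random.Generator
                    ) -> tuple[list[ReadPair], pd.DataFrame]:
    """Draw read pairs from a species mixture.

    read1 is the 5' ``read_length`` bp of the template, read2 the reverse
    complement of the 3' ``read_length`` bp (non-overlapping for templates
    longer than two read lengths).  With probability ``chimera_rate`` mate 2
    comes from a different, uniformly chosen species (template-switch
    chimera).  Phred qualities are constant and consistent with the error
    model.
    """
    cfg = world.cfg
    names = sorted(mixture)
    unknown = [n for n in names if n not in world.templates]
    if unknown:
        raise ValueError(f"mixture references unknown taxa: {unknown}")
    props = np.array([mixture[n] for n in names], dtype=float)
    props = props / props.sum()
    all_species = world.species_names

    qual = 40 if cfg.per_base_error <= 0 else int(round(
        -10.0 * math.log10(cfg.per_base_error)))
    L = cfg.read_length

    draws = rng.choice(len(names), size=n_pairs, p=props)
    chimeric = rng.random(n_pairs) < cfg.chimera_rate

    pairs: list[ReadPair] = []
    truth_rows = []
    for i in range(n_pairs):
        sp1 = names[draws[i]]
        tpl1 = world.templates[sp1]
        pid = f"{sample_id}:p{i + 1:06d}"
        is_chimera = bool(chimeric[i]) and len(all_species) > 1
        if is_chimera:
            others = [s for s in all_species if s != sp1]
            sp2 = others[int(rng.integers(0, len(others)))]
        else:
            sp2 = sp1
        tpl2 = world.templates[sp2]
        seq1 = _apply_errors(tpl1[:L], cfg.per_base_error, rng)
        seq2 = _apply_errors(reverse_complement(tpl2[-L:]),
                             cfg.per_base_error, rng)
        pairs.append(ReadPair(
            pid,
            RawRead(pid, seq1, (qual,) * len(seq1), mate=1),
            RawRead(pid, seq2, (qual,) * len(seq2), mate=2),
            sample_id))
        truth_rows.append({
            "pair_id": pid, "sample_id": sample_id,
            "source_species": sp1,
            "source_taxid": world.species_taxids[sp1],
            "is_chimera": is_chimera,
            "mate2_species": sp2,
            "mate2_taxid": world.species_taxids[sp2],
            "tpl1_start": 0, "tpl2_start": len(tpl2) - L,
        })
    return pairs, pd.DataFrame(truth_rows)


def simulate_all_samples(world: SynthWorld
                         ) -> tuple[list[ReadPair], pd.DataFrame]:
    """Simulate every sample in the config, with per-sample sub-seeds
    derived deterministically from the master seed."""
    all_pairs: list[ReadPair] = []
    truths = []
    for i, spec in enumerate(world.cfg.samples):
        rng = np.random.default_rng((world.cfg.seed * 1000 + 7 * i) % 2**31)
        pairs, truth = simulate_sample(world, spec.mixture, spec.n_pairs,
                                       spec.sample_id, rng)
        all_pairs.extend(pairs)
        truths.append(truth)
    truth = pd.concat(truths, ignore_index=True) if truths \
        else pd.DataFrame()
    return all_pairs, truth


# ---------------------------------------------------------------------------
# HSP table simulation (stands in for a BLAST search of the references)


def simulate_hsps_for_read(read_id: str, sequence: str, mate: int,
                           world: SynthWorld,
                           min_bit: float = 50.0) -> list[HspRecord]:
    """Score one read against every reference with a monotone bit-score
    surrogate: bit = 2*matches - 6*(mismatches + indels).  A full-length
    perfect mate scores ~2 bits per base (~600 for 300 bp), so the LCA's
    600-bit threshold is meaningful in simulation.  Percent identity is
    exact, from the alignment."""
    query = sequence if mate == 1 else reverse_complement(sequence)
    out = []
    for ref in world.refs.accessions:
        stats, _ = align_segments(query, ref.sequence, mode="HW")
        if stats.columns == 0:
            continue
        bit = 2.0 * stats.matches - 6.0 * (stats.mismatches + stats.indels)
        if bit < min_bit:
            continue
        pident = 100.0 * stats.matches / stats.columns
        out.append(HspRecord(read_id, ref.accession, bit, pident,
                             ref.taxid))
    return out


def simulate_hsp_tables(reads: list[tuple[str, str, int]],
                        world: SynthWorld,
                        min_bit: float = 50.0) -> list[HspRecord]:
    """HSPs for a list of (read_id, sequence, mate) triples."""
    out: list[HspRecord] = []
    for read_id, seq, mate in reads:
        out.extend(simulate_hsps_for_read(read_id, seq, mate, world,
                                          min_bit))
    return out


def write_hsp_table(hsps: list[HspRecord], path) -> None:
    """BLAST outfmt-6 with a 13th staxids column.  Unused positional
    columns are emitted as zeros."""
    with open(path, "w") as fh:
        for h in sorted(hsps, key=lambda h: (h.read_id, -h.bit_score,
                                             h.accession)):
            fh.write("\t".join([
                h.read_id, h.accession, f"{h.percent_identity:.2f}",
                "0", "0", "0", "0", "0", "0", "0", "0.0",
                f"{h.bit_score:.1f}", str(h.taxid),
            ]) + "\n")


# ---------------------------------------------------------------------------
# Taxdump emission


def write_taxdump(world: SynthWorld, nodes_path, names_path) -> None:
    with open(nodes_path, "w") as fh:
        for taxid in sorted(world.tree.nodes):
            parent, rank = world.tree.nodes[taxid]
            fh.write(f"{taxid}\t|\t{parent}\t|\t{rank}\t|\n")
    with open(names_path, "w") as fh:
        for taxid in sorted(world.tree.names):
            fh.write(f"{taxid}\t|\t{world.tree.names[taxid]}\t|\t\t|\t"
                     f"scientific name\t|\n")


# ---------------------------------------------------------------------------
# Ground-truth evaluation


def evaluate_run(world: SynthWorld, truth: pd.DataFrame,
                 mappings, assignments, otus) -> dict:
    """Score a pipeline run against the simulation truth table.

    Returns recovery of non-chimeric pairs to their true species or genus,
    the number of cross-family chimeric pairs counted at species level, and
    OTU purity (fraction of OTUs whose non-chimeric members all derive from
    one species).
    """
    tree = world.tree
    truth_rows = {r.pair_id: (bool(r.is_chimera), int(r.source_taxid),
                              int(r.mate2_taxid))
                  for r in truth.itertuples()}
    assign_by_otu = {a.otu_id: a for a in assignments}

    def family_of(taxid: int):
        fam = tree.rank_vector(taxid).at("family")
        return fam[0] if fam else None

    n_nonchimeric = n_recovered = 0
    n_crossfam_chimera_species = 0
    for pm in mappings:
        is_chimera, source_taxid, mate2_taxid = truth_rows[pm.pair_id]
        counted = (pm.status == "mapped" and pm.otu_id in assign_by_otu
                   and assign_by_otu[pm.otu_id].assigned)
        a = assign_by_otu.get(pm.otu_id) if counted else None
        if not is_chimera:
            n_nonchimeric += 1
            if a is not None:
                rv = tree.rank_vector(source_taxid)
                true_sp = rv.at("species")
                true_gen = rv.at("genus")
                if a.taxid in {t[0] for t in (true_sp, true_gen) if t}:
                    n_recovered += 1
        else:
            cross_family = (family_of(source_taxid)
                            != family_of(mate2_taxid))
            if (cross_family and a is not None
                    and a.assigned_rank == "species"):
                n_crossfam_chimera_species += 1

    pure = impure = 0
    for otu in otus:
        members = [m for m in otu.member_ids if m in truth_rows]
        sources = {truth_rows[m][1] for m in members
                   if not truth_rows[m][0]}
        if not sources:
            continue
        if len(sources) == 1:
            pure += 1
        else:
            impure += 1

    return {
        "n_nonchimeric_pairs": n_nonchimeric,
        "nonchimeric_recovery": (n_recovered / n_nonchimeric
                                 if n_nonchimeric else float("nan")),
        "crossfamily_chimera_species_assignments":
            n_crossfam_chimera_species,
        "otu_purity": pure / (pure + impure) if (pure + impure) else
            float("nan"),
        "n_otus_scored": pure + impure,
    }


# ---------------------------------------------------------------------------
# Canonical study-scale scenarios


def endtoend_config(seed: int = 1, n_pairs: int = 20000) -> SimConfig:
    """Three mixed samples over 5 species / 3 genera / 2 families."""
    cfg = SimConfig(seed=seed)
    world = make_taxonomy_and_refs(cfg)
    sp = world.species_names
    mixes = [
        dict(zip(sp, (0.40, 0.30, 0.15, 0.10, 0.05))),
        dict(zip(sp, (0.05, 0.10, 0.15, 0.30, 0.40))),
        dict(zip(sp, (0.20, 0.20, 0.20, 0.20, 0.20))),
    ]
    samples = tuple(SampleSpec(f"S{i + 1}", m, n_pairs)
                    for i, m in enumerate(mixes))
    return replace(cfg, samples=samples)


def replicate_config(seed: int = 1, n_replicates: int = 5,
                     n_pairs: int = 2000) -> SimConfig:
    """Two mixtures, ``n_replicates`` independent samples each — the
    replicate-structure scenario (within-mixture similarity should beat
    between-mixture similarity)."""
    cfg = SimConfig(seed=seed, chimera_rate=0.0)
    world = make_taxonomy_and_refs(cfg)
    sp = world.species_names
    mix_a = dict(zip(sp, (0.50, 0.20, 0.15, 0.10, 0.05)))
    mix_b = dict(zip(sp, (0.05, 0.10, 0.15, 0.20, 0.50)))
    samples = []
    for r in range(n_replicates):
        samples.append(SampleSpec(f"A{r + 1}", mix_a, n_pairs))
        samples.append(SampleSpec(f"B{r + 1}", mix_b, n_pairs))
    return replace(cfg, samples=tuple(samples))
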