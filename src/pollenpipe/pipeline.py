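"""End-to-end pipeline orchestration with a single validated config,
structured per-stage logging, and resumable intermediate artifacts.

Stage order: simulate (optional) -> qc -> cluster -> assign -> quantify.
Every stage reads and writes plain standard-format files (FASTQ, FASTA,
TSV, taxdump dialect), so any stage can be replaced by an external tool's
output — e.g. a real BLAST tabular file in place of simulated HSPs.  A run
manifest records per-stage status, input signatures and read-fate counts;
a stage is rerun only when its inputs changed or ``force`` is set.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import yaml

from . import lca as lca_mod
from . import otu as otu_mod
from . import quant as quant_mod
from . import readqc, scaffold, synth, taxonomy

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "cluster", "assign", "quantify")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    output_dir: str
    seed: int = 1
    simulate: synth.SimConfig | None = None
    samples: list[dict] = field(default_factory=list)
    reference_fasta: str | None = None
    accession_map: str | None = None
    nodes_dmp: str | None = None
    names_dmp: str | None = None
    hsp_table: str | None = None
    chimera_scores: str | None = None
    primer_read1: str = readqc.DEFAULT_PRIMER_READ1
    primer_read2: str = readqc.DEFAULT_PRIMER_READ2
    trim: readqc.TrimParams = field(default_factory=readqc.TrimParams)
    map: otu_mod.MapParams = field(default_factory=otu_mod.MapParams)
    lca: lca_mod.LcaParams = field(default_factory=lca_mod.LcaParams)
    quant: quant_mod.QuantParams = field(
        default_factory=quant_mod.QuantParams)
    otu_threshold: float = 0.97
    reference_precluster_threshold: float = 0.95
    chimera_score_threshold: float = 30.0
    curation: list[lca_mod.CurationRule] = field(default_factory=list)

    def __post_init__(self):
        for name in ("otu_threshold", "reference_precluster_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")

    def out(self, *parts) -> Path:
        return Path(self.output_dir).joinpath(*parts)


def _build_dataclass(cls, data: dict, context: str):
    allowed = {f.name for f in dc_fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{context}: {exc}") from exc


def validate_config(source) -> PipelineConfig:
    """Parse and validate a pipeline config from a YAML file path or a
    dict.  Unknown keys are rejected; defaults fill every parameter the
    user does not set."""
    if isinstance(source, dict):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    if "output_dir" not in raw:
        raise ConfigError("config requires output_dir")

    nested = {}
    if "simulate" in raw and raw["simulate"] is not None:
        sim = dict(raw.pop("simulate"))
        specs = [synth.SampleSpec(**s) for s in sim.pop("samples", [])]
        sim["samples"] = tuple(specs)
        nested["simulate"] = _build_dataclass(synth.SimConfig, sim,
                                              "simulate")
    for key, cls in (("trim", readqc.TrimParams),
                     ("map", otu_mod.MapParams),
                     ("lca", lca_mod.LcaParams),
                     ("quant", quant_mod.QuantParams)):
        if key in raw and raw[key] is not None:
            nested[key] = _build_dataclass(cls, dict(raw.pop(key)), key)
        else:
            raw.pop(key, None)
    if "curation" in raw and raw["curation"] is not None:
        rules = []
        for r in raw.pop("curation"):
            r = dict(r)
            for k in ("accessions", "names"):
                if k in r:
                    r[k] = tuple(r[k])
            rules.append(_build_dataclass(lca_mod.CurationRule, r,
                                          "curation rule"))
        nested["curation"] = rules
    else:
        raw.pop("curation", None)

    cfg = _build_dataclass(PipelineConfig, {**raw, **nested}, "config")

    if cfg.simulate is None:
        required = ("samples", "reference_fasta", "accession_map",
                    "nodes_dmp", "names_dmp", "hsp_table")
        for name in required:
            if not getattr(cfg, name):
                raise ConfigError(
                    f"{name} is required when no simulate block is given")
        for name in ("reference_fasta", "accession_map", "nodes_dmp",
                     "names_dmp", "hsp_table", "chimera_scores"):
            path = getattr(cfg, name)
            if path and not Path(path).exists():
                raise ConfigError(f"{name}: no such file: {path}")
        for s in cfg.samples:
            for key in ("fastq1", "fastq2"):
                if not Path(s[key]).exists():
                    raise ConfigError(f"no such file: {s[key]}")
    return cfg


# ---------------------------------------------------------------------------
# Manifest


def _checksum_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _config_signature(cfg: PipelineConfig) -> str:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: enc(getattr(obj, f.name))
                    for f in dc_fields(obj)}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in sorted(obj.items())}
        return obj
    blob = json.dumps(enc(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class RunManifest:
    def __init__(self, path: Path):
        self.path = Path(path)
        self.stages: dict[str, dict] = {}
        if self.path.exists():
            self.stages = json.loads(self.path.read_text())

    def save(self) -> None:
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps(self.stages, indent=1,
                                        sort_keys=True))

    def is_current(self, stage: str, signature: str) -> bool:
        rec = self.stages.get(stage)
        if not rec or rec.get("status") != "complete":
            return False
        if rec.get("signature") != signature:
            return False
        return all(Path(p).exists() for p in rec.get("outputs", []))

    def record(self, stage: str, signature: str, outputs: list[Path],
               counts: dict, wall_time: float) -> None:
        self.stages[stage] = {
            "status": "complete",
            "signature": signature,
            "outputs": [str(p) for p in outputs],
            "output_checksums": {str(p): _checksum_file(p)
                                 for p in outputs},
            "counts": counts,
            "wall_time_s": round(wall_time, 3),
        }
        self.save()


# ---------------------------------------------------------------------------
# Stage implementations (disk-to-disk, so any stage can resume)


def _sample_specs(cfg: PipelineConfig) -> list[tuple[str, Path, Path]]:
    if cfg.simulate is not None:
        return [(s.sample_id,
                 cfg.out("raw", f"{s.sample_id}_R1.fastq"),
                 cfg.out("raw", f"{s.sample_id}_R2.fastq"))
                for s in cfg.simulate.samples]
    return [(s["sample_id"], Path(s["fastq1"]), Path(s["fastq2"]))
            for s in cfg.samples]


def _stage_simulate(cfg: PipelineConfig) -> tuple[list[Path], dict]:
    world = synth.make_taxonomy_and_refs(cfg.simulate)
    raw_dir = cfg.out("raw")
    raw_dir.mkdir(parents=True, exist_ok=True)
    outputs = []
    all_pairs, truth = synth.simulate_all_samples(world)
    by_sample: dict[str, list] = {}
    for p in all_pairs:
        by_sample.setdefault(p.sample_id, []).append(p)
    for sid, p1, p2 in _sample_specs(cfg):
        readqc.write_fastq_pairs(by_sample.get(sid, []), p1, p2)
        outputs.extend([p1, p2])
    truth_path = cfg.out("raw", "truth.tsv")
    truth.to_csv(truth_path, sep="\t", index=False)
    ref_path = cfg.out("raw", "reference.fasta")
    world.refs.write_fasta(ref_path)
    acc_path = cfg.out("raw", "acc2taxid.tsv")
    taxonomy.write_accession_map(world.acc2taxid, acc_path)
    nodes_path = cfg.out("raw", "nodes.dmp")
    names_path = cfg.out("raw", "names.dmp")
    synth.write_taxdump(world, nodes_path, names_path)
    outputs += [truth_path, ref_path, acc_path, nodes_path, names_path]
    return outputs, {"pairs_out": len(all_pairs)}


def _resolve_inputs(cfg: PipelineConfig):
    """Paths of reference/taxonomy inputs (simulated or user-supplied)."""
    if cfg.simulate is not None:
        return {
            "reference_fasta": cfg.out("raw", "reference.fasta"),
            "accession_map": cfg.out("raw", "acc2taxid.tsv"),
            "nodes_dmp": cfg.out("raw", "nodes.dmp"),
            "names_dmp": cfg.out("raw", "names.dmp"),
        }
    return {
        "reference_fasta": Path(cfg.reference_fasta),
        "accession_map": Path(cfg.accession_map),
        "nodes_dmp": Path(cfg.nodes_dmp),
        "names_dmp": Path(cfg.names_dmp),
    }


def _stage_qc(cfg: PipelineConfig) -> tuple[list[Path], dict]:
    qc_dir = cfg.out("qc")
    qc_dir.mkdir(parents=True, exist_ok=True)
    primers1 = readqc.expand_primers(cfg.primer_read1)
    primers2 = readqc.expand_primers(cfg.primer_read2)
    outputs: list[Path] = []
    fate: dict[str, int] = {}
    n_in = n_out = 0
    report_rows = []
    for sid, p1, p2 in _sample_specs(cfg):
        pairs = readqc.read_fastq_pairs(p1, p2, sample_id=sid)
        kept = []
        reasons: dict[str, int] = {}
        for pair in pairs:
            trimmed, reason = readqc.qc_pair(pair, primers1, primers2,
                                             cfg.trim)
            if trimmed is None:
                reasons[reason] = reasons.get(reason, 0) + 1
            else:
                kept.append(trimmed)
        o1 = qc_dir / f"{sid}_R1.fastq"
        o2 = qc_dir / f"{sid}_R2.fastq"
        readqc.write_fastq_pairs(kept, o1, o2)
        outputs += [o1, o2]
        n_in += len(pairs)
        n_out += len(kept)
        for r, c in reasons.items():
            fate[r] = fate.get(r, 0) + c
            report_rows.append((sid, r, c))
        report_rows.append((sid, "pass", len(kept)))
    report = qc_dir / "qc_report.tsv"
    with open(report, "w") as fh:
        fh.write("sample\treason\tn_pairs\n")
        for sid, r, c in sorted(report_rows):
            fh.write(f"{sid}\t{r}\t{c}\n")
    outputs.append(report)
    counts = {"pairs_in": n_in, "pairs_out": n_out, "dropped": fate}
    if n_in != n_out + sum(fate.values()):
        raise StageError("qc read-fate accounting does not conserve pairs")
    return outputs, counts


def _load_qc_scaffolds(cfg: PipelineConfig) -> list[scaffold.Scaffold]:
    scaffolds = []
    for sid, _, _ in _sample_specs(cfg):
        pairs = readqc.read_fastq_pairs(cfg.out("qc", f"{sid}_R1.fastq"),
                                        cfg.out("qc", f"{sid}_R2.fastq"),
                                        sample_id=sid)
        for pair in pairs:
            scaffolds.append(
                scaffold.mask_scaffold(scaffold.build_scaffold(pair)))
    return scaffolds


def _stage_cluster(cfg: PipelineConfig) -> tuple[list[Path], dict]:
    inputs = _resolve_inputs(cfg)
    acc2taxid = taxonomy.load_accession_map(inputs["accession_map"])
    refdb = otu_mod.ReferenceDb.from_fasta(inputs["reference_fasta"],
                                           acc2taxid)
    refdb, clusters = otu_mod.precluster_reference(
        refdb, cfg.reference_precluster_threshold)

    scaffolds = _load_qc_scaffolds(cfg)
    by_id = {sc.id: sc for sc in scaffolds}
    bins, unbinned = otu_mod.bin_pairs(scaffolds, refdb, cfg.map, clusters)

    otus: list[otu_mod.Otu] = []
    for bin_key in sorted(bins):
        members = [by_id[i] for i in bins[bin_key]
                   if by_id[i].clustering_eligible]
        otus.extend(otu_mod.greedy_cluster(members, cfg.otu_threshold,
                                           start_index=len(otus) + 1))
    recaptured = otu_mod.recapture_unclustered(
        [by_id[i] for i in unbinned], otus, cfg.map, cfg.otu_threshold)
    otus.extend(recaptured)

    # third mapping: consensus from pairs mapped against representatives
    map1 = otu_mod.map_pairs_to_otus(scaffolds, otus, cfg.map,
                                     use_consensus=False)
    by_otu: dict[str, list] = {}
    for pm in map1:
        if pm.status == "mapped":
            by_otu.setdefault(pm.otu_id, []).append(pm)
    for otu in otus:
        otu.consensus = otu_mod.build_consensus(
            otu, by_otu.get(otu.otu_id, []))

    if cfg.chimera_scores:
        scores = otu_mod.load_chimera_scores(cfg.chimera_scores)
        otus, removed = otu_mod.apply_chimera_scores(
            otus, scores, cfg.chimera_score_threshold)
        logger.info("chimera filter removed %d OTUs", len(removed))

    # fourth mapping, against consensus sequences: the counting mapping
    map2 = otu_mod.map_pairs_to_otus(scaffolds, otus, cfg.map,
                                     use_consensus=True,
                                     want_projection=False)

    cdir = cfg.out("cluster")
    cdir.mkdir(parents=True, exist_ok=True)
    rep_path = cdir / "otus_rep.fasta"
    with open(rep_path, "w") as fh:
        for otu in otus:
            rep = otu.representative
            fh.write(f">{otu.otu_id} len1={rep.len1} len2={rep.len2} "
                     f"members={len(otu.member_ids)}\n{rep.sequence}\n")
    cons_path = cdir / "otus_consensus.fasta"
    otu_mod.write_otus_fasta(otus, cons_path, consensus=True)
    memb_path = cdir / "membership.tsv"
    otu_mod.write_membership_tsv(otus, memb_path)
    map_path = cdir / "mappings.tsv"
    with open(map_path, "w") as fh:
        fh.write("pair_id\tsample_id\totu_id\tstatus\tidentity\tindels\n")
        for pm in map2:
            fh.write(f"{pm.pair_id}\t{pm.sample_id}\t{pm.otu_id or 'NA'}\t"
                     f"{pm.status}\t{pm.identity:.4f}\t"
                     f"{pm.indel_positions}\n")
    status_counts: dict[str, int] = {}
    for pm in map2:
        status_counts[pm.status] = status_counts.get(pm.status, 0) + 1
    if sum(status_counts.values()) != len(scaffolds):
        raise StageError("mapping accounting does not conserve pairs")
    counts = {"pairs_in": len(scaffolds), "n_otus": len(otus),
              "mapping": status_counts}
    return [rep_path, cons_path, memb_path, map_path], counts


def _load_otus(cfg: PipelineConfig) -> list[otu_mod.Otu]:
    from Bio import SeqIO
    membership: dict[str, list[str]] = {}
    with open(cfg.out("cluster", "membership.tsv")) as fh:
        next(fh)
        for line in fh:
            otu_id, member = line.rstrip("\n").split("\t")
            membership.setdefault(otu_id, []).append(member)
    otus = []
    cons = {rec.id: str(rec.seq) for rec in SeqIO.parse(
        str(cfg.out("cluster", "otus_consensus.fasta")), "fasta")}
    for rec in SeqIO.parse(str(cfg.out("cluster", "otus_rep.fasta")),
                           "fasta"):
        attrs = dict(kv.split("=") for kv in rec.description.split()[1:])
        rep = scaffold.Scaffold(rec.id, str(rec.seq), int(attrs["len1"]),
                                int(attrs["len2"]))
        otus.append(otu_mod.Otu(rec.id, rep,
                                membership.get(rec.id, []),
                                consensus=cons.get(rec.id)))
    return otus


def _load_mappings(cfg: PipelineConfig) -> list[otu_mod.PairMapping]:
    out = []
    with open(cfg.out("cluster", "mappings.tsv")) as fh:
        next(fh)
        for line in fh:
            pid, sid, otu_id, status, ident, indels = \
                line.rstrip("\n").split("\t")
            out.append(otu_mod.PairMapping(
                pid, sid, None if otu_id == "NA" else otu_id, status,
                float(ident), int(indels)))
    return out


def _stage_assign(cfg: PipelineConfig) -> tuple[list[Path], dict]:
    inputs = _resolve_inputs(cfg)
    tree = taxonomy.load_taxdump(inputs["nodes_dmp"], inputs["names_dmp"])
    acc2taxid = taxonomy.load_accession_map(inputs["accession_map"])
    otus = _load_otus(cfg)

    adir = cfg.out("assign")
    adir.mkdir(parents=True, exist_ok=True)
    hsp_path = cfg.out("assign", "hsps.tsv")
    if cfg.hsp_table:
        hsp_path = Path(cfg.hsp_table)
    else:
        if cfg.simulate is None:
            raise StageError("assign requires hsp_table when not simulating")
        from ._seq import reverse_complement
        world = synth.make_taxonomy_and_refs(cfg.simulate)
        reads = []
        for otu in otus:
            rep = otu.representative
            reads.append((f"{otu.otu_id}/1", rep.seg1, 1))
            reads.append((f"{otu.otu_id}/2",
                          reverse_complement(rep.seg2), 2))
        synth.write_hsp_table(synth.simulate_hsp_tables(reads, world),
                              hsp_path)

    hsps = lca_mod.parse_hsp_table(hsp_path, acc2taxid, cfg.lca)
    hsps = lca_mod.filter_accessions(hsps, cfg.curation, tree)
    by_read: dict[str, list] = {}
    for h in hsps:
        by_read.setdefault(h.read_id, []).append(h)

    assignments = []
    for otu in otus:
        assignments.append(lca_mod.paired_lca(
            by_read.get(f"{otu.otu_id}/1", []),
            by_read.get(f"{otu.otu_id}/2", []),
            tree, cfg.lca, otu_id=otu.otu_id))
    assignments = lca_mod.apply_curation(assignments, cfg.curation, tree)

    assign_path = adir / "assignments.tsv"
    lca_mod.write_assignments_tsv(assignments, assign_path)

    mapped_counts: dict[str, int] = {}
    for pm in _load_mappings(cfg):
        if pm.status == "mapped":
            mapped_counts[pm.otu_id] = mapped_counts.get(pm.otu_id, 0) + 1
    summary = lca_mod.assignment_rank_summary(assignments, mapped_counts)
    summary_path = adir / "rank_summary.tsv"
    summary.to_csv(summary_path, sep="\t", index=False)

    outputs = [assign_path, summary_path]
    if not cfg.hsp_table:
        outputs.append(hsp_path)
    n_assigned = sum(1 for a in assignments if a.assigned)
    return outputs, {"n_otus": len(otus), "n_assigned": n_assigned}


def _load_assignments(cfg: PipelineConfig) -> list[lca_mod.Assignment]:
    out = []
    with open(cfg.out("assign", "assignments.tsv")) as fh:
        next(fh)
        for line in fh:
            (otu_id, rank, taxid, name, comb, pid, bit, target,
             conflict) = line.rstrip("\n").split("\t")
            out.append(lca_mod.Assignment(
                otu_id=otu_id,
                assigned_rank=None if rank == "NA" else rank,
                taxid=None if taxid == "NA" else int(taxid),
                taxon_name=None if name == "NA" else name,
                combined_score=float(comb),
                mean_percent_identity=float(pid),
                mean_bit_score=float(bit),
                in_target=bool(int(target)),
                conflict_flag=bool(int(conflict))))
    return out


RAREFACTION_DEPTHS = (100, 200, 500, 1000, 2000, 5000, 10000, 20000, 50000)


def _stage_quantify(cfg: PipelineConfig) -> tuple[list[Path], dict]:
    mappings = _load_mappings(cfg)
    assignments = _load_assignments(cfg)
    samples = [sid for sid, _, _ in _sample_specs(cfg)]
    matrix = quant_mod.tally_counts(mappings, assignments, samples)
    matrix = quant_mod.filter_min_total(matrix, cfg.quant)
    cpm = quant_mod.to_cpm(matrix, cfg.quant)

    qdir = cfg.out("quant")
    qdir.mkdir(parents=True, exist_ok=True)
    counts_path = qdir / "counts.tsv"
    quant_mod.write_count_matrix(matrix, counts_path)
    cpm_path = qdir / "cpm.tsv"
    cpm_out = cpm.copy()
    cpm_out.index = ["\t".join(map(str, t)) for t in cpm_out.index]
    with open(cpm_path, "w") as fh:
        fh.write("taxid\tname\trank\t" + "\t".join(cpm.columns) + "\n")
        for idx, row in zip(cpm_out.index, cpm_out.to_numpy()):
            fh.write(idx + "\t" + "\t".join(f"{v:.2f}" for v in row) + "\n")

    # species-level plant counts drive diversity and rarefaction
    species_rows = [t for t in matrix.taxa if t[2] == "species"]
    sp = matrix.counts.loc[species_rows] if species_rows \
        else matrix.counts.iloc[0:0]
    div_path = qdir / "diversity.tsv"
    with open(div_path, "w") as fh:
        fh.write("sample\tn_species\tn_counts\teffective_species\n")
        for s in matrix.samples:
            col = sp[s] if s in sp.columns else None
            if col is None or col.sum() == 0:
                fh.write(f"{s}\t0\t0\tNA\n")
                continue
            d = quant_mod.chao_shen_diversity(col.to_numpy())
            fh.write(f"{s}\t{int((col > 0).sum())}\t{int(col.sum())}\t"
                     f"{d:.4f}\n")

    bc_path = qdir / "bray_curtis.tsv"
    if len(matrix.samples) >= 2 and len(matrix.taxa) > 0:
        bc = quant_mod.bray_curtis_matrix(cpm)
        bc.to_csv(bc_path, sep="\t", float_format="%.4f")
    else:
        bc_path.write_text("")

    rare_path = qdir / "rarefaction.tsv"
    with open(rare_path, "w") as fh:
        fh.write("sample\tdepth\texpected_richness\n")
        for s in matrix.samples:
            col = sp[s].to_numpy() if s in sp.columns else []
            n = int(sum(col))
            if n == 0:
                continue
            depths = [d for d in RAREFACTION_DEPTHS if d <= n] or [n]
            if depths[-1] != n:
                depths.append(n)
            for d, e in zip(depths,
                            quant_mod.rarefaction_curve(col, depths)):
                fh.write(f"{s}\t{d}\t{e:.4f}\n")

    counts = {"n_taxa": len(matrix.taxa),
              "library_sizes": {s: int(matrix.library_sizes[s])
                                for s in matrix.samples}}
    return [counts_path, cpm_path, div_path, bc_path, rare_path], counts


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "cluster": _stage_cluster,
    "assign": _stage_assign,
    "quantify": _stage_quantify,
}


def run_pipeline(cfg: PipelineConfig, stages=None,
                 force: bool = False) -> RunManifest:
    """Execute the requested stages in order, skipping stages whose inputs
    are unchanged since the last complete run."""
    requested = list(stages) if stages else list(STAGES)
    for s in requested:
        if s not in STAGES:
            raise ConfigError(f"unknown stage {s!r}")
    if cfg.simulate is None and "simulate" in requested:
        requested.remove("simulate")

    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(out_dir / "manifest.json")
    base_sig = _config_signature(cfg)

    prev_sig = base_sig
    for stage in STAGES:
        if stage == "simulate" and cfg.simulate is None:
            continue
        sig = hashlib.sha256(
            f"{prev_sig}:{stage}".encode()).hexdigest()[:16]
        if stage in requested:
            if not force and manifest.is_current(stage, sig):
                logger.info("stage %s up to date; skipped", stage)
            else:
                logger.info("running stage %s", stage)
                t0 = time.time()
                try:
                    outputs, counts = _STAGE_FUNCS[stage](cfg)
                except (ConfigError, StageError):
                    raise
                except Exception as exc:
                    raise StageError(f"stage {stage} failed: {exc}") from exc
                manifest.record(stage, sig, outputs, counts,
                                time.time() - t0)
        prev_sig = sig
    return manifest
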