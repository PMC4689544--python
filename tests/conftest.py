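import numpy as np
import pandas as pd
import pytest

from pollenpipe import pipeline, synth
from pollenpipe.taxonomy import TaxonomyTree


@pytest.fixture
def tree() -> TaxonomyTree:
    """Hand-built taxonomy: a plant clade (with and without a tribe node)
    and a fungal outgroup."""
    nodes = {
        1: (1, "no rank"),
        2: (1, "kingdom"),      # Viridiplantae
        3: (2, "order"),        # Poales
        4: (3, "family"),       # Poaceae
        5: (4, "tribe"),        # Triticeae
        6: (5, "genus"),        # Elymus
        7: (6, "species"),      # Elymus repens
        8: (4, "genus"),        # Zea (no tribe in lineage)
        9: (8, "species"),      # Zea mays
        10: (1, "kingdom"),     # Fungi
        11: (10, "order"),
        12: (11, "family"),
        13: (12, "genus"),
        14: (13, "species"),
    }
    names = {
        1: "root", 2: "Viridiplantae", 3: "Poales", 4: "Poaceae",
        5: "Triticeae", 6: "Elymus", 7: "Elymus repens", 8: "Zea",
        9: "Zea mays", 10: "Fungi", 11: "Hypocreales", 12: "Nectriaceae",
        13: "Fusarium", 14: "Fusarium graminearum",
    }
    return TaxonomyTree(nodes, names)


def _run_pipeline_with_eval(sim_cfg, out_dir):
    cfg = pipeline.PipelineConfig(output_dir=str(out_dir), seed=sim_cfg.seed,
                                  simulate=sim_cfg)
    manifest = pipeline.run_pipeline(cfg)
    world = synth.make_taxonomy_and_refs(sim_cfg)
    truth = pd.read_csv(cfg.out("raw", "truth.tsv"), sep="\t")
    mappings = pipeline._load_mappings(cfg)
    assignments = pipeline._load_assignments(cfg)
    otus = pipeline._load_otus(cfg)
    metrics = synth.evaluate_run(world, truth, mappings, assignments, otus)
    return {
        "cfg": cfg, "manifest": manifest, "world": world, "truth": truth,
        "mappings": mappings, "assignments": assignments, "otus": otus,
        "metrics": metrics,
    }


@pytest.fixture(scope="session")
def endtoend_run(tmp_path_factory):
    """The study-scale synthetic run: 3 samples x 20,000 pairs over
    5 species / 3 genera / 2 families, error 0.001, chimera rate 0.02."""
    sim = synth.endtoend_config(seed=1)
    return _run_pipeline_with_eval(sim, tmp_path_factory.mktemp("e2e"))


@pytest.fixture(scope="session")
def replicate_run(tmp_path_factory):
    """Two mixtures x five replicate samples of 2,000 pairs each."""
    sim = synth.replicate_config(seed=11)
    return _run_pipeline_with_eval(sim, tmp_path_factory.mktemp("reps"))
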