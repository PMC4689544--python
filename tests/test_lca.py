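"""Paired-read LCA assignment: score tables, windows, curation, summaries."""

import numpy as np
import pytest

from pollenpipe.lca import (Assignment, CurationRule, HspRecord, LcaParams,
                            apply_curation, assignment_rank_summary,
                            filter_accessions, keep_top_accessions,
                            paired_lca, parse_hsp_table)
from pollenpipe.taxonomy import TaxonomyTree

PARAMS = LcaParams()


def _hsp(read_id, acc, bit, taxid, pid=98.0):
    return HspRecord(read_id, acc, bit, pid, taxid)


@pytest.fixture
def two_species_tree():
    """Two species in one genus plus a species in a second genus (same
    family) and a fungal branch."""
    nodes = {
        1: (1, "no rank"),
        2: (1, "kingdom"),      # Viridiplantae
        3: (2, "order"),
        4: (3, "family"),
        5: (4, "genus"),
        6: (5, "species"),
        7: (5, "species"),
        8: (4, "genus"),
        9: (8, "species"),
        10: (1, "kingdom"),     # Fungi
        11: (10, "order"), 12: (11, "family"), 13: (12, "genus"),
        14: (13, "species"),
    }
    names = {1: "root", 2: "Viridiplantae", 3: "OrderA", 4: "FamilyA",
             5: "GenusA", 6: "Species A1", 7: "Species A2", 8: "GenusB",
             9: "Species B1", 10: "Fungi", 11: "OrderF", 12: "FamilyF",
             13: "GenusF", 14: "Species F1"}
    return TaxonomyTree(nodes, names)


class TestPairedLca:
    def test_single_candidate_above_threshold(self, two_species_tree):
        a = paired_lca([_hsp("o/1", "a1", 350, 6)],
                       [_hsp("o/2", "a1", 350, 6)],
                       two_species_tree, PARAMS, otu_id="o")
        assert a.assigned_rank == "species"
        assert a.taxon_name == "Species A1"
        assert a.combined_score == 700
        assert a.in_target

    def test_tie_within_window_rolls_up_to_genus(self, two_species_tree):
        # combined 700 and 690: 690 >= 0.97*700 -> species undetermined;
        # shared genus scores max(350,345)+max(350,345)=700 -> genus
        m1 = [_hsp("o/1", "x1", 350, 6), _hsp("o/1", "x2", 345, 7)]
        m2 = [_hsp("o/2", "x1", 350, 6), _hsp("o/2", "x2", 345, 7)]
        a = paired_lca(m1, m2, two_species_tree, PARAMS)
        assert a.assigned_rank == "genus"
        assert a.taxon_name == "GenusA"
        assert a.combined_score == 700

    def test_runner_up_outside_window_keeps_species(self, two_species_tree):
        # 650 > 600 but 650 < 0.97*700 = 679 -> only the leader qualifies
        m1 = [_hsp("o/1", "x1", 350, 6), _hsp("o/1", "x2", 325, 7)]
        m2 = [_hsp("o/2", "x1", 350, 6), _hsp("o/2", "x2", 325, 7)]
        a = paired_lca(m1, m2, two_species_tree, PARAMS)
        assert a.assigned_rank == "species"
        assert a.taxon_name == "Species A1"

    def test_window_margin_at_threshold_is_18_bits(self):
        assert PARAMS.min_margin_at_threshold == pytest.approx(18.0)

    def test_conflicting_mates_unassigned_and_flagged(self,
                                                      two_species_tree):
        # plant family on mate 1 vs fungal family on mate 2, no combined
        # score above 600 at any rank
        a = paired_lca([_hsp("o/1", "p", 400, 6)],
                       [_hsp("o/2", "f", 380, 14)],
                       two_species_tree, PARAMS)
        assert not a.assigned
        assert a.conflict_flag

    def test_single_mate_support_is_insufficient(self, two_species_tree):
        a = paired_lca([_hsp("o/1", "x", 650, 6)], [],
                       two_species_tree, PARAMS)
        assert not a.assigned

    def test_strictly_greater_than_600(self, two_species_tree):
        a = paired_lca([_hsp("o/1", "x", 300, 6)],
                       [_hsp("o/2", "x", 300, 6)],
                       two_species_tree, PARAMS)
        assert not a.assigned  # combined exactly 600 does not qualify
        b = paired_lca([_hsp("o/1", "x", 300.5, 6)],
                       [_hsp("o/2", "x", 300, 6)],
                       two_species_tree, PARAMS)
        assert b.assigned_rank == "species"

    def test_mean_stats_over_winning_taxon_hsps(self, two_species_tree):
        m1 = [_hsp("o/1", "x1", 400, 6, pid=98.0),
              _hsp("o/1", "x2", 350, 6, pid=96.0)]
        m2 = [_hsp("o/2", "x1", 380, 6, pid=97.0)]
        a = paired_lca(m1, m2, two_species_tree, PARAMS)
        assert a.mean_bit_score == pytest.approx((400 + 350 + 380) / 3)
        assert a.mean_percent_identity == pytest.approx((98 + 96 + 97) / 3)

    def test_monotonicity_adding_winner_hsp(self, two_species_tree):
        m1 = [_hsp("o/1", "x1", 350, 6), _hsp("o/1", "x2", 325, 7)]
        m2 = [_hsp("o/2", "x1", 350, 6)]
        before = paired_lca(m1, m2, two_species_tree, PARAMS)
        assert before.assigned_rank == "species"
        m2b = m2 + [_hsp("o/2", "x3", 360, 6)]
        after = paired_lca(m1, m2b, two_species_tree, PARAMS)
        assert after.assigned_rank == "species"
        assert after.combined_score >= before.combined_score

    def test_wider_window_never_adds_species_assignments(
            self, two_species_tree):
        rng = np.random.default_rng(8)
        narrow = LcaParams(rel_window=0.03)
        wide = LcaParams(rel_window=0.10)
        n_narrow = n_wide = 0
        for _ in range(60):
            m1 = [_hsp("o/1", f"a{t}", float(rng.integers(250, 420)), t)
                  for t in (6, 7, 9)]
            m2 = [_hsp("o/2", f"b{t}", float(rng.integers(250, 420)), t)
                  for t in (6, 7, 9)]
            n_narrow += paired_lca(m1, m2, two_species_tree,
                                   narrow).assigned_rank == "species"
            n_wide += paired_lca(m1, m2, two_species_tree,
                                 wide).assigned_rank == "species"
        assert n_wide <= n_narrow


class TestHspTable:
    def test_top_25_distinct_accessions(self):
        hsps = [_hsp("r/1", f"acc{i:02d}", 500 - i, 6) for i in range(30)]
        kept = keep_top_accessions(hsps, 25)
        assert len(kept) == 25
        assert max(h.bit_score for h in hsps) in [h.bit_score for h in kept]
        assert all(h.bit_score >= 500 - 24 for h in kept)

    def test_few_accessions_all_retained(self):
        hsps = [_hsp("r/1", f"acc{i}", 300 + i, 6) for i in range(3)]
        assert len(keep_top_accessions(hsps, 25)) == 3

    def test_parse_tabular(self, tmp_path):
        path = tmp_path / "hsps.tsv"
        rows = [
            "r/1\tACC1\t98.5\t0\t0\t0\t0\t0\t0\t0\t0.0\t450.0\t6",
            "r/1\tACC1\t97.0\t0\t0\t0\t0\t0\t0\t0\t0.0\t430.0\t6",
            "r/1\tACC2\t95.0\t0\t0\t0\t0\t0\t0\t0\t0.0\t400.0\t7",
        ]
        path.write_text("\n".join(rows) + "\n")
        hsps = parse_hsp_table(path)
        assert len(hsps) == 2  # duplicate (read, accession) keeps max bit
        by_acc = {h.accession: h for h in hsps}
        assert by_acc["ACC1"].bit_score == 450.0

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("r/1\tACC1\tnope\n")
        with pytest.raises(ValueError, match=":1"):
            parse_hsp_table(path)


class TestFilterAccessions:
    def test_environmental_sample_lineage_removed(self, two_species_tree):
        tree = two_species_tree
        tree.names[13] = "environmental sample clone"
        rules = [CurationRule("exclude_name_substring",
                              substring="environmental sample")]
        hsps = [_hsp("r/1", "env", 400, 14), _hsp("r/1", "ok", 400, 6)]
        kept = filter_accessions(hsps, rules, tree)
        assert [h.accession for h in kept] == ["ok"]

    def test_excluded_accession_removed(self, two_species_tree):
        rules = [CurationRule("exclude_accession",
                              accessions=("FJ860088.1",))]
        hsps = [_hsp("r/1", "FJ860088.1", 400, 6),
                _hsp("r/1", "ok", 400, 6)]
        kept = filter_accessions(hsps, rules, two_species_tree)
        assert [h.accession for h in kept] == ["ok"]

    def test_clean_lineage_kept(self, two_species_tree):
        rules = [CurationRule("exclude_name_substring",
                              substring="environmental sample")]
        hsps = [_hsp("r/1", "ok", 400, 6)]
        assert filter_accessions(hsps, rules, two_species_tree) == hsps


class TestCuration:
    def _trees(self):
        nodes = {1: (1, "no rank"), 2: (1, "kingdom"), 3: (2, "order"),
                 4: (3, "family"), 5: (4, "genus"), 6: (5, "species"),
                 7: (4, "genus"), 8: (7, "species"), 9: (7, "species"),
                 10: (7, "species")}
        names = {1: "root", 2: "Viridiplantae", 3: "Poales", 4: "Poaceae",
                 5: "Alopecurus", 6: "Dupontia fisheri", 7: "Melilotus",
                 8: "Melilotus officinalis", 9: "Melilotus alba",
                 10: "Melilotus dentatus"}
        return TaxonomyTree(nodes, names)

    def test_reassign_to_genus(self):
        tree = self._trees()
        a = Assignment("o1", "species", 6, "Dupontia fisheri", 700, 95, 400,
                       True, False)
        rules = [CurationRule("reassign_taxon",
                              match_name="Dupontia fisheri",
                              target_name="Alopecurus",
                              target_rank="genus")]
        (out,) = apply_curation([a], rules, tree)
        assert out.assigned_rank == "genus"
        assert out.taxon_name == "Alopecurus"

    def test_merge_species_pools_names(self):
        tree = self._trees()
        assigns = [Assignment(f"o{i}", "species", t, n, 700, 98, 400, True,
                              False)
                   for i, (t, n) in enumerate(
                       [(9, "Melilotus alba"), (10, "Melilotus dentatus"),
                        (8, "Melilotus officinalis")])]
        rules = [CurationRule("merge_species",
                              names=("Melilotus alba", "Melilotus dentatus"),
                              target_name="Melilotus officinalis")]
        out = apply_curation(assigns, rules, tree)
        assert {a.taxon_name for a in out} == {"Melilotus officinalis"}

    def test_empty_rules_noop(self):
        tree = self._trees()
        a = Assignment("o1", "species", 8, "Melilotus officinalis", 700,
                       98, 400, True, False)
        assert apply_curation([a], [], tree) == [a]

    def test_unknown_target_taxon_raises(self):
        tree = self._trees()
        rules = [CurationRule("reassign_taxon", match_name="x",
                              target_name="NoSuchTaxon",
                              target_rank="genus")]
        with pytest.raises(ValueError, match="NoSuchTaxon"):
            apply_curation([], rules, tree)


class TestRankSummary:
    def _assignment(self, otu_id, rank, in_target=True):
        return Assignment(otu_id, rank, 6 if rank else None,
                          "x" if rank else None, 700, 98, 400,
                          in_target if rank else False, False)

    def test_all_species_fraction_one(self):
        assigns = [self._assignment(f"o{i}", "species") for i in range(4)]
        df = assignment_rank_summary(assigns, {f"o{i}": 10
                                               for i in range(4)})
        row = df[df["bin"] == "species"].iloc[0]
        assert row.fraction_otus == 1.0
        assert row.fraction_read_pairs == 1.0

    def test_equal_counts_half_half(self):
        assigns = [self._assignment("o1", "species"),
                   self._assignment("o2", "genus")]
        df = assignment_rank_summary(assigns, {"o1": 10, "o2": 10})
        assert df.set_index("bin").loc["species",
                                       "fraction_otus"] == 0.5
        assert df.set_index("bin").loc["genus",
                                       "fraction_read_pairs"] == 0.5

    def test_unequal_counts_shift_read_basis_only(self):
        assigns = [self._assignment("o1", "species"),
                   self._assignment("o2", "genus")]
        df = assignment_rank_summary(assigns, {"o1": 30, "o2": 10})
        idx = df.set_index("bin")
        assert idx.loc["species", "fraction_otus"] == 0.5
        assert idx.loc["species", "fraction_read_pairs"] == 0.75
        assert df.fraction_otus.sum() == pytest.approx(1.0)
        assert df.fraction_read_pairs.sum() == pytest.approx(1.0)
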