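"""OTU clustering, binning, mapping, consensus, chimera filtering."""

import numpy as np
import pytest

from pollenpipe._seq import reverse_complement
from pollenpipe.otu import (MapParams, Otu, ReferenceDb, RefSeq,
                            apply_chimera_scores, bin_pairs, build_consensus,
                            greedy_cluster, map_pairs_to_otus,
                            precluster_reference, recapture_unclustered,
                            scaffold_identity)
from pollenpipe.scaffold import LINKER_LEN, Scaffold

PARAMS = MapParams()


def _seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


def _scaffold(sid, seg1, seg2, sample="S1"):
    return Scaffold(sid, seg1 + "N" * LINKER_LEN + seg2,
                    len(seg1), len(seg2), sample)


def _mutate(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestGreedyCluster:
    def test_identical_scaffolds_one_cluster(self):
        a = _scaffold("a", _seq(260, 1), _seq(260, 2))
        b = _scaffold("b", a.seg1, a.seg2)
        otus = greedy_cluster([a, b])
        assert len(otus) == 1
        assert sorted(otus[0].member_ids) == ["a", "b"]

    def test_far_apart_scaffolds_two_clusters(self):
        a = _scaffold("a", _seq(260, 3), _seq(260, 4))
        b = _scaffold("b", _seq(260, 5), _seq(260, 6))
        assert len(greedy_cluster([a, b])) == 2

    def test_97_percent_boundary(self):
        # 500 informative bases; 15 substitutions = 0.970, 16 = 0.968
        seg1, seg2 = _seq(250, 7), _seq(250, 8)
        a = _scaffold("a", seg1, seg2)
        b15 = _scaffold("b", _mutate(seg1, range(0, 150, 10)), seg2)
        b16 = _scaffold("c", _mutate(seg1, range(0, 160, 10)), seg2)
        assert scaffold_identity(a, b15) == pytest.approx(0.97, abs=1e-6)
        assert len(greedy_cluster([a, b15])) == 1
        assert len(greedy_cluster([a, b16])) == 2

    def test_representative_is_longest_and_members_meet_threshold(self):
        seg1, seg2 = _seq(262, 9), _seq(260, 10)
        long = _scaffold("long", seg1, seg2)
        short = _scaffold("short", seg1[:255], seg2)
        otus = greedy_cluster([short, long])
        assert len(otus) == 1
        assert otus[0].representative.id == "long"
        for member in (long, short):
            assert scaffold_identity(member, otus[0].representative) >= 0.97

    def test_empty_input(self):
        assert greedy_cluster([]) == []

    def test_deterministic(self):
        scaffolds = [_scaffold(f"s{i}", _seq(260, 20 + i // 3),
                               _seq(260, 40 + i // 3)) for i in range(9)]
        a = greedy_cluster(scaffolds)
        b = greedy_cluster(scaffolds)
        assert [(o.otu_id, o.member_ids) for o in a] == \
            [(o.otu_id, o.member_ids) for o in b]


def _refdb():
    refs = [RefSeq(f"ACC{i}", _seq(900, 100 + i), 100 + i)
            for i in range(3)]
    return ReferenceDb(refs)


def _pair_from_ref(sid, ref_seq, read_len=300):
    seg1 = ref_seq[:read_len]
    seg2 = ref_seq[-read_len:]
    return _scaffold(sid, seg1, seg2)


class TestBinPairs:
    def test_exact_pair_binned_to_its_accession(self):
        db = _refdb()
        sc = _pair_from_ref("p1", db.accessions[0].sequence)
        bins, unbinned = bin_pairs([sc], db, PARAMS)
        assert bins == {"ACC0": ["p1"]}
        assert unbinned == []

    def test_discordant_mates_unbinned(self):
        db = _refdb()
        chimera = _scaffold("p1", db.accessions[0].sequence[:300],
                            db.accessions[1].sequence[-300:])
        bins, unbinned = bin_pairs([chimera], db, PARAMS)
        assert unbinned == ["p1"]

    def test_insert_above_1100_unbinned(self):
        long_ref = RefSeq("LONG", _seq(1300, 500), 500)
        db = ReferenceDb([long_ref])
        sc = _scaffold("p1", long_ref.sequence[:300],
                       long_ref.sequence[-300:])  # implied insert 1300
        bins, unbinned = bin_pairs([sc], db, PARAMS)
        assert unbinned == ["p1"]

    def test_partition_is_complete_and_disjoint(self):
        db = _refdb()
        scaffolds = [_pair_from_ref(f"p{i}",
                                    db.accessions[i % 3].sequence)
                     for i in range(6)]
        scaffolds.append(_scaffold("odd", _seq(300, 999), _seq(300, 998)))
        bins, unbinned = bin_pairs(scaffolds, db, PARAMS)
        binned = [pid for ids in bins.values() for pid in ids]
        assert sorted(binned + unbinned) == sorted(s.id for s in scaffolds)
        assert len(binned) == len(set(binned))


class TestPrecluster:
    def test_near_identical_references_collapse(self):
        base = _seq(900, 60)
        db = ReferenceDb([RefSeq("A", base, 1),
                          RefSeq("B", _mutate(base, range(0, 90, 3)), 2),
                          RefSeq("C", _seq(900, 61), 3)])
        reps, membership = precluster_reference(db, threshold=0.95)
        assert len(reps) == 2
        assert membership["B"] == membership["A"]
        assert membership["C"] == "C"


class TestMapPairs:
    def _otus(self):
        rep_a = _scaffold("ra", _seq(260, 70), _seq(260, 71))
        rep_b = _scaffold("rb", _seq(260, 72), _seq(260, 73))
        return [Otu("OTU000001", rep_a, ["ra"]),
                Otu("OTU000002", rep_b, ["rb"])]

    def test_error_free_pair_maps_perfectly(self):
        otus = self._otus()
        sc = _scaffold("p", otus[0].representative.seg1,
                       otus[0].representative.seg2)
        (pm,) = map_pairs_to_otus([sc], otus, PARAMS)
        assert pm.status == "mapped"
        assert pm.otu_id == "OTU000001"
        assert pm.identity == 1.0
        assert pm.indel_positions == 0

    def test_six_indels_rejected(self):
        otus = self._otus()
        seg1 = otus[0].representative.seg1
        sc = _scaffold("p", seg1[:100] + seg1[106:],
                       otus[0].representative.seg2)
        (pm,) = map_pairs_to_otus([sc], otus, PARAMS)
        assert pm.status == "unmapped"

    def test_five_indels_allowed(self):
        otus = self._otus()
        seg1 = otus[0].representative.seg1
        sc = _scaffold("p", seg1[:100] + seg1[105:],
                       otus[0].representative.seg2)
        (pm,) = map_pairs_to_otus([sc], otus, PARAMS)
        assert pm.status == "mapped" and pm.indel_positions == 5

    def test_chimeric_pair_discordant(self):
        otus = self._otus()
        sc = _scaffold("p", otus[0].representative.seg1,
                       otus[1].representative.seg2)
        (pm,) = map_pairs_to_otus([sc], otus, PARAMS)
        assert pm.status == "discordant"
        assert pm.otu_id is None

    def test_equal_score_tie_goes_to_smallest_otu_id(self):
        rep = _scaffold("r", _seq(260, 80), _seq(260, 81))
        twin = _scaffold("t", rep.seg1, rep.seg2)
        otus = [Otu("OTU000002", rep, ["r"]), Otu("OTU000001", twin, ["t"])]
        sc = _scaffold("p", rep.seg1, rep.seg2)
        (pm,) = map_pairs_to_otus([sc], otus, PARAMS)
        assert pm.otu_id == "OTU000001"


class TestRecapture:
    def test_novel_scaffold_founds_new_otu(self):
        otus = greedy_cluster([_scaffold("a", _seq(260, 90), _seq(260, 91))])
        novel = _scaffold("n", _seq(260, 92), _seq(260, 93))
        new = recapture_unclustered([novel], otus, PARAMS)
        assert len(new) == 1
        assert new[0].otu_id == "OTU000002"
        assert new[0].member_ids == ["n"]

    def test_matching_scaffold_not_recaptured(self):
        rep = _scaffold("a", _seq(260, 94), _seq(260, 95))
        otus = greedy_cluster([rep])
        near = _scaffold("n", _mutate(rep.seg1, range(3)), rep.seg2)
        assert recapture_unclustered([near], otus, PARAMS) == []

    def test_two_novel_pairs_one_new_otu(self):
        otus = greedy_cluster([_scaffold("a", _seq(260, 96), _seq(260, 97))])
        seg1, seg2 = _seq(260, 98), _seq(260, 99)
        novel = [_scaffold("n1", seg1, seg2),
                 _scaffold("n2", _mutate(seg1, range(4)), seg2)]
        new = recapture_unclustered(novel, otus, PARAMS)
        assert len(new) == 1
        assert sorted(new[0].member_ids) == ["n1", "n2"]


class TestConsensus:
    def test_identical_members_give_representative(self):
        rep = _scaffold("r", _seq(100, 110), _seq(100, 111))
        otu = Otu("OTU000001", rep, ["r"])
        members = [_scaffold(f"m{i}", rep.seg1, rep.seg2) for i in range(3)]
        maps = map_pairs_to_otus(members, [otu], PARAMS)
        assert build_consensus(otu, maps) == rep.sequence

    def test_majority_overrides_lone_substitution(self):
        rep = _scaffold("r", _seq(100, 112), _seq(100, 113))
        otu = Otu("OTU000001", rep, ["r"])
        members = [_scaffold(f"m{i}", rep.seg1, rep.seg2) for i in range(4)]
        members.append(_scaffold("m4", _mutate(rep.seg1, [50]), rep.seg2))
        maps = map_pairs_to_otus(members, [otu], PARAMS)
        assert build_consensus(otu, maps) == rep.sequence

    def test_zero_coverage_falls_back_to_representative(self):
        rep = _scaffold("r", _seq(100, 114), _seq(100, 115))
        otu = Otu("OTU000001", rep, ["r"])
        assert build_consensus(otu, []) == rep.sequence

    def test_linker_columns_stay_n(self):
        rep = _scaffold("r", _seq(100, 116), _seq(100, 117))
        otu = Otu("OTU000001", rep, ["r"])
        members = [_scaffold("m", rep.seg1, rep.seg2)]
        maps = map_pairs_to_otus(members, [otu], PARAMS)
        cons = build_consensus(otu, maps)
        assert cons[100:100 + LINKER_LEN] == "N" * LINKER_LEN


class TestChimeraScores:
    def test_threshold_application(self):
        otus = [Otu(f"OTU{i}", _scaffold(f"r{i}", _seq(60, 120 + i),
                                         _seq(60, 140 + i)), [])
                for i in range(3)]
        scores = {"OTU0": 31.0, "OTU1": 29.9}
        kept, removed = apply_chimera_scores(otus, scores, threshold=30)
        assert [o.otu_id for o in removed] == ["OTU0"]
        assert [o.otu_id for o in kept] == ["OTU1", "OTU2"]
        assert otus[2].chimera_score is None  # no entry -> kept
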