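import numpy as np
import pandas as pd
import pytest

from fungpcr import classify
from fungpcr.io_formats import BlastHit, HmmHit, PfamAnnotation
from fungpcr.topology import TMTopology


def make_hit(evalue=1e-10, qcov=0.9, scov=0.9, qlen=100, slen=100):
    qspan = max(1, round(qcov * qlen))
    sspan = max(1, round(scov * slen))
    return BlastHit("q", "s", evalue, 100.0, 1, qspan, 1, sspan, qlen, slen)


def topology_with(n_helices, first="outside", last="inside"):
    segments = []
    pos = 1
    side = first
    other = {"outside": "inside", "inside": "outside"}
    for _ in range(n_helices):
        segments.append((side, pos, pos + 9)); pos += 10
        segments.append(("TMhelix", pos, pos + 19)); pos += 20
        side = other[side]
    segments.append((last, pos, pos + 9)); pos += 10
    return TMTopology.from_segments(segments, seq_len=pos - 1)


class TestClassTable:
    def test_seventeen_classes(self):
        assert sorted(classify.CLASS_TABLE) == list(range(1, 18))

    def test_accessions_unique_except_frizzled_pair(self):
        all_accs = [a for c in classify.CLASS_TABLE.values()
                    for a in c.accessions]
        assert len(all_accs) == len(set(all_accs)) == 18
        assert classify.CLASS_TABLE[17].accessions == ("PF01534", "PF01392")

    def test_known_domain_assignments(self):
        assert classify.CLASS_TABLE[14].domains == ("CFEM",)
        assert classify.CLASS_TABLE[14].accessions == ("PF05730",)
        assert classify.CLASS_TABLE[15].accessions == ("PF00001",)

    def test_wide_helix_rule_on_classes_9_and_11(self):
        for cid in (9, 11):
            assert classify.CLASS_TABLE[cid].tmh_rule.allowed == {7, 8, 9}
        assert classify.CLASS_TABLE[3].tmh_rule.allowed == {6, 7}


class TestBlastGate:
    def test_passing_hit_kept(self):
        assert classify.blast_gate([make_hit(1e-6, 0.80, 0.81)])

    def test_coverage_exactly_at_threshold_dropped(self):
        assert classify.blast_gate([make_hit(1e-6, 0.75, 0.9)]) == []

    def test_evalue_at_threshold_dropped(self):
        assert classify.blast_gate([make_hit(1e-4, 0.9, 0.9)]) == []
        assert classify.blast_gate([make_hit(1e-5, 0.9, 0.9)]) == []

    def test_brute_force_agreement_on_random_hits(self):
        # oracle: literal re-evaluation of the published rule per hit
        rng = np.random.default_rng(42)
        hits = []
        for _ in range(10_000):
            qlen, slen = rng.integers(50, 500, size=2)
            qs = int(rng.integers(1, qlen + 1)); qe = int(rng.integers(qs, qlen + 1))
            ss = int(rng.integers(1, slen + 1)); se = int(rng.integers(ss, slen + 1))
            ev = float(10.0 ** rng.uniform(-40, 2))
            hits.append(BlastHit("q", "s", ev, 50.0, qs, qe, ss, se,
                                 int(qlen), int(slen)))
        expected = [
            h for h in hits
            if h.evalue < 1e-5
            and (h.qend - h.qstart + 1) / h.qlen > 0.75
            and (h.send - h.sstart + 1) / h.slen > 0.75
        ]
        assert classify.blast_gate(hits) == expected


class TestHmmGate:
    def test_strict_threshold(self):
        keep = HmmHit("a", 1, 1e-12, 50.0)
        drop = HmmHit("b", 1, 1e-5, 50.0)
        assert classify.hmm_gate([keep, drop]) == [keep]

    def test_empty(self):
        assert classify.hmm_gate([]) == []


class TestAssignClass:
    def test_smallest_evalue_wins(self):
        hits = [HmmHit("s", 1, 1e-7, 40.0), HmmHit("s", 2, 1e-10, 40.0)]
        c = classify.assign_class("s", hits, topology_with(7))
        assert c.class_id == 2

    def test_wrong_helix_count_rejected(self):
        hits = [HmmHit("s", 14, 1e-10, 40.0)]
        c = classify.assign_class("s", hits, topology_with(5))
        assert c.class_id is None and c.tmh_pass is False
        assert c.hmm_pass is True

    def test_nine_helices_allowed_for_class_9(self):
        hits = [HmmHit("s", 9, 1e-10, 40.0)]
        c = classify.assign_class("s", hits, topology_with(9))
        assert c.class_id == 9

    def test_bad_orientation_rejected(self):
        hits = [HmmHit("s", 1, 1e-10, 40.0)]
        c = classify.assign_class(
            "s", hits, topology_with(7, first="inside", last="outside"))
        assert c.class_id is None and c.topology_pass is False

    def test_tie_breaks_on_bitscore_then_index(self):
        hits = [HmmHit("s", 5, 1e-10, 40.0), HmmHit("s", 3, 1e-10, 60.0)]
        assert classify.assign_class("s", hits, topology_with(7)).class_id == 3
        hits = [HmmHit("s", 5, 1e-10, 40.0), HmmHit("s", 3, 1e-10, 40.0)]
        assert classify.assign_class("s", hits, topology_with(7)).class_id == 3

    def test_classified_implies_gates_passed(self, screen_bundle):
        b = screen_bundle
        for rec in b.records:
            c = classify.assign_class(rec.id, b.hmm_hits, b.topologies[rec.id])
            if c.class_id is not None:
                assert c.tmh_pass and c.topology_pass

    def test_recovers_planted_classes(self, screen_bundle):
        b = screen_bundle
        gated = classify.hmm_gate(b.hmm_hits)
        for rec in b.records:
            c = classify.assign_class(rec.id, gated, b.topologies[rec.id])
            assert c.class_id == b.truth[rec.id]


class TestScreenMammalian:
    def annot(self, domain, evalue=1e-9, seq_id="s"):
        acc = {"7tm_1": "PF00001", "7tm_3": "PF00003", "Frizzled": "PF01534",
               "Fz": "PF01392", "TAS2R": "PF05296"}[domain]
        return PfamAnnotation(seq_id, domain, acc, evalue)

    def test_rhodopsin_assigned_class_15(self):
        res = classify.screen_mammalian(
            [self.annot("7tm_1")], {"s": topology_with(7)})
        assert res[0].class_id == 15 and res[0].pfam_consistent == "yes"

    def test_six_helices_rejected(self):
        res = classify.screen_mammalian(
            [self.annot("7tm_3")], {"s": topology_with(6)})
        assert res[0].class_id is None and res[0].tmh_pass is False

    def test_taste2_recorded_but_unassigned(self):
        res = classify.screen_mammalian(
            [self.annot("TAS2R")], {"s": topology_with(7)})
        assert res[0].class_id is None
        assert "Taste2" in res[0].candidate_note

    def test_weak_evalue_ignored(self):
        assert classify.screen_mammalian(
            [self.annot("7tm_1", evalue=1e-4)], {"s": topology_with(7)}) == []

    def test_frizzled_via_either_domain(self):
        for d in ("Frizzled", "Fz"):
            res = classify.screen_mammalian(
                [self.annot(d)], {"s": topology_with(7)})
            assert res[0].class_id == 17


class TestConsistencyReport:
    def test_published_count_arithmetic(self):
        assert classify.consistency_percentage(12587, 12772) == 98.6

    def test_all_consistent(self):
        assert classify.consistency_percentage(7, 7) == 100.0

    def test_undefined_when_no_domains(self):
        with pytest.raises(ValueError, match="undefined"):
            classify.consistency_percentage(0, 0)

    def test_report_over_classifications(self):
        cs = [
            classify.Classification("a", class_id=3, tmh_pass=True,
                                    topology_pass=True,
                                    pfam_domains=("Git3",),
                                    pfam_consistent="yes"),
            classify.Classification("b", class_id=3, tmh_pass=True,
                                    topology_pass=True,
                                    pfam_domains=("CFEM",),
                                    pfam_consistent="no"),
            classify.Classification("c", class_id=3, tmh_pass=True,
                                    topology_pass=True),
        ]
        assert classify.pfam_consistency_report(cs) == (2, 1, 50.0)

    def test_annotate_multi_domain_no_penalty(self):
        cs = [classify.Classification("a", class_id=14, tmh_pass=True,
                                      topology_pass=True)]
        annots = [PfamAnnotation("a", "CFEM", "PF05730", 1e-9),
                  PfamAnnotation("a", "Kinase", "PF00069", 1e-3)]
        (out,) = classify.annotate_pfam_consistency(cs, annots)
        assert out.pfam_consistent == "yes"


class TestAbundance:
    def make(self, counts):
        cs = []
        i = 0
        for (species, class_id), n in counts.items():
            for _ in range(n):
                cs.append(classify.Classification(
                    f"s{i}", class_id=class_id, species=species,
                    tmh_pass=True, topology_pass=True))
                i += 1
        return cs

    def test_mammalian_class_shares(self):
        cs = self.make({("sp", 15): 984, ("sp", 16): 918, ("sp", 17): 187})
        m = classify.abundance_matrix(cs)
        props = classify.class_proportions(m)
        assert props[15] == 47.1
        assert props[16] == 43.9
        # 187/2089 = 8.95...%; this implementation rounds half-up to 9.0
        assert props[17] == 9.0

    def test_counts_sum(self, screen_bundle):
        b = screen_bundle
        gated = classify.hmm_gate(b.hmm_hits)
        cs = [classify.assign_class(r.id, gated, b.topologies[r.id],
                                    species=r.species)
              for r in b.records]
        m = classify.abundance_matrix(cs)
        n_classified = sum(1 for c in cs if c.class_id is not None)
        assert m.to_numpy().sum() == n_classified

    def test_single_class(self):
        m = classify.abundance_matrix(self.make({("sp", 1): 5}))
        assert classify.class_proportions(m)[1] == 100.0

    def test_empty(self):
        assert classify.abundance_matrix([]).empty
        assert classify.class_proportions(pd.DataFrame()).empty
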