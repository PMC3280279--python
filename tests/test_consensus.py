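"""Locus building, consensus selection, and re-annotation bookkeeping."""

import pytest

from aedqc.aed import compute_aed, compute_aed_set
from aedqc.consensus import (build_loci, detect_evidence_only_loci,
                             prioritize_for_review, select_consensus,
                             summarize_reannotation)
from aedqc.gff import AnnotationSet, GeneModel
from aedqc.intervals import intersection_size
from aedqc.simulate import FixtureSpec, generate

from conftest import make_evidence, make_transcript


def single_gene_set(label, *transcripts):
    genes = [GeneModel(id=t.gene_id, seqid=t.seqid, strand=t.strand,
                       transcripts=[t]) for t in transcripts]
    return AnnotationSet(label=label, genes=genes)


def records_for(sets, evidence):
    recs = {}
    for s in sets:
        recs.update(compute_aed_set(s, {"EST": evidence}))
    return recs


class TestBuildLoci:
    def test_same_place_two_sets(self):
        a = single_gene_set("ref", make_transcript([(1, 100)], tid="a1",
                                                   source_set="ref"))
        b = single_gene_set("alt", make_transcript([(50, 150)], tid="b1",
                                                   source_set="alt"))
        loci = build_loci([a, b], [])
        assert len(loci) == 1 and sorted(loci[0].member_ids) == ["a1", "b1"]

    def test_disjoint_transcripts_one_locus_each(self):
        a = single_gene_set("ref",
                            make_transcript([(1, 100)], tid="a1", gene_id="g1"),
                            make_transcript([(500, 600)], tid="a2", gene_id="g2"))
        assert len(build_loci([a], [])) == 2

    def test_chain_merges_transitively(self):
        a = make_transcript([(1, 100)], tid="A", gene_id="gA")
        b = make_transcript([(90, 200)], tid="B", gene_id="gB")
        c = make_transcript([(190, 300)], tid="C", gene_id="gC")
        loci = build_loci([single_gene_set("s", a, b, c)], [])
        assert len(loci) == 1 and sorted(loci[0].member_ids) == ["A", "B", "C"]

    def test_requires_a_set(self):
        with pytest.raises(ValueError):
            build_loci([], [])


class TestSelectConsensus:
    def test_minimal_aed_wins(self):
        ref_t = make_transcript([(1, 100)], tid="r1", source_set="ref")
        alt_t = make_transcript([(1, 80)], tid="a1", gene_id="g2", source_set="alt")
        ev = [make_evidence([(1, 80)])]
        sets = [single_gene_set("ref", ref_t), single_gene_set("alt", alt_t)]
        loci = build_loci(sets, ev)
        decisions, chosen = select_consensus(
            loci, records_for(sets, ev), reference_label="ref",
            source_priority=["ref", "alt"])
        (d,) = decisions
        assert d.chosen_id == "a1" and d.status == "replaced"
        assert not d.review_flag
        assert [t.id for t in chosen.transcripts()] == ["a1"]

    def test_reference_kept_when_best(self):
        ref_t = make_transcript([(1, 80)], tid="r1", source_set="ref")
        alt_t = make_transcript([(1, 100)], tid="a1", gene_id="g2", source_set="alt")
        ev = [make_evidence([(1, 80)])]
        sets = [single_gene_set("ref", ref_t), single_gene_set("alt", alt_t)]
        decisions, _ = select_consensus(
            build_loci(sets, ev), records_for(sets, ev),
            reference_label="ref", source_priority=["ref", "alt"])
        assert decisions[0].chosen_id == "r1"
        assert decisions[0].status == "kept_unchanged"

    def test_tie_breaks(self):
        # equal AED = 1 (no evidence): larger exon-base count wins
        big = make_transcript([(1, 400)], tid="zz-big", source_set="ref")
        small = make_transcript([(1, 300)], tid="aa-small", gene_id="g2",
                                source_set="alt")
        sets = [single_gene_set("ref", big), single_gene_set("alt", small)]
        decisions, _ = select_consensus(
            build_loci(sets, []), records_for(sets, []),
            reference_label="ref", source_priority=["ref", "alt"])
        assert decisions[0].chosen_id == "zz-big"

        # equal AED and equal size: source priority, then transcript id
        twin_a = make_transcript([(1, 300)], tid="zz", source_set="ref")
        twin_b = make_transcript([(1, 300)], tid="aa", gene_id="g2",
                                 source_set="alt")
        sets = [single_gene_set("ref", twin_a), single_gene_set("alt", twin_b)]
        decisions, _ = select_consensus(
            build_loci(sets, []), records_for(sets, []),
            reference_label="ref", source_priority=["ref", "alt"])
        assert decisions[0].chosen_id == "zz"  # ref set has priority
        decisions, _ = select_consensus(
            build_loci(sets, []), records_for(sets, []),
            reference_label="ref", source_priority=["alt", "ref"])
        assert decisions[0].chosen_id == "aa"

    def test_sole_unsupported_candidate_flagged(self):
        t = make_transcript([(1, 100)], tid="r1", source_set="ref")
        sets = [single_gene_set("ref", t)]
        decisions, _ = select_consensus(
            build_loci(sets, []), records_for(sets, []),
            reference_label="ref", source_priority=["ref"])
        (d,) = decisions
        assert d.status == "unsupported" and d.review_flag
        assert d.chosen_id == "r1"

    def test_consensus_output_is_non_redundant(self):
        fx = generate(FixtureSpec(seed=11, n_genes=40, n_annotation_sets=2))
        sets = fx.annotation_sets
        recs = records_for(sets, fx.evidence)
        loci = build_loci(sets, fx.evidence)
        _, chosen = select_consensus(loci, recs, reference_label="reference",
                                     source_priority=[s.label for s in sets])
        ts = chosen.transcripts()
        for i in range(len(ts)):
            for j in range(i + 1, len(ts)):
                if ts[i].seqid == ts[j].seqid:
                    assert intersection_size(ts[i].exons, ts[j].exons) == 0

    def test_rerun_on_own_output_is_fixed_point(self):
        fx = generate(FixtureSpec(seed=3, n_genes=30, n_annotation_sets=2))
        sets = fx.annotation_sets
        recs = records_for(sets, fx.evidence)
        loci = build_loci(sets, fx.evidence)
        _, chosen = select_consensus(loci, recs, reference_label="reference",
                                     source_priority=[s.label for s in sets])
        chosen = AnnotationSet(label="reference", genes=chosen.genes)
        for t in chosen.transcripts():
            t.source_set = "reference"
        recs2 = records_for([chosen], fx.evidence)
        decisions2, chosen2 = select_consensus(
            build_loci([chosen], fx.evidence), recs2,
            reference_label="reference", source_priority=["reference"])
        assert all(d.chosen_id in d.reference_ids for d in decisions2)
        assert sorted(t.id for t in chosen2.transcripts()) == \
               sorted(t.id for t in chosen.transcripts())


class TestEvidenceOnly:
    def test_single_est_synthesizes_zero_aed_model(self):
        t = make_transcript([(1, 100)], tid="r1", source_set="ref")
        ev = [make_evidence([(1, 100)], eid="near"),
              make_evidence([(5000, 5100)], eid="far")]
        loci = build_loci([single_gene_set("ref", t)], ev)
        decisions, models = detect_evidence_only_loci(loci)
        (d,) = decisions
        assert d.status == "evidence_only" and d.chosen_aed == 0.0
        (m,) = models.transcripts()
        assert m.exons.intervals == ((5000, 5100),)

    def test_annotated_loci_excluded(self):
        t = make_transcript([(1, 100)], tid="r1", source_set="ref")
        ev = [make_evidence([(1, 100)])]
        decisions, _ = detect_evidence_only_loci(
            build_loci([single_gene_set("ref", t)], ev))
        assert decisions == []

    def test_two_overlapping_ests_merge(self):
        t = make_transcript([(1, 100)], tid="r1", source_set="ref")
        ev = [make_evidence([(5000, 5200)], eid="x"),
              make_evidence([(5100, 5300)], eid="y")]
        _, models = detect_evidence_only_loci(
            build_loci([single_gene_set("ref", t)], ev))
        (m,) = models.transcripts()
        assert m.exons.intervals == ((5000, 5300),)


class TestSummarize:
    def test_mixed_statuses(self):
        fx = generate(FixtureSpec(seed=2, n_genes=25, n_annotation_sets=2,
                                  fraction_unsupported=0.2,
                                  fraction_evidence_only=0.2))
        sets = fx.annotation_sets
        recs = records_for(sets, fx.evidence)
        loci = build_loci(sets, fx.evidence)
        decisions, _ = select_consensus(loci, recs, reference_label="reference",
                                        source_priority=[s.label for s in sets])
        ev_dec, _ = detect_evidence_only_loci(loci)
        summary = summarize_reannotation(decisions + ev_dec, "reference")
        assert summary == fx.expected_summary
        assert summary.n_altered + summary.n_unchanged == summary.n_input_reference

    def test_all_kept(self):
        t = make_transcript([(1, 100)], tid="r1", source_set="ref")
        ev = [make_evidence([(1, 100)])]
        decisions, _ = select_consensus(
            build_loci([single_gene_set("ref", t)], ev),
            records_for([single_gene_set("ref", t)], ev),
            reference_label="ref", source_priority=["ref"])
        summary = summarize_reannotation(decisions, "ref")
        assert summary.n_altered == 0 and summary.n_unchanged == 1
        assert summary.n_flagged_unsupported == 0


class TestPrioritize:
    def test_worst_first_and_flags(self):
        t = make_transcript([(1, 100)])
        recs = [compute_aed(make_transcript([(1, 100)], tid=f"t{k}"), evs,
                            already_clustered=True)
                for k, evs in enumerate([
                    [make_evidence([(1, 100)])],          # aed 0
                    [],                                   # aed 1
                    [make_evidence([(1, 50)])],           # aed 0.25
                ])]
        ordered = prioritize_for_review(recs, threshold=0.95)
        aeds = [r.aed for r, _ in ordered]
        assert aeds == sorted(aeds, reverse=True)
        assert [f for _, f in ordered] == [True, False, False]

    def test_stable_on_ties(self):
        recs = [compute_aed(make_transcript([(1, 100)], tid=tid), [],
                            already_clustered=True)
                for tid in ("b", "a", "c")]
        ordered = prioritize_for_review(recs)
        assert [r.transcript_id for r, _ in ordered] == ["a", "b", "c"]
        assert all(flag for _, flag in ordered)
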