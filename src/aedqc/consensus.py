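"""Consensus selection across competing annotation sets and re-annotation bookkeeping.

Legacy re-annotation pools one designated *reference* annotation set with
any number of alternate sets and with the aligned evidence, clusters
everything into loci by transitive overlap, and at each locus carries
forward the single candidate model most consistent with the evidence —
operationalized as minimal AED. Loci where evidence exists but no model
does yield synthesized evidence-derived models (candidate novel genes).
The bookkeeping mirrors a re-annotation experiment's accounting: every
reference model is either *altered* (displaced by a better-scoring
candidate) or *unchanged*, so ``n_altered + n_unchanged`` always equals the
reference-model count; chosen models with no meaningful evidence support
(AED at or above the review threshold) are flagged for manual review as
possible false positives.

This module performs model selection and evidence-derived novel models
only; it does not revise exon boundaries of existing models with ab initio
predictors, so "altered" always means displacement by a provided or
synthesized candidate.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

from .aed import AEDRecord, compute_aed
from .gff import AnnotationSet, EvidenceAlignment, GeneModel, Transcript
from .intervals import LocusCluster, cluster_single_linkage, normalize

__all__ = ["LocusDecision", "ReannotationSummary", "build_loci",
           "select_consensus", "detect_evidence_only_loci",
           "summarize_reannotation", "prioritize_for_review",
           "write_decisions_table", "write_summary_table"]

#: Candidates with AED at or above this are flagged as lacking evidence
#: support. 1.0 flags only models with literally no overlapping evidence;
#: 0.95 additionally catches the near-1 spike of marginally supported models.
DEFAULT_REVIEW_THRESHOLD = 1.0


@dataclass
class LocusDecision:
    """Outcome of consensus selection at one locus."""

    locus_id: str
    candidate_ids: list[tuple[str, float, str]]  # (transcript id, AED, source set)
    chosen_id: str
    chosen_aed: float
    chosen_source: str
    status: str  # kept_unchanged | replaced | evidence_only | unsupported
    review_flag: bool
    reference_ids: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ReannotationSummary:
    n_input_reference: int
    n_altered: int
    n_new_loci: int
    n_unchanged: int
    n_flagged_unsupported: int

    def __post_init__(self) -> None:
        assert self.n_altered + self.n_unchanged == self.n_input_reference
        assert self.n_flagged_unsupported <= self.n_unchanged + self.n_altered


def build_loci(annotation_sets: Sequence[AnnotationSet],
               evidence: Sequence[EvidenceAlignment],
               *,
               strand_mode: str = "aware",
               min_overlap: int = 1) -> list[LocusCluster]:
    """Cluster all candidate transcripts and evidence into loci.

    Every transcript from every set and every evidence alignment lands in
    exactly one single-linkage cluster; a locus is a maximal group connected
    by chains of pairwise overlap.
    """
    if not annotation_sets:
        raise ValueError("at least one annotation set is required")
    features: list = [t for s in annotation_sets for t in s.transcripts()]
    features.extend(evidence)
    return cluster_single_linkage(features, strand_mode=strand_mode,
                                  min_overlap=min_overlap)


def _locus_parts(locus: LocusCluster) -> tuple[list[Transcript], list[EvidenceAlignment]]:
    ts = [m for m in locus.members if isinstance(m, Transcript)]
    ev = [m for m in locus.members if isinstance(m, EvidenceAlignment)]
    return ts, ev


def select_consensus(loci: Sequence[LocusCluster],
                     records: Mapping[str, AEDRecord],
                     *,
                     reference_label: str,
                     source_priority: Sequence[str] | None = None,
                     review_threshold: float = DEFAULT_REVIEW_THRESHOLD,
                     ) -> tuple[list[LocusDecision], AnnotationSet]:
    """Choose the best-supported model per locus.

    Selection is by minimal AED; ties break toward (1) larger exon-base
    count, (2) earlier source set in ``source_priority`` (input order of the
    annotation sets), (3) lexicographically smaller transcript id. The
    decision status is ``replaced`` when the winner is not a reference-set
    model at a locus that has one, ``kept_unchanged`` when the reference
    model wins, and ``unsupported`` (with ``review_flag``) when the winner's
    AED reaches ``review_threshold``. Evidence-only loci are skipped here
    (see :func:`detect_evidence_only_loci`).

    Returns the decisions plus the consensus (non-redundant) annotation set.
    """
    priority = {label: k for k, label in enumerate(source_priority or [])}
    decisions: list[LocusDecision] = []
    consensus_genes: list[GeneModel] = []

    for n, locus in enumerate(loci, 1):
        transcripts, _ = _locus_parts(locus)
        if not transcripts:
            continue
        locus_id = f"locus-{n:05d}"

        def sort_key(t: Transcript):
            return (records[t.id].aed,
                    -t.exon_bases,
                    priority.get(t.source_set, len(priority)),
                    t.id)

        ranked = sorted(transcripts, key=sort_key)
        chosen = ranked[0]
        aed = records[chosen.id].aed
        ref_ids = [t.id for t in transcripts if t.source_set == reference_label]

        if aed >= review_threshold:
            status = "unsupported"
        elif ref_ids and chosen.id in ref_ids:
            status = "kept_unchanged"
        elif ref_ids:
            status = "replaced"
        else:
            status = "kept_unchanged"  # novel locus contributed by an alternate set
        decisions.append(LocusDecision(
            locus_id=locus_id,
            candidate_ids=[(t.id, records[t.id].aed, t.source_set)
                           for t in ranked],
            chosen_id=chosen.id, chosen_aed=aed, chosen_source=chosen.source_set,
            status=status, review_flag=aed >= review_threshold,
            reference_ids=ref_ids))
        consensus_genes.append(GeneModel(
            id=chosen.gene_id or chosen.id, seqid=chosen.seqid,
            strand=chosen.strand, transcripts=[chosen]))

    return decisions, AnnotationSet(label="consensus", genes=consensus_genes)


def detect_evidence_only_loci(loci: Sequence[LocusCluster],
                              *,
                              review_threshold: float = DEFAULT_REVIEW_THRESHOLD,
                              ) -> tuple[list[LocusDecision], AnnotationSet]:
    """Synthesize candidate models at loci with evidence but no annotation.

    The synthesized model's exons are the merged evidence parts of the locus
    (book-ended segments stay split), and its AED is computed against its own
    cluster — 0 by construction, since the model equals the evidence union.
    """
    decisions: list[LocusDecision] = []
    genes: list[GeneModel] = []
    for n, locus in enumerate(loci, 1):
        transcripts, evidence = _locus_parts(locus)
        if transcripts or not evidence:
            continue
        gid = f"evidence-gene-{n:05d}"
        exons = normalize([p for e in evidence for p in e.parts.intervals],
                          seqid=locus.seqid)
        strands = {e.strand for e in evidence if e.strand != "."}
        strand = strands.pop() if len(strands) == 1 else "."
        model = Transcript(id=f"{gid}.t1", gene_id=gid, seqid=locus.seqid,
                           strand=strand, exons=exons, source_set="evidence")
        rec = compute_aed(model, evidence, already_clustered=True)
        decisions.append(LocusDecision(
            locus_id=f"locus-ev-{n:05d}",
            candidate_ids=[(model.id, rec.aed, "evidence")],
            chosen_id=model.id, chosen_aed=rec.aed, chosen_source="evidence",
            status="evidence_only",
            review_flag=rec.aed >= review_threshold))
        genes.append(GeneModel(id=gid, seqid=locus.seqid, strand=strand,
                               transcripts=[model]))
    return decisions, AnnotationSet(label="evidence_only", genes=genes)


def summarize_reannotation(decisions: Iterable[LocusDecision],
                           reference_label: str) -> ReannotationSummary:
    """Count altered / new / unchanged / flagged models over one consensus run.

    A reference transcript is *unchanged* when it is the chosen model at its
    locus and *altered* otherwise, so altered + unchanged equals the
    reference input count by construction. Evidence-only loci are the new
    models; flagged counts review-flagged decisions at loci holding at least
    one reference model (the summary accounts for the reference set, so
    flagged novel loci from alternate sets are reported per-decision only).
    """
    n_ref = n_unchanged = n_new = n_flagged = 0
    for d in decisions:
        if d.status == "evidence_only":
            n_new += 1
            continue
        n_ref += len(d.reference_ids)
        if d.chosen_id in d.reference_ids:
            n_unchanged += 1
        if d.review_flag and d.reference_ids:
            n_flagged += 1
    return ReannotationSummary(
        n_input_reference=n_ref, n_altered=n_ref - n_unchanged,
        n_new_loci=n_new, n_unchanged=n_unchanged,
        n_flagged_unsupported=n_flagged)


def prioritize_for_review(records: Iterable[AEDRecord],
                          threshold: float = DEFAULT_REVIEW_THRESHOLD,
                          ) -> list[tuple[AEDRecord, bool]]:
    """Sort records worst-supported first and flag those at/above threshold.

    Descending AED puts likely false positives at the top of a curation
    queue; equal AEDs order stably by transcript id.
    """
    ordered = sorted(records, key=lambda r: (-r.aed, r.transcript_id))
    return [(r, r.aed >= threshold) for r in ordered]


def write_decisions_table(decisions: Iterable[LocusDecision],
                          sink: IO[str] | None = None) -> None:
    fh = sink or sys.stdout
    fh.write("locus_id\tchosen_id\tchosen_aed\tchosen_source\tstatus\t"
             "review_flag\tn_candidates\tcandidates\n")
    for d in decisions:
        cands = ",".join(f"{tid}:{aed:.4f}:{src}" for tid, aed, src in d.candidate_ids)
        fh.write(f"{d.locus_id}\t{d.chosen_id}\t{d.chosen_aed:.4f}\t"
                 f"{d.chosen_source}\t{d.status}\t{d.review_flag}\t"
                 f"{len(d.candidate_ids)}\t{cands}\n")


def write_summary_table(summary: ReannotationSummary,
                        sink: IO[str] | None = None) -> None:
    fh = sink or sys.stdout
    fh.write("n_input_reference\tn_altered\tn_new_loci\tn_unchanged\t"
             "n_flagged_unsupported\n")
    fh.write(f"{summary.n_input_reference}\t{summary.n_altered}\t"
             f"{summary.n_new_loci}\t{summary.n_unchanged}\t"
             f"{summary.n_flagged_unsupported}\n")
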