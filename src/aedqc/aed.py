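"""Annotation Edit Distance against clustered experimental evidence.

A gene prediction cannot usually be scored against a trusted reference
model, because for most genomes none exists. Instead, the experimental
evidence aligned to the genome (ESTs, protein alignments, mRNA-seq) is
clustered by transitive overlap, and the evidence union within a
prediction's own cluster stands in for the reference. With *i* the set of
positions covered by a transcript's exons and *j* the union of evidence
positions in its cluster:

    SN = |i ∩ j| / |j|          (sensitivity; 0 when the cluster is empty)
    SP = |i ∩ j| / |i|          (specificity)
    C  = (SN + SP) / 2          (congruency — "accuracy" against evidence)
    AED = D = 1 − C

AED 0 means the annotation's exon union coincides exactly with the evidence
union; AED 1 means no overlapping evidence at all. Sorting annotations by
descending AED ranks them from least to best supported, which is the basis
for review prioritization downstream.

|j| is the *union* of evidence positions, not the sum over alignments: a
sum would let redundant ESTs stack up |j| and drive SN toward 0 even for an
annotation in perfect agreement with every alignment. The sum reading is
available behind ``evidence_size="sum"`` for comparison.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

from .gff import AnnotationSet, EvidenceAlignment, GeneModel, Transcript
from .intervals import (IntervalSet, cluster_single_linkage,
                        intersection_size, normalize)

__all__ = ["AEDRecord", "compute_aed", "compute_aed_set", "gene_aed",
           "gene_aeds", "write_aed_table"]


@dataclass(frozen=True)
class AEDRecord:
    """Per-transcript evidence-agreement scores and provenance."""

    transcript_id: str
    sn: float
    sp: float
    congruency: float
    aed: float
    n_evidence: int
    evidence_ids: tuple[str, ...] = ()
    gene_id: str = ""
    seqid: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        assert abs(self.congruency - (self.sn + self.sp) / 2.0) < 1e-12
        assert abs(self.aed - (1.0 - self.congruency)) < 1e-12
        assert -1e-12 <= self.aed <= 1 + 1e-12


def _aed_from_sets(i: IntervalSet, j_union: IntervalSet | None,
                   j_size: int) -> tuple[float, float, float, float]:
    """Return (sn, sp, congruency, aed) for exon set *i* vs evidence size |j|."""
    i_size = i.covered_bases
    overlap = intersection_size(i, j_union) if j_union is not None else 0
    sn = overlap / j_size if j_size > 0 else 0.0
    sp = overlap / i_size
    c = (sn + sp) / 2.0
    return sn, sp, c, 1.0 - c


def _cluster_evidence(transcript: Transcript,
                      evidence: Sequence[EvidenceAlignment],
                      strand_mode: str,
                      min_overlap: int) -> list[EvidenceAlignment]:
    """Evidence in the transcript's single-linkage cluster."""
    clusters = cluster_single_linkage([transcript, *evidence],
                                      strand_mode=strand_mode,
                                      min_overlap=min_overlap)
    for cl in clusters:
        if any(m is transcript for m in cl.members):
            return [m for m in cl.members if isinstance(m, EvidenceAlignment)]
    raise AssertionError("transcript missing from its own clustering")


def compute_aed(transcript: Transcript,
                evidence: Iterable[EvidenceAlignment],
                *,
                already_clustered: bool = False,
                use_cds: bool = False,
                evidence_size: str = "union",
                strand_mode: str = "aware",
                min_overlap: int = 1) -> AEDRecord:
    """Annotation Edit Distance of one transcript against evidence.

    Parameters
    ----------
    transcript
        The annotation *i*; scored on its exon union (or CDS union with
        ``use_cds=True``, falling back to exons when no CDS is recorded).
    evidence
        Either the transcript's own cluster (``already_clustered=True``) or
        any collection from which the cluster is derived by single-linkage
        overlap with the transcript. Evidence elsewhere on the chromosome
        never affects the result.
    evidence_size
        ``"union"`` (default) sizes |j| as the union of evidence positions;
        ``"sum"`` uses the total per-alignment covered bases instead.
    """
    ev = [e for e in (evidence or []) if e.seqid == transcript.seqid]
    if not already_clustered:
        ev = _cluster_evidence(transcript, ev, strand_mode, min_overlap)

    i = transcript.cds if (use_cds and transcript.cds) else transcript.exons
    if not i:
        raise ValueError(f"transcript {transcript.id!r} has an empty exon set")

    if ev:
        pairs = [p for e in ev for p in e.parts.intervals]
        j_union = normalize(pairs, seqid=transcript.seqid)
        j_size = (sum(e.parts.covered_bases for e in ev)
                  if evidence_size == "sum" else j_union.covered_bases)
    else:
        j_union, j_size = None, 0
    sn, sp, c, d = _aed_from_sets(i, j_union, j_size)
    return AEDRecord(
        transcript_id=transcript.id, sn=sn, sp=sp, congruency=c, aed=d,
        n_evidence=len(ev), evidence_ids=tuple(e.id for e in ev),
        gene_id=transcript.gene_id, seqid=transcript.seqid,
        strand=transcript.strand)


def compute_aed_set(annotations: AnnotationSet,
                    evidence_by_class: Mapping[str, Sequence[EvidenceAlignment]],
                    *,
                    pooling: str = "pooled",
                    use_cds: bool = False,
                    evidence_size: str = "union",
                    strand_mode: str = "aware",
                    min_overlap: int = 1) -> dict[str, AEDRecord]:
    """AED records for every transcript of an annotation set.

    ``pooling="pooled"`` (default) merges evidence from all classes into one
    union *j* per cluster; ``pooling="best-class"`` scores each class
    separately and keeps, per transcript, the record with minimal AED.
    Deterministic given identical inputs regardless of input file order.
    """
    if pooling not in ("pooled", "best-class"):
        raise ValueError(f"unknown pooling mode {pooling!r}")
    kwargs = dict(use_cds=use_cds, evidence_size=evidence_size,
                  strand_mode=strand_mode, min_overlap=min_overlap)
    transcripts = sorted(annotations.transcripts(), key=lambda t: t.id)

    pools: list[list[EvidenceAlignment]]
    if pooling == "pooled":
        pools = [sorted((e for ev in evidence_by_class.values() for e in ev),
                        key=lambda e: e.id)]
    else:
        pools = [sorted(evidence_by_class.get(cls, []), key=lambda e: e.id)
                 for cls in sorted(evidence_by_class)]
        pools = [p for p in pools if p] or [[]]

    records: dict[str, AEDRecord] = {}
    for t in transcripts:
        best: AEDRecord | None = None
        for pool in pools:
            rec = compute_aed(t, pool, **kwargs)
            if best is None or rec.aed < best.aed:
                best = rec
        records[t.id] = best  # type: ignore[assignment]
    return records


def gene_aed(gene: GeneModel, records: Mapping[str, AEDRecord]) -> float:
    """Gene-level AED: the minimum over the gene's transcripts.

    A gene is as well supported as its best-supported isoform.
    """
    return min(records[t.id].aed for t in gene.transcripts)


def gene_aeds(annotations: AnnotationSet,
              records: Mapping[str, AEDRecord]) -> dict[str, float]:
    return {g.id: gene_aed(g, records) for g in annotations.genes}


def write_aed_table(records: Iterable[AEDRecord], sink: IO[str] | None = None) -> None:
    """Tab-separated report: one row per transcript, fractions to 4 decimals."""
    fh = sink or sys.stdout
    fh.write("transcript_id\tgene_id\tseqid\tstrand\tsn\tsp\taed\tn_evidence\n")
    for r in records:
        fh.write(f"{r.transcript_id}\t{r.gene_id}\t{r.seqid}\t{r.strand}\t"
                 f"{r.sn:.4f}\t{r.sp:.4f}\t{r.aed:.4f}\t{r.n_evidence}\n")
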