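"""GFF3 reading and writing for gene-annotation hierarchies and evidence.

Annotations arrive as gene → mRNA → exon/CDS hierarchies linked by
ID/Parent; evidence alignments arrive as match → match_part hierarchies
(``expressed_sequence_match``, ``protein_match``, ``cDNA_match`` and plain
``match`` are all accepted) or as bare aligned-segment rows grouped by ID.
Parsing is delegated to :mod:`gffutils` with an in-memory database; this
module maps the parsed features onto the lightweight containers the rest of
the package computes with, and writes annotated GFF3 back out with ``_AED``
quality-control attributes on mRNA rows.

Real-world GFF3 dialects vary, so transcript-level rows may be typed
``mRNA``, ``transcript``, or anything else that is the child of a gene and
has exon children. The evidence class (EST / protein / mRNA-seq) is supplied
by the caller per file rather than inferred from the GFF3 type, mirroring
how annotation pipelines take separate EST / protein / RNA-seq channels.
"""

from __future__ import annotations

import gzip
import logging
import os
import tempfile
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import gffutils

from .intervals import IntervalSet, normalize

logger = logging.getLogger(__name__)

__all__ = [
    "Transcript",
    "GeneModel",
    "EvidenceAlignment",
    "AnnotationSet",
    "GFFError",
    "read_annotations",
    "read_evidence",
    "write_annotations",
    "write_evidence",
    "EVIDENCE_CLASSES",
]

EVIDENCE_CLASSES = ("EST", "protein", "mRNA-seq")

#: GFF3 types accepted as transcript-level rows without structural checks.
TRANSCRIPT_TYPES = {"mRNA", "transcript"}

#: GFF3 types accepted as top-level evidence matches.
MATCH_TYPES = {"match", "expressed_sequence_match", "protein_match",
               "cDNA_match", "EST_match", "translated_nucleotide_match",
               "nucleotide_to_protein_match"}


class GFFError(ValueError):
    """Structural problem in a GFF3 input (dangling Parent, empty mRNA, ...)."""


@dataclass
class Transcript:
    """One transcript model: an identified set of exon intervals.

    ``exons`` (and ``cds`` when present) are normalized
    :class:`~aedqc.intervals.IntervalSet` objects on one seqid/strand.
    ``source_set`` labels the annotation set the transcript came from, and
    ``attributes`` carries the GFF3 column-9 map for round-tripping.
    """

    id: str
    gene_id: str
    seqid: str
    strand: str
    exons: IntervalSet
    cds: IntervalSet | None = None
    source_set: str = ""
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            raise GFFError(f"transcript {self.id!r} has no exons")

    @property
    def intervals(self) -> IntervalSet:
        """Alias so transcripts are directly clusterable."""
        return self.exons

    @property
    def exon_bases(self) -> int:
        return self.exons.covered_bases

    @property
    def span(self) -> tuple[int, int]:
        return self.exons.span


@dataclass
class GeneModel:
    id: str
    seqid: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)
    attributes: dict[str, str] = field(default_factory=dict)

    @property
    def span(self) -> tuple[int, int]:
        starts, ends = zip(*(t.span for t in self.transcripts))
        return min(starts), max(ends)


@dataclass
class EvidenceAlignment:
    """An aligned piece of experimental evidence (EST, protein, or mRNA-seq).

    ``parts`` holds the aligned-segment intervals in genome coordinates
    exactly as given in the GFF3 (protein alignments are *not* codon-scaled).
    """

    id: str
    evidence_class: str
    seqid: str
    strand: str
    parts: IntervalSet
    score: float | None = None

    @property
    def intervals(self) -> IntervalSet:
        return self.parts


@dataclass
class AnnotationSet:
    label: str
    genes: list[GeneModel] = field(default_factory=list)
    provenance: str = ""

    def transcripts(self) -> list[Transcript]:
        return [t for g in self.genes for t in g.transcripts]

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _open_db(source: str | os.PathLike | IO[str]) -> gffutils.FeatureDB | None:
    """Build an in-memory gffutils database; None for a feature-less file."""
    if hasattr(source, "read"):
        data = source.read()
    else:
        path = os.fspath(source)
        opener = gzip.open if path.endswith(".gz") else open
        with opener(path, "rt") as fh:  # type: ignore[operator]
            data = fh.read()
    try:
        return gffutils.create_db(data, ":memory:", from_string=True,
                                  keep_order=True, merge_strategy="create_unique")
    except gffutils.exceptions.EmptyInputError:
        return None


def _first(attrs: Mapping, key: str) -> str | None:
    vals = attrs.get(key)
    return vals[0] if vals else None


def _attr_map(feature: gffutils.Feature) -> dict[str, str]:
    return {k: ",".join(v) for k, v in feature.attributes.items()}


def _check_parents(db: gffutils.FeatureDB) -> None:
    """Reject dangling Parent references, naming the offending feature."""
    known = {f.id for f in db.all_features()}
    for feat in db.all_features():
        for pid in feat.attributes.get("Parent", []):
            if pid not in known:
                raise GFFError(
                    f"{feat.featuretype} at {feat.seqid}:{feat.start}-{feat.end} "
                    f"references missing Parent {pid!r}"
                )


def read_annotations(source: str | os.PathLike | IO[str], label: str) -> AnnotationSet:
    """Parse a GFF3 gene-annotation file into an :class:`AnnotationSet`.

    Every mRNA/transcript row (or any gene child with exon children) becomes
    a :class:`Transcript` with its exon :class:`IntervalSet`; a gene with no
    transcript children but with direct exon children is wrapped in an
    implicit single transcript named ``<gene>.t1``. Feature types other than
    gene / transcript-level / exon / CDS are ignored (a count is logged).

    Raises
    ------
    GFFError
        On a dangling Parent reference or a transcript with zero exons.
    """
    db = _open_db(source)
    provenance = os.fspath(source) if not hasattr(source, "read") else "<stream>"
    if db is None:
        return AnnotationSet(label=label, genes=[], provenance=provenance)
    _check_parents(db)

    genes: list[GeneModel] = []
    ignored = 0
    consumed: set[str] = set()

    for gene_feat in db.features_of_type("gene", order_by=("seqid", "start")):
        consumed.add(gene_feat.id)
        gene = GeneModel(id=gene_feat.id, seqid=gene_feat.seqid,
                         strand=gene_feat.strand, attributes=_attr_map(gene_feat))
        direct_exons: list[gffutils.Feature] = []
        for child in db.children(gene_feat.id, level=1):
            consumed.add(child.id)
            if child.featuretype == "exon":
                direct_exons.append(child)
                continue
            if child.featuretype == "CDS":
                continue
            exon_feats = list(db.children(child.id, featuretype="exon", level=1))
            if child.featuretype not in TRANSCRIPT_TYPES and not exon_feats:
                ignored += 1
                continue
            if not exon_feats:
                raise GFFError(f"transcript {child.id!r} has no exon children")
            for e in exon_feats:
                consumed.add(e.id)
            cds_feats = list(db.children(child.id, featuretype="CDS", level=1))
            for c in cds_feats:
                consumed.add(c.id)
            exons = normalize([(e.start, e.end) for e in exon_feats],
                              seqid=gene_feat.seqid)
            cds = (normalize([(c.start, c.end) for c in cds_feats],
                             seqid=gene_feat.seqid) if cds_feats else None)
            gene.transcripts.append(Transcript(
                id=child.id, gene_id=gene_feat.id, seqid=gene_feat.seqid,
                strand=child.strand, exons=exons, cds=cds,
                source_set=label, attributes=_attr_map(child)))
        if not gene.transcripts and direct_exons:
            exons = normalize([(e.start, e.end) for e in direct_exons],
                              seqid=gene_feat.seqid)
            gene.transcripts.append(Transcript(
                id=f"{gene_feat.id}.t1", gene_id=gene_feat.id,
                seqid=gene_feat.seqid, strand=gene_feat.strand,
                exons=exons, source_set=label))
        if not gene.transcripts:
            raise GFFError(f"gene {gene_feat.id!r} has no transcripts or exons")
        genes.append(gene)

    for feat in db.all_features():
        if feat.id not in consumed and feat.featuretype not in ("exon", "CDS"):
            ignored += 1
    if ignored:
        logger.info("read_annotations(%s): ignored %d non-gene-hierarchy features",
                    provenance, ignored)

    seen: set[str] = set()
    for g in genes:
        for t in g.transcripts:
            if t.id in seen:
                raise GFFError(f"duplicate transcript id {t.id!r} in set {label!r}")
            seen.add(t.id)
    return AnnotationSet(label=label, genes=genes, provenance=provenance)


def read_evidence(source: str | os.PathLike | IO[str],
                  evidence_class: str) -> list[EvidenceAlignment]:
    """Parse evidence alignments from GFF3 match/match_part hierarchies.

    One :class:`EvidenceAlignment` per top-level match, with ``parts`` taken
    from its match_part children; a match without parts becomes a single-part
    alignment over its own span. Bare match_part rows sharing an ID (or
    lacking a Parent) are grouped into one alignment per ID.
    """
    if evidence_class not in EVIDENCE_CLASSES:
        raise ValueError(
            f"unknown evidence class {evidence_class!r}; expected one of {EVIDENCE_CLASSES}")
    db = _open_db(source)
    if db is None:
        return []
    _check_parents(db)

    alignments: list[EvidenceAlignment] = []
    top_ids: set[str] = set()
    for ftype in sorted(MATCH_TYPES):
        for match in db.features_of_type(ftype):
            top_ids.add(match.id)
            parts = [(p.start, p.end) for p in db.children(match.id, level=1)]
            if not parts:
                parts = [(match.start, match.end)]
            score = None
            if match.score not in (".", None, ""):
                score = float(match.score)
            alignments.append(EvidenceAlignment(
                id=match.id, evidence_class=evidence_class,
                seqid=match.seqid, strand=match.strand,
                parts=normalize(parts, seqid=match.seqid), score=score))

    # bare match_part rows with no top-level parent, grouped by ID
    orphans: dict[str, list[gffutils.Feature]] = {}
    for part in db.features_of_type("match_part"):
        parents = part.attributes.get("Parent", [])
        if not parents or all(p not in top_ids for p in parents):
            orphans.setdefault(part.id, []).append(part)
    for pid, feats in orphans.items():
        alignments.append(EvidenceAlignment(
            id=pid, evidence_class=evidence_class,
            seqid=feats[0].seqid, strand=feats[0].strand,
            parts=normalize([(f.start, f.end) for f in feats],
                            seqid=feats[0].seqid)))

    alignments.sort(key=lambda a: (a.seqid, a.parts.span[0], a.id))
    return alignments


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

# GFF3 column 9: ; = , and control characters are reserved in values
_COL9_ESCAPES = {";": "%3B", "=": "%3D", "&": "%26", ",": "%2C",
                 "%": "%25", "\t": "%09", "\n": "%0A", "\r": "%0D"}


def _escape(value: str) -> str:
    out = value.replace("%", "%25")
    for ch, code in _COL9_ESCAPES.items():
        if ch != "%":
            out = out.replace(ch, code)
    return out


def _fmt_attrs(attrs: dict[str, str]) -> str:
    return ";".join(f"{_escape(k)}={_escape(v)}" for k, v in attrs.items())


def _row(seqid: str, source: str, ftype: str, start: int, end: int,
         strand: str, attrs: dict[str, str]) -> str:
    return "\t".join([seqid, source, ftype, str(start), str(end), ".",
                      strand, ".", _fmt_attrs(attrs)])


def write_evidence(alignments: Iterable[EvidenceAlignment],
                   sink: str | os.PathLike | IO[str],
                   source: str = "aedqc") -> None:
    """Write evidence alignments as GFF3 match/match_part hierarchies."""
    own = not hasattr(sink, "write")
    fh: IO[str] = open(os.fspath(sink), "w") if own else sink  # type: ignore[arg-type]
    try:
        fh.write("##gff-version 3\n")
        for aln in alignments:
            s, e = aln.parts.span
            score = "." if aln.score is None else f"{aln.score:g}"
            fh.write("\t".join([aln.seqid, source, "match", str(s), str(e),
                                score, aln.strand, ".",
                                _fmt_attrs({"ID": aln.id})]) + "\n")
            for n, (ps, pe) in enumerate(aln.parts.intervals, 1):
                fh.write("\t".join([aln.seqid, source, "match_part",
                                    str(ps), str(pe), ".", aln.strand, ".",
                                    _fmt_attrs({"ID": f"{aln.id}:p{n}",
                                                "Parent": aln.id})]) + "\n")
    finally:
        if own:
            fh.close()


def write_annotations(annotations: AnnotationSet,
                      sink: str | os.PathLike | IO[str],
                      aed_records: Mapping[str, object] | None = None,
                      status: Mapping[str, str] | None = None,
                      source: str = "aedqc") -> None:
    """Write an annotation set as GFF3, attaching QC attributes to mRNA rows.

    ``aed_records`` maps transcript id → AED record (anything with an
    ``aed`` attribute, or a bare float); when present the mRNA row gains an
    ``_AED=<value>`` attribute rendered to 2 decimals. ``status`` optionally
    maps transcript id → a ``maker_status`` label (consensus bookkeeping).
    Output is written atomically when ``sink`` is a path.
    """
    own = not hasattr(sink, "write")
    if own:
        path = os.fspath(sink)
        fd, tmp = tempfile.mkstemp(dir=os.path.dirname(path) or ".", suffix=".gff3.tmp")
        fh: IO[str] = os.fdopen(fd, "w")
    else:
        fh = sink  # type: ignore[assignment]
    try:
        fh.write("##gff-version 3\n")
        for gene in annotations.genes:
            gstart, gend = gene.span
            gattrs = {"ID": gene.id, **{k: v for k, v in gene.attributes.items()
                                        if k != "ID"}}
            fh.write(_row(gene.seqid, source, "gene", gstart, gend,
                          gene.strand, gattrs) + "\n")
            for t in gene.transcripts:
                tattrs = {"ID": t.id, "Parent": gene.id}
                tattrs.update({k: v for k, v in t.attributes.items()
                               if k not in ("ID", "Parent", "_AED", "maker_status")})
                if aed_records is not None and t.id in aed_records:
                    rec = aed_records[t.id]
                    aed = getattr(rec, "aed", rec)
                    tattrs["_AED"] = f"{float(aed):.2f}"
                elif "_AED" in t.attributes:
                    tattrs["_AED"] = t.attributes["_AED"]
                if status is not None and t.id in status:
                    tattrs["maker_status"] = status[t.id]
                elif "maker_status" in t.attributes:
                    tattrs["maker_status"] = t.attributes["maker_status"]
                ts, te = t.span
                fh.write(_row(t.seqid, source, "mRNA", ts, te, t.strand, tattrs) + "\n")
                for n, (s, e) in enumerate(t.exons.intervals, 1):
                    fh.write(_row(t.seqid, source, "exon", s, e, t.strand,
                                  {"ID": f"{t.id}:exon:{n}", "Parent": t.id}) + "\n")
                if t.cds:
                    for n, (s, e) in enumerate(t.cds.intervals, 1):
                        fh.write(_row(t.seqid, source, "CDS", s, e, t.strand,
                                      {"ID": f"{t.id}:cds:{n}", "Parent": t.id}) + "\n")
        if own:
            fh.close()
            os.replace(tmp, path)
    except BaseException:
        if own:
            fh.close()
            os.unlink(tmp)
        raise
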