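"""Reference-based evaluation of a prediction set at two stringencies.

Given a prediction set *i* and a trusted reference set *j*, sensitivity,
specificity and accuracy are

    SN = |i ∩ j| / |j|,   SP = |i ∩ j| / |i|,   accuracy = (SN + SP) / 2

evaluated at the nucleotide level (position unions per seqid/strand) and at
the exon level (an exon matches only when both boundaries are exactly equal
on the same seqid/strand). Overlapping isoform exons are flattened by union
for the nucleotide level and deduplicated by coordinate for the exon level,
so both levels are well defined on multi-isoform annotation sets.
Opposite-strand overlap never counts.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from typing import IO, Iterable

from .gff import AnnotationSet
from .intervals import IntervalSet, intersection_size, normalize

__all__ = ["ComparisonStats", "nucleotide_stats", "exon_stats", "write_comparison_table"]


class EmptySetError(ValueError):
    """SN or SP is undefined because one side covers nothing."""


@dataclass(frozen=True)
class ComparisonStats:
    level: str  # "nucleotide" | "exon"
    sn: float
    sp: float

    @property
    def accuracy(self) -> float:
        return (self.sn + self.sp) / 2.0


def _position_unions(annotations: AnnotationSet) -> dict[tuple[str, str], IntervalSet]:
    """Exon-position union per (seqid, strand)."""
    pairs: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for t in annotations.transcripts():
        pairs.setdefault((t.seqid, t.strand), []).extend(t.exons.intervals)
    return {key: normalize(v, seqid=key[0]) for key, v in pairs.items()}


def _exon_coords(annotations: AnnotationSet) -> set[tuple[str, str, int, int]]:
    """Distinct exon coordinates (seqid, strand, start, end) across isoforms."""
    return {(t.seqid, t.strand, s, e)
            for t in annotations.transcripts()
            for s, e in t.exons.intervals}


def nucleotide_stats(pred: AnnotationSet, ref: AnnotationSet) -> ComparisonStats:
    """Base-pair-level SN/SP/accuracy of predictions against a reference."""
    pred_u = _position_unions(pred)
    ref_u = _position_unions(ref)
    n_pred = sum(s.covered_bases for s in pred_u.values())
    n_ref = sum(s.covered_bases for s in ref_u.values())
    if n_ref == 0:
        raise EmptySetError("reference covers no positions; SN undefined")
    if n_pred == 0:
        raise EmptySetError("prediction covers no positions; SP undefined")
    overlap = sum(intersection_size(pred_u[key], ref_u[key])
                  for key in pred_u.keys() & ref_u.keys())
    return ComparisonStats("nucleotide", sn=overlap / n_ref, sp=overlap / n_pred)


def exon_stats(pred: AnnotationSet, ref: AnnotationSet) -> ComparisonStats:
    """Exon-level stats under the exact-boundary rule.

    An exon is matched only when an exon with identical start *and* end
    exists in the other set on the same seqid/strand; a one-base boundary
    shift fails. Exons are deduplicated by coordinate within each set.
    """
    pred_exons = _exon_coords(pred)
    ref_exons = _exon_coords(ref)
    if not ref_exons:
        raise EmptySetError("reference has no exons; SN undefined")
    if not pred_exons:
        raise EmptySetError("prediction has no exons; SP undefined")
    matched = len(pred_exons & ref_exons)
    return ComparisonStats("exon", sn=matched / len(ref_exons),
                           sp=matched / len(pred_exons))


def write_comparison_table(stats: Iterable[ComparisonStats],
                           sink: IO[str] | None = None) -> None:
    """TSV report with percentages to 2 decimals (e.g. ``88.48``)."""
    fh = sink or sys.stdout
    fh.write("level\tsn_pct\tsp_pct\taccuracy_pct\n")
    for s in stats:
        fh.write(f"{s.level}\t{100 * s.sn:.2f}\t{100 * s.sp:.2f}\t"
                 f"{100 * s.accuracy:.2f}\n")
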