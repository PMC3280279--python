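"""Deterministic synthetic fixtures with planted ground truth.

The generator lays out multi-exon gene models along an abstract coordinate
axis (no nucleotide sequence — only coordinates matter to every computation
in this package) and constructs evidence alignments whose agreement with
each gene is planted at a chosen target AED. For a gene whose exon union
covers L bases and a target distance t, the evidence keeps an overlap of
o = round((1-t)·L) exon bases and adds an extension of
e = round(o·t/(1-t)) bases beyond the gene span, which makes both
sensitivity and specificity equal 1-t up to integer rounding and hence the
analytically achieved AED equal t (exactly when the rounding is exact; the
truth table records the achieved value). A planted fraction of genes gets
no overlapping evidence at all (true AED 1), and extra evidence-only loci
with no gene model are interleaved between genes.

When alternate annotation sets are requested, each supported gene with a
positive target AED receives a competing model identical to its evidence
union (AED 0), so a consensus run must replace exactly those reference
models — the planted re-annotation summary is fully determined.

Loci are placed collision-free (successive loci separated by a gap larger
than any evidence extension), so locus counts are exactly controllable.
Identical spec + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .consensus import ReannotationSummary
from .gff import (AnnotationSet, EvidenceAlignment, GeneModel, Transcript,
                  write_annotations, write_evidence)
from .intervals import IntervalSet, normalize
from .reporting import BLAST_COLUMNS

__all__ = ["FixtureSpec", "Fixture", "generate"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``target_aed`` may be a scalar applied to every supported gene, a
    per-gene sequence (length ``n_genes``), or None to draw per-gene targets
    uniformly from [0, 0.9). ``fraction_unsupported`` genes are overridden
    to AED 1 (no evidence); ``fraction_evidence_only`` (of ``n_genes``)
    extra loci carry evidence but no model. ``n_annotation_sets`` counts the
    reference plus alternates.
    """

    seed: int = 0
    n_genes: int = 50
    exon_count: tuple[int, int] = (2, 6)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (60, 200)
    target_aed: float | Sequence[float] | None = None
    evidence_redundancy: int = 2
    fraction_unsupported: float = 0.1
    fraction_evidence_only: float = 0.1
    n_annotation_sets: int = 1
    n_partner_species: int = 1
    seqid: str = "chr1"
    locus_gap: int = 500
    evidence_class: str = "EST"


@dataclass
class Fixture:
    """A generated dataset plus its planted truth."""

    spec: FixtureSpec
    reference: AnnotationSet
    alternates: list[AnnotationSet]
    evidence: list[EvidenceAlignment]
    attribute: dict[str, bool]
    hits: dict[str, tuple[pd.DataFrame, pd.DataFrame]]
    truth: pd.DataFrame
    expected_summary: ReannotationSummary

    @property
    def annotation_sets(self) -> list[AnnotationSet]:
        return [self.reference, *self.alternates]

    def write(self, outdir: str | os.PathLike) -> dict[str, str]:
        """Write all fixture files under ``outdir``; returns role → path."""
        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        paths: dict[str, str] = {}

        def p(name: str) -> str:
            return os.path.join(outdir, name)

        write_annotations(self.reference, p("reference.gff3"))
        paths["reference"] = p("reference.gff3")
        for alt in self.alternates:
            write_annotations(alt, p(f"{alt.label}.gff3"))
            paths[alt.label] = p(f"{alt.label}.gff3")
        write_evidence(self.evidence, p("evidence.gff3"))
        paths["evidence"] = p("evidence.gff3")

        with open(p("attributes.tsv"), "w") as fh:
            for gid in sorted(self.attribute):
                fh.write(f"{gid}\t{int(self.attribute[gid])}\n")
        paths["attributes"] = p("attributes.tsv")

        for species, (ab, ba) in self.hits.items():
            ab.to_csv(p(f"hits_ref_vs_{species}.tsv"), sep="\t",
                      header=False, index=False)
            ba.to_csv(p(f"hits_{species}_vs_ref.tsv"), sep="\t",
                      header=False, index=False)
            paths[f"hits_ab_{species}"] = p(f"hits_ref_vs_{species}.tsv")
            paths[f"hits_ba_{species}"] = p(f"hits_{species}_vs_ref.tsv")

        self.truth.to_csv(p("truth.tsv"), sep="\t", index=False)
        paths["truth"] = p("truth.tsv")
        return paths


def _resolve_targets(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.target_aed is None:
        return rng.uniform(0.0, 0.9, size=spec.n_genes)
    if np.isscalar(spec.target_aed):
        return np.full(spec.n_genes, float(spec.target_aed))
    targets = np.asarray(spec.target_aed, dtype=float)
    if targets.shape != (spec.n_genes,):
        raise ValueError(
            f"target_aed sequence has length {len(targets)}, expected {spec.n_genes}")
    return targets


def _plant_evidence(exons: IntervalSet, t: float) -> tuple[list[tuple[int, int]], float]:
    """Evidence parts achieving AED ≈ t against exon set; returns (parts, achieved).

    Keeps the first o exon bases and extends e bases beyond the span so that
    SP = o/L and SN = o/(o+e) both approximate 1-t.
    """
    L = exons.covered_bases
    if t >= 1.0:
        return [], 1.0
    o = round((1.0 - t) * L)
    if o < 1:
        raise ValueError(
            f"target AED {t} infeasible for a {L}-base exon union "
            "(zero overlap bases would remain)")
    e = round(o * t / (1.0 - t))
    parts: list[tuple[int, int]] = []
    remaining = o
    for s, end in exons.intervals:
        if remaining <= 0:
            break
        take = min(remaining, end - s + 1)
        parts.append((s, s + take - 1))
        remaining -= take
    if e > 0:
        span_end = exons.span[1]
        parts.append((span_end + 1, span_end + e))
    sn = o / (o + e)
    sp = o / L
    return parts, 1.0 - (sn + sp) / 2.0


def generate(spec: FixtureSpec) -> Fixture:
    """Generate a complete fixture with planted per-gene truth.

    Raises
    ------
    ValueError
        When a target AED is infeasible at the drawn exon sizes (the overlap
        would round to zero bases), or on malformed spec fields.
    """
    if not 0 <= spec.fraction_unsupported <= 1:
        raise ValueError("fraction_unsupported must lie in [0, 1]")
    if spec.n_annotation_sets < 1:
        raise ValueError("need at least one annotation set")
    rng = np.random.default_rng(spec.seed)
    targets = _resolve_targets(spec, rng)
    if np.any((targets < 0) | (targets > 1)):
        raise ValueError("target AED values must lie in [0, 1]")

    n = spec.n_genes
    n_unsupported = round(spec.fraction_unsupported * n)
    unsupported = np.zeros(n, dtype=bool)
    unsupported[rng.permutation(n)[:n_unsupported]] = True
    targets = np.where(unsupported, 1.0, targets)

    n_evidence_only = round(spec.fraction_evidence_only * n)
    # interleave evidence-only loci among genes deterministically
    ev_only_after = set(rng.permutation(n)[:n_evidence_only].tolist())

    has_alternates = spec.n_annotation_sets >= 2
    genes: list[GeneModel] = []
    alt_genes: list[list[GeneModel]] = [[] for _ in range(spec.n_annotation_sets - 1)]
    evidence: list[EvidenceAlignment] = []
    truth_rows: list[dict] = []
    cursor = 1
    width = len(str(max(n, 1)))

    for g in range(n):
        gid = f"gene{g + 1:0{width}d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(spec.exon_count[0], spec.exon_count[1] + 1))
        pairs: list[tuple[int, int]] = []
        pos = cursor
        for k in range(n_exons):
            elen = int(rng.integers(spec.exon_length[0], spec.exon_length[1] + 1))
            pairs.append((pos, pos + elen - 1))
            pos += elen
            if k < n_exons - 1:
                pos += int(rng.integers(spec.intron_length[0],
                                        spec.intron_length[1] + 1))
        exons = normalize(pairs, seqid=spec.seqid)
        tx = Transcript(id=f"{gid}.t1", gene_id=gid, seqid=spec.seqid,
                        strand=strand, exons=exons, source_set="reference")
        genes.append(GeneModel(id=gid, seqid=spec.seqid, strand=strand,
                               transcripts=[tx]))

        t = float(targets[g])
        parts, achieved = _plant_evidence(exons, t)
        max_extent = exons.span[1]
        if parts:
            for r in range(spec.evidence_redundancy):
                evidence.append(EvidenceAlignment(
                    id=f"ev-{gid}-{r + 1}", evidence_class=spec.evidence_class,
                    seqid=spec.seqid, strand=strand,
                    parts=normalize(parts, seqid=spec.seqid)))
            max_extent = max(max_extent, parts[-1][1])

        altered = has_alternates and parts and achieved > 0
        if has_alternates and parts:
            # first alternate set offers the evidence-exact model only where
            # the reference disagrees with the evidence
            if achieved > 0:
                alt_tx = Transcript(
                    id=f"{gid}.alt1", gene_id=f"{gid}.alt", seqid=spec.seqid,
                    strand=strand, exons=normalize(parts, seqid=spec.seqid),
                    source_set="alternate-1")
                alt_genes[0].append(GeneModel(
                    id=f"{gid}.alt", seqid=spec.seqid, strand=strand,
                    transcripts=[alt_tx]))

        truth_rows.append({
            "gene_id": gid, "transcript_id": tx.id,
            "target_aed": t, "achieved_aed": achieved,
            "supported": bool(parts),
            "expected_status": ("unsupported" if not parts
                                else "replaced" if altered else "kept_unchanged"),
            "has_attribute": achieved < 0.5,
            "has_ortholog": achieved < 0.5,
        })
        cursor = max_extent + spec.locus_gap

        if g in ev_only_after:
            width_ev = int(rng.integers(spec.exon_length[0], spec.exon_length[1] + 1))
            ev_parts = [(cursor, cursor + width_ev - 1),
                        (cursor + width_ev + 50, cursor + width_ev + 50 + width_ev - 1)]
            evidence.append(EvidenceAlignment(
                id=f"ev-only-{g + 1:0{width}d}", evidence_class=spec.evidence_class,
                seqid=spec.seqid, strand=strand,
                parts=normalize(ev_parts, seqid=spec.seqid)))
            cursor = ev_parts[-1][1] + spec.locus_gap

    reference = AnnotationSet(label="reference", genes=genes,
                              provenance="<synthetic>")
    alternates = [AnnotationSet(label=f"alternate-{k + 1}", genes=gs,
                                provenance="<synthetic>")
                  for k, gs in enumerate(alt_genes)]

    truth = pd.DataFrame(truth_rows)
    attribute = dict(zip(truth["gene_id"], truth["has_attribute"]))

    hits: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    for s in range(spec.n_partner_species):
        species = f"species{s + 1}"
        ab_rows, ba_rows = [], []
        for row in truth_rows:
            gid = row["gene_id"]
            partner = f"{species}_{gid}"
            if row["has_ortholog"]:
                ab_rows.append(_hit_row(gid, partner, 1e-30, 500.0))
                ba_rows.append(_hit_row(partner, gid, 1e-28, 480.0))
                # weaker decoy hit exercising best-hit selection
                ab_rows.append(_hit_row(gid, f"{species}_decoy", 1e-5, 60.0))
            else:
                ab_rows.append(_hit_row(gid, partner, 1e-3, 30.0))
                ba_rows.append(_hit_row(partner, gid, 1e-3, 30.0))
        hits[species] =(pd.DataFrame(ab_rows, columns=BLAST_COLUMNS),
                         pd.DataFrame(ba_rows, columns=BLAST_COLUMNS))

    n_altered = int((truth["expected_status"] == "replaced").sum())
    n_unchanged = n - n_altered
    expected = ReannotationSummary(
        n_input_reference=n, n_altered=n_altered, n_new_loci=n_evidence_only,
        n_unchanged=n_unchanged,
        n_flagged_unsupported=int((~truth["supported"]).sum()))

    return Fixture(spec=spec, reference=reference, alternates=alternates,
                   evidence=evidence, attribute=attribute, hits=hits,
                   truth=truth, expected_summary=expected)


def _hit_row(q: str, s: str, evalue: float, bitscore: float) -> dict:
    return {"qseqid": q, "sseqid": s, "pident": 95.0, "length": 200,
            "mismatch": 10, "gapopen": 0, "qstart": 1, "qend": 200,
            "sstart": 1, "send": 200, "evalue": evalue, "bitscore": bitscore}
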