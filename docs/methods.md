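# Methods

## Model

`aedqc` treats a genome annotation as a set of transcript models — each an
identified collection of exon intervals (1-based, fully closed, GFF3
convention) on one sequence and strand — and experimental evidence as
identified collections of aligned-segment intervals tagged with a class
(EST, protein, or mRNA-seq). No nucleotide sequence is consulted anywhere:
every statistic in the package is a function of coordinates alone.

Because most genomes lack a trusted reference gene set, evidence clustered
by transitive genomic overlap stands in for the reference. A *locus* is a
maximal single-linkage cluster: two features are linked when their interval
sets share at least one base (configurable minimum) on compatible strands,
and clusters are the connected components of that graph. With *i* the
transcript's exon-position union and *j* the union of evidence positions in
the transcript's own cluster,

SN = |i∩j|/|j| (0 when the cluster is empty), SP = |i∩j|/|i|,
congruency C = (SN+SP)/2, and the Annotation Edit Distance AED = 1 − C.
AED is 0 exactly when the two position unions coincide, 1 exactly when they
are disjoint, and symmetric in *i* and *j* (an average of two mirror-image
ratios). Evidence elsewhere on the chromosome never influences a
transcript's score.

Reference-based evaluation uses the same SN/SP/accuracy formulas against a
trusted annotation set at two stringencies: nucleotide level (position
unions per seqid/strand) and exon level, where an exon matches only when
both boundaries agree exactly and exons are deduplicated by coordinate
within each set.

Consensus re-annotation clusters all candidate transcripts (reference plus
alternates) together with the evidence, and carries forward the minimal-AED
candidate per locus. "Most consistent with the evidence" is operationalized
as minimal AED; no other criterion is defined for this selection. Loci with
evidence but no model yield synthesized models whose exons are the merged
evidence parts (AED 0 against their own cluster by construction). The
summary counts satisfy `altered + unchanged = reference input` because each
reference transcript is classified by exactly one locus decision.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| strand mode | `aware` | same strand links; unstranded links either. `strict` and `ignore` available. Protein alignments are often unstranded, hence the permissive default. |
| minimum linkage overlap | 1 base | simplest defensible overlap rule; configurable. |
| evidence size \|j\| | union | union of cluster-evidence positions. A per-alignment *sum* is available (`evidence_size="sum"`) but lets redundant ESTs drive SN toward 0 for perfect models, so it is not the default. |
| evidence pooling | pooled | one union over all classes; `best-class` scores classes separately and keeps the best. |
| scored coordinates | exons | evidence includes untranslated ESTs; CDS-restricted scoring available (`use_cds`). |
| review threshold | 1.0 | flags models with literally no evidence support; 0.95 additionally catches the near-1 spike of marginal models. |
| RBH e-value ceiling | 1e-6, inclusive | both best-hit e-values must satisfy it. |
| quartile bins | [0,.25), [.25,.5), [.5,.75), [.75,1] | the last bin is right-closed so AED 1 is counted; 0.25 falls in the second bin. |

## Numerical and convention choices

- Book-ended intervals (`[1,10]`,`[11,20]`) are not merged during
  normalization: the covered-base count is unchanged and exon boundaries
  survive for exon-level metrics. Union/intersection sizes are computed by
  sorted two-pointer sweeps, so all counts are exact integers and AED values
  are exact ratios (the test suite checks agreement with explicit
  position-set enumeration to 1e-12).
- Gene-level AED is the minimum over the gene's transcripts: a gene is as
  supported as its best isoform.
- Consensus tie-breaks are deterministic: AED, then larger exon-base count,
  then source-set priority in input order, then transcript id. Review
  queues order equal AEDs by transcript id.
- Protein alignment coordinates are consumed as genomic nucleotide
  coordinates exactly as given in the GFF3; no codon scaling is applied.
- Transcript-level GFF3 rows may be `mRNA`, `transcript`, or any gene child
  with exon children; a gene with direct exon children gets an implicit
  single transcript. Empty GFF3 files parse to empty sets rather than
  erroring.
- Best BLAST hit per query: minimal e-value, then maximal bit score, then
  lexicographic subject id; self-hits are discarded before selection.

## Synthetic data generator

The generator (`aedqc.simulate`) plants ground truth rather than emulating
biology. Genes with 2–6 exons of 80–300 bases separated by 60–200 base
introns are laid out collision-free along one abstract chromosome
(successive loci separated by a gap larger than any evidence extension), so
locus counts are exactly controllable. For a target distance *t* and exon
union of L bases, evidence keeps o = round((1−t)L) leading exon bases and
adds e = round(o·t/(1−t)) bases beyond the gene span, making SN ≈ SP ≈ 1−t;
the achieved AED equals *t* up to integer rounding (well within ±0.02 at
these exon sizes; the truth table records the exact achieved value, and a
target whose overlap would round to zero bases raises an error). A planted
fraction of genes receives no evidence (true AED 1); extra evidence-only
loci carry evidence and no model. With two annotation sets, the alternate
set supplies an evidence-exact competitor precisely at supported loci where
the reference disagrees with the evidence, which fixes the expected
consensus summary in advance. Hit tables plant mutual best hits (e-value
1e-30/1e-28 plus weak decoys) for genes with achieved AED < 0.5, and
sub-threshold hits (1e-3) otherwise; the attribute table marks the same
genes positive.

What the generator does **not** emulate: real splice-site structure,
alignment noise and soft-clipping, chimeric or partial alignments,
cross-locus evidence bridging, multi-isoform genes, and paralogy in the hit
tables. Passing tests therefore demonstrate correctness of the computations
and bookkeeping under clean planted conditions, not robustness to messy
real-world alignments.

All randomness flows from one `numpy.random.default_rng(seed)`; identical
spec and seed reproduce byte-identical files.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
1000 random instances for the oracle comparison (sequences ≤ 10 kb), 200
genes for the consensus run, 20 genes per planted decile target. These sizes
make every statistic exact or near-exact while the whole suite completes in
seconds on one CPU.

## Design decisions that were genuinely open

- The clustering linkage rule and strand policy are not externally fixed;
  single linkage at ≥ 1 base with strand-aware matching is this package's
  choice, and both knobs are exposed.
- |j| as union versus sum (union chosen; see above), and pooled versus
  per-class evidence (pooled chosen) — both alternatives remain available
  behind flags.
- "Altered" during re-annotation means *displaced by a better-scoring
  provided or synthesized candidate*. Boundary revision by ab initio
  predictors is out of scope, so this package's altered/unchanged counts
  reflect model selection only.
- Mean orthologs per gene in the orthology-by-quartile report is computed
  over the orthologous subset, not all genes.
- Enrichment-report domain filtering is a keyword exclusion applied to a
  (gene, domain) table; running a domain scanner is out of scope.

## Known limitations

- Exon-level comparison conventions (isoform flattening, deduplication) are
  this package's own well-defined choices; other evaluation tools may count
  shared isoform exons differently.
- AED here is the plain positional distance; no splice-junction-weighted
  variant is implemented.
- GFF3 FASTA sections and full sequence-ontology validation are not
  supported; GTF input is not accepted.
- The consensus step never merges partial models or re-predicts structure;
  it selects among the models it is given plus evidence-derived ones.
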