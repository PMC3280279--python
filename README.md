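# aedqc

Evidence-based quality control for genome annotations.

Most newly sequenced genomes have no trusted "gold standard" gene set to
evaluate an annotation against. What they do have is aligned experimental
evidence — EST, protein, and mRNA-seq alignments. `aedqc` scores every gene
model directly against that evidence with the **Annotation Edit Distance
(AED)**, compares competing annotation builds, selects a consensus model per
locus during re-annotation, and produces the summary reports curators use to
decide which models to review first.

## The statistic

Evidence alignments and gene models are clustered into loci by transitive
genomic overlap (single linkage, ≥ 1 shared base, strand-aware). For a
transcript with exon-position set *i* and the union *j* of evidence
positions in its own cluster:

    SN  = |i ∩ j| / |j|        sensitivity   (0 when the cluster has no evidence)
    SP  = |i ∩ j| / |i|        specificity
    C   = (SN + SP) / 2        congruency
    AED = 1 − C

AED = 0 means the annotation agrees exactly with the evidence union;
AED = 1 means no overlapping evidence at all. Sorting models by descending
AED ranks them worst-supported first — a ready-made manual-review queue, with
models at or near 1 flagged as possible false positives.

The same SN/SP/accuracy formulas, applied against a trusted reference set
instead of evidence, give the classical nucleotide-level and exon-level
comparison statistics (`aedqc compare`); at the exon level a feature counts
as matched only when both boundaries agree exactly.

During consensus re-annotation (`aedqc consensus`), the reference set, any
number of alternate sets, and the evidence are clustered into loci; the
candidate with minimal AED is carried forward at each locus (ties: larger
exon span, then source priority, then id). Loci with evidence but no model
yield synthesized evidence-derived models — candidate novel genes. The
bookkeeping guarantees `altered + unchanged = reference input count`.

## Worked example

Generate a small synthetic dataset with known ground truth, then score it:

```
aedqc simulate --seed 11 --n-genes 6 --fraction-unsupported 0.17 \
      --fraction-evidence-only 0.17 --out demo/fixture
aedqc aed --annotations demo/fixture/reference.gff3 \
      --est demo/fixture/evidence.gff3 --out demo/aed
cat demo/aed/aed.tsv
```

```
transcript_id	gene_id	seqid	strand	sn	sp	aed	n_evidence
gene1.t1	gene1	chr1	+	0.8844	0.8844	0.1156	2
gene2.t1	gene2	chr1	-	0.5505	0.5505	0.4495	2
gene3.t1	gene3	chr1	+	0.0000	0.0000	1.0000	0
gene4.t1	gene4	chr1	+	0.9739	0.9739	0.0261	2
gene5.t1	gene5	chr1	-	0.8660	0.8660	0.1340	2
gene6.t1	gene6	chr1	+	0.1647	0.1651	0.8351	2
```

`gene3.t1` has no overlapping evidence (AED 1.0000, `n_evidence` 0): it
would be flagged for manual review as a possible false positive. `gene4.t1`
agrees with its two supporting alignments on 97% of positions (AED 0.0261).
The accompanying `annotations.gff3` carries the score on each mRNA row:

```
chr1	aedqc	mRNA	1	1943	.	+	.	ID=gene1.t1;Parent=gene1;_AED=0.12
```

As a single-transcript illustration of the formula: exons `[101,200]`
(100 bases) against one EST covering `[151,270]` (120 bases) share 50
positions, so SN = 50/120 ≈ 0.4167, SP = 50/100 = 0.5000, and
AED = 1 − (0.4167 + 0.5000)/2 ≈ 0.5417.

Other subcommands: `compare` (a prediction set against a reference —
identical sets print 100.00% at both nucleotide and exon stringency),
`consensus`, `report-cdf`, `report-quartiles`, and `rbh`
(reciprocal best hits from 12-column tabular files, e-value ≤ 1e-6 by
default). See `aedqc <subcommand> --help`.

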