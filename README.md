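# vectortx

ORF-centric classification and quantification of direct-RNA (dRNA)
nanopore reads from adenovirus-vectored vaccine genomes.

Replication-deficient adenovirus vectors (ChAdOx1-class: E1/E3-deleted)
carry an intronless transgene cassette in the deleted E1 locus. Directly
sequencing the mRNA of infected cells answers three safety-relevant
questions: whether the transgene mRNA dominates the vector-derived
transcriptome in nonpermissive cells, how often transcripts from the
transgene promoter are spliced at all (every such junction is
unintended, and one that disrupts the transgene ORF would express a
novel protein), and whether any transcript encodes an E1 protein
(evidence of replication-competent adenovirus contamination).

`vectortx` is for vector developers and analysts with spliced long-read
alignments in hand. It:

* decodes SAM/BAM spliced alignments into exon chains (N CIGAR ops open
  exon blocks; small deletions are absorbed);
* canonicalizes each read against a feature catalog — junction ends
  snap independently to annotated donors/acceptors (±10 nt), 5' ends
  assign to a TSS at or upstream within 100 nt (dRNA reads are
  5'-truncated), 3' ends match polyA sites ±30 nt;
* collapses reads into **transcript groups** keyed by
  (strand, TSS, junction chain, polyA) and registers frequencies;
* assigns each group its **5'-proximal ORF**: the first AUG of the
  TSS-anchored mature mRNA, matched exactly against catalog start
  codons — anything else is "None from the list" and its peptide is
  reported;
* produces per-ORF gene tables, a transgene splice audit
  (spliced per 100 unspliced transcripts from the transgene promoter),
  an E1/RCA screen, novel 5'-end clusters (candidate promoters),
  read accounting, and BED12 transcript models.

A built-in simulator (`vectortx.simulate`) generates a toy annotated
vector genome and noisy dRNA reads with ground truth (geometric 5'
truncation, base errors, polyA tails), so the entire pipeline is
testable offline; see `docs/methods.md` for the model and defaults.

## Worked example

Simulate 5,000 reads from the nonpermissive (transgene-dominated)
profile and classify them:

```bash
vectortx run --n-reads 5000 --profile nonpermissive --seed 7 --out run7
vectortx report --run run7
```

The gene table (`run7/gene_table.tsv`) shows the transgene mRNA
dominating, with the aberrant transcripts tabulated as "None from the
list" because their cryptic splice removes the transgene start codon:

```
# total_reads	5000
feature	count	percent
transgene	4301	86.02
None from the list	135	2.7
Fibre (L5)	124	2.48
E4 orf3	120	2.4
DBP (E2A)	112	2.24
52/55K (L1)	107	2.14
Hexon (L3)	101	2.02
```

The splice audit (`run7/splice_audit.tsv`) reports 118 spliced vs 3,701
unspliced transgene-promoter reads — 3.2 spliced per 100 unspliced, and
flags the one junction whose acceptor lies inside the transgene ORF:

```
# promoter	CMV
# unspliced_reads	3701
# spliced_reads	118
# pct_spliced_vs_unspliced	3.2
donor	acceptor	count	inside_orf
1151	1601	118	yes
```

`run7/rca_summary.txt` reports `e1_orf_read_count=0` and the verdict
`no E1 transcripts detected`: no simulated model encodes an E1 protein,
and a single E1-calling read would flip the verdict.

To classify your own data, align dRNA reads with a spliced long-read
aligner (e.g. `minimap2 -ax splice -uf -k14 vector.fasta reads.fastq`)
and run:

```bash
vectortx classify --genome vector.fasta --catalog features.tsv \
    --alignments aln.sam --mapped-host 698670 --out myrun
```

`features.tsv` is a 6-column catalog (class, label, start, end, strand,
tags) documented in `vectortx.genome_model.load_feature_catalog`; a
GFF3 reader is also provided.

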