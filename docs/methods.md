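# Methods

## Problem and model

Replication-deficient adenovirus vaccine vectors carry an intronless
transgene expression cassette in the deleted E1 locus. Two safety
questions about such a vector are answerable directly from native mRNA:
(i) is the dominant vector-derived transcript the intended transgene
mRNA, with essentially no backbone transcription in nonpermissive
(E1-noncomplementing) cells, and (ii) how often do transcripts from the
transgene promoter carry *any* splice junction — every junction there is
unintended, and one that removes or disrupts the transgene ORF would
express a novel protein. A third question, whether any transcript
encodes an E1 protein, screens for replication-competent adenovirus
(RCA) contamination.

`vectortx` answers these from spliced long-read alignments of direct
RNA (dRNA) nanopore reads against the annotated vector genome. The unit
of quantification is the **transcript group**: all reads sharing a
strand, a TSS assignment, a snapped splice-junction chain, and a polyA
assignment. Each group is then assigned the ORF a scanning ribosome
would translate — the **5'-proximal ORF** of its mature mRNA — and
groups are aggregated into per-ORF gene tables.

## Canonicalization

dRNA molecules thread through the pore 3'-first, so 3' ends are intact
but 5' ends are frequently truncated. The end-assignment rules encode
this asymmetry:

* **TSS assignment** accepts only catalog TSSs *upstream* (in
  transcription direction) of the observed 5' end, within a window
  (default 100 nt); the nearest wins and the downstream offset is
  recorded. Default chosen to absorb the bulk of a geometric truncation
  with mean ≈ 50 nt while rarely crossing between promoters.
* **polyA assignment** matches the observed 3' end to the nearest
  catalog site within a symmetric ±30 nt tolerance.
* **Junction snapping** moves each end of each observed junction
  independently to the nearest catalog donor/acceptor within ±10 nt.
  A junction either of whose ends has no match keeps its observed
  coordinates and is flagged **novel** — a half-annotated junction is
  still novel, because cryptic-site usage is exactly the event the
  audit must not absorb. Snapping is idempotent, and widening the
  tolerance can only merge groups, never split them.
* Equidistant candidates resolve to the lower genomic coordinate, for
  reproducibility.

Junction coordinates are the half-open block edges of the alignment: on
the plus strand the donor is the first intronic base and the acceptor
the first exonic base after the intron; on the minus strand the roles
of the two edges swap. Internally everything is 0-based half-open;
reports are 1-based.

Reads with no junctions that fail both end assignments are counted as
unclassified; everything else forms a group (a group may have an
unassigned TSS or polyA — such groups feed the novel-end clustering,
which single-links unassigned 5' ends with gap ≤ 20 nt and reports
clusters of ≥ 10 reads as promoter candidates).

## ORF calling

The group's representative chain is anchored at the assigned catalog
TSS rather than the truncated observed 5' end — otherwise truncation
would spuriously shift the first AUG. The mature mRNA is the
concatenation of exon blocks (reverse-complemented for minus-strand
groups); the first AUG is located, mapped back to genomic coordinates,
and compared with catalog ORF start codons. An exact same-strand match
calls that ORF; any other AUG yields a "None from the list" call with
the translated peptide (standard genetic code, to the first stop or
transcript end); no AUG yields no call. No fuzzy or near-cognate
matching is attempted, matching the binary known/"not known" bookkeeping
the tables report.

Gene-table percentages use a declared denominator — the number of
classified reads — recorded in the table metadata; percentages are
computed exactly (decimal arithmetic, round-half-up) at a configurable
precision (default 2 dp).

## Splice audit and RCA screen

Transcripts assigned to the transgene promoter are partitioned into
unspliced vs ≥1-junction. The headline statistic is **spliced per 100
unspliced** (a `denominator="total"` variant is available, since the
spliced-over-unspliced convention is unusual; it is kept as the default
for comparability with the way such audits are reported). Junctions
with either end inside the transgene ORF are listed separately — those
are the ones that disrupt the immunogen.

The RCA screen counts reads in groups whose ORF call carries the "E1"
category tag. The default threshold is 0: any vector-derived E1
transcript flips the verdict, which is the correct semantics for a
safety screen. Reads mapped to a separate host-integrated E1 contig
(expected in permissive cells) are passed through as a count and never
affect the vector verdict.

## Synthetic data generator

`build_toy_genome` lays out a 35 kb single-contig vector emulating the
transcriptional architecture the pipeline audits:

* an intronless **transgene** cassette near the left end (deleted-E1
  position): own promoter, 500 nt ATG-free 5' leader, a 400-codon ORF
  whose interior uses A/T-free codons (so neither a premature stop nor
  a spurious AUG can arise in any frame), own polyA site;
* one **aberrant** transcript from the same promoter whose cryptic
  junction (absent from the catalog, hence novel) runs from the 5'
  leader into the ORF, splicing out the start codon; its first AUG is a
  planted out-of-frame internal AUG, so it translates a novel peptide
  and is tabulated as "None from the list";
* a **major-late-like** forward unit: three spliced mRNAs sharing one
  promoter and one leader exon, each ending at its own polyA site;
* two **reverse-strand** early units (one spliced, one not);
* optionally a separate 3 kb **host-E1 contig** with its own expressed
  ORF, emulating reads from the E1 region integrated in permissive
  producer cells.

UTR segments are scrubbed of AUG (or of its minus-strand complement)
so that every model's 5'-proximal ORF is exactly the ORF it was built
to encode; this is what makes exact oracle equivalence between
grouping output and the generator's ground truth meaningful.

Reads are drawn multinomially from an abundance profile. Two default
profiles define the study conditions:

* **nonpermissive** — transgene 0.86; aberrant 0.86·0.03/0.97 ≈ 0.027
  (i.e., an aberrant rate of 3% *among transgene-promoter transcripts*,
  so the expected spliced-per-100-unspliced is 100·0.03/0.97 ≈ 3.09,
  inside the 2.4–3.4% range such audits report); the remainder spread
  equally over the five backbone models; host-E1 zero.
* **permissive** — transgene 0.08, late units weighted 3× over reverse
  units within the remaining budget (late ≫ transgene rank order),
  host-E1 0.002.

Noise emulates dRNA artefacts: geometric 5' truncation (default mean
50 nt, capped so at least 30 nt survive), per-base substitutions /
insertions / deletions (defaults 3% / 1% / 2%), and a Poisson polyA
tail (mean 60 nt). Truncation applies to coordinates as well, so the
TSS window is genuinely exercised. The ground-truth SAM carries the
truncated exon chain with exact M/N CIGAR coordinates and the
uncorrupted sequence; base errors appear only in the FASTQ, which is
intended for an external spliced aligner (e.g.
`minimap2 -ax splice -uf -k14 genome.fasta reads.fastq`). This keeps
the repository testable offline without re-implementing alignment; it
also means the built-in tests exercise coordinate noise (truncation)
but not aligner-induced junction wobble, which is instead covered by a
synthetic jitter test of the snapping tolerance.

What the generator does **not** emulate: realistic nanopore quality
scores or signal-level behaviour, homopolymer-biased errors,
template-switching chimeras, alternative 3'-end heterogeneity beyond
the catalog sites, and host-transcriptome background (host-side mapped
counts are accepted as externally supplied numbers). Passing tests
therefore demonstrate the classification logic under controlled
conditions, not aligner robustness on real signal.

## Numerical choices

* All percentages go through one routine (`percent_of`): exact decimal
  division, round-half-up at the requested precision. Average read
  length is also rounded half-up to an integer.
* Deletions up to 30 nt in a CIGAR are absorbed into the exon block;
  larger deletions and every N op open a junction (aligner dialects
  differ on small-gap encoding).
* Only primary alignments are counted by default; supplementary
  alignments are dropped (logged), not stitched — conservative in the
  absence of a chimeric-read policy.
* One seed drives genome construction, the multinomial draw and all
  corruption; outputs are bytewise reproducible for a fixed config,
  and the run manifest records a config hash (output directory
  excluded) so identical analyses are provably identical.

## Problem sizes used in tests

Simulated experiments use 5,000 reads per run; the parameter-recovery
experiment averages 20 replicates (100,000 reads total); convergence
checks use up to 20,000 reads. At these sizes the transgene-percent
standard error per run is ≈ 0.5 points and the aberrant-ratio relative
standard error of the 20-replicate mean is ≈ 2%, comfortably inside
the ±2-point and 10%-relative acceptance bands.

## Known limitations

* The full published datasets require download and spliced alignment,
  which is out of desk scale here; the pipeline accepts any SAM/BAM
  from an external aligner via `classify`.
* ORF identity is decided purely by the first-AUG genomic position;
  leaky scanning, non-AUG initiation and uORFs are out of scope.
* The group key treats all TSS-unassigned reads of one splice/polyA
  signature as one group; distinct unannotated promoters on the same
  transcript backbone are separated only by the novel-end clustering
  report, not by the group table.
* The cluster-gap/min-count defaults (20 nt, 10 reads) and the
  tolerance defaults are field-plausible settings, all config-exposed;
  the audited publication-grade pipelines do not state theirs.
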