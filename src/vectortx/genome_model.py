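"""Annotated vector genome: sequence, feature catalog, mature mRNA, first-ORF translation.

The genome of an adenovirus-derived vaccine vector is a single linear
contig carrying a dense, bidirectional annotation: ORFs (backbone genes
plus the inserted transgene), transcription start sites (TSSs),
polyadenylation sites, splice donors/acceptors, and the bounds of the
transgene expression cassette.  All internal coordinates are 0-based
half-open; human-readable reports convert to 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

VALID_BASES = frozenset("ACGTN")

#: sentinel label for transcripts whose 5'-proximal ORF is not in the catalog
NONE_FROM_LIST = "None from the list"


class GenomeFormatError(ValueError):
    """Raised for malformed genome or catalog input files."""


class CatalogValidationError(ValueError):
    """Raised when a feature catalog violates its invariants."""


@dataclass(frozen=True)
class VectorGenome:
    """A single-contig vector genome (uppercase A/C/G/T/N)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise GenomeFormatError(
                f"non-nucleotide characters in genome {self.name!r}: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ExonChain:
    """Ordered genomic blocks of one (spliced) transcript or alignment.

    ``blocks`` are 0-based half-open intervals sorted ascending regardless
    of strand; transcription order on the minus strand runs from the last
    block to the first.
    """

    strand: str
    blocks: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.blocks:
            raise ValueError("exon chain needs at least one block")
        prev_end = None
        for s, e in self.blocks:
            if e - s < 1:
                raise ValueError(f"block [{s},{e}) shorter than 1 nt")
            if prev_end is not None and s < prev_end:
                raise ValueError("blocks overlap or are unsorted")
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the 5'-terminal base."""
        return self.blocks[0][0] if self.strand == "+" else self.blocks[-1][1] - 1

    @property
    def three_prime(self) -> int:
        """Genomic coordinate of the 3'-terminal base."""
        return self.blocks[-1][1] - 1 if self.strand == "+" else self.blocks[0][0]

    def introns(self) -> tuple[tuple[int, int], ...]:
        """Half-open gaps between consecutive blocks, ascending."""
        return tuple(
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
        )


class SiteFeature(NamedTuple):
    label: str
    position: int
    strand: str


@dataclass(frozen=True)
class OrfFeature:
    """An ORF anchored by its genomic start codon.

    ``start_codon_pos`` is the coordinate of the A of the ATG on the
    coding strand; ``stop_pos`` the last base of the stop codon in
    transcription direction (so stop_pos < start_codon_pos on '-').
    """

    label: str
    strand: str
    start_codon_pos: int
    stop_pos: int
    category_tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.strand == "+" and self.stop_pos <= self.start_codon_pos:
            raise CatalogValidationError(
                f"ORF {self.label!r}: stop must follow start on + strand"
            )
        if self.strand == "-" and self.stop_pos >= self.start_codon_pos:
            raise CatalogValidationError(
                f"ORF {self.label!r}: stop must precede start coordinate on - strand"
            )

    @property
    def genomic_interval(self) -> tuple[int, int]:
        """Half-open genomic footprint of the ORF, strand-independent."""
        lo = min(self.start_codon_pos, self.stop_pos)
        hi = max(self.start_codon_pos, self.stop_pos)
        return lo, hi + 1


@dataclass
class FeatureCatalog:
    """All annotated features of one vector genome."""

    orfs: list[OrfFeature]
    tss_sites: list[SiteFeature]
    polya_sites: list[SiteFeature]
    donors: list[tuple[int, str]]
    acceptors: list[tuple[int, str]]
    cassette: tuple[int, int]
    transgene_tss_label: str = ""

    def validate(self, genome_length: int) -> None:
        problems: list[str] = []
        for klass, labels in (
            ("orf", [o.label for o in self.orfs]),
            ("tss", [t.label for t in self.tss_sites]),
            ("polya", [p.label for p in self.polya_sites]),
        ):
            seen: set[str] = set()
            for lab in labels:
                if lab in seen:
                    problems.append(f"duplicate {klass} label {lab!r}")
                seen.add(lab)
        positions: list[tuple[str, int]] = []
        positions += [("orf-start", o.start_codon_pos) for o in self.orfs]
        positions += [("orf-stop", o.stop_pos) for o in self.orfs]
        positions += [("tss", t.position) for t in self.tss_sites]
        positions += [("polya", p.position) for p in self.polya_sites]
        positions += [("donor", p) for p, _ in self.donors]
        positions += [("acceptor", p) for p, _ in self.acceptors]
        for klass, pos in positions:
            if not 0 <= pos < genome_length:
                problems.append(f"{klass} position {pos} outside [0,{genome_length})")
        if not self.cassette[0] < self.cassette[1]:
            problems.append(f"cassette start {self.cassette[0]} !< end {self.cassette[1]}")
        if problems:
            raise CatalogValidationError("; ".join(problems))

    def transgene_orf(self) -> Optional[OrfFeature]:
        for orf in self.orfs:
            if "transgene" in orf.category_tags:
                return orf
        return None

    def orf_by_start(self, pos: int, strand: str) -> Optional[OrfFeature]:
        for orf in self.orfs:
            if orf.start_codon_pos == pos and orf.strand == strand:
                return orf
        return None


def load_genome(path: str | Path) -> VectorGenome:
    """Read the first record of a FASTA file as the vector genome."""
    records = SeqIO.parse(str(path), "fasta")
    try:
        rec = next(records)
    except StopIteration:
        raise GenomeFormatError(f"no FASTA records in {path}") from None
    seq = str(rec.seq).upper()
    if not seq:
        raise GenomeFormatError(f"empty sequence for record {rec.id!r} in {path}")
    return VectorGenome(name=rec.id, sequence=seq)


# bespoke 6-column catalog TSV: class  label  start  end  strand  tags
_CATALOG_CLASSES = {"orf", "tss", "polya", "donor", "acceptor", "cassette"}


def load_feature_catalog(path: str | Path, genome: VectorGenome) -> FeatureCatalog:
    """Load a feature catalog from the 6-column TSV schema.

    Columns: class (orf|tss|polya|donor|acceptor|cassette), label, start,
    end ('.' where not applicable), strand ('.' for cassette), tags
    (comma-separated, '.' for none).  '#' lines are comments.  For an
    'orf' row, start is the start-codon A and end the last stop-codon
    base, both in transcription direction.  A row with class 'tss' whose
    tags include 'transgene' names the transgene promoter.
    """
    orfs: list[OrfFeature] = []
    tss: list[SiteFeature] = []
    polya: list[SiteFeature] = []
    donors: list[tuple[int, str]] = []
    acceptors: list[tuple[int, str]] = []
    cassette: Optional[tuple[int, int]] = None
    transgene_tss = ""
    bad_rows: list[str] = []

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                bad_rows.append(f"line {lineno}: expected 6 columns, got {len(parts)}")
                continue
            klass, label, start_s, end_s, strand, tags_s = parts
            if klass not in _CATALOG_CLASSES:
                bad_rows.append(f"line {lineno}: unknown class {klass!r}")
                continue
            try:
                start = int(start_s)
                end = None if end_s == "." else int(end_s)
            except ValueError:
                bad_rows.append(f"line {lineno}: non-integer coordinate")
                continue
            tags = frozenset() if tags_s in (".", "") else frozenset(tags_s.split(","))
            try:
                if klass == "orf":
                    if end is None:
                        raise CatalogValidationError("orf row needs an end coordinate")
                    orfs.append(OrfFeature(label, strand, start, end, tags))
                elif klass == "tss":
                    tss.append(SiteFeature(label, start, strand))
                    if "transgene" in tags:
                        transgene_tss = label
                elif klass == "polya":
                    polya.append(SiteFeature(label, start, strand))
                elif klass == "donor":
                    donors.append((start, strand))
                elif klass == "acceptor":
                    acceptors.append((start, strand))
                elif klass == "cassette":
                    if end is None:
                        raise CatalogValidationError("cassette row needs an end")
                    cassette = (start, end)
            except CatalogValidationError as exc:
                bad_rows.append(f"line {lineno}: {exc}")

    if cassette is None:
        bad_rows.append("missing 'cassette' row")
    if bad_rows:
        raise CatalogValidationError("; ".join(bad_rows))
    assert cassette is not None
    catalog = FeatureCatalog(
        orfs=orfs, tss_sites=tss, polya_sites=polya, donors=donors,
        acceptors=acceptors, cassette=cassette, transgene_tss_label=transgene_tss,
    )
    catalog.validate(genome.length)
    return catalog


def load_feature_catalog_gff3(path: str | Path, genome: VectorGenome) -> FeatureCatalog:
    """Map a GFF3 annotation onto the catalog types.

    Recognized GFF3 types: CDS -> orf (start codon from strand);
    TSS/transcription_start_site -> tss; polyA_site -> polya;
    five_prime_cis_splice_site -> donor; three_prime_cis_splice_site ->
    acceptor; region with Name=cassette -> cassette bounds.  Tags come
    from a free-form ``tags`` attribute.
    """
    orfs: list[OrfFeature] = []
    tss: list[SiteFeature] = []
    polya: list[SiteFeature] = []
    donors: list[tuple[int, str]] = []
    acceptors: list[tuple[int, str]] = []
    cassette: Optional[tuple[int, int]] = None
    transgene_tss = ""

    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise GenomeFormatError(f"malformed GFF3 line: {line!r}")
            _, _, ftype, start_s, end_s, _, strand, _, attrs_s = cols
            start1, end1 = int(start_s), int(end_s)  # GFF3 is 1-based inclusive
            start, end = start1 - 1, end1
            attrs = dict(
                kv.split("=", 1) for kv in attrs_s.split(";") if "=" in kv
            )
            label = attrs.get("Name", attrs.get("ID", f"{ftype}:{start}"))
            tags = frozenset(attrs["tags"].split(",")) if "tags" in attrs else frozenset()
            if ftype == "CDS":
                if strand == "+":
                    orfs.append(OrfFeature(label, "+", start, end - 1, tags))
                else:
                    orfs.append(OrfFeature(label, "-", end - 1, start, tags))
            elif ftype in ("TSS", "transcription_start_site"):
                tss.append(SiteFeature(label, start, strand))
                if "transgene" in tags:
                    transgene_tss = label
            elif ftype == "polyA_site":
                polya.append(SiteFeature(label, start, strand))
            elif ftype == "five_prime_cis_splice_site":
                donors.append((start, strand))
            elif ftype == "three_prime_cis_splice_site":
                acceptors.append((start, strand))
            elif ftype == "region" and label == "cassette":
                cassette = (start, end)

    if cassette is None:
        raise CatalogValidationError("GFF3 lacks a region feature named 'cassette'")
    catalog = FeatureCatalog(
        orfs=orfs, tss_sites=tss, polya_sites=polya, donors=donors,
        acceptors=acceptors, cassette=cassette, transgene_tss_label=transgene_tss,
    )
    catalog.validate(genome.length)
    return catalog


def spliced_sequence(genome: VectorGenome, chain: ExonChain) -> str:
    """Mature-mRNA sequence (sense strand) for an exon chain.

    Blocks are concatenated in ascending genomic order and the result is
    reverse-complemented for minus-strand transcripts, so the returned
    string always reads 5'->3' on the transcript.
    """
    lo, hi = chain.span
    if lo < 0 or hi > genome.length:
        raise ValueError(f"chain [{lo},{hi}) exceeds genome [0,{genome.length})")
    seq = "".join(genome.sequence[s:e] for s, e in chain.blocks)
    if chain.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


class FirstOrf(NamedTuple):
    peptide: str
    start_offset: int  # nt offset of the A of the first AUG; -1 if no AUG
    stop_found: bool


def translate_first_orf(mrna: str) -> FirstOrf:
    """Scan a mature mRNA 5'->3' for the first AUG and translate it.

    Translation uses the standard genetic code and runs to the first stop
    codon or to the end of the transcript (``stop_found`` False).  With no
    AUG at all the result is ``("", -1, False)``.
    """
    if not mrna:
        raise ValueError("empty mRNA")
    start = mrna.find("ATG")
    if start == -1:
        return FirstOrf("", -1, False)
    coding = mrna[start:]
    coding = coding[: len(coding) - len(coding) % 3]
    aa = str(Seq(coding).translate())
    stop_idx = aa.find("*")
    if stop_idx == -1:
        return FirstOrf(aa, start, False)
    return FirstOrf(aa[:stop_idx], start, True)


def mrna_offset_to_genomic(chain: ExonChain, offset: int) -> int:
    """Map an offset on the mature mRNA back to its genomic coordinate."""
    if offset < 0 or offset >= chain.length:
        raise ValueError(f"offset {offset} outside mRNA of length {chain.length}")
    blocks = chain.blocks if chain.strand == "+" else chain.blocks[::-1]
    remaining = offset
    for s, e in blocks:
        blen = e - s
        if remaining < blen:
            return s + remaining if chain.strand == "+" else e - 1 - remaining
        remaining -= blen
    raise AssertionError("unreachable")
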