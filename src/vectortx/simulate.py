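"""Synthetic direct-RNA data for an adenovirus-vector-like toy genome.

The generator builds a small annotated vector genome that reproduces, in
miniature, the transcriptional architecture the pipeline is designed to
audit: an intronless transgene expression cassette in the deleted-E1
locus under its own strong promoter, a major-late-like forward unit
whose spliced mRNAs share a common leader exon, reverse-strand early
units, and one rare aberrant transcript from the transgene promoter
whose cryptic splice removes the transgene start codon.  Reads are
sampled from a configurable abundance profile and corrupted with the
characteristic direct-RNA artefacts: geometric 5' truncation (molecules
thread through the pore 3'-first, so 3' ends stay intact), base errors,
and a polyA tail.

Every read is paired with a ground-truth SAM record that encodes the
true (truncated) exon chain with M/N CIGAR operations and the
uncorrupted sequence, so the coordinate path of the pipeline can be
exercised offline without an external aligner; the noisy FASTQ is meant
for an external spliced aligner such as minimap2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .genome_model import (
    ExonChain,
    FeatureCatalog,
    NONE_FROM_LIST,
    OrfFeature,
    SiteFeature,
    VectorGenome,
    spliced_sequence,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# codons free of A and T: cannot create ATG or a stop in any frame
_GC_CODONS = ["GCC", "GGC", "CGC", "CCG", "GCG", "CGG", "GGG", "CCC"]

# canonical adenovirus late/early gene names for toy ORF labels
_LATE_LABELS = ["52/55K (L1)", "Hexon (L3)", "Fibre (L5)", "100K (L4)", "pV (L2)"]
_REVERSE_LABELS = ["E4 orf3", "DBP (E2A)", "E4 orf2", "IVa2"]


@dataclass(frozen=True)
class TranscriptModel:
    """One ground-truth transcript species of the simulation."""

    model_id: str
    chain: ExonChain
    tss_label: str
    polya_label: str
    encodes_orf: str
    contig: str
    aberrant: bool = False


@dataclass(frozen=True)
class AbundanceProfile:
    """Expected per-model read fractions (sum to 1)."""

    fractions: dict[str, float]
    profile_name: str = "custom"

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("fractions must be non-negative")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")


@dataclass(frozen=True)
class NoiseModel:
    """Read-corruption parameters for direct-RNA emulation.

    ``truncation_mean`` is the mean of the geometric 5' loss in nt;
    rates are per-base probabilities; ``polya_len_mean`` the Poisson
    mean of the appended tail.
    """

    truncation_mean: float = 50.0
    sub_rate: float = 0.03
    ins_rate: float = 0.01
    del_rate: float = 0.02
    polya_len_mean: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            r = getattr(self, name)
            if not 0 <= r < 1:
                raise ValueError(f"{name}={r} outside [0,1)")
        if self.truncation_mean < 0:
            raise ValueError("truncation_mean must be >= 0")


NOISELESS = NoiseModel(truncation_mean=0, sub_rate=0, ins_rate=0, del_rate=0,
                       polya_len_mean=0, seed=0)


@dataclass(frozen=True)
class ToyParams:
    """Layout parameters of the toy vector genome."""

    genome_length: int = 35_000
    n_late_orfs: int = 3
    n_reverse_units: int = 2
    transgene_codons: int = 400
    late_codons: int = 299
    include_host_e1: bool = True


@dataclass
class ToyVector:
    """Toy genome bundle: sequence, catalog, transcript models, host contig."""

    genome: VectorGenome
    catalog: FeatureCatalog
    models: list[TranscriptModel]
    host_contig: Optional[VectorGenome] = None


class SimulationError(ValueError):
    pass


def _scrub(seq: bytearray, lo: int, hi: int, trigram: bytes) -> None:
    """Destroy every occurrence of ``trigram`` in seq[lo:hi] in place."""
    while True:
        idx = seq.find(trigram, lo, hi)
        if idx == -1:
            return
        seq[idx + 1] = ord("C")


def _plant_orf_fwd(seq: bytearray, start: int, n_codons: int,
                   rng: np.random.Generator) -> int:
    """Write ATG + A/T-free interior + TAA from ``start``; return stop_pos."""
    codons = [_GC_CODONS[i] for i in rng.integers(0, len(_GC_CODONS), n_codons - 1)]
    orf = "ATG" + "".join(codons) + "TAA"
    seq[start:start + len(orf)] = orf.encode()
    return start + len(orf) - 1


def _plant_orf_rev(seq: bytearray, start: int, n_codons: int,
                   rng: np.random.Generator) -> int:
    """Plant a minus-strand ORF whose start-codon A sits at ``start``."""
    codons = [_GC_CODONS[i] for i in rng.integers(0, len(_GC_CODONS), n_codons - 1)]
    orf = "ATG" + "".join(codons) + "TAA"
    rc = str(Seq(orf).reverse_complement())
    lo = start - len(orf) + 1
    seq[lo:start + 1] = rc.encode()
    return lo  # stop_pos: last stop-codon base in transcription direction


def build_toy_genome(params: ToyParams | None = None, seed: int = 0) -> ToyVector:
    """Construct the deterministic toy vector genome and its transcript models.

    Layout (plus strand left to right): transgene cassette near the left
    end (deleted-E1 position), a shared-leader late unit in the middle,
    and reverse-strand units near the right end, mirroring the
    bidirectional organisation of adenovirus genomes.
    """
    p = params or ToyParams()
    if p.n_late_orfs < 1:
        raise SimulationError("need at least one forward late ORF")
    if p.n_reverse_units < 1:
        raise SimulationError("need at least one reverse-strand unit")
    if p.n_late_orfs > len(_LATE_LABELS) or p.n_reverse_units > len(_REVERSE_LABELS):
        raise SimulationError("too many units for the toy label sets")

    L = p.genome_length
    rng = np.random.default_rng(seed)
    seq = bytearray(_BASES[rng.integers(0, 4, L)].tobytes())

    orfs: list[OrfFeature] = []
    tss: list[SiteFeature] = []
    polya: list[SiteFeature] = []
    donors: list[tuple[int, str]] = []
    acceptors: list[tuple[int, str]] = []
    models: list[TranscriptModel] = []

    # --- transgene cassette (intronless ORF under its own promoter) ---
    tg_tss, tg_start = 700, 1200
    tg_stop = _plant_orf_fwd(seq, tg_start, p.transgene_codons, rng)
    tg_polya = tg_stop + 198
    if tg_polya >= L:
        raise SimulationError("transgene ORF exceeds genome")
    # internal out-of-frame ATG: the first AUG of the aberrant mRNA
    internal_atg = tg_start + 454
    seq[internal_atg:internal_atg + 3] = b"ATG"
    _scrub(seq, tg_tss, tg_start, b"ATG")          # 5'UTR
    ab_donor, ab_acceptor = tg_tss + 450, tg_start + 400
    seq[ab_donor - 2:ab_donor] = b"CC"             # no AUG across the splice
    tss.append(SiteFeature("CMV", tg_tss, "+"))
    polya.append(SiteFeature("TG-pA", tg_polya, "+"))
    orfs.append(OrfFeature("transgene", "+", tg_start, tg_stop,
                           frozenset({"transgene"})))
    cassette = (tg_tss - 100, tg_polya + 100)
    models.append(TranscriptModel(
        "transgene", ExonChain("+", ((tg_tss, tg_polya + 1),)),
        "CMV", "TG-pA", "transgene", contig="toy_vector"))
    # cryptic splice from the 5'UTR into the ORF: removes the start codon
    models.append(TranscriptModel(
        "aberrant-TG",
        ExonChain("+", ((tg_tss, ab_donor), (ab_acceptor, tg_polya + 1))),
        "CMV", "TG-pA", NONE_FROM_LIST, contig="toy_vector", aberrant=True))

    # --- major-late-like forward unit: shared leader, one ORF per mRNA ---
    mlp_tss, leader_end = 6000, 6200
    _scrub(seq, mlp_tss, leader_end, b"ATG")
    seq[leader_end - 2:leader_end] = b"CC"
    tss.append(SiteFeature("MLP", mlp_tss, "+"))
    donors.append((leader_end, "+"))
    fwd_end = leader_end
    for i in range(p.n_late_orfs):
        acc = 9800 + 5000 * i
        start = acc + 200
        stop = _plant_orf_fwd(seq, start, p.late_codons, rng)
        pa = stop + 298
        if pa >= L:
            raise SimulationError("late ORFs exceed genome length")
        _scrub(seq, acc, start, b"ATG")
        seq[acc:acc + 2] = b"CC"
        label = _LATE_LABELS[i]
        acceptors.append((acc, "+"))
        polya.append(SiteFeature(f"L{i + 1}-pA", pa, "+"))
        orfs.append(OrfFeature(label, "+", start, stop, frozenset({"late"})))
        models.append(TranscriptModel(
            f"late-{i + 1}", ExonChain("+", ((mlp_tss, leader_end), (acc, pa + 1))),
            "MLP", f"L{i + 1}-pA", label, contig="toy_vector"))
        fwd_end = pa

    # --- reverse-strand units (right to left) ---
    # spliced E4-like unit anchored at the right genome end
    r_tss = L - 500
    hi_block = (L - 2000, r_tss + 1)
    r_donor, r_acceptor = L - 2000, L - 3000
    lo_block_start = L - 5000
    r_orf_start = r_acceptor - 200
    r_stop = _plant_orf_rev(seq, r_orf_start, 199, rng)
    _scrub(seq, r_orf_start + 1, r_acceptor + 1, b"CAT")
    _scrub(seq, hi_block[0], hi_block[1], b"CAT")
    seq[r_donor:r_donor + 2] = b"GG"
    tss.append(SiteFeature("E4", r_tss, "-"))
    donors.append((r_donor, "-"))
    acceptors.append((r_acceptor, "-"))
    polya.append(SiteFeature("E4-pA", lo_block_start, "-"))
    orfs.append(OrfFeature(_REVERSE_LABELS[0], "-", r_orf_start, r_stop,
                           frozenset({"early"})))
    models.append(TranscriptModel(
        "rev-1", ExonChain("-", ((lo_block_start, r_acceptor), hi_block)),
        "E4", "E4-pA", _REVERSE_LABELS[0], contig="toy_vector"))
    rev_low = lo_block_start
    if lo_block_start <= fwd_end + 100:
        raise SimulationError("reverse units collide with forward units")

    # unspliced E2-like units stacked leftwards
    for j in range(1, p.n_reverse_units):
        u_tss = rev_low - 600 - 1700 * (j - 1)
        u_pa = u_tss - 1400
        u_start = u_tss - 500
        u_stop = _plant_orf_rev(seq, u_start, 150, rng)
        _scrub(seq, u_start + 1, u_tss + 1, b"CAT")
        label = _REVERSE_LABELS[j]
        tss.append(SiteFeature(f"E2-{j}", u_tss, "-"))
        polya.append(SiteFeature(f"E2-{j}-pA", u_pa, "-"))
        orfs.append(OrfFeature(label, "-", u_start, u_stop, frozenset({"early"})))
        models.append(TranscriptModel(
            f"rev-{j + 1}", ExonChain("-", ((u_pa, u_tss + 1),)),
            f"E2-{j}", f"E2-{j}-pA", label, contig="toy_vector"))
        if u_pa <= fwd_end + 100:
            raise SimulationError("reverse units collide with forward units")

    genome = VectorGenome("toy_vector", seq.decode())
    catalog = FeatureCatalog(
        orfs=orfs, tss_sites=tss, polya_sites=polya, donors=donors,
        acceptors=acceptors, cassette=cassette, transgene_tss_label="CMV")
    catalog.validate(genome.length)

    host = None
    if p.include_host_e1:
        hrng = np.random.default_rng(seed + 1)
        hseq = bytearray(_BASES[hrng.integers(0, 4, 3000)].tobytes())
        _plant_orf_fwd(hseq, 500, 299, hrng)
        _scrub(hseq, 400, 500, b"ATG")
        host = VectorGenome("host_E1", hseq.decode())
        models.append(TranscriptModel(
            "host-E1", ExonChain("+", ((400, 1700),)),
            "hostE1-TSS", "hostE1-pA", "E1-host", contig="host_E1"))
    return ToyVector(genome, catalog, models, host)


def nonpermissive_profile(models: Sequence[TranscriptModel],
                          transgene_fraction: float = 0.86,
                          aberrant_rate: float = 0.03) -> AbundanceProfile:
    """Transgene-dominated profile of E1-noncomplementing cells.

    ``aberrant_rate`` is the aberrant share *among transgene-promoter
    transcripts*, so the expected spliced-per-100-unspliced statistic is
    100*a/(1-a).  Backbone models share the small remainder equally; a
    host-E1 model gets zero (no integrated E1 in these cells).
    """
    ab_frac = transgene_fraction * aberrant_rate / (1 - aberrant_rate)
    backbone = [m for m in models
                if m.contig != "host_E1" and not m.aberrant
                and m.encodes_orf != "transgene"]
    rest = 1.0 - transgene_fraction - ab_frac
    fr = {m.model_id: 0.0 for m in models}
    for m in models:
        if m.aberrant:
            fr[m.model_id] = ab_frac
        elif m.encodes_orf == "transgene":
            fr[m.model_id] = transgene_fraction
        elif m in backbone:
            fr[m.model_id] = rest / len(backbone)
    # absorb float dust into the transgene fraction
    fr[next(m.model_id for m in models if m.encodes_orf == "transgene")] += \
        1.0 - sum(fr.values())
    return AbundanceProfile(fr, "nonpermissive")


def permissive_profile(models: Sequence[TranscriptModel],
                       transgene_fraction: float = 0.08,
                       aberrant_rate: float = 0.03,
                       host_e1_fraction: float = 0.002) -> AbundanceProfile:
    """Full-repertoire profile of E1-complementing cells: late >> transgene."""
    ab_frac = transgene_fraction * aberrant_rate / (1 - aberrant_rate)
    fr = {m.model_id: 0.0 for m in models}
    has_host = any(m.contig == "host_E1" for m in models)
    budget = 1.0 - transgene_fraction - ab_frac - (host_e1_fraction if has_host else 0)
    weights = {m.model_id: (3.0 if m.model_id.startswith("late") else 1.0)
               for m in models
               if m.contig != "host_E1" and not m.aberrant
               and m.encodes_orf != "transgene"}
    wtot = sum(weights.values())
    for m in models:
        if m.contig == "host_E1":
            fr[m.model_id] = host_e1_fraction
        elif m.aberrant:
            fr[m.model_id] = ab_frac
        elif m.encodes_orf == "transgene":
            fr[m.model_id] = transgene_fraction
        else:
            fr[m.model_id] = budget * weights[m.model_id] / wtot
    first_late = next(m.model_id for m in models if m.model_id.startswith("late"))
    fr[first_late] += 1.0 - sum(fr.values())
    return AbundanceProfile(fr, "permissive")


@dataclass
class ReadSet:
    """Output bundle of one simulation: reads, truth alignments, truth table."""

    fastq_records: list[SeqRecord]
    sam_header: dict
    sam_records: list[pysam.AlignedSegment]
    ground_truth: pd.DataFrame

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            SeqIO.write(self.fastq_records, fh, "fastq")

    def write_sam(self, path: str | Path) -> None:
        with pysam.AlignmentFile(str(path), "wh",
                                 header=pysam.AlignmentHeader.from_dict(self.sam_header)) as fh:
            for rec in self.sam_records:
                fh.write(rec)

    def write_ground_truth(self, path: str | Path) -> None:
        self.ground_truth.to_csv(path, sep="\t", index=False)


def _truncate_chain(chain: ExonChain, k: int) -> ExonChain:
    """Remove k nt from the 5' end of an exon chain (genomic coordinates)."""
    if k <= 0:
        return chain
    if chain.strand == "+":
        blocks = list(chain.blocks)
        out = []
        for s, e in blocks:
            if k >= e - s:
                k -= e - s
                continue
            out.append((s + k, e))
            k = 0
        return ExonChain("+", tuple(out))
    out = []
    for s, e in reversed(chain.blocks):
        if k >= e - s:
            k -= e - s
            continue
        out.append((s, e - k))
        k = 0
    return ExonChain("-", tuple(reversed(out)))


_BYTE_TO_IDX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BYTE_TO_IDX[_b] = _i


def _corrupt(seq: str, noise: NoiseModel, rng: np.random.Generator) -> tuple[str, int]:
    """Apply substitutions, insertions and deletions; return (seq, n_errors)."""
    if noise.sub_rate == noise.ins_rate == noise.del_rate == 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    L = len(arr)
    sub = rng.random(L) < noise.sub_rate
    if sub.any():
        idx = _BYTE_TO_IDX[arr[sub]]
        arr[sub] = _BASES[(idx + rng.integers(1, 4, sub.sum())) % 4]
    keep = rng.random(L) >= noise.del_rate
    kept = arr[keep]
    ins = rng.random(len(kept)) < noise.ins_rate
    n_ins = int(ins.sum())
    if n_ins:
        pos = np.arange(len(kept)) + np.cumsum(ins) - ins
        out = np.empty(len(kept) + n_ins, dtype=np.uint8)
        out[pos] = kept
        out[pos[ins] + 1] = _BASES[rng.integers(0, 4, n_ins)]
    else:
        out = kept
    n_err = int(sub.sum()) + int(L - keep.sum()) + n_ins
    return out.tobytes().decode(), n_err


def _chain_to_cigar(chain: ExonChain) -> list[tuple[int, int]]:
    ops = []
    for i, (s, e) in enumerate(chain.blocks):
        if i:
            ops.append((3, s - chain.blocks[i - 1][1]))  # N
        ops.append((0, e - s))  # M
    return ops


def sample_reads(genome: VectorGenome,
                 models: Sequence[TranscriptModel],
                 profile: AbundanceProfile,
                 n: int,
                 noise: NoiseModel,
                 host_contig: Optional[VectorGenome] = None) -> ReadSet:
    """Draw ``n`` reads multinomially from the profile and corrupt them.

    FASTQ records carry the noisy sequence plus polyA tail with constant
    quality; the ground-truth SAM records the truncated exon chain with
    exact coordinates (M/N CIGAR) and the uncorrupted, tail-free
    sequence.
    """
    if n < 0:
        raise SimulationError("n must be >= 0")
    missing = [m.model_id for m in models if m.model_id not in profile.fractions]
    if missing:
        raise SimulationError(f"profile missing fractions for {missing}")

    contigs = {genome.name: genome}
    if host_contig is not None:
        contigs[host_contig.name] = host_contig
    for m in models:
        if m.contig not in contigs:
            raise SimulationError(f"model {m.model_id} on unknown contig {m.contig}")

    rng = np.random.default_rng(noise.seed)
    p = np.array([profile.fractions[m.model_id] for m in models])
    counts = rng.multinomial(n, p) if n else np.zeros(len(models), dtype=int)

    mrnas = {m.model_id: spliced_sequence(contigs[m.contig], m.chain) for m in models}

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c.name, "LN": c.length} for c in contigs.values()],
    }
    pysam_header = pysam.AlignmentHeader.from_dict(header)
    tids = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}

    fastq: list[SeqRecord] = []
    sam: list[pysam.AlignedSegment] = []
    truth_rows: list[tuple[str, str, int, int]] = []
    ridx = 0
    for m, cnt in zip(models, counts):
        mrna = mrnas[m.model_id]
        max_trunc = max(0, len(mrna) - 30)
        for _ in range(cnt):
            rid = f"r{ridx:06d}"
            ridx += 1
            if noise.truncation_mean > 0:
                k = int(rng.geometric(1.0 / (noise.truncation_mean + 1.0))) - 1
                k = min(k, max_trunc)
            else:
                k = 0
            seq_t = mrna[k:]
            noisy, n_err = _corrupt(seq_t, noise, rng)
            tail = int(rng.poisson(noise.polya_len_mean)) if noise.polya_len_mean > 0 else 0
            read_seq = noisy + "A" * tail
            rec = SeqRecord(Seq(read_seq), id=rid, description="")
            rec.letter_annotations["phred_quality"] = [20] * len(read_seq)
            fastq.append(rec)

            tchain = _truncate_chain(m.chain, k)
            seg = pysam.AlignedSegment(pysam_header)
            seg.query_name = rid
            seg.reference_id = tids[m.contig]
            seg.reference_start = tchain.blocks[0][0]
            seg.flag = 16 if m.chain.strand == "-" else 0
            seg.mapping_quality = 60
            seg.cigartuples = _chain_to_cigar(tchain)
            qseq = seq_t if m.chain.strand == "+" else str(Seq(seq_t).reverse_complement())
            seg.query_sequence = qseq
            sam.append(seg)
            truth_rows.append((rid, m.model_id, k, n_err))

    truth = pd.DataFrame(truth_rows,
                         columns=["read_id", "model_id", "truncated_nt", "n_errors"])
    return ReadSet(fastq, header, sam, truth)
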