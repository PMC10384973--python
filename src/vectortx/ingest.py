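"""Decode spliced long-read alignments into exon chains; read accounting.

The CIGAR of a spliced alignment is reduced to an exon chain: M/=/X
extend the current block, N always opens a new block, small deletions
(default <= 30 nt, an aligner-dialect threshold) are absorbed into the
block while larger ones are treated as junctions, and S/H/I consume
only the read.  Host-transcriptome mapping is accepted as an external
count; only vector-side alignments are decoded here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pysam

from .genome_model import ExonChain

logger = logging.getLogger(__name__)

DEFAULT_MAX_ABSORBED_DELETION = 30


@dataclass(frozen=True)
class AlignedRead:
    """One read's strand and ordered genomic blocks on one contig."""

    read_id: str
    chain: ExonChain
    read_length: int
    is_primary: bool
    contig: str

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError(f"read {self.read_id!r}: read_length must be > 0")


@dataclass(frozen=True)
class AccountingRow:
    """One sample's read-accounting summary (host counts supplied externally)."""

    sample: str
    total_reads: int
    longest_read: int
    average_read_length: int
    mapped_host: int
    mapped_vaccine: int
    mapped_e1: Optional[int]
    vaccine_pct_of_host: Optional[float]


def percent_of(numerator: int, denominator: int, decimals: int) -> float:
    """100*numerator/denominator, rounded half-up to ``decimals`` places."""
    if denominator <= 0:
        raise ValueError(f"denominator must be > 0, got {denominator}")
    q = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


# CIGAR op codes: M=0 I=1 D=2 N=3 S=4 H=5 P=6 ==7 X=8
_REF_BLOCK_OPS = {0, 7, 8}


def _cigar_to_blocks(pos: int, cigartuples: Sequence[tuple[int, int]],
                     max_absorbed_del: int) -> tuple[tuple[int, int], ...]:
    blocks: list[tuple[int, int]] = []
    cur_start, cur = pos, pos
    for op, length in cigartuples:
        if op in _REF_BLOCK_OPS:
            cur += length
        elif op == 2:  # D
            if length <= max_absorbed_del:
                cur += length
            else:
                if cur > cur_start:
                    blocks.append((cur_start, cur))
                cur += length
                cur_start = cur
        elif op == 3:  # N
            if cur > cur_start:
                blocks.append((cur_start, cur))
            cur += length
            cur_start = cur
        elif op in (1, 4, 5, 6):  # I, S, H, P: no reference advance
            continue
        else:
            raise ValueError(f"unsupported CIGAR op code {op}")
    if cur > cur_start:
        blocks.append((cur_start, cur))
    if not blocks:
        raise ValueError("alignment consumes no reference bases")
    return tuple(blocks)


def parse_spliced_alignments(
    path: str | Path,
    max_absorbed_deletion: int = DEFAULT_MAX_ABSORBED_DELETION,
) -> list[AlignedRead]:
    """Decode primary/secondary mapped records of a SAM/BAM into AlignedReads.

    Unmapped records are excluded; malformed records are logged and
    skipped rather than aborting the run.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    reads: list[AlignedRead] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            try:
                blocks = _cigar_to_blocks(rec.reference_start, rec.cigartuples or [],
                                          max_absorbed_deletion)
                chain = ExonChain("-" if rec.is_reverse else "+", blocks)
                rlen = rec.infer_read_length() or rec.query_length
                reads.append(AlignedRead(
                    read_id=rec.query_name,
                    chain=chain,
                    read_length=int(rlen),
                    is_primary=not (rec.is_secondary or rec.is_supplementary),
                    contig=rec.reference_name,
                ))
            except (ValueError, TypeError) as exc:
                skipped += 1
                logger.warning("skipping record %s: %s", rec.query_name, exc)
    if skipped:
        logger.warning("skipped %d malformed alignment records", skipped)
    return reads


def filter_alignments(reads: Iterable[AlignedRead],
                      min_read_length: int = 0,
                      primary_only: bool = True) -> list[AlignedRead]:
    """Drop secondary/supplementary and short reads; order is preserved."""
    out, n_secondary, n_short = [], 0, 0
    for r in reads:
        if primary_only and not r.is_primary:
            n_secondary += 1
            continue
        if r.read_length < min_read_length:
            n_short += 1
            continue
        out.append(r)
    if n_secondary or n_short:
        logger.info("filtered %d non-primary and %d short reads", n_secondary, n_short)
    if not out:
        logger.warning("no reads remain after filtering")
    return out


def _round_half_up(x: float) -> int:
    return int(Decimal(x).quantize(Decimal(1), rounding=ROUND_HALF_UP))


def read_accounting(read_lengths: Sequence[int],
                    mapped_host: int,
                    vaccine_reads: Sequence[AlignedRead],
                    e1_reads: Optional[int] = None,
                    sample: str = "sample") -> AccountingRow:
    """Dataset summary: totals, longest/average length, vaccine % of host."""
    if mapped_host < 0:
        raise ValueError("mapped_host must be >= 0")
    total = len(read_lengths)
    longest = max(read_lengths) if read_lengths else 0
    average = _round_half_up(sum(read_lengths) / total) if total else 0
    mapped_vaccine = len(vaccine_reads)
    pct = percent_of(mapped_vaccine, mapped_host, 1) if mapped_host > 0 else None
    if mapped_host == 0 and mapped_vaccine:
        logger.warning("mapped_host is 0; vaccine %% of host reported as missing")
    return AccountingRow(sample, total, longest, average, mapped_host,
                         mapped_vaccine, e1_reads, pct)


def write_accounting_tsv(rows: Sequence[AccountingRow], path: str | Path) -> None:
    cols = ["sample", "total_reads", "longest_read", "average_read_length",
            "mapped_host", "mapped_vaccine", "mapped_e1", "vaccine_pct_of_host"]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            vals = [r.sample, r.total_reads, r.longest_read, r.average_read_length,
                    r.mapped_host, r.mapped_vaccine,
                    "." if r.mapped_e1 is None else r.mapped_e1,
                    "." if r.vaccine_pct_of_host is None else r.vaccine_pct_of_host]
            fh.write("\t".join(str(v) for v in vals) + "\n")
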