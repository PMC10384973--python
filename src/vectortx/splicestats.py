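"""Transgene-cassette splice audit and the E1/RCA transcript screen.

The central safety question for an intronless transgene cassette is how
often transcripts from its promoter carry *any* splice junction (the
cassette was designed without one, so every junction there is
unintended), and whether any transcript encodes an E1 protein, which
would indicate replication-competent adenovirus (RCA) contamination.
The headline statistic follows the convention of expressing spliced
transcripts per 100 unspliced transcripts from the same promoter; a
spliced-over-total variant is available via ``denominator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .genome_model import FeatureCatalog
from .grouping import Junction, TranscriptGroup
from .ingest import percent_of
from .orfcall import CATEGORY_CATALOG, OrfCall

VERDICT_NEGATIVE = "no E1 transcripts detected"
VERDICT_POSITIVE = "E1 transcripts present"


@dataclass
class PromoterSpliceStat:
    promoter: str
    unspliced_count: int
    spliced_count: int
    pct_spliced_vs_unspliced: Optional[float]
    junctions_in_orf: list[Junction] = field(default_factory=list)


@dataclass(frozen=True)
class RcaScreenResult:
    e1_orf_read_count: int
    e1_contig_read_count: int
    verdict: str


def transgene_splice_stats(groups: Sequence[TranscriptGroup],
                           catalog: FeatureCatalog,
                           denominator: str = "unspliced") -> PromoterSpliceStat:
    """Audit splicing among transcripts assigned to the transgene promoter.

    Counts are read counts (group counts summed).  With
    ``denominator="unspliced"`` the percentage is spliced per 100
    unspliced; with ``"total"`` it is spliced per 100 transcripts from
    the promoter.  Junctions with either end inside the transgene ORF
    are listed — those are the ones that disrupt the immunogen.
    """
    if denominator not in ("unspliced", "total"):
        raise ValueError("denominator must be 'unspliced' or 'total'")
    promoter = catalog.transgene_tss_label
    tg_groups = [g for g in groups if g.tss == promoter]
    unspliced = sum(g.count for g in tg_groups if not g.is_spliced)
    spliced = sum(g.count for g in tg_groups if g.is_spliced)

    orf = catalog.transgene_orf()
    in_orf: list[Junction] = []
    if orf is not None:
        lo, hi = orf.genomic_interval
        for g in tg_groups:
            for j in g.junctions:
                if lo <= j.donor < hi or lo <= j.acceptor < hi:
                    in_orf.append(j)

    denom = unspliced if denominator == "unspliced" else unspliced + spliced
    pct = percent_of(spliced, denom, 1) if denom > 0 else None
    return PromoterSpliceStat(promoter, unspliced, spliced, pct, in_orf)


def screen_e1(calls: Sequence[OrfCall], groups: Sequence[TranscriptGroup],
              catalog: FeatureCatalog, e1_contig_count: int = 0,
              threshold: int = 0) -> RcaScreenResult:
    """Count vector reads whose ORF call carries the E1 tag.

    ``e1_contig_count`` passes through reads mapped to a separate
    host-integrated E1 contig (expected in E1-complementing cells); it
    does not affect the vector verdict.  Any vector E1 count above
    ``threshold`` (default 0: safety-screen semantics) is positive.
    """
    e1_labels = {o.label for o in catalog.orfs if "E1" in o.category_tags}
    counts_by_group = {g.group_id: g.count for g in groups}
    n = sum(
        counts_by_group.get(c.group_id, 0)
        for c in calls
        if c.category == CATEGORY_CATALOG and c.orf_label in e1_labels
    )
    verdict = VERDICT_POSITIVE if n > threshold else VERDICT_NEGATIVE
    return RcaScreenResult(n, e1_contig_count, verdict)


def write_splice_audit_tsv(stat: PromoterSpliceStat, groups, path) -> None:
    """One row per distinct transgene-promoter junction, 1-based coords."""
    from collections import Counter

    promoter = stat.promoter
    jcounts: Counter = Counter()
    for g in groups:
        if g.tss != promoter:
            continue
        for j in g.junctions:
            jcounts[j] += g.count
    in_orf = set(stat.junctions_in_orf)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# promoter\t{promoter}\n")
        fh.write(f"# unspliced_reads\t{stat.unspliced_count}\n")
        fh.write(f"# spliced_reads\t{stat.spliced_count}\n")
        pct = "." if stat.pct_spliced_vs_unspliced is None else stat.pct_spliced_vs_unspliced
        fh.write(f"# pct_spliced_vs_unspliced\t{pct}\n")
        fh.write("donor\tacceptor\tcount\tinside_orf\n")
        for j, cnt in sorted(jcounts.items()):
            fh.write(f"{j.donor + 1}\t{j.acceptor + 1}\t{cnt}\t"
                     f"{'yes' if j in in_orf else 'no'}\n")
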