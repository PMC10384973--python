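"""5'-proximal ORF assignment per transcript group; per-ORF gene tables.

The identity of the protein a transcript "codes for" is decided the way
a scanning ribosome would: build the mature mRNA of the group's
representative chain (anchored at the assigned catalog TSS so that 5'
truncation cannot shift the scan start), find the first AUG, and map it
back to genomic coordinates.  If the AUG coincides exactly with a
catalog ORF start codon the group counts toward that ORF; otherwise it
is a "None from the list" transcript and its translated peptide is
reported.  No fuzzy or near-cognate matching is attempted.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .genome_model import (
    FeatureCatalog,
    NONE_FROM_LIST,
    VectorGenome,
    mrna_offset_to_genomic,
    spliced_sequence,
    translate_first_orf,
)
from .grouping import TranscriptGroup
from .ingest import percent_of

CATEGORY_CATALOG = "catalog"
CATEGORY_NONE_FROM_LIST = "none_from_list"
CATEGORY_NO_ORF = "no_orf"


@dataclass(frozen=True)
class OrfCall:
    group_id: str
    category: str
    orf_label: Optional[str] = None
    peptide: str = ""
    start_offset: int = -1       # nt offset of the AUG in the mature mRNA


def assign_orf(group: TranscriptGroup, genome: VectorGenome,
               catalog: FeatureCatalog) -> OrfCall:
    """Call the 5'-proximal ORF of one transcript group."""
    mrna = spliced_sequence(genome, group.representative_chain)
    first = translate_first_orf(mrna)
    if first.start_offset == -1:
        return OrfCall(group.group_id, CATEGORY_NO_ORF)
    genomic_start = mrna_offset_to_genomic(group.representative_chain,
                                           first.start_offset)
    hit = catalog.orf_by_start(genomic_start, group.strand)
    if hit is not None:
        return OrfCall(group.group_id, CATEGORY_CATALOG, orf_label=hit.label,
                       start_offset=first.start_offset)
    return OrfCall(group.group_id, CATEGORY_NONE_FROM_LIST,
                   peptide=first.peptide, start_offset=first.start_offset)


@dataclass
class GeneTable:
    """Per-ORF transcription table: (feature, count, percent of total)."""

    rows: pd.DataFrame          # columns: feature, count, percent
    total_reads: int

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# total_reads\t{self.total_reads}\n")
            self.rows.to_csv(fh, sep="\t", index=False)

    def percent(self, feature: str) -> Optional[float]:
        hit = self.rows.loc[self.rows["feature"] == feature, "percent"]
        return None if hit.empty else float(hit.iloc[0])


def gene_table(calls: Sequence[OrfCall], groups: Sequence[TranscriptGroup],
               total: int, decimals: int = 2) -> GeneTable:
    """Aggregate group counts per called ORF label.

    ``total`` is the declared denominator (classified reads); it is
    recorded in the table metadata rather than inferred, because the
    denominator choice is part of the reporting contract.
    """
    if total <= 0:
        raise ValueError("total must be > 0")
    counts_by_group = {g.group_id: g.count for g in groups}
    agg: dict[str, int] = defaultdict(int)
    for call in calls:
        if call.category == CATEGORY_CATALOG:
            assert call.orf_label is not None
            agg[call.orf_label] += counts_by_group[call.group_id]
        elif call.category == CATEGORY_NONE_FROM_LIST:
            agg[NONE_FROM_LIST] += counts_by_group[call.group_id]
        # no_orf groups contribute no row
    rows = sorted(agg.items(), key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame(
        [(label, cnt, percent_of(cnt, total, decimals)) for label, cnt in rows],
        columns=["feature", "count", "percent"],
    )
    return GeneTable(rows=df, total_reads=total)
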