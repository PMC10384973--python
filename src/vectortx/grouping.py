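"""Canonicalize reads against the feature catalog and collapse into groups.

A transcript group is the unit of quantification: all reads sharing a
strand, a TSS assignment, a snapped splice-junction chain and a polyA
assignment.  TSS assignment tolerates the 5' truncation characteristic
of direct-RNA reads by accepting any catalog TSS *upstream* of the
observed 5' end within a window; junction ends snap independently to
the nearest catalog donor/acceptor so that a half-annotated junction is
still flagged novel; 3' ends match polyA sites within a symmetric
tolerance (direct-RNA 3' ends are intact, so the window is small).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

from .genome_model import ExonChain, FeatureCatalog
from .ingest import AlignedRead


@dataclass(frozen=True)
class GroupingParams:
    junction_tol: int = 10
    tss_window: int = 100
    polya_tol: int = 30
    cluster_gap: int = 20
    min_cluster_count: int = 10

    def __post_init__(self) -> None:
        for name in ("junction_tol", "tss_window", "polya_tol", "cluster_gap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class Junction(NamedTuple):
    donor: int
    acceptor: int
    strand: str
    is_novel: bool


class EndAssignment(NamedTuple):
    label: str
    offset: int


@dataclass
class TranscriptGroup:
    group_id: str
    strand: str
    tss: Optional[str]            # catalog label, or None when unassigned
    junctions: tuple[Junction, ...]
    polya: Optional[str]
    count: int
    representative_chain: ExonChain

    @property
    def has_novel_junction(self) -> bool:
        return any(j.is_novel for j in self.junctions)

    @property
    def is_spliced(self) -> bool:
        return bool(self.junctions)


@dataclass(frozen=True)
class NovelEndCluster:
    cluster_id: str
    position: int        # modal end position
    strand: str
    count: int
    kind: str            # "promoter-candidate" | "polya-candidate"


def _nearest(sites: Sequence[int], pos: int, tol: int) -> Optional[int]:
    """Nearest site within +/-tol; equidistant ties go to the lower coordinate."""
    best: Optional[int] = None
    best_d = tol + 1
    for s in sorted(sites):
        d = abs(s - pos)
        if d < best_d:
            best, best_d = s, d
    return best


def chain_junctions(chain: ExonChain) -> list[tuple[int, int]]:
    """(donor, acceptor) boundary coordinates of each intron, in
    transcription order.  Boundaries are half-open block edges: on '+'
    the donor is the first intronic base and the acceptor the first
    exonic base after the intron; on '-' the roles of the two edges swap.
    """
    introns = chain.introns()
    if chain.strand == "+":
        return [(d, a) for d, a in introns]
    return [(a, d) for d, a in reversed(introns)]


def snap_junctions(chain: ExonChain, catalog: FeatureCatalog,
                   tol: int) -> list[Junction]:
    """Snap each observed junction end to the nearest catalog site within tol.

    Each end snaps independently; a junction either of whose ends has no
    catalog match keeps its observed coordinates and is flagged novel.
    Snapping is idempotent: an already-snapped junction re-snaps to itself.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    donors = [p for p, s in catalog.donors if s == chain.strand]
    acceptors = [p for p, s in catalog.acceptors if s == chain.strand]
    out: list[Junction] = []
    for donor, acceptor in chain_junctions(chain):
        sd = _nearest(donors, donor, tol)
        sa = _nearest(acceptors, acceptor, tol)
        if sd is None or sa is None:
            out.append(Junction(donor, acceptor, chain.strand, True))
        else:
            out.append(Junction(sd, sa, chain.strand, False))
    return out


def assign_tss(chain: ExonChain, catalog: FeatureCatalog,
               window: int) -> Optional[EndAssignment]:
    """Assign the observed 5' end to a catalog TSS at or upstream of it.

    Only upstream candidates are considered because direct-RNA reads are
    5'-truncated, never 5'-extended; the downstream offset is recorded.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    obs = chain.five_prime
    best: Optional[EndAssignment] = None
    for site in sorted(catalog.tss_sites, key=lambda t: t.position):
        if site.strand != chain.strand:
            continue
        offset = obs - site.position if chain.strand == "+" else site.position - obs
        if 0 <= offset <= window and (best is None or offset < best.offset):
            best = EndAssignment(site.label, offset)
    return best


def assign_polya(chain: ExonChain, catalog: FeatureCatalog,
                 tol: int) -> Optional[EndAssignment]:
    """Match the observed 3' end to the nearest catalog polyA site within tol."""
    if tol < 0:
        raise ValueError("tol must be >= 0")
    obs = chain.three_prime
    best: Optional[EndAssignment] = None
    best_d = tol + 1
    for site in sorted(catalog.polya_sites, key=lambda p: p.position):
        if site.strand != chain.strand:
            continue
        d = abs(site.position - obs)
        if d < best_d:
            best = EndAssignment(site.label, site.position - obs)
            best_d = d
    return best


def _canonical_chain(chain: ExonChain, junctions: Sequence[Junction],
                     tss_pos: Optional[int], polya_pos: Optional[int]) -> ExonChain:
    """Rebuild a chain with snapped junction edges and catalog-anchored ends."""
    five = chain.five_prime if tss_pos is None else tss_pos
    three = chain.three_prime if polya_pos is None else polya_pos
    if chain.strand == "+":
        edges = [(j.donor, j.acceptor) for j in junctions]
        bounds = [five] + [c for e in edges for c in e] + [three + 1]
    else:
        edges = [(j.acceptor, j.donor) for j in reversed(junctions)]
        bounds = [three] + [c for e in edges for c in e] + [five + 1]
    blocks = tuple((bounds[i], bounds[i + 1]) for i in range(0, len(bounds), 2))
    return ExonChain(chain.strand, blocks)


def group_transcripts(
    reads: Sequence[AlignedRead],
    catalog: FeatureCatalog,
    params: GroupingParams | None = None,
) -> tuple[list[TranscriptGroup], int]:
    """Collapse reads into transcript groups keyed by their signature.

    The key is (strand, TSS assignment, snapped junction chain, polyA
    assignment).  Reads with no junctions that fail both end assignments
    are counted as unclassified.  Groups come back sorted by descending
    count (group id as the deterministic tie-break).
    """
    p = params or GroupingParams()
    tss_pos = {t.label: t.position for t in catalog.tss_sites}
    pa_pos = {t.label: t.position for t in catalog.polya_sites}

    buckets: dict[tuple, list[tuple[AlignedRead, list[Junction]]]] = defaultdict(list)
    unclassified = 0
    for read in reads:
        chain = read.chain
        juncs = snap_junctions(chain, catalog, p.junction_tol)
        tss = assign_tss(chain, catalog, p.tss_window)
        polya = assign_polya(chain, catalog, p.polya_tol)
        if tss is None and polya is None and not juncs:
            unclassified += 1
            continue
        key = (
            chain.strand,
            tss.label if tss else None,
            tuple((j.donor, j.acceptor, j.is_novel) for j in juncs),
            polya.label if polya else None,
        )
        buckets[key].append((read, juncs))

    groups: list[TranscriptGroup] = []
    for key, members in buckets.items():
        strand, tss_label, _, polya_label = key
        # longest member spans the most complete observed structure
        rep_read, rep_juncs = max(
            members, key=lambda rj: (rj[0].chain.length, rj[0].read_id))
        try:
            rep = _canonical_chain(
                rep_read.chain, rep_juncs,
                tss_pos.get(tss_label) if tss_label else None,
                pa_pos.get(polya_label) if polya_label else None,
            )
        except ValueError:
            # anchoring would produce a degenerate block; keep the observed chain
            rep = rep_read.chain
        groups.append(TranscriptGroup(
            group_id="", strand=strand, tss=tss_label,
            junctions=tuple(rep_juncs), polya=polya_label,
            count=len(members), representative_chain=rep,
        ))
    groups.sort(key=lambda g: (-g.count, g.strand, g.tss or "", g.polya or "",
                               g.representative_chain.blocks))
    for i, g in enumerate(groups, 1):
        g.group_id = f"TG{i:04d}"
    return groups, unclassified


def cluster_novel_ends(reads: Sequence[AlignedRead],
                       gap: int,
                       min_cluster_count: int,
                       kind: str = "promoter-candidate") -> list[NovelEndCluster]:
    """Single-linkage clustering of unassigned transcript ends.

    ``reads`` should already be restricted to those whose relevant end
    had no catalog assignment.  Ends (5' for promoter candidates, 3' for
    polyA candidates) closer than ``gap`` on the same strand join one
    cluster; clusters below ``min_cluster_count`` are dropped; the modal
    position is reported (lower coordinate on ties).
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    by_strand: dict[str, list[int]] = defaultdict(list)
    for r in reads:
        pos = r.chain.five_prime if kind == "promoter-candidate" else r.chain.three_prime
        by_strand[r.chain.strand].append(pos)

    clusters: list[NovelEndCluster] = []
    for strand in sorted(by_strand):
        ends = sorted(by_strand[strand])
        run: list[int] = []
        for pos in ends + [None]:  # type: ignore[list-item]
            if run and (pos is None or pos - run[-1] > gap):
                if len(run) >= min_cluster_count:
                    mode = min(Counter(run).most_common(),
                               key=lambda kv: (-kv[1], kv[0]))[0]
                    clusters.append(NovelEndCluster(
                        cluster_id="", position=mode, strand=strand,
                        count=len(run), kind=kind))
                run = []
            if pos is not None:
                run.append(pos)
    clusters.sort(key=lambda c: (-c.count, c.position))
    return [
        NovelEndCluster(f"NC{i:03d}", c.position, c.strand, c.count, c.kind)
        for i, c in enumerate(clusters, 1)
    ]


def write_group_tsv(groups: Sequence[TranscriptGroup], path) -> None:
    """Group table with 1-based junction coordinates for human readers."""
    cols = ["group_id", "strand", "tss", "junctions", "polya", "count",
            "novel_junction"]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for g in groups:
            jtxt = ",".join(f"{j.donor + 1}-{j.acceptor + 1}" for j in g.junctions)
            fh.write("\t".join([
                g.group_id, g.strand, g.tss or "novel", jtxt or ".",
                g.polya or "novel", str(g.count),
                "yes" if g.has_novel_junction else "no",
            ]) + "\n")
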