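"""Junction snapping, end assignment, transcript grouping, end clustering."""

import dataclasses
import random

import pytest

import vectortx as vx
from vectortx.genome_model import ExonChain, FeatureCatalog, SiteFeature
from vectortx.grouping import (
    GroupingParams,
    assign_polya,
    assign_tss,
    cluster_novel_ends,
    group_transcripts,
    snap_junctions,
)
from vectortx.ingest import AlignedRead


@pytest.fixture()
def flat_catalog():
    return FeatureCatalog(
        orfs=[],
        tss_sites=[SiteFeature("T1", 1000, "+"), SiteFeature("T2", 8000, "+")],
        polya_sites=[SiteFeature("P1", 7000, "+")],
        donors=[(4998, "+")],
        acceptors=[(7003, "+")],
        cassette=(0, 10),
    )


def test_snap_within_tolerance(flat_catalog):
    chain = ExonChain("+", ((1000, 5000), (7000, 7100)))
    (j,) = snap_junctions(chain, flat_catalog, tol=10)
    assert (j.donor, j.acceptor, j.is_novel) == (4998, 7003, False)


def test_snap_far_end_is_novel(flat_catalog):
    chain = ExonChain("+", ((1000, 5000), (7043, 7100)))  # acceptor 40 nt off
    (j,) = snap_junctions(chain, flat_catalog, tol=10)
    assert j.is_novel and (j.donor, j.acceptor) == (5000, 7043)


def test_snap_single_block_no_junctions(flat_catalog):
    assert snap_junctions(ExonChain("+", ((0, 100),)), flat_catalog, 10) == []


def test_snap_idempotent(flat_catalog):
    chain = ExonChain("+", ((1000, 5000), (7000, 7100)))
    once = snap_junctions(chain, flat_catalog, 10)
    snapped_chain = ExonChain("+", ((1000, once[0].donor), (once[0].acceptor, 7100)))
    assert snap_junctions(snapped_chain, flat_catalog, 10) == once


def test_assign_tss_examples(flat_catalog):
    assert assign_tss(ExonChain("+", ((1030, 2000),)), flat_catalog, 100) == ("T1", 30)
    assert assign_tss(ExonChain("+", ((1000, 2000),)), flat_catalog, 100) == ("T1", 0)
    assert assign_tss(ExonChain("+", ((1500, 2000),)), flat_catalog, 100) is None
    # upstream-only: a read starting before the TSS cannot be assigned to it
    assert assign_tss(ExonChain("+", ((990, 2000),)), flat_catalog, 100) is None


def test_assign_tss_minus_strand():
    cat = FeatureCatalog([], [SiteFeature("T", 5000, "-")], [], [], [], (0, 1))
    assert assign_tss(ExonChain("-", ((3000, 4981),)), cat, 100) == ("T", 20)


def test_assign_polya_examples(flat_catalog):
    assert assign_polya(ExonChain("+", ((6000, 6996),)), flat_catalog, 30) == ("P1", 5)
    assert assign_polya(ExonChain("+", ((6000, 7101),)), flat_catalog, 30) is None
    assert assign_polya(ExonChain("+", ((6000, 7001),)), flat_catalog, 0) == ("P1", 0)


def _read(i, chain):
    return AlignedRead(f"r{i}", chain, chain.length, True, "vec")


def test_identical_reads_form_one_group(flat_catalog):
    chain = ExonChain("+", ((1000, 5000), (7000, 7001)))
    groups, uncl = group_transcripts([_read(i, chain) for i in range(3)], flat_catalog)
    assert uncl == 0
    assert len(groups) == 1 and groups[0].count == 3


def test_truncated_reads_share_group(flat_catalog):
    full = ExonChain("+", ((1000, 5000), (7000, 7001)))
    trunc = ExonChain("+", ((1060, 5000), (7000, 7001)))
    groups, _ = group_transcripts([_read(0, full), _read(1, trunc)], flat_catalog)
    assert len(groups) == 1 and groups[0].count == 2
    # representative chain re-anchors at the catalog TSS
    assert groups[0].representative_chain.blocks[0][0] == 1000


def test_unclassifiable_read_counted(flat_catalog):
    # single block, 5' far from any TSS, 3' far from any polyA
    stray = ExonChain("+", ((3000, 3500),))
    groups, uncl = group_transcripts([_read(0, stray)], flat_catalog)
    assert groups == [] and uncl == 1


def test_conservation_classified_plus_unclassified(noise_free_run):
    groups = noise_free_run["groups"]
    total = sum(g.count for g in groups) + noise_free_run["unclassified"]
    assert total == len(noise_free_run["vector_reads"])


def test_noise_free_groups_equal_ground_truth(toy, noise_free_run):
    """Oracle equivalence: grouping reproduces the generator's aggregation."""
    truth = noise_free_run["readset"].ground_truth
    expected = truth[truth.model_id != "host-E1"].model_id.value_counts().to_dict()
    by_sig = {}
    for m in toy.models:
        if m.contig != toy.genome.name:
            continue
        by_sig[(m.chain.strand, m.tss_label, m.polya_label, m.chain.blocks)] = m.model_id
    got = {}
    for g in noise_free_run["groups"]:
        sig = (g.strand, g.tss, g.polya, g.representative_chain.blocks)
        assert sig in by_sig, f"group {g.group_id} matches no generating model"
        got[by_sig[sig]] = g.count
    assert got == expected


def test_tolerance_monotonicity(toy):
    """Wider junction tolerance can only merge groups, never split them."""
    rng = random.Random(0)
    reads = []
    i = 0
    for m in toy.models:
        if m.contig != toy.genome.name or len(m.chain.blocks) < 2:
            continue
        for _ in range(30):
            blocks = tuple(
                (s + rng.randint(-15, 15), e + rng.randint(-15, 15))
                for s, e in m.chain.blocks)
            reads.append(_read(i, ExonChain(m.chain.strand, blocks)))
            i += 1
    counts = []
    for tol in (0, 5, 10, 20, 40):
        groups, _ = group_transcripts(reads, toy.catalog,
                                      GroupingParams(junction_tol=tol))
        counts.append(len(groups))
    assert counts == sorted(counts, reverse=True)


def test_cluster_novel_ends_examples():
    def reads_at(positions):
        return [_read(i, ExonChain("+", ((p, p + 500),)))
                for i, p in enumerate(positions)]

    (c,) = cluster_novel_ends(reads_at([1000, 1003, 1008]), gap=10, min_cluster_count=3)
    assert (c.position, c.count, c.kind) == (1000, 3, "promoter-candidate")

    two = cluster_novel_ends(reads_at([1000, 2000]), gap=10, min_cluster_count=1)
    assert len(two) == 2

    assert cluster_novel_ends(reads_at([1000, 1001, 1002]), 10, 5) == []


def test_cluster_modal_position():
    reads = [_read(i, ExonChain("+", ((p, p + 100),)))
             for i, p in enumerate([50, 52, 52, 52, 60])]
    (c,) = cluster_novel_ends(reads, gap=10, min_cluster_count=2)
    assert c.position == 52 and c.count == 5
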