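"""Simulator determinism, noise behaviour, and profile conservation."""

import dataclasses
import io

import numpy as np
import pytest

import vectortx as vx
from vectortx.simulate import SimulationError, ToyParams, _truncate_chain
from vectortx.genome_model import ExonChain, spliced_sequence


def test_build_toy_genome_deterministic():
    a = vx.build_toy_genome(seed=1)
    b = vx.build_toy_genome(seed=1)
    assert a.genome.sequence == b.genome.sequence
    assert a.catalog == b.catalog
    assert a.models == b.models


def test_toy_genome_structure(toy):
    ids = {m.model_id for m in toy.models}
    assert "transgene" in ids
    spliced_fwd = [m for m in toy.models
                   if m.chain.strand == "+" and len(m.chain.blocks) > 1
                   and not m.aberrant]
    assert len(spliced_fwd) >= 3
    assert len({m.tss_label for m in spliced_fwd}) == 1  # shared late promoter
    assert sum(m.chain.strand == "-" for m in toy.models) >= 2
    assert any(m.aberrant for m in toy.models)
    assert toy.host_contig is not None


def test_transgene_model_is_intronless_with_leader(toy):
    tg = next(m for m in toy.models if m.encodes_orf == "transgene")
    assert len(tg.chain.blocks) == 1
    mrna = spliced_sequence(toy.genome, tg.chain)
    first = vx.translate_first_orf(mrna)
    assert first.start_offset == 500  # 5' leader precedes the transgene AUG
    assert "ATG" not in mrna[:500]


def test_aberrant_splice_removes_transgene_start(toy):
    ab = next(m for m in toy.models if m.aberrant)
    tg_orf = toy.catalog.transgene_orf()
    donor_gap = ab.chain.introns()[0]
    # the intron swallows the start codon: donor before it, acceptor inside the ORF
    assert donor_gap[0] < tg_orf.start_codon_pos < donor_gap[1]


def test_infeasible_params_rejected():
    with pytest.raises(SimulationError):
        vx.build_toy_genome(ToyParams(n_late_orfs=0))
    with pytest.raises(SimulationError):
        vx.build_toy_genome(ToyParams(genome_length=12_000))


def test_profiles_sum_to_one(toy):
    for prof in (vx.nonpermissive_profile(toy.models),
                 vx.permissive_profile(toy.models)):
        assert abs(sum(prof.fractions.values()) - 1) < 1e-9
        assert set(prof.fractions) == {m.model_id for m in toy.models}


def test_profile_rejects_bad_fractions():
    with pytest.raises(ValueError):
        vx.AbundanceProfile({"a": 0.5, "b": 0.6})
    with pytest.raises(ValueError):
        vx.AbundanceProfile({"a": -0.1, "b": 1.1})


def _readset(toy, n, noise):
    profile = vx.nonpermissive_profile(toy.models)
    return vx.sample_reads(toy.genome, toy.models, profile, n, noise,
                           host_contig=toy.host_contig)


def test_sample_reads_empty(toy):
    rs = _readset(toy, 0, vx.NOISELESS)
    assert rs.fastq_records == [] and rs.sam_records == []
    assert len(rs.ground_truth) == 0


def test_noiseless_reads_equal_model_mrna_plus_tail(toy):
    noise = dataclasses.replace(vx.NOISELESS, polya_len_mean=40.0, seed=2)
    rs = _readset(toy, 200, noise)
    mrnas = {}
    for m in toy.models:
        g = toy.genome if m.contig == toy.genome.name else toy.host_contig
        mrnas[m.model_id] = spliced_sequence(g, m.chain)
    truth = rs.ground_truth.set_index("read_id")
    for rec in rs.fastq_records:
        mrna = mrnas[truth.loc[rec.id, "model_id"]]
        s = str(rec.seq)
        assert s.startswith(mrna)
        assert set(s[len(mrna):]) <= {"A"}  # pure polyA tail


def test_truncation_mean_recovered(toy):
    noise = dataclasses.replace(vx.NOISELESS, truncation_mean=50.0, seed=3)
    rs = _readset(toy, 10_000, noise)
    mean = rs.ground_truth["truncated_nt"].mean()
    assert abs(mean - 50) / 50 < 0.05


def test_multinomial_conservation_and_convergence(toy):
    profile = vx.nonpermissive_profile(toy.models)
    n = 20_000
    rs = _readset(toy, n, dataclasses.replace(vx.NOISELESS, seed=7))
    counts = rs.ground_truth["model_id"].value_counts()
    assert counts.sum() == n
    for mid, p in profile.fractions.items():
        obs = counts.get(mid, 0) / n
        assert abs(obs - p) <= 3 * np.sqrt(p * (1 - p) / n) + 1e-12


def test_outputs_bytewise_reproducible(toy, tmp_path):
    noise = vx.NoiseModel(seed=9)
    out = []
    for tag in ("a", "b"):
        rs = _readset(toy, 300, noise)
        fq, sam = tmp_path / f"{tag}.fastq", tmp_path / f"{tag}.sam"
        rs.write_fastq(fq)
        rs.write_sam(sam)
        out.append((fq.read_bytes(), sam.read_bytes()))
    assert out[0] == out[1]


def test_profile_must_cover_all_models(toy):
    profile = vx.AbundanceProfile({"transgene": 1.0})
    with pytest.raises(SimulationError, match="missing"):
        vx.sample_reads(toy.genome, toy.models, profile, 10, vx.NOISELESS,
                        host_contig=toy.host_contig)


def test_truncate_chain_spans_blocks():
    chain = ExonChain("+", ((0, 10), (20, 30)))
    assert _truncate_chain(chain, 15).blocks == ((25, 30),)
    rev = ExonChain("-", ((0, 10), (20, 30)))
    assert _truncate_chain(rev, 15).blocks == ((0, 5),)
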