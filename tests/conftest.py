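import dataclasses

import pytest

import vectortx as vx


@pytest.fixture(scope="session")
def toy():
    """Deterministic toy vector genome shared across the suite."""
    return vx.build_toy_genome(seed=11)


@pytest.fixture(scope="session")
def noise_free_run(toy, tmp_path_factory):
    """5,000 noise-free reads written to SAM, parsed back, and grouped."""
    noise = dataclasses.replace(vx.NOISELESS, seed=5)
    profile = vx.nonpermissive_profile(toy.models)
    readset = vx.sample_reads(toy.genome, toy.models, profile, 5000, noise,
                              host_contig=toy.host_contig)
    sam = tmp_path_factory.mktemp("nf") / "truth.sam"
    readset.write_sam(sam)
    reads = vx.parse_spliced_alignments(sam)
    vector_reads = [r for r in reads if r.contig == toy.genome.name]
    groups, unclassified = vx.group_transcripts(vector_reads, toy.catalog)
    calls = [vx.assign_orf(g, toy.genome, toy.catalog) for g in groups]
    return {
        "readset": readset,
        "reads": reads,
        "vector_reads": vector_reads,
        "groups": groups,
        "unclassified": unclassified,
        "calls": calls,
    }


@pytest.fixture()
def tiny_genome():
    """Hand-built 500 nt genome with two plus-strand ORFs for splice tests.

    ORF A: ATG at 100, 5 glycine codons, TAA ending at 120.
    ORF B: ATG at 300, 5 glycine codons, TAA ending at 320.
    Background is all C so the first AUG is unambiguous.
    """
    seq = ["C"] * 500
    for start in (100, 300):
        orf = "ATG" + "GGT" * 5 + "TAA"
        seq[start:start + len(orf)] = list(orf)
    genome = vx.VectorGenome("tiny", "".join(seq))
    catalog = vx.FeatureCatalog(
        orfs=[
            vx.OrfFeature("orfA", "+", 100, 120),
            vx.OrfFeature("orfB", "+", 300, 320),
        ],
        tss_sites=[vx.genome_model.SiteFeature("T1", 50, "+")],
        polya_sites=[vx.genome_model.SiteFeature("P1", 400, "+")],
        donors=[(90, "+")],
        acceptors=[(250, "+")],
        cassette=(50, 401),
        transgene_tss_label="T1",
    )
    catalog.validate(genome.length)
    return genome, catalog
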