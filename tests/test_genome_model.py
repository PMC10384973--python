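"""Genome I/O, catalog validation, mature-mRNA extraction, first-ORF scan."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from vectortx.genome_model import (
    CatalogValidationError,
    ExonChain,
    GenomeFormatError,
    VectorGenome,
    load_feature_catalog,
    load_genome,
    mrna_offset_to_genomic,
    spliced_sequence,
    translate_first_orf,
)


# ---------- FASTA loading ----------

def test_load_genome_single_record(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">vec desc\n" + "ACGT" * 25 + "\n")
    g = load_genome(p)
    assert g.name == "vec"
    assert g.length == 100


def test_load_genome_uppercases(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">x\nacgt\n")
    assert load_genome(p).sequence == "ACGT"


def test_load_genome_rejects_empty_and_bad_alphabet(tmp_path):
    empty = tmp_path / "e.fa"
    empty.write_text("")
    with pytest.raises(GenomeFormatError):
        load_genome(empty)
    bad = tmp_path / "b.fa"
    bad.write_text(">x\nACGU\n")
    with pytest.raises(GenomeFormatError):
        load_genome(bad)


# ---------- catalog TSV ----------

CATALOG_HEADER = "# class\tlabel\tstart\tend\tstrand\ttags\n"


def _write_catalog(tmp_path, rows):
    p = tmp_path / "cat.tsv"
    p.write_text(CATALOG_HEADER + "".join(r + "\n" for r in rows))
    return p


def test_catalog_three_orfs(tmp_path):
    g = VectorGenome("v", "A" * 1000)
    p = _write_catalog(tmp_path, [
        "orf\tA\t10\t40\t+\t.",
        "orf\tB\t100\t160\t+\tlate",
        "orf\tC\t300\t250\t-\tearly",
        "tss\tT1\t5\t.\t+\ttransgene",
        "polya\tP1\t500\t.\t+\t.",
        "cassette\tcass\t0\t600\t.\t.",
    ])
    cat = load_feature_catalog(p, g)
    assert len(cat.orfs) == 3
    assert cat.transgene_tss_label == "T1"
    assert cat.cassette == (0, 600)


def test_catalog_out_of_range_position(tmp_path):
    g = VectorGenome("v", "A" * 100)
    p = _write_catalog(tmp_path, [
        "tss\tT1\t100\t.\t+\t.",   # == genome length: out of range
        "cassette\tcass\t0\t50\t.\t.",
    ])
    with pytest.raises(CatalogValidationError, match="outside"):
        load_feature_catalog(p, g)


def test_catalog_duplicate_label(tmp_path):
    g = VectorGenome("v", "A" * 1000)
    p = _write_catalog(tmp_path, [
        "orf\tFibre (L5)\t10\t40\t+\t.",
        "orf\tFibre (L5)\t100\t160\t+\t.",
        "cassette\tcass\t0\t600\t.\t.",
    ])
    with pytest.raises(CatalogValidationError, match="duplicate"):
        load_feature_catalog(p, g)


def test_catalog_missing_cassette(tmp_path):
    g = VectorGenome("v", "A" * 1000)
    p = _write_catalog(tmp_path, ["orf\tA\t10\t40\t+\t."])
    with pytest.raises(CatalogValidationError, match="cassette"):
        load_feature_catalog(p, g)


# ---------- spliced_sequence ----------

def test_spliced_sequence_examples():
    g = VectorGenome("v", "ATGCCCAAATTT")
    assert spliced_sequence(g, ExonChain("+", ((0, 6),))) == "ATGCCC"
    assert spliced_sequence(g, ExonChain("+", ((0, 3), (6, 9)))) == "ATGAAA"
    assert spliced_sequence(g, ExonChain("-", ((0, 3),))) == "CAT"


def test_spliced_sequence_out_of_range():
    g = VectorGenome("v", "ACGT")
    with pytest.raises(ValueError):
        spliced_sequence(g, ExonChain("+", ((0, 10),)))


def test_exon_chain_rejects_overlap_and_empty_block():
    with pytest.raises(ValueError):
        ExonChain("+", ((0, 10), (5, 20)))
    with pytest.raises(ValueError):
        ExonChain("+", ((3, 3),))


@settings(deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 400), min_size=2, max_size=8, unique=True),
       st.sampled_from(["+", "-"]))
def test_spliced_length_equals_block_sum(bounds, strand):
    bounds = sorted(bounds)
    blocks = tuple((bounds[i], bounds[i + 1]) for i in range(0, len(bounds) - 1, 2))
    if not blocks:
        return
    chain = ExonChain(strand, blocks)
    g = VectorGenome("v", "ACGT" * 100)
    assert len(spliced_sequence(g, chain)) == sum(e - s for s, e in blocks)


def test_minus_strand_is_reverse_complement_of_plus():
    g = VectorGenome("v", "ATGCCCAAATTTGGG")
    blocks = ((1, 5), (8, 13))
    fwd = spliced_sequence(g, ExonChain("+", blocks))
    rev = spliced_sequence(g, ExonChain("-", blocks))
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    assert rev == "".join(comp[b] for b in reversed(fwd))


# ---------- translate_first_orf ----------

# independent oracle: standard-code lookup built from the canonical 64-mer
_B = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_CODE = {a + b + c: _AA[16 * i + 4 * j + k]
         for i, a in enumerate(_B) for j, b in enumerate(_B) for k, c in enumerate(_B)}


def _oracle_first_orf(mrna):
    start = mrna.find("ATG")
    if start == -1:
        return "", -1, False
    pep = []
    for i in range(start, len(mrna) - 2, 3):
        aa = _CODE[mrna[i:i + 3]]
        if aa == "*":
            return "".join(pep), start, True
        pep.append(aa)
    return "".join(pep), start, False


@pytest.mark.parametrize("mrna,expected", [
    ("AAATGGCCTAA", ("MA", 2, True)),
    ("CCCCCC", ("", -1, False)),
    ("ATGAAA", ("MK", 0, False)),
])
def test_translate_first_orf_examples(mrna, expected):
    assert tuple(translate_first_orf(mrna)) == expected


def test_translate_first_orf_empty_input():
    with pytest.raises(ValueError):
        translate_first_orf("")


def test_translate_first_orf_matches_bruteforce_oracle():
    rng = random.Random(42)
    for _ in range(1000):
        mrna = "".join(rng.choice("ACGT") for _ in range(60))
        assert tuple(translate_first_orf(mrna)) == _oracle_first_orf(mrna)


def test_mrna_offset_roundtrip_minus_strand():
    chain = ExonChain("-", ((10, 20), (30, 40)))
    # 5' end of a minus chain is the last base of the last block
    assert mrna_offset_to_genomic(chain, 0) == 39
    assert mrna_offset_to_genomic(chain, 10) == 19
    with pytest.raises(ValueError):
        mrna_offset_to_genomic(chain, 20)
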