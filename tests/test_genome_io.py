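"""I/O round trips, sequence normalisation and coordinate conventions."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from igtscan import (
    Compartment,
    GeneModel,
    Genome,
    read_fasta,
    read_gene_table,
    read_segments_bed,
    write_fasta,
    write_gene_table,
    write_segments_bed,
)
from igtscan.genome_io import normalize_sequence, reverse_complement

dna = st.text(alphabet="ACGTN", min_size=1, max_size=200)


def test_read_fasta_normalises_and_counts_ambiguous(tmp_path):
    p = tmp_path / "x.fa"
    p.write_text(">x\nacgt\n>y\nACGRU\n")
    genomes = read_fasta(p)
    assert [g.record_id for g in genomes] == ["x", "y"]
    assert genomes[0].sequence == "ACGT" and genomes[0].length_bp == 4
    # R -> N (counted), U -> T (not counted)
    assert genomes[1].sequence == "ACGNT"
    assert genomes[1].n_ambiguous == 1


def test_read_fasta_errors(tmp_path):
    empty = tmp_path / "empty.fa"
    empty.write_text("")
    with pytest.raises(ValueError, match="empty"):
        read_fasta(empty)
    dup = tmp_path / "dup.fa"
    dup.write_text(">a\nACGT\n>a\nTTTT\n")
    with pytest.raises(ValueError, match="a"):
        read_fasta(dup)


@given(seqs=st.lists(dna, min_size=1, max_size=5))
def test_fasta_round_trip(tmp_path_factory, seqs):
    tmp = tmp_path_factory.mktemp("fa")
    genomes = [
        Genome("sp", Compartment.MITOCHONDRIAL, s, record_id=f"r{i}")
        for i, s in enumerate(seqs)
    ]
    write_fasta(genomes, tmp / "g.fa")
    back = read_fasta(tmp / "g.fa")
    assert [g.sequence for g in back] == seqs
    assert all(g.compartment == Compartment.MITOCHONDRIAL for g in back)


def test_gene_table_coordinate_conversion(tmp_path):
    p = tmp_path / "genes.tsv"
    p.write_text("cox1\tmitochondrial\t101\t200\t+\tcomplexIV\n")
    (g,) = read_gene_table(p)
    assert (g.start, g.end) == (100, 200)
    assert g.functional_category == "complexIV"


def test_gene_table_round_trip(tmp_path):
    genes = [
        GeneModel("cox1", Compartment.MITOCHONDRIAL, 100, 200, "+", "complexIV"),
        GeneModel("nad1", Compartment.MITOCHONDRIAL, 0, 50, "-", "complexI"),
    ]
    write_gene_table(genes, tmp_path / "g.tsv")
    back = read_gene_table(tmp_path / "g.tsv")
    assert [(g.gene_id, g.start, g.end, g.strand) for g in back] == [
        ("cox1", 100, 200, "+"),
        ("nad1", 0, 50, "-"),
    ]


def test_gene_table_rejects_bad_rows(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("cox1\tmitochondrial\t200\t100\t+\tx\n")
    with pytest.raises(ValueError, match="row 1"):
        read_gene_table(p)
    p.write_text("cox1\tplastidzz\t1\t10\t+\tx\n")
    with pytest.raises(ValueError, match="compartment"):
        read_gene_table(p)
    p.write_text("")
    assert read_gene_table(p) == []


def test_normalize_sequence_policy():
    seq, n_bad = normalize_sequence("acgu RyN")
    assert seq == "ACGTNNNN"
    assert n_bad == 3  # space, R, Y (N itself is permitted)


@given(s=st.text(alphabet="ACGTN", min_size=1, max_size=100))
def test_reverse_complement_involution(s):
    assert reverse_complement(reverse_complement(s)) == s


def test_segments_bed_round_trip(tmp_path, small_trio):
    from igtscan import scan_transfers

    segs = scan_transfers(small_trio.mitochondrial, small_trio.nuclear)
    assert segs, "fixture trio should contain detectable numts"
    write_segments_bed(segs, tmp_path / "s.bed")
    back = read_segments_bed(tmp_path / "s.bed")
    assert len(back) == len(segs)
    for a, b in zip(segs, back):
        assert a.hsp.t_start == b.hsp.t_start and a.hsp.t_end == b.hsp.t_end
        assert a.segment_class == b.segment_class
        assert a.hsp.raw_score == b.hsp.raw_score
        assert a.hsp.matches == b.hsp.matches
    # score column carries 10 x identity%
    line = (tmp_path / "s.bed").read_text().splitlines()[1].split("\t")
    assert int(line[4]) == int(round(segs[0].hsp.identity * 1000))


def test_segments_bed_empty_list(tmp_path):
    write_segments_bed([], tmp_path / "e.bed")
    text = (tmp_path / "e.bed").read_text()
    assert text.startswith("#")
    assert read_segments_bed(tmp_path / "e.bed") == []


def test_genome_rejects_bad_symbols():
    with pytest.raises(ValueError):
        Genome("s", Compartment.NUCLEAR, "ACGX")
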