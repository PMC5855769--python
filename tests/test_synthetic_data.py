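"""Simulator contracts: determinism, capacity accounting, planted-feature fidelity."""

import numpy as np
import pytest

from igtscan import (
    SimConfig,
    generate_trio,
    make_repeat_library,
    read_truth_table,
    write_trio,
)
from igtscan.genome_io import RepeatClass
from igtscan.synthetic_data import _erode

from oracles import make_sw_aligner


def _cfg(**kw):
    base = dict(seed=7, species_id="sim", nuclear_len=40_000, mt_len=30_000,
                cp_len=12_000, n_numts=4, n_mtpts=4, n_genes=8)
    base.update(kw)
    return SimConfig(**base)


def test_determinism_byte_identical(tmp_path):
    t1 = generate_trio(_cfg())
    t2 = generate_trio(_cfg())
    assert t1.nuclear.sequence == t2.nuclear.sequence
    assert t1.mitochondrial.sequence == t2.mitochondrial.sequence
    assert t1.chloroplast.sequence == t2.chloroplast.sequence
    write_trio(t1, tmp_path / "a")
    write_trio(t2, tmp_path / "b")
    for name in ("sim_nuclear.fa", "sim_mitochondrial.fa", "sim_truth.tsv"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
    # and a different seed changes the output
    assert generate_trio(_cfg(seed=8)).nuclear.sequence != t1.nuclear.sequence


def test_capacity_conservation():
    cfg = _cfg()
    trio = generate_trio(cfg)
    nuclear_inserts = sum(
        t.recipient_end - t.recipient_start
        for t in trio.truth
        if t.recipient_compartment == "nuclear"
    )
    assert trio.nuclear.length_bp == cfg.nuclear_len + nuclear_inserts
    mt_inserts = sum(
        t.recipient_end - t.recipient_start
        for t in trio.truth
        if t.event_type == "mtpt"
    )
    assert trio.mitochondrial.length_bp == cfg.mt_len + mt_inserts


def test_overcrowded_request_is_an_error():
    with pytest.raises(ValueError, match="50%"):
        generate_trio(_cfg(nuclear_len=5000, n_numts=10,
                           transfer_len_bounds=(1000, 1001)))


def test_truth_identity_matches_planted(sw_aligner):
    """Planted inserts align to their donor interval at the recorded identity."""
    trio = generate_trio(_cfg(seed=19, transfer_len_bounds=(150, 500)))
    for t in trio.truth:
        if t.event_type != "numt":
            continue
        insert = trio.nuclear.sequence[t.recipient_start:t.recipient_end]
        if t.orientation == "-":
            from igtscan import reverse_complement

            insert = reverse_complement(insert)
        donor = trio.mitochondrial.sequence[t.donor_start:t.donor_end]
        aln = sw_aligner.align(insert, donor)
        matches = sum(
            a == b and a != "-"
            for a, b in zip(str(aln[0][0]), str(aln[0][1]))
        )
        identity = matches / (t.recipient_end - t.recipient_start)
        assert identity == pytest.approx(t.planted_identity, abs=0.02)


def test_erosion_rate_calibrated():
    rng = np.random.default_rng(0)
    idents = []
    for _ in range(30):
        _, ident = _erode(rng, "ACGT" * 250, 0.02)
        idents.append(ident)
    assert 0.96 <= np.mean(idents) <= 0.995


def test_pseudogenization_fraction():
    cfg = _cfg(seed=3, n_genes=24, nuclear_len=80_000, mt_len=45_000,
               gene_lost_fraction=0.0, gene_transfer_fraction=1.0,
               pseudogenize_fraction=0.5, n_numts=0, n_mtpts=0)
    trio = generate_trio(cfg)
    copies = [t for t in trio.truth if t.event_type == "gene_copy"]
    assert len(copies) == 24
    n_trunc = sum(t.truncated for t in copies)
    # binomial(24, 0.5) within 4 sigma
    assert abs(n_trunc - 12) <= 4 * np.sqrt(24 * 0.25)
    for t in copies:
        if t.truncated:
            assert 0.25 <= t.truncation_coverage <= 0.75
        else:
            assert t.truncation_coverage == 1.0


def test_truth_table_round_trip(tmp_path):
    trio = generate_trio(_cfg())
    write_trio(trio, tmp_path)
    back = read_truth_table(tmp_path / "sim_truth.tsv")
    assert len(back) == len(trio.truth)
    for a, b in zip(trio.truth, back):
        assert (a.event_id, a.event_type, a.recipient_start, a.recipient_end) == (
            b.event_id, b.event_type, b.recipient_start, b.recipient_end
        )
        assert a.microhomology_left == b.microhomology_left
        assert a.truncated == b.truncated


def test_repeat_library_composition():
    lib = make_repeat_library(seed=1, n_per_class=2)
    assert len(lib) == 14
    assert {e.repeat_class for e in lib} == set(RepeatClass)
    # low-complexity entries have low mononucleotide entropy
    for e in lib:
        if e.repeat_class is RepeatClass.LOW_COMPLEXITY:
            counts = np.array([e.sequence.count(c) for c in "ACGT"], dtype=float)
            p = counts[counts > 0] / counts.sum()
            entropy = -(p * np.log2(p)).sum()
            assert entropy < 1.0
    # LTR-style entries begin and end with the same 80 bp terminal repeat
    for e in lib:
        if e.repeat_class in (RepeatClass.COPIA, RepeatClass.GYPSY, RepeatClass.LTR_RETRO):
            assert e.sequence[:80] == e.sequence[-80:]
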