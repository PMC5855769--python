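"""Junction extraction, micro-homology calls and cross-species motif intersection."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from igtscan import (
    SimConfig,
    call_microhomology,
    cross_species_report,
    generate_trio,
    junctions_from_coords,
    reverse_complement,
)
from igtscan.junction_analysis import JunctionContext, RepairCall

dna = st.text(alphabet="ACGT", min_size=6, max_size=20)


def _ctx(side, flank, edge):
    return JunctionContext(species_id="s", side=side, recipient_flank=flank, insert_edge=edge)


def test_extraction_coordinates(random_dna):
    seq = random_dna(400, seed=80)
    left, right = junctions_from_coords(seq, 100, 200, flank_bp=20)
    assert left.recipient_flank == seq[80:100]
    assert left.insert_edge == seq[100:120]
    assert right.recipient_flank == seq[200:220]
    assert right.insert_edge == seq[180:200]
    assert not left.truncated_flank and not right.truncated_flank


def test_edge_clamping_flags_short_flank(random_dna):
    seq = random_dna(300, seed=81)
    left, right = junctions_from_coords(seq, 5, 100, flank_bp=20)
    assert len(left.recipient_flank) == 5
    assert left.truncated_flank


def test_microhomology_examples():
    # flank ...CAT + insert AT... share "AT"
    ctx = call_microhomology(_ctx("left", "GGCCCCAT", "ATGGTTCC"))
    assert ctx.microhomology == "AT"
    assert ctx.repair_call == RepairCall.MICROHOMOLOGY
    # no overlap at all: blunt end
    ctx = call_microhomology(_ctx("left", "AAACCC", "TGACCA"))
    assert ctx.microhomology == ""
    assert ctx.repair_call == RepairCall.BLUNT_END
    # long identical overlap is capped at 4
    ctx = call_microhomology(_ctx("left", "TTGGGGGG", "GGGGGGTT"))
    assert ctx.microhomology == "GGGG"
    # right side: insert suffix vs flank prefix
    ctx = call_microhomology(_ctx("right", "ATCCGG", "GGGGAT"))
    assert ctx.microhomology == "AT"


@given(flank=dna, edge=dna)
def test_call_invariants(flank, edge):
    for side in ("left", "right"):
        ctx = call_microhomology(_ctx(side, flank, edge))
        assert 0 <= len(ctx.microhomology) <= 4
        assert (ctx.repair_call == RepairCall.BLUNT_END) == (len(ctx.microhomology) == 0)
        # determinism
        again = call_microhomology(_ctx(side, flank, edge))
        assert again.microhomology == ctx.microhomology


def test_reverse_complement_consistency(random_dna):
    """Mirrored coordinates on the reverse complement give the same repair calls."""
    seq = random_dna(500, seed=82)
    start, end = 150, 300
    fwd = [call_microhomology(c) for c in junctions_from_coords(seq, start, end)]
    rc = reverse_complement(seq)
    n = len(seq)
    rev = [
        call_microhomology(c)
        for c in junctions_from_coords(rc, n - end, n - start)
    ]
    # left junction of the forward strand is the right junction of the reverse
    assert fwd[0].repair_call == rev[1].repair_call
    assert fwd[1].repair_call == rev[0].repair_call
    assert fwd[0].microhomology == reverse_complement(rev[1].microhomology)
    assert fwd[1].microhomology == reverse_complement(rev[0].microhomology)


def test_planted_microhomology_visible_in_flanks():
    cfg = SimConfig(
        seed=17, species_id="mh", n_numts=0, n_mtpts=6,
        gene_transfer_fraction=0.0, inverted_fraction=0.0,
        microhomology_probs=(0.0, 0.0, 0.0, 1.0, 0.0),  # always 3 bp
    )
    trio = generate_trio(cfg)
    mt = trio.mitochondrial.sequence
    for t in [t for t in trio.truth if t.event_type == "mtpt"]:
        assert len(t.microhomology_left) == 3
        left, right = junctions_from_coords(mt, t.recipient_start, t.recipient_end)
        assert left.recipient_flank.endswith(t.microhomology_left)
        assert left.insert_edge.startswith(t.microhomology_left)
        assert right.recipient_flank.startswith(t.microhomology_right)
        assert right.insert_edge.endswith(t.microhomology_right)
        called = call_microhomology(left)
        assert len(called.microhomology) >= 3


def test_called_length_never_below_planted():
    cfg = SimConfig(
        seed=23, species_id="mh2", n_numts=0, n_mtpts=20,
        transfer_len_bounds=(150, 1200),
        gene_transfer_fraction=0.0, inverted_fraction=0.0,
    )
    trio = generate_trio(cfg)
    mt = trio.mitochondrial.sequence
    n_seen = 0
    for t in [t for t in trio.truth if t.event_type == "mtpt"]:
        left, right = junctions_from_coords(mt, t.recipient_start, t.recipient_end)
        for ctx, planted in ((left, t.microhomology_left), (right, t.microhomology_right)):
            called = call_microhomology(ctx).microhomology
            assert len(called) >= len(planted)
            if planted:
                n_seen += 1
    assert n_seen >= 10


def test_cross_species_motif_intersection():
    def member(flank_l, edge_l, edge_r, flank_r):
        return (
            _ctx("left", flank_l, edge_l),
            _ctx("right", flank_r, edge_r),
        )

    groups = {
        "eudicots": {
            "sp1": member("TTAGGGG", "GGGGCAT", "CCCGTAT", "ATGACCA"),
            "sp2": member("CCTGGGG", "GGGGTTA", "ACGTAAT", "ATCGGTA"),
            "sp3": member("ACAGGGG", "GGGGACC", "TTTACAT", "ATACGGC"),
        },
        "mixed": {
            "sp4": member("TTAGGGG", "GGGGCAT", "CCCGTTT", "GGGACCA"),
            "sp5": member("CCTCCGG", "GGAATTA", "ACGTACC", "TTCGGTA"),
        },
        "lonely": {"sp6": member("AAAA", "AAAA", "AAAA", "AAAA")},
    }
    report = cross_species_report("trnH", groups)
    assert report.conserved_left["eudicots"] == "GGGG"
    assert report.conserved_right["eudicots"] == "AT"
    assert report.conserved_left["mixed"] == "GG"   # shortened to the shared overlap
    assert report.conserved_right["mixed"] == ""
    assert "lonely" not in report.species_groups   # singleton excluded
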