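"""Aligner unit tests: gates, oracle equivalence, strand symmetry, merging."""

import numpy as np
import pytest

from igtscan import (
    Compartment,
    Genome,
    SearchParams,
    find_hsps,
    reverse_complement,
    scan_transfers,
    total_transferred_bp,
)
from igtscan.homology_search import SegmentClass, best_hsp, evalue_of

from oracles import make_sw_aligner, sw_oracle

LOOSE = SearchParams(
    evalue_max=10.0, min_identity=1e-6, min_length=11, word_size=11,
    search_both_strands=False,
)


def _mutate(rng, s, sub, ind=0.0):
    out = []
    for c in s:
        r = rng.random()
        if r < sub:
            out.append("ACGT"[rng.integers(4)])
        elif r < sub + ind:
            if rng.random() < 0.5:
                continue
            out.append(c)
            out.append("ACGT"[rng.integers(4)])
        else:
            out.append(c)
    return "".join(out)


def test_perfect_containment(random_dna):
    target = random_dna(5000, seed=1)
    q = target[1000:1150]
    (h,) = find_hsps(q, target, SearchParams(min_length=100))
    assert (h.t_start, h.t_end) == (1000, 1150)
    assert h.identity == 1.0
    assert h.aligned_length == 150
    assert h.strand == "+"


def test_short_perfect_match_fails_length_gate(random_dna):
    target = random_dna(5000, seed=2)
    q = target[2000:2090]
    assert find_hsps(q, target, SearchParams.for_mode("numt")) == []
    hits = find_hsps(q, target, SearchParams.for_mode("mtpt"))
    assert [(h.t_start, h.t_end) for h in hits] == [(2000, 2090)]


def test_planted_segment_matches_sw_oracle(random_dna, sw_aligner):
    """A 120 bp ~96% identity insert must align exactly as full Smith-Waterman does."""
    rng = np.random.default_rng(5)
    target = random_dna(5000, seed=5)
    seg = list(target[3000:3120])
    for i in (5, 30, 60, 90, 115):
        seg[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seg[i]]
    q = "".join(seg)
    (h,) = find_hsps(q, target, SearchParams(min_identity=0.9, min_length=100))
    score, q0, q1, t0, t1, matches, seeded = sw_oracle(q, target, sw_aligner)
    assert seeded
    assert h.raw_score == score
    assert (h.t_start, h.t_end, h.matches) == (t0, t1, matches)


def test_oracle_equivalence_random_pairs(sw_aligner):
    """Best HSP score equals the Smith-Waterman optimum whenever the optimal
    alignment contains an exact word-size seed (50 seeded random pairs)."""
    rng = np.random.default_rng(77)
    bases = np.array(list("ACGT"))

    def rnd(n):
        return "".join(bases[rng.integers(0, 4, n)])

    n_seeded = 0
    for _ in range(50):
        tlen = int(rng.integers(300, 3000))
        qlen = int(rng.integers(60, 300))
        target = rnd(tlen)
        ins = int(rng.integers(0, tlen - qlen))
        q = _mutate(rng, target[ins:ins + qlen], 0.06, 0.01)[:300]
        score, *_rest, seeded = sw_oracle(q, target, sw_aligner)
        hits = find_hsps(q, target, LOOSE)
        best = max((h.raw_score for h in hits), default=0)
        if seeded:
            n_seeded += 1
            assert best == score
    assert n_seeded >= 40  # the condition must actually be exercised


def test_strand_symmetry(random_dna):
    """Searching the reverse complement of the target mirrors coordinates and strands."""
    rng = np.random.default_rng(9)
    target = random_dna(4000, seed=9)
    q = _mutate(rng, target[1500:1800], 0.03)
    params = SearchParams(min_identity=0.9, min_length=100)
    fwd = find_hsps(q, target, params)
    rev = find_hsps(q, reverse_complement(target), params)
    assert len(fwd) == len(rev) >= 1
    n = len(target)
    fwd_set = {(h.t_start, h.t_end, h.strand, h.raw_score) for h in fwd}
    mirrored = {
        (n - h.t_end, n - h.t_start, "+" if h.strand == "-" else "-", h.raw_score)
        for h in rev
    }
    assert fwd_set == mirrored


def test_gate_monotonicity(random_dna):
    """Raising min_length or min_identity never increases the number of hits."""
    rng = np.random.default_rng(13)
    target = random_dna(6000, seed=13)
    parts = []
    for start, sub in ((500, 0.01), (2000, 0.04), (4000, 0.08)):
        parts.append(_mutate(rng, target[start:start + 200], sub))
    q = ("N" * 20).join(parts)
    base = dict(evalue_max=10.0, word_size=11, search_both_strands=False)
    counts_by_len = [
        len(find_hsps(q, target, SearchParams(min_identity=0.5, min_length=L, **base)))
        for L in (11, 50, 100, 150, 250)
    ]
    assert counts_by_len == sorted(counts_by_len, reverse=True)
    counts_by_id = [
        len(find_hsps(q, target, SearchParams(min_identity=i, min_length=100, **base)))
        for i in (0.5, 0.9, 0.95, 0.99, 1.0)
    ]
    assert counts_by_id == sorted(counts_by_id, reverse=True)


def test_all_n_query_returns_empty(random_dna):
    assert find_hsps("N" * 200, random_dna(1000, seed=3), LOOSE) == []


def test_evalue_formula_and_gate(random_dna):
    target = random_dna(3000, seed=21)
    q = target[500:650]
    (h,) = find_hsps(q, target, SearchParams(min_length=100))
    assert h.evalue == pytest.approx(evalue_of(h.raw_score, len(q), len(target)))
    # an absurdly strict E-value gate suppresses the hit
    assert find_hsps(q, target, SearchParams(min_length=100, evalue_max=1e-200)) == []


def test_best_hsp_tie_break():
    from igtscan.homology_search import HSP

    a = HSP("q", "t", 0, 100, 0, 100, "+", 100, 98, 90, 1e-30)
    b = HSP("q", "t", 0, 100, 500, 600, "+", 100, 98, 90, 1e-30)
    assert best_hsp([b, a]) is a  # equal score/evalue/length: lower t_start wins
    c = HSP("q", "t", 0, 120, 800, 920, "+", 120, 100, 95, 1e-33)
    assert best_hsp([a, b, c]) is c


def test_scan_transfers_classes_and_union(random_dna):
    donor_seq = random_dna(8000, seed=31)
    bg = random_dna(20000, seed=32)
    insert = donor_seq[1000:3000]
    recipient_seq = bg[:5000] + insert + bg[5000:]
    donor = Genome("sp", Compartment.MITOCHONDRIAL, donor_seq)
    recipient = Genome("sp", Compartment.NUCLEAR, recipient_seq)
    segs = scan_transfers(donor, recipient)
    assert len(segs) == 1
    assert segs[0].segment_class == SegmentClass.NUMT
    # breakpoints recovered up to chance flank matches (a few bp)
    assert abs(segs[0].hsp.t_start - 5000) <= 4
    assert abs(segs[0].hsp.t_end - 7000) <= 4
    assert insert[4:-4] in segs[0].sequence
    assert abs(total_transferred_bp(segs) - 2000) <= 8
    with pytest.raises(ValueError, match="compartment"):
        scan_transfers(donor, Genome("sp", Compartment.MITOCHONDRIAL, bg))


def test_interval_union_counts_overlaps_once():
    from igtscan.intervals import union_length

    assert union_length([(0, 200), (150, 450)]) == 450
    assert union_length([(0, 100), (200, 400)]) == 300
    assert union_length([]) == 0
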