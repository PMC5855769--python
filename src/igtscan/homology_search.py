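"""Seed-and-extend local alignment with BLAST-style detection gates.

This is the in-package replacement for the BLASTN screens used to detect
organellar transfer segments: an exact word seed (both strands), an ungapped
X-drop pre-filter, and an exact affine-gap Smith-Waterman over a window around
each seed cluster.  Scoring is fixed at +1 match / -2 mismatch, gap of length
k costing 5 + 2k (open -5, extend -2 in the BLAST convention), with ungapped
Karlin-Altschul statistics (K = 0.71, lambda = 1.37) so E-values are
deterministic and documented.  A hit is reported only if it passes ALL gates:
E-value <= evalue_max, identity >= min_identity, aligned length >= min_length.

N is never a match: it mismatches every symbol, including N, in both the score
and the identity numerator, and words containing N never seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Union

import numpy as np

from .genome_io import Compartment, Genome, reverse_complement
from .intervals import union_length

logger = logging.getLogger(__name__)

MATCH = 1
MISMATCH = -2
GAP_OPEN = 5   # positive costs; gap of length k costs GAP_OPEN + GAP_EXTEND * k
GAP_EXTEND = 2
KA_K = 0.71
KA_LAMBDA = 1.37

_DIAG_BAND = 10      # diagonal band for cluster merging and HSP overlap merging
_SEED_JOIN_GAP = 150  # max query gap joining seeds into one cluster
_XDROP = 25
_PREFILTER_MARGIN = 15
_WINDOW_PAD = 120
_MAX_WINDOW = 6000   # DP dimension cap per window

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = np.where(codes < 4, 3 - codes, codes).astype(np.uint8)
    return out[::-1]


class SegmentClass(str, Enum):
    NUMT = "numt"
    NUPT = "nupt"
    MTPT = "mtpt"
    MT_TO_CP = "mt_to_cp"
    OTHER = "other"


_PAIR_TO_CLASS = {
    (Compartment.MITOCHONDRIAL, Compartment.NUCLEAR): SegmentClass.NUMT,
    (Compartment.CHLOROPLAST, Compartment.NUCLEAR): SegmentClass.NUPT,
    (Compartment.CHLOROPLAST, Compartment.MITOCHONDRIAL): SegmentClass.MTPT,
    (Compartment.MITOCHONDRIAL, Compartment.CHLOROPLAST): SegmentClass.MT_TO_CP,
}


@dataclass(frozen=True)
class SearchParams:
    """Detection gates and seeding parameters.

    min_length defaults to the nuclear-insertion gate (100 bp); use
    :meth:`for_mode` to get the 50 bp organelle-to-organelle gate.
    identity_mode selects what min_identity gates: the aligned-column identity
    of the HSP (default) or the query coverage of the hit.
    """

    evalue_max: float = 1e-5
    min_identity: float = 0.95
    min_length: int = 100
    word_size: int = 11
    search_both_strands: bool = True
    identity_mode: str = "alignment"   # or "query_coverage"
    mask_low_complexity: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if not (self.min_length >= self.word_size >= 4):
            raise ValueError("need min_length >= word_size >= 4")
        if self.identity_mode not in ("alignment", "query_coverage"):
            raise ValueError("identity_mode must be 'alignment' or 'query_coverage'")

    @classmethod
    def for_mode(cls, mode: str, **overrides) -> "SearchParams":
        mode = mode.lower()
        if mode in ("numt", "nupt"):
            defaults = dict(min_length=100)
        elif mode in ("mtpt", "mt_to_cp"):
            defaults = dict(min_length=50)
        else:
            raise ValueError(f"unknown search mode {mode!r}")
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class HSP:
    """A local alignment hit; coordinates 0-based half-open on the forward strands."""

    query_id: str
    target_id: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str
    aligned_length: int
    matches: int
    raw_score: int
    evalue: float

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_length if self.aligned_length else 0.0

    @property
    def diagonal(self) -> int:
        return self.t_start - self.q_start


@dataclass
class TransferSegment:
    donor_compartment: Compartment
    recipient_compartment: Compartment
    species_id: str
    hsp: HSP
    segment_class: SegmentClass
    segment_id: str = ""
    sequence: str = ""   # recipient-strand sequence of the inserted interval

    def __post_init__(self) -> None:
        expected = _PAIR_TO_CLASS.get(
            (self.donor_compartment, self.recipient_compartment), SegmentClass.OTHER
        )
        if self.segment_class != expected:
            raise ValueError(
                f"segment_class {self.segment_class} inconsistent with "
                f"{self.donor_compartment.value}->{self.recipient_compartment.value}"
            )


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

def _kmer_table(codes: np.ndarray, k: int, mask_low_complexity: bool = False):
    """Positions and integer codes of all N-free k-mers."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win < 4).all(axis=1)
    if mask_low_complexity:
        # dust-like seed filter: drop words built from <= 2 distinct bases
        srt = np.sort(win, axis=1)
        n_distinct = 1 + (np.diff(srt.astype(np.int16), axis=1) > 0).sum(axis=1)
        valid &= n_distinct > 2
    pows = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    vals = win.astype(np.int64) @ pows
    pos = np.nonzero(valid)[0].astype(np.int64)
    return pos, vals[pos]


def _seed_pairs(qc: np.ndarray, tc: np.ndarray, k: int, mask: bool):
    """All (q_pos, t_pos) exact k-mer matches."""
    q_pos, q_vals = _kmer_table(qc, k, mask_low_complexity=mask)
    t_pos, t_vals = _kmer_table(tc, k)
    if len(q_pos) == 0 or len(t_pos) == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    order = np.argsort(t_vals, kind="stable")
    t_vals_s, t_pos_s = t_vals[order], t_pos[order]
    left = np.searchsorted(t_vals_s, q_vals, side="left")
    right = np.searchsorted(t_vals_s, q_vals, side="right")
    counts = right - left
    hit = counts > 0
    if not hit.any():
        return np.empty(0, np.int64), np.empty(0, np.int64)
    q_rep = np.repeat(q_pos[hit], counts[hit])
    idx = np.concatenate([np.arange(l, r) for l, r in zip(left[hit], right[hit])])
    return q_rep, t_pos_s[idx]


@dataclass
class _Cluster:
    q_min: int
    q_max: int
    t_min: int
    t_max: int
    d_min: int
    d_max: int
    seeds: list = field(default_factory=list)   # sample of (q, t)


def _cluster_seeds(q_arr: np.ndarray, t_arr: np.ndarray, k: int) -> list[_Cluster]:
    """Group seeds into diagonal-band clusters (band +-_DIAG_BAND, query gap <= _SEED_JOIN_GAP)."""
    if len(q_arr) == 0:
        return []
    diag = t_arr - q_arr
    order = np.lexsort((q_arr, diag))
    clusters: list[_Cluster] = []
    active: list[_Cluster] = []
    for i in order:
        q, t, d = int(q_arr[i]), int(t_arr[i]), int(diag[i])
        active = [c for c in active if d - c.d_max <= _DIAG_BAND]
        placed = None
        for c in active:
            if c.q_min - _SEED_JOIN_GAP <= q <= c.q_max + _SEED_JOIN_GAP:
                placed = c
                break
        if placed is None:
            placed = _Cluster(q, q + k, t, t + k, d, d, [(q, t)])
            clusters.append(placed)
            active.append(placed)
        else:
            placed.q_min = min(placed.q_min, q)
            placed.q_max = max(placed.q_max, q + k)
            placed.t_min = min(placed.t_min, t)
            placed.t_max = max(placed.t_max, t + k)
            placed.d_min = min(placed.d_min, d)
            placed.d_max = max(placed.d_max, d)
            if len(placed.seeds) < 32:
                placed.seeds.append((q, t))
    return clusters


# ---------------------------------------------------------------------------
# Ungapped X-drop extension (pre-filter)
# ---------------------------------------------------------------------------

def _xdrop_half(qc: np.ndarray, tc: np.ndarray) -> int:
    """Best cumulative score of an extension along paired arrays, X-drop terminated."""
    n = min(len(qc), len(tc))
    if n == 0:
        return 0
    a, b = qc[:n], tc[:n]
    s = np.where((a == b) & (a < 4), MATCH, MISMATCH).astype(np.int64)
    cum = np.cumsum(s)
    runmax = np.maximum.accumulate(cum)
    dropped = cum - runmax < -_XDROP
    if dropped.any():
        stop = int(np.argmax(dropped))
        cum = cum[: stop + 1]
    return max(int(cum.max()), 0)


def _ungapped_seed_score(qc, tc, q, t, k) -> int:
    right = _xdrop_half(qc[q + k:], tc[t + k:])
    left = _xdrop_half(qc[:q][::-1], tc[:t][::-1])
    return k * MATCH + left + right


# ---------------------------------------------------------------------------
# Windowed affine-gap Smith-Waterman (exact within the window)
# ---------------------------------------------------------------------------

def _sw_window(qc: np.ndarray, tc: np.ndarray, forbid_diag: int | None = None):
    """Exact local affine alignment of two code arrays.

    Returns (score, q0, q1, t0, t1, matches, aligned_length) for the best
    local alignment, or None if the best score is 0.  Gap of length k costs
    GAP_OPEN + GAP_EXTEND*k.  Rows are vectorised; the in-row gap recurrence
    uses a prefix-max scan, which is exact for affine costs.
    """
    m, n = len(qc), len(tc)
    if m == 0 or n == 0:
        return None
    first = GAP_OPEN + GAP_EXTEND   # cost of the first gap column
    ext = GAP_EXTEND
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    F = np.full(n + 1, np.iinfo(np.int32).min // 2, dtype=np.int32)
    j_idx = np.arange(n + 1, dtype=np.int64)
    t_match = tc < 4
    for i in range(1, m + 1):
        qi = qc[i - 1]
        sub = np.where((tc == qi) & (qi < 4) & t_match, MATCH, MISMATCH).astype(np.int32)
        if forbid_diag is not None:
            jt = (i - 1) + forbid_diag   # cell aligning a position to itself
            if 0 <= jt < n:
                sub[jt] = -(10**6)
        Hprev = H[i - 1]
        F = np.maximum(Hprev - first, F - ext)
        diag = np.zeros(n + 1, dtype=np.int32)
        diag[1:] = Hprev[:-1] + sub
        H0 = np.maximum(np.maximum(diag, F), 0)
        # in-row gap: E[j] = max_{j'<j} H0[j'] - first - ext*(j - j' - 1)
        G = H0 + ext * j_idx
        P = np.maximum.accumulate(G)
        E = np.full(n + 1, -1, dtype=np.int64)
        E[1:] = P[:-1] - first - ext * (j_idx[1:] - 1)
        H[i] = np.maximum(H0, E.astype(np.int32))
    score = int(H.max())
    if score <= 0:
        return None
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    i, j = int(i), int(j)
    q1, t1 = i, j
    matches = 0
    cols = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        h = int(H[i, j])
        qi, tj = qc[i - 1], tc[j - 1]
        s = MATCH if (qi == tj and qi < 4) else MISMATCH
        if forbid_diag is not None and (j - 1) == (i - 1) + forbid_diag:
            s = -(10**6)
        if h == H[i - 1, j - 1] + s:
            matches += int(s == MATCH)
            cols += 1
            i, j = i - 1, j - 1
            continue
        # horizontal gap (consumes target)
        g = 1
        moved = False
        while j - g >= 0:
            if h == int(H[i, j - g]) - first - ext * (g - 1):
                cols += g
                j -= g
                moved = True
                break
            g += 1
            if g > j:
                break
        if moved:
            continue
        # vertical gap (consumes query)
        g = 1
        while i - g >= 0:
            if h == int(H[i - g, j]) - first - ext * (g - 1):
                cols += g
                i -= g
                moved = True
                break
            g += 1
            if g > i:
                break
        if not moved:   # safety: should not happen
            break
    return score, i, q1, j, t1, matches, cols


def evalue_of(score: int, m: int, n: int) -> float:
    """Ungapped Karlin-Altschul E-value, E = K*m*n*exp(-lambda*S)."""
    return KA_K * m * n * math.exp(-KA_LAMBDA * score)


def _score_gate(params: SearchParams, m: int, n: int) -> int:
    """Minimum raw score any reportable HSP can have under the gates."""
    s_eval = math.log(KA_K * max(m, 1) * max(n, 1) / params.evalue_max) / KA_LAMBDA
    # an HSP of length L and identity >= id scores at least L*(8*id - 7)
    s_len = params.min_length * (8 * params.min_identity - 7)
    if params.identity_mode != "alignment":
        s_len = 0.0
    return max(int(math.floor(max(s_eval, s_len, 0.0))), 0)


# ---------------------------------------------------------------------------
# Main search
# ---------------------------------------------------------------------------

def _as_sequence(obj: Union[Genome, str]) -> tuple[str, str]:
    if isinstance(obj, Genome):
        return obj.sequence, obj.record_id
    return obj, "query"


def _search_one_strand(qc, tc, params: SearchParams, exclude_self: bool):
    """Raw candidate alignments (score, q0, q1, t0, t1, matches, cols) on one strand."""
    k = params.word_size
    q_arr, t_arr = _seed_pairs(qc, tc, k, params.mask_low_complexity)
    if exclude_self and len(q_arr):
        keep = q_arr != t_arr
        q_arr, t_arr = q_arr[keep], t_arr[keep]
    clusters = _cluster_seeds(q_arr, t_arr, k)
    gate = _score_gate(params, len(qc), len(tc))
    small_query = len(qc) <= 512
    out = []
    for c in clusters:
        best_ungapped = 0
        seeds = c.seeds
        sample = [seeds[0], seeds[len(seeds) // 2], seeds[-1]] if len(seeds) > 2 else seeds
        for q, t in sample:
            best_ungapped = max(best_ungapped, _ungapped_seed_score(qc, tc, q, t, k))
            if best_ungapped + _PREFILTER_MARGIN >= gate:
                break
        if best_ungapped + _PREFILTER_MARGIN < gate:
            continue
        if small_query:
            q0, q1 = 0, len(qc)
            pad_t = len(qc) + _WINDOW_PAD
            t0 = max(0, c.t_min - pad_t)
            t1 = min(len(tc), c.t_max + pad_t)
        else:
            q0 = max(0, c.q_min - _WINDOW_PAD)
            q1 = min(len(qc), c.q_max + _WINDOW_PAD)
            t0 = max(0, c.t_min - _WINDOW_PAD)
            t1 = min(len(tc), c.t_max + _WINDOW_PAD)
        if q1 - q0 > _MAX_WINDOW or t1 - t0 > _MAX_WINDOW:
            logger.warning("alignment window clipped to %d bp", _MAX_WINDOW)
            q1 = min(q1, q0 + _MAX_WINDOW)
            t1 = min(t1, t0 + _MAX_WINDOW)
        forbid = (q0 - t0) if exclude_self else None
        res = _sw_window(qc[q0:q1], tc[t0:t1], forbid_diag=forbid)
        if res is None:
            continue
        score, wq0, wq1, wt0, wt1, matches, cols = res
        out.append((score, q0 + wq0, q0 + wq1, t0 + wt0, t0 + wt1, matches, cols))
    return out


def find_hsps(
    query: Union[Genome, str],
    target: Union[Genome, str],
    params: SearchParams | None = None,
    query_id: str | None = None,
    target_id: str | None = None,
    _exclude_trivial_self: bool = False,
) -> list[HSP]:
    """Local homologies of ``query`` in ``target`` passing all detection gates.

    Seeds on exact ``word_size`` matches on both strands (if configured),
    pre-filters clusters with an ungapped X-drop extension, then runs an exact
    affine Smith-Waterman on a window around each cluster.  Overlapping HSPs
    in the same diagonal band are merged, keeping the highest raw score.
    Output is sorted by (target_id, t_start).
    """
    params = params or SearchParams()
    q_seq, q_id_default = _as_sequence(query)
    t_seq, t_id_default = _as_sequence(target)
    query_id = query_id or q_id_default
    target_id = target_id or t_id_default
    if not q_seq or not t_seq:
        raise ValueError("query and target must be non-empty")
    qc = encode(q_seq)
    tc = encode(t_seq)
    if (qc == 4).all():
        logger.warning("query %s is all N; no search performed", query_id)
        return []
    m, n = len(qc), len(tc)
    hsps: list[HSP] = []
    strands = ["+"] + (["-"] if params.search_both_strands else [])
    for strand in strands:
        tcs = tc if strand == "+" else _revcomp_codes(tc)
        raw = _search_one_strand(
            qc, tcs, params, exclude_self=_exclude_trivial_self and strand == "+"
        )
        for score, q0, q1, t0, t1, matches, cols in raw:
            if strand == "-":
                t0, t1 = n - t1, n - t0
            hsp = HSP(
                query_id=query_id,
                target_id=target_id,
                q_start=q0,
                q_end=q1,
                t_start=t0,
                t_end=t1,
                strand=strand,
                aligned_length=cols,
                matches=matches,
                raw_score=score,
                evalue=evalue_of(score, m, n),
            )
            if _passes_gates(hsp, params, m):
                hsps.append(hsp)
    hsps = _merge_overlaps(hsps)
    hsps.sort(key=lambda h: (h.target_id, h.t_start, h.t_end))
    return hsps


def _passes_gates(hsp: HSP, params: SearchParams, query_len: int) -> bool:
    if hsp.evalue > params.evalue_max:
        return False
    if hsp.aligned_length < params.min_length:
        return False
    if params.identity_mode == "alignment":
        return hsp.identity >= params.min_identity
    return (hsp.q_end - hsp.q_start) / query_len >= params.min_identity


def _merge_overlaps(hsps: list[HSP]) -> list[HSP]:
    """Drop the lower-scoring of any two HSPs that overlap on the same target
    strand within one diagonal band (+-_DIAG_BAND); cross-diagonal overlaps kept."""
    kept: list[HSP] = []
    for h in sorted(hsps, key=lambda x: (-x.raw_score, x.evalue, -x.aligned_length, x.t_start)):
        redundant = False
        for g in kept:
            if (
                g.strand == h.strand
                and g.target_id == h.target_id
                and abs(g.diagonal - h.diagonal) <= _DIAG_BAND
                and min(g.t_end, h.t_end) - max(g.t_start, h.t_start) >= 1
            ):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def best_hsp(hsps: Iterable[HSP]) -> Optional[HSP]:
    """Highest-scoring HSP; ties by (lower evalue, longer aligned_length, lower t_start)."""
    hsps = list(hsps)
    if not hsps:
        return None
    return min(hsps, key=lambda h: (-h.raw_score, h.evalue, -h.aligned_length, h.t_start))


# ---------------------------------------------------------------------------
# Transfer scanning
# ---------------------------------------------------------------------------

def scan_transfers(
    donor: Genome,
    recipient: Genome,
    params: SearchParams | None = None,
) -> list[TransferSegment]:
    """Scan a whole donor genome against a recipient genome for transfer segments.

    The segment class follows the compartment pair (mitochondrial->nuclear =
    numt, chloroplast->nuclear = nupt, chloroplast->mitochondrial = mtpt,
    mitochondrial->chloroplast = mt_to_cp).  Same-compartment pairs are an
    error.  Default params follow the class mode gates.
    """
    if donor.compartment == recipient.compartment:
        raise ValueError("donor and recipient must be different compartments")
    seg_class = _PAIR_TO_CLASS.get((donor.compartment, recipient.compartment), SegmentClass.OTHER)
    if params is None:
        params = (
            SearchParams.for_mode(seg_class.value)
            if seg_class != SegmentClass.OTHER
            else SearchParams()
        )
    hsps = find_hsps(donor, recipient, params)
    segments = []
    for i, h in enumerate(hsps):
        segments.append(
            TransferSegment(
                donor_compartment=donor.compartment,
                recipient_compartment=recipient.compartment,
                species_id=recipient.species_id,
                hsp=h,
                segment_class=seg_class,
                segment_id=f"{seg_class.value}_{i:04d}",
                sequence=recipient.sequence[h.t_start:h.t_end],
            )
        )
    return segments


def total_transferred_bp(segments: Iterable[TransferSegment]) -> int:
    """Union length of recipient intervals (overlaps counted once), per target record."""
    by_target: dict[str, list[tuple[int, int]]] = {}
    for s in segments:
        by_target.setdefault(s.hsp.target_id, []).append((s.hsp.t_start, s.hsp.t_end))
    return sum(union_length(ivs) for ivs in by_target.values())
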