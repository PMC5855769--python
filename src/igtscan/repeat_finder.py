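"""Within-genome repeat quantification and repeat-class attribution.

``find_self_repeats`` aligns a genome against itself (both strands) with the
same seed-and-extend engine used for transfer detection, drops the trivial
full-length self match and one of each mirrored duplicate pair, and tallies
the two size tiers reported for mitogenomes (> 1 kb and > 100 bp) plus the
union size of all repeat-involved intervals.

``classify_repeat_segments`` is the library-matching stand-in for
RepeatMasker: each transferred segment is aligned against every entry of a
labelled repeat library and assigned the class of its best hit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .genome_io import Genome, RepeatClass, RepeatLibraryEntry
from .homology_search import HSP, SearchParams, TransferSegment, find_hsps
from .intervals import union_length


@dataclass(frozen=True)
class RepeatPair:
    """Two similar intervals within one genome (0-based half-open)."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    orientation: str       # "direct" | "inverted"
    length: int            # aligned length of the pair
    identity: float


@dataclass(frozen=True)
class RepeatSummary:
    repeat_size_bp: int    # union of all repeat-involved intervals
    n_over_1kb: int
    n_over_100bp: int


@dataclass
class RepeatClassAssignment:
    segment: TransferSegment
    repeat_class: RepeatClass
    best_hit_identity: float
    unassigned_flag: bool


def find_self_repeats(
    genome: Genome,
    min_len: int = 100,
    min_identity: float = 0.95,
    evalue_max: float = 1e-5,
) -> tuple[list[RepeatPair], RepeatSummary]:
    """Repeat pairs within one genome plus the two-tier summary.

    The trivial full-diagonal self match is excluded at seeding time; of each
    mirrored duplicate pair the copy with the lower-coordinate first interval
    is kept (a_start < b_start, or a_start <= b_start with swap canonical).
    Inverted (minus-strand) self hits are counted.
    """
    params = SearchParams(
        min_length=min_len, min_identity=min_identity, evalue_max=evalue_max
    )
    hsps = find_hsps(genome, genome, params, _exclude_trivial_self=True)
    seen: set[tuple] = set()
    pairs: list[RepeatPair] = []
    for h in hsps:
        a = (h.q_start, h.q_end)
        b = (h.t_start, h.t_end)
        if a == b:
            continue
        if b < a:
            a, b = b, a
        orientation = "direct" if h.strand == "+" else "inverted"
        key = (a, b, orientation)
        if key in seen:
            continue
        seen.add(key)
        pairs.append(
            RepeatPair(
                a_start=a[0], a_end=a[1], b_start=b[0], b_end=b[1],
                orientation=orientation, length=h.aligned_length,
                identity=h.identity,
            )
        )
    pairs.sort(key=lambda p: (p.a_start, p.b_start))
    summary = summarize_repeats(pairs)
    return pairs, summary


def summarize_repeats(pairs: Sequence[RepeatPair]) -> RepeatSummary:
    intervals = [(p.a_start, p.a_end) for p in pairs] + [
        (p.b_start, p.b_end) for p in pairs
    ]
    return RepeatSummary(
        repeat_size_bp=union_length(intervals),
        n_over_1kb=sum(p.length > 1000 for p in pairs),
        n_over_100bp=sum(p.length > 100 for p in pairs),
    )


#: default gates for library matching: shorter and more divergent hits count
#: than for transfer detection, since library elements are family consensi.
LIBRARY_MATCH_PARAMS = SearchParams(
    evalue_max=1e-5, min_identity=0.80, min_length=50, word_size=11
)


def classify_repeat_segments(
    segments: Sequence[TransferSegment],
    library: Sequence[RepeatLibraryEntry],
    params: SearchParams | None = None,
) -> tuple[list[RepeatClassAssignment], dict[str, int]]:
    """Assign each transferred segment to the repeat class of its best library hit.

    Best hit = highest raw score; ties broken by (higher identity, longer
    aligned length, class name lexicographic).  Segments with no hit get
    class ``unspecified`` with the unassigned flag set.  Also returns total
    recipient bp per class over all segments.
    """
    if not library:
        raise ValueError("repeat library must be non-empty")
    params = params or LIBRARY_MATCH_PARAMS
    assignments: list[RepeatClassAssignment] = []
    per_class_bp: dict[str, int] = {c.value: 0 for c in RepeatClass}
    for seg in segments:
        if not seg.sequence:
            raise ValueError(f"segment {seg.segment_id}: no sequence attached")
        best: Optional[tuple] = None
        for entry in library:
            for h in find_hsps(
                seg.sequence, entry.sequence, params,
                query_id=seg.segment_id, target_id=entry.repeat_id,
            ):
                key = (h.raw_score, h.identity, h.aligned_length)
                if (
                    best is None
                    or key > best[0]
                    or (key == best[0] and entry.repeat_class.value < best[1].value)
                ):
                    best = (key, entry.repeat_class, h)
        if best is None:
            assignments.append(
                RepeatClassAssignment(seg, RepeatClass.UNSPECIFIED, 0.0, True)
            )
            cls = RepeatClass.UNSPECIFIED
        else:
            cls = best[1]
            assignments.append(RepeatClassAssignment(seg, cls, best[2].identity, False))
        per_class_bp[cls.value] += seg.hsp.t_end - seg.hsp.t_start
    return assignments, per_class_bp
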