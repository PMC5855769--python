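"""Half-open interval helpers used across the pipeline."""

from __future__ import annotations

from typing import Iterable, Sequence


def merge_intervals(intervals: Iterable[Sequence[int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent 0-based half-open intervals; returns sorted list."""
    ivs = sorted((int(a), int(b)) for a, b in intervals)
    merged: list[tuple[int, int]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def union_length(intervals: Iterable[Sequence[int]]) -> int:
    """Total bp covered by the union of half-open intervals (overlaps counted once)."""
    return sum(b - a for a, b in merge_intervals(intervals))
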