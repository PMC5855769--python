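"""Insertion-breakpoint flanks, 1-4 bp micro-homology calls, and cross-species
conserved junction motifs.

Each insertion has two junctions (left and right of the insert in recipient
coordinates).  A micro-homology is the longest exact overlap (up to 4 bp by
default) between the recipient flank boundary and the insert edge boundary at
the fusion point; a junction with no overlap is called blunt-end repair.
Everything here is deterministic string arithmetic on the recipient strand:
the physical fusion only exists on that strand, so flanks and insert edges
are stored in recipient orientation (a helper exposes the donor-oriented
edge for minus-strand inserts).

Because a blunt junction can show a 1 bp overlap by chance (p ~ 1/4 per
side), reports carry the motif and its length, not only the binary call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Optional, Sequence

import logging

from .genome_io import Genome, reverse_complement
from .homology_search import TransferSegment

logger = logging.getLogger(__name__)

DEFAULT_FLANK_BP = 20
DEFAULT_MAX_MICROHOMOLOGY = 4


class RepairCall(str, Enum):
    MICROHOMOLOGY = "microhomology"
    BLUNT_END = "blunt_end"


@dataclass
class JunctionContext:
    """Flank sequences around one side of one insertion breakpoint.

    ``recipient_flank`` is recipient-native sequence adjacent to the insert;
    ``insert_edge`` is the terminal inserted sequence, both read on the
    recipient forward strand so that for a left junction the physical fusion
    reads flank + edge and for a right junction edge + flank.
    """

    species_id: str
    side: str                      # "left" | "right"
    recipient_flank: str
    insert_edge: str
    segment: Optional[TransferSegment] = None
    insert_strand: str = "+"
    microhomology: str = ""
    repair_call: Optional[RepairCall] = None
    truncated_flank: bool = False

    def donor_oriented_edge(self) -> str:
        return self.insert_edge if self.insert_strand == "+" else reverse_complement(self.insert_edge)


@dataclass
class CrossSpeciesJunctionReport:
    locus_id: str
    species_groups: Mapping[str, Sequence[str]]
    conserved_left: Mapping[str, str]
    conserved_right: Mapping[str, str]
    contexts: Mapping[str, Mapping[str, tuple]] = field(default_factory=dict)


def junctions_from_coords(
    recipient_seq: str,
    start: int,
    end: int,
    species_id: str = "",
    flank_bp: int = DEFAULT_FLANK_BP,
    segment: TransferSegment | None = None,
    insert_strand: str = "+",
) -> tuple[JunctionContext, JunctionContext]:
    """Left/right junction contexts for an insert occupying [start, end)."""
    if flank_bp < 4:
        raise ValueError("flank_bp must be >= 4")
    if not (0 <= start < end <= len(recipient_seq)):
        raise ValueError("insert interval must lie inside the recipient")
    left_flank = recipient_seq[max(0, start - flank_bp):start]
    right_flank = recipient_seq[end:end + flank_bp]
    insert = recipient_seq[start:end]
    left = JunctionContext(
        species_id=species_id,
        side="left",
        recipient_flank=left_flank,
        insert_edge=insert[:flank_bp],
        segment=segment,
        insert_strand=insert_strand,
        truncated_flank=len(left_flank) < flank_bp,
    )
    right = JunctionContext(
        species_id=species_id,
        side="right",
        recipient_flank=right_flank,
        insert_edge=insert[-flank_bp:],
        segment=segment,
        insert_strand=insert_strand,
        truncated_flank=len(right_flank) < flank_bp,
    )
    if left.truncated_flank or right.truncated_flank:
        logger.warning(
            "insert at %d..%d within flank_bp of a contig end; shorter flank returned",
            start, end,
        )
    return left, right


def extract_junctions(
    segment: TransferSegment,
    recipient: Genome,
    donor: Genome | None = None,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> tuple[JunctionContext, JunctionContext]:
    """Junction contexts around a detected transfer segment's recipient interval."""
    h = segment.hsp
    return junctions_from_coords(
        recipient.sequence,
        h.t_start,
        h.t_end,
        species_id=segment.species_id,
        flank_bp=flank_bp,
        segment=segment,
        insert_strand=h.strand,
    )


def _boundary_overlap(ctx: JunctionContext, k: int) -> Optional[str]:
    """The k-bp fusion-point overlap string if flank and edge agree at k, else None."""
    flank, edge = ctx.recipient_flank, ctx.insert_edge
    if k > len(flank) or k > len(edge):
        return None
    if ctx.side == "left":
        # ...flank | insert... : flank suffix vs insert prefix
        return flank[-k:] if flank[-k:] == edge[:k] else None
    # ...insert | flank... : insert suffix vs flank prefix
    return edge[-k:] if edge[-k:] == flank[:k] else None


def call_microhomology(
    ctx: JunctionContext, max_len: int = DEFAULT_MAX_MICROHOMOLOGY
) -> JunctionContext:
    """Longest exact fusion-point overlap (capped at ``max_len``) and the repair call."""
    motif = ""
    for k in range(max_len, 0, -1):
        s = _boundary_overlap(ctx, k)
        if s is not None:
            motif = s
            break
    return replace(
        ctx,
        microhomology=motif,
        repair_call=RepairCall.MICROHOMOLOGY if motif else RepairCall.BLUNT_END,
    )


def cross_species_report(
    locus_id: str,
    groups: Mapping[str, Mapping[str, tuple[JunctionContext, JunctionContext]]],
    max_len: int = DEFAULT_MAX_MICROHOMOLOGY,
) -> CrossSpeciesJunctionReport:
    """Per-group conserved fusion-boundary motifs across species.

    ``groups`` maps a group label (e.g. ``eudicots``) to {species: (left, right)}.
    For each side the longest string (<= ``max_len``) that is a fusion-point
    overlap in EVERY member, and identical across members, is reported;
    groups with none report the empty string.  Singleton groups are excluded
    with a warning.
    """
    conserved_left: dict[str, str] = {}
    conserved_right: dict[str, str] = {}
    kept_groups: dict[str, list[str]] = {}
    for label, members in groups.items():
        if len(members) < 2:
            logger.warning("group %s has < 2 species; excluded", label)
            continue
        kept_groups[label] = sorted(members)
        for side_idx, out in ((0, conserved_left), (1, conserved_right)):
            motif = ""
            for k in range(max_len, 0, -1):
                strings = {
                    _boundary_overlap(ctxs[side_idx], k) for ctxs in members.values()
                }
                if None not in strings and len(strings) == 1:
                    motif = strings.pop()
                    break
            out[label] = motif
    return CrossSpeciesJunctionReport(
        locus_id=locus_id,
        species_groups=kept_groups,
        conserved_left=conserved_left,
        conserved_right=conserved_right,
        contexts=groups,
    )


def junction_table(contexts: Sequence[JunctionContext]):
    """Tabular (pandas) report: species, side, flanks, motif, call."""
    import pandas as pd

    return pd.DataFrame(
        {
            "species_id": [c.species_id for c in contexts],
            "side": [c.side for c in contexts],
            "recipient_flank": [c.recipient_flank for c in contexts],
            "insert_edge": [c.insert_edge for c in contexts],
            "microhomology": [c.microhomology for c in contexts],
            "repair_call": [c.repair_call.value if c.repair_call else "" for c in contexts],
        }
    )
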