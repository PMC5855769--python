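"""On-disk artifacts: genomes, gene tables, repeat libraries, transfer-segment BED.

Conventions
-----------
Internal coordinates are 0-based half-open everywhere.  On-disk tables are
1-based inclusive, except BED which keeps its native 0-based half-open form.
Sequences are normalised to uppercase over {A, C, G, T, N}: lowercase is
uppercased, U becomes T, and any other symbol becomes N (counted per record).
N never counts as a match in downstream identity computations.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID = frozenset("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Compartment(str, Enum):
    NUCLEAR = "nuclear"
    MITOCHONDRIAL = "mitochondrial"
    CHLOROPLAST = "chloroplast"


class RepeatClass(str, Enum):
    COPIA = "copia"
    GYPSY = "gypsy"
    LOW_COMPLEXITY = "low_complexity"
    LTR_RETRO = "ltr_retro"
    SIMPLE_REPEAT = "simple_repeat"
    TE = "te"
    UNSPECIFIED = "unspecified"


def normalize_sequence(raw: str) -> tuple[str, int]:
    """Uppercase, U->T, anything outside {A,C,G,T,N} -> N.

    Returns (sequence, count of symbols replaced by N).
    """
    seq = raw.upper().replace("U", "T")
    n_bad = len(seq) - sum(seq.count(c) for c in _VALID)
    if n_bad:
        seq = _NON_ACGTN.sub("N", seq)
    return seq, n_bad


@dataclass
class Genome:
    """One sequence compartment (nuclear/mitochondrial/chloroplast) of one species."""

    species_id: str
    compartment: Compartment
    sequence: str
    record_id: str = ""
    n_ambiguous: int = 0

    def __post_init__(self) -> None:
        self.compartment = Compartment(self.compartment)
        if not self.record_id:
            self.record_id = f"{self.species_id}_{self.compartment.value}"
        if not set(self.sequence) <= _VALID:
            raise ValueError(
                f"genome {self.record_id}: sequence contains symbols outside ACGTN"
            )

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """Reference gene on its host compartment; 0-based half-open internally."""

    gene_id: str
    compartment: Compartment
    start: int
    end: int
    strand: str = "+"
    functional_category: str = ""

    def __post_init__(self) -> None:
        self.compartment = Compartment(self.compartment)
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: need 0 <= start < end")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass
class RepeatLibraryEntry:
    repeat_id: str
    repeat_class: RepeatClass
    sequence: str

    def __post_init__(self) -> None:
        self.repeat_class = RepeatClass(self.repeat_class)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _parse_description(desc: str) -> dict[str, str]:
    return dict(
        tok.split("=", 1) for tok in desc.split() if "=" in tok and not tok.startswith("=")
    )


def read_fasta(
    path: str | Path,
    species_id: str | None = None,
    compartment: Compartment | str | None = None,
) -> list[Genome]:
    """Read a multi-FASTA into Genomes, order preserved.

    ``species=`` / ``compartment=`` tokens in the description override the
    arguments; records lacking both fall back to the record id and ``nuclear``.
    Duplicate record ids and empty files are hard errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty FASTA file")
    seen: set[str] = set()
    genomes: list[Genome] = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq, n_bad = normalize_sequence(str(rec.seq))
        if n_bad:
            logger.warning(
                "%s: record %s: %d ambiguous symbol(s) replaced by N", path, rec.id, n_bad
            )
        tokens = _parse_description(rec.description)
        genomes.append(
            Genome(
                species_id=tokens.get("species", species_id or rec.id),
                compartment=Compartment(
                    tokens.get("compartment", compartment or Compartment.NUCLEAR)
                ),
                sequence=seq,
                record_id=rec.id,
                n_ambiguous=n_bad,
            )
        )
    return genomes


def write_fasta(genomes: Iterable[Genome], path: str | Path) -> None:
    records = [
        SeqRecord(
            Seq(g.sequence),
            id=g.record_id,
            description=f"species={g.species_id} compartment={g.compartment.value}",
        )
        for g in genomes
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Gene tables (TSV, 1-based inclusive on disk) and GFF3
# ---------------------------------------------------------------------------

_GENE_COLUMNS = ("gene_id", "compartment", "start", "end", "strand", "category")


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Tab-delimited gene table -> GeneModels (0-based half-open internally).

    On-disk columns: gene_id, compartment, start, end, strand, category with
    1-based inclusive coordinates.  Bad rows raise with their row number.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for row_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if row_no == 1 and parts[0] == "gene_id":
                continue
            if len(parts) < 6:
                raise ValueError(f"{path}: row {row_no}: expected 6 columns")
            gene_id, comp, start_s, end_s, strand, category = parts[:6]
            try:
                comp_e = Compartment(comp)
            except ValueError:
                raise ValueError(
                    f"{path}: row {row_no}: unknown compartment {comp!r}"
                ) from None
            start1, end1 = int(start_s), int(end_s)
            if start1 < 1 or end1 < start1:
                raise ValueError(
                    f"{path}: row {row_no}: bad coordinates {start1}..{end1}"
                )
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    compartment=comp_e,
                    start=start1 - 1,
                    end=end1,
                    strand=strand,
                    functional_category=category,
                )
            )
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.compartment.value}\t{g.start + 1}\t{g.end}\t"
                f"{g.strand}\t{g.functional_category}\n"
            )


def read_gff3_genes(path: str | Path, compartment: Compartment | str = Compartment.MITOCHONDRIAL) -> list[GeneModel]:
    """GFF3 alternative annotation input; only ID, coordinates and strand are consumed."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                compartment=Compartment(compartment),
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
            )
        )
    return genes


# ---------------------------------------------------------------------------
# Repeat library FASTA (class carried as a ``class=`` header token)
# ---------------------------------------------------------------------------

def read_repeat_library(path: str | Path) -> list[RepeatLibraryEntry]:
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = _parse_description(rec.description)
        seq, _ = normalize_sequence(str(rec.seq))
        entries.append(
            RepeatLibraryEntry(
                repeat_id=rec.id,
                repeat_class=RepeatClass(tokens.get("class", "unspecified")),
                sequence=seq,
            )
        )
    return entries


def write_repeat_library(entries: Iterable[RepeatLibraryEntry], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(e.sequence), id=e.repeat_id, description=f"class={e.repeat_class.value}")
        for e in entries
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Transfer-segment BED (BED6 core + extra columns so the round trip is lossless)
# ---------------------------------------------------------------------------

_BED_HEADER = (
    "#chrom\tstart\tend\tname\tscore\tstrand\tspecies_id\tdonor_compartment\t"
    "recipient_compartment\tsegment_class\tquery_id\tq_start\tq_end\t"
    "aligned_length\tmatches\traw_score\tevalue"
)


def write_segments_bed(segments: Sequence, path: str | Path) -> None:
    """BED6 (+ extra columns) for transfer segments.

    Core BED columns: recipient record, 0-based half-open interval, name
    ``<donor compartment>:<segment id>``, score = round(10 x identity%), strand.
    """
    with open(path, "w") as fh:
        fh.write(_BED_HEADER + "\n")
        for seg in segments:
            h = seg.hsp
            score = int(round(h.identity * 1000))
            fh.write(
                f"{h.target_id}\t{h.t_start}\t{h.t_end}\t"
                f"{seg.donor_compartment.value}:{seg.segment_id}\t{score}\t{h.strand}\t"
                f"{seg.species_id}\t{seg.donor_compartment.value}\t"
                f"{seg.recipient_compartment.value}\t{seg.segment_class.value}\t"
                f"{h.query_id}\t{h.q_start}\t{h.q_end}\t"
                f"{h.aligned_length}\t{h.matches}\t{h.raw_score}\t{h.evalue:.6g}\n"
            )


def read_segments_bed(path: str | Path) -> list:
    from .homology_search import HSP, SegmentClass, TransferSegment

    segments = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            (
                chrom, start, end, name, _score, strand, species, donor, recip,
                seg_class, query_id, q_start, q_end, aln_len, matches, raw_score,
                evalue,
            ) = line.split("\t")
            hsp = HSP(
                query_id=query_id,
                target_id=chrom,
                q_start=int(q_start),
                q_end=int(q_end),
                t_start=int(start),
                t_end=int(end),
                strand=strand,
                aligned_length=int(aln_len),
                matches=int(matches),
                raw_score=int(raw_score),
                evalue=float(evalue),
            )
            segments.append(
                TransferSegment(
                    donor_compartment=Compartment(donor),
                    recipient_compartment=Compartment(recip),
                    species_id=species,
                    hsp=hsp,
                    segment_class=SegmentClass(seg_class),
                    segment_id=name.split(":", 1)[1],
                )
            )
    return segments
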