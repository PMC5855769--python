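"""Synthetic genome trios with planted intergenomic transfers and ground truth.

One :class:`SimConfig` describes a species trio: i.i.d. background sequence at
a configurable GC content; a reference organellar gene set embedded in the
mitogenome; planted repeat duplications inside the mitogenome; and planted
transfer events (mt->nuc numts, cp->mt mtpts, mt->cp inserts, plus nuclear
gene copies that are intact or truncated).  Every planted feature is emitted
as a :class:`TruthRecord` with final-genome coordinates, so detection and
classification can be scored against known truth.

Planting mechanics
------------------
* Transfers copy a donor-core interval, erode identity with i.i.d.
  substitutions at the configured rate (an indel-rate option exists, default
  0 so alignment oracles stay simple), optionally reverse-complement the
  insert, then write the configured junction micro-homology by rewriting the
  recipient flank to match the insert edge (donor sequence stays a pristine
  reference).
* Donor coordinates are drawn on the pre-insertion "core" of each compartment
  and remapped to final coordinates, and insertion points avoid embedded
  genes and each other by a margin, so planted features never collide.
* Same seed + config => byte-identical genomes and truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    Compartment,
    GeneModel,
    Genome,
    RepeatClass,
    RepeatLibraryEntry,
    reverse_complement,
    write_fasta,
)

_BASES = np.array(list("ACGT"))

#: standard plant mitochondrial genes used as the default reference set.
#: This is a documented stand-in list (synthetic sequences are generated per
#: seed); supply your own (GeneModel, sequence) pairs to replace it.
_DEFAULT_GENE_NAMES: list[tuple[str, str]] = [
    ("nad1", "complex I"), ("nad2", "complex I"), ("nad3", "complex I"),
    ("nad4", "complex I"), ("nad4L", "complex I"), ("nad5", "complex I"),
    ("nad6", "complex I"), ("nad7", "complex I"), ("nad9", "complex I"),
    ("sdh3", "complex II"), ("sdh4", "complex II"),
    ("cob", "complex III"),
    ("cox1", "complex IV"), ("cox2", "complex IV"), ("cox3", "complex IV"),
    ("atp1", "complex V"), ("atp4", "complex V"), ("atp6", "complex V"),
    ("atp8", "complex V"), ("atp9", "complex V"),
    ("ccmB", "cytochrome c maturation"), ("ccmC", "cytochrome c maturation"),
    ("ccmFc", "cytochrome c maturation"), ("ccmFn", "cytochrome c maturation"),
    ("rpl2", "ribosomal subunit"), ("rpl5", "ribosomal subunit"),
    ("rpl16", "ribosomal subunit"), ("rps1", "ribosomal subunit"),
    ("rps3", "ribosomal subunit"), ("rps4", "ribosomal subunit"),
    ("rps7", "ribosomal subunit"), ("rps12", "ribosomal subunit"),
    ("matR", "maturase"), ("mttB", "transport"),
]


@dataclass
class SimConfig:
    seed: int = 0
    species_id: str = "sim01"
    nuclear_len: int = 90_000
    mt_len: int = 45_000
    cp_len: int = 20_000
    n_numts: int = 10
    n_mtpts: int = 10
    n_mt_to_cp: int = 0
    transfer_len_bounds: tuple[int, int] = (150, 3000)   # log-uniform draw
    identity_erosion: float = 0.02        # substitutions per bp
    indel_rate: float = 0.0               # indels per bp (default off)
    microhomology_probs: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)  # len 0..4
    junction_motif_left: Optional[str] = None    # force this left motif on transfers
    junction_motif_right: Optional[str] = None
    inverted_fraction: float = 0.3        # fraction of inserts planted on - strand
    n_genes: int = 24
    gene_lost_fraction: float = 0.15
    gene_transfer_fraction: float = 0.6   # of non-lost genes, get a nuclear copy
    pseudogenize_fraction: float = 0.5    # of planted gene copies, truncated
    truncation_fraction_range: tuple[float, float] = (0.3, 0.7)  # fraction removed
    repeat_plants: tuple[tuple[int, int], ...] = ((1500, 1), (300, 2), (150, 2))
    gene_set: Optional[Sequence[tuple[GeneModel, str]]] = None
    gc_content: float = 0.44
    flank_margin: int = 60                # min clearance around insertion points

    def __post_init__(self) -> None:
        for name in ("nuclear_len", "mt_len", "cp_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "identity_erosion", "indel_rate", "gene_lost_fraction",
            "gene_transfer_fraction", "pseudogenize_fraction", "gc_content",
            "inverted_fraction",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(sum(self.microhomology_probs) - 1) > 1e-9 or len(self.microhomology_probs) != 5:
            raise ValueError("microhomology_probs must be 5 probabilities summing to 1")


@dataclass
class TruthRecord:
    """One planted feature, with final-genome coordinates."""

    event_id: str
    event_type: str            # numt | nupt | mtpt | mt_to_cp | repeat | gene_copy
    species_id: str
    donor_compartment: str
    recipient_compartment: str
    donor_start: int
    donor_end: int
    recipient_record: str
    recipient_start: int
    recipient_end: int
    planted_identity: float
    microhomology_left: str = ""
    microhomology_right: str = ""
    orientation: str = "+"
    truncated: bool = False
    truncation_coverage: float = 1.0
    gene_id: str = ""
    planted_state: str = ""

    @property
    def microhomology(self) -> str:
        return self.microhomology_left


@dataclass
class TrioResult:
    config: SimConfig
    nuclear: Genome
    mitochondrial: Genome
    chloroplast: Genome
    truth: list[TruthRecord]
    gene_set: list[tuple[GeneModel, str]]
    gene_states: dict[str, str]

    def genomes(self) -> dict[Compartment, Genome]:
        return {
            Compartment.NUCLEAR: self.nuclear,
            Compartment.MITOCHONDRIAL: self.mitochondrial,
            Compartment.CHLOROPLAST: self.chloroplast,
        }


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _erode(rng: np.random.Generator, seq: str, sub_rate: float, indel_rate: float = 0.0):
    """Substitute (and optionally indel) bases; returns (sequence, identity)."""
    arr = np.array(list(seq))
    n = len(arr)
    sub_mask = rng.random(n) < sub_rate
    for i in np.nonzero(sub_mask)[0]:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    out = list(arr)
    n_indels = 0
    if indel_rate > 0:
        pos = np.nonzero(rng.random(n) < indel_rate)[0]
        for i in sorted(pos, reverse=True):
            n_indels += 1
            if rng.random() < 0.5 and len(out) > 1:
                del out[i]
            else:
                out.insert(i, str(_BASES[rng.integers(4)]))
    identity = 1.0 - (int(sub_mask.sum()) + n_indels) / n
    return "".join(out), max(identity, 0.0)


def _pick_free_interval(
    rng: np.random.Generator, length: int, host_len: int,
    occupied: list[tuple[int, int]], margin: int, max_tries: int = 2000,
) -> tuple[int, int]:
    for _ in range(max_tries):
        start = int(rng.integers(margin, host_len - length - margin))
        iv = (start - margin, start + length + margin)
        if all(iv[1] <= a or iv[0] >= b for a, b in occupied):
            occupied.append((start, start + length))
            return start, start + length
    raise RuntimeError("could not place interval; genome too crowded")


@dataclass
class _InsertSpec:
    seq: str
    mh_left: int
    mh_right: int
    motif_left: Optional[str]
    motif_right: Optional[str]
    meta: dict


def _plant_insertions(
    rng: np.random.Generator,
    background: str,
    inserts: list[_InsertSpec],
    margin: int,
) -> tuple[str, list[tuple[int, int, _InsertSpec]]]:
    """Insert sequences at random well-separated points, writing micro-homologies.

    Returns the final sequence and, per insert, its final half-open interval.
    The recipient flank is rewritten to match the insert edge (or forced
    motifs rewrite both edge and flank), so the donor copy stays pristine.
    """
    total = sum(len(s.seq) for s in inserts)
    if total > 0.5 * len(background):
        raise ValueError(
            f"requested plants ({total} bp) exceed 50% of host ({len(background)} bp)"
        )
    occupied: list[tuple[int, int]] = []
    points = []
    for spec in inserts:
        p, _ = _pick_free_interval(rng, 1, len(background), occupied, margin)
        points.append((p, spec))
    points.sort(key=lambda t: t[0])
    bg = list(background)
    for p, spec in points:
        seq = spec.seq
        if spec.motif_left:
            seq = spec.motif_left + seq[len(spec.motif_left):]
            spec.mh_left = len(spec.motif_left)
        if spec.motif_right:
            seq = seq[: len(seq) - len(spec.motif_right)] + spec.motif_right
            spec.mh_right = len(spec.motif_right)
        spec.seq = seq
        if spec.mh_left:
            bg[p - spec.mh_left: p] = list(seq[: spec.mh_left])
        if spec.mh_right:
            bg[p: p + spec.mh_right] = list(seq[len(seq) - spec.mh_right:])
    final_parts = []
    placed = []
    cursor = 0
    offset = 0
    for p, spec in points:
        final_parts.append("".join(bg[cursor:p]))
        start = p + offset
        final_parts.append(spec.seq)
        placed.append((start, start + len(spec.seq), spec))
        offset += len(spec.seq)
        cursor = p
    final_parts.append("".join(bg[cursor:]))
    return "".join(final_parts), placed


def _offset_map(points_lens: list[tuple[int, int]]):
    """Core-coordinate -> final-coordinate map for a set of insertions."""
    pts = sorted(points_lens)

    def remap(x: int) -> int:
        return x + sum(ln for p, ln in pts if p <= x)

    return remap


# ---------------------------------------------------------------------------
# gene set and library
# ---------------------------------------------------------------------------

def default_gene_set(
    rng: np.random.Generator, n_genes: int = 24, gc: float = 0.44
) -> list[tuple[GeneModel, str]]:
    """Synthetic reference sequences for standard plant mitochondrial genes."""
    names = _DEFAULT_GENE_NAMES[:n_genes]
    out = []
    for name, category in names:
        length = int(rng.integers(300, 1501))
        seq = _random_seq(rng, length, gc)
        out.append(
            (
                GeneModel(
                    gene_id=name,
                    compartment=Compartment.MITOCHONDRIAL,
                    start=0,
                    end=length,
                    strand="+",
                    functional_category=category,
                ),
                seq,
            )
        )
    return out


def make_repeat_library(
    seed: int = 0, n_per_class: int = 2, element_len: int = 400, gc: float = 0.44
) -> list[RepeatLibraryEntry]:
    """Synthetic labelled repeat elements, one construction style per class.

    copia/gypsy/ltr_retro carry 80 bp terminal direct repeats (LTR-like);
    te carries 30 bp terminal inverted repeats; low_complexity is a skewed
    two-letter draw; simple_repeat is a short tandem; unspecified is plain
    random sequence.
    """
    rng = np.random.default_rng(seed)
    entries: list[RepeatLibraryEntry] = []
    for cls in RepeatClass:
        for i in range(n_per_class):
            rid = f"{cls.value}_{i}"
            if cls in (RepeatClass.COPIA, RepeatClass.GYPSY, RepeatClass.LTR_RETRO):
                ltr = _random_seq(rng, 80, gc)
                body = _random_seq(rng, max(element_len - 160, 40), gc)
                seq = ltr + body + ltr
            elif cls is RepeatClass.TE:
                tir = _random_seq(rng, 30, gc)
                body = _random_seq(rng, max(element_len - 60, 40), gc)
                seq = tir + body + reverse_complement(tir)
            elif cls is RepeatClass.LOW_COMPLEXITY:
                pair = ["AT", "GC", "AG", "CT"][i % 4]
                draws = rng.choice(2, size=element_len, p=[0.9, 0.1])
                seq = "".join(pair[d] for d in draws)
            elif cls is RepeatClass.SIMPLE_REPEAT:
                unit = _random_seq(rng, int(rng.integers(2, 7)), gc)
                seq = (unit * (element_len // len(unit) + 1))[:element_len]
            else:
                seq = _random_seq(rng, element_len, gc)
            entries.append(RepeatLibraryEntry(rid, cls, seq))
    return entries


# ---------------------------------------------------------------------------
# trio generation
# ---------------------------------------------------------------------------

def _draw_len(rng: np.random.Generator, bounds: tuple[int, int]) -> int:
    lo, hi = bounds
    return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))


def generate_trio(config: SimConfig) -> TrioResult:
    """Build one species trio with planted transfers, repeats and gene copies."""
    rng = np.random.default_rng(config.seed)
    sp = config.species_id
    mh_lens = np.arange(5)

    gene_set = list(config.gene_set) if config.gene_set is not None else default_gene_set(
        rng, config.n_genes, config.gc_content
    )

    # --- per-gene fate plan -------------------------------------------------
    gene_states: dict[str, str] = {}
    for gene, _seq in gene_set:
        if rng.random() < config.gene_lost_fraction:
            gene_states[gene.gene_id] = "lost"
        elif rng.random() >= config.gene_transfer_fraction:
            gene_states[gene.gene_id] = "not_transferred"
        elif rng.random() < config.pseudogenize_fraction:
            gene_states[gene.gene_id] = "pseudogene"
        else:
            gene_states[gene.gene_id] = "intact_homolog"

    # --- mitochondrial core: background + genes + repeat duplications -------
    mt_core = list(_random_seq(rng, config.mt_len, config.gc_content))
    occupied_mt: list[tuple[int, int]] = []
    mt_gene_coords: dict[str, tuple[int, int]] = {}
    placed_genes: list[tuple[GeneModel, str]] = []
    for gene, seq in gene_set:
        if gene_states[gene.gene_id] == "lost":
            continue
        s, e = _pick_free_interval(
            rng, len(seq), len(mt_core), occupied_mt, config.flank_margin
        )
        mt_core[s:e] = list(seq)
        mt_gene_coords[gene.gene_id] = (s, e)
        placed_genes.append((replace(gene, start=s, end=e), seq))

    truth: list[TruthRecord] = []
    eid = 0

    def next_id(kind: str) -> str:
        nonlocal eid
        eid += 1
        return f"{sp}_{kind}_{eid:04d}"

    repeat_core_coords: list[tuple[int, int, int, int, str]] = []
    for length, count in config.repeat_plants:
        for _ in range(count):
            a0, a1 = _pick_free_interval(
                rng, length, len(mt_core), occupied_mt, config.flank_margin
            )
            b0, b1 = _pick_free_interval(
                rng, length, len(mt_core), occupied_mt, config.flank_margin
            )
            inverted = rng.random() < config.inverted_fraction
            src = "".join(mt_core[a0:a1])
            mt_core[b0:b1] = list(reverse_complement(src) if inverted else src)
            repeat_core_coords.append((a0, a1, b0, b1, "-" if inverted else "+"))

    cp_core = _random_seq(rng, config.cp_len, config.gc_content)
    mt_core_str = "".join(mt_core)

    # --- plant mtpts (cp -> mt) ---------------------------------------------
    def build_transfer(donor_core: str, kind: str):
        length = _draw_len(rng, config.transfer_len_bounds)
        length = min(length, len(donor_core) - 2 * config.flank_margin)
        d0 = int(rng.integers(0, len(donor_core) - length))
        d1 = d0 + length
        seq, identity = _erode(
            rng, donor_core[d0:d1], config.identity_erosion, config.indel_rate
        )
        strand = "-" if rng.random() < config.inverted_fraction else "+"
        if strand == "-":
            seq = reverse_complement(seq)
        mh_l = int(rng.choice(mh_lens, p=config.microhomology_probs))
        mh_r = int(rng.choice(mh_lens, p=config.microhomology_probs))
        spec = _InsertSpec(
            seq=seq, mh_left=mh_l, mh_right=mh_r,
            motif_left=config.junction_motif_left,
            motif_right=config.junction_motif_right,
            meta=dict(kind=kind, d0=d0, d1=d1, identity=identity, strand=strand),
        )
        return spec

    mtpt_specs = [build_transfer(cp_core, "mtpt") for _ in range(config.n_mtpts)]
    mt_final_str, mtpt_placed = _plant_insertions(
        rng, mt_core_str, mtpt_specs, config.flank_margin
    )
    # core insertion points (pre-insertion coordinates) for the remap
    mt_points_lens = []
    shift = 0
    for start, end, spec in sorted(mtpt_placed, key=lambda t: t[0]):
        core_point = start - shift
        mt_points_lens.append((core_point, len(spec.seq)))
        shift += len(spec.seq)
    mt_remap = _offset_map(mt_points_lens)

    for start, end, spec in mtpt_placed:
        m = spec.meta
        truth.append(
            TruthRecord(
                event_id=next_id("mtpt"), event_type="mtpt", species_id=sp,
                donor_compartment="chloroplast", recipient_compartment="mitochondrial",
                donor_start=m["d0"], donor_end=m["d1"],
                recipient_record=f"{sp}_mitochondrial",
                recipient_start=start, recipient_end=end,
                planted_identity=m["identity"],
                microhomology_left=spec.seq[: spec.mh_left],
                microhomology_right=spec.seq[len(spec.seq) - spec.mh_right:] if spec.mh_right else "",
                orientation=m["strand"],
            )
        )

    # remap gene and repeat coordinates into the final mitogenome
    mt_genes_final = [
        (replace(g, start=mt_remap(g.start), end=mt_remap(g.start) + (g.end - g.start)), seq)
        for g, seq in placed_genes
    ]
    for a0, a1, b0, b1, orient in repeat_core_coords:
        truth.append(
            TruthRecord(
                event_id=next_id("repeat"), event_type="repeat", species_id=sp,
                donor_compartment="mitochondrial", recipient_compartment="mitochondrial",
                donor_start=mt_remap(a0), donor_end=mt_remap(a0) + (a1 - a0),
                recipient_record=f"{sp}_mitochondrial",
                recipient_start=mt_remap(b0), recipient_end=mt_remap(b0) + (b1 - b0),
                planted_identity=1.0, orientation=orient,
            )
        )

    # --- plant mt -> cp inserts ---------------------------------------------
    mt_to_cp_specs = [build_transfer(mt_core_str, "mt_to_cp") for _ in range(config.n_mt_to_cp)]
    cp_final_str, cp_placed = _plant_insertions(
        rng, cp_core, mt_to_cp_specs, config.flank_margin
    )
    for start, end, spec in cp_placed:
        m = spec.meta
        truth.append(
            TruthRecord(
                event_id=next_id("mt_to_cp"), event_type="mt_to_cp", species_id=sp,
                donor_compartment="mitochondrial", recipient_compartment="chloroplast",
                donor_start=mt_remap(m["d0"]), donor_end=mt_remap(m["d0"]) + (m["d1"] - m["d0"]),
                recipient_record=f"{sp}_chloroplast",
                recipient_start=start, recipient_end=end,
                planted_identity=m["identity"],
                microhomology_left=spec.seq[: spec.mh_left],
                microhomology_right=spec.seq[len(spec.seq) - spec.mh_right:] if spec.mh_right else "",
                orientation=m["strand"],
            )
        )

    # --- numts and nuclear gene copies --------------------------------------
    # numt donors are drawn on the mt core so they stay contiguous in the
    # final mitogenome (insertion points never split them: donors must not
    # contain an mtpt insertion point)
    numt_specs = []
    for _ in range(config.n_numts):
        for _try in range(200):
            length = _draw_len(rng, config.transfer_len_bounds)
            length = min(length, len(mt_core_str) - 2 * config.flank_margin)
            d0 = int(rng.integers(0, len(mt_core_str) - length))
            d1 = d0 + length
            if all(not (d0 < p < d1) for p, _ln in mt_points_lens):
                break
        seq, identity = _erode(
            rng, mt_core_str[d0:d1], config.identity_erosion, config.indel_rate
        )
        strand = "-" if rng.random() < config.inverted_fraction else "+"
        if strand == "-":
            seq = reverse_complement(seq)
        mh_l = int(rng.choice(mh_lens, p=config.microhomology_probs))
        mh_r = int(rng.choice(mh_lens, p=config.microhomology_probs))
        numt_specs.append(
            _InsertSpec(
                seq=seq, mh_left=mh_l, mh_right=mh_r,
                motif_left=config.junction_motif_left,
                motif_right=config.junction_motif_right,
                meta=dict(kind="numt", d0=d0, d1=d1, identity=identity, strand=strand),
            )
        )

    gene_copy_specs = []
    for gene, seq in gene_set:
        state = gene_states[gene.gene_id]
        if state not in ("pseudogene", "intact_homolog"):
            continue
        if state == "pseudogene":
            lo, hi = config.truncation_fraction_range
            frac_removed = float(rng.uniform(lo, hi))
            keep = max(int(round(len(seq) * (1 - frac_removed))), 30)
            copy = seq[:keep]
            coverage = keep / len(seq)
        else:
            copy = seq
            coverage = 1.0
        copy, identity = _erode(rng, copy, config.identity_erosion, config.indel_rate)
        gene_copy_specs.append(
            _InsertSpec(
                seq=copy, mh_left=0, mh_right=0, motif_left=None, motif_right=None,
                meta=dict(
                    kind="gene_copy", gene_id=gene.gene_id, identity=identity,
                    coverage=coverage, state=state,
                ),
            )
        )

    nuc_bg = _random_seq(rng, config.nuclear_len, config.gc_content)
    nuc_final_str, nuc_placed = _plant_insertions(
        rng, nuc_bg, numt_specs + gene_copy_specs, config.flank_margin
    )
    for start, end, spec in nuc_placed:
        m = spec.meta
        if m["kind"] == "numt":
            truth.append(
                TruthRecord(
                    event_id=next_id("numt"), event_type="numt", species_id=sp,
                    donor_compartment="mitochondrial", recipient_compartment="nuclear",
                    donor_start=mt_remap(m["d0"]), donor_end=mt_remap(m["d0"]) + (m["d1"] - m["d0"]),
                    recipient_record=f"{sp}_nuclear",
                    recipient_start=start, recipient_end=end,
                    planted_identity=m["identity"],
                    microhomology_left=spec.seq[: spec.mh_left],
                    microhomology_right=spec.seq[len(spec.seq) - spec.mh_right:] if spec.mh_right else "",
                    orientation=m["strand"],
                )
            )
        else:
            g0, g1 = mt_gene_coords[m["gene_id"]]
            truth.append(
                TruthRecord(
                    event_id=next_id("gene"), event_type="gene_copy", species_id=sp,
                    donor_compartment="mitochondrial", recipient_compartment="nuclear",
                    donor_start=mt_remap(g0), donor_end=mt_remap(g0) + (end - start),
                    recipient_record=f"{sp}_nuclear",
                    recipient_start=start, recipient_end=end,
                    planted_identity=m["identity"],
                    truncated=m["state"] == "pseudogene",
                    truncation_coverage=m["coverage"],
                    gene_id=m["gene_id"], planted_state=m["state"],
                )
            )

    nuclear = Genome(sp, Compartment.NUCLEAR, nuc_final_str, record_id=f"{sp}_nuclear")
    mitochondrial = Genome(
        sp, Compartment.MITOCHONDRIAL, mt_final_str, record_id=f"{sp}_mitochondrial"
    )
    chloroplast = Genome(
        sp, Compartment.CHLOROPLAST, cp_final_str, record_id=f"{sp}_chloroplast"
    )
    return TrioResult(
        config=config,
        nuclear=nuclear,
        mitochondrial=mitochondrial,
        chloroplast=chloroplast,
        truth=truth,
        gene_set=[(g, s) for g, s in gene_set],
        gene_states=gene_states,
    )


def make_repeat_toy(
    seed: int = 0,
    length: int = 10_000,
    plants: Sequence[tuple[int, int]] = ((1500, 1), (600, 1), (120, 2)),
    inverted_fraction: float = 0.3,
    gc: float = 0.44,
    species_id: str = "toy",
    margin: int = 170,
) -> tuple[Genome, list[tuple[int, int, int, int, str]]]:
    """Small genome with planted exact duplications for repeat-detector checks.

    Each planted pair is exact-copy; the bases flanking the second copy are
    rewritten so they can never extend a detected repeat past the planted
    boundary by chance, and copies are kept well separated so two planted
    features can never merge into one local alignment.  Returns the genome
    and the planted (a_start, a_end, b_start, b_end, orientation) tuples,
    orientation "+" direct / "-" inverted.
    """
    rng = np.random.default_rng(seed)
    bg = list(_random_seq(rng, length, gc))
    occupied: list[tuple[int, int]] = []
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    planted = []
    for size, count in plants:
        for _ in range(count):
            a0, a1 = _pick_free_interval(rng, size, length, occupied, margin=margin)
            b0, b1 = _pick_free_interval(rng, size, length, occupied, margin=margin)
            if b0 < a0:
                a0, a1, b0, b1 = b0, b1, a0, a1
            inverted = rng.random() < inverted_fraction
            src = "".join(bg[a0:a1])
            bg[b0:b1] = list(reverse_complement(src) if inverted else src)
            # boundary breakers: make flanks of copy B disagree with copy A's
            for k in range(1, 5):
                if inverted:
                    # pairing is seq[a0+t] vs comp(seq[b1-1-t]); a match one
                    # base past either boundary needs comp agreement, so
                    # copying (not complementing) the partner base breaks it
                    bg[b0 - k] = bg[a1 - 1 + k]
                    bg[b1 - 1 + k] = bg[a0 - k]
                else:
                    bg[b0 - k] = comp[bg[a0 - k]]
                    bg[b1 - 1 + k] = comp[bg[a1 - 1 + k]]
            planted.append((a0, a1, b0, b1, "-" if inverted else "+"))
    genome = Genome(species_id, Compartment.MITOCHONDRIAL, "".join(bg),
                    record_id=f"{species_id}_mt")
    planted.sort()
    return genome, planted


def generate_library_planting(
    library: Sequence[RepeatLibraryEntry],
    n_segments: int = 20,
    host_len: int = 40_000,
    identity_erosion: float = 0.02,
    seed: int = 0,
    gc: float = 0.44,
    species_id: str = "libsim",
):
    """Host genome with eroded copies of labelled library elements planted in it.

    Returns (host Genome, list of (TransferSegment-ready interval, true class)):
    per plant a dict with recipient_start/end and the source repeat_class, for
    scoring repeat-class attribution end to end.
    """
    rng = np.random.default_rng(seed)
    bg = _random_seq(rng, host_len, gc)
    specs = []
    classes = []
    for i in range(n_segments):
        entry = library[int(rng.integers(len(library)))]
        seq, identity = _erode(rng, entry.sequence, identity_erosion)
        specs.append(
            _InsertSpec(seq=seq, mh_left=0, mh_right=0, motif_left=None,
                        motif_right=None, meta=dict(cls=entry.repeat_class))
        )
        classes.append(entry.repeat_class)
    final, placed = _plant_insertions(rng, bg, specs, margin=60)
    host = Genome(species_id, Compartment.MITOCHONDRIAL, final,
                  record_id=f"{species_id}_mt")
    plants = [
        dict(recipient_start=s, recipient_end=e, repeat_class=spec.meta["cls"])
        for s, e, spec in placed
    ]
    return host, plants


# ---------------------------------------------------------------------------
# on-disk truth tables
# ---------------------------------------------------------------------------

_TRUTH_COLUMNS = [
    "event_id", "event_type", "species_id", "donor_compartment",
    "recipient_compartment", "donor_start", "donor_end", "recipient_record",
    "recipient_start", "recipient_end", "planted_identity",
    "microhomology_left", "microhomology_right", "orientation", "truncated",
    "truncation_coverage", "gene_id", "planted_state",
]


def write_truth_table(truth: Sequence[TruthRecord], path) -> None:
    df = pd.DataFrame([vars(t) for t in truth], columns=_TRUTH_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_truth_table(path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        d = row.to_dict()
        d["truncated"] = bool(d["truncated"]) and str(d["truncated"]) != "False"
        records.append(TruthRecord(**d))
    return records


def write_trio(result: TrioResult, outdir) -> None:
    """Three FASTA files, gene table and truth TSV for one simulated species."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sp = result.config.species_id
    write_fasta([result.nuclear], outdir / f"{sp}_nuclear.fa")
    write_fasta([result.mitochondrial], outdir / f"{sp}_mitochondrial.fa")
    write_fasta([result.chloroplast], outdir / f"{sp}_chloroplast.fa")
    write_truth_table(result.truth, outdir / f"{sp}_truth.tsv")
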