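"""Four-state fate classification of reference organellar genes.

For each (gene, species) pair the gene's reference sequence is searched in the
donor organellar genome and in the recipient genome:

* absent from the donor                      -> ``lost``
* donor only                                 -> ``not_transferred``
* both, recipient chain coverage >= cutoff   -> ``intact_homolog``
* both, recipient chain coverage <  cutoff   -> ``pseudogene``

"Full length" is operationalised as chained query coverage of the best
co-linear chain of recipient hits (default cutoff 0.95).  Pseudogene calls
are coverage (truncation) based; internal stop codons are not assessed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .genome_io import Compartment, GeneModel, Genome
from .homology_search import HSP, SearchParams, best_hsp, find_hsps

_CHAIN_TOL = 10   # bp of query/target overlap tolerated between chained hits


class GeneFate(str, Enum):
    LOST = "lost"
    NOT_TRANSFERRED = "not_transferred"
    INTACT_HOMOLOG = "intact_homolog"
    PSEUDOGENE = "pseudogene"


@dataclass
class FateRecord:
    gene_id: str
    species_id: str
    donor_compartment: Compartment
    recipient_compartment: Compartment
    state: GeneFate
    donor_hit: Optional[HSP] = None
    recipient_hit: Optional[HSP] = None
    recipient_coverage: float = 0.0
    short_gene_flag: bool = False


def _chain_coverage(hsps: Sequence[HSP], gene_len: int) -> tuple[float, list[HSP]]:
    """Best co-linear non-overlapping chain of recipient hits, scored by query bp covered.

    Hits are chainable when they share target record and strand, appear in
    query order, and their query/target intervals do not overlap by more than
    a small tolerance; recipient-side gaps of any size are allowed.
    """
    if not hsps:
        return 0.0, []
    hits = sorted(hsps, key=lambda h: (h.q_start, h.q_end))
    n = len(hits)
    covered = [h.q_end - h.q_start for h in hits]
    best_cov = list(covered)
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            a, b = hits[j], hits[i]
            if a.target_id != b.target_id or a.strand != b.strand:
                continue
            if b.q_start < a.q_end - _CHAIN_TOL:
                continue
            if a.strand == "+":
                if b.t_start < a.t_end - _CHAIN_TOL:
                    continue
            else:
                if b.t_end > a.t_start + _CHAIN_TOL:
                    continue
            overlap = max(0, a.q_end - b.q_start)
            gain = covered[i] - overlap
            if best_cov[j] + gain > best_cov[i]:
                best_cov[i] = best_cov[j] + gain
                prev[i] = j
        # i stands alone by default (already initialised)
    k = max(range(n), key=lambda i: best_cov[i])
    chain = []
    while k != -1:
        chain.append(hits[k])
        k = prev[k]
    chain.reverse()
    return min(best_cov[max(range(n), key=lambda i: best_cov[i])] / gene_len, 1.0), chain


def _collect_hits(gene_seq: str, genomes, params: SearchParams, gene_id: str) -> list[HSP]:
    if isinstance(genomes, Genome):
        genomes = [genomes]
    hits: list[HSP] = []
    for g in genomes:
        hits.extend(find_hsps(gene_seq, g, params, query_id=gene_id))
    return hits


def classify_gene(
    gene: GeneModel,
    gene_seq: str,
    donor: Union[Genome, Sequence[Genome]],
    recipient: Union[Genome, Sequence[Genome]],
    params: SearchParams | None = None,
    full_length_min_coverage: float = 0.95,
) -> FateRecord:
    """Classify one reference gene for one species.

    A gene shorter than ``params.min_length`` is classified with the length
    gate lowered to the gene length and flagged in the record.
    """
    if not gene_seq:
        raise ValueError(f"gene {gene.gene_id}: empty reference sequence")
    if not (0 < full_length_min_coverage <= 1):
        raise ValueError("full_length_min_coverage must be in (0, 1]")
    params = params or SearchParams()
    short_flag = False
    if len(gene_seq) < params.min_length:
        short_flag = True
        params = replace(params, min_length=max(params.word_size, len(gene_seq)))
    donor_list = [donor] if isinstance(donor, Genome) else list(donor)
    recip_list = [recipient] if isinstance(recipient, Genome) else list(recipient)
    donor_comp = donor_list[0].compartment
    recip_comp = recip_list[0].compartment
    species = recip_list[0].species_id

    donor_hits = _collect_hits(gene_seq, donor_list, params, gene.gene_id)
    if not donor_hits:
        return FateRecord(
            gene.gene_id, species, donor_comp, recip_comp, GeneFate.LOST,
            short_gene_flag=short_flag,
        )
    recip_hits = _collect_hits(gene_seq, recip_list, params, gene.gene_id)
    if not recip_hits:
        return FateRecord(
            gene.gene_id, species, donor_comp, recip_comp, GeneFate.NOT_TRANSFERRED,
            donor_hit=best_hsp(donor_hits), short_gene_flag=short_flag,
        )
    coverage, _chain = _chain_coverage(recip_hits, len(gene_seq))
    state = (
        GeneFate.INTACT_HOMOLOG
        if coverage >= full_length_min_coverage
        else GeneFate.PSEUDOGENE
    )
    return FateRecord(
        gene.gene_id, species, donor_comp, recip_comp, state,
        donor_hit=best_hsp(donor_hits), recipient_hit=best_hsp(recip_hits),
        recipient_coverage=coverage, short_gene_flag=short_flag,
    )


def fate_matrix(
    genes: Sequence[tuple[GeneModel, str]],
    trios: Mapping[str, Mapping[Union[Compartment, str], Union[Genome, Sequence[Genome]]]],
    params: SearchParams | None = None,
    donor_compartment: Compartment = Compartment.MITOCHONDRIAL,
    recipient_compartment: Compartment = Compartment.NUCLEAR,
    full_length_min_coverage: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Species x gene matrix of fate states plus per-state counts per species.

    ``trios`` maps species id -> {compartment: Genome or list of Genomes}.
    A species missing either genome yields a row of NA.  Cell vocabulary is
    exactly {lost, not_transferred, intact_homolog, pseudogene}.
    """
    gene_ids = [g.gene_id for g, _ in genes]
    rows = {}
    for species, genomes in trios.items():
        genomes = {Compartment(k): v for k, v in genomes.items()}
        donor = genomes.get(donor_compartment)
        recipient = genomes.get(recipient_compartment)
        if donor is None or recipient is None:
            rows[species] = [pd.NA] * len(gene_ids)
            continue
        row = []
        for gene, seq in genes:
            rec = classify_gene(
                gene, seq, donor, recipient, params,
                full_length_min_coverage=full_length_min_coverage,
            )
            row.append(rec.state.value)
        rows[species] = row
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=gene_ids)
    matrix.index.name = "species_id"
    counts = pd.DataFrame(
        {
            state.value: (matrix == state.value).sum(axis=1)
            for state in GeneFate
        }
    )
    counts.index.name = "species_id"
    return matrix, counts


def write_fate_matrix(matrix: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# states: lost | not_transferred | intact_homolog | pseudogene\n")
        matrix.to_csv(fh, sep="\t", na_rep="NA")
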