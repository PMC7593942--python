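"""Differential-expression gene selection and promoter-region extraction.

The promoter window is 500 bp upstream plus 50 bp downstream of a gene's
start codon ("550-bp region"); the downstream 50 bp begin at, and include,
the first base of the start codon.  Windows are truncated at contig edges
unless the contig is flagged circular, in which case they wrap.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

from .io_formats import (
    ExpressionRecord,
    GeneModel,
    GenomeRecord,
    reverse_complement,
)

logger = logging.getLogger(__name__)

DEFAULT_UPSTREAM = 500
DEFAULT_DOWNSTREAM = 50


@dataclasses.dataclass(frozen=True)
class PromoterRegion:
    """A strand-oriented promoter window anchored at a start codon.

    ``start``/``end`` are genomic (forward-strand, 0-based half-open);
    ``sequence`` reads in the transcription direction of the gene, i.e. it
    is the reverse complement of the genomic slice for ``-`` strand genes.
    """

    locus_tag: str
    contig_id: str
    start: int
    end: int
    strand: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def select_induced_genes(
    expr: Sequence[ExpressionRecord],
    condition: str,
    min_fold: float = 3.0,
    max_q: float = 0.05,
) -> set[str]:
    """Loci induced under *condition*: fold_change >= min_fold and q <= max_q.

    Both thresholds are inclusive ("at least threefold", "maximum q-value
    ... 0.05").
    """
    available = {r.condition for r in expr}
    if condition not in available:
        raise ValueError(
            f"condition {condition!r} not present; available: {sorted(available)}")
    return {
        r.locus_tag
        for r in expr
        if r.condition == condition and r.fold_change >= min_fold and r.q_value <= max_q
    }


def qualifying_first_genes(
    genes: Sequence[GeneModel],
    expr: Sequence[ExpressionRecord],
    condition: str,
    max_q: float = 0.05,
) -> set[str]:
    """First genes of operons with >=1 significantly induced member.

    Significance alone (q <= max_q) qualifies the operon — no fold threshold —
    but the change must be an increase (fold_change > 1), since a q-value is
    sign-blind.  Returns the ``operon_index == 1`` gene of each such operon.
    """
    significant = {
        r.locus_tag
        for r in expr
        if r.condition == condition and r.q_value <= max_q and r.fold_change > 1.0
    }
    qualifying_operons = {g.operon_id for g in genes if g.locus_tag in significant}
    return {
        g.locus_tag
        for g in genes
        if g.operon_id in qualifying_operons and g.operon_index == 1
    }


def extract_550bp_region(
    genome: GenomeRecord,
    gene: GeneModel,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> PromoterRegion:
    """Extract the promoter window around a gene's start codon.

    For a ``+`` strand gene with start-codon first base at ``s`` the genomic
    interval is ``[s - upstream, s + downstream)``; for a ``-`` strand gene
    on ``[b, e)`` (start codon at ``e - 1``) it is ``[e - downstream,
    e + upstream)`` and the sequence is reverse complemented.
    """
    length = len(genome.sequence)
    if gene.contig_id != genome.contig_id:
        raise ValueError(
            f"gene {gene.locus_tag} on {gene.contig_id!r}, not on contig "
            f"{genome.contig_id!r}")
    if gene.end > length:
        raise ValueError(
            f"gene {gene.locus_tag} [{gene.start}, {gene.end}) exceeds contig "
            f"length {length}")

    if gene.strand == "+":
        lo, hi = gene.start - upstream, gene.start + downstream
    else:
        lo, hi = gene.end - downstream, gene.end + upstream

    if genome.is_circular:
        seq = "".join(genome.sequence[i % length] for i in range(lo, hi))
        start, end = lo % length, hi % length if hi % length else length
    else:
        lo_c, hi_c = max(lo, 0), min(hi, length)
        seq = genome.sequence[lo_c:hi_c]
        start, end = lo_c, hi_c
    if gene.strand == "-":
        seq = reverse_complement(seq)
    return PromoterRegion(
        locus_tag=gene.locus_tag, contig_id=gene.contig_id,
        start=start, end=end, strand=gene.strand, sequence=seq)


def regions_for_loci(
    genome: GenomeRecord | Sequence[GenomeRecord],
    genes: Sequence[GeneModel],
    loci: Iterable[str],
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> list[PromoterRegion]:
    """Promoter regions for a locus set, deduplicated and coordinate-sorted."""
    genomes = {genome.contig_id: genome} if isinstance(genome, GenomeRecord) else {
        g.contig_id: g for g in genome}
    by_locus = {g.locus_tag: g for g in genes}
    loci = set(loci)
    missing = loci - by_locus.keys()
    if missing:
        raise ValueError(f"no gene model for loci: {sorted(missing)}")
    if not loci:
        logger.info("empty locus set: no regions extracted")
        return []
    regions = []
    for locus in loci:
        gene = by_locus[locus]
        if gene.contig_id not in genomes:
            raise ValueError(f"gene {locus} on unknown contig {gene.contig_id!r}")
        regions.append(
            extract_550bp_region(genomes[gene.contig_id], gene, upstream, downstream))
    regions.sort(key=lambda r: (r.contig_id, r.start, r.locus_tag))
    return regions
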