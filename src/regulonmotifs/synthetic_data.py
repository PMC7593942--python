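"""Synthetic genomes with planted regulon motifs, expression and homologs.

The generator emulates the statistical structure the pipeline assumes in
real data: a bacterial chromosome with non-overlapping genes grouped into
operons; a palindromic binding motif (default the 15-bp consensus
``TCCCGGTSACCGGGA``) planted once upstream of the first gene of each
regulon operon; an expression table in which every regulon gene is induced
(fold >= 3, q <= 0.05) under one condition while background genes hover
around fold 1 with uniform q; and mutated homolog copies of seed promoter
regions whose planted sites are better conserved than their surroundings.
Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .io_formats import (
    DNA_ALPHABET,
    ExpressionRecord,
    GeneModel,
    GenomeRecord,
    reverse_complement,
)
from .regions import PromoterRegion, extract_550bp_region

_IUPAC_BASES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

DEFAULT_PLANTED_CONSENSUS = "TCCCGGTSACCGGGA"


@dataclasses.dataclass
class SimulationConfig:
    """Knobs of the synthetic dataset; defaults define the study conditions."""

    seed: int = 0
    n_genes: int = 300
    genes_per_operon: tuple[int, int] = (1, 4)        # uniform inclusive range
    gene_length: tuple[int, int] = (300, 900)
    intergenic_length: tuple[int, int] = (560, 800)   # between operons
    operon_gap: tuple[int, int] = (10, 60)            # within operons
    gc_content: float = 0.5
    regulon_size: int = 30
    planted_consensus: str = DEFAULT_PLANTED_CONSENSUS
    planted_mutations: int = 1       # max substitutions per planted site
    site_offset: tuple[int, int] = (20, 470)          # within the oriented window
    induced_fold: tuple[float, float] = (3.0, 50.0)
    induced_q: tuple[float, float] = (1e-6, 0.05)
    background_fold: tuple[float, float] = (0.8, 1.25)
    background_q: tuple[float, float] = (0.06, 1.0)  # floor keeps nulls non-significant
    homolog_substitution_rate: float = 0.10
    site_conservation_factor: float = 0.25  # in-site rate = rate * factor
    n_homologs: int = 20
    condition: str = "LCA"
    upstream: int = 500
    downstream: int = 50
    contig_id: str = "sim_contig_1"

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie in (0, 1)")
        if self.planted_mutations < 0:
            raise ValueError("planted_mutations must be >= 0")


@dataclasses.dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted motif occurrence."""

    operon_id: str
    locus_tag: str
    contig_id: str
    start: int
    strand: str
    sequence: str  # as written on the forward genome strand

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


@dataclasses.dataclass
class SimulatedDataset:
    """A complete synthetic study: genome, annotation, truth and expression."""

    config: SimulationConfig
    genome: GenomeRecord
    genes: list[GeneModel]
    regulon_operons: list[str]
    manifest: list[PlantedSite]
    expression: list[ExpressionRecord]


def consensus_to_matrix(consensus: str) -> np.ndarray:
    """Probability matrix of an IUPAC consensus (uniform over allowed bases)."""
    rows = []
    for c in consensus.upper():
        if c not in _IUPAC_BASES:
            raise ValueError(f"non-IUPAC symbol {c!r} in consensus")
        allowed = _IUPAC_BASES[c]
        row = np.zeros(4)
        for b in allowed:
            row[DNA_ALPHABET.index(b)] = 1.0 / len(allowed)
        rows.append(row)
    return np.array(rows)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=probs)
    return "".join(DNA_ALPHABET[i] for i in idx)


def generate_genome(config: SimulationConfig) -> tuple[GenomeRecord, list[GeneModel]]:
    """One contig of i.i.d. bases with operon-grouped, non-overlapping genes.

    Operons occupy alternating positions left to right; each operon's genes
    share a strand (chosen at random) and are separated by short gaps, while
    neighbouring operons are separated by ``intergenic_length`` gaps large
    enough to hold a full upstream promoter window.  For ``-`` strand
    operons the first gene (operon_index 1) is the rightmost.
    """
    rng = np.random.default_rng(config.seed)
    structures: list[int] = []
    total = 0
    while total < config.n_genes:
        k = int(rng.integers(config.genes_per_operon[0], config.genes_per_operon[1] + 1))
        k = min(k, config.n_genes - total)
        structures.append(k)
        total += k

    genes: list[GeneModel] = []
    pos = int(rng.integers(*config.intergenic_length))
    for op_no, k in enumerate(structures, start=1):
        strand = "+" if rng.random() < 0.5 else "-"
        operon_id = f"op_{op_no:04d}"
        intervals = []
        for j in range(k):
            glen = int(rng.integers(config.gene_length[0], config.gene_length[1] + 1))
            intervals.append((pos, pos + glen))
            pos += glen
            if j < k - 1:
                pos += int(rng.integers(config.operon_gap[0], config.operon_gap[1] + 1))
        pos += int(rng.integers(config.intergenic_length[0], config.intergenic_length[1] + 1))
        order = intervals if strand == "+" else intervals[::-1]
        for idx, (b, e) in enumerate(order, start=1):
            locus = f"SIM_{len(genes) + 1:05d}"
            genes.append(GeneModel(
                locus_tag=locus, contig_id=config.contig_id,
                start=b, end=e, strand=strand,
                operon_id=operon_id, operon_index=idx))
    contig_len = pos + int(rng.integers(*config.intergenic_length))
    sequence = _random_sequence(rng, contig_len, config.gc_content)
    genes.sort(key=lambda g: g.start)
    genome = GenomeRecord(config.contig_id, sequence)
    for g in genes:
        if g.end > contig_len:
            raise ValueError(
                "genes do not fit the contig; increase intergenic_length")
    return genome, genes


def choose_regulon(genes: Sequence[GeneModel], config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> list[str]:
    """Deterministically choose the operons that will carry the planted motif."""
    rng = rng or np.random.default_rng(config.seed + 1)
    operon_ids = sorted({g.operon_id for g in genes})
    if config.regulon_size > len(operon_ids):
        raise ValueError(
            f"regulon_size {config.regulon_size} exceeds {len(operon_ids)} operons")
    chosen = rng.choice(len(operon_ids), size=config.regulon_size, replace=False)
    return [operon_ids[i] for i in sorted(chosen)]


def _sample_site(rng: np.random.Generator, matrix: np.ndarray, n_mut: int) -> str:
    bases = [DNA_ALPHABET[rng.choice(4, p=row)] for row in matrix]
    n = int(rng.integers(0, n_mut + 1)) if n_mut else 0
    if n:
        for pos in rng.choice(len(bases), size=min(n, len(bases)), replace=False):
            current = bases[pos]
            alternatives = [b for b in DNA_ALPHABET if b != current]
            bases[pos] = alternatives[int(rng.integers(3))]
    return "".join(bases)


def plant_motif(
    genome: GenomeRecord,
    genes: Sequence[GeneModel],
    config: SimulationConfig,
    regulon_operons: Sequence[str] | None = None,
) -> tuple[GenomeRecord, list[PlantedSite]]:
    """Write one sampled motif occurrence into each regulon first-gene window.

    The site is drawn from the consensus matrix (with up to
    ``planted_mutations`` substitutions), placed at a random offset of the
    oriented promoter window on a uniformly chosen strand, and recorded in
    the returned manifest with genomic coordinates.  Offsets colliding with
    a gene body are re-sampled (up to 100 attempts).
    """
    rng = np.random.default_rng(config.seed + 2)
    if regulon_operons is None:
        regulon_operons = choose_regulon(genes, config)
    if not regulon_operons:
        return genome, []
    matrix = consensus_to_matrix(config.planted_consensus)
    w = matrix.shape[0]
    seq = list(genome.sequence)
    gene_intervals = [(g.start, g.end) for g in genes]
    first_by_operon = {
        g.operon_id: g for g in genes if g.operon_index == 1}
    manifest: list[PlantedSite] = []
    for operon_id in regulon_operons:
        gene = first_by_operon[operon_id]
        site = _sample_site(rng, matrix, config.planted_mutations)
        placed = False
        for _attempt in range(100):
            offset = int(rng.integers(config.site_offset[0], config.site_offset[1] + 1))
            if gene.strand == "+":
                gstart = gene.start - config.upstream + offset
            else:
                gstart = gene.end + config.upstream - offset - w
            if gstart < 0 or gstart + w > len(seq):
                continue
            if any(b < gstart + w and gstart < e for b, e in gene_intervals):
                continue
            flip = rng.random() < 0.5
            oriented = reverse_complement(site) if flip else site
            written = oriented if gene.strand == "+" else reverse_complement(oriented)
            seq[gstart:gstart + w] = list(written)
            strand = gene.strand if not flip else ("-" if gene.strand == "+" else "+")
            manifest.append(PlantedSite(
                operon_id=operon_id, locus_tag=gene.locus_tag,
                contig_id=genome.contig_id, start=gstart,
                strand=strand, sequence=written))
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place a site upstream of {gene.locus_tag} "
                "after 100 attempts (window truncated or crowded)")
    return GenomeRecord(genome.contig_id, "".join(seq), genome.is_circular), manifest


def generate_expression(
    genes: Sequence[GeneModel],
    config: SimulationConfig,
    regulon_operons: Sequence[str],
) -> list[ExpressionRecord]:
    """Expression table: regulon genes induced, everything else background."""
    rng = np.random.default_rng(config.seed + 3)
    regulon = set(regulon_operons)
    records = []
    for g in genes:
        if g.operon_id in regulon:
            fold = float(rng.uniform(*config.induced_fold))
            q = float(rng.uniform(*config.induced_q))
        else:
            fold = float(rng.uniform(*config.background_fold))
            q = float(rng.uniform(*config.background_q))
        records.append(ExpressionRecord(g.locus_tag, config.condition, fold, q))
    return records


def generate_homologs(
    region: PromoterRegion,
    manifest: Sequence[PlantedSite],
    n: int,
    substitution_rate: float,
    seed: int,
    site_conservation_factor: float = 0.25,
) -> list[tuple[str, float, str]]:
    """Mutated homolog copies of a seed region, ranked by observed identity.

    Substitutions hit each base at ``substitution_rate`` outside planted
    sites and at ``substitution_rate * site_conservation_factor`` inside
    them, emulating purifying selection on binding sites.  Returns
    ``(homolog_id, rank_score, sequence)`` sorted by descending rank score,
    where rank score is 1 - observed divergence.
    """
    if n < 0:
        raise ValueError(f"number of homologs must be >= 0, got {n}")
    rng = np.random.default_rng(seed)
    L = len(region.sequence)
    in_site = np.zeros(L, dtype=bool)
    for site in manifest:
        if site.contig_id != region.contig_id:
            continue
        lo = max(site.start, region.start) - region.start
        hi = min(site.end, region.end) - region.start
        if lo < hi:
            if region.strand == "+":
                in_site[lo:hi] = True
            else:
                in_site[L - hi:L - lo] = True
    rate = np.where(in_site, substitution_rate * site_conservation_factor,
                    substitution_rate)
    homologs = []
    base_idx = {b: i for i, b in enumerate(DNA_ALPHABET)}
    for h in range(n):
        chars = list(region.sequence)
        mutate = rng.random(L) < rate
        n_sub = 0
        for pos in np.nonzero(mutate)[0]:
            if chars[pos] not in base_idx:
                continue
            alternatives = [b for b in DNA_ALPHABET if b != chars[pos]]
            chars[pos] = alternatives[int(rng.integers(3))]
            n_sub += 1
        rank = 1.0 - n_sub / L
        homologs.append((f"{region.locus_tag}_hom{h + 1:02d}", rank, "".join(chars)))
    homologs.sort(key=lambda t: (-t[1], t[0]))
    return homologs


def build_homolog_table(
    dataset: SimulatedDataset,
    seed_loci: Sequence[str],
) -> dict[str, list[tuple[str, float, str]]]:
    """Homolog tables for a set of seed loci, derived from the dataset truth."""
    cfg = dataset.config
    by_locus = {g.locus_tag: g for g in dataset.genes}
    table = {}
    for i, locus in enumerate(seed_loci):
        region = extract_550bp_region(
            dataset.genome, by_locus[locus], cfg.upstream, cfg.downstream)
        table[locus] = generate_homologs(
            region, dataset.manifest, cfg.n_homologs,
            cfg.homolog_substitution_rate, seed=cfg.seed + 100 + i,
            site_conservation_factor=cfg.site_conservation_factor)
    return table


def simulate(config: SimulationConfig, plant: bool = True) -> SimulatedDataset:
    """Generate a full synthetic study from one seed.

    With ``plant=False`` the regulon operons are still induced in the
    expression table but no motif is written into the genome — the null
    condition in which expression carries no sequence signal.
    """
    genome, genes = generate_genome(config)
    regulon = choose_regulon(genes, config)
    if plant:
        genome, manifest = plant_motif(genome, genes, config, regulon)
    else:
        manifest = []
    expression = generate_expression(genes, config, regulon)
    return SimulatedDataset(
        config=config, genome=genome, genes=genes,
        regulon_operons=regulon, manifest=manifest, expression=expression)
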