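"""Regulator-likeness filters, the end-to-end pipeline, and footprinting.

Two filters separate transcription-factor-like motifs from promoter or
low-complexity signals:

* **Criterion A** — at most 1000 q-passing sites genome-wide (more suggests
  a promoter element or a microsatellite-like repeat); the boundary is
  inclusive.
* **Criterion B** — strictly more than 10% of the sites fall inside 550-bp
  regions of first genes of operons containing at least one significantly
  induced gene.  Significance alone (q <= 0.05, fold > 1) qualifies an
  operon; the 3-fold induction rule applies only to the discovery gene set.

The phylogenetic-footprinting variant pools each seed promoter with its
top-ranked homolog promoters before discovery, rescans the genome's own
regions, re-estimates each motif from its in-genome sites only, scans once
more, and keeps a motif if either scan round satisfies both criteria.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

from .config import PipelineConfig
from .io_formats import ExpressionRecord, GeneModel, GenomeRecord
from .motif_discovery import (
    BackgroundModel,
    Motif,
    build_background,
    discover_motifs,
    is_palindrome,
    reestimate_from_sites,
)
from .regions import (
    PromoterRegion,
    extract_550bp_region,
    qualifying_first_genes,
    regions_for_loci,
    select_induced_genes,
)
from .scanner import ScanResult, SiteHit, scan

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class FilterVerdict:
    """Criterion A/B accounting for one motif's q-passing site set."""

    motif_id: str
    n_sites: int
    n_in_qualifying: int
    fraction: float
    passes_A: bool
    passes_B: bool

    @property
    def passes(self) -> bool:
        return self.passes_A and self.passes_B


def criterion_A(sites: Sequence[SiteHit], max_sites: int = 1000) -> bool:
    """True iff the motif has no more than ``max_sites`` sites (inclusive)."""
    return len(sites) <= max_sites


def _sites_in_regions(sites: Sequence[SiteHit], regions: Sequence[PromoterRegion]) -> int:
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_contig.setdefault(r.contig_id, []).append((r.start, r.end))
    n = 0
    for s in sites:
        for start, end in by_contig.get(s.contig_id, ()):
            if start <= s.start < end:
                n += 1
                break
    return n


def criterion_B(
    sites: Sequence[SiteHit],
    qualifying_regions: Sequence[PromoterRegion],
    min_fraction: float = 0.10,
) -> FilterVerdict:
    """Fraction of sites whose start lies in a qualifying first-gene region.

    Passes iff the fraction is strictly greater than ``min_fraction``; an
    empty site set fails.
    """
    n_sites = len(sites)
    n_in = _sites_in_regions(sites, qualifying_regions)
    fraction = n_in / n_sites if n_sites else 0.0
    motif_id = sites[0].motif_id if sites else ""
    return FilterVerdict(
        motif_id=motif_id, n_sites=n_sites, n_in_qualifying=n_in,
        fraction=fraction, passes_A=True, passes_B=fraction > min_fraction)


def evaluate_motif(
    motif_id: str,
    sites: Sequence[SiteHit],
    qualifying_regions: Sequence[PromoterRegion],
    max_sites: int = 1000,
    min_fraction: float = 0.10,
) -> FilterVerdict:
    """Full Criterion A + B verdict for one motif's q-passing sites."""
    verdict = criterion_B(sites, qualifying_regions, min_fraction)
    return dataclasses.replace(
        verdict, motif_id=motif_id, passes_A=criterion_A(sites, max_sites))


@dataclasses.dataclass
class MotifReport:
    """One pipeline motif with its verdict and supporting sites."""

    motif: Motif
    verdict: FilterVerdict
    palindromic: bool
    sites: list[SiteHit]


class PipelineResult(Sequence):
    """Sequence of (motif, verdict) pairs with per-motif detail and status."""

    def __init__(self, reports: list[MotifReport], status: str = "ok"):
        self.reports = reports
        self.status = status

    def __getitem__(self, i):
        rep = self.reports[i]
        return (rep.motif, rep.verdict)

    def __len__(self) -> int:
        return len(self.reports)

    def passing(self) -> list[MotifReport]:
        return [r for r in self.reports if r.verdict.passes]


def run_motif_pipeline(
    genome: GenomeRecord,
    genes: Sequence[GeneModel],
    expr: Sequence[ExpressionRecord],
    condition: str,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """The full motif-search procedure on one annotated genome.

    1. select genes induced >= ``min_fold`` at q <= ``max_q_deg``;
    2. extract their 550-bp regions;
    3. discover motifs in those regions (ANR EM, E <= ``max_evalue``);
    4. scan the 550-bp regions of *all* genes per motif at site
       q <= ``max_q_site``;
    5. apply Criteria A and B.

    Returns every discovered motif with its verdict; an empty induced set
    yields an empty result with an explanatory status, not an exception.
    """
    cfg = config or PipelineConfig()
    induced = select_induced_genes(expr, condition, cfg.min_fold, cfg.max_q_deg)
    if not induced:
        return PipelineResult([], status="no genes passed the induction filter")
    induced_regions = regions_for_loci(
        genome, genes, induced, cfg.upstream, cfg.downstream)
    if len(induced_regions) < 2:
        return PipelineResult(
            [], status=f"only {len(induced_regions)} induced region(s); need >= 2")
    logger.info("pipeline: %d induced genes -> %d regions", len(induced), len(induced_regions))

    motifs = discover_motifs(
        induced_regions, wmin=cfg.wmin, wmax=cfg.wmax, max_evalue=cfg.max_evalue,
        max_motifs=cfg.max_motifs, both_strands=cfg.both_strands, seed=cfg.seed,
        width_sweep=cfg.width_sweep, n_starts=cfg.n_starts,
        n_refine=cfg.n_refine, n_shuffles=cfg.n_shuffles)
    logger.info("pipeline: %d motif(s) discovered", len(motifs))
    if not motifs:
        return PipelineResult([], status="no significant motif found")

    all_regions = regions_for_loci(
        genome, genes, [g.locus_tag for g in genes], cfg.upstream, cfg.downstream)
    scan_bg = build_background([r.sequence for r in all_regions], order=0)
    qual_loci = qualifying_first_genes(genes, expr, condition, cfg.max_q_deg)
    qual_regions = regions_for_loci(
        genome, genes, qual_loci, cfg.upstream, cfg.downstream)

    reports = []
    for motif in motifs:
        result = scan(all_regions, motif, scan_bg, max_q=cfg.max_q_site, bins=cfg.bins)
        verdict = evaluate_motif(
            motif.motif_id, result.hits, qual_regions,
            cfg.max_sites, cfg.min_fraction)
        reports.append(MotifReport(
            motif=motif, verdict=verdict,
            palindromic=is_palindrome(motif.consensus.replace("N", "")) if motif.consensus.strip("N") else False,
            sites=result.hits))
        logger.info(
            "pipeline: %s sites=%d in_qualifying=%d A=%s B=%s",
            motif.motif_id, verdict.n_sites, verdict.n_in_qualifying,
            verdict.passes_A, verdict.passes_B)
    return PipelineResult(reports, status="ok")


# ---------------------------------------------------------------------------
# phylogenetic footprinting
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FootprintSet:
    """Seed promoters pooled with their ranked homolog promoters."""

    seed_loci: list[str]
    homologs_per_seed: dict[str, list[PromoterRegion]]
    regions: list[PromoterRegion]


def build_footprint_set(
    seed_loci: Sequence[str],
    homolog_table: Mapping[str, Sequence[tuple[str, float, str]]],
    genome: GenomeRecord,
    genes: Sequence[GeneModel],
    top_n: int = 20,
    upstream: int = 500,
    downstream: int = 50,
) -> FootprintSet:
    """Combine each seed's own region with its ``top_n`` best-ranked homologs.

    ``homolog_table`` maps seed locus -> iterable of
    ``(homolog_id, rank_score, region_sequence)``; higher rank_score means a
    more significant homolog.  A seed with fewer than ``top_n`` homologs
    contributes all it has.
    """
    by_locus = {g.locus_tag: g for g in genes}
    regions: list[PromoterRegion] = []
    homologs: dict[str, list[PromoterRegion]] = {}
    for seed in seed_loci:
        if seed not in by_locus:
            raise ValueError(f"footprinting seed {seed!r} has no gene model")
        seed_region = extract_550bp_region(genome, by_locus[seed], upstream, downstream)
        regions.append(seed_region)
        ranked = sorted(homolog_table.get(seed, ()), key=lambda h: -h[1])[:top_n]
        homologs[seed] = [
            PromoterRegion(
                locus_tag=f"{seed}|{hom_id}", contig_id=f"homolog:{hom_id}",
                start=0, end=len(seq), strand="+", sequence=seq.upper())
            for hom_id, _score, seq in ranked
        ]
        regions.extend(homologs[seed])
    return FootprintSet(
        seed_loci=list(seed_loci), homologs_per_seed=homologs, regions=regions)


@dataclasses.dataclass
class FootprintReport:
    """A footprinting motif with both scan rounds and verdicts."""

    motif: Motif
    refined_motif: Motif | None
    verdict_initial: FilterVerdict
    verdict_refined: FilterVerdict | None
    sites_initial: list[SiteHit]
    sites_refined: list[SiteHit]

    @property
    def passes(self) -> bool:
        if self.verdict_initial.passes:
            return True
        return self.verdict_refined is not None and self.verdict_refined.passes


def run_footprinting(
    cluster_operons: Sequence[str],
    genome: GenomeRecord,
    genes: Sequence[GeneModel],
    expr: Sequence[ExpressionRecord],
    condition: str,
    homolog_table: Mapping[str, Sequence[tuple[str, float, str]]],
    config: PipelineConfig | None = None,
) -> list[FootprintReport]:
    """Phylogenetic-footprinting motif search over a gene cluster.

    Steps: (1-2) pool 550-bp regions of the first genes of the cluster's
    qualifying operons with their top homolog regions; (3) discover motifs
    on the pooled set; (4) scan the genome's own 550-bp regions; (5)
    re-estimate each motif from its in-genome sites and rescan; (6) keep
    motifs whose step-4 or step-5 sites satisfy Criteria A and B.
    """
    cfg = config or PipelineConfig()
    cluster = set(cluster_operons)
    significant = {
        r.locus_tag for r in expr
        if r.condition == condition and r.q_value <= cfg.max_q_deg and r.fold_change > 1.0}
    qualifying_ops = {
        g.operon_id for g in genes
        if g.operon_id in cluster and g.locus_tag in significant}
    seeds = sorted(
        (g for g in genes if g.operon_id in qualifying_ops and g.operon_index == 1),
        key=lambda g: (g.contig_id, g.start))
    if len(seeds) < 2:
        raise ValueError(
            f"footprinting needs >= 2 qualifying operons, got {len(seeds)}")
    seed_loci = [g.locus_tag for g in seeds]

    fpset = build_footprint_set(
        seed_loci, homolog_table, genome, genes,
        top_n=cfg.top_n_homologs, upstream=cfg.upstream, downstream=cfg.downstream)
    logger.info("footprinting: %d seeds -> %d pooled regions",
                len(seed_loci), len(fpset.regions))

    motifs = discover_motifs(
        fpset.regions, wmin=cfg.wmin, wmax=cfg.wmax, max_evalue=cfg.max_evalue,
        max_motifs=cfg.max_motifs, both_strands=cfg.both_strands, seed=cfg.seed,
        width_sweep=cfg.width_sweep, n_starts=cfg.n_starts,
        n_refine=cfg.n_refine, n_shuffles=cfg.n_shuffles)
    if not motifs:
        return []

    all_regions = regions_for_loci(
        genome, genes, [g.locus_tag for g in genes], cfg.upstream, cfg.downstream)
    scan_bg = build_background([r.sequence for r in all_regions], order=0)
    qual_loci = qualifying_first_genes(genes, expr, condition, cfg.max_q_deg)
    qual_regions = regions_for_loci(
        genome, genes, qual_loci, cfg.upstream, cfg.downstream)

    reports: list[FootprintReport] = []
    for motif in motifs:
        res4 = scan(all_regions, motif, scan_bg, max_q=cfg.max_q_site, bins=cfg.bins)
        verdict4 = evaluate_motif(
            motif.motif_id, res4.hits, qual_regions, cfg.max_sites, cfg.min_fraction)
        refined: Motif | None = None
        verdict5: FilterVerdict | None = None
        sites5: list[SiteHit] = []
        if len(res4.hits) >= 2:
            refined = reestimate_from_sites(res4.hits, genome, motif.width, scan_bg)
            refined.motif_id = f"{motif.motif_id}_refined"
            refined.significance = motif.significance
            res5 = scan(all_regions, refined, scan_bg, max_q=cfg.max_q_site, bins=cfg.bins)
            sites5 = res5.hits
            verdict5 = evaluate_motif(
                refined.motif_id, sites5, qual_regions, cfg.max_sites, cfg.min_fraction)
        report = FootprintReport(
            motif=motif, refined_motif=refined,
            verdict_initial=verdict4, verdict_refined=verdict5,
            sites_initial=res4.hits, sites_refined=sites5)
        if report.passes:
            reports.append(report)
        else:
            logger.info("footprinting: motif %s aborted (fails criteria in both rounds)",
                        motif.motif_id)
    return reports
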