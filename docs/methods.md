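# Methods

This note records the models, parameter choices and numerical decisions
behind `regulonmotifs`, in the spirit of a methods appendix: what is
computed, under which assumptions, and what the synthetic benchmarks do and
do not demonstrate.

## Coordinates and formats

All in-memory coordinates are 0-based half-open on the forward strand;
GFF3 (1-based inclusive) converts at the I/O boundary, and round-trip
tests assert zero drift. Genomes are FASTA over `{A,C,G,T,N}`; windows
containing `N` are excluded from discovery and scanning. Contigs are
treated as linear by default — promoter windows truncate at contig edges —
with wraparound only when a contig is explicitly flagged circular, since
truncation is the conservative choice when origin-spanning behaviour is
unspecified. Motifs are serialised in MEME-minimal format (round-trip
exact to six decimals and parseable by Biopython), sites as BED6 plus a
TSV carrying p- and q-values and region assignments.

## Promoter windows and gene selection

The promoter window spans 500 bp upstream and 50 bp downstream of the
start codon, 550 bp in total. The downstream window is anchored to
*include* the first base of the start codon (positions s…s+49 for a `+`
strand gene starting at s); anchoring at the codon makes the window
deterministic where "50 bp downstream" alone would be ambiguous. For a
`-` strand gene on [b, e) the window is [e−50, e+500), reverse
complemented; a property test asserts exact equality with the `+` strand
rule applied to the reverse-complemented genome. Overlapping windows of
neighbouring genes are all kept — extraction is per gene.

Discovery regions come from genes induced at fold ≥ 3 and q ≤ 0.05, both
bounds inclusive. Criterion B's qualifying operons use significance only
(q ≤ 0.05) — no fold threshold — but additionally require fold > 1, since
a q-value alone is direction-blind and the criterion concerns *increased*
expression.

## Background model

Order-k Markov backgrounds are counted on both strands (sequence plus
reverse complement) with add-0.1 smoothing per context cell; order 0 is
the default everywhere, matching standard promoter-scanning practice. The
stationary vector is the fixed point of the context chain (for k = 0, the
smoothed base frequencies); both-strand counting makes it automatically
strand-symmetric (A = T, C = G).

## ANR motif discovery

Every width-w window of the region set, on both strands, is modelled as a
two-component mixture: a motif occurrence with prior λ (ANR — any number
of occurrences per region) or background. MAP-EM with a Dirichlet prior
on the probability matrix (pseudocount 0.1 × stationary frequency per
cell, applied everywhere motifs are normalised) maximises the
log-likelihood ratio against the all-background model plus the log prior;
this objective is mathematically non-decreasing and the implementation
raises if it ever drops beyond float roundoff. λ is initialised at 1/550
(one expected site per region) and clipped to [1e-8, 0.5].

**Search strategy.** For each width in the sweep {8, 10, 12, 15, 18, 21,
25, 29, 34, 41, 50} (a geometric ladder over the 8–50 bp range,
configurable to exhaustive), candidate seeds are the 100 w-mers with the
highest background-corrected frequency (count over expected count; ties
broken lexicographically). The 16 best-ranked seeds are scored by their
initial-matrix mixture objective (seed base probability 0.55) and the top
2 run EM for up to 10 iterations. Objectives are not comparable across
widths — wider motifs accumulate likelihood on uninformative columns — so
the per-width winner is penalised BIC-style by 1.5·ln(n)·w before widths
compete. The overall winner is then warm-started and run to full
convergence (relative improvement < 1e-6 or 50 iterations). Flanking
columns with information content below 0.2 bits are trimmed (down to the
minimum width), as flat flanks carry no binding signal.

**Significance.** Analytic MEME-style E-values are not re-derived.
Instead, each candidate's sweep-budget objective is compared with the best
objective found by the *identical* search protocol (same width, same seed
ranking, one refinement) on R = 20 mononucleotide-preserving shuffles of
the current regions: E = (1 + #{null ≥ observed}) / (R + 1). Ties within
roundoff count as null exceedances, so degenerate inputs (e.g.
homopolymer regions, which are invariant under shuffling) are always
rejected. The 0.1 reporting threshold applies to this proxy; its floor is
1/21 ≈ 0.048, and printed E-values are not comparable with MEME's. The
shuffle search refines one seed where the observed search refines two,
a slight anti-conservative bias accepted for speed; the null-condition
benchmark below bounds its practical effect. Reported motifs' sites
(posterior > 0.5) are masked with `N` and the search repeats, up to
`max_motifs`; the loop stops at the first insignificant candidate.

**Performance.** The E/M pass is a single fused numba kernel over the
window matrix (uint8), with saturation guards on the posterior; a full
pipeline run on a ~270 kb simulated genome takes roughly 10 s on one CPU.

## Scanning and multiple testing

Scanning scores each window by log₂ odds against the order-0 stationary
background — even when a higher-order background is available, mirroring
FIMO's p-value construction and documented as a divergence source. The
score matrix is discretised onto a shared integer grid (1000 bins over the
achievable score range) and the exact null distribution of a random w-mer
is obtained by column-wise convolution under the stationary frequencies.
Windows are scored on the same grid, so reported p-values are exact for
the discretised matrix; tests assert equality with exhaustive enumeration
over all 4^w words for w ≤ 8 and a per-window score discretisation error
below w/2 bin widths. Benjamini–Hochberg q-values are computed per motif
across *all* tested positions (both strands, N-free; the BH denominator
equals the tested-position count, asserted in tests), and hits are
reported at q ≤ 0.05, deduplicated by genomic (contig, start, strand). A
site is "in" a region iff its start coordinate lies in the region's
interval — a deterministic boundary rule.

## Criteria and footprinting

Criterion A passes at ≤ 1000 q-passing sites (1000 passes, 1001 fails);
Criterion B passes at a fraction strictly greater than 0.10 (10.1%
passes, exactly 10.0% fails); zero sites fail B. Footprinting pools each
seed's own 550-bp region with its `top_n = 20` highest-ranked homolog
regions (rank = the homolog table's score column, descending significance;
a seed with fewer homologs contributes all it has), discovers on the pool,
scans the genome's own regions, re-estimates each motif from the
strand-oriented sequences of its q-passing in-genome sites (one
refinement round), rescans, and keeps a motif if either round passes both
criteria. Homolog retrieval itself (e.g. BLASTP against a reference
database) is consumed as an input table, not performed.

## Synthetic data

The generator emulates the structure the pipeline assumes in real data.
Defaults: 300 genes in operons of 1–4 genes (uniform), gene lengths
300–900 bp, within-operon gaps 10–60 bp, between-operon gaps 560–800 bp
(wide enough that every first gene has a clean upstream window), GC 0.5,
one contig (~270 kb). A 30-operon regulon carries one planted site per
first-gene window: the planted consensus is by default the 15-bp perfect
palindrome `TCCCGGTSACCGGGA`, sampled with 0–1 substitutions per site at
a uniform offset 20–470 within the oriented window, on a uniformly random
strand. Regulon genes draw fold from U(3, 50) and q from U(1e-6, 0.05);
background genes draw fold from U(0.8, 1.25) and q from U(0.06, 1) — the
q floor keeps background genes deterministically non-significant so the
generator's contract (induced genes always pass the selection rule,
background genes never do) holds exactly. Homologs are substitution-only
copies (no indels, so site offsets are preserved): 10% per-base
substitution outside planted sites and a quarter of that inside them,
ranked by observed identity. The null condition keeps the induced
expression pattern but plants no motif, so expression carries no sequence
signal while the pipeline still runs in full.

What the benchmarks do **not** show: real promoters are not i.i.d.
sequence (they contain −10/−35 elements, RNA-binding structures and
compositional bias that inflate motif discovery's false-positive pressure),
real homologs diverge by indels and rearrangement, real DEG tables have
correlated errors, and operon calls are imperfect. Passing synthetic
recovery therefore validates the machinery and its statistics, not
biological sensitivity on any particular genome.

## Benchmark problem sizes

The replicated studies behind the test suite and `scripts/acceptance.py`
use: pipeline recovery — 20 seeded simulations at the default study size
(30-operon regulon), two motif rounds per run; footprinting recovery — 10
seeded 8-operon clusters (150 genes, 20 homologs per seed); null
condition — 50 seeded runs. The acceptance script runs 5/3/10 replicates
of the same three studies. These sizes were chosen as the smallest giving
stable pass/fail statistics for the rates being estimated.

## Known limitations

* The empirical E proxy saturates at 1/(R+1) and cannot reproduce printed
  MEME E-values; it only thresholds discovery.
* Exact p-values are exact for the *discretised* score matrix; extremely
  fine score distinctions below one bin width are not resolved.
* The ANR model has no per-region occurrence cap; a pathological region
  set consisting of one repeated k-mer is rejected only by the shuffle
  null, not by the likelihood itself.
* With highly conserved homologs (the synthetic default of 90% identity),
  footprinting legitimately reports additional "conserved promoter
  segment" motifs besides the planted one; on real, more diverged
  homologs these are rarer. Step 6 removes them only when they fail the
  site-count or first-gene-enrichment filters.
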