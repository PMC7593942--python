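"""De novo motif discovery with a two-component ANR mixture model.

The model follows the MEME "any number of repetitions" formulation: every
width-``w`` window of the input regions (both strands) is either a motif
occurrence, drawn column-wise from a position probability matrix ``theta``,
or background, drawn from the order-0 stationary distribution of a Markov
background model.  A window is a site with prior probability ``lambda``.
EM alternates the posterior site probability of each window (E-step) with
the Dirichlet-regularised update of ``theta`` and ``lambda`` (M-step); the
penalised log-likelihood-ratio objective is non-decreasing by construction
and asserted at every iteration.

Motif significance is an empirical E-value proxy: the best objective found
on the real regions is compared with the best objectives found on
mononucleotide-preserving shuffles of the same regions,
``E = (1 + #{null >= observed}) / (R + 1)``.  Analytic MEME E-values are not
reproduced; the discovery threshold (E <= 0.1) applies to this proxy.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from typing import Mapping, Sequence

import numba
import numpy as np

from .io_formats import (
    DNA_ALPHABET,
    EmptyInputError,
    encode_sequence,
    iupac_reverse_complement,
    reverse_complement,
)

logger = logging.getLogger(__name__)

#: Default width sweep inside the 8-50 bp range (geometric-ish ladder;
#: exhaustive sweep available via ``width_sweep="all"``).
DEFAULT_WIDTH_SWEEP = (8, 10, 12, 15, 18, 21, 25, 29, 34, 41, 50)

_IUPAC_PAIR = {
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
}

PSEUDOCOUNT_WEIGHT = 0.1   # Dirichlet weight, scaled by stationary background
EM_TOL = 1e-6
EM_MAX_ITER = 50
SWEEP_MAX_ITER = 10        # short EM during the width sweep; winner converges fully
SITE_PRIOR = 1.0 / 550.0   # initial per-window site probability
SEED_MATCH_PROB = 0.55     # seed-base probability when initialising theta
N_SEED_EVAL = 16           # pool members given a one-iteration EM score
TRIM_IC_BITS = 0.20        # flanking columns below this information content are trimmed


# ---------------------------------------------------------------------------
# background model
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BackgroundModel:
    """Order-``k`` Markov background over ACGT.

    ``conditional_probs`` maps each length-``k`` context to a 4-vector of
    next-base probabilities; ``stationary`` is the single-base marginal the
    chain implies.  Frequencies are counted on both strands with add-0.1
    smoothing per cell, mirroring the MEME-suite background tool.
    """

    order: int
    conditional_probs: dict[str, np.ndarray]
    stationary: np.ndarray

    def log_stationary(self) -> np.ndarray:
        return np.log(self.stationary)


def build_background(sequences: Sequence[str], order: int = 0) -> BackgroundModel:
    """Estimate an order-``k`` background from sequences (plus reverse strands)."""
    if order < 0:
        raise ValueError(f"background order must be >= 0, got {order}")
    seqs = [s.upper() for s in sequences if s]
    if not seqs or sum(len(s) for s in seqs) == 0:
        raise EmptyInputError("cannot build a background model from empty input")

    both = list(seqs) + [reverse_complement(s) for s in seqs]
    contexts = ["".join(c) for c in itertools.product(DNA_ALPHABET, repeat=order)]
    counts = {c: np.full(4, 0.1) for c in contexts}  # add-0.1 smoothing
    index = {b: i for i, b in enumerate(DNA_ALPHABET)}
    for seq in both:
        for i in range(len(seq) - order):
            ctx = seq[i:i + order]
            nxt = seq[i + order]
            if nxt not in index or any(b not in index for b in ctx):
                continue  # skip windows touching N
            counts[ctx][index[nxt]] += 1.0
    conditional = {c: v / v.sum() for c, v in counts.items()}
    stationary = _stationary_of(conditional, order)
    return BackgroundModel(order=order, conditional_probs=conditional, stationary=stationary)


def _stationary_of(conditional: Mapping[str, np.ndarray], order: int) -> np.ndarray:
    if order == 0:
        return np.array(conditional[""], dtype=float)
    contexts = sorted(conditional)
    n = len(contexts)
    ctx_index = {c: i for i, c in enumerate(contexts)}
    trans = np.zeros((n, n))
    for c in contexts:
        for b_idx, b in enumerate(DNA_ALPHABET):
            nxt = (c + b)[1:]
            trans[ctx_index[c], ctx_index[nxt]] += conditional[c][b_idx]
    # power iteration for the stationary context distribution
    pi = np.full(n, 1.0 / n)
    for _ in range(200):
        new = pi @ trans
        new /= new.sum()
        if np.abs(new - pi).max() < 1e-12:
            pi = new
            break
        pi = new
    stationary = np.zeros(4)
    for c, w in zip(contexts, pi):
        stationary[DNA_ALPHABET.index(c[-1])] += w
    return stationary / stationary.sum()


# ---------------------------------------------------------------------------
# motif record
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Motif:
    """A discovered motif: count and probability matrices plus bookkeeping.

    ``sites`` records the supporting windows as ``(region_index, offset,
    strand)`` in the coordinates of the oriented region sequences.
    """

    motif_id: str
    counts: np.ndarray
    probs: np.ndarray
    nsites: float
    significance: float
    sites: list[tuple[int, int, str]] = dataclasses.field(default_factory=list)
    objective: float = 0.0

    @property
    def width(self) -> int:
        return int(self.probs.shape[0])

    @property
    def consensus(self) -> str:
        return consensus_of(self)

    def information_content(self, background: np.ndarray | None = None) -> np.ndarray:
        """Per-column information content in bits relative to the background."""
        bg = np.full(4, 0.25) if background is None else np.asarray(background)
        p = np.clip(self.probs, 1e-12, 1.0)
        return (p * np.log2(p / bg)).sum(axis=1)


def consensus_of(motif: Motif, strong: float = 0.5, pair: float = 0.8) -> str:
    """IUPAC consensus: dominant base, two-letter code, or N per column.

    A column reports its single top base when that base's probability is at
    least ``strong`` and it is the unique maximum; otherwise the two-letter
    IUPAC code when the top two probabilities sum to at least ``pair``;
    otherwise ``N``.
    """
    letters = []
    for row in motif.probs:
        order = np.argsort(row)[::-1]
        top, second = order[0], order[1]
        if row[top] >= strong and row[top] > row[second]:
            letters.append(DNA_ALPHABET[top])
        elif row[top] + row[second] >= pair:
            letters.append(_IUPAC_PAIR[frozenset((DNA_ALPHABET[top], DNA_ALPHABET[second]))])
        else:
            letters.append("N")
    return "".join(letters)


def is_palindrome(consensus: str) -> bool:
    """True iff the IUPAC consensus equals its own IUPAC reverse complement."""
    return iupac_reverse_complement(consensus) == consensus.upper()


# ---------------------------------------------------------------------------
# window bookkeeping
# ---------------------------------------------------------------------------

class _WindowSet:
    """All width-``w`` windows of a region set, both strands, N-free.

    Windows are stored as an ``(n, w)`` uint8 matrix with provenance arrays
    ``region_idx``, ``offset`` (position of the window in the *oriented*
    region sequence) and ``strand`` ('+' = as-written, '-' = reverse
    complement of the written sequence).
    """

    def __init__(self, sequences: Sequence[str], width: int, both_strands: bool = True):
        mats, regions, offsets, strands = [], [], [], []
        for idx, seq in enumerate(sequences):
            enc = encode_sequence(seq)
            if len(enc) < width:
                continue
            wins = np.lib.stride_tricks.sliding_window_view(enc, width)
            ok = ~(wins == 255).any(axis=1)
            pos = np.nonzero(ok)[0]
            if pos.size:
                mats.append(wins[pos])
                regions.append(np.full(pos.size, idx, dtype=np.int32))
                offsets.append(pos.astype(np.int32))
                strands.append(np.zeros(pos.size, dtype=np.uint8))
            if both_strands:
                rev = enc[::-1].astype(np.int16)
                rc = (3 - rev)
                rc[rev == 255] = 255
                wins_rc = np.lib.stride_tricks.sliding_window_view(rc.astype(np.uint8), width)
                ok = ~(wins_rc == 255).any(axis=1)
                pos = np.nonzero(ok)[0]
                if pos.size:
                    mats.append(wins_rc[pos])
                    regions.append(np.full(pos.size, idx, dtype=np.int32))
                    # rc-window at rc-offset p covers oriented [L-p-w, L-p)
                    offsets.append((len(enc) - pos - width).astype(np.int32))
                    strands.append(np.ones(pos.size, dtype=np.uint8))
        if mats:
            self.windows = np.concatenate(mats).astype(np.uint8)
            self.region_idx = np.concatenate(regions)
            self.offset = np.concatenate(offsets)
            self.strand = np.concatenate(strands)
        else:
            self.windows = np.empty((0, width), dtype=np.uint8)
            self.region_idx = np.empty(0, dtype=np.int32)
            self.offset = np.empty(0, dtype=np.int32)
            self.strand = np.empty(0, dtype=np.uint8)
        self.width = width
        self.n = self.windows.shape[0]
    def log_background(self, stationary: np.ndarray) -> np.ndarray:
        logbg = np.log(stationary)
        return logbg[self.windows].sum(axis=1)


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class _EMResult:
    theta: np.ndarray
    lam: float
    objective: float
    z: np.ndarray
    counts: np.ndarray


@numba.njit(fastmath=False)
def _anr_pass(W, logpbg, logtheta, loglam, log1mlam, counts, z):  # pragma: no cover
    """One fused E/M pass: objective at the current parameters, posterior
    site probabilities ``z`` and weighted base counts for the update."""
    n, w = W.shape
    obj = 0.0
    for j in range(w):
        for b in range(4):
            counts[j, b] = 0.0
    for i in range(n):
        a = loglam
        for j in range(w):
            a += logtheta[j, W[i, j]]
        b_ = logpbg[i] + log1mlam
        d = b_ - a
        if d > 35.0:
            zi = 0.0
            obj += b_ - logpbg[i]
        elif d < -35.0:
            zi = 1.0
            obj += a - logpbg[i]
        else:
            hi = a if a > b_ else b_
            obj += hi + math.log1p(math.exp(-abs(d))) - logpbg[i]
            zi = 1.0 / (1.0 + math.exp(d))
        z[i] = zi
        if zi > 1e-12:
            for j in range(w):
                counts[j, W[i, j]] += zi
    return obj


def _run_em(
    ws: _WindowSet,
    logpbg: np.ndarray,
    theta0: np.ndarray,
    stationary: np.ndarray,
    lam0: float = SITE_PRIOR,
    max_iter: int = EM_MAX_ITER,
    tol: float = EM_TOL,
) -> _EMResult:
    """MAP-EM for the two-component ANR mixture.

    The objective is the observed-data log-likelihood ratio against the
    all-background model plus the Dirichlet log-prior on ``theta``; it is
    non-decreasing across iterations (asserted, with numerical slack).
    """
    W = np.ascontiguousarray(ws.windows)
    n, w = ws.n, ws.width
    pc = (PSEUDOCOUNT_WEIGHT * stationary)[None, :].repeat(w, axis=0)  # (w,4)
    theta = np.clip(theta0, 1e-9, 1.0)
    theta = theta / theta.sum(axis=1, keepdims=True)
    lam = float(np.clip(lam0, 1e-8, 0.5))
    logpbg64 = np.ascontiguousarray(logpbg, dtype=np.float64)
    prev_obj = -np.inf
    z = np.zeros(n)
    counts = np.zeros((w, 4))
    obj = -np.inf
    for _ in range(max_iter):
        logtheta = np.log(theta)
        obj = _anr_pass(W, logpbg64, logtheta, math.log(lam), math.log1p(-lam),
                        counts, z)
        obj = float(obj + (pc * logtheta).sum())
        # MAP-EM makes this objective non-decreasing; fail loudly if not
        if obj < prev_obj - 1e-9 * (1.0 + abs(prev_obj)):
            raise AssertionError(
                f"EM objective decreased: {prev_obj} -> {obj}")
        converged = obj - prev_obj < tol * (1.0 + abs(obj))
        prev_obj = obj
        theta = (counts + pc) / (counts + pc).sum(axis=1, keepdims=True)
        lam = float(np.clip(z.mean(), 1e-8, 0.5))
        if converged:
            break
    return _EMResult(theta=theta, lam=lam, objective=obj, z=z.copy(),
                     counts=counts.copy())


def _seed_theta(wmer: np.ndarray, stationary: np.ndarray) -> np.ndarray:
    w = wmer.shape[0]
    theta = np.full((w, 4), (1.0 - SEED_MATCH_PROB) / 3.0)
    theta[np.arange(w), wmer] = SEED_MATCH_PROB
    return theta


def _top_seed_wmers(ws: _WindowSet, stationary: np.ndarray, n_starts: int) -> np.ndarray:
    """The highest background-corrected-frequency w-mers among the windows."""
    wins = np.ascontiguousarray(ws.windows)
    void = wins.view(np.dtype((np.void, ws.width)))[:, 0]
    uniq, counts = np.unique(void, return_counts=True)  # lexicographically sorted
    arr = uniq.view(np.uint8).reshape(len(uniq), ws.width)
    logbg = np.log(stationary)
    scores = np.log(counts.astype(np.float64)) - logbg[arr].sum(axis=1)
    # stable sort on -score keeps the lexicographic order as the tie-break
    order = np.argsort(-scores, kind="stable")[:n_starts]
    return arr[order].copy()


def _evaluate_seeds(
    ws: _WindowSet,
    logpbg: np.ndarray,
    seeds: np.ndarray,
    stationary: np.ndarray,
) -> np.ndarray:
    """Mixture objective of each seed's initial matrix (cheap seed ranking)."""
    objs = np.empty(len(seeds))
    for k, seed in enumerate(seeds):
        em = _run_em(ws, logpbg, _seed_theta(seed, stationary), stationary,
                     max_iter=1, tol=-1.0)
        objs[k] = em.objective
    return objs


@dataclasses.dataclass
class _Candidate:
    width: int
    em: _EMResult
    ws: _WindowSet
    penalized: float


def _best_motif_at_width(
    sequences: Sequence[str],
    width: int,
    stationary: np.ndarray,
    both_strands: bool,
    n_starts: int,
    n_refine: int,
    max_iter: int = EM_MAX_ITER,
) -> _Candidate | None:
    ws = _WindowSet(sequences, width, both_strands=both_strands)
    if ws.n < 2:
        return None
    logpbg = ws.log_background(stationary)
    seeds = _top_seed_wmers(ws, stationary, n_starts)
    if seeds.size == 0:
        return None
    # the pool is ranked by background-corrected frequency; the one-iteration
    # EM score decides among the best-ranked members only
    seeds = seeds[:N_SEED_EVAL]
    objs = _evaluate_seeds(ws, logpbg, seeds, stationary)
    order = np.argsort(objs)[::-1][:n_refine]
    best: _EMResult | None = None
    for idx in order:
        em = _run_em(ws, logpbg, _seed_theta(seeds[idx], stationary), stationary,
                     max_iter=max_iter)
        if best is None or em.objective > best.objective:
            best = em
    if best is None:
        return None
    # BIC-style penalty makes objectives comparable across widths
    penalized = best.objective - 1.5 * np.log(max(ws.n, 2)) * width
    return _Candidate(width=width, em=best, ws=ws, penalized=penalized)


def _converge_candidate(cand: _Candidate, stationary: np.ndarray) -> _Candidate:
    """Warm-start the sweep winner and run EM to full convergence."""
    logpbg = cand.ws.log_background(stationary)
    em = _run_em(cand.ws, logpbg, cand.em.theta, stationary,
                 lam0=cand.em.lam, max_iter=EM_MAX_ITER)
    penalized = em.objective - 1.5 * np.log(max(cand.ws.n, 2)) * cand.width
    return _Candidate(width=cand.width, em=em, ws=cand.ws, penalized=penalized)


def _shuffle_evalue(
    sequences: Sequence[str],
    width: int,
    observed_objective: float,
    stationary: np.ndarray,
    both_strands: bool,
    n_starts: int,
    rng: np.random.Generator,
    n_shuffles: int,
    max_evalue: float = 1.0,
) -> float:
    """Empirical E-value proxy from mononucleotide-preserving shuffles.

    Stops early once enough null exceedances have accrued that the E proxy
    cannot come back under ``max_evalue``; the motif is rejected either way.
    """
    exceed = 0
    done = 0
    for _ in range(n_shuffles):
        shuffled = ["".join(rng.permutation(list(s))) for s in sequences]
        cand = _best_motif_at_width(
            shuffled, width, stationary, both_strands,
            n_starts=n_starts, n_refine=1, max_iter=SWEEP_MAX_ITER)
        done += 1
        # ties (within roundoff) count as null exceedances
        if cand is not None and cand.em.objective >= observed_objective - 1e-9 * (
                1.0 + abs(observed_objective)):
            exceed += 1
            if (1 + exceed) / (n_shuffles + 1) > max_evalue:
                return (1 + exceed) / (done + 1)
    return (1 + exceed) / (n_shuffles + 1)


def _trim_candidate(cand: _Candidate, stationary: np.ndarray, wmin: int) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Trim flanking low-information columns; returns (counts, theta, left, right)."""
    theta = cand.em.theta
    counts = cand.em.counts
    p = np.clip(theta, 1e-12, 1.0)
    ic = (p * np.log2(p / stationary)).sum(axis=1)
    left, right = 0, theta.shape[0]
    while right - left > wmin and ic[left] < TRIM_IC_BITS:
        left += 1
    while right - left > wmin and ic[right - 1] < TRIM_IC_BITS:
        right -= 1
    return counts[left:right], theta[left:right], left, theta.shape[0] - right


def discover_motifs(
    regions: Sequence,
    wmin: int = 8,
    wmax: int = 50,
    max_evalue: float = 0.1,
    max_motifs: int = 5,
    both_strands: bool = True,
    seed: int = 1,
    background: BackgroundModel | None = None,
    width_sweep: Sequence[int] | str | None = None,
    n_starts: int = 100,
    n_refine: int = 2,
    n_shuffles: int = 20,
) -> list[Motif]:
    """Iterative ANR motif discovery over promoter regions.

    For each width in the sweep the best EM solution from the top seed
    w-mers is kept; the best width (penalised objective) becomes a
    candidate motif, its significance is estimated by shuffle null, and, if
    it passes ``max_evalue``, its sites are masked with ``N`` and the search
    repeats, up to ``max_motifs`` motifs.  Output is ordered by significance
    (ties by objective, descending).

    ``regions`` may be :class:`~regulonmotifs.regions.PromoterRegion`
    objects or plain strings.
    """
    if wmin > wmax:
        raise ValueError(f"wmin {wmin} > wmax {wmax}")
    sequences = [r if isinstance(r, str) else r.sequence for r in regions]
    if len(sequences) < 2:
        raise ValueError("motif discovery requires at least 2 regions")
    if background is None:
        background = build_background(sequences, order=0)
    stationary = background.stationary

    if width_sweep == "all":
        widths = list(range(wmin, wmax + 1))
    elif width_sweep is not None:
        widths = [w for w in width_sweep if wmin <= w <= wmax]
    else:
        widths = [w for w in DEFAULT_WIDTH_SWEEP if wmin <= w <= wmax]
        if not widths:
            widths = [wmin]

    rng = np.random.default_rng(seed)
    work = [list(s) for s in sequences]  # mutable copies for masking
    motifs: list[Motif] = []

    for motif_no in range(1, max_motifs + 1):
        current = ["".join(s) for s in work]
        best: _Candidate | None = None
        for w in widths:
            cand = _best_motif_at_width(
                current, w, stationary, both_strands, n_starts, n_refine,
                max_iter=SWEEP_MAX_ITER)
            if cand is not None and (best is None or cand.penalized > best.penalized):
                best = cand
        if best is None:
            break
        # the null comparison uses the sweep-budget objective so observed and
        # shuffled data get the same search effort
        sweep_objective = best.em.objective
        best = _converge_candidate(best, stationary)
        site_mask = best.em.z > 0.5
        if site_mask.sum() < 2:
            break
        sub_seed = int(rng.integers(0, 2**31 - 1))
        evalue = _shuffle_evalue(
            current, best.width, sweep_objective, stationary, both_strands,
            n_starts, np.random.default_rng(sub_seed), n_shuffles,
            max_evalue=max_evalue)
        if evalue > max_evalue:
            break

        counts, theta, trim_left, trim_right = _trim_candidate(best, stationary, wmin)
        new_width = theta.shape[0]
        idx = np.nonzero(site_mask)[0]
        sites: list[tuple[int, int, str]] = []
        for i in idx:
            reg = int(best.ws.region_idx[i])
            off = int(best.ws.offset[i])
            strand = "+" if best.ws.strand[i] == 0 else "-"
            # map trimming into the oriented-region frame
            if strand == "+":
                off_t = off + trim_left
            else:
                off_t = off + trim_right
            sites.append((reg, off_t, strand))
            # mask the untrimmed window span
            for j in range(off, off + best.width):
                if 0 <= j < len(work[reg]):
                    work[reg][j] = "N"
        motif = Motif(
            motif_id=f"motif_{motif_no}",
            counts=counts,
            probs=theta,
            nsites=float(site_mask.sum()),
            significance=evalue,
            sites=sites,
            objective=best.em.objective,
        )
        motifs.append(motif)
        logger.info(
            "motif %s: width %d, %d sites, E=%.3g, consensus %s",
            motif.motif_id, new_width, len(sites), evalue, motif.consensus)

    motifs.sort(key=lambda m: (m.significance, -m.objective))
    for i, m in enumerate(motifs, start=1):
        m.motif_id = f"motif_{i}"
    return motifs


def reestimate_from_sites(
    sites: Sequence,
    genome,
    width: int,
    background: BackgroundModel,
) -> Motif:
    """Rebuild a motif from the strand-oriented sequences of genomic sites.

    Counts are plain per-column base counts of the (reverse-complemented
    where on '-') site sequences; probabilities add the standard pseudocount
    of ``0.1 x stationary`` per cell.
    """
    if len(sites) < 2:
        raise ValueError(
            f"re-estimation requires at least 2 sites, got {len(sites)}")
    genomes = {genome.contig_id: genome} if not isinstance(genome, (list, tuple)) else {
        g.contig_id: g for g in genome}
    counts = np.zeros((width, 4))
    for site in sites:
        g = genomes[site.contig_id]
        seq = g.sequence[site.start:site.start + width]
        if len(seq) != width:
            raise ValueError(
                f"site at {site.contig_id}:{site.start} truncated by contig edge")
        if site.strand == "-":
            seq = reverse_complement(seq)
        enc = encode_sequence(seq)
        if (enc == 255).any():
            continue
        counts[np.arange(width), enc] += 1.0
    pc = PSEUDOCOUNT_WEIGHT * background.stationary
    probs = (counts + pc) / (counts + pc).sum(axis=1, keepdims=True)
    return Motif(
        motif_id=getattr(sites[0], "motif_id", "reestimated"),
        counts=counts,
        probs=probs,
        nsites=float(len(sites)),
        significance=0.0,
    )
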