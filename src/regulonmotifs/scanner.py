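"""Genome-wide PWM scanning with exact p-values and BH q-values.

Scores are log-odds in bits against the order-0 stationary background.  For
p-values the score matrix is discretised onto a shared integer grid and the
null score distribution of a random w-mer is obtained by exact dynamic
programming (column-wise convolution under the stationary base frequencies),
the same construction FIMO uses.  Every scanned window is scored on the
discretised grid, so reported p-values are exact for the discretised matrix;
the grid has 1000 bins by default and the discretisation error of the score
itself is bounded by ``width x binwidth / 2``.

Multiple testing is controlled per motif with Benjamini-Hochberg across all
tested window positions (both strands, N-free), and hits are reported at
q <= 0.05 by default.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .io_formats import GenomeRecord, encode_sequence
from .motif_discovery import BackgroundModel, Motif
from .regions import PromoterRegion


@dataclasses.dataclass(frozen=True)
class SiteHit:
    """A motif occurrence in genomic coordinates (0-based, forward strand)."""

    motif_id: str
    contig_id: str
    start: int
    strand: str
    width: int
    score: float
    p_value: float
    q_value: float
    region_locus: str | None = None

    @property
    def end(self) -> int:
        return self.start + self.width


class ScanResult(Sequence):
    """Coordinate-sorted q-passing hits plus the BH test count."""

    def __init__(self, hits: list[SiteHit], n_tested: int):
        self.hits = hits
        self.n_tested = n_tested

    def __getitem__(self, i):
        return self.hits[i]

    def __len__(self) -> int:
        return len(self.hits)


def log_odds(motif: Motif, background: BackgroundModel) -> np.ndarray:
    """Log2 odds matrix: ``log2(motif prob / stationary background prob)``."""
    bg = np.asarray(background.stationary, dtype=float)
    if np.any(bg <= 0):
        raise ValueError("background stationary frequencies must be positive")
    probs = np.clip(np.asarray(motif.probs, dtype=float), 1e-12, 1.0)
    return np.log2(probs / bg)


@dataclasses.dataclass
class ScorePValueTable:
    """Exact null distribution of discretised PWM scores.

    ``int_matrix`` holds the discretised (integer) log-odds entries;
    ``pvalue_of_int`` maps an integer window score to
    ``P(random w-mer scores >= s)`` under the stationary background.
    """

    int_matrix: np.ndarray
    bin_width: float
    min_int_score: int
    survival: np.ndarray  # survival[k] = P(int score >= min_int_score + k)

    def pvalue_of_int(self, scores: np.ndarray) -> np.ndarray:
        raw = np.asarray(scores) - self.min_int_score
        idx = np.clip(raw, 0, len(self.survival) - 1)
        p = self.survival[idx]
        p = np.where(raw <= 0, 1.0, p)
        p = np.where(raw > len(self.survival) - 1, 0.0, p)
        return p

    def pvalue(self, score: float) -> float:
        """p-value of a raw (bit) score threshold."""
        s = int(np.round(score / self.bin_width)) if self.bin_width > 0 else 0
        return float(self.pvalue_of_int(np.array([s]))[0])


def score_pvalues(lom: np.ndarray, background: BackgroundModel, bins: int = 1000) -> ScorePValueTable:
    """Exact p-values for all discretised scores of a log-odds matrix."""
    if bins < 10:
        raise ValueError(f"bins must be >= 10, got {bins}")
    lom = np.asarray(lom, dtype=float)
    if not np.all(np.isfinite(lom)):
        raise ValueError("log-odds matrix contains non-finite entries")
    span = lom.max(axis=1).sum() - lom.min(axis=1).sum()
    bin_width = span / bins if span > 0 else 1.0
    int_matrix = np.round(lom / bin_width).astype(np.int64)

    bg = np.asarray(background.stationary, dtype=float)
    col_min = int_matrix.min(axis=1)
    col_max = int_matrix.max(axis=1)
    min_score, max_score = int(col_min.sum()), int(col_max.sum())
    size = max_score - min_score + 1
    pmf = np.zeros(size)
    pmf[0] = 1.0
    total_min = 0
    for i in range(int_matrix.shape[0]):
        new = np.zeros(size)
        for b in range(4):
            shift = int(int_matrix[i, b] - col_min[i])
            new[shift:] += bg[b] * pmf[: size - shift if shift else size]
        pmf = new
        total_min += col_min[i]
    survival = np.cumsum(pmf[::-1])[::-1]
    survival = np.clip(survival, 0.0, 1.0)
    return ScorePValueTable(
        int_matrix=int_matrix,
        bin_width=bin_width,
        min_int_score=min_score,
        survival=survival,
    )


def bh_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _window_int_scores(enc: np.ndarray, table: ScorePValueTable) -> tuple[np.ndarray, np.ndarray]:
    """Discretised scores for all N-free forward windows of an encoded sequence.

    Returns (positions, int_scores).
    """
    w = table.int_matrix.shape[0]
    if len(enc) < w:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    wins = np.lib.stride_tricks.sliding_window_view(enc, w)
    ok = ~(wins == 255).any(axis=1)
    pos = np.nonzero(ok)[0]
    if pos.size == 0:
        return pos, np.empty(0, dtype=np.int64)
    wins = wins[pos]
    scores = table.int_matrix[np.arange(w)[None, :], wins].sum(axis=1)
    return pos, scores


def _float_scores(enc_windows_pos: np.ndarray, enc: np.ndarray, lom: np.ndarray) -> np.ndarray:
    w = lom.shape[0]
    if enc_windows_pos.size == 0:
        return np.empty(0)
    wins = np.lib.stride_tricks.sliding_window_view(enc, w)[enc_windows_pos]
    return lom[np.arange(w)[None, :], wins].sum(axis=1)


def scan(
    targets,
    motif: Motif,
    background: BackgroundModel,
    max_q: float = 0.05,
    bins: int = 1000,
    regions: Sequence[PromoterRegion] | None = None,
) -> ScanResult:
    """Scan a genome or a promoter-region set for occurrences of a motif.

    Every position on both strands is scored; p-values come from the exact
    discretised null, q-values from per-motif BH over all tested positions.
    Hits with ``q <= max_q`` are returned in genomic coordinate order,
    deduplicated by (contig, start, strand).  When scanning regions, each
    hit is annotated with its region's locus; when scanning a genome with
    ``regions`` supplied, a hit is annotated with any region whose interval
    contains the hit start.
    """
    if isinstance(targets, GenomeRecord):
        targets = [targets]
    targets = list(targets)
    if not targets:
        return ScanResult([], 0)
    scanning_regions = isinstance(targets[0], PromoterRegion)

    w = motif.width
    lom = log_odds(motif, background)
    table = score_pvalues(lom, background, bins=bins)

    # one block per (target, scanned strand); only arrays are kept per window
    blocks = []  # (target, enc_strand, pos, p, fscores)
    n_tested = 0
    for tgt in targets:
        seq = tgt.sequence
        if len(seq) < w:
            if not scanning_regions:
                raise ValueError(
                    f"motif width {w} exceeds target "
                    f"{getattr(tgt, 'contig_id', '?')} length {len(seq)}")
            continue
        enc = encode_sequence(seq)
        rev = enc[::-1].astype(np.int16)
        rc = 3 - rev
        rc[rev == 255] = 255
        enc_rc = rc.astype(np.uint8)
        for enc_strand, arr in (("fwd", enc), ("rc", enc_rc)):
            pos, iscores = _window_int_scores(arr, table)
            n_tested += pos.size
            if pos.size == 0:
                continue
            p = table.pvalue_of_int(iscores)
            fscores = _float_scores(pos, arr, lom)
            blocks.append((tgt, enc_strand, pos, p, fscores))

    if not blocks:
        return ScanResult([], n_tested)
    # BH across ALL tested positions (every N-free window is recorded above,
    # so the BH denominator equals n_tested)
    all_p = np.concatenate([b[3] for b in blocks])
    all_q = bh_qvalues(all_p)

    region_index = None
    if regions is not None and not scanning_regions:
        region_index = sorted(regions, key=lambda r: (r.contig_id, r.start))

    hits: list[SiteHit] = []
    seen: set[tuple[str, int, str]] = set()
    cursor = 0
    raw: list[SiteHit] = []
    for tgt, enc_strand, pos, p, fscores in blocks:
        q = all_q[cursor:cursor + pos.size]
        cursor += pos.size
        keep = np.nonzero(q <= max_q)[0]
        L = len(tgt.sequence)
        for k in keep:
            o = int(pos[k])
            if scanning_regions:
                if enc_strand == "fwd":
                    ostart, rel = o, "+"
                else:
                    ostart, rel = L - o - w, "-"
                if tgt.strand == "+":
                    gstart, gstrand = tgt.start + ostart, rel
                else:
                    gstart = tgt.end - ostart - w
                    gstrand = "-" if rel == "+" else "+"
                locus: str | None = tgt.locus_tag
            else:
                if enc_strand == "fwd":
                    gstart, gstrand = o, "+"
                else:
                    gstart, gstrand = L - o - w, "-"
                locus = None
            raw.append(SiteHit(
                motif_id=motif.motif_id, contig_id=tgt.contig_id, start=gstart,
                strand=gstrand, width=w, score=float(fscores[k]),
                p_value=float(p[k]), q_value=float(q[k]), region_locus=locus))
    for hit in sorted(raw, key=lambda h: (h.contig_id, h.start, h.strand)):
        key = (hit.contig_id, hit.start, hit.strand)
        if key in seen:
            continue
        seen.add(key)
        if region_index is not None:
            locus = next(
                (r.locus_tag for r in region_index
                 if r.contig_id == hit.contig_id and r.start <= hit.start < r.end),
                None)
            hit = dataclasses.replace(hit, region_locus=locus)
        hits.append(hit)
    return ScanResult(hits, n_tested)
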