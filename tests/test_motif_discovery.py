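"""Background models, ANR EM discovery, consensus and palindrome utilities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regulonmotifs.io_formats import FormatError, GenomeRecord, reverse_complement
from regulonmotifs.motif_discovery import (
    Motif,
    _WindowSet,
    _run_em,
    _seed_theta,
    build_background,
    consensus_of,
    discover_motifs,
    is_palindrome,
    reestimate_from_sites,
)
from regulonmotifs.scanner import SiteHit

from conftest import random_dna


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------

class TestBuildBackground:
    def test_uniform_composition(self):
        bg = build_background(["ACGTACGTACGT"], order=0)
        np.testing.assert_allclose(bg.stationary, [0.25] * 4, atol=1e-12)

    def test_order1_matches_bigram_counting_oracle(self):
        """Order-1 conditionals equal brute-force bigram ratios with add-0.1
        smoothing, counted on both strands."""
        seq = "ACGGTTACGCATGGCATTACGGATCCGGATACGGTTAACC"  # fixed 40-mer
        bg = build_background([seq], order=1)

        # independent oracle: explicit dictionary counting
        counts = {a: {b: 0.1 for b in "ACGT"} for a in "ACGT"}
        for s in (seq, reverse_complement(seq)):
            for x, y in zip(s, s[1:]):
                counts[x][y] += 1.0
        for ctx in "ACGT":
            total = sum(counts[ctx].values())
            expected = np.array([counts[ctx][b] / total for b in "ACGT"])
            np.testing.assert_allclose(bg.conditional_probs[ctx], expected, atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_background([])

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            build_background(["ACGT"], order=-1)

    def test_rows_normalised_and_stationary_consistent(self, rng):
        seq = random_dna(rng, 500, gc=0.62)
        bg = build_background([seq], order=1)
        for vec in bg.conditional_probs.values():
            assert abs(vec.sum() - 1.0) < 1e-9
        # stationary is the fixed point of the order-1 chain
        pi = bg.stationary
        step = np.zeros(4)
        for i, ctx in enumerate("ACGT"):
            step += pi[i] * bg.conditional_probs[ctx]
        np.testing.assert_allclose(step, pi, atol=1e-8)
        # both-strand counting makes the background strand-symmetric
        np.testing.assert_allclose(pi[0], pi[3], atol=1e-12)  # A == T
        np.testing.assert_allclose(pi[1], pi[2], atol=1e-12)  # C == G


# ---------------------------------------------------------------------------
# consensus / palindrome
# ---------------------------------------------------------------------------

def _motif_from_rows(rows):
    probs = np.asarray(rows, dtype=float)
    return Motif("m", probs * 10, probs, 10, 0.01)


class TestConsensus:
    @pytest.mark.parametrize(
        "row,letter",
        [
            ((0.05, 0.45, 0.45, 0.05), "S"),
            ((1.0, 0.0, 0.0, 0.0), "A"),
            ((0.3, 0.3, 0.2, 0.2), "N"),
            ((0.6, 0.2, 0.1, 0.1), "A"),
            ((0.45, 0.04, 0.06, 0.45), "W"),
        ],
    )
    def test_column_rules(self, row, letter):
        assert consensus_of(_motif_from_rows([row])) == letter

    def test_tied_maximum_below_pair_sum_is_n(self):
        assert consensus_of(_motif_from_rows([(0.39, 0.39, 0.11, 0.11)])) == "N"


class TestIsPalindrome:
    def test_known_palindromic_consensus(self):
        assert is_palindrome("TCCCGGTSACCGGGA")

    def test_self_complementary_word(self):
        assert is_palindrome("ACGT")

    def test_non_palindrome(self):
        assert not is_palindrome("AAA")

    def test_non_iupac_symbol_rejected(self):
        with pytest.raises(FormatError):
            is_palindrome("AXGT")

    @given(st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=30))
    @settings(deadline=None, max_examples=300)
    def test_palindromy_is_strand_invariant(self, s):
        from regulonmotifs.io_formats import iupac_reverse_complement

        assert is_palindrome(s) == is_palindrome(iupac_reverse_complement(s))
        assert is_palindrome(s) == (iupac_reverse_complement(s) == s)


# ---------------------------------------------------------------------------
# EM machinery
# ---------------------------------------------------------------------------

class TestEM:
    def test_objective_monotone_over_iterations(self, rng):
        """The MAP objective never decreases; _run_em raises otherwise, so a
        clean return on many random starts is the assertion."""
        seqs = [random_dna(rng, 200, gc=float(g)) for g in rng.uniform(0.3, 0.7, 12)]
        bg = build_background(seqs)
        ws = _WindowSet(seqs, 10)
        logpbg = ws.log_background(bg.stationary)
        for _ in range(10):
            wmer = rng.integers(0, 4, size=10).astype(np.uint8)
            em = _run_em(ws, logpbg, _seed_theta(wmer, bg.stationary), bg.stationary)
            assert np.isfinite(em.objective)
            assert em.theta.shape == (10, 4)
            np.testing.assert_allclose(em.theta.sum(axis=1), 1.0, atol=1e-9)

    def test_window_set_skips_n_windows(self):
        ws = _WindowSet(["ACGTNACGTACGT"], 4, both_strands=False)
        # positions 1-4 touch the N at index 4
        assert ws.n == 13 - 4 + 1 - 4
        assert not (ws.windows == 255).any()

    def test_window_set_reverse_strand_offsets(self):
        seq = "ACGTTTTT"
        ws = _WindowSet([seq], 5, both_strands=True)
        rc_rows = ws.strand == 1
        # rc window at oriented offset o covers seq[o:o+5] reverse complemented
        for wmer, off in zip(ws.windows[rc_rows], ws.offset[rc_rows]):
            expect = reverse_complement(seq[off:off + 5])
            got = "".join("ACGT"[b] for b in wmer)
            assert got == expect


# ---------------------------------------------------------------------------
# discovery
# ---------------------------------------------------------------------------

def _plant_regions(rng, n_regions=30, length=550, consensus="TACGGCTAGGTCCAT",
                   max_mut=1):
    """Random regions each carrying one planted site with <=max_mut changes."""
    regions = []
    truth = []
    for _ in range(n_regions):
        seq = list(random_dna(rng, length))
        site = list(consensus)
        for pos in rng.choice(len(site), size=int(rng.integers(0, max_mut + 1)),
                              replace=False):
            site[pos] = "ACGT"[int(rng.integers(4))]
        off = int(rng.integers(0, length - len(site)))
        seq[off:off + len(site)] = site
        regions.append("".join(seq))
        truth.append(off)
    return regions, truth


def hamming_to_plant(consensus: str, plant: str) -> int:
    """Distance between a reported consensus and the planted one: the best
    sliding-window Hamming distance over the plant, on either strand.  A
    consensus wider than the plant matches if any window does; a narrower
    consensus pays the missing columns as mismatches."""
    from regulonmotifs.io_formats import iupac_reverse_complement

    best = len(plant)
    for cand in (consensus, iupac_reverse_complement(consensus)):
        if len(cand) >= len(plant):
            for off in range(len(cand) - len(plant) + 1):
                window = cand[off:off + len(plant)]
                best = min(best, sum(a != b for a, b in zip(plant, window)))
        else:
            deficit = len(plant) - len(cand)
            for off in range(deficit + 1):
                window = plant[off:off + len(cand)]
                d = sum(a != b for a, b in zip(cand, window)) + deficit
                best = min(best, d)
    return best


class TestDiscoverMotifs:
    def test_planted_site_recovered(self, rng):
        regions, _ = _plant_regions(rng)
        motifs = discover_motifs(regions, seed=5, max_motifs=1)
        assert motifs, "no motif reported on planted input"
        assert motifs[0].significance <= 0.1
        assert hamming_to_plant(motifs[0].consensus, "TACGGCTAGGTCCAT") <= 2

    def test_reported_motifs_respect_width_and_evalue_bounds(self, rng):
        regions, _ = _plant_regions(rng, n_regions=20)
        for m in discover_motifs(regions, seed=2, max_motifs=2):
            assert 8 <= m.width <= 50
            assert m.significance <= 0.1

    def test_degenerate_homopolymer_input_yields_nothing(self):
        regions = ["A" * 200] * 10
        assert discover_motifs(regions, seed=1) == []

    def test_fewer_than_two_regions_rejected(self):
        with pytest.raises(ValueError):
            discover_motifs(["ACGTACGTACGT"], seed=1)

    def test_bad_width_range_rejected(self):
        with pytest.raises(ValueError):
            discover_motifs(["ACGT" * 40] * 3, wmin=20, wmax=10, seed=1)

    def test_deterministic_given_seed(self, rng):
        regions, _ = _plant_regions(rng, n_regions=15, length=300)
        a = discover_motifs(regions, seed=9, max_motifs=1)
        b = discover_motifs(regions, seed=9, max_motifs=1)
        assert [m.consensus for m in a] == [m.consensus for m in b]
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.probs, mb.probs)
            assert ma.sites == mb.sites

    def test_strand_invariance_up_to_reverse_complement(self, rng):
        from regulonmotifs.io_formats import iupac_reverse_complement

        regions, _ = _plant_regions(rng, n_regions=20, length=300)
        fwd = discover_motifs(regions, seed=4, max_motifs=1)
        rev = discover_motifs([reverse_complement(r) for r in regions],
                              seed=4, max_motifs=1)
        assert len(fwd) == len(rev) == 1
        assert fwd[0].consensus in (
            rev[0].consensus, iupac_reverse_complement(rev[0].consensus))

    def test_masked_sites_not_rediscovered(self, rng):
        """After the first motif's windows are masked, a second motif must not
        overlap them."""
        consensus_a = "TACGGCTAGGTCCAT"
        consensus_b = "GGATCCGGAA"
        regions = []
        occupied = []  # (region_idx, start, end) of first plant
        for i in range(25):
            seq = list(random_dna(rng, 200))
            off_a = int(rng.integers(0, 80))
            seq[off_a:off_a + len(consensus_a)] = consensus_a
            off_b = int(rng.integers(110, 190 - len(consensus_b)))
            seq[off_b:off_b + len(consensus_b)] = consensus_b
            regions.append("".join(seq))
            occupied.append((i, off_a, off_a + len(consensus_a)))
        motifs = discover_motifs(regions, seed=6, max_motifs=2,
                                 width_sweep=(10, 15))
        assert len(motifs) >= 2
        first_by_region = {}
        for idx, lo, hi in occupied:
            first_by_region[idx] = (lo, hi)
        # identify which motif matched plant A
        dists = [hamming_to_plant(m.consensus, consensus_a) for m in motifs]
        second = motifs[1 - int(np.argmin(dists))]
        for reg, off, strand in second.sites:
            lo, hi = first_by_region[reg]
            assert off + second.width <= lo or off >= hi, (
                f"second motif site [{off}, {off + second.width}) overlaps "
                f"masked window [{lo}, {hi}) in region {reg}")


# ---------------------------------------------------------------------------
# re-estimation from sites
# ---------------------------------------------------------------------------

class TestReestimateFromSites:
    def _genome_with_sites(self, word, starts, strands, length=500, seed=0):
        rng = np.random.default_rng(seed)
        seq = list(random_dna(rng, length))
        for s, st_ in zip(starts, strands):
            written = word if st_ == "+" else reverse_complement(word)
            seq[s:s + len(word)] = written
        genome = GenomeRecord("c", "".join(seq))
        hits = [SiteHit("m", "c", s, st_, len(word), 10.0, 1e-9, 1e-6)
                for s, st_ in zip(starts, strands)]
        return genome, hits

    def test_identical_sites_give_indicator_columns(self):
        word = "ACGTACGTAC"
        genome, hits = self._genome_with_sites(word, [10, 40, 80, 120, 160,
                                                      200, 240, 280, 320, 360],
                                               ["+"] * 10)
        bg = build_background([genome.sequence])
        motif = reestimate_from_sites(hits, genome, 10, bg)
        for j, base in enumerate(word):
            assert motif.probs[j].argmax() == "ACGT".index(base)
            assert motif.probs[j].max() > 0.95
        assert motif.nsites == 10

    def test_minus_strand_sites_contribute_reverse_complement(self):
        word = "AAACCCGGGT"
        genome, hits = self._genome_with_sites(word, [50, 100], ["-", "-"])
        bg = build_background([genome.sequence])
        motif = reestimate_from_sites(hits, genome, 10, bg)
        for j, base in enumerate(word):
            assert motif.probs[j].argmax() == "ACGT".index(base)

    def test_too_few_sites_rejected(self):
        genome, hits = self._genome_with_sites("ACGTACGTAC", [50], ["+"])
        bg = build_background([genome.sequence])
        with pytest.raises(ValueError, match="at least 2"):
            reestimate_from_sites(hits[:1], genome, 10, bg)
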