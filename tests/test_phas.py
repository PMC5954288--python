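"""Phasing statistics, window scan, merging/FDR and locus calling."""

import math
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from phasikit import phas
from phasikit.core_align import Alignment, Reference
from phasikit.phas import (
    MergedRegion,
    PhaseWindow,
    benjamini_hochberg,
    cluster_loci,
    phase_position,
    phase_score,
    phasing_pvalue,
)
from phasikit.synthetic import LibraryPlan, PhasPlan, SimulationConfig
from conftest import detect_phas, random_sequence


def oracle_tail(n, k, m, p):
    """Brute-force hypergeometric upper tail with exact rationals.

    Independent path: factorial-based binomials, full pmf enumeration.
    """
    def binom(a, b):
        if b < 0 or b > a:
            return 0
        return Fraction(math.factorial(a),
                        math.factorial(b) * math.factorial(a - b))

    denom = binom(p * m, n)
    pmf = [binom(m, j) * binom((p - 1) * m, n - j) / denom for j in range(m + 1)]
    assert sum(pmf) == 1  # the pmf must be exactly normalised
    return sum(pmf[k:])


class TestPhasingPvalue:
    @pytest.mark.parametrize("n", [1, 5, 17, 30])
    @pytest.mark.parametrize("p", [21, 24])
    def test_tail_at_k0_is_exactly_one(self, n, p):
        assert phasing_pvalue(n, 0, 10, p) == 1.0

    def test_fully_phased_single_term(self):
        assert phasing_pvalue(10, 10, 10, 21) == pytest.approx(
            1 / math.comb(210, 10), rel=1e-15)

    def test_example_against_rational_oracle(self):
        got = phasing_pvalue(6, 3, 10, 21)
        assert got == pytest.approx(float(oracle_tail(6, 3, 10, 21)), rel=1e-12)

    @pytest.mark.parametrize("p", [21, 24])
    def test_oracle_equivalence_full_grid(self, p):
        """All n <= 30, k <= min(n, 10): exact-rational tail to 1e-12 relative."""
        for n in range(0, 31):
            for k in range(0, min(n, 10) + 1):
                expect = float(oracle_tail(n, k, 10, p))
                assert phasing_pvalue(n, k, 10, p) == pytest.approx(expect, rel=1e-12)

    def test_scipy_hypergeom_cross_check(self):
        # independent library route: sf over the same urn model
        for (n, k, p) in [(12, 4, 21), (25, 7, 24), (9, 9, 21)]:
            expect = hypergeom.sf(k - 1, p * 10, 10, n)
            assert phasing_pvalue(n, k, 10, p) == pytest.approx(expect, rel=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(1, 30), st.integers(1, 10), st.sampled_from([21, 24]))
    def test_monotone_nonincreasing_in_k(self, n, k, p):
        k = min(k, n)
        assert phasing_pvalue(n, k, 10, p) <= phasing_pvalue(n, k - 1, 10, p)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            phasing_pvalue(5, 6)          # k > n
        with pytest.raises(ValueError):
            phasing_pvalue(5, 11)         # k > m
        with pytest.raises(ValueError):
            phasing_pvalue(211, 5, 10, 21)  # n > p*m


class TestPhaseScore:
    def test_closed_form_ln101(self):
        assert phase_score([10] + [0] * 9, [0] * 10, 3) == pytest.approx(math.log(101))

    def test_closed_form_2ln6(self):
        assert phase_score([5] + [0] * 9, [9] + [0] * 9, 4) == pytest.approx(
            2 * math.log(6))

    def test_zero_phased_reads_scores_zero(self):
        assert phase_score([0] * 10, [3] * 10, 5) == 0.0

    def test_k_below_three_has_no_score(self):
        assert phase_score([5] * 10, [0] * 10, 2) is None

    def test_monotonicity_grid(self):
        """Increasing in sum(P) and k; decreasing in sum(U); non-negative."""
        base = phase_score([4, 2] + [0] * 8, [1] * 10, 4)
        assert base >= 0
        assert phase_score([5, 2] + [0] * 8, [1] * 10, 4) > base
        assert phase_score([4, 2] + [0] * 8, [2] + [1] * 9, 4) < base
        assert phase_score([4, 2] + [0] * 8, [1] * 10, 5) > base
        # linear in k - 2
        s3 = phase_score([7] + [0] * 9, [0] * 10, 3)
        s5 = phase_score([7] + [0] * 9, [0] * 10, 5)
        assert s5 == pytest.approx(3 * s3)


class TestPhasePosition:
    def test_plus_read_register_zero(self):
        a = Alignment("A" * 21, "c", 5001, "+", 0)
        assert (phase_position(a, 21) - 5001) % 21 == 0

    def test_minus_read_two_nt_offset(self):
        a = Alignment("A" * 21, "c", 4999, "-", 0)
        assert phase_position(a, 21) == 5001

    def test_off_phase_register(self):
        a = Alignment("A" * 21, "c", 5003, "+", 0)
        assert (phase_position(a, 21) - 5001) % 21 == 2


class TestScan:
    def _ladder_alignments(self, genome, start, cycles, p=21, extra_offsets=()):
        al = []
        for c in range(cycles):
            pos = start + c * p
            al.append(Alignment(genome.fetch("Chr1", pos, pos + p - 1), "Chr1",
                                pos, "+", 0))
        for off in extra_offsets:
            pos = start + off
            al.append(Alignment(genome.fetch("Chr1", pos, pos + p - 1), "Chr1",
                                pos, "+", 0))
        return al

    def test_perfect_ladder_counts(self, rng):
        genome = Reference("g", {"Chr1": random_sequence(rng, 2000)})
        al = self._ladder_alignments(genome, 501, 10)
        track = phas.scan(al, genome, 21)
        w = next(w for w in track.windows if w.start == 501)
        assert (w.n, w.k) == (10, 10)

    def test_off_register_tags_raise_n_not_k(self, rng):
        genome = Reference("g", {"Chr1": random_sequence(rng, 2000)})
        offsets = [5, 26, 47, 68, 89]  # five distinct off-phase placements
        al = self._ladder_alignments(genome, 501, 10, extra_offsets=offsets)
        track = phas.scan(al, genome, 21)
        w = next(w for w in track.windows if w.start == 501)
        assert (w.n, w.k) == (15, 10)

    def test_empty_region_emits_no_windows(self, rng):
        genome = Reference("g", {"Chr1": random_sequence(rng, 2000)})
        track = phas.scan([], genome, 21)
        assert track.windows == []


def _window(ref, start, pvalue, score=None, p=21):
    return PhaseWindow(ref, start, p, 10, 5, 3, [1] * 10, [0] * 10, pvalue, score)


class TestMergeAndCorrect:
    def _track(self, windows, length=5000):
        genome = Reference("g", {"Chr1": "A" * length})
        t = phas.PhaseTrack(genome, 21, 10)
        t.windows = windows
        return t

    def test_extended_overlapping_windows_merge(self):
        track = self._track([_window("Chr1", 1000, 0.01),
                             _window("Chr1", 1250, 0.02)])
        regions = phas.merge_and_correct(track)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (900, 1559)

    def test_bh_hand_computed(self):
        assert benjamini_hochberg([0.01, 0.02, 0.04]) == pytest.approx(
            [0.03, 0.03, 0.04])

    def test_single_window_region_clipped(self):
        track = self._track([_window("Chr1", 50, 0.01)])
        (r,) = phas.merge_and_correct(track)
        assert (r.start, r.end) == (1, 50 + 209 + 100)

    def test_min_member_pvalue_and_qvalues(self):
        track = self._track([_window("Chr1", 1000, 0.01),
                             _window("Chr1", 1100, 0.002),
                             _window("Chr1", 4000, 0.03)])
        regions = phas.merge_and_correct(track)
        assert [r.pvalue for r in regions] == [0.002, 0.03]
        assert regions[0].qvalue == pytest.approx(0.004)
        assert regions[1].qvalue == pytest.approx(0.03)

    def test_nonqualifying_windows_excluded(self):
        track = self._track([_window("Chr1", 1000, 0.2)])
        assert phas.merge_and_correct(track) == []


class TestCallLoci:
    def test_low_score_region_not_called(self):
        cfg = SimulationConfig(seed=13, chrom_length=10_000,
                               phas_plan=[PhasPlan(21, 10, 4001, "both", 5, 0.0)],
                               library_plan=[LibraryPlan("L1", 100, 0.0)])
        *_, track, loci = detect_phas(cfg, score_threshold=1e9)
        assert loci == []  # same pipeline, unreachable score bar

    def test_planted_clean_locus_called_with_phasirnas(self):
        cfg = SimulationConfig(seed=13, chrom_length=10_000,
                               phas_plan=[PhasPlan(21, 10, 4001, "+", 5, 0.0)],
                               library_plan=[LibraryPlan("L1", 100, 0.0)])
        *_, loci = detect_phas(cfg)
        assert len(loci) == 1
        locus = loci[0]
        assert locus.start <= 4001 and locus.end >= 4210
        assert locus.n_unique == 10
        assert [s.name for s in locus.phasirnas] == [
            f"{locus.name}_siR{i}" for i in range(1, 11)]
        assert locus.name.startswith("P21_Chr1_")

    def test_fewer_than_four_unique_not_reported(self, rng):
        genome = Reference("g", {"Chr1": random_sequence(rng, 3000)})
        al = []
        for c in range(3):  # only three unique phased tags, very deep
            pos = 1001 + c * 21
            al.append(Alignment(genome.fetch("Chr1", pos, pos + 20), "Chr1",
                                pos, "+", 0))
        counts = {a.tag: 500 for a in al}
        track = phas.scan(al, genome, 21, counts=counts)
        regions = phas.merge_and_correct(track)
        loci = phas.call_loci(track, regions)
        assert loci == []


class TestClusters:
    def _locus(self, name, start, end, ref="Chr1", p=21):
        return phas.PhasLocus(name, ref, start, end, p, 0, 1e-6, 1e-5, 10.0, [])

    def test_gap_under_2000_chains(self):
        loci = [self._locus("a", 9000, 10_000), self._locus("b", 11_500, 12_000)]
        clusters = cluster_loci(loci)
        assert len(clusters) == 1 and len(clusters[0].loci) == 2

    def test_gap_exactly_2000_separates(self):
        loci = [self._locus("a", 9000, 10_000), self._locus("b", 12_000, 12_500)]
        assert len(cluster_loci(loci)) == 2

    def test_singleton(self):
        assert len(cluster_loci([self._locus("a", 1, 210)])) == 1
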