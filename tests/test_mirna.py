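"""Folding, homolog discovery, hairpin screens and naming."""

import pytest

from phasikit.core_align import Reference, revcomp
from phasikit.folding import FoldResult, fold
from phasikit.mirna import (
    HairpinCandidate,
    MirnaAnnotation,
    assign_names,
    discover_conserved,
    duplex_paired_nt,
    extract_candidates,
    find_homolog_loci,
    fold_candidate,
    match_mature_only,
    screen_conserved_precursor,
    screen_novel_precursor,
)
from phasikit.preprocess import UniqueTag
from phasikit.synthetic import hairpin_precursor, plant_hairpin
from phasikit.core_align import Alignment
from conftest import random_sequence

MATURE = "TGACAGAAGAGAGTGAGCACA"


class TestFold:
    def test_unique_maximal_helix(self):
        assert fold("GGGAAACCC").structure == "(((...)))"

    def test_homopolymer_unstructured(self):
        fr = fold("A" * 30)
        assert fr.n_pairs == 0 and fr.energy == 0.0

    def test_planted_stem_reaches_18_pairs(self):
        stem = "GCTAGCTAGGCATCGATCGAT"
        fr = fold(stem + "TCTCT" + revcomp(stem))
        assert fr.n_pairs >= 18

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            fold("ACGTXACGT")

    def test_pair_table_balanced(self):
        fr = fold("GGGAAACCC")
        pt = fr.pair_table()
        assert pt[1] == 9 and pt[9] == 1 and pt[4] == 0


class TestHomologSearch:
    @pytest.fixture
    def genome_with_copy(self, rng):
        seq = random_sequence(rng, 4000)
        seq = seq[:1000] + MATURE + seq[1000 + len(MATURE):]
        return Reference("g", {"Chr1": seq})

    def test_exact_copy_found(self, genome_with_copy):
        hits = find_homolog_loci({"ath-miR000": MATURE}, genome_with_copy)
        assert any(a.start == 1001 and a.mismatches == 0 for _, a in hits)

    def test_two_substitutions_found_three_rejected(self, rng):
        seq = random_sequence(rng, 4000)
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        two = list(MATURE)
        for i in (3, 10):
            two[i] = flip[two[i]]
        three = list(MATURE)
        for i in (3, 10, 17):
            three[i] = flip[three[i]]
        seq = seq[:500] + "".join(two) + seq[521:1500] + "".join(three) + seq[1521:]
        genome = Reference("g", {"Chr1": seq})
        hits = find_homolog_loci({"q": MATURE}, genome)
        starts = {a.start for _, a in hits}
        assert 501 in starts and 1501 not in starts

    def test_empty_catalog_rejected(self, genome_with_copy):
        with pytest.raises(ValueError, match="empty"):
            find_homolog_loci({}, genome_with_copy)


class TestExtractCandidates:
    def test_six_windows_with_expected_spans(self, small_genome):
        hit = Alignment(small_genome.fetch("Chr1", 1000, 1020), "Chr1", 1000, "+", 0)
        wins = extract_candidates(hit, small_genome)
        assert len(wins) == 6
        w80 = [w for w in wins if w.flank == 80]
        assert {(w.start, w.end) for w in w80} == {(920, 1020), (1000, 1100)}

    def test_clipping_flagged(self, small_genome):
        hit = Alignment(small_genome.fetch("Chr1", 10, 30), "Chr1", 10, "+", 0)
        up130 = next(w for w in extract_candidates(hit, small_genome)
                     if w.flank == 130 and w.side == "upstream")
        assert up130.start == 1 and up130.clipped


def _perfect_candidate(mature=MATURE):
    precursor, star, m_iv, s_iv = hairpin_precursor(mature)
    fr = fold(precursor)
    return HairpinCandidate(fr.sequence, fr.structure, fr.energy, m_iv,
                            star_interval=s_iv), star


class TestConservedScreen:
    def test_fully_paired_mature_passes(self):
        cand, _ = _perfect_candidate()
        ok, reason = screen_conserved_precursor(cand)
        assert ok, reason

    def test_four_nt_unpaired_run_fails(self):
        # symmetric 4-nt internal loop inside the mature (positions 11-14)
        left = "(" * 10 + "...." + "(" * 7
        structure = left + "..." + _mirror(left)
        cand = HairpinCandidate("A" * len(structure), structure, 0.0, (1, 21))
        ok, reason = screen_conserved_precursor(cand)
        assert not ok and reason == "continuous-mismatches"

    def test_six_scattered_mismatches_fail(self):
        # 6 isolated unpaired mature positions, all in symmetric loops
        left = "((.((.((.((.((.((.((("
        structure = left + "..." + _mirror(left)
        cand = HairpinCandidate("A" * len(structure), structure, 0.0, (1, 21))
        ok, reason = screen_conserved_precursor(cand)
        assert not ok and reason == "mismatches"

    def test_loop_spanning_mature_fails(self):
        structure = "....((((((......))))))...."
        cand = HairpinCandidate("A" * 26, structure, 0.0, (5, 25))
        ok, reason = screen_conserved_precursor(cand)
        assert not ok and reason == "loop-spanning"


def _mirror(left):
    """Closing arm matching a left-arm dot-bracket draft (test helper)."""
    return left[::-1].translate(str.maketrans("()", ")("))


class TestNovelScreen:
    def _tags(self, star, star_pos, mature_reads=100, star_reads=5):
        tags = [(UniqueTag(MATURE, {"L": mature_reads}), 1)]
        if star_reads:
            tags.append((UniqueTag(star, {"L": star_reads}), star_pos))
        return tags

    def test_planted_hairpin_with_star_accepted(self):
        cand, star = _perfect_candidate()
        ann, reason = screen_novel_precursor(
            cand, self._tags(star, cand.star_interval[0]))
        assert reason == "ok"
        assert ann.mature == MATURE and ann.star == star

    def test_star_absent_rejected(self):
        cand, star = _perfect_candidate()
        ann, reason = screen_novel_precursor(
            cand, self._tags(star, cand.star_interval[0], star_reads=0))
        assert ann is None and reason == "no-star"

    def test_energy_above_gate_rejected(self):
        cand, star = _perfect_candidate()
        weak = HairpinCandidate(cand.sequence, cand.structure, -35.0,
                                cand.mature_interval,
                                star_interval=cand.star_interval)
        ann, reason = screen_novel_precursor(
            weak, self._tags(star, cand.star_interval[0]))
        assert ann is None and reason == "energy"

    def test_duplex_pairing_below_18_rejected(self):
        # hairpin whose mature pairs only 15 nt into the opposite arm
        left = "(" * 15 + "." * 6
        structure = left + "..." + _mirror(left)
        cand = HairpinCandidate("A" * len(structure), structure, -60.0, (1, 21))
        ann, reason = screen_novel_precursor(
            cand, [(UniqueTag(MATURE, {"L": 100}), 1),
                   (UniqueTag("C" * 15, {"L": 5}), 25)])
        assert ann is None and reason == "pairing"

    def test_no_expression(self):
        cand, _ = _perfect_candidate()
        assert screen_novel_precursor(cand, []) == (None, "no-expression")


class TestEndToEndDiscovery:
    def test_planted_conserved_mature_recovered(self, rng):
        genome = Reference("g", {"Chr1": random_sequence(rng, 5000)})
        genome, planted = plant_hairpin(genome, MATURE, flank=30, start=2000)
        anns = discover_conserved({"osa-miR171x": MATURE}, genome)
        assert any(a.mature == MATURE and a.status == "conserved-with-precursor"
                   for a in anns)

    def test_mature_only_mismatch_cap(self):
        tag2 = "TGACAGAAGAGAGTGAGCATT"   # 2 substitutions
        tag3 = "TGACAGAAGAGAGTGAGTTTT"   # 4 substitutions
        anns = match_mature_only(
            [UniqueTag(tag2, {"L": 3}), UniqueTag(tag3, {"L": 3})],
            {"miR171": MATURE})
        assert [a.mature for a in anns] == [tag2]


class TestNaming:
    def _ann(self, mature, family, start, status="conserved-with-precursor"):
        return MirnaAnnotation(family, "Chr1", start, start + 100, "+",
                               mature, status)

    def test_prior_catalog_name_inherited(self):
        anns = assign_names([self._ann(MATURE, "156", 100)],
                            prior_catalog={MATURE: "miR156a"})
        assert anns[0].name == "miR156a"

    def test_letters_in_genomic_order(self):
        anns = assign_names([self._ann("A" * 21, "171", 5000),
                             self._ann("C" * 21, "171", 100)])
        by_start = {a.start: a.name for a in anns}
        assert by_start[100] == "MIR171a" and by_start[5000] == "MIR171b"

    def test_naming_is_deterministic(self):
        anns = [self._ann("A" * 21, "171", 500),
                self._ann("C" * 21, "171", 100),
                self._ann("G" * 21, "396", 900, status="novel")]
        n1 = [a.name for a in assign_names([MirnaAnnotation(**vars(a)) for a in anns])]
        n2 = [a.name for a in assign_names([MirnaAnnotation(**vars(a)) for a in anns])]
        assert n1 == n2
        assert any(n.startswith("MIRN") for n in n1)
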