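"""Degradome target identification, valid reads, class rules, TAS3, T-plots."""

import numpy as np
import pytest

from phasikit.core_align import Alignment, Reference, revcomp
from phasikit.synthetic import DegradomePlan, simulate_degradome
from phasikit.preprocess import collapse_unique, process_degradome_fastq
from phasikit.targets import (
    TargetSite,
    call_targets,
    count_valid_reads,
    find_sites,
    find_tas3,
    site_position_pairing,
    tplot_data,
)
from conftest import random_sequence

QUERY = "TGACAGAAGAGAGTGAGCACA"  # 21 nt


def _transcript_with_site(rng, query=QUERY, at=100, length=400, mutate=()):
    site = list(revcomp(query))
    flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
    for qpos in mutate:
        # site position pairing query position qpos
        j = len(query) - qpos  # 0-based index into site
        site[j] = flip[site[j]]
    seq = random_sequence(rng, length)
    seq = seq[:at - 1] + "".join(site) + seq[at - 1 + len(query):]
    return Reference("tx", {"T1": seq})


class TestFindSites:
    def test_exact_reverse_complement_scores_zero(self, rng):
        ref = _transcript_with_site(rng)
        sites = find_sites(QUERY, ref, 4.0)
        assert [(s.start, s.end, s.score) for s in sites] == [(100, 120, 0.0)]

    def test_gu_wobble_scores_half(self, rng):
        # query position 9 is G; put a T opposite it -> G:U wobble
        assert QUERY[8] == "G"
        ref = _transcript_with_site(rng)
        seq = ref.sequences["T1"]
        j = 100 - 1 + (21 - 9)  # 0-based transcript index pairing q9
        assert seq[j] == "C"
        seq = seq[:j] + "T" + seq[j + 1:]
        sites = find_sites(QUERY, Reference("tx", {"T1": seq}), 4.0)
        assert sites and sites[0].score == 0.5

    def test_score_above_cap_excluded(self, rng):
        ref = _transcript_with_site(rng, mutate=(2, 4, 6, 13, 15))  # 5 mismatches
        assert find_sites(QUERY, ref, 4.0) == []

    def test_scoring_symmetry_under_reverse_complement(self, rng):
        """Reverse-complementing both query and site preserves the score."""
        ref = _transcript_with_site(rng, mutate=(5, 12))
        (site,) = find_sites(QUERY, ref, 4.0)
        flipped = Reference("tx", {"T1": revcomp(ref.sequences["T1"])})
        (site2,) = find_sites(revcomp(QUERY), flipped, 4.0)
        assert site2.score == site.score


class TestValidReads:
    def test_pairing_geometry(self):
        site = TargetSite("q", QUERY, "T1", 100, 120, 0.0)
        assert site_position_pairing(site, 1) == 120
        assert [site_position_pairing(site, q) for q in (9, 10, 11)] == [112, 111, 110]

    def test_reads_at_9_to_11_valid_elsewhere_not(self):
        site = TargetSite("q", QUERY, "T1", 100, 120, 0.0)
        for qpos in range(5, 16):
            vec = np.zeros(400, dtype=int)
            vec[site_position_pairing(site, qpos) - 1] = 7
            valid = count_valid_reads(site, vec)
            if qpos in (9, 10, 11):
                assert valid == 7, qpos
            else:
                assert valid == 0, qpos

    def test_planted_cleavage_counted(self, rng):
        ref = _transcript_with_site(rng)
        recs = simulate_degradome(ref, [DegradomePlan("T1", 111, 30)], seed=1)
        tags = collapse_unique(process_degradome_fastq(recs))
        al = [Alignment(t.sequence, "T1",
                        ref.sequences["T1"].find(t.sequence) + 1, "+", 0)
              for t in tags]
        vec = tplot_data("T1", 400, al, {t.sequence: t.total for t in tags})
        site = find_sites(QUERY, ref, 4.0)[0]
        assert count_valid_reads(site, vec) == 30


class TestClassRules:
    # (class, score, valid reads, expected decision): 12 constructed scenarios
    TRUTH_TABLE = [
        ("conserved", 0.0, 0, True),
        ("conserved", 4.0, 0, True),
        ("conserved", 4.5, 0, False),
        ("conserved", 2.0, 5, True),
        ("novel", 2.0, 0, False),
        ("novel", 2.0, 1, True),
        ("novel", 4.0, 3, False),
        ("novel", 3.5, 1, True),
        ("phasiRNA", 0.0, 0, True),
        ("phasiRNA", 3.0, 0, False),
        ("phasiRNA", 3.0, 1, True),
        ("phasiRNA", 3.5, 2, False),
    ]

    @pytest.mark.parametrize("cls,score,valid,expected", TRUTH_TABLE)
    def test_acceptance_rules(self, cls, score, valid, expected):
        site = TargetSite("q", QUERY, "T1", 100, 120, score, valid_reads=valid)
        (decided,) = call_targets([site], cls)
        assert decided.accepted is expected

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown query class"):
            call_targets([], "mystery")


class TestTplot:
    def test_counts_and_conservation(self):
        al = ([Alignment("A" * 20, "T1", 111, "+", 0)] * 30
              + [Alignment("C" * 20, "T1", 500, "+", 0)] * 2)
        vec = tplot_data("T1", 600, al)
        assert vec[110] == 30 and vec[499] == 2
        assert vec.sum() == 32  # conservation: sum equals mapped reads

    def test_empty_degradome_all_zero(self):
        assert tplot_data("T1", 100, []).sum() == 0


MIR390 = "AAGCTCAGGAGGGATAGCGCC"
TASIARF = "TTCTTGACCTTGTAAGACCCC"


class TestTas3:
    def _genome(self, rng, with_5p=True, with_3p=True):
        site = revcomp(MIR390)
        spacer = random_sequence(rng, 21)
        locus = ((site if with_5p else random_sequence(rng, 21))
                 + spacer + TASIARF
                 + (site if with_3p else random_sequence(rng, 21)))
        chrom = random_sequence(rng, 2000) + locus + random_sequence(rng, 2000)
        return Reference("g", {"Chr2": chrom})

    def test_two_site_construct_reported(self, rng):
        g = self._genome(rng)
        (locus,) = find_tas3({"tasiARF": TASIARF}, g, MIR390)
        assert locus.name == "TAS3a"
        assert locus.site5 == (2001, 2021)
        assert locus.site3 == (2064, 2084)
        assert locus.tasirna_interval == (2043, 2063)

    @pytest.mark.parametrize("with_5p,with_3p", [(False, True), (True, False)])
    def test_single_site_not_reported(self, rng, with_5p, with_3p):
        g = self._genome(rng, with_5p, with_3p)
        assert find_tas3({"tasiARF": TASIARF}, g, MIR390) == []

    def test_three_mismatch_tasiarf_not_found(self, rng):
        g = self._genome(rng)
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        mutated = list(TASIARF)
        for i in (2, 9, 16):
            mutated[i] = flip[mutated[i]]
        assert find_tas3({"tasiARF": "".join(mutated)}, g, MIR390) == []
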