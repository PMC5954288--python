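"""Conserved and novel miRNA discovery from hairpin structure and star evidence.

Conserved miRNAs are found by mapping known plant mature sequences to the
genome with at most 2 substitutions, excising candidate precursor
windows (80/130/180-nt flanks, each extended up- or downstream of the
mature), folding them, and applying MIRcheck-style structural criteria
to the mature within the hairpin (<= 5 unpaired, <= 2 bulged or
asymmetrically unpaired, <= 3 consecutive unpaired).  Novel miRNAs
require, on a folded candidate extended 300 nt around an expressed tag
locus: >= 18 paired nucleotides in the mature:star duplex, folding
energy below -40 kcal/mol, and a sequenced star tag forming a duplex
with 2-nt 3' overhangs on the opposite arm — the classic community
annotation criteria for plant miRNAs.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .core_align import Alignment, Reference, SeedIndex, build_index, map_tags, revcomp
from .folding import FoldResult, fold
from .preprocess import UniqueTag

FLANKS = (80, 130, 180)
NOVEL_EXTENSION = 300
MIN_DUPLEX_PAIRED = 18
MAX_ENERGY = -40.0
OVERHANG_TOL = 1


@dataclass
class HairpinCandidate:
    """A folded precursor candidate with the mature placed on it (1-based)."""

    sequence: str
    structure: str
    energy: float
    mature_interval: Tuple[int, int]
    star_interval: Optional[Tuple[int, int]] = None
    arm: Optional[str] = None
    # genomic provenance
    ref_id: Optional[str] = None
    start: Optional[int] = None
    strand: str = "+"
    clipped: bool = False

    def __post_init__(self):
        if len(self.structure) != len(self.sequence):
            raise ValueError("structure length must equal sequence length")
        ms, me = self.mature_interval
        if not (1 <= ms <= me <= len(self.sequence)):
            raise ValueError("mature interval outside precursor")

    def pair_table(self) -> List[int]:
        return FoldResult(self.sequence, self.structure, self.energy).pair_table()


@dataclass
class MirnaAnnotation:
    family: str
    ref_id: str
    start: int
    end: int
    strand: str
    mature: str
    status: str                # conserved-with-precursor | conserved-mature-only | novel
    star: Optional[str] = None
    precursor: Optional[str] = None
    name: Optional[str] = None


def find_homolog_loci(
    known_matures: Mapping[str, str],
    genome: Reference,
    max_mismatch: int = 2,
    index: Optional[SeedIndex] = None,
) -> List[Tuple[str, Alignment]]:
    """Genomic placements of known mature miRNAs with <= 2 substitutions.

    ``known_matures`` maps catalog names (e.g. "ath-miR156a") to mature
    sequences (RNA or DNA alphabet).  Returns (catalog name, alignment)
    for every placement on either strand.
    """
    if not known_matures:
        raise ValueError("empty known-mature catalog")
    idx = index or build_index(genome)
    out: List[Tuple[str, Alignment]] = []
    for qname in sorted(known_matures):
        seq = known_matures[qname].upper().replace("U", "T")
        for aln in map_tags([seq], idx, max_mismatch):
            out.append((qname, aln))
    return out


@dataclass
class CandidateWindow:
    ref_id: str
    start: int
    end: int
    flank: int
    side: str                  # 'upstream' or 'downstream'
    mature_offset: Tuple[int, int]  # mature interval within the window, 1-based
    clipped: bool


def extract_candidates(
    hit: Alignment, genome: Reference, flanks: Sequence[int] = FLANKS
) -> List[CandidateWindow]:
    """Candidate precursor windows around a mature hit.

    For each flank size two windows are produced: one extended upstream
    of the mature and one downstream (a pre-miRNA carries its mature on
    one arm, so one side holds the rest of the hairpin).  Windows
    clipped at chromosome ends are flagged.
    """
    L = genome.length(hit.ref_id)
    out = []
    for f in flanks:
        for side, (s, e) in (
            ("upstream", (hit.start - f, hit.end)),
            ("downstream", (hit.start, hit.end + f)),
        ):
            cs, ce = max(1, s), min(L, e)
            out.append(
                CandidateWindow(
                    hit.ref_id, cs, ce, f, side,
                    (hit.start - cs + 1, hit.end - cs + 1),
                    clipped=(cs != s or ce != e),
                )
            )
    return out


def fold_candidate(
    window: CandidateWindow, genome: Reference, strand: str = "+", engine=None
) -> HairpinCandidate:
    """Fold a candidate window into a :class:`HairpinCandidate`.

    For minus-strand hits the window sequence is reverse complemented
    before folding, and the mature interval is mirrored accordingly.
    """
    seq = genome.fetch(window.ref_id, window.start, window.end)
    ms, me = window.mature_offset
    if strand == "-":
        seq = revcomp(seq)
        n = len(seq)
        ms, me = n - me + 1, n - ms + 1
    fr = fold(seq, engine=engine)
    return HairpinCandidate(
        fr.sequence, fr.structure, fr.energy, (ms, me),
        ref_id=window.ref_id, start=window.start, strand=strand,
        clipped=window.clipped,
    )


# ---------------------------------------------------------------------------
# structural screens


def _unpaired_runs(pt: List[int], lo: int, hi: int) -> List[Tuple[int, int]]:
    """Maximal runs of unpaired positions within [lo, hi] (1-based)."""
    runs = []
    i = lo
    while i <= hi:
        if pt[i] == 0:
            j = i
            while j <= hi and pt[j] == 0:
                j += 1
            runs.append((i, j - 1))
            i = j
        else:
            i += 1
    return runs


def screen_conserved_precursor(
    candidate: HairpinCandidate,
    mature_interval: Optional[Tuple[int, int]] = None,
    max_mismatch: int = 5,
    max_bulged: int = 2,
    max_run: int = 3,
) -> Tuple[bool, str]:
    """MIRcheck-style screen of the mature within the folded hairpin.

    Fails "loop-spanning" when the mature pairs with itself (it crosses
    the terminal loop).  Unpaired mature positions count as mismatches
    (cap 5); positions unpaired while the opposing arm has no
    accommodating gap count as bulged/asymmetric (cap 2); runs of more
    than 3 consecutive unpaired mature positions fail.
    """
    ms, me = mature_interval or candidate.mature_interval
    pt = candidate.pair_table()
    if any(ms <= pt[i] <= me for i in range(ms, me + 1) if pt[i]):
        return False, "loop-spanning"
    unpaired = [i for i in range(ms, me + 1) if pt[i] == 0]
    if len(unpaired) > max_mismatch:
        return False, "mismatches"
    runs = _unpaired_runs(pt, ms, me)
    if runs and max(b - a + 1 for a, b in runs) > max_run:
        return False, "continuous-mismatches"
    bulged = 0
    for a, b in runs:
        if a - 1 < ms or b + 1 > me or pt[a - 1] == 0 or pt[b + 1] == 0:
            continue  # boundary run: no flanking pair geometry to compare
        opp_gap = abs(pt[a - 1] - pt[b + 1]) - 1
        bulged += max(0, (b - a + 1) - opp_gap)
    if bulged > max_bulged:
        return False, "bulged"
    return True, "ok"


def duplex_paired_nt(candidate: HairpinCandidate) -> int:
    """Mature nucleotides paired to the opposite arm (the duplex pairing count)."""
    ms, me = candidate.mature_interval
    pt = candidate.pair_table()
    return sum(1 for i in range(ms, me + 1) if pt[i] and not ms <= pt[i] <= me)


def screen_novel_precursor(
    candidate: HairpinCandidate,
    tags: Sequence[Tuple[UniqueTag, int]],
    min_paired: int = MIN_DUPLEX_PAIRED,
    max_energy: float = MAX_ENERGY,
    pairing_mode: str = "duplex",
    overhang_tol: int = OVERHANG_TOL,
) -> Tuple[Optional[MirnaAnnotation], str]:
    """Screen a candidate precursor for a novel miRNA call.

    ``tags`` are (unique tag, 1-based start on the precursor) for the
    sRNAs aligned to the candidate.  The most abundant tag is taken as
    the mature; acceptance requires, in order: (1) >= ``min_paired``
    paired nucleotides ("duplex" mode counts mature positions paired to
    the opposite arm, "hairpin" mode counts all paired nucleotides in
    the structure); (2) folding energy < ``max_energy``; (3) a second
    sequenced tag lying on the opposite arm as a miRNA* with 2-nt 3'
    overhangs on both duplex ends.  Returns (annotation, "ok") or
    (None, first failed criterion).
    """
    if not tags:
        return None, "no-expression"
    ordered = sorted(tags, key=lambda t: (-t[0].total, t[0].sequence))
    mature_tag, m_start = ordered[0]
    ms, me = m_start, m_start + len(mature_tag.sequence) - 1
    cand = HairpinCandidate(
        candidate.sequence, candidate.structure, candidate.energy, (ms, me),
        ref_id=candidate.ref_id, start=candidate.start, strand=candidate.strand,
    )
    pt = cand.pair_table()
    if pairing_mode == "duplex":
        paired = duplex_paired_nt(cand)
    else:
        paired = sum(1 for i in range(1, len(pt)) if pt[i])
    if paired < min_paired:
        return None, "pairing"
    if not cand.energy < max_energy:
        return None, "energy"
    # expected star interval from the duplex geometry: the star ends 2 nt
    # past the partner of the mature 5' end, and starts at the partner of
    # the mature position me-2 (2-nt 3' overhangs on both ends)
    a1 = pt[ms]
    inner = me - 2 if me - 2 >= ms else ms
    a2 = pt[inner]
    if not a1 or not a2:
        return None, "no-star"
    exp_star = (min(a1, a2), max(a1, a2) + 2)
    for tag, s_start in ordered[1:]:
        s_iv = (s_start, s_start + len(tag.sequence) - 1)
        if (
            abs(s_iv[0] - exp_star[0]) <= overhang_tol
            and abs(s_iv[1] - exp_star[1]) <= overhang_tol
        ):
            mid = (ms + me) / 2
            arm = "5p" if mid < (s_iv[0] + s_iv[1]) / 2 else "3p"
            ann = MirnaAnnotation(
                family="novel",
                ref_id=cand.ref_id or "precursor",
                start=cand.start or 1,
                end=(cand.start or 1) + len(cand.sequence) - 1,
                strand=cand.strand,
                mature=mature_tag.sequence,
                star=tag.sequence,
                status="novel",
                precursor=cand.sequence,
            )
            ann.family = arm  # record the arm in lieu of a family
            return ann, "ok"
    return None, "no-star"


# ---------------------------------------------------------------------------
# conserved discovery driver


def _family_of(catalog_name: str) -> str:
    """Family digits from a catalog name: 'ath-miR156a' -> '156'."""
    core = catalog_name.split("miR")[-1] if "miR" in catalog_name else catalog_name
    digits = "".join(c for c in core if c.isdigit())
    return digits or catalog_name


def discover_conserved(
    known_matures: Mapping[str, str],
    genome: Reference,
    engine=None,
    max_mismatch: int = 2,
    index: Optional[SeedIndex] = None,
) -> List[MirnaAnnotation]:
    """Conserved-miRNA discovery: homolog hits -> fold -> structural screen.

    For each genomic hit the six candidate windows are folded and the
    first window passing the structural screen yields a
    conserved-with-precursor annotation.  One annotation per distinct
    locus (ref, start, strand), keeping the first passing catalog query.
    """
    hits = find_homolog_loci(known_matures, genome, max_mismatch, index)
    seen = set()
    out: List[MirnaAnnotation] = []
    for qname, hit in hits:
        key = (hit.ref_id, hit.start, hit.strand)
        if key in seen:
            continue
        for window in extract_candidates(hit, genome):
            cand = fold_candidate(window, genome, hit.strand, engine)
            ok, _ = screen_conserved_precursor(cand)
            if ok:
                seen.add(key)
                out.append(
                    MirnaAnnotation(
                        family=_family_of(qname),
                        ref_id=hit.ref_id,
                        start=window.start,
                        end=window.end,
                        strand=hit.strand,
                        mature=hit.tag,
                        status="conserved-with-precursor",
                        precursor=cand.sequence,
                    )
                )
                break
    return out


def match_mature_only(
    tags: Sequence[UniqueTag],
    catalog: Mapping[str, str],
    max_mismatch: int = 2,
) -> List[MirnaAnnotation]:
    """Mature-only conserved miRNAs: expressed tags matching the catalog.

    Tags within ``max_mismatch`` substitutions of a known mature (same
    length, ungapped) are annotated without precursor support.
    """
    cat = {n: s.upper().replace("U", "T") for n, s in sorted(catalog.items())}
    out = []
    for t in tags:
        for name, seq in cat.items():
            if len(seq) == len(t.sequence):
                mm = sum(1 for a, b in zip(seq, t.sequence) if a != b)
                if mm <= max_mismatch:
                    out.append(
                        MirnaAnnotation(
                            family=_family_of(name), ref_id="", start=0, end=0,
                            strand="+", mature=t.sequence,
                            status="conserved-mature-only",
                        )
                    )
                    break
    return out


def annotations_to_gff3(annotations: Sequence[MirnaAnnotation], path) -> None:
    """miRNA annotations as GFF3 (precursor + mature features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            if not a.ref_id:
                continue  # mature-only records have no genomic locus
            fh.write(
                f"{a.ref_id}\tphasikit\tmiRNA_primary_transcript\t{a.start}\t"
                f"{a.end}\t.\t{a.strand}\t.\tID={a.name};status={a.status}\n"
            )


def assign_names(
    annotations: Sequence[MirnaAnnotation],
    prior_catalog: Optional[Mapping[str, str]] = None,
) -> List[MirnaAnnotation]:
    """Name annotations deterministically.

    Matures whose sequence appears in ``prior_catalog`` (sequence ->
    published name) inherit that name.  Remaining conserved annotations
    are named MIR{family}{letter} with letters in genomic order within
    each family; novel ones get sequential MIRN{serial} ids.  Collisions
    are resolved by a deterministic numeric suffix.
    """
    prior = {s.upper().replace("U", "T"): n for s, n in (prior_catalog or {}).items()}
    used: Dict[str, int] = {}

    def unique(name: str) -> str:
        if name not in used:
            used[name] = 0
            return name
        used[name] += 1
        return f"{name}-{used[name]}"

    named: List[MirnaAnnotation] = []
    # genomic order is the naming order throughout
    ordered = sorted(
        annotations, key=lambda a: (a.status, a.ref_id, a.start, a.mature)
    )
    family_letter: Dict[str, int] = {}
    novel_serial = 0
    for a in ordered:
        if a.mature in prior:
            a.name = unique(prior[a.mature])
        elif a.status == "novel":
            novel_serial += 1
            a.name = unique(f"MIRN{novel_serial}")
        else:
            idx = family_letter.get(a.family, 0)
            family_letter[a.family] = idx + 1
            letters = string.ascii_lowercase
            suffix = letters[idx] if idx < 26 else letters[idx // 26 - 1] + letters[idx % 26]
            a.name = unique(f"MIR{a.family}{suffix}")
        named.append(a)
    return named
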