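"""PHAS locus detection: sliding-window phasing statistics and locus calling.

phasiRNAs are produced in exact head-to-tail 21- or 24-nt increments, so
a genuine PHAS locus concentrates distinct small RNAs at positions that
share one residue modulo the phase length (the phase register).  The
detector scans every genomic position with a window of m = 10 phase
cycles (210 or 240 nt), counts the unique p-nt sRNAs in the window (n)
and the distinct phased positions they occupy (k), and scores phasing by
a hypergeometric upper tail:

    P = sum_{j=k}^{m}  C((p-1)m, n-j) C(m, j) / C(pm, n)

i.e. the chance that at least k of n occupied positions fall on the m
in-register positions of the p*m-nt window.  A per-position phase score

    score = (k - 2) * ln(1 + 10 * sum(P_i) / (1 + sum(U_i)))     (k >= 3)

weights the phased/non-phased read-count ratio by the number of distinct
phased sRNAs.  Minus-strand reads enter the register space at their
leftmost coordinate + 2, because duplex partners carry 2-nt 3'
overhangs.  Windows with P < 0.05 are extended 100 bp, merged,
FDR-corrected across merged regions, and regions with max score > 5,
corrected P < 0.05 and >= 4 unique phasiRNAs become PHAS loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core_align import Alignment, Reference, to_bed_interval

DEFAULT_M = 10


# ---------------------------------------------------------------------------
# statistics


@lru_cache(maxsize=100_000)
def phasing_pvalue(n: int, k: int, m: int = DEFAULT_M, phase_length: int = 21) -> float:
    """Hypergeometric upper-tail P-value for k phased among n occupied positions.

    Exact integer combinatorics (arbitrary precision) converted to float
    at the end; terms with n - j < 0 vanish.  The tail at k = 0 is
    exactly 1.
    """
    p = phase_length
    if not 0 <= k <= m:
        raise ValueError("k must be in [0, m]")
    if k > n:
        raise ValueError("k cannot exceed n")
    if n > p * m:
        raise ValueError("n cannot exceed the number of window positions p*m")
    num = 0
    for j in range(k, m + 1):
        if n - j < 0:
            continue
        num += math.comb((p - 1) * m, n - j) * math.comb(m, j)
    return float(Fraction(num, math.comb(p * m, n)))


def phase_score(P: Sequence[float], U: Sequence[float], k: int) -> Optional[float]:
    """Per-position phase score; defined only when k >= 3 (else None)."""
    if k < 3:
        return None
    sp = float(sum(P))
    su = float(sum(U))
    if sp < 0 or su < 0:
        raise ValueError("read counts must be non-negative")
    return (k - 2) * math.log1p(10.0 * sp / (1.0 + su))


def phase_position(alignment: Alignment, phase_length: int) -> int:
    """Effective plus-strand register position of a p-nt read.

    Plus-strand reads sit at their leftmost coordinate; minus-strand
    reads are shifted +2 so that the two strands of a phased duplex
    (2-nt 3' overhangs) land on the same register.
    """
    if len(alignment.tag) != phase_length:
        raise ValueError("alignment tag length must equal the phase length")
    return alignment.start if alignment.strand == "+" else alignment.start + 2


# ---------------------------------------------------------------------------
# window scan


@dataclass
class PhaseWindow:
    ref_id: str
    start: int                 # 1-based window start = anchor register
    phase_length: int
    m: int
    n: int                     # unique p-nt sRNAs in the window
    k: int                     # distinct occupied in-register positions
    P: List[int]               # phased read counts per cycle
    U: List[int]               # non-phased read counts per cycle
    pvalue: float
    score: Optional[float]

    @property
    def end(self) -> int:
        return self.start + self.phase_length * self.m - 1


class PhaseTrack:
    """Scan result: per-reference tag placements plus all evaluated windows."""

    def __init__(self, reference: Reference, phase_length: int, m: int):
        self.reference = reference
        self.phase_length = phase_length
        self.m = m
        self.windows: List[PhaseWindow] = []
        # per ref: parallel arrays (effective position, tag index, read count)
        self._eff: Dict[str, np.ndarray] = {}
        self._tag: Dict[str, np.ndarray] = {}
        self._cnt: Dict[str, np.ndarray] = {}
        self.tag_sequences: List[str] = []

    def phased_tags(
        self, ref_id: str, start: int, end: int, register: int
    ) -> List[Tuple[int, str]]:
        """Unique (position, sequence) of in-register tags within [start, end]."""
        if ref_id not in self._eff:
            return []
        eff, tag = self._eff[ref_id], self._tag[ref_id]
        lo, hi = np.searchsorted(eff, (start, end + 1))
        p = self.phase_length
        out = {
            (int(e), self.tag_sequences[t])
            for e, t in zip(eff[lo:hi], tag[lo:hi])
            if (int(e) - register) % p == 0
        }
        return sorted(out)


def scan(
    alignments: Iterable[Alignment],
    reference: Reference,
    phase_length: int = 21,
    m: int = DEFAULT_M,
    counts: Optional[Mapping[str, int]] = None,
    exclude: Optional[set] = None,
    min_pvalue_keep: float = 1.0,
) -> PhaseTrack:
    """Slide a p*m-nt window over every position and compute Eq.-style stats.

    Only alignments of exactly ``phase_length``-nt tags participate; tags
    in ``exclude`` (e.g. repeat-annotated sequences) are ignored.
    ``counts`` maps tag sequence -> read count (default 1 per unique
    tag); multi-mapping tags contribute at every placement.  Windows
    containing no tag are skipped; ``min_pvalue_keep`` < 1 additionally
    drops windows above that P-value from the result (placements are
    always retained in the track).
    """
    track = PhaseTrack(reference, phase_length, m)
    p, W = phase_length, phase_length * m
    exclude = exclude or set()

    by_ref: Dict[str, List[Tuple[int, int, int]]] = {}
    tag_index: Dict[str, int] = {}
    for a in alignments:
        if len(a.tag) != p or a.tag in exclude:
            continue
        if a.tag not in tag_index:
            tag_index[a.tag] = len(track.tag_sequences)
            track.tag_sequences.append(a.tag)
        eff = phase_position(a, p)
        c = counts.get(a.tag, 1) if counts is not None else 1
        by_ref.setdefault(a.ref_id, []).append((eff, tag_index[a.tag], c))

    for rid in sorted(by_ref):
        recs = sorted(set(by_ref[rid]))
        eff = np.array([r[0] for r in recs], dtype=np.int64)
        tag = np.array([r[1] for r in recs], dtype=np.int64)
        cnt = np.array([r[2] for r in recs], dtype=np.int64)
        track._eff[rid], track._tag[rid], track._cnt[rid] = eff, tag, cnt
        L = reference.length(rid)
        # candidate starts: any position whose window holds >= 1 placement
        starts = set()
        for e in eff:
            lo = max(1, int(e) - W + 1)
            hi = min(int(e), L - W + 1)
            starts.update(range(lo, hi + 1))
        for s in sorted(starts):
            lo, hi = np.searchsorted(eff, (s, s + W))
            if lo == hi:
                continue
            we, wt, wc = eff[lo:hi], tag[lo:hi], cnt[lo:hi]
            regs = (we - s) % p
            phased_mask = regs == 0
            n = len(set(wt.tolist()))
            k = len(set(we[phased_mask].tolist()))
            cycles = (we - s) // p
            P = [0] * m
            U = [0] * m
            for cyc, ph, c in zip(cycles.tolist(), phased_mask.tolist(), wc.tolist()):
                if ph:
                    P[cyc] += c
                else:
                    U[cyc] += c
            n_eff = min(n, p * m)
            k_eff = min(k, n_eff)
            pv = phasing_pvalue(n_eff, k_eff, m, p)
            sc = phase_score(P, U, k)
            if pv <= min_pvalue_keep or sc is not None:
                track.windows.append(
                    PhaseWindow(rid, s, p, m, n, k, P, U, pv, sc)
                )
    return track


# ---------------------------------------------------------------------------
# merging, FDR, locus calling


@dataclass
class MergedRegion:
    ref_id: str
    start: int
    end: int
    phase_length: int
    pvalue: float              # minimum member-window P-value
    qvalue: float = math.nan
    windows: List[PhaseWindow] = field(default_factory=list)

    @property
    def max_score(self) -> float:
        scores = [w.score for w in self.windows if w.score is not None]
        return max(scores) if scores else -math.inf

    @property
    def anchor_window(self) -> PhaseWindow:
        """Member window with the maximal phase score (leftmost on ties)."""
        best = None
        for w in sorted(self.windows, key=lambda w: w.start):
            if w.score is None:
                continue
            if best is None or w.score > best.score:
                best = w
        return best if best is not None else min(self.windows, key=lambda w: w.pvalue)


def benjamini_hochberg(pvalues: Sequence[float]) -> List[float]:
    """BH step-up adjusted P-values (monotone, capped at 1)."""
    N = len(pvalues)
    order = sorted(range(N), key=lambda i: pvalues[i])
    adj = [0.0] * N
    prev = 1.0
    for rank_from_top in range(N, 0, -1):
        i = order[rank_from_top - 1]
        q = min(prev, pvalues[i] * N / rank_from_top)
        adj[i] = q
        prev = q
    return adj


def storey_qvalues(pvalues: Sequence[float], lam: float = 0.5) -> List[float]:
    """Storey-style q-values: BH scaled by the pi0 estimate at ``lam``."""
    N = len(pvalues)
    pi0 = min(1.0, sum(1 for p in pvalues if p > lam) / ((1 - lam) * N)) if N else 1.0
    return [min(1.0, q * pi0) for q in benjamini_hochberg(pvalues)]


def merge_and_correct(
    track: PhaseTrack,
    alpha: float = 0.05,
    extend: int = 100,
    method: str = "bh",
) -> List[MergedRegion]:
    """Extend windows with P < alpha by 100 bp, merge overlaps, FDR-correct.

    Each merged region inherits the minimum member P-value; correction
    ("bh" or "qvalue") is applied across merged regions.
    """
    qualifying = [w for w in track.windows if w.pvalue < alpha]
    regions: List[MergedRegion] = []
    by_ref: Dict[str, List[PhaseWindow]] = {}
    for w in qualifying:
        by_ref.setdefault(w.ref_id, []).append(w)
    for rid in sorted(by_ref):
        L = track.reference.length(rid)
        wins = sorted(by_ref[rid], key=lambda w: w.start)
        cur: Optional[MergedRegion] = None
        for w in wins:
            s = max(1, w.start - extend)
            e = min(L, w.end + extend)
            if cur is not None and s <= cur.end:
                cur.end = max(cur.end, e)
                cur.pvalue = min(cur.pvalue, w.pvalue)
                cur.windows.append(w)
            else:
                cur = MergedRegion(rid, s, e, track.phase_length, w.pvalue, windows=[w])
                regions.append(cur)
    if regions:
        pv = [r.pvalue for r in regions]
        qv = benjamini_hochberg(pv) if method == "bh" else storey_qvalues(pv)
        for r, q in zip(regions, qv):
            r.qvalue = q
    return regions


@dataclass
class PhasiRNA:
    name: str
    position: int              # effective (register) position, 1-based
    sequence: str


@dataclass
class PhasLocus:
    name: str                  # e.g. P21_Chr6_2
    ref_id: str
    start: int
    end: int
    phase_length: int
    anchor_register: int       # anchor position mod phase_length
    pvalue: float
    qvalue: float
    max_score: float
    phasirnas: List[PhasiRNA] = field(default_factory=list)

    @property
    def n_unique(self) -> int:
        return len(self.phasirnas)


def call_loci(
    track: PhaseTrack,
    regions: Sequence[MergedRegion],
    score_threshold: float = 5.0,
    q_threshold: float = 0.05,
    min_unique: int = 4,
) -> List[PhasLocus]:
    """Report merged regions passing the joint thresholds as PHAS loci.

    A region qualifies when its maximal phase score exceeds
    ``score_threshold``, its corrected P-value is below ``q_threshold``
    and it contains at least ``min_unique`` unique phased tags at the
    anchor register.  Loci are named P{p}_{ref}_{serial} with serials by
    position within each reference; member phasiRNAs are named
    {locus}_siR{serial} in positional order.
    """
    kept: List[Tuple[MergedRegion, List[Tuple[int, str]]]] = []
    for r in sorted(regions, key=lambda r: (r.ref_id, r.start)):
        if not (r.max_score > score_threshold) or not (r.qvalue < q_threshold):
            continue
        anchor = r.anchor_window
        register = anchor.start % track.phase_length
        phased = track.phased_tags(r.ref_id, r.start, r.end, register)
        if len(phased) < min_unique:
            continue
        kept.append((r, phased))

    loci: List[PhasLocus] = []
    serial: Dict[str, int] = {}
    for r, phased in kept:
        serial[r.ref_id] = serial.get(r.ref_id, 0) + 1
        name = f"P{track.phase_length}_{r.ref_id}_{serial[r.ref_id]}"
        anchor = r.anchor_window
        phasirnas = [
            PhasiRNA(f"{name}_siR{i + 1}", pos, seq)
            for i, (pos, seq) in enumerate(phased)
        ]
        loci.append(
            PhasLocus(
                name, r.ref_id, r.start, r.end, track.phase_length,
                anchor.start % track.phase_length, r.pvalue, r.qvalue,
                r.max_score, phasirnas,
            )
        )
    return loci


@dataclass
class PhasCluster:
    loci: List[PhasLocus]

    @property
    def span(self) -> Tuple[str, int, int]:
        return (self.loci[0].ref_id, self.loci[0].start, self.loci[-1].end)


def cluster_loci(loci: Sequence[PhasLocus], gap: int = 2000) -> List[PhasCluster]:
    """Chain same-reference, same-phase loci separated by < ``gap`` bp."""
    clusters: List[PhasCluster] = []
    for key in sorted({(l.ref_id, l.phase_length) for l in loci}):
        members = sorted(
            (l for l in loci if (l.ref_id, l.phase_length) == key),
            key=lambda l: l.start,
        )
        cur: List[PhasLocus] = []
        for l in members:
            if cur and l.start - cur[-1].end < gap:
                cur.append(l)
            else:
                if cur:
                    clusters.append(PhasCluster(cur))
                cur = [l]
        if cur:
            clusters.append(PhasCluster(cur))
    return clusters


# ---------------------------------------------------------------------------
# exports


def loci_to_bed(loci: Sequence[PhasLocus], path) -> None:
    with open(path, "w") as fh:
        for l in loci:
            s, e = to_bed_interval(l.start, l.end)
            fh.write(f"{l.ref_id}\t{s}\t{e}\t{l.name}\t{l.max_score:.3f}\t.\n")


def loci_to_gff3(loci: Sequence[PhasLocus], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for l in loci:
            fh.write(
                f"{l.ref_id}\tphasikit\tphas_locus\t{l.start}\t{l.end}\t"
                f"{l.max_score:.3f}\t.\t.\tID={l.name};qvalue={l.qvalue:.3g};"
                f"n_phasirnas={l.n_unique}\n"
            )
            for s in l.phasirnas:
                fh.write(
                    f"{l.ref_id}\tphasikit\tphasirna\t{s.position}\t"
                    f"{s.position + l.phase_length - 1}\t.\t.\t.\t"
                    f"ID={s.name};Parent={l.name}\n"
                )


def loci_report(loci: Sequence[PhasLocus], path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tref_id\tstart\tend\tphase_length\tpvalue\tqvalue\tmax_score\tn_phasirnas\n")
        for l in loci:
            fh.write(
                f"{l.name}\t{l.ref_id}\t{l.start}\t{l.end}\t{l.phase_length}\t"
                f"{l.pvalue:.3g}\t{l.qvalue:.3g}\t{l.max_score:.3f}\t{l.n_unique}\n"
            )


def phasirna_fasta(loci: Sequence[PhasLocus], path) -> None:
    from .core_align import write_fasta

    write_fasta({s.name: s.sequence for l in loci for s in l.phasirnas}, path)


def score_bedgraph(track: PhaseTrack, path) -> None:
    """Per-position phase-score track (positions with k >= 3 only)."""
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="phase_score"\n')
        for w in sorted(track.windows, key=lambda w: (w.ref_id, w.start)):
            if w.score is not None:
                fh.write(f"{w.ref_id}\t{w.start - 1}\t{w.start}\t{w.score:.4f}\n")
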