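"""Degradome-supported target identification for miRNAs, tasiRNAs and phasiRNAs.

A small RNA binds its target by ungapped reverse-complementarity: site
position j (1-based, 5'->3' on the transcript) pairs query position
L - j + 1.  Sites are scored by counting non-Watson-Crick pairs, with
G:U wobbles costing 0.5 by default.  Degradome (PARE) tags mark cleaved
5' ends; a "valid read" starts at a transcript position pairing query
positions 9-11, the canonical slicer window.  Acceptance rules differ
by query class: conserved miRNAs need score <= 4; novel miRNAs need at
least one valid read and score < 4; phasiRNAs need either a perfect
site or at least one valid read with score <= 3.  TAS3 loci are found
by mapping known tasiARFs and requiring miR390 complementary sites on
both sides of the tasiRNA region (the two-hit trigger geometry).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core_align import Alignment, Reference, build_index, map_tags, revcomp

GU_WOBBLE_COST = 0.5
VALID_READ_POSITIONS = (9, 10, 11)

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}  # DNA alphabet: G:U == (G, T)


@dataclass
class TargetSite:
    query_id: str
    query: str
    transcript_id: str
    start: int                 # 1-based site interval on the transcript
    end: int
    score: float               # mismatch score, G:U = 0.5 steps
    valid_reads: int = 0
    query_class: Optional[str] = None
    accepted: Optional[bool] = None


def _pair_cost(q: str, t: str, gu_cost: float) -> float:
    if (q, t) in _WC:
        return 0.0
    if (q, t) in _GU:
        return gu_cost
    return 1.0


def find_sites(
    query: str,
    transcripts: Reference,
    max_mismatch: float = 4.0,
    query_id: str = "query",
    gu_cost: float = GU_WOBBLE_COST,
) -> List[TargetSite]:
    """Scan every transcript for reverse-complementary sites of ``query``.

    Ungapped scoring at every offset; all sites with score <=
    ``max_mismatch`` are returned (ties all reported).
    """
    q = query.upper().replace("U", "T")
    if not 20 <= len(q) <= 24:
        raise ValueError("query must be 20-24 nt")
    L = len(q)
    out: List[TargetSite] = []
    for tid in sorted(transcripts.sequences):
        seq = transcripts.sequences[tid]
        for s in range(len(seq) - L + 1):
            site = seq[s : s + L]
            score = 0.0
            for j in range(L):
                # site position j+1 pairs query position L-j
                score += _pair_cost(q[L - 1 - j], site[j], gu_cost)
                if score > max_mismatch:
                    break
            if score <= max_mismatch:
                out.append(TargetSite(query_id, q, tid, s + 1, s + L, score))
    return out


def site_position_pairing(site: TargetSite, query_position: int) -> int:
    """Transcript coordinate pairing a given query position (1-based)."""
    return site.end - query_position + 1


def tplot_data(
    transcript_id: str,
    transcript_length: int,
    degradome: Iterable[Alignment],
    counts: Optional[Mapping[str, int]] = None,
) -> np.ndarray:
    """Per-position degradome 5'-end read-count vector (index 0 = position 1).

    Counts sense-strand degradome tag starts, each weighted by its
    collapsed read count when ``counts`` (tag sequence -> reads) is
    given; the vector sums to the number of mapped degradome reads on
    the transcript.
    """
    vec = np.zeros(transcript_length, dtype=np.int64)
    for a in degradome:
        if a.ref_id == transcript_id and a.strand == "+":
            vec[a.start - 1] += counts.get(a.tag, 1) if counts else 1
    return vec


def count_valid_reads(
    site: TargetSite,
    tplot: np.ndarray,
    positions: Sequence[int] = VALID_READ_POSITIONS,
) -> int:
    """Degradome reads whose 5' ends pair query positions 9-11 of the site."""
    total = 0
    for qpos in positions:
        t = site_position_pairing(site, qpos)
        if 1 <= t <= len(tplot):
            total += int(tplot[t - 1])
    return total


def call_targets(
    sites: Sequence[TargetSite], query_class: str
) -> List[TargetSite]:
    """Apply the per-class acceptance rule; returns sites with decisions set.

    conserved: score <= 4; novel: >= 1 valid read and score < 4;
    phasiRNA: score == 0, or >= 1 valid read and score <= 3.
    """
    if query_class not in ("conserved", "novel", "phasiRNA"):
        raise ValueError(f"unknown query class {query_class!r}")
    out = []
    for s in sites:
        if query_class == "conserved":
            ok = s.score <= 4.0
        elif query_class == "novel":
            ok = s.valid_reads >= 1 and s.score < 4.0
        else:
            ok = s.score == 0.0 or (s.valid_reads >= 1 and s.score <= 3.0)
        s.query_class = query_class
        s.accepted = ok
        out.append(s)
    return out


def find_phas_triggers(
    mirnas: Mapping[str, str],
    locus_sequences: Mapping[str, str],
    tplots: Optional[Mapping[str, np.ndarray]] = None,
    max_mismatch: float = 4.0,
) -> List[TargetSite]:
    """miRNA trigger sites on PHAS locus transcripts (both strands).

    A site is kept when it has at least one valid degradome read or
    scores below 4 mismatches, the conserved-trigger rule.
    """
    out = []
    for lid, seq in sorted(locus_sequences.items()):
        both = Reference("phas-strands", {f"{lid}|+": seq, f"{lid}|-": revcomp(seq)})
        for qid in sorted(mirnas):
            for site in find_sites(mirnas[qid], both, max_mismatch, query_id=qid):
                if tplots is not None and site.transcript_id.endswith("|+"):
                    tp = tplots.get(lid)
                    if tp is not None:
                        site.valid_reads = count_valid_reads(site, tp)
                if site.valid_reads >= 1 or site.score < 4.0:
                    out.append(site)
    return out


# ---------------------------------------------------------------------------
# TAS3


@dataclass
class Tas3Locus:
    name: str
    ref_id: str
    start: int                 # cut-out locus interval on the genome, 1-based
    end: int
    strand: str
    site5: Tuple[int, int]     # genomic coordinates of the 5' miR390 site
    site3: Tuple[int, int]
    tasirna_interval: Tuple[int, int]


def find_tas3(
    known_tasiarfs: Mapping[str, str],
    genome: Reference,
    mir390: str,
    flank: int = 250,
    max_mismatch: int = 2,
    site_max_mismatch: float = 4.0,
) -> List[Tas3Locus]:
    """TAS3 discovery via the two-hit miR390 geometry.

    Known tasiARFs are mapped to the genome (<= 2 substitutions), the
    matched loci are cut out with 250-nt flanks, and miR390
    complementary sites are required on both sides of the tasiRNA
    region.  Loci are named TAS3a, TAS3b, ... in genomic order.
    """
    idx = build_index(genome)
    hits: List[Alignment] = []
    for name in sorted(known_tasiarfs):
        seq = known_tasiarfs[name].upper().replace("U", "T")
        hits.extend(map_tags([seq], idx, max_mismatch))
    # merge overlapping tasiARF hits into candidate tasiRNA regions
    hits.sort(key=lambda a: (a.ref_id, a.start))
    regions: List[Tuple[str, int, int, str]] = []
    for a in hits:
        if regions and regions[-1][0] == a.ref_id and a.start <= regions[-1][2] + 1:
            r = regions[-1]
            regions[-1] = (r[0], r[1], max(r[2], a.end), r[3])
        else:
            regions.append((a.ref_id, a.start, a.end, a.strand))
    loci: List[Tas3Locus] = []
    for rid, rs, re_, strand in regions:
        L = genome.length(rid)
        cs, ce = max(1, rs - flank), min(L, re_ + flank)
        cut = genome.fetch(rid, cs, ce)
        if strand == "-":
            cut = revcomp(cut)
        cutref = Reference("tas3-cutout", {"cut": cut})
        sites = find_sites(mir390, cutref, site_max_mismatch, query_id="miR390")
        if strand == "+":
            tas_lo, tas_hi = rs - cs + 1, re_ - cs + 1
            to_genomic = lambda a, b: (cs + a - 1, cs + b - 1)
        else:
            n = len(cut)
            tas_lo, tas_hi = n - (re_ - cs + 1) + 1, n - (rs - cs + 1) + 1
            to_genomic = lambda a, b: (ce - b + 1, ce - a + 1)
        up = [s for s in sites if s.end < tas_lo]
        down = [s for s in sites if s.start > tas_hi]
        if up and down:
            s5 = max(up, key=lambda s: s.end)       # nearest upstream site
            s3 = min(down, key=lambda s: s.start)   # nearest downstream site
            loci.append(
                Tas3Locus(
                    "", rid, cs, ce, strand,
                    to_genomic(s5.start, s5.end),
                    to_genomic(s3.start, s3.end),
                    (rs, re_),
                )
            )
    loci.sort(key=lambda l: (l.ref_id, l.start))
    for i, l in enumerate(loci):
        l.name = "TAS3" + "abcdefghijklmnopqrstuvwxyz"[i % 26]
    return loci


# ---------------------------------------------------------------------------
# exports


def targets_to_tsv(sites: Sequence[TargetSite], path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\ttranscript_id\tstart\tend\tscore\tvalid_reads\tclass\taccepted\n")
        for s in sites:
            fh.write(
                f"{s.query_id}\t{s.transcript_id}\t{s.start}\t{s.end}\t{s.score}\t"
                f"{s.valid_reads}\t{s.query_class or ''}\t{s.accepted}\n"
            )


def tplot_to_tsv(transcript_id: str, vec: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tposition\treads\n")
        for i, v in enumerate(vec, start=1):
            fh.write(f"{transcript_id}\t{i}\t{int(v)}\n")


def tas3_report(loci: Sequence[Tas3Locus], path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tref_id\tstart\tend\tstrand\tsite5_start\tsite5_end\tsite3_start\tsite3_end\ttasirna_start\ttasirna_end\n")
        for l in loci:
            fh.write(
                f"{l.name}\t{l.ref_id}\t{l.start}\t{l.end}\t{l.strand}\t"
                f"{l.site5[0]}\t{l.site5[1]}\t{l.site3[0]}\t{l.site3[1]}\t"
                f"{l.tasirna_interval[0]}\t{l.tasirna_interval[1]}\n"
            )
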