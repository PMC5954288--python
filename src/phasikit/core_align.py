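"""Reference handling and mismatch-tolerant mapping of short sRNA tags.

All coordinates in this package are 1-based inclusive on the plus strand;
minus-strand placements are reported by their leftmost plus-strand
coordinate.  Export helpers convert to 0-based half-open only at the BED
boundary.  Alignment is ungapped (substitutions only), matching the
short-tag aligners classically used for sRNA data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

_VALID = set("ACGTN")
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# byte encoding used for vectorized Hamming scans; N never matches anything
_ENC = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i + 1


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (keeps case, maps N->N)."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode ACGT as 1..4, anything else as 0 (never matches)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class Reference:
    """A named set of reference sequences (genome or transcript set)."""

    name: str
    sequences: Dict[str, str]

    def __post_init__(self):
        if not self.sequences:
            raise ValueError("no sequences")
        for rid, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"reference sequence {rid!r} is empty")
            bad = set(seq.upper()) - _VALID
            if bad:
                raise ValueError(
                    f"reference {rid!r} contains invalid characters: {sorted(bad)}"
                )
        # normalise to uppercase once
        object.__setattr__(
            self, "sequences", {r: s.upper() for r, s in self.sequences.items()}
        )

    def __len__(self) -> int:
        return len(self.sequences)

    def length(self, ref_id: str) -> int:
        return len(self.sequences[ref_id])

    def fetch(self, ref_id: str, start: int, end: int) -> str:
        """1-based inclusive subsequence, clipped to the sequence bounds."""
        seq = self.sequences[ref_id]
        return seq[max(start, 1) - 1 : min(end, len(seq))]


@dataclass(frozen=True)
class Alignment:
    """An ungapped placement of a tag on a reference.

    ``start`` is the leftmost 1-based plus-strand coordinate regardless of
    strand; ``mismatches`` counts substitutions only.
    """

    tag: str
    ref_id: str
    start: int
    strand: str
    mismatches: int

    @property
    def end(self) -> int:
        return self.start + len(self.tag) - 1


class SeedIndex:
    """Exact-word index over both strands of a reference.

    Stores, for every ``word_size``-mer, its plus-strand occurrences of the
    word itself and of its reverse complement.  Also keeps byte-encoded
    sequence arrays used by the vectorized mismatch scan in
    :func:`map_tags`.
    """

    def __init__(self, reference: Reference, word_size: int = 10):
        if not 8 <= word_size <= 14:
            raise ValueError("word_size must be between 8 and 14")
        self.reference = reference
        self.word_size = word_size
        self.encoded: Dict[str, np.ndarray] = {
            rid: encode(seq) for rid, seq in reference.sequences.items()
        }
        self._index: Dict[str, List[Tuple[str, int, str]]] = {}
        w = word_size
        for rid, seq in sorted(reference.sequences.items()):
            for i in range(len(seq) - w + 1):
                word = seq[i : i + w]
                if "N" in word:
                    continue
                self._index.setdefault(word, []).append((rid, i + 1, "+"))
                self._index.setdefault(revcomp(word), []).append((rid, i + 1, "-"))

    def lookup(self, word: str) -> List[Tuple[str, int, str]]:
        """All (ref_id, 1-based plus-strand start, strand) exact occurrences."""
        if len(word) != self.word_size:
            raise ValueError("word length must equal the index word size")
        return list(self._index.get(word.upper(), ()))


def build_index(reference: Reference, word_size: int = 10) -> SeedIndex:
    """Build an exact-word :class:`SeedIndex` over both strands."""
    return SeedIndex(reference, word_size)


def _scan_one_strand(
    tag_enc: np.ndarray, ref_enc: np.ndarray, max_mismatch: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized full Hamming scan: returns (0-based starts, mismatch counts)."""
    L, ell = ref_enc.size, tag_enc.size
    if ell > L:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    n_pos = L - ell + 1
    mism = np.zeros(n_pos, dtype=np.int32)
    for i in range(ell):
        mism += ref_enc[i : i + n_pos] != tag_enc[i]
    hits = np.nonzero(mism <= max_mismatch)[0]
    return hits, mism[hits]


def map_tags(
    tags: Iterable,
    index: SeedIndex,
    max_mismatch: int = 2,
) -> List[Alignment]:
    """Map tag sequences to the indexed reference, both strands, all placements.

    Accepts plain sequences or objects with a ``sequence`` attribute
    (:class:`~phasikit.preprocess.UniqueTag`).  Tags with non-ACGT
    characters are skipped with a single summary warning.  Alignment is
    ungapped; every placement with at most ``max_mismatch`` substitutions
    is returned, minus-strand placements by leftmost plus-strand
    coordinate.
    """
    if max_mismatch > 3:
        raise ValueError("max_mismatch must be <= 3")
    skipped = 0
    out: List[Alignment] = []
    for tag in tags:
        seq = getattr(tag, "sequence", tag).upper()
        if not 15 <= len(seq) <= 30:
            raise ValueError(f"tag length {len(seq)} outside 15-30 nt: {seq!r}")
        if set(seq) - set("ACGT"):
            skipped += 1
            continue
        fwd = encode(seq)
        rev = encode(revcomp(seq))
        for rid in sorted(index.encoded):
            ref_enc = index.encoded[rid]
            for strand, enc in (("+", fwd), ("-", rev)):
                starts, mm = _scan_one_strand(enc, ref_enc, max_mismatch)
                for s, m in zip(starts, mm):
                    out.append(Alignment(seq, rid, int(s) + 1, strand, int(m)))
    if skipped:
        warnings.warn(f"skipped {skipped} tag(s) with non-ACGT characters")
    return out


# ---------------------------------------------------------------------------
# FASTA / TSV interfaces


def read_fasta(path, name: str | None = None) -> Reference:
    """Read a FASTA file into a :class:`Reference` (ids = record ids)."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return Reference(name or str(path), seqs)


def write_fasta(sequences: Mapping[str, str], path) -> None:
    """Write sequences as 60-column wrapped FASTA."""
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def alignments_to_tsv(alignments: Sequence[Alignment], path) -> None:
    """Write an alignment table (tag, ref, start, strand, mismatches)."""
    with open(path, "w") as fh:
        fh.write("tag\tref_id\tstart\tstrand\tmismatches\n")
        for a in alignments:
            fh.write(f"{a.tag}\t{a.ref_id}\t{a.start}\t{a.strand}\t{a.mismatches}\n")


def to_bed_interval(start: int, end: int) -> Tuple[int, int]:
    """Convert a 1-based inclusive interval to BED 0-based half-open."""
    return start - 1, end
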