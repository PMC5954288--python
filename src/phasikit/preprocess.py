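"""Read QC, adapter trimming, tag collapsing and category annotation.

sRNA reads are kept when at most 5 nucleotides score below Q25; the 3'
adapter is located by an exact >= 8-nt prefix match (or a full-adapter
match with <= 1 mismatch) and inserts of 18-30 nt are retained.  Degradome
reads are kept when the first 20 nucleotides all score >= Q20 and are then
truncated to exactly those 20 nt.  Surviving reads collapse to unique
tags carrying per-library counts, the unit of all downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .core_align import Reference, SeedIndex, build_index, write_fasta

PHRED_OFFSET = 33

CATEGORY_UNMAPPED = "unmapped"
CATEGORY_GENOME_ONLY = "genome-only"


@dataclass
class FastqRead:
    name: str
    sequence: str
    quality: str

    def __post_init__(self):
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.name!r}: sequence/quality length mismatch"
            )

    @property
    def scores(self) -> List[int]:
        return [ord(c) - PHRED_OFFSET for c in self.quality]


def read_fastq(source) -> List[FastqRead]:
    """Parse 4-line FASTQ (path, open file, or list of record strings)."""
    if isinstance(source, (list, tuple)):
        lines = "".join(source).splitlines()
    else:
        fh = open(source) if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__") else source
        lines = fh.read().splitlines()
        if fh is not source:
            fh.close()
    reads = []
    for i in range(0, len(lines) - 3, 4):
        if not lines[i].startswith("@"):
            raise ValueError(f"malformed FASTQ at line {i + 1}")
        reads.append(FastqRead(lines[i][1:].split()[0], lines[i + 1].upper(), lines[i + 3]))
    return reads


@dataclass
class UniqueTag:
    """A collapsed small-RNA (or degradome-tag) sequence with library counts."""

    sequence: str
    counts: Dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def filter_srna_read(read: FastqRead, min_q: int = 25, max_low: int = 5) -> bool:
    """Keep an sRNA read unless more than ``max_low`` positions score < ``min_q``."""
    low = sum(1 for s in read.scores if s < min_q)
    return low <= max_low


def trim_adapter(
    sequence: str,
    adapter: str,
    min_insert: int = 18,
    max_insert: int = 30,
) -> Tuple[Optional[str], str]:
    """Trim the 3' adapter; returns (insert or None, reason).

    The adapter is located at the leftmost position where either its
    first 8 nt match exactly, or the full adapter fits with at most one
    mismatch.  Reasons: "ok", "no-adapter", "too-short", "too-long".
    """
    if len(adapter) < 8:
        raise ValueError("adapter must be >= 8 nt")
    seq = sequence.upper()
    adapter = adapter.upper()
    prefix = adapter[:8]
    pos = -1
    for i in range(len(seq) - 7):
        if seq[i : i + 8] == prefix:
            pos = i
            break
        if i + len(adapter) <= len(seq):
            mm = sum(1 for a, b in zip(seq[i : i + len(adapter)], adapter) if a != b)
            if mm <= 1:
                pos = i
                break
    if pos < 0:
        return None, "no-adapter"
    insert = seq[:pos]
    if len(insert) < min_insert:
        return None, "too-short"
    if len(insert) > max_insert:
        return None, "too-long"
    return insert, "ok"


def filter_degradome_read(read: FastqRead, min_q: int = 20) -> Tuple[Optional[str], str]:
    """QC + truncate a degradome read to its first 20 nt.

    Returns (20-nt tag, "ok"), or (None, reason) for short or low-quality
    reads: the read is dropped if any of its first 20 positions scores
    below ``min_q``.
    """
    if len(read.sequence) < 20:
        return None, "too-short"
    if any(s < min_q for s in read.scores[:20]):
        return None, "low-quality"
    return read.sequence[:20], "ok"


def collapse_unique(reads: Iterable[Tuple[str, str]]) -> List[UniqueTag]:
    """Collapse (library_id, sequence) reads to unique tags.

    Per-library read counts are conserved exactly; output order is by
    decreasing total count then sequence, so it is independent of input
    order.
    """
    table: Dict[str, Dict[str, int]] = {}
    for lib, seq in reads:
        seq = seq.upper()
        table.setdefault(seq, {})
        table[seq][lib] = table[seq].get(lib, 0) + 1
    tags = [UniqueTag(seq, counts) for seq, counts in table.items()]
    tags.sort(key=lambda t: (-t.total, t.sequence))
    return tags


def process_srna_fastq(
    source,
    library_id: str,
    adapter: str = "",
    min_q: int = 25,
    max_low: int = 5,
    min_insert: int = 18,
    max_insert: int = 30,
) -> List[Tuple[str, str]]:
    """Full sRNA read path: QC filter, optional adapter trim, length select."""
    out = []
    for read in read_fastq(source):
        if not filter_srna_read(read, min_q, max_low):
            continue
        if adapter:
            insert, reason = trim_adapter(read.sequence, adapter, min_insert, max_insert)
            if insert is None:
                continue
        else:
            insert = read.sequence
            if not min_insert <= len(insert) <= max_insert:
                continue
        out.append((library_id, insert))
    return out


def process_degradome_fastq(source, library_id: str = "degradome") -> List[Tuple[str, str]]:
    """Degradome read path: QC on the first 20 nt, then truncate to 20 nt."""
    out = []
    for read in read_fastq(source):
        tag, reason = filter_degradome_read(read)
        if tag is not None:
            out.append((library_id, tag))
    return out


def annotate_categories(
    tags: Sequence[UniqueTag],
    refs: Sequence[Tuple[str, Reference]],
    genome: Optional[Reference] = None,
) -> Dict[str, str]:
    """Assign each tag the label of the first reference it maps to exactly.

    ``refs`` is priority-ordered, e.g. [("other-ncRNA", rfam), ("repeat",
    repeats), ("mRNA", transcripts)].  Tags matching none of them are
    "genome-only" if they occur in ``genome`` (either strand, 0
    mismatches) else "unmapped".  Exact matching is used because category
    assignment is an annotation step, not quantification.
    """
    from .core_align import revcomp

    def membership(ref: Reference) -> set:
        words = set()
        for seq in ref.sequences.values():
            words.add(seq)
        return words

    # exact substring membership via per-reference scan; tags are short so
    # a simple find() is adequate at the scales this package targets
    def maps_to(tag: str, ref: Reference) -> bool:
        rc = revcomp(tag)
        for seq in ref.sequences.values():
            if tag in seq or rc in seq:
                return True
        return False

    labels: Dict[str, str] = {}
    for t in tags:
        label = None
        for name, ref in refs:
            if maps_to(t.sequence, ref):
                label = name
                break
        if label is None and genome is not None and maps_to(t.sequence, genome):
            label = CATEGORY_GENOME_ONLY
        labels[t.sequence] = label or CATEGORY_UNMAPPED
    return labels


def category_summary(
    tags: Sequence[UniqueTag], labels: Mapping[str, str]
) -> Dict[str, Tuple[int, int]]:
    """Per-category (unique tags, total reads) summary table."""
    out: Dict[str, Tuple[int, int]] = {}
    for t in tags:
        lab = labels[t.sequence]
        u, r = out.get(lab, (0, 0))
        out[lab] = (u + 1, r + t.total)
    return out


def write_category_summary(
    tags: Sequence[UniqueTag], labels: Mapping[str, str], path
) -> None:
    """Category summary TSV (category, unique tags, total reads)."""
    summary = category_summary(tags, labels)
    with open(path, "w") as fh:
        fh.write("category\tunique_tags\ttotal_reads\n")
        for cat in sorted(summary):
            u, r = summary[cat]
            fh.write(f"{cat}\t{u}\t{r}\n")


def write_collapsed_fasta(tags: Sequence[UniqueTag], path) -> None:
    """Collapsed tags as FASTA with ">tagN_xCOUNT" headers."""
    seqs = {
        f"tag{i + 1}_x{t.total}": t.sequence for i, t in enumerate(tags)
    }
    write_fasta(seqs, path)


def write_count_matrix(tags: Sequence[UniqueTag], libraries: Sequence[str], path) -> None:
    """Tag-by-library read-count matrix as TSV."""
    with open(path, "w") as fh:
        fh.write("tag\t" + "\t".join(libraries) + "\n")
        for t in tags:
            fh.write(t.sequence + "\t" + "\t".join(str(t.counts.get(l, 0)) for l in libraries) + "\n")
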