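"""Synthetic genomes, sRNA libraries and degradome libraries.

The generator plants the two kinds of features the pipeline detects —
phased siRNA ladders (PHAS loci) and miRNA hairpin precursors — into a
uniform-random background genome, then simulates multi-library collapsed
sRNA sequencing (phased reads on both strands with the 2-nt duplex
offset, off-phase noise, length-structured background with the 21/24-nt
peaks typical of plant sRNA libraries) and degradome 5'-tag pileups
concentrated at planted cleavage positions.  Every feature's exact
coordinates are recorded in a :class:`GroundTruth` so detection can be
scored without external data.

Quality strings are constant high quality ("I" = Q40); QC behaviour is
tested on explicitly constructed degraded reads, keeping the simulator
independent of any sequencing-error model.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core_align import Reference, revcomp

_BASES = np.array(list("ACGT"))

# background read-length mix mimicking the 21/24-nt peaks of plant libraries
BACKGROUND_LENGTH_WEIGHTS = {21: 0.35, 22: 0.10, 23: 0.10, 24: 0.45}

HAIRPIN_LOOP = "TCTCTCTC"  # 8 nt, pyrimidine-only so it cannot self-pair
STAR_OVERHANG = "CC"


@dataclass
class PhasPlan:
    """One planted phased-siRNA ladder."""

    phase_length: int          # 21 or 24
    cycles: int                # number of phased positions (m')
    start: int                 # 1-based first register on the chromosome
    strand: str = "+"          # '+', '-' or 'both'
    abundance: int = 5         # reads per cycle per emitting strand
    noise_rate: float = 0.0    # off-phase reads per phased read
    ref_id: Optional[str] = None

    def __post_init__(self):
        if self.phase_length not in (21, 24):
            raise ValueError("phase_length must be 21 or 24")
        if self.strand not in ("+", "-", "both"):
            raise ValueError("strand must be '+', '-' or 'both'")
        if self.abundance < 0:
            raise ValueError("abundance must be >= 0")

    @property
    def end(self) -> int:
        return self.start + self.phase_length * self.cycles - 1


@dataclass
class HairpinPlan:
    """One planted miRNA hairpin precursor."""

    mature: str                # 20-22 nt mature sequence (DNA alphabet)
    arm: str = "5p"
    flank: int = 20
    start: Optional[int] = None  # 1-based insert position; auto-placed if None
    strand: str = "+"
    mature_reads: int = 100
    star_reads: int = 5
    ref_id: Optional[str] = None

    def __post_init__(self):
        self.mature = self.mature.upper().replace("U", "T")
        if not 20 <= len(self.mature) <= 22:
            raise ValueError("mature must be 20-22 nt")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")


@dataclass
class LibraryPlan:
    library_id: str
    depth: int = 1000          # scales the background read count
    background_rate: float = 0.0  # background reads = round(depth * rate)

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


@dataclass
class DegradomePlan:
    transcript_id: str
    position: int              # 1-based 5'-end of the cleavage tags
    count: int


@dataclass
class InsertPlan:
    """An arbitrary sequence written into the genome (e.g. a TAS3 construct)."""

    sequence: str
    start: int
    label: str = "insert"
    ref_id: Optional[str] = None

    def __post_init__(self):
        self.sequence = self.sequence.upper().replace("U", "T")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 1
    chrom_length: int = 20_000
    phas_plan: List[PhasPlan] = field(default_factory=list)
    hairpin_plan: List[HairpinPlan] = field(default_factory=list)
    library_plan: List[LibraryPlan] = field(default_factory=list)
    degradome_plan: List[DegradomePlan] = field(default_factory=list)
    insert_plan: List[InsertPlan] = field(default_factory=list)
    adapter: str = ""          # appended 3' adapter; empty = pre-trimmed reads

    def __post_init__(self):
        if self.chrom_length < 2000:
            raise ValueError("chrom_length must be >= 2 kb")


@dataclass
class PlantedPhas:
    ref_id: str
    start: int
    end: int
    phase_length: int
    strand: str
    cycles: int
    register: int              # start mod phase_length, the phase register


@dataclass
class PlantedHairpin:
    ref_id: str
    start: int                 # precursor start (1-based, incl. flanks)
    end: int
    strand: str
    precursor: str
    mature: str
    star: str
    mature_interval: Tuple[int, int]   # on the precursor, 1-based
    star_interval: Tuple[int, int]


@dataclass
class PlantedCleavage:
    transcript_id: str
    position: int
    count: int


@dataclass
class PlantedInsert:
    label: str
    ref_id: str
    start: int
    end: int


@dataclass
class GroundTruth:
    phas: List[PlantedPhas] = field(default_factory=list)
    hairpins: List[PlantedHairpin] = field(default_factory=list)
    cleavages: List[PlantedCleavage] = field(default_factory=list)
    inserts: List[PlantedInsert] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "phas": [asdict(x) for x in self.phas],
                    "hairpins": [asdict(x) for x in self.hairpins],
                    "cleavages": [asdict(x) for x in self.cleavages],
                    "inserts": [asdict(x) for x in self.inserts],
                },
                fh,
                indent=1,
            )

    def to_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for i, x in enumerate(self.phas, 1):
                fh.write(
                    f"{x.ref_id}\tphasikit-sim\tphas_locus\t{x.start}\t{x.end}\t.\t"
                    f"{x.strand if x.strand != 'both' else '.'}\t.\t"
                    f"ID=planted_phas_{i};phase={x.phase_length}\n"
                )
            for i, x in enumerate(self.hairpins, 1):
                fh.write(
                    f"{x.ref_id}\tphasikit-sim\tmiRNA_primary_transcript\t{x.start}\t"
                    f"{x.end}\t.\t{x.strand}\t.\tID=planted_hairpin_{i}\n"
                )


def hairpin_precursor(mature: str) -> Tuple[str, str, Tuple[int, int], Tuple[int, int]]:
    """Build a fold-back precursor for a mature sequence.

    Layout is mature + 8-nt loop + star, where the star is the reverse
    complement of all but the last two mature nucleotides plus a 2-nt
    unpaired tail, so the excised mature:star duplex carries 2-nt 3'
    overhangs on both ends.  Returns (precursor, star, mature interval,
    star interval), intervals 1-based on the precursor.
    """
    mature = mature.upper().replace("U", "T")
    star = revcomp(mature[:-2]) + STAR_OVERHANG
    precursor = mature + HAIRPIN_LOOP + star
    m_iv = (1, len(mature))
    s_iv = (len(mature) + len(HAIRPIN_LOOP) + 1, len(precursor))
    return precursor, star, m_iv, s_iv


def _random_chrom(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def make_genome(config: SimulationConfig) -> Tuple[Reference, GroundTruth]:
    """Generate the background genome and plant all configured features.

    Planted features must not overlap; an overlap raises an error naming
    the offending pair.  Identical configs produce byte-identical genomes.
    """
    rng = np.random.default_rng(config.seed)
    chroms = {
        f"Chr{i + 1}": _random_chrom(rng, config.chrom_length)
        for i in range(config.n_chromosomes)
    }
    truth = GroundTruth()

    intervals: List[Tuple[str, int, int, str]] = []  # (ref, start, end, label)

    def claim(ref_id: str, start: int, end: int, label: str):
        if ref_id not in chroms:
            raise ValueError(f"unknown chromosome {ref_id!r} for {label}")
        if start < 1 or end > config.chrom_length:
            raise ValueError(
                f"{label} [{start},{end}] outside chromosome {ref_id} "
                f"(length {config.chrom_length})"
            )
        for (r2, s2, e2, l2) in intervals:
            if r2 == ref_id and start <= e2 and s2 <= end:
                raise ValueError(f"planted features overlap: {label} and {l2}")
        intervals.append((ref_id, start, end, label))

    default_ref = "Chr1"
    for idx, pp in enumerate(config.phas_plan):
        rid = pp.ref_id or default_ref
        claim(rid, pp.start, pp.end, f"phas[{idx}]")
        truth.phas.append(
            PlantedPhas(
                rid, pp.start, pp.end, pp.phase_length, pp.strand, pp.cycles,
                pp.start % pp.phase_length,
            )
        )

    for idx, ip in enumerate(config.insert_plan):
        rid = ip.ref_id or default_ref
        end = ip.start + len(ip.sequence) - 1
        claim(rid, ip.start, end, f"insert[{idx}]")
        chroms[rid][ip.start - 1 : end] = list(ip.sequence)
        truth.inserts.append(PlantedInsert(ip.label, rid, ip.start, end))

    # auto-place hairpins left to right after the last claimed interval
    for idx, hp in enumerate(config.hairpin_plan):
        rid = hp.ref_id or default_ref
        precursor, star, m_iv, s_iv = hairpin_precursor(hp.mature)
        total = len(precursor) + 2 * hp.flank
        if hp.start is not None:
            start = hp.start
        else:
            used = [e for (r2, _, e, _) in intervals if r2 == rid]
            start = (max(used) if used else 0) + 500
        end = start + total - 1
        claim(rid, start, end, f"hairpin[{idx}]")
        prec_start = start + hp.flank
        insert = precursor if hp.strand == "+" else revcomp(precursor)
        arr = chroms[rid]
        arr[prec_start - 1 : prec_start - 1 + len(precursor)] = list(insert)
        truth.hairpins.append(
            PlantedHairpin(
                rid, prec_start, prec_start + len(precursor) - 1, hp.strand,
                precursor, hp.mature, star, m_iv, s_iv,
            )
        )

    ref = Reference("synthetic-genome", {r: "".join(a) for r, a in chroms.items()})
    return ref, truth


def plant_hairpin(
    genome: Reference, mature: str, flank: int = 20,
    ref_id: Optional[str] = None, start: Optional[int] = None, strand: str = "+",
) -> Tuple[Reference, PlantedHairpin]:
    """Insert a miRNA fold-back precursor into an existing genome.

    The precursor (mature + loop + star, see :func:`hairpin_precursor`)
    replaces genome sequence at ``start + flank``; the surrounding
    ``flank`` nt of native sequence are left in place as precursor
    context.  Returns the modified genome and the planted-hairpin record.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    precursor, star, m_iv, s_iv = hairpin_precursor(mature)
    rid = ref_id or next(iter(genome.sequences))
    seq = genome.sequences[rid]
    if start is None:
        start = len(seq) // 2
    prec_start = start + flank
    if prec_start < 1 or prec_start + len(precursor) - 1 > len(seq):
        raise ValueError("hairpin does not fit inside the chromosome")
    insert = precursor if strand == "+" else revcomp(precursor)
    new_seq = seq[: prec_start - 1] + insert + seq[prec_start - 1 + len(precursor):]
    seqs = dict(genome.sequences)
    seqs[rid] = new_seq
    planted = PlantedHairpin(
        rid, prec_start, prec_start + len(precursor) - 1, strand,
        precursor, mature.upper().replace("U", "T"), star, m_iv, s_iv,
    )
    return Reference(genome.name, seqs), planted


# ---------------------------------------------------------------------------
# library simulation


def _fastq_record(name: str, seq: str) -> str:
    return f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n"


def _phased_reads(genome: Reference, ph: PlantedPhas, abundance: int,
                  noise_rate: float, rng: np.random.Generator) -> List[str]:
    p = ph.phase_length
    seqs: List[str] = []
    strands = ["+", "-"] if ph.strand == "both" else [ph.strand]
    for c in range(ph.cycles):
        reg = ph.start + c * p
        for strand in strands:
            if strand == "+":
                s = genome.fetch(ph.ref_id, reg, reg + p - 1)
            else:
                # duplex partner: leftmost + 2 == plus register
                left = reg - 2
                if left < 1:
                    continue
                s = revcomp(genome.fetch(ph.ref_id, left, left + p - 1))
            if len(s) == p:
                seqs.extend([s] * abundance)
    n_noise = int(round(noise_rate * len(seqs)))
    for _ in range(n_noise):
        off = int(rng.integers(1, p))          # never on-register
        cyc = int(rng.integers(0, ph.cycles))
        pos = ph.start + cyc * p + off
        s = genome.fetch(ph.ref_id, pos, pos + p - 1)
        if len(s) == p:
            seqs.append(s)
    return seqs


def _background_reads(genome: Reference, n: int, rng: np.random.Generator) -> List[str]:
    lengths = np.array(sorted(BACKGROUND_LENGTH_WEIGHTS))
    weights = np.array([BACKGROUND_LENGTH_WEIGHTS[l] for l in lengths], dtype=float)
    weights /= weights.sum()
    rids = sorted(genome.sequences)
    out = []
    for _ in range(n):
        rid = rids[int(rng.integers(0, len(rids)))]
        L = int(rng.choice(lengths, p=weights))
        limit = genome.length(rid) - L
        pos = int(rng.integers(1, limit + 1))
        s = genome.fetch(rid, pos, pos + L - 1)
        if rng.integers(0, 2):
            s = revcomp(s)
        out.append(s)
    return out


def simulate_srna_library(
    genome: Reference,
    truth: GroundTruth,
    plan: LibraryPlan,
    config: SimulationConfig,
    path=None,
) -> List[str]:
    """Simulate one sRNA library; returns FASTQ records (and writes them).

    Emits the planted phased ladders (both strands where configured, with
    the minus-strand duplex offset), mature/star reads for planted
    hairpins, off-phase noise at each ladder's configured rate, and
    ``round(depth * background_rate)`` uniform background reads.  Constant
    quality "I"; the configured 3' adapter, if any, is appended to every
    read.  Deterministic for a fixed config seed and library id.
    """
    lib_seed = (config.seed * 100003 + zlib.crc32(plan.library_id.encode()) % 65536) % (2**31)
    rng = np.random.default_rng(lib_seed)
    seqs: List[str] = []
    for ph in truth.phas:
        pp = next(
            (x for x in config.phas_plan
             if (x.ref_id or "Chr1") == ph.ref_id and x.start == ph.start),
            None,
        )
        abundance = pp.abundance if pp else 0
        noise = pp.noise_rate if pp else 0.0
        seqs.extend(_phased_reads(genome, ph, abundance, noise, rng))
    for hp_truth, hp_plan in zip(truth.hairpins, config.hairpin_plan):
        # mature/star sequences are strand-intrinsic (read off the transcript)
        seqs.extend([hp_truth.mature] * hp_plan.mature_reads)
        seqs.extend([hp_truth.star] * hp_plan.star_reads)
    n_bg = int(round(plan.depth * plan.background_rate))
    seqs.extend(_background_reads(genome, n_bg, rng))
    records = [
        _fastq_record(f"{plan.library_id}_r{i + 1}", s + config.adapter)
        for i, s in enumerate(seqs)
    ]
    if path is not None:
        with open(path, "w") as fh:
            fh.writelines(records)
    return records


def simulate_degradome(
    transcripts: Reference,
    plan: Sequence[DegradomePlan],
    seed: int = 0,
    background: int = 0,
    read_length: int = 20,
    path=None,
) -> List[str]:
    """Simulate a degradome (PARE) library.

    Each planted cleavage yields ``count`` tags whose 5' ends start
    exactly at the planted transcript position; ``background`` additional
    tags start uniformly along random transcripts.  Tags are
    ``read_length`` >= 20 nt.
    """
    if read_length < 20:
        raise ValueError("degradome reads must be >= 20 nt")
    rng = np.random.default_rng(seed)
    seqs: List[str] = []
    for d in plan:
        tlen = transcripts.length(d.transcript_id)
        if d.position < 1 or d.position + 20 - 1 > tlen:
            raise ValueError(
                f"cleavage position {d.position} out of range for "
                f"{d.transcript_id} (length {tlen})"
            )
        end = min(d.position + read_length - 1, tlen)
        s = transcripts.fetch(d.transcript_id, d.position, end)
        seqs.extend([s] * d.count)
    tids = sorted(transcripts.sequences)
    for _ in range(background):
        tid = tids[int(rng.integers(0, len(tids)))]
        tlen = transcripts.length(tid)
        pos = int(rng.integers(1, tlen - read_length + 2))
        seqs.append(transcripts.fetch(tid, pos, pos + read_length - 1))
    records = [_fastq_record(f"deg_r{i + 1}", s) for i, s in enumerate(seqs)]
    if path is not None:
        with open(path, "w") as fh:
            fh.writelines(records)
    return records
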