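"""End-to-end pipeline: simulate -> preprocess -> discover -> detect -> validate.

Every numeric threshold lives in :class:`PipelineConfig` with the
published defaults of the analysis this package implements (QC: > 5 nt
below Q25 drops a read; 18-30-nt inserts; <= 2 mismatches for homolog
search; 80/130/180-nt candidate flanks; 300-nt novel extension; >= 18
duplex-paired nt and energy < -40; m = 10 phase cycles; 100-bp window
extension; phase score > 5; corrected P < 0.05; >= 4 unique phasiRNAs;
2000-bp cluster gap; target caps 4 / "<4 + valid" / "0 or <=3 + valid";
RPTM filters 5/2/1).  Unknown config keys are rejected; every run
writes a manifest recording the seed, thresholds and input checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import pandas as pd
import yaml

from . import __version__
from .core_align import Reference, build_index, map_tags, read_fasta, write_fasta, alignments_to_tsv
from . import phas as phas_mod
from . import synthetic as sim_mod
from . import preprocess as pre_mod
from . import mirna as mirna_mod
from . import targets as tgt_mod
from . import expression as expr_mod


@dataclass
class PipelineConfig:
    seed: int = 0
    # read QC / trimming
    qc_min_quality: int = 25
    qc_max_low: int = 5
    insert_min: int = 18
    insert_max: int = 30
    adapter: str = ""
    # miRNA discovery
    homolog_max_mismatch: int = 2
    flanks: List[int] = field(default_factory=lambda: [80, 130, 180])
    novel_extension: int = 300
    min_duplex_paired: int = 18
    max_folding_energy: float = -40.0
    mature_only_max_mismatch: int = 2
    # PHAS detection
    phase_lengths: List[int] = field(default_factory=lambda: [21])
    m: int = 10
    window_pvalue: float = 0.05
    window_extend: int = 100
    fdr_method: str = "bh"
    score_threshold: float = 5.0
    q_threshold: float = 0.05
    min_unique_phasirnas: int = 4
    cluster_gap: int = 2000
    # target analysis
    gu_wobble_cost: float = 0.5
    conserved_target_max_mismatch: float = 4.0
    max_target_queries: int = 8
    # TAS3 discovery
    mir390: str = "AAGCTCAGGAGGGATAGCGCC"
    tasiarf_catalog: Dict[str, str] = field(default_factory=dict)
    tas3_flank: int = 250
    # expression
    rptm_min: float = 5.0
    rptm_min_libraries: int = 2
    rptm_min_sd: float = 1.0
    # simulation plan (passed through to the synthetic-data generator)
    simulation: Dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: Dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)


def _sim_config(config: PipelineConfig) -> sim_mod.SimulationConfig:
    s = dict(config.simulation)
    plans = {
        "phas_plan": sim_mod.PhasPlan,
        "hairpin_plan": sim_mod.HairpinPlan,
        "library_plan": sim_mod.LibraryPlan,
        "degradome_plan": sim_mod.DegradomePlan,
        "insert_plan": sim_mod.InsertPlan,
    }
    kwargs: Dict[str, Any] = {"seed": config.seed}
    for key, val in s.items():
        if key in plans:
            kwargs[key] = [plans[key](**entry) for entry in val]
        else:
            kwargs[key] = val
    return sim_mod.SimulationConfig(**kwargs)


_DEMO_TASIARF = "TTCTTGACCTTGTAAGACCCC"
_DEMO_MIR390 = "AAGCTCAGGAGGGATAGCGCC"
# revcomp(miR390) | 21-nt spacer | tasiARF | revcomp(miR390)
_DEMO_TAS3 = ("GGCGCTATCCCTCCTGAGCTT" + "GTACGTACGTACGTACGTACG"
              + _DEMO_TASIARF + "GGCGCTATCCCTCCTGAGCTT")


def default_config() -> PipelineConfig:
    """A self-contained demonstration configuration (simulated inputs)."""
    return PipelineConfig(
        tasiarf_catalog={"tasiARF_demo": _DEMO_TASIARF},
        mir390=_DEMO_MIR390,
        simulation={
            "n_chromosomes": 1,
            "chrom_length": 20_000,
            "phas_plan": [
                {"phase_length": 21, "cycles": 10, "start": 5_001,
                 "strand": "both", "abundance": 4, "noise_rate": 0.1},
                {"phase_length": 21, "cycles": 8, "start": 9_001,
                 "strand": "both", "abundance": 3, "noise_rate": 0.1},
            ],
            "hairpin_plan": [
                {"mature": "TGACAGAAGAGAGTGAGCACA", "flank": 30,
                 "start": 14_001, "mature_reads": 100, "star_reads": 8},
            ],
            "library_plan": [
                {"library_id": "leaf_1", "depth": 1000, "background_rate": 0.5},
                {"library_id": "leaf_2", "depth": 1000, "background_rate": 0.5},
                {"library_id": "root_1", "depth": 1000, "background_rate": 0.5},
            ],
            "insert_plan": [
                {"sequence": _DEMO_TAS3, "start": 17_001, "label": "TAS3"},
            ],
            # cleavage inside the first ladder: cis-validates its phasiRNAs
            "degradome_plan": [
                {"transcript_id": "Chr1", "position": 5_010, "count": 30},
            ],
        },
    )


class PipelineError(RuntimeError):
    pass


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing artifact {path.name}: run the '{stage}' stage first"
        )
    return path


def _manifest(outdir: Path, stage: str, config: PipelineConfig, inputs: List[Path]):
    entry = {
        "stage": stage,
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            k: v for k, v in config.to_dict().items() if k != "simulation"
        },
        "inputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()[:16]
            for p in inputs if p.exists()
        },
    }
    path = outdir / "manifest.json"
    log = json.loads(path.read_text()) if path.exists() else []
    log = [e for e in log if e["stage"] != stage] + [entry]
    path.write_text(json.dumps(log, indent=1))


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    sc = _sim_config(config)
    genome, truth = sim_mod.make_genome(sc)
    write_fasta(genome.sequences, outdir / "genome.fasta")
    truth.to_json(outdir / "truth.json")
    truth.to_gff3(outdir / "truth.gff3")
    libs = []
    for plan in sc.library_plan:
        sim_mod.simulate_srna_library(
            genome, truth, plan, sc, outdir / f"srna_{plan.library_id}.fastq"
        )
        libs.append(plan.library_id)
    if sc.degradome_plan:
        sim_mod.simulate_degradome(
            genome, sc.degradome_plan, seed=sc.seed + 17,
            path=outdir / "degradome.fastq",
        )
    (outdir / "libraries.json").write_text(json.dumps(libs))
    _manifest(outdir, "simulate", config, [outdir / "genome.fasta"])


def stage_preprocess(config: PipelineConfig, outdir: Path) -> None:
    libs = json.loads(_require(outdir / "libraries.json", "simulate").read_text())
    reads = []
    for lib in libs:
        fq = _require(outdir / f"srna_{lib}.fastq", "simulate")
        reads.extend(
            pre_mod.process_srna_fastq(
                str(fq), lib, adapter=config.adapter,
                min_q=config.qc_min_quality, max_low=config.qc_max_low,
                min_insert=config.insert_min, max_insert=config.insert_max,
            )
        )
    tags = pre_mod.collapse_unique(reads)
    pre_mod.write_collapsed_fasta(tags, outdir / "tags.fasta")
    pre_mod.write_count_matrix(tags, libs, outdir / "tag_counts.tsv")
    deg_fq = outdir / "degradome.fastq"
    if deg_fq.exists():
        deg = pre_mod.collapse_unique(pre_mod.process_degradome_fastq(str(deg_fq)))
        pre_mod.write_collapsed_fasta(deg, outdir / "degradome_tags.fasta")
    _manifest(outdir, "preprocess", config,
              [outdir / f"srna_{l}.fastq" for l in libs])


def _load_tags(outdir: Path) -> List[pre_mod.UniqueTag]:
    path = _require(outdir / "tag_counts.tsv", "preprocess")
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [
        pre_mod.UniqueTag(seq, {l: int(c) for l, c in row.items() if c > 0})
        for seq, row in df.iterrows()
    ]


def stage_phas(config: PipelineConfig, outdir: Path) -> None:
    genome = read_fasta(_require(outdir / "genome.fasta", "simulate"))
    tags = _load_tags(outdir)
    idx = build_index(genome)
    for p in config.phase_lengths:
        p_tags = [t for t in tags if len(t.sequence) == p]
        alignments = map_tags(p_tags, idx, max_mismatch=0)
        counts = {t.sequence: t.total for t in p_tags}
        track = phas_mod.scan(alignments, genome, p, config.m, counts)
        regions = phas_mod.merge_and_correct(
            track, config.window_pvalue, config.window_extend, config.fdr_method
        )
        loci = phas_mod.call_loci(
            track, regions, config.score_threshold, config.q_threshold,
            config.min_unique_phasirnas,
        )
        clusters = phas_mod.cluster_loci(loci, config.cluster_gap)
        phas_mod.loci_to_bed(loci, outdir / f"phas{p}.bed")
        phas_mod.loci_to_gff3(loci, outdir / f"phas{p}.gff3")
        phas_mod.loci_report(loci, outdir / f"phas{p}_report.tsv")
        phas_mod.phasirna_fasta(loci, outdir / f"phasirnas{p}.fasta")
        phas_mod.score_bedgraph(track, outdir / f"phase_score{p}.bedgraph")
        with open(outdir / f"phas{p}_clusters.tsv", "w") as fh:
            fh.write("cluster\tref_id\tstart\tend\tn_loci\tmembers\n")
            for i, c in enumerate(clusters, 1):
                rid, s, e = c.span
                fh.write(f"C{p}_{i}\t{rid}\t{s}\t{e}\t{len(c.loci)}\t"
                         + ",".join(l.name for l in c.loci) + "\n")
    _manifest(outdir, "phas", config, [outdir / "tag_counts.tsv"])


def stage_mirna(
    config: PipelineConfig, outdir: Path,
    known_matures: Optional[Dict[str, str]] = None,
) -> None:
    genome = read_fasta(_require(outdir / "genome.fasta", "simulate"))
    tags = _load_tags(outdir)
    annotations: List[mirna_mod.MirnaAnnotation] = []
    if known_matures:
        annotations.extend(
            mirna_mod.discover_conserved(
                known_matures, genome, max_mismatch=config.homolog_max_mismatch
            )
        )
        annotations.extend(
            mirna_mod.match_mature_only(
                tags, known_matures, config.mature_only_max_mismatch
            )
        )
    # novel discovery seeded at the most abundant tag loci
    idx = build_index(genome)
    top = [t for t in sorted(tags, key=lambda t: (-t.total, t.sequence))
           if 20 <= len(t.sequence) <= 22][:20]
    seen = set()
    # grade candidate windows from tight to the full extension: the tight
    # windows keep the baseline (maximum-pairing) folds anchored on the
    # local hairpin, the wide ones give a thermodynamic engine its context
    extensions = sorted(
        {10, 20, 30, 50}
        | {f for f in config.flanks if f <= config.novel_extension}
        | {config.novel_extension}
    )
    accepted_spans: List[tuple] = []
    for t in top:
        for aln in map_tags([t], idx, 0):
            key = (aln.ref_id, aln.start // 50)
            if key in seen:
                continue
            seen.add(key)
            if any(r == aln.ref_id and s <= aln.start and aln.end <= e
                   for r, s, e in accepted_spans):
                continue  # tag (e.g. the star) inside an annotated precursor
            # grade the candidate window outward until a hairpin passes
            for ext in extensions:
                s = max(1, aln.start - ext)
                e = min(genome.length(aln.ref_id), aln.end + ext)
                window = genome.fetch(aln.ref_id, s, e)
                if aln.strand == "-":
                    from .core_align import revcomp
                    window = revcomp(window)
                fr = mirna_mod.fold(window)
                cand = mirna_mod.HairpinCandidate(
                    fr.sequence, fr.structure, fr.energy, (1, len(t.sequence)),
                    ref_id=aln.ref_id, start=s, strand=aln.strand,
                )
                on_prec = []
                for t2 in tags:
                    pos = window.find(t2.sequence)
                    if pos >= 0:
                        on_prec.append((t2, pos + 1))
                ann, reason = mirna_mod.screen_novel_precursor(
                    cand, on_prec, config.min_duplex_paired,
                    config.max_folding_energy,
                )
                if ann is not None:
                    annotations.append(ann)
                    accepted_spans.append((ann.ref_id, ann.start, ann.end))
                    break
    named = mirna_mod.assign_names(annotations)
    with open(outdir / "mirna_annotations.tsv", "w") as fh:
        fh.write("name\tfamily\tstatus\tref_id\tstart\tend\tstrand\tmature\tstar\n")
        for a in named:
            fh.write(
                f"{a.name}\t{a.family}\t{a.status}\t{a.ref_id}\t{a.start}\t"
                f"{a.end}\t{a.strand}\t{a.mature}\t{a.star or ''}\n"
            )
    write_fasta(
        {a.name: a.mature for a in named}, outdir / "mature_mirnas.fasta"
    )
    stars = {f"{a.name}*": a.star for a in named if a.star}
    if stars:
        write_fasta(stars, outdir / "star_mirnas.fasta")
    precs = {a.name: a.precursor for a in named if a.precursor}
    if precs:
        write_fasta(precs, outdir / "precursors.fasta")
    mirna_mod.annotations_to_gff3(named, outdir / "mirna_annotations.gff3")
    _manifest(outdir, "mirna", config, [outdir / "tag_counts.tsv"])


def stage_tas3(config: PipelineConfig, outdir: Path) -> None:
    genome = read_fasta(_require(outdir / "genome.fasta", "simulate"))
    loci = tgt_mod.find_tas3(
        config.tasiarf_catalog, genome, config.mir390, config.tas3_flank
    ) if config.tasiarf_catalog else []
    tgt_mod.tas3_report(loci, outdir / "tas3_report.tsv")
    _manifest(outdir, "tas3", config, [outdir / "genome.fasta"])


def stage_targets(config: PipelineConfig, outdir: Path) -> None:
    """Degradome validation of discovered miRNAs and phasiRNAs.

    The simulated genome doubles as the transcript set: degradome tags
    are mapped sense-only and small-RNA queries are scanned against it.
    """
    from Bio import SeqIO

    genome = read_fasta(_require(outdir / "genome.fasta", "simulate"))
    deg_fa = _require(outdir / "degradome_tags.fasta", "preprocess")
    deg = []
    for rec in SeqIO.parse(str(deg_fa), "fasta"):
        count = int(rec.id.rsplit("_x", 1)[1])
        deg.append(pre_mod.UniqueTag(str(rec.seq), {"degradome": count}))
    idx = build_index(genome)
    deg_aln = [a for a in map_tags(deg, idx, 0) if a.strand == "+"]
    counts = {t.sequence: t.total for t in deg}
    tplots = {
        rid: tgt_mod.tplot_data(rid, genome.length(rid), deg_aln, counts)
        for rid in sorted(genome.sequences)
    }
    queries: List[tuple] = []  # (id, sequence, class)
    mat_fa = outdir / "mature_mirnas.fasta"
    if mat_fa.exists():
        status = {}
        for row in (outdir / "mirna_annotations.tsv").read_text().splitlines()[1:]:
            f = row.split("\t")
            status[f[0]] = "novel" if f[2] == "novel" else "conserved"
        for rec in SeqIO.parse(str(mat_fa), "fasta"):
            queries.append((rec.id, str(rec.seq), status.get(rec.id, "conserved")))
    for p in config.phase_lengths:
        fa = outdir / f"phasirnas{p}.fasta"
        if fa.exists():
            for rec in SeqIO.parse(str(fa), "fasta"):
                queries.append((rec.id, str(rec.seq), "phasiRNA"))
    queries = queries[: config.max_target_queries]
    sites: List[tgt_mod.TargetSite] = []
    for qid, seq, cls in queries:
        found = tgt_mod.find_sites(
            seq, genome, config.conserved_target_max_mismatch, query_id=qid,
            gu_cost=config.gu_wobble_cost,
        )
        for s in found:
            s.valid_reads = tgt_mod.count_valid_reads(s, tplots[s.transcript_id])
        sites.extend(tgt_mod.call_targets(found, cls))
    tgt_mod.targets_to_tsv(sites, outdir / "targets.tsv")
    for rid, vec in tplots.items():
        if vec.any():
            tgt_mod.tplot_to_tsv(rid, vec, outdir / f"tplot_{rid}.tsv")
    _manifest(outdir, "targets", config, [deg_fa])


def stage_expression(config: PipelineConfig, outdir: Path) -> None:
    path = _require(outdir / "tag_counts.tsv", "preprocess")
    counts = pd.read_csv(path, sep="\t", index_col=0)
    matrix = expr_mod.rptm(counts)
    matrix.to_csv(outdir / "rptm.tsv", sep="\t")
    try:
        selected = expr_mod.select_for_clustering(
            matrix, config.rptm_min, config.rptm_min_libraries, config.rptm_min_sd
        )
        if len(selected) >= 2:
            cc, _, newick = expr_mod.correlate_and_cluster(selected)
            cc.to_csv(outdir / "correlation.tsv", sep="\t")
            (outdir / "dendrogram.nwk").write_text(newick + "\n")
        if matrix.shape[1] >= 3:
            coords, frac = expr_mod.pca(matrix, config.rptm_min)
            coords.to_csv(outdir / "pca.tsv", sep="\t")
            pd.Series(frac, index=coords.columns, name="explained_fraction").to_csv(
                outdir / "pca_variance.tsv", sep="\t"
            )
    except ValueError as exc:
        print(f"[expression] skipped summaries: {exc}", file=sys.stderr)
    _manifest(outdir, "expression", config, [path])


def run(stage: str, config: PipelineConfig, outdir) -> None:
    """Run one pipeline stage (or 'all') into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = {
        "simulate": stage_simulate,
        "preprocess": stage_preprocess,
        "phas": stage_phas,
        "mirna": stage_mirna,
        "tas3": stage_tas3,
        "targets": stage_targets,
        "expression": stage_expression,
    }
    if stage == "all":
        for name in ("simulate", "preprocess", "phas", "mirna", "tas3",
                     "targets", "expression"):
            stages[name](config, outdir)
    elif stage in stages:
        stages[stage](config, outdir)
    else:
        raise ValueError(f"unknown stage {stage!r}")
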