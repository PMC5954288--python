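# Methods

This note records the models, numeric choices and their rationale, what
the synthetic data does and does not emulate, and the package's known
limitations.

## Coordinates, mapping and the register space

All coordinates are 1-based inclusive on the plus strand; BED output
converts to 0-based half-open at the export boundary only. Tag mapping
is ungapped (substitutions only), mirroring the short-tag aligners used
for sRNA data; all placements of a multi-mapping tag are retained and
each placement contributes to every window it falls in, which preserves
phased ladders at near-duplicated loci. Correctness of the mapper is
pinned to an exhaustive Hamming-scan oracle in the tests.

Phasing analysis works in a single combined register space: a
plus-strand p-nt read sits at its leftmost coordinate, a minus-strand
read at leftmost + 2, because the two strands of a phased duplex carry
2-nt 3' overhangs. This makes a minus-strand-only locus exactly
coordinate-identical to its plus-strand mirror, which the tests assert.

## The phasing statistics

For a window of length p·m starting at position s (m = 10 phases
throughout):

- **n** — distinct unique p-nt sRNA sequences with at least one
  effective position inside the window;
- **k** — distinct *occupied in-register positions* (effective position
  ≡ s mod p). The count of "phased unique sRNAs" is ambiguous between
  sequences and positions when several distinct sequences share one
  register position (e.g. the two strands of one duplex); counting
  positions keeps k ≤ m, the support of the hypergeometric model, so
  that is the default. Multiple tags at one phased position still all
  count toward the phased read totals P_i.

The P-value is the exact hypergeometric upper tail
Σ_{j=k..m} C((p−1)m, n−j)·C(m, j) / C(pm, n), evaluated with integer
combinatorics and converted to float once (cached per (n, k, m, p)).
The printed constants of the 21-nt case (20m, 21m) generalise by p for
24-nt phasing; that is the only reading consistent with applying one
method to both phase lengths. The tail at k = 0 is exactly 1 and the
enumerated pmf sums to exactly 1; the tests verify both and compare the
implementation against an independent factorial-based rational
enumeration to 1e-12 relative over all n ≤ 30, k ≤ 10, and against
scipy's hypergeometric survival function.

The phase score at positions with k ≥ 3 is
(k − 2)·ln(1 + 10·ΣP_i/(1 + ΣU_i)), with P_i/U_i counted in the m
cycles downstream of the position ("from the position"); positions with
k < 3 carry no score. The score is non-negative, increasing in ΣP and
k, decreasing in ΣU, and linear in k − 2.

Windows slide by 1 nt (the score is defined per position; merging
collapses the redundancy). Windows with P < 0.05 are extended ±100 bp
and merged transitively; a merged region inherits its minimum member
P-value — the region is treated as its best window — and
Benjamini–Hochberg correction runs across merged regions (a
Storey-style q-value is available as a config switch). A region becomes
a PHAS locus when max score > 5, corrected P < 0.05 and at least 4
unique phased tags lie at the anchor register (the register of the
maximal-score member window). Loci are named P{p}_{chrom}_{serial} by
position within each chromosome, phasiRNAs {locus}_siR{serial} by
position; same-chromosome, same-phase loci closer than 2,000 bp
(strictly) chain into clusters.

## Read processing

sRNA reads are dropped when more than 5 positions score below Q25; the
3' adapter is located at the leftmost exact 8-nt prefix match or a
full-adapter match with ≤ 1 mismatch (the original trimmer's algorithm
is unstated; this dialect is deterministic and testable), and inserts
of 18–30 nt are kept. Degradome reads are dropped when any of the first
20 positions scores below Q20 and are then truncated to exactly 20 nt.
Collapsing conserves per-library read counts exactly and is
order-independent. Category annotation (ncRNA/repeat/mRNA/genome)
assigns each tag the first matching reference in priority order, with
exact matching by default since the original database-mapping
stringency is unstated; repeat- and ncRNA-labelled tags are excluded
from miRNA and PHAS discovery.

## Folding and miRNA screening

The built-in folder maximises pairs + 2·(stacked pairs) over
no-multibranch (single stem-loop) nested structures with a minimum loop
of 3 — a quadratic DP. The stacking term makes long contiguous helices
dominate scattered isolated pairs, which a plain maximum-pairing
objective does not guarantee; without it a planted 19-bp stem can lose
to diffuse random pairing in wide windows. The reported energy is the
negated objective: a *pseudo-energy*, not a thermodynamic free energy.
The −40 kcal/mol gate is therefore meaningful only with a thermodynamic
engine (an RNAfold-executable adapter is provided and auto-detected) or
on synthetic constructs whose pseudo-energy is deliberately placed
relative to the gate, which is how the tests use it.

Novel-miRNA screening, in order: (1) ≥ 18 paired nucleotides, counted
over the mature:star duplex (mature positions paired to the opposite
arm) — the duplex reading of the criterion; a whole-hairpin mode is a
config switch; (2) folding energy below −40; (3) a second sequenced tag
on the opposite arm forming a duplex with 2-nt 3' overhangs on both
ends (±1 nt tolerance against the fold's pair table). Rejections report
the first failed criterion, and deleting the star reads flips an
otherwise-passing call — the property the tests pin.

Conserved screening checks the mature within the folded hairpin:
≤ 5 unpaired positions, ≤ 3 consecutive unpaired, and ≤ 2 bulged or
asymmetrically unpaired — a mature position counts as bulged when its
unpaired run exceeds the gap available on the opposing arm (symmetric
internal-loop positions count only toward the 5-mismatch cap); runs
touching the mature boundary have no flanking pair geometry and count
as mismatches only. A mature pairing with itself spans the terminal
loop and fails outright. Candidate windows use 80/130/180-nt flanks
extended up- or downstream of the mature hit; novel candidates grade a
window ladder (10–300 nt) outward and accept the first passing fold,
keeping the baseline folder anchored on the local hairpin.

Naming: matures identical to a prior catalog inherit the published
name; other conserved members get MIR{family}{letter} with letters in
genomic order; novel ones get sequential MIRN ids; collisions resolve
with a deterministic numeric suffix.

## Degradome analysis

Target sites are ungapped reverse-complement matches scored by
mismatch count with G:U wobble = 0.5 (configurable to 1.0; the original
analysis does not state its wobble cost). Site position j pairs query
position L − j + 1; a valid read starts at the transcript positions
pairing query positions 9–11. Class rules: conserved score ≤ 4; novel
≥ 1 valid read and score < 4; phasiRNA score 0 or ≥ 1 valid read and
score ≤ 3. PHAS-trigger search reuses the site scan on both strands of
the locus with the conserved rule (valid read or score < 4). TAS3 loci
require miR390 complementary sites on both sides of a mapped tasiARF
region within ±250 nt; all equal-score sites are reported (no
tie-breaking).

## Expression summaries

RPTM = count / library total × 1e7, with the denominator defaulting to
all sequencing tags of the library (a mapped-only switch exists).
Clustering keeps rows with ≥ 5 RPTM in ≥ 2 libraries and SD ≥ 1, takes
Pearson correlation of ln(x+1) between libraries, and clusters 1 − CC
with complete linkage; natural log and complete linkage are the
package's choices where the original base and linkage are unstated. PCA
uses rows with mean RPTM ≥ 5, ln(x+1), column centring and SVD; signs
of components are arbitrary and the tests compare sign-invariantly.

## Synthetic data: what it emulates, and what it does not

The generator plants phased ladders (both-strand duplex geometry with
the 2-nt offset, configurable per-cycle abundance and off-phase noise),
miRNA hairpins (mature + 8-nt unpairable loop + star with 2-nt 3'
overhangs), arbitrary sequence inserts (used for TAS3 constructs) and
degradome cleavage pileups, over uniform-random background with read
lengths drawn from {21: 0.35, 22: 0.10, 23: 0.10, 24: 0.45} to mimic
the 21/24-nt length peaks of plant libraries. Quality strings are
constant Q40: QC behaviour is tested on explicitly constructed degraded
reads, so simulator realism and QC testing stay decoupled. Not
emulated: sequencing errors, adapter-ligation bias, repeat-rich genome
structure, transcriptome-scale multi-mapping, or expression dispersion
across biological replicates — so passing tests demonstrate algorithmic
correctness under the stated geometry and noise, not performance on
real libraries.

Problem sizes in the test and acceptance runs are desk-scale by design:
12–20-kb chromosomes, hundreds to a few thousand reads per library, 20
simulation seeds per calibration experiment. The study-condition
defaults are 8–10 cycle ladders with per-cycle abundance 2–5, 10–20%
off-phase noise, and background at ~0.03 unique placements per nt.

## Null calibration and its limits

At the default background density, 20 background-only genomes yield
zero PHAS calls at the joint thresholds (score > 5, corrected P < 0.05,
≥ 4 unique phasiRNAs). This null is density-sensitive: at several-fold
higher unique-read densities, chance windows with 4–5 occupied
in-register positions occasionally clear all thresholds (inspection of
such calls shows genuine k = 4–5 coincidences among thousands of
windows, not implementation artifacts). Real analyses mitigate this by
removing repeat-derived reads before scanning and by the much larger
multiple-testing burden of a full genome; users scanning unusually
dense tag sets should raise the score threshold or the minimum unique
phasiRNA count.

## Degenerate inputs and numerical notes

The P-value cache is keyed on (n, k, m, p); n is clipped to p·m (the
window's position count) in the rare case more unique sequences than
positions occur. Zero-read windows are skipped. ΣP = 0 gives score 0
regardless of k. Zero-variance libraries are excluded from correlation
with a warning. FASTA/FASTQ parsing is strict 4-line FASTQ and 60-column
wrapped FASTA; sequences are uppercased on ingest and U is mapped to T
throughout.
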