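# phasikit

Plant genomes produce two classes of regulatory small RNAs that this
package detects and validates: microRNAs (miRNAs), excised from fold-back
precursors as miRNA/miRNA* duplexes with 2-nt 3' overhangs, and phased
secondary siRNAs (phasiRNAs), cut head-to-tail in exact 21- or 24-nt
increments from PHAS loci after a miRNA-guided cleavage sets the phase
register. `phasikit` implements the full analysis a small-RNA study needs
around these: read QC and collapsing, mismatch-tolerant tag mapping,
hairpin-based miRNA annotation, sliding-window PHAS detection, TAS3
discovery via the two-hit miR390 geometry, degradome (PARE) target
validation, and RPTM expression summaries — plus a synthetic-data
generator that plants all of these features into toy genomes so every
stage is testable without external downloads.

## The phasing statistics

A window of m = 10 phase cycles (210 nt for 21-nt phasing, 240 nt for
24-nt) slides over every genomic position. Minus-strand reads enter the
register space at their leftmost coordinate + 2 (the duplex overhang
correction). With *n* unique p-nt sRNAs in the window of which *k* occupy
distinct in-register positions, phasing significance is the
hypergeometric upper tail

    P = Σ_{j=k..m}  C((p−1)m, n−j) · C(m, j) / C(pm, n)

computed with exact integer combinatorics. Each position with k ≥ 3 also
receives a phase score

    score = (k − 2) · ln(1 + 10 · ΣP_i / (1 + ΣU_i))

where P_i and U_i are phased and non-phased read counts in cycle *i*.
Windows with P < 0.05 are extended 100 bp, merged, Benjamini–Hochberg
corrected across merged regions, and regions with max score > 5,
corrected P < 0.05 and ≥ 4 unique phasiRNAs are reported as PHAS loci
(named `P21_Chr6_2`-style; members `..._siR1`, `..._siR2`, …). Loci
closer than 2 kb form PHAS clusters.

miRNA annotation uses the community criteria: ≥ 18 paired nucleotides in
the mature:star duplex, folding energy below −40 kcal/mol, and a
sequenced miRNA* with 2-nt 3' overhangs for novel calls; MIRcheck-style
structural caps (≤ 5 unpaired, ≤ 2 bulged, ≤ 3 consecutive unpaired in
the mature) for conserved homologs. Degradome validation follows the
SeqTar conventions: ungapped complementarity with G:U wobbles scoring
0.5, and "valid reads" whose 5' ends pair query positions 9–11.

## Worked example

The bundled demonstration configuration simulates one 20-kb chromosome
with two planted 21-nt phasiRNA ladders, one miRNA hairpin, a TAS3
construct and a degradome cleavage, then runs the whole chain:

```sh
phasikit all --seed 4 --out demo_out
```

`demo_out/phas21_report.tsv` (both planted ladders at 5,001–5,210 and
9,001–9,168 are recovered inside the two calls, with their window
P-value, corrected P, and maximal phase score):

```text
name        ref_id  start  end    phase_length  pvalue    qvalue    max_score  n_phasirnas
P21_Chr1_1  Chr1    3893   5517   21            1.77e-07  1.77e-06  35.156     22
P21_Chr1_2  Chr1    5533   10374  21            4.62e-06  2.31e-05  26.706     22
```

`demo_out/mirna_annotations.tsv` — the planted hairpin is called as a
novel miRNA because both the mature and its star were "sequenced":

```text
name   family  status  ref_id  start  end    strand  mature                 star
MIRN1  5p      novel   Chr1    13981  14101  +       TGACAGAAGAGAGTGAGCACA  TGCTCACTCTCTTCTGTCACC
```

`demo_out/tas3_report.tsv` — the TAS3 construct is reported with both
miR390 complementary sites flanking the tasiRNA region:

```text
name   ref_id  start  end    strand  site5_start  site5_end  site3_start  site3_end  tasirna_start  tasirna_end
TAS3a  Chr1    16793  17313  +       17001        17021      17064        17084      17043          17063
```

and `demo_out/targets.tsv` shows the planted degradome cleavage
validating one of the extracted phasiRNAs (30 valid reads at its
complementary site). The statistics are also usable directly:

```pycon
>>> from phasikit import phasing_pvalue, phase_score
>>> phasing_pvalue(15, 10, 10, 21)   # 10 of 15 unique sRNAs in register
8.121278244454302e-14
>>> phase_score([4]*10, [1]*10, 10)  # deeply phased window
28.96558353358291
```

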