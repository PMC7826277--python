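# uvtfbs

Dissecting how UV-induced DNA damage and nucleotide excision repair (NER)
jointly shape the somatic mutation rate at transcription factor binding
sites (TFBS).

In UV-exposed genomes (melanoma being the canonical case), mutation rate is
elevated at many TFBS. Two mechanisms can produce this: the bound protein
can increase the *formation* of cyclobutane pyrimidine dimers (CPDs) at
specific dipyrimidines, and it can impair NER's access to lesions, slowing
their *removal*. `uvtfbs` implements the analysis that separates the two,
for researchers working with single-nucleotide CPD maps (Damage-seq-style,
fixed sequencing depth per timepoint), somatic mutation cohorts, ChIP-seq
peaks, JASPAR motifs and DHS open-chromatin calls — plus a fully synthetic
study generator with planted ground truth so the whole pipeline is testable
without any external data.

## The analysis

**Windows and regions.** Every active motif instance (a PWM match inside a
ChIP-seq peak that overlaps DHS in all supplied cell types) contributes one
2001-bp window centered on the motif, strand-inverted so all windows share
the motif orientation. Four concentric regions partition the window: motif
(21 bp), TFBS (101 bp, containing the motif), DHS flanks (200 bp per side)
and flanks (750 bp per side). Windows of one motif type are stacked and
per-position event counts summed. Motifs with fewer than 5000 active sites,
or a per-position median below 2 mutations, are excluded.

**Expected mutations.** The cohort is reduced to UV-dominated samples
(≥ 70% C>T counting G>A as C>T) and to C>T records. A trinucleotide (or
pentanucleotide) model assigns each pyrimidine-centered context *m* a
mutability

&nbsp;&nbsp;&nbsp;&nbsp;p(m) = (cohort mutations at genome occurrences of m) / (genome occurrences of m),

and the expected count at offset *i* of window *w* with m_w observed
mutations is the multinomial expectation
m_w · p(m_{w,i}) / Σ_j p(m_{w,j}), summed over windows — so the expected
profile conserves each window's observed total exactly. A seeded
Monte-Carlo mode implements the same randomization explicitly.

**Damage and repair.** CPD maps at a fixed depth per timepoint only carry
relative information. With rel_t(i) the position-normalized CPD fraction at
timepoint *t*, *relative repair* is rel_0(i) − rel_48(i) (zero-sum over the
window by construction); region-level repair is compared as
log2(mean repair in region / mean repair in flanks). Formation effects are
read against naked-DNA (deproteinized, irradiated in vitro) maps. Within
the motif, every dipyrimidine conserved in ≥ 50% of instances is compared
with dipyrimidines of the same type in the same tetranucleotide context
sampled from the window's own flanks (50 iterations, averaged). Late
damage for a 0h-only dataset is predicted by transferring the per-position
factor f_i = rel(ref48)_i / rel(ref0)_i learned from a two-timepoint
reference dataset. Significance uses chi-squared goodness of fit, G-tests
and 2×k chi-squared homogeneity with expected-count pooling.

## Worked example

Generate a synthetic study — 6000 active sites of one motif, a 136-sample
C>T-dominated cohort, and naked/0h/48h CPD maps in which the planted 48h
survival is 0.8 at the motif and 0.4 at the flanks (relative to the genomic
background) — and run everything:

```sh
uvmut-tfbs run-all --seed 1 --out results/demo
```

or from Python, reproducing the numbers below:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Key lines of the output (seed 1):

```json
"mutations_motif_log2_obs_exp":        {"value": 0.802, "n": 6000},
"cpd0_vs_naked_motif_log2":            {"value": -0.0005, "n": 6000},
"repair_ratio_motif_vs_flanks_log2":   {"value": -1.703, "n": 6000},
"within_motif_repair_pp_diff":         {"value": 39.90, "n": 14},
"spiked_site_percent_over_expected":   {"value": 102.8, "n": 800},
"pearson_r_mutations_vs_cpd0h":        {"value": -0.032, "n": 10},
"pearson_r_mutations_vs_cpd48h_predicted": {"value": 0.901, "n": 10}
```

Reading these: the motif shows ~2^0.8 ≈ 1.7× more mutations than the
trinucleotide background predicts, yet **no** excess CPD formation over
naked DNA (log2 ≈ 0) — the mutation excess is driven by repair. The motif
is repaired at well under half the flanks' rate (log2 ratio −1.7), and the
within-motif analysis quantifies it as ~+40 percentage points more damage
surviving at motif dipyrimidines than at matched flank dipyrimidines —
exactly the planted 0.8 vs 0.4 survival contrast. A separate study with a
2.0× formation spike at a single motif dipyrimidine reads out at ~+100%
over its tetranucleotide-matched expectation. Finally, across a 10-motif
panel, mutation rate correlates with damage *surviving at 48 h* (r ≈ 0.9)
but not with initial damage — the repair-centric mechanism the pipeline is
built to expose.

## Layout

| module | role |
| --- | --- |
| `uvtfbs.io_formats` | FASTA/BED/JASPAR/mutation-TSV/VCF/CPD-map readers & writers; 0-based half-open everywhere except the 1-based mutations TSV |
| `uvtfbs.tfbs_catalog` | PWM construction, peak scanning, DHS activity calls, bedtools-style jaccard |
| `uvtfbs.window_stacking` | 2001-bp oriented windows, region masks, event mapping, inclusion filters |
| `uvtfbs.mutation_expectation` | cohort filter, k-mer mutability model, analytic + Monte-Carlo expected profiles |
| `uvtfbs.damage_repair` | relative repair, naked-DNA comparison, 48h prediction, damage–mutation correlation |
| `uvtfbs.within_motif` | conserved dipyrimidines, tetranucleotide-matched flank sampling, repair percentage-point differences |
| `uvtfbs.region_stats` | chi-squared/G tests with pooling, region summaries, BH-FDR column |
| `uvtfbs.synthetic_data` | the synthetic study generator with planted, recorded truth |
| `uvtfbs.pipeline`, `uvtfbs.cli` | orchestration, run manifest, `uvmut-tfbs` command line |

See `docs/methods.md` for the model assumptions, parameter defaults, and
the design decisions behind the generator and the statistics.
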