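# Methods

This note documents the models, parameter choices and numerical decisions
behind `uvtfbs`, in the order the pipeline runs them.

## Coordinates and containers

All internal coordinates are 0-based, half-open (BED-native); the mutations
TSV is the single 1-based boundary, converted once on read and write. Bulk
event sets (mutations, CPD records) are pandas DataFrames; per-record
dataclasses exist at the io boundary for validation. A CPD record stores
`pos5` = the **leftmost** genomic base of the dipyrimidine; on the `-`
strand the reference therefore shows a purine pair. CPD records failing the
dipyrimidine check against a supplied genome are dropped (not errored), and
the drop count is exposed — this tolerates reference-version mismatches.
N-containing contexts are excluded from all counting, never imputed.

## Binding-site catalog

PWMs are standard log2-odds matrices,
`log2(((c_bi + λ·q_b)/(Σ_b c_bi + λ)) / q_b)` with pseudocount λ = 0.8
split by the background q (uniform by default; the genome composition can
be supplied). Scanning reports sites scoring at least a fraction (default
0.85) of the PWM maximum on either strand. A fraction-of-max threshold is
used instead of a p-value threshold because it is reproducible without a
background-distribution algorithm; a p-value mode is out of scope.
Overlapping hits within one peak are resolved best-score-first (ties:
leftmost start, then + strand); non-overlapping hits in one peak are all
kept. The center of a motif of length L is `start + floor(L/2)`, giving a
deterministic single base for window alignment also for even L.

A site is *active* iff it overlaps (≥ 1 bp) at least one DHS interval in
**every** supplied DHS set (the study design uses two cell types, so that
damage maps and mutation cohorts from different tissues address the same
bound sites). Overlap between active site sets of two TFs uses bedtools-
jaccard semantics on center ± 50 bp windows after per-set merging.

## Window stacking

Each active site contributes a 2001-bp window (1000 nt per side of the
motif center), strand-inverted for minus-strand motifs so offsets are
motif-oriented. Windows crossing chromosome ends are discarded (counted),
not truncated, keeping all 2001 columns at equal depth. Events falling in
two overlapping windows count once per window (stack-then-sum semantics).
CPD records map their `pos5` exactly like a point event; on inverted
windows the mapped offset is the mirrored coordinate of that base. Region
masks: motif |offset| ≤ 10; TFBS |offset| ≤ 50 (21 + 80 positions; region
summaries for "TFBS" include the motif); DHS flanks 50 < |offset| ≤ 250;
flanks |offset| > 250. Motifs are kept iff ≥ 5000 windows stacked **and**
the median of the 2001 per-position mutation counts is ≥ 2.

## Expected mutation rate

The cohort filter keeps samples with ≥ 70% C>T (G>A counted as C>T on the
opposite strand) and then drops non-C>T records. The k-mer model (k = 3
default, k = 5 switchable) counts each genomic position once under its
pyrimidine-centered representation — purine-centered positions contribute
their reverse complement — making the model strand-symmetric by
construction; k-mer abundances are pyrimidine-strand occurrences (this
convention is documented rather than configurable twice over: reverse-
complement symmetry makes double-strand counting a global factor 2 that
cancels in every expectation).

The expected profile conditions on each window's observed mutation total:
`E[i | w] = m_w · p_wi / Σ_j p_wj`, the expectation of multinomial
redistribution. This makes per-window conservation exact and the estimator
deterministic; the seeded Monte-Carlo mode (`expected_profile_mc`) verifies
the equivalence by explicit resampling. Purine positions score the
mutability of their opposite-strand context (their observed G>A records
are in the counts, so their expectation must not be zero); positions whose
context runs past the window edge (the outermost (k−1)/2 offsets) or
contains N get mutability 0 — at 2001 bp this is negligible and keeps the
computation window-local. The observed mutation rate at inactive TFBS of
the same motif, rescaled to the active total, is available as an
alternative background with identical interfaces.

## Relative repair

Fixed-depth damage maps destroy absolute lesion counts, so only the
*redistribution* of damage between timepoints is identifiable. Two related
quantities are computed and labelled separately:

* profile subtraction `repair(i) = rel0(i) − rel48(i)` for per-position
  profiles (window scope: both tracks normalized to the window total, so
  Σ repair = 0 exactly; genome scope: normalized by genome-wide totals);
* percent change `100·(rel48 − rel0)/rel0` for within-motif comparisons.

Region-level repair is summarized as log2 of **means** (not sums) of
per-position repair, so regions of different widths are comparable. With
window-scope normalization any region whose damage survival exceeds the
window-weighted mean has negative mean "repair" (the flanks dominate the
window weights), which makes the motif/flanks log-ratio undefined whenever
the motif is the least-repaired region — i.e. in the typical case. Region
repair ratios therefore use genome-scope normalization, where the heavily
dominant genomic background anchors the scale and all regions with any net
repair stay positive. Negative per-position repair (apparent CPD increase)
is retained, never clipped. The significance call for differential repair
between a region and the reference is a 2-cell G-test of the 48h counts
[region, reference] against the 0h-proportional expectation.

## 48h prediction

The per-position transformation `f_i = rel(ref48)_i / rel(ref0)_i` learned
on a two-timepoint reference dataset is applied to an independent 0h map
and renormalized. Zero-count positions are tamed by (i) a pseudocount
(default 0.5) applied to the reference tracks after rescaling them to mean
1 — equivalent to add-half when the mean per-position count is 1, and
exactly scale-invariant in all three inputs — and (ii) a 5-bp moving
average of f before application. Setting `pseudocount=0, smooth_window=1`
recovers the exact identities (target = ref ⇒ prediction = rel(ref48);
ref48 = ref0 ⇒ prediction = rel(target0)).

## Within-motif analysis

A dipyrimidine site is reported at motif offset j, orientation-relative
strand s, when one specific type (TT/TC/CT/CC, read 5'→3' on s) occurs at
(j, j+1) in at least 50% of the motif's windows. Both strands are assessed
because CPDs are strand-specific; the specific-type requirement (rather
than "any pyrimidine pair") is what makes tetranucleotide matching
well-defined. The null: for each iteration and each carrier window, one
flank position (|offset| > 250, pair fully in the flanks, either strand)
carrying the same tetranucleotide (5' base + dipyrimidine + 3' base) is
drawn uniformly; windows without a match are skipped and counted. Event
counts at the drawn positions are summed per iteration; the expectation is
the mean over 50 iterations, and the same drawn positions are reused for
every track of a site (0h and 48h CPDs in particular), which removes
sampling noise from their contrast. Observed mutation counts sum both
bases of the pair (strandless); CPD counts use the stranded record at the
pair's leftmost base.

Within-motif repair normalizes 0h and 48h counts by the genome-wide map
totals, computes the percent change at the site and at the sampled flank
null, and reports the difference in percentage points. Site-level
significance is the Poisson deviance G-test
`G = 2(O·ln(O/E) − (O − E))`, df = 1, treating the sampled expectation as
the Poisson mean.

## Statistics

Goodness of fit uses Pearson's X² and the G statistic with expected counts
scaled to the observed total, deterministic left-to-right pooling of cells
until every expected count is ≥ 5, and df = cells − 1; timepoint
comparisons use the 2×k contingency chi-squared with the analogous
pooling. The G-test is the default for region deviation calls and the
chi-squared for timepoint homogeneity. Region-level deviation is tested on
2 cells — [region, rest of window] observed vs expected — because a
per-position test inside the region would test the *shape* of the profile,
not its level. P-values are reported raw (the P < 0.05 convention); a
Benjamini–Hochberg column is emitted alongside for users who want it.

Whenever a check runs across all 2001 offsets simultaneously (Monte-Carlo
vs analytic expectation; null repair flatness), per-offset z-scores are
compared against the family-wise 3σ threshold, z* = Φ⁻¹(1 − α/(2·2001))
≈ 4.83 at α = 0.0027 — a raw per-offset 3σ bound would be exceeded
somewhere by chance in essentially every run.

Note that with very deep counts the goodness-of-fit tests treat the
expected track as exact; when the expectation itself is a second sampled
map (naked DNA), tiny relative deviations become formally significant.
Effect sizes (log2 ratios) are the quantities to interpret at depth.

## The synthetic study generator

The generator emulates the statistical structure of the real inputs — not
their biology — and its defaults are the package's study conditions:

* **Genome/sites**: i.i.d. genome (GC 0.5), 6000 active + 600 inactive
  instances of one 21-bp motif on a grid with 2101-bp spacing (windows
  disjoint), random strands. Instances are drawn from a sharp PFM (97%
  consensus per column) with rejection until they score ≥ 0.9 of the PWM
  maximum — bound sites are high-affinity matches, and this guarantees the
  catalog recovers the planted truth at the 0.85 scan threshold. Active
  sites get DHS cover in both synthetic cell types; all sites get peaks.
* **Damage law**: per-dipyrimidine 0h intensity = type baseline
  (TT 1.0, TC 0.35, CT 0.25, CC 0.10 — TT lesions dominate CPD formation)
  × an optional formation multiplier at active-site motifs (a Tryptophan-
  cluster-like spike targets one oriented dipyrimidine); naked intensity =
  baseline only; 48h intensity = 0h × survival. Survival fractions are
  defined **relative to the genomic background** (background ≡ 1.0):
  motif 0.8, TFBS 0.7, DHS flanks 0.5, flanks 0.4 around active sites.
  Because fixed-depth maps only identify relative repair, the recoverable
  within-motif contrast is 100·(s_motif − s_flank)/s̄ with s̄ the
  intensity-weighted genome-mean survival; anchoring the background at 1
  and giving it 249× the window mass (one TF's 6000×2001-bp footprint is
  ~0.4% of a mammalian genome) makes s̄ ≈ 0.998, so the planted contrast
  (+40 pp) is directly recoverable. The background mass rides on a compact
  carrier chromosome (`chrBg`, 2 Mb of real sequence, genuine dipyrimidine
  positions, exact totals) instead of materializing gigabases.
* **Maps**: each timepoint is an independent multinomial draw of the
  *same* total read count over all dipyrimidine cells — absolute repair
  information is deliberately destroyed, as in fixed-depth Damage-seq.
* **Cohort**: 136 samples × 30,000 mutations at 90% C>T. UV records are
  placed at cytosines of C-containing dipyrimidine cells with probability
  ∝ damage surviving at 48 h (switchable to 0h damage as a negative
  control); minus-strand lesions are recorded as G>A. The remainder is
  uniform non-C>T noise. Mutation burden and C>T dominance match deeply
  UV-exposed melanoma genomes.
* Every output is a pure function of (params, seed).

What the generator does **not** emulate: chromatin covariates (replication
timing, nucleosomes, expression), mutational-signature mixtures beyond a
single C>T process, antibody bias of damage maps, soft/degenerate real
PFMs, overlapping or clustered motifs, and read-level sequencing artifacts.
Passing tests therefore demonstrate that the estimators recover planted
damage/repair/mutation structure under the stated sampling model — not
that real data are free of those confounders.

## Problem sizes in the test and acceptance runs

Chosen as the package's own verification scales: the flagship planted-
repair run uses the full default study (6000 sites, 10⁴ reads/window); the
Monte-Carlo oracle uses a 500-window stack with 10⁴ randomizations; the
damage-spike screen runs 20 seeds of an 800-site study at 2×10³
reads/window; the damage-vs-mutation panel runs 20 replicates of 10 motifs
× 150 sites; calibration uses 10⁴ null replicates per test. Determinism is
checked by running the full pipeline twice at 5000 sites and comparing
outputs byte for byte.

## Known limitations

* Absolute repair rates are out of reach by design (fixed-depth maps);
  every repair quantity is relative, and the 48h prediction inherits the
  under-specification of the transformation (pseudocount and smoothing are
  exposed and documented rather than hidden).
* The fraction-of-max PWM threshold is not calibrated to a match p-value;
  results sensitive to the threshold cannot be compared bit-exactly with
  p-value-thresholded scans.
* The trinucleotide background adjusts for sequence composition only;
  covariate-adjusted backgrounds (expression, replication timing) and
  signature decomposition are non-goals.
* Region p-values are reported uncorrected (with a BH column); at deep
  CPD counts, formal significance against a sampled expectation is nearly
  guaranteed and effect sizes should carry the interpretation.
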