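# Methods

This note documents the models, parameter choices, numerical conventions
and limitations of medipkit. Nothing here reports an empirical result the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and intervals

All positional arithmetic is 0-based, half-open (`[start, end)`), the BED
convention; GFF3 is converted on I/O. On the `−` strand the TSS is the last
covered base (`end − 1`) and the TTS is `start`, so promoter and gene-body
windows measured "along the gene" mirror exactly under genome reflection —
a property the test suite checks directly.

## Region definitions

- **Promoter**: −700/+200 bp around the TSS, strand-aware, clipped at the
  contig start with a logged warning (clipping is a data property, not an
  error).
- **Gene body**: TSS+2000 bp to the TTS, only for genes *strictly* longer
  than 3000 bp ("longer than" is read as a strict inequality; a 3000 bp
  gene has no body).
- **Candidate window**: a separate ±500 bp TSS window exists in the
  configuration (`DmrConfig.candidate_window`) for candidate reporting;
  it is deliberately distinct from the scoring window, since both extents
  are conventional in this analysis style and are not interchangeable.

## CpG-island detection

Criteria: length ≥ 200 bp, GC ≥ 0.50, Gardiner–Garden obs/exp =
(N_CpG/(N_C·N_G))·L ≥ 0.6, all thresholds inclusive (minimum-qualifying
reading); obs/exp is defined as 0 when a sequence lacks C or G; windows
containing N never qualify.

**Definition of an island.** Let Q be the set of *all* substrings of
length ≥ 200 satisfying the three criteria. Islands are the maximal
intervals of ∪Q; a maximal interval that itself fails the criteria (unions
of qualifying substrings need not qualify — e.g. two windows joined across
a GC-rich core can dip below 50 % GC overall) is refined into its longest
qualifying substrings, leftmost on ties, recursing into the flanks. Every
reported island therefore re-passes all three criteria exactly. This
substring-union definition was chosen over a fixed 200 bp sliding window
because a qualifying long substring need not contain any qualifying 200 bp
window (e.g. GC 75/0/75 across three 100 bp thirds), so the two
definitions genuinely differ; the exhaustive-substring definition is the
one an enumeration oracle can verify, and the test suite checks exact
equivalence against an independently coded brute-force oracle on seeded
random sequences.

**Complexity.** The implementation computes, per start position, the
maximal qualifying end via prefix-sum vectorization (O(L) per start).
Sequences longer than 4096 bp are scanned in 4096 bp tiles stepped by
2048 bp, then merged and re-qualified; this is exact for islands spanning
≤ 2048 bp, far above anything the simulations embed, and is the stated
approximation for genome-scale scans.

**Behavioral caveat.** Because qualification is a property of whole
substrings, an island can extend from a CpG-rich core into moderately
GC-rich flanking sequence until the GC constraint binds (reported islands
often sit at exactly 50.0 % GC for this reason). Dilution with AT sequence
*raises* obs/exp (L grows, N_C·N_G fixed) while lowering GC — a known
property of the Gardiner–Garden statistic that the boundary tests take
into account: the obs/exp detection boundary can only be resolved to about
±0.09 (one CpG per 200 bp window), so the no-detection side of that sweep
is asserted up to ratio 0.51.

Integer cross-multiplied comparisons (`n_gc ≥ min_gc·L`,
`n_cpg·L ≥ min_oe·n_c·n_g`) avoid float-division edge cases at the
thresholds.

## MeDIP scoring

Reads are extended to 250 bp from their 5′ end (`+`: keep start; `−`: keep
end; clipped at 0). A region's score counts extended reads overlapping by
≥ 1 bp — the simplest monotone overlap rule, adopted because no minimum
overlap or midpoint rule is specified in this analysis style. Duplicates
are retained. Status thresholds 9.48/50.62 reads·kb⁻¹ are treated as fixed
configuration (their provenance is a fit to real data not reproducible
here); "between" is read as the closed interval so the three classes
partition [0, ∞). Scores are unnormalized by default, since the thresholds
are absolute; a reads-per-million option exists because cross-sample
comparison otherwise conflates depth with methylation, and the pipeline
logs when group depths differ by more than 10 %.

## DMR calling

The underlying publication style reports "P < 0.05 and fold change > 1.5"
without naming the test, so two are provided and neither is claimed to
replicate the original: the default Welch's *t* on log₂(score + 0.5)
(robust at n = 4; the log stabilizes the count-like variance), and a
two-sided permutation test on the log-score mean difference — exact
enumeration of all label splits when there are ≤ C(16,8) = 12,870 of them,
otherwise seeded Monte-Carlo with the +1 correction. Fold change uses
pseudocounted means ((m_trn+0.5)/(m_sed+0.5)) folded to ≥ 1 with the
direction recorded separately, so one threshold serves hyper- and
hypomethylation. The reliability filter "MeDIP score > 10" is applied to
the *larger* group mean (the natural reading when one group may have lost
methylation); a both-group-mean variant would be stricter and is noted
here as the alternative. No multiple-testing correction is applied by
default (the cascade filters on raw p); Benjamini–Hochberg q-values are
available behind `DmrConfig(adjust=True)`.

## Enrichment and motifs

GSEA uses the classic weighted Kolmogorov–Smirnov running sum: hits add
|metric|^p normalized over set members (default p = 1; p = 0 for the
analytically checkable cases), misses subtract 1/(N−N_hit); the ES is the
extremum of largest magnitude, with the positive extremum winning an exact
tie (a convention both the implementation and the test oracle encode).
Significance is by gene-label permutation — with four animals per group a
sample-permutation null is impossible, and this competitive null is the
stated limitation — with p = (1+#{|ES₀|≥|ES|})/(1+n_perm) and
NES = ES / mean|ES₀| over same-signed nulls. The default ranking metric is
the promoter signed log₂ fold change. A hypergeometric over-representation
test covers unranked inputs.

PWMs are read/written in JASPAR text (via Bio.motifs). Log-odds use a
pseudocount of 0.8 distributed by the background (JASPAR/MEME convention);
scanning covers both strands (the reverse strand scores the reverse
complement), N-containing windows score −∞, and the fraction-of-max
threshold t maps to min + t·(max−min) of achievable scores (default 0.8;
0.95 for planted-consensus recovery, where one mismatch of the bundled
synthetic NBRE-like matrix costs ~5 bits against a ~2 bit margin). The
bundled `NBRE_synthetic` matrix is an invented nuclear-receptor half-site
(consensus AAAGGTCA) for testing and demonstration, not a database matrix.

## Pyrosequencing

Percent methylation is 100·C/(C+T) per CpG. Non-CpG cytosines are the
conversion control; the default minimum efficiency is 0.95 (the control is
standard, the cut-off is this package's choice), and failing samples are
excluded from the tests. The two-way ANOVA (condition × CpG site with
interaction) uses balanced closed-form sums of squares and rejects
unbalanced tables explicitly; constant data reports p = 1 by convention.
Whether the original analysis treated CpG site as a repeated measure
within animal is unknown; the fixed-effects balanced ANOVA is implemented
and this is a noted deviation risk. Per-site exercise-effect tests are
unadjusted pooled-variance two-sample *t*-tests (matching per-site
significance stars as conventionally drawn); percentages are analyzed
untransformed by default.

## Synthetic data

The generator emulates the two-group endurance-training design: default
n = 4 per group (group sizes for sequencing are not stated in the source
design, so this is configurable), ~10,000 reads per sample (Poisson),
10 % of promoters planted as DMRs at a 3-fold multiplicative shift, half
hyper / half hypo.

- **Background sequence**: i.i.d. bases with per-kb GC blocks ~
  N(0.40, 0.04) clipped to [0.30, 0.47], then 75 % of CpG dinucleotides
  mutated G→A — reproducing the CpG depletion and GC heterogeneity of
  mammalian genomes. The GC cap sits below the island criterion so
  detected islands stay local to planted CpG-rich segments.
- **Genes**: non-overlapping, random strands, lengths uniform 1.2–4 kb
  (so both body-bearing and body-less genes occur), spaced ≥ 1.6 kb so two
  facing promoters always fit between neighbors.
- **Promoter CpG enrichment**: every TSS receives a 250 bp CpG-enriched
  segment (GC 0.55, planted CpGs every ~10 bp), reflecting that most
  mammalian promoters are CpG-island promoters; these segments are *not*
  part of the island truth list, which contains only the intergenic
  islands controlled by `island_density` (default 10 per 100 kb; GC 0.65,
  250–600 bp, verified against the criteria at construction).
- **Methylation levels** (sedentary, uniform): promoters 0.10–0.30
  (CpG-island promoters are lowly methylated), gene bodies 0.50–0.80,
  intergenic islands 0.05–0.20, 1 kb background bins 0.40–0.70. Planted
  hyper promoters multiply by the effect (capped at 0.95); hypo divide.
- **Reads**: per sample, total ~ Poisson(depth); a `background_rate`
  fraction (default 0.1) is uniform over the genome, the rest multinomial
  over regions with weight level × CpG count — the simplest model making
  MeDIP-score proportional to methylation. Read start uniform in the
  region, length uniform 36–150 bp (the sequenced end of a sonicated
  fragment; the 250 bp extension downstream exists precisely because reads
  are shorter than fragments), strand uniform.
- **Pyro counts**: nC ~ Binomial(depth, site level) at CpGs — conversion
  at assayed CpGs is treated as complete, with efficiency entering only
  through the non-CpG controls (unconverted ~ Binomial(depth, 1−eff)).
  Site levels are the regional truth plus a per-site offset (sd 0.03,
  shared across samples); the offset can be disabled for estimator
  checks.
- **RNG discipline**: one root seed; per-sample streams keyed by
  (seed, group, sample index), so adding samples never reshuffles earlier
  ones; genome, methylome and pyro stages use distinct fixed stream keys.

**What the generator does not emulate**: fragment-size selection biases,
CpG-density-dependent IP efficiency saturation, PCR duplicates, mappability
and repeats, diploidy, or copy-number variation. Passing tests therefore
demonstrate the correctness of the analysis chain under a clean abundance
model, not robustness to those real-data artifacts.

## Problem sizes used in verification

- Planted-DMR recovery runs 10 seeds of 200 genes on a 900 kb genome
  (200 non-overlapping genes with 900 bp promoters and 1.6 kb spacing
  need ~820 kb, so a 50 kb genome cannot host them), depth 10,000,
  n = 4/group: pooled sensitivity ≥ 0.8 and observed FDR ≤ 0.25 are the
  asserted bounds.
- The null calibration (nothing planted, exact permutation) uses
  n = 5 per group: with C(10,5) = 252 label splits and two-sided symmetry
  the attainable significance levels near 0.05 include 12/252 ≈ 0.0476,
  so the rejection rate is informative. At n = 4, C(8,4) = 70 splits make
  the smallest attainable two-sided level 2/70 ≈ 0.029 — *below* 0.05 —
  so a rejection-rate check at the 0.05 level would measure discreteness,
  not calibration. This is a property of exact permutation tests, decided
  analytically; n = 4 remains the default everywhere else.
- Island oracle equivalence: 50 seeded random sequences of 300–3000 bp,
  GC 0.40–0.60, against a naive incremental-counting oracle.
- Welch type-I error, GSEA null uniformity (KS), and per-CpG test type-I
  error are checked by seeded simulation at the sizes recorded in the
  tests.

## Known limitations

- The island definition can report generous boundaries in GC-rich
  neighborhoods (see above); it matches its own specification exactly but
  not, e.g., UCSC island tracks.
- Genome-scale island scanning is exact only for islands ≤ 2048 bp.
- The enrichment null is competitive (gene permutation), not
  self-contained (sample permutation).
- The DMR test at n = 4 has limited power for planted effects below
  ~2-fold at the default depth; the permutation variant's p-values are
  discrete in steps of 2/70.
- `score_matrix` holds reads in memory as Python objects; the intended
  scale is simulation-sized (≤ ~10⁶ reads), not production sequencing.
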