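# Methods

`goosepan` implements the analysis chain of a bird (goose) pan-genome
presence–absence variation (PAV) study as a reusable, tested library plus a
set of narrative analysis drivers. Every stage consumes plain-text inputs
(FASTA, TSV, BED, VCF) and every stage can be exercised on synthetic data
with known ground truth, so correctness is established without any
sequencing download. This note describes the models and procedures, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## Non-reference contig triage (`pangenome`)

Contigs assembled from reads that fail to map to a reference are triaged
against precomputed alignment records (BLAST outfmt-6, PAF, or the native
block TSV). The rules, applied in order:

1. **Length filter** — contigs shorter than 500 bp are dropped (length
   ≥ 500 retained).
2. **Anchoring** — an alignment block is a *reliable region* iff its contig
   span is strictly longer than 300 bp **and** its identity is strictly
   above 0.90. A contig with no reliable region is *fully unaligned* and
   enters the candidate set whole.
3. **Partial extraction** — for anchored contigs, the maximal intervals of
   the contig **not** covered by any reliable region are computed by
   interval complement; intervals strictly longer than 500 bp become
   candidate sequences. Low-identity alignment regions are never reliable
   and therefore fall into the complement; this single interval-algebra
   reading replaces any per-alignment bookkeeping and is the one genuinely
   open design choice in this stage.
4. **Redundancy removal** — greedy longest-first clustering (the CD-HIT
   convention, ties broken by lexicographic id): a candidate is discarded
   iff hits at identity ≥ 0.90 to already-retained candidates cover ≥ 90%
   of its length, with hit intervals unioned (never double-counted).
5. **Decontamination** — candidates whose source sequence carries a
   taxonomy label in {archaea, viruses, bacteria, fungi, Viridiplantae,
   microbial} are removed; unlabeled sequences are kept (absence of
   evidence keeps the sequence).

Throughout the package, thresholds phrased as "larger than" / "over" /
"more than" are strict and "at least" is inclusive, applied consistently.
Coordinates are 0-based half-open internally; 1-based formats are
converted on read/write. A gene is flagged as a *PAV gene* when strictly
more than 80% of its span lies inside retained non-reference intervals.

## Coverage-based presence calling (`pav_call`)

A gene is *present* in a sample iff at least `min_cov` reads (per-base
depth proxy) cover at least a `lost_cutoff` fraction of the union of its
exon bases; defaults `min_cov = 2`, `lost_cutoff = 0.2`. Both comparisons
are inclusive, and the exon union (not the double-counted sum) is the
denominator. The call is monotone: adding depth can only flip
absent → present; raising the cutoff can only flip present → absent;
`lost_cutoff = 0` makes every gene with exons present. Promoter presence
uses the same criterion on strand-aware upstream windows (0–1, 1–2 and
2–3 kb from the gene span start on the plus strand, mirrored past the span
end on the minus strand; truncated at chromosome bounds, empty windows
dropped — strand handling is a package choice, stated here because
upstream conventions differ between tools).

Depth tracks are per-sample TSVs (chrom, 1-based position, depth);
positions absent from a track are depth 0. Tracks can be streamed, so a
cohort never needs to be memory-resident.

## Occupancy classification and saturation (`pav_classify`)

With k = presence count and n = accessions, the four classes form a
partition: core (k = n), softcore (0.99 ≤ k/n < 1), shell
(0.01 ≤ k/n < 0.99), cloud (0 < k/n < 0.01); k = 0 is the `absent`
sentinel, excluded from pan-gene totals. Published class descriptions
overlap at their edges; the partition above keeps "core = present in all"
and makes the four counts disjoint and summable. Boundary comparisons are
exact integer arithmetic (`100·k` vs `99·n`), never floating point, and are
verified against a rational-number oracle for every (k, n) with n ≤ 300.

The saturation curve subsamples accessions without replacement, `reps`
(default 100) replicates per size. Subsampling is *nested*: each replicate
draws one permutation of the accessions and evaluates all sizes on its
prefixes. Each prefix is still a uniform without-replacement sample of its
size, and nesting makes pan non-decreasing and core non-increasing in size
*within every replicate* by set monotonicity — so the per-size means are
exactly monotone rather than monotone only in expectation.

## Frequency differentials and association (`freq_diff`)

Group-vs-group gene frequencies are compared with the two-sided Fisher
exact test on presence counts (minimum-likelihood definition: the sum of
hypergeometric point probabilities not exceeding the observed table's,
with 1e-7 relative tolerance on the comparison; delegated to
`scipy.stats.fisher_exact` and verified in tests against exact integer
enumeration for all tables with group sizes ≤ 30). P-values are
Benjamini–Hochberg adjusted; a gene is called differential iff
`p_adj < 0.001` **and** the frequency fold change strictly exceeds 2.
"Frequency difference > 2" is read as a ratio (fold change), matching the
companion definition used for the same gene lists; when one frequency is
zero and the other positive the fold is infinite and passes the gate;
genes absent in both groups are never tested.

Term enrichment is the upper-tail hypergeometric test P(X ≥ x) per term,
BH-adjusted across terms, significant below adjusted p 0.05; the default
universe is the annotated gene set.

PAV–phenotype association is a covariate-adjusted per-gene linear model
`phenotype ~ intercept + covariates + presence`, reported as the two-sided
t-test on the presence coefficient with a Bonferroni threshold
`alpha / m` over the m genes actually tested. Monomorphic genes are
skipped with a NaN sentinel and excluded from m. A mixed-model scan is out
of scope; the simple adjusted regression is the documented substitute.
Covariates are projected out of phenotype and presence once
(Frisch–Waugh), so the per-gene fit is closed-form with the correct
residual degrees of freedom (n − q − 1, q = intercept + covariates); the
implementation is verified against a full OLS fit.

## Population-genetic statistics (`popgen`)

**Fst.** The Weir & Cockerham (1984) two-population moment estimator from
unphased diploid dosages: per-site variance components a (among
populations), b (among individuals within populations) and c (within
individuals); per-site ratio a/(a+b+c); genome-wide *weighted* estimate
Σa / Σ(a+b+c). Both the weighted value and the mean of per-site ratios are
reported, since windowed tools commonly print either. Missing genotypes
are excluded per site; a site needs ≥ 2 genotyped individuals per
population. The estimator has a small negative O(1/n) bias term at
identical allele frequencies — tests assert near-zero only at sample sizes
where it is negligible.

**π.** Per site, unbiased heterozygosity (n/(n−1))(1 − Σp²) over the n
observed allele copies; window π sums site values and divides by the
*full window length* (the windowed-π convention of VCFtools), not the
segregating-site count.

**Sweep-window aggregation.** Per-position selection scores (e.g. XP-CLR
likelihoods computed by an external scanner) are averaged over
non-overlapping 10-kb windows tiling each chromosome from position 1
(1-based inclusive tiles). The top-fraction rule is an order statistic:
with m = ⌈fraction × window count⌉, the threshold is the m-th largest
mean and every window ≥ threshold is flagged (ties included) — chosen over
interpolated quantiles because it is deterministic and oracle-checkable.
Windows in the top 20% that are adjacent or separated by one window are
merged into regions spanning first to last member (bridged gaps
included); the region score is the maximum member mean. The top-5%
"strong" flag is computed on unmerged window means, and a merged region is
strong iff it contains a top-5% window; whether flagging precedes or
follows merging is ambiguous in the source procedure, and this ordering is
the documented choice. For genes overlapping a region, weighted Fst is
recomputed over the gene span ± 5 kb.

## Haplotype association (`haplotypes`)

A candidate gene's haplotype region is its span plus 1 kb upstream and
500 bp downstream, strand-aware, truncated at chromosome bounds. A
sample's haplotype is the exact vector of unphased dosage calls across the
region's SNPs (the CandiHap convention — no statistical phasing); samples
with any missing call are excluded and reported rather than treated as a
distinct allele, which would inflate haplotype counts. Haplotypes are
ranked by descending carrier count, ties by genotype string, and labeled
Hap1, Hap2, …

Association across haplotypes with ≥ `min_group` carriers (default 2)
uses the tie-corrected Kruskal–Wallis statistic, chosen over ANOVA for
robustness at the small group sizes haplotype tables produce. For total
qualifying n ≤ 12 the p-value is *exact*, by enumerating every assignment
of samples to the observed group sizes; above that, the chi-square
approximation applies. The exact path is verified against brute-force
relabeling with an independent statistic implementation; rank-basedness
makes the p invariant under monotone phenotype transforms.

## Expression and TAU (`expression`)

CPM = count × 10⁶ / library size; FPKM = count × 10⁹ / (library size ×
gene length); the two satisfy FPKM × length/10³ = CPM per gene. The
tissue-specificity index over n ≥ 2 group means x₁..xₙ is

    TAU = n/(n−1) − Σxᵢ / ((n−1) · max xᵢ)

0 for uniform expression, 1 for single-group expression, undefined (NaN)
when every mean is zero. Group means enter on the CPM scale by default
(FPKM supported); the unit does not change TAU for uniform gene length and
the choice is reported. The specificity cutoff (default TAU ≥ 0.8) is a
package parameter, configurable and recorded in outputs. Specific genes
are assigned to their argmax-mean group (ties resolved by column order and
flagged) and crossed with PAV occupancy categories (per-group proportions
summing to 1) and presence-frequency distributions.

## Synthetic data (`simulate`)

All generators draw from one integer seed; each generator derives an
independent named stream (`SeedSequence([seed, crc32(name)])`), so outputs
are byte-identical under a fixed seed and independent across generators.
Defaults describe the emulated study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_samples` | 200 | accessions in the PAV cohort |
| `n_genes` | 1000 | genes in the pan-gene set |
| `class_spec` | 75.9% core @1.0, 6.5% softcore @0.995, 13.3% shell @0.5, 4.3% cloud @0.005 | occupancy mix mirroring the observed goose pan-genome proportions |
| `mean_depth` | 10 | per-base Poisson depth of present genes |
| `noise_depth_fraction` | 0.05 | exon-base fraction of *absent* genes receiving depth ≥ minCov (kept below lostCutoff so truth is recoverable; `hard_mode` draws it from U[0, 0.4] to straddle the decision boundary) |
| `fst_target` | 0.2 | Balding–Nichols F for two populations |
| `n_sites` | 5000 | biallelic SNPs |
| `effect_size`, `noise_sd` | 2.0, 1.0 | phenotype units per presence allele; residual SD |
| `n_groups` | 9 | expression groups (the study profiles nine organs/tissues) |
| `specific_fold` | 50 | expression elevation of planted specific genes in their one group |

Genotypes follow the Balding–Nichols model — ancestral frequency uniform
on [0.1, 0.9], population frequency Beta(p(1−F)/F, (1−p)(1−F)/F),
genotypes Binomial(2, ·) — chosen because it is the standard generative
model whose differentiation parameter the Weir–Cockerham estimator
targets. Selection tracks are Exponential(1) background scores with
planted windows shifted by +20 (≫ the background scale, so recovery in the
top 5% is essentially certain). The contig scenario is a hand-constructed
60-contig set (8 too-short, 10 fully aligned, 16 fully unaligned of which
6 are retained duplicate partners, 10 anchored-with-tail, 6 redundant
duplicates, 10 contaminants) whose categories are forced by construction.

**What the generators do not emulate:** read-level errors and mapping
bias, linkage disequilibrium (sites are independent, which makes region
haplotypes far more diverse than real data at equal SNP density),
indels/SVs, library-composition effects in expression, and population
structure beyond two Balding–Nichols demes. Passing parameter-recovery
tests therefore demonstrates the correctness of each estimator under its
own generative assumptions — not robustness to real-data artifacts such as
mappability-driven false absences.

## Problem sizes and verification

Test and driver problem sizes are chosen so every stage runs comfortably
on a laptop: presence-recovery at 200 samples × 500 genes (≥ 99%
agreement observed: in fact 100%); Fst recovery at 5,000 sites and 50+50
samples (±0.03); association power over 100 replicates of a 1,000-gene
cohort (≥ 90% detection at 0.05/m; observed 100%); saturation at 100
replicates. The exact-enumeration oracles (Fisher over all group sizes
≤ 30, Kruskal–Wallis permutations at n ≤ 12, occupancy classes at
n ≤ 300) are exhaustive, not sampled.

## Known limitations

* The contig triage consumes alignment/hit tables; it does not run
  aligners, so its fidelity to any particular aligner's output depends on
  that tool's identity definition.
* `region_presence` interprets "reads covering a base" as per-base depth;
  fragment-level double counting of overlapping mates is not modeled.
* Only two-population Fst is implemented; the estimator generalizes to
  r > 2 but the package scope is pairwise contrasts.
* The PAV association is a fixed-effects adjusted regression; relatedness
  beyond supplied covariates (e.g. PCA axes) is not modeled.
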