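# Methods

This note documents the models implemented in `allelescan`, the defaults and
conventions chosen where the procedure admits more than one reading, and what
the synthetic-data generators do and do not emulate.

## MPRA design

For a biallelic SNV the design generator emits twelve 120-nt cores: both
alleles, both strands, and three window offsets placing the variant at −20,
0 and +20 bp from the oligo center. Each core is flanked by the fixed
synthesis adapters `ACTGGCCGCTTGACG` (5′) and `CACTGCGGCTCCTGC` (3′).

*Center convention.* A 120-nt sequence has no middle base; we fix the core
"center" at 0-based index 60, so offset *o* places the variant at in-core
index 60 + *o* on the plus strand. Minus-strand designs are the reverse
complement of the corresponding plus-strand core (variant at index
119 − (60 + *o*)). This is a documented convention, not an inference; the
alternative (index 59) would shift every design by one base without
changing any cardinality or downstream behaviour.

Indels are rejected: the assay design is defined for single-nucleotide
substitutions only.

## MPRA quantification

Barcode–oligo alignments are filtered (≤ 4 mismatches within the designed
oligo; no mismatch within 10 bp of the variant — 10 bp exactly counts as
"within"). Combinations with < 2 supporting reads are dropped; a barcode
hitting several oligos is rescued only when ≥ 50 reads support the barcode
and one combination holds ≥ 95 % of them. Both the read total and the 95 %
fraction are computed over the combinations that survive the 2-read floor;
this is the one place the compound rule is ambiguous, and the choice is
isolated in `call_barcode_map`.

DNA and RNA counts are normalised per replicate library to counts per 10
million reads, and each barcode's activity is
b_i = log2((1 + RNA_i)/(1 + DNA_i)) — the log of the full pseudocounted
ratio. A variant's log2 score is the weighted mean activity of its
alternative-allele barcodes minus that of its reference-allele barcodes,
pooled over the six genomic contexts and all replicates (replicates pool at
the barcode level; they are not meta-analysed). The default weight is 1 per
barcode; DNA-abundance weighting (weight 1 + DNA_norm) is available behind
`weighting="dna"` for screens where barcode representation is very uneven.

*Significance.* Two-sided permutation test on allele labels:
p = (1 + #{|score_perm| ≥ |score_obs|}) / (1 + n_permutations), with
exhaustive enumeration over all label assignments when their number is small
(≤ 20 000), in which case p is the exact fraction of assignments at least as
extreme. Benjamini–Hochberg q-values are computed across the scoreable
variants of a screen. Degenerate variants (all activities equal) get p = 1;
an allele with zero barcodes makes the variant unscoreable rather than an
error.

## ATAC-seq signal

Cut sites are single-bp Tn5 insertion centers: plus-strand read starts are
shifted +4, minus-strand read ends −5 (the conventional Tn5 dimer offset;
configurable only by pre-shifting inputs). Coordinates are 0-based
half-open throughout, BED taken at face value.

The local intensity over a region is computed on a 150-bp window grid with
10-bp steps (windows overhanging the region end are dropped):

d_ij = (sites of sample j in window i / window length) /
(sites of sample j in region / region length).

The per-sample normaliser makes d invariant to sequencing depth; a sample
with zero sites in the region yields an all-zero column and is flagged
rather than dropped silently.

*TSS enrichment QC.* Per gene, the cut-site depth profile over
[TSS − 1000, TSS + 1000) is normalised by the mean depth of the two
outermost 100-bp flanks; the gene score is the normalised depth averaged
over a 21-bp central window (to damp shot noise at single-bp resolution —
the text convention "average score across all genes" does not fix the
per-gene summary, and the central-window mean was chosen over the ENCODE
profile-maximum as the more conservative statistic). Minus-strand profiles
are flipped before scoring. The sample score is the mean over genes; genes
with zero flank depth are skipped with a warning; samples below score 3
fail QC.

## caQTL detection

**Correlation scan.** Per window, Pearson r between d_i· and the dosage
vector g, two-sided p from the t transform with J − 2 degrees of freedom,
BH q across the region's windows. Windows with constant intensity (or a
constant genotype vector) are undefined and excluded from the FDR
correction. Dosage codes the minor-allele count 0/1/2. Samples with missing
dosage should be dropped from both d and g before analysis; the model has
no missingness term.

**caQTLseg.** The segmentation minimises

Σ_s ( λ2 + (1/J) Σ_j Σ_{i∈s} λ^(s) ‖d_ij − f_ij^(s)‖² )

over partitions of the window grid into alternating allele-independent
segments (per-window fit f_i = mean_j d_ij, λ^(s) = 1) and allele-dependent
segments (per-window OLS fit f_ij = a_i + g_j·b_i, λ^(s) = λ1 > 1). λ1
taxes the extra flexibility of the dependent model — which always fits at
least as well — and λ2 charges per segment, trading over- against
under-segmentation. Defaults: λ1 = 1.075, λ2 = 10^−1.5.

Because both fits are per-window, the residual term is additive over
windows, and the optimum over all alternating partitions is found exactly
by a two-state dynamic program with a segment-opening penalty λ2 — O(I)
after the per-window fits. Equivalence with the partition-space definition
is asserted against exhaustive enumeration over all 2^I labelings in the
tests. Whether λ^(s) multiplies residuals before or after the 1/J average
is a scalar identity and irrelevant.

*Ties and degeneracies.* Ties are broken toward fewer segments, then toward
the allele-independent label (conservative calls). A constant genotype
vector forces the dependent slope to 0, so the dependent fit degenerates to
the mean and (because λ1 > 1) is never selected. Constant intensity yields
a single allele-independent segment of cost λ2.

*π0.* n1 = base pairs covered by the union of allele-dependent windows
under the true genotypes (overlapping windows merged); n0 = the mean of the
same quantity over uniformly random genotype permutations (default 500);
π0 = min(n0/n1, 1), defined as 1 when n1 = 0 (nothing called). Base pairs,
not window counts, are used because overlapping 150-bp windows at 10-bp
steps would otherwise overweight long runs; the bp-accounting convention is
isolated in `dependent_bp`. n0 is a Monte Carlo average: jointly permuting
sample order leaves the segmentation and n1 exactly invariant, while π0 is
invariant in distribution (the permutation draws differ numerically for a
fixed seed).

*Robustness sweep.* `lambda_sweep` re-segments over a grid spanning
λ1 ∈ [1.025, 1.20] and λ2 ∈ [10^−1, 10^−5] and reports per-point calls plus
the minimum pairwise Jaccard overlap of allele-dependent base pairs. A
caveat discovered with the synthetic benchmark: at λ1 = 1.025 a window is
called dependent whenever the linear fit lowers its residual sum of squares
by ≥ 2.4 %, which happens by chance for roughly 5 % of null windows at
J = 161 (the null r² threshold is scale-free, so deeper sequencing does not
help), and λ2 ≤ 10^−2 does not prune such windows. Calls are therefore
stable across the grid for λ1 ≥ 1.05 but over-call at the most liberal
corner; the π0 statistic exists precisely to expose this regime.

## Synthetic data

The generators define the benchmark conditions; they are study conditions,
not tuning knobs.

* **Genotypes**: Binomial(2, MAF) minor-allele dosages (Hardy–Weinberg),
  default MAF 0.2 — a common-variant GWAS regime.
* **ATAC cut sites**: homogeneous Poisson background at 0.05 sites/bp/sample
  (≈ 250 sites over the default 5-kb region, a realistic per-locus yield
  for a 50 k-cell ATAC library), with positions uniform. Inside the planted
  interval the rate is multiplied by 1 + effect·dosage; the default
  benchmark plants a 400-bp interval with effect 1.0 per allele in 161
  samples. Cut sites are generated directly as insertion centers (the
  analysis operates on cut sites); `cutsites_to_read_stubs` un-shifts them
  into read stubs so the Tn5 adjustment is testable.
* **MPRA counts**: DNA barcode counts are negative-binomial with mean 50
  and dispersion 10 (variance = μ + μ²/dispersion), drawn per replicate;
  RNA counts are Poisson with mean DNA-proportional × 2^(baseline +
  effect·[allele = alt]). Each of the 12 contexts per variant gets the same
  number of barcodes (default 100/oligo, matching a well-covered screen).

Not emulated: sequencing error, barcode collisions and chimeras, linkage
between multiple variants, covariates and batch structure, haplotype
phasing, fragment-length structure, or any spatial autocorrelation of
accessibility beyond the planted interval. Passing tests therefore show
that the estimators recover the signals the model family describes under
realistic counting noise — not that real libraries satisfy the model.

## Benchmark conventions and sizes

The acceptance-level tests run at the study scale that the method targets
(161 samples, 5-kb region, 486 windows; MPRA screens of 5–10 variants with
20–100 barcodes per oligo and 3 replicates), with 100 permutations for π0
and up to 999 for MPRA p-values; exhaustive DP verification uses 12-window
fixtures (4096 labelings × 25 fixtures).

Boundary recovery for the planted caQTL is measured against the
population-optimal boundary rather than the planted bp edges: a 150-bp
window overlapping the planted interval by even 10 bp is genuinely (if
weakly) allele-dependent, so the planted bp edge is not the estimand at
window resolution — the optimal call boundary sits where the tapering
per-window signal variance crosses (λ1 − 1) × noise variance. That
boundary is located at test time by an independent per-window rule (no
dynamic program) applied to a 4000-sample simulation, and is stable across
oracle seeds; the test then requires the 161-sample calls to land within
±2 windows of it in ≥ 90 % of seeds.

## Known limitations

* The permutation p-value floor is 1/(n_permutations + 1); screens needing
  very small q-values must raise `n_permutations` accordingly.
* caQTLseg models a single lead variant; multi-variant or haplotype effects
  and covariate adjustment are out of scope.
* The segmentation assumes shared breakpoints across samples (inherited
  variants have comparable effects across individuals); sample-specific
  somatic events violate this.
* `read_vcf_dosages` handles one biallelic site from a plain-text VCF; full
  VCF cohort handling belongs upstream.
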