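# allelescan

Tools for dissecting non-coding disease risk variants in regions of linkage
disequilibrium (LD), for researchers who need to go from a GWAS association
signal to the causal regulatory variant. The package covers the two
computational arms of that workflow:

1. **MPRA design and scoring** — for every candidate SNV, design the twelve
   120-nt reporter constructs (two alleles × two strands × three sliding
   windows placing the variant at −20, 0 or +20 bp from the oligo center,
   flanked by fixed 15-nt adapters), then quantify allelic transcriptional
   activity from barcode counts: each barcode's activity is

   b_i = log2((1 + #RNA_i) / (1 + #DNA_i)),

   with counts library-normalised to counts per 10 million reads, and a
   variant's log2 score is the weighted mean activity of alternative-allele
   barcodes minus that of reference-allele barcodes, pooled over the six
   genomic contexts and all replicates. Significance comes from an
   allele-label permutation test with Benjamini–Hochberg FDR across the
   screen; strand-restricted scores expose strand bias.

2. **caQTL detection** — from per-sample ATAC-seq Tn5 cut sites, build the
   normalised local intensity d_ij (cut-site density in 150-bp windows every
   10 bp, normalised by each sample's region-wide density) and associate it
   with the lead-variant dosage g_j by (a) a per-window Pearson correlation
   scan with BH q-values and (b) **caQTLseg**, a penalized segmentation that
   partitions the region into alternating allele-independent segments
   (f_i = mean_j d_ij, residual weight 1) and allele-dependent segments
   (f_ij = a_i + g_j·b_i, residual weight λ1 > 1), minimising

   Σ_s ( λ2 + (1/J) Σ_j Σ_{i∈s} λ^(s) ‖d_ij − f_ij^(s)‖² ),

   solved exactly by dynamic programming. A permutation statistic
   π0 = min(n0/n1, 1) — allele-dependent base pairs under permuted genotypes
   relative to the true call — estimates the fraction of called signal
   attributable to noise.

A seeded synthetic-data module generates Hardy–Weinberg genotypes, cut-site
data with planted allele-dependent intervals, and MPRA count tables with
planted allelic effects, so the whole pipeline is testable end to end
without restricted patient data.

## Worked example

Simulate 161 samples over a 5-kb LD region with a 400-bp accessibility
interval at 2300–2700 bp whose cut-site rate increases by 1× per minor
allele (MAF 0.2), then scan and segment:

```python
import numpy as np
from allelescan import (AtacSimConfig, simulate_atac, make_window_grid, Region,
                        local_intensity, segment_caqtl, estimate_pi0, scan_correlation)

config = AtacSimConfig(n_samples=161, region_length=5000, maf=0.2,
                       background_rate=0.05, planted_start=2300, planted_end=2700,
                       effect_per_allele=1.0, seed=7)
cut_sites, truth = simulate_atac(config)
grid = make_window_grid(Region("chr1", 0, 5000))
matrix = local_intensity(cut_sites, grid)
g = truth.genotypes.astype(float)

scan = scan_correlation(matrix, g)
top = scan.loc[scan["q"].idxmin()]
print(f"scan: best window {int(top.window_start)}-{int(top.window_end)}, "
      f"r = {top.r:.3f}, q = {top.q:.3g}")

seg = segment_caqtl(matrix, g)          # lambda1 = 1.075, lambda2 = 10**-1.5
for s in seg.segments:
    print(f"segment windows {s.i0:>3}-{s.i1:>3}  {s.label:<19} cost {s.cost:.4f}")
pi0 = estimate_pi0(matrix, g, n_permutations=100, seed=7)
print(f"pi0 = {pi0.pi0:.3g} (n1 = {pi0.n1} bp dependent, n0 = {pi0.n0:.1f} bp under permutation)")
```

Output:

```
scan: best window 2530-2680, r = 0.797, q = 5.29e-34
segment windows   0-218  allele-independent  cost 27.1474
segment windows 219-264  allele-dependent    cost 7.3810
segment windows 265-485  allele-independent  cost 27.7084
pi0 = 0 (n1 = 600 bp dependent, n0 = 0.0 bp under permutation)
```

The correlation scan flags windows inside the planted interval at extreme
FDR; caQTLseg calls a single allele-dependent segment whose 600 covered bp
contain the planted 400-bp interval (the 150-bp windows smear the edges),
and the permutation null never calls dependent base pairs, so the noise
fraction π0 is 0.

The estimators also compose with scikit-learn conventions
(`CaQTLSegmenter(lambda1=1.075, lambda2=10**-1.5).fit(X, g)` with `X` of
shape `(n_samples, n_windows)`, fitted attributes `labels_`, `segments_`,
`cost_`; `CorrelationScanner`; `MPRAScorer`), and every stage is available
from the shell via the `allelescan` command (`allelescan design`,
`allelescan mpra score`, `allelescan atac intensity|qc`,
`allelescan caqtl scan|segment|pi0|sweep`, `allelescan simulate atac|mpra`).

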