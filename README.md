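# qtlbridge

Cross-species candidate-gene prioritization: combine the statistical power
of quantitative trait locus (QTL) mapping in a recombinant-inbred (RI)
mouse panel with the positional precision of a human GWAS, then screen the
surviving genes by coexpression.

The package is aimed at statistical geneticists who have (a) strain-mean
phenotypes and genotypes for an RI panel such as the BXD set, (b) SNP-level
summary statistics from a human GWAS plus pairwise LD for the matching
ancestral population, and (c) probe-level expression data for
guilt-by-association follow-up. It implements the full chain from marker
scan to candidate call on plain-text inputs, and ships a synthetic-data
module that generates every input with the statistical structure the
analysis assumes, so the whole pipeline is testable without any downloads.

## The method

**Mouse stage.** For each strain-mean trait *y*, every marker is tested by
single-marker regression on the genotype code *x* ∈ {−1, +1} (the two
parental homozygotes; RI lines are inbred). The scan statistic is the
likelihood-ratio score

LRS = *n* · ln(RSS₀ / RSS₁),  LOD = LRS / 4.61,

with RSS₀ from the intercept-only fit and RSS₁ from the genotype fit, and
the additive coefficient *a* = (mean_D − mean_B)/2 (negative *a* means the
B allele increases the trait). Genome-wide significance uses permutations
of the trait values across strains (5000 by default): a marker is
significant iff its LRS strictly exceeds the 95th-percentile order
statistic of the permuted genome-wide maxima. Runs of significant markers
become QTL regions; nearby runs merge into a parent region that keeps both
peaks as sub-regions, and overlapping regions from different traits are
union-merged into consensus regions.

**Human stage.** SNP p-values inside each gene are combined into gene-level
p-values two ways. GATES, an extended Simes test, sorts the gene's *M*
p-values and takes

P = min_j [ M_e · p₍ⱼ₎ / m_e(j) ],

where M_e = M − Σᵢ I(λᵢ>1)(λᵢ−1) is the effective number of independent
tests from the eigenvalues λ of the p-value correlation matrix (derived
from LD r²) and m_e(j) is the same quantity for the top *j* SNPs. HYST
partitions the SNPs into LD blocks, takes each block's GATES p-value, and
combines T = −2 Σ ln p_k with a scaled chi-square whose variance uses
Brown's covariance approximation between block key SNPs.

**Cross-species gate.** Mouse genes overlapping each QTL region are mapped
to human homologs (one-to-one); each region gets its own Bonferroni
threshold α / (n_homologs × 2), and a homolog is called a candidate when
min(GATES p, HYST p) passes its region's threshold.

**Coexpression follow-up.** Pearson correlation matrices with a
probe-count-adjusted alpha (α/n_probes; pairs must also reach |r| ≥ 0.5),
condition-wise coexpression values (the fraction of a target gene's
two-fold up-regulated conditions in which another gene is also up),
probe-consistency and phenotype screens, hypergeometric over-representation
analysis with Benjamini–Hochberg adjustment, and PC1 synthetic traits.

## Worked example

```python
from qtlbridge import (
    RiPanelSpec, QtlPlantSpec, simulate_ri_panel, simulate_strain_trait,
    lrs_scan, permutation_threshold, significant_intervals, region_threshold,
)

geno = simulate_ri_panel(RiPanelSpec(n_lines=75, chromosomes=[("chr1", 100.0, 50)], seed=1))
trait = simulate_strain_trait(geno, QtlPlantSpec("chr1_m25", effect=1.0, h2=0.5), seed=2)
scan = lrs_scan(geno, trait)
thr = permutation_threshold(geno, trait, n_perm=1000, alpha=0.05, seed=3)
regions = significant_intervals(scan, thr.threshold)

print(f"peak LRS {scan.max_lrs:.2f} at {scan.table['lrs'].idxmax()}")
print(f"genome-wide threshold (alpha 0.05, 1000 permutations): {thr.threshold:.2f}")
for r in regions:
    print(f"region {r.chrom}:{r.start_mb:.1f}-{r.end_mb:.1f} Mbp, peak {r.peak_marker}")
print(f"Bonferroni threshold for 30 homologs x 2 tests: {region_threshold(0.05, 30, 2):.2e}")
```

prints

```
peak LRS 63.33 at chr1_m25
genome-wide threshold (alpha 0.05, 1000 permutations): 8.97
region chr1:18.0-18.0 Mbp, peak chr1_m9
region chr1:22.0-22.0 Mbp, peak chr1_m11
region chr1:28.0-64.0 Mbp, peak chr1_m25
Bonferroni threshold for 30 homologs x 2 tests: 8.33e-04
```

The planted QTL at marker `chr1_m25` (heritability 0.5 over 75 lines)
towers over the permutation threshold and is recovered as the main
region's peak; the two flanking single-marker regions are the shoulders of
the same linkage signal. A human gene under this region would then need a
GATES or HYST p-value below 8.33e-04 (30 homologous genes, two tests) to
be called a candidate.

The same stages are exposed on the command line via `qtlbridge simulate
panel|trait|gwas`, `qtlbridge qtl`, `qtlbridge assoc`, `qtlbridge
prioritize` and `qtlbridge coexpress`.

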