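# Methods

This note documents the statistical models behind `qtlbridge`, the
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical conventions at the edges.

## QTL mapping on strain means

The mapping unit is the strain mean of an RI line, not an individual
animal; with two parental homozygotes per marker the model is

y_s = μ + a·x_s + e_s,  x_s ∈ {−1, +1},

and the scan statistic LRS = n·ln(RSS₀/RSS₁) compares the intercept-only
and genotype fits. Single-marker regression stands in for interval
mapping: on a dense marker map the peak-marker statistic defines the same
regions, and downstream stages consume regions, not between-marker
positions. No kinship/mixed-model correction is applied — the procedure
mirrors classical RI-panel scans that treat line means as exchangeable
under permutation.

* **Permutations** shuffle trait values across strains, one shared
  shuffled order per genome scan (equivalent to jointly permuting genotype
  rows). The threshold is the k-th smallest of the permuted genome-wide
  maxima with k = ⌈(1−α)·n_perm⌉, and significance is *strict* (observed >
  threshold); ties at the threshold are non-significant. Default n_perm =
  5000, α = 0.05. Because each permutation reuses the same scan kernel,
  the whole null ensemble is computed as one matrix product per batch.
* **Degenerate cases.** A zero-variance trait yields an all-zero scan with
  a warning; a marker with a single allele class among non-missing lines
  has no defined LRS and is reported missing; a perfect fit (RSS₁ = 0) is
  capped at n·ln(RSS₀/ε) with ε = 10⁻¹²·RSS₀ so ordering is preserved
  without infinities. Mapping requires ≥ 8 shared strains.
* **Regions.** Maximal runs of significant markers; two runs separated by
  ≤ `max_gap_markers` sub-threshold markers (default 0) merge into a
  parent carrying both runs as sub-regions, which is how a broad linkage
  signal that "separates into two smaller QTL" is represented. Region
  spans are reported at marker positions (Mbp); the homolog stage
  additionally records the span of the overlapping genes, since published
  region tables conventionally print gene-span bounds.

## Gene-based association (GATES and HYST)

Both tests consume only SNP p-values and pairwise LD r², never raw
genotypes.

* **p-value correlation.** The correlation between two SNPs' p-values is
  approximated by ρ_p = r². The mapping is exact at r² ∈ {0, 1}, monotone
  in between, and deliberately a single pluggable function so a polynomial
  refinement can be swapped in without touching callers. Empirically (for
  two-sided normal p-values) ρ_p = r² slightly over-states the true
  p-value correlation, which makes the effective-number correction — and
  hence GATES — conservative rather than liberal. Absent LD pairs count
  as r² = 0, also conservative.
* **Effective number of tests.** M_e = M − Σᵢ I(λᵢ>1)(λᵢ−1) over the
  eigenvalues of the ρ_p matrix, clamped to [1, M]. GATES evaluates
  M_e·p₍ⱼ₎/m_e(j) over the sorted p-values, recomputing m_e(j) on the
  leading j×j submatrix; ties in p are broken by position order, ties in
  the minimized term by the smallest j.
* **LD blocks.** Greedy left-to-right: a position-sorted SNP joins the
  current block iff its r² with the block's last member is ≥ 0.8
  (configurable). Each block's key SNP is the SNP achieving its GATES
  minimum; between-block correlation is ρ_p of the key SNPs.
* **HYST.** T = −2Σ ln p_k with E = 2K and Var = 4K + 2Σ ρ̂(3.25+0.75ρ̂),
  ρ̂ = max(ρ_p, 0) (Brown's approximation); the p-value is the upper tail
  of χ²_f at T/c with c = Var/2E, f = 2E²/Var. K = 1 reduces exactly to
  the block p; independent blocks reduce to Fisher's method. Measured
  against the empirical covariance of −2 ln p for two-sided tests, Brown's
  term with ρ̂ = r² is accurate to a few percent.
* **Known limitation.** Two-moment matching is accurate near the center of
  the null distribution but under-weights the extreme upper tail when
  between-block correlations are large. In the worst configuration —
  every SNP its own block with adjacent r² just below the block-join
  threshold — the HYST tail at p ≈ 10⁻³ runs ~3× nominal. GATES does not
  share this behavior (its deep tail is accurate), and the block machinery
  is calibrated whenever blocks capture the strong LD, i.e. when
  between-block r² is modest. The end-to-end simulations therefore model
  dense within-gene SNPs as a single high-LD block (AR ρ = 0.9, adjacent
  r² = 0.81), the regime the combination is designed for.
* **SNP→gene assignment** uses 1-based inclusive gene spans with a
  configurable flank (default 0: gene body only, since the flank used by
  any particular GWAS-annotation tool is not a portable constant). A SNP
  inside two overlapping genes is assigned to both; genes with no SNPs are
  flagged untested.

## Cross-species candidate calls

Each QTL region's threshold is α/(n × 2) where n counts homologous genes
in the region *whether or not they carry SNPs*: published thresholds
derive from annotated homolog counts, and dropping untested genes would
make the gate anti-conservative relative to those. The passing rule is
inclusive (p ≤ threshold); published comparisons read "lower than", but no
printed case sits exactly on a threshold, so the orderings agree. A gene
inside both a parent region and its sub-region is evaluated once per
region against each region's own threshold; the final candidate list is
the set of distinct passing genes.

## Coexpression stage

* **Adjusted alpha.** The published procedure describes "dividing the
  p-value by the number of probes", but dividing an observed p-value makes
  results *more* significant, contradicting the printed worked threshold
  (0.05/63 = 7.94e-4 used as a cut-off). The package divides the family
  alpha by the probe count — a Bonferroni gate that reproduces the printed
  number. Calls additionally require |r| ≥ 0.5. The |r| implied by the
  adjusted alpha at the data's sample size is reported rather than
  asserted, since it depends on n.
* **Pearson p-values** are two-sided, from the t transform with
  pair-specific (pairwise-complete) n; pairs need ≥ 3 shared samples.
  Sidedness is a convention choice; two-sided is the safer default when
  negative coexpression is also of interest.
* **Conditional coexpression** of gene g with target t is
  |up(g) ∩ up(t)| / |up(t)| over binary two-fold up-calls. The published
  database behind this value does not state its p-value definition; a
  one-sided binomial upper tail at g's marginal up-frequency is used,
  documented and pluggable. The value depends only on the binary calls,
  so any re-thresholding that preserves up-calls preserves it.
* **Phenotype screen** keeps phenotypes correlated (|r| ≥ 0.5, p ≤ 0.05)
  with *every* retained probe of a gene, with a consistent sign across
  probes — mixed signs would make "correlates with all probes" ambiguous.
  Single-probe genes keep their probe with a logged caveat.
* **ORA** is the hypergeometric upper tail with Benjamini–Hochberg
  adjustment across the supplied term sets against a user-supplied
  universe (no hosted annotation content is bundled).
* **PC1 synthetic traits** standardize columns by default (traits mix
  scales such as beam breaks and log2 intensity), and fix the orientation
  so the loading sum is ≥ 0. For two traits the variance fraction is
  exactly (1+|r|)/2.

## Synthetic data: what it emulates, and what it does not

* **RI panel.** Each line is a homozygous parental mosaic generated by a
  first-order switch process along each chromosome. The per-interval
  switch probability applies RI map expansion for sib-mating,
  R = 4r/(1+6r), to Haldane recombination fractions from the genetic map
  (default density 0.5 cM/Mbp, the mouse genome-wide average). Markers are
  evenly spaced; heterozygous calls never occur, and an optional
  missingness rate encodes unknowns. This reproduces the LD structure a
  scan needs, not the real BXD marker map, breakpoint interference, or
  segregation distortion.
* **Traits.** y = μ + a·x + e with σ² set from the heritability,
  h² = Var(a·x)/(Var(a·x)+σ²) at Var(x) = 1 (balanced alleles), so
  σ = |a|·√((1−h²)/h²); h² = 1 is noise-free. For a null trait (a = 0,
  h² = 0) the formula leaves the scale free and unit residual sd is used —
  the scan is scale-invariant, so nothing downstream depends on it.
* **GWAS.** Summary-level only: per gene, Z ~ MVN(non-centrality vector,
  AR(ρ) correlation), p two-sided; the LD store records the exact r² = ρ²ᵈ
  used. There is no individual-level sampling, allele-frequency structure,
  or case/control ascertainment — the pipeline only ever consumes
  p-values and r², as the analysis it models did.
* **Annotation.** Genes tile regions without overlap; homologs are
  assigned one-to-one at a configurable rate. Real gene-length variation
  and many-to-many homology families are not modeled (non-1:1 groups are
  skipped at read time anyway).
* **Expression.** Probe value = loading·factor + gene noise + probe noise,
  one standard-normal factor per module; condition up-calls threshold
  simulated log2 fold changes (loading·module activity + unit noise) at
  two-fold. Genes sharing a factor with loading ℓ have expected cross-gene
  probe correlation ℓ²/(ℓ² + σ_g² + σ_p²). Real probe-level artifacts
  (GC bias, cross-hybridization, batch structure) are not modeled, so
  passing tests demonstrate the statistics, not robustness to array
  artifacts.

Passing calibration tests on these generators shows the estimators are
correct under their assumed sampling models; it does not certify behavior
on real data with population structure, assay noise, or annotation error.

## Reference simulation sizes

The calibration and power experiments (shared between the test suite and
`scripts/acceptance.py`) use: 2000 null genes × 8 SNPs (AR ρ = 0.8) for
the GATES size; 500 null traits × 1000 permutations on a 20-marker ×
40-line panel for the genome-wide FWER; 100 replicates of a 75-line,
two-chromosome panel (planted h² = 0.5) for QTL coverage; 200 replicates
of the full pipeline with 30 homologs and per-SNP non-centrality 5.5
(single-block gene LD, AR ρ = 0.9) for end-to-end recovery, plus 200 null
replicates for the false-candidate rate; and 100 replicates of a 3-gene
module (expected cross-gene r 0.7, 30 strains, one probe per gene) for
module recovery. Permutation counts are scaled from the 5000 used on real
data to 1000 per replicate, which moves the threshold's order statistic
by far less than its replicate-to-replicate spread.

Measured under these conditions, the module-recovery rate sits near 0.85
rather than above 0.9: with 30 strains the sample correlation of a
true-0.7 pair falls below the 0.5 call gate about 4% of the time, and all
three within-module pairs must pass simultaneously. This is a property of
the stated sample size and gate, not of the implementation; raising
n_strains or the module correlation moves recovery above 0.9.
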