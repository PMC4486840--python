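"""Calibration and power experiments run under the pipeline's study conditions.

Each function simulates inputs with :mod:`qtlbridge.synthetic`, runs the
relevant pipeline stage, and returns an empirical rate.  They exist so the
same experiment definitions back both the test suite and the reproduction
script; every function is deterministic given its seed.

Problem sizes are the package's reference conditions: 2000 null genes of 8
SNPs for gene-test calibration, 500 null traits × 1000 permutations on a
20-marker × 40-line panel for the genome-wide threshold, 100 replicates of
a 75-line panel for planted-QTL coverage, 200 replicates of the full
mouse→human pipeline with 30 homologous genes, and 100 replicates of a
3-gene planted coexpression module among singleton background genes.
"""

from __future__ import annotations

import numpy as np

from .assoc import GeneSnpSet, assign_snps_to_genes, gates, gene_association
from .coexpression import coexpression_calls, correlation_matrix
from .prioritize import call_candidates, homologs_in_region
from .qtl import (
    consensus_regions,
    lrs_scan,
    permutation_threshold,
    significant_intervals,
)
from .synthetic import (
    ExprSimSpec,
    GwasSimSpec,
    QtlPlantSpec,
    RiPanelSpec,
    simulate_annotation,
    simulate_expression,
    simulate_gwas_region,
    simulate_ri_panel,
    simulate_strain_trait,
)

__all__ = [
    "gates_null_type1_error",
    "qtl_null_fwer",
    "planted_qtl_coverage",
    "end_to_end_run",
    "end_to_end_recovery_rate",
    "end_to_end_false_candidate_rate",
    "module_recovery_rate",
]


def gates_null_type1_error(
    seed: int, n_genes: int = 2000, n_snps: int = 8, rho: float = 0.8,
    alpha: float = 0.05,
) -> float:
    """Fraction of null AR-LD genes with GATES p ≤ alpha."""
    spec = GwasSimSpec([(f"G{i}", n_snps) for i in range(n_genes)], rho=rho, seed=seed)
    table, _ = simulate_gwas_region(spec)
    rec = table.records
    corr = np.array(
        [[(rho ** abs(i - j)) ** 2 for j in range(n_snps)] for i in range(n_snps)]
    )
    np.fill_diagonal(corr, 1.0)
    hits = 0
    for i in range(n_genes):
        sub = rec.iloc[i * n_snps : (i + 1) * n_snps][["snp", "bp", "p"]]
        p, _ = gates(GeneSnpSet(f"G{i}", sub.reset_index(drop=True), corr))
        hits += p <= alpha
    return hits / n_genes


def qtl_null_fwer(
    seed: int, n_traits: int = 500, n_perm: int = 1000, n_markers: int = 20,
    n_lines: int = 40, alpha: float = 0.05,
) -> float:
    """Fraction of null traits with any genome-wide-significant marker."""
    geno = simulate_ri_panel(
        RiPanelSpec(n_lines, [("chr1", 100.0, n_markers)], seed=seed)
    )
    null = QtlPlantSpec(geno.markers.index[0], 0.0, 0.0)
    hits = 0
    for rep in range(n_traits):
        trait = simulate_strain_trait(geno, null, seed=seed + 1 + rep)
        scan = lrs_scan(geno, trait)
        thr = permutation_threshold(
            geno, trait, n_perm=n_perm, alpha=alpha, seed=seed + 100_000 + rep
        )
        lrs = np.nan_to_num(scan.table["lrs"].to_numpy(), nan=-np.inf)
        hits += bool(np.any(lrs > thr.threshold))
    return hits / n_traits


def planted_qtl_coverage(
    seed: int, n_rep: int = 100, n_lines: int = 75, h2: float = 0.5,
    n_perm: int = 1000, alpha: float = 0.05,
) -> float:
    """Fraction of replicates whose consensus region covers the planted marker.

    The panel carries two 50-marker chromosomes; the QTL sits mid-chromosome 1.
    """
    covered = 0
    for rep in range(n_rep):
        geno = simulate_ri_panel(
            RiPanelSpec(n_lines, [("chr1", 100.0, 50), ("chr2", 100.0, 50)],
                        seed=seed + rep)
        )
        plant = QtlPlantSpec("chr1_m25", 1.0, h2)
        trait = simulate_strain_trait(geno, plant, seed=seed + 10_000 + rep)
        scan = lrs_scan(geno, trait)
        thr = permutation_threshold(
            geno, trait, n_perm=n_perm, alpha=alpha, seed=seed + 20_000 + rep
        )
        regions = consensus_regions([significant_intervals(scan, thr.threshold)])
        pos = float(geno.markers.loc["chr1_m25", "Mb"])
        covered += any(
            r.chrom == "chr1" and r.start_mb <= pos <= r.end_mb for r in regions
        )
    return covered / n_rep


def end_to_end_run(
    seed: int, ncp: float, n_homologs: int = 30, n_lines: int = 75,
    h2: float = 0.5, n_perm: int = 1000, rho: float = 0.9, n_snps: int = 8,
    alpha: float = 0.05,
) -> tuple[str | None, list[str]]:
    """One full mouse→human replicate.

    A QTL is planted mid-chromosome; the detected consensus region is tiled
    with ``n_homologs`` fully homologous genes; the homolog of the mouse
    gene nearest the planted marker is made causal (per-SNP non-centrality
    ``ncp``; 0 for a null run).  Gene LD is a single high-LD block (AR
    ρ = 0.9), the regime in which the block-combination machinery is
    calibrated.  Returns (planted human gene or None, candidate list).
    """
    geno = simulate_ri_panel(RiPanelSpec(n_lines, [("chr1", 100.0, 50)], seed=seed))
    trait = simulate_strain_trait(geno, QtlPlantSpec("chr1_m25", 1.0, h2), seed=seed + 1)
    scan = lrs_scan(geno, trait)
    thr = permutation_threshold(geno, trait, n_perm=n_perm, alpha=alpha, seed=seed + 2)
    regions = [
        r
        for r in consensus_regions([significant_intervals(scan, thr.threshold)])
        if r.chrom == "chr1"
    ]
    if not regions:
        return None, []
    region = max(regions, key=lambda r: r.peak_lrs)
    mouse_genes, human_genes, hmap = simulate_annotation(
        [("chr1", region.start_mb, region.end_mb)], n_homologs, 1.0, seed=seed + 3
    )
    rset = homologs_in_region(region, mouse_genes, hmap)
    g = mouse_genes.genes
    planted_pos = float(geno.markers.loc["chr1_m25", "Mb"]) * 1e6
    nearest = g.iloc[int(((g["start"] + g["end"]) / 2 - planted_pos).abs().argmin())]
    planted = hmap.mouse_to_human[nearest["gene_id"]]
    gwas_spec = GwasSimSpec(
        [(h, n_snps) for h in rset.human_gene_ids],
        rho=rho,
        ncp={planted: ncp} if ncp > 0 else {},
        seed=seed + 4,
    )
    gwas, store = simulate_gwas_region(gwas_spec, human_genes)
    sets, _ = assign_snps_to_genes(gwas, human_genes, store)
    associations = {gid: gene_association(s, store) for gid, s in sets.items()}
    _, candidates = call_candidates([rset], associations, alpha=alpha)
    return planted, candidates


def end_to_end_recovery_rate(seed: int, n_rep: int = 200, ncp: float = 5.5) -> float:
    """Fraction of replicates where the planted gene is the unique candidate."""
    ok = 0
    for rep in range(n_rep):
        planted, candidates = end_to_end_run(seed + 97 * rep, ncp=ncp)
        ok += planted is not None and candidates == [planted]
    return ok / n_rep


def end_to_end_false_candidate_rate(seed: int, n_rep: int = 200) -> float:
    """Fraction of fully null replicates producing ≥ 1 candidate."""
    false = 0
    for rep in range(n_rep):
        _, candidates = end_to_end_run(seed + 97 * rep, ncp=0.0)
        false += len(candidates) >= 1
    return false / n_rep


def module_recovery_rate(
    seed: int, n_rep: int = 100, n_strains: int = 30, expected_r: float = 0.7,
) -> float:
    """Fraction of replicates where a planted 3-gene module is exactly recovered.

    Three genes share one latent factor (loading 1); the residual variance
    is set by the variance decomposition so the expected cross-gene probe
    correlation equals ``expected_r``; three background genes sit on
    singleton factors.  Recovery means every within-module pair is called
    coexpressing and no cross-module (or background) pair is.
    """
    resid_var = (1.0 - expected_r) / expected_r  # loading² = factor var = 1
    sd = float(np.sqrt(resid_var / 2.0))
    modules = {f"gA{i}": "F1" for i in range(3)}
    modules |= {f"gB{i}": f"B{i}" for i in range(3)}
    loadings = {g: 1.0 for g in modules}
    recovered = 0
    for rep in range(n_rep):
        spec = ExprSimSpec(modules, loadings, gene_noise_sd=sd, probe_noise_sd=sd,
                           n_strains=n_strains, probes_per_gene=1, seed=seed + rep)
        expr, _ = simulate_expression(spec)
        corr = correlation_matrix(expr.values)
        calls = coexpression_calls(corr, alpha=0.05, n_probes=len(expr.values))
        probes = list(expr.values.index)
        mod = [p for p in probes if p.startswith("gA")]
        rest = [p for p in probes if not p.startswith("gA")]
        within_ok = all(
            calls.calls.loc[a, b] for i, a in enumerate(mod) for b in mod[i + 1 :]
        )
        cross_hit = any(calls.calls.loc[a, b] for a in mod for b in rest) or any(
            calls.calls.loc[a, b] for i, a in enumerate(rest) for b in rest[i + 1 :]
        )
        recovered += within_ok and not cross_hit
    return recovered / n_rep
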