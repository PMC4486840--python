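"""Synthetic data generators for every input the pipeline consumes.

The generators emulate, at the statistical level the analysis assumes:

* an RI (recombinant-inbred) genotype panel — each line a homozygous mosaic
  of the two parental allele states produced by a first-order switch process
  along each chromosome, with RI map expansion (sib-mating: the per-interval
  switch probability is R = 4r/(1+6r) for underlying recombination fraction
  r from Haldane's map function);
* strain-mean traits with one planted additive QTL at a chosen heritability;
* GWAS summary statistics — per-gene Z-vectors drawn from a multivariate
  normal with first-order autoregressive LD and mean equal to a planted
  non-centrality vector, converted to two-sided p-values, with the exact
  pairwise r² recorded in an :class:`~qtlbridge.containers.LdStore`;
* gene annotations tiled across regions with a configurable homolog rate;
* probe-level expression with planted coexpression modules (shared latent
  factor per module) and binary condition × gene up-regulation calls from a
  two-fold threshold on simulated fold changes.

All outputs are deterministic given the spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ConditionMatrix,
    ExpressionMatrix,
    GeneSet,
    GenotypeMatrix,
    GwasSnpTable,
    HomologyMap,
    LdStore,
    TraitTable,
)

__all__ = [
    "RiPanelSpec",
    "QtlPlantSpec",
    "GwasSimSpec",
    "ExprSimSpec",
    "simulate_ri_panel",
    "simulate_strain_trait",
    "simulate_gwas_region",
    "simulate_annotation",
    "simulate_expression",
]


@dataclass
class RiPanelSpec:
    """Specification of a synthetic RI genotype panel.

    ``chromosomes`` lists (name, length in Mbp, n_markers); markers are
    evenly spaced.  ``cm_per_mbp`` sets the genetic map density (default
    0.5 cM/Mbp, the genome-wide mouse average).  ``fixed_switch_prob``
    overrides the map-derived strand-switch probability with a constant
    (useful for the no-recombination and independence limits).
    """

    n_lines: int
    chromosomes: list[tuple[str, float, int]]
    seed: int = 0
    cm_per_mbp: float = 0.5
    fixed_switch_prob: float | None = None
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("n_lines must be ≥ 2")
        for name, length, n_markers in self.chromosomes:
            if n_markers < 1:
                raise ValueError(f"chromosome {name} has zero markers")
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        if self.fixed_switch_prob is not None and not (
            0.0 <= self.fixed_switch_prob <= 0.5
        ):
            raise ValueError("switch probability must lie in [0, 0.5]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class QtlPlantSpec:
    """A planted additive QTL: trait = μ + a·x + e, x ∈ {−1, +1} for {B, D}.

    Positive ``effect`` means the D allele increases the trait (so the
    additive coefficient recovered by the scan is positive); ``h2`` fixes
    the residual variance through h² = Var(a·x)/[Var(a·x) + σ²] with
    Var(x) = 1 (balanced alleles).
    """

    marker: str
    effect: float
    h2: float
    mean: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError("h² must lie in [0, 1]")
        if self.effect != 0.0 and self.h2 == 0.0:
            raise ValueError("h² = 0 with a non-zero effect is inconsistent")
        if self.effect == 0.0 and self.h2 > 0.0:
            raise ValueError("a = 0 with h² > 0 is inconsistent")


@dataclass
class GwasSimSpec:
    """Specification of summary-level GWAS simulation.

    ``genes`` lists (gene id, n_snps).  ``rho`` is the first-order
    autoregressive correlation between adjacent SNP Z-scores; the implied
    pairwise LD is r² = ρ^(2|i−j|).  ``ncp`` maps a gene id to its per-SNP
    non-centrality (scalar or vector); genes absent from the map are null.
    """

    genes: list[tuple[str, int]]
    rho: float = 0.8
    ncp: dict[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("autoregressive correlation must lie in [0, 1)")
        for gene, n in self.genes:
            if n < 1:
                raise ValueError(f"gene {gene} needs ≥ 1 SNP")
        for gene, val in self.ncp.items():
            if np.any(np.asarray(val, dtype=float) < 0):
                raise ValueError(f"non-centralities must be ≥ 0 (gene {gene})")


@dataclass
class ExprSimSpec:
    """Specification of probe-level expression with planted modules.

    ``modules`` maps gene id → latent factor id; genes sharing a factor
    with loading ℓ and factor variance 1 have expected cross-gene probe
    correlation ℓ²/(ℓ² + gene_noise_sd² + probe_noise_sd²).
    """

    modules: dict[str, str]
    loading: dict[str, float]
    gene_noise_sd: float = 0.5
    probe_noise_sd: float = 0.5
    n_strains: int = 30
    probes_per_gene: int = 2
    n_conditions: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 3:
            raise ValueError("n_strains must be ≥ 3 (correlation p undefined below)")
        if self.gene_noise_sd < 0 or self.probe_noise_sd < 0:
            raise ValueError("noise sds must be ≥ 0")
        if self.gene_noise_sd == 0 and self.probe_noise_sd == 0:
            pass  # allowed: deterministic probes (r = 1 within a module)
        for gene in self.modules:
            val = self.loading.get(gene, 1.0)
            if not np.isfinite(val):
                raise ValueError(f"loading for {gene} must be finite")
        if self.probes_per_gene < 1:
            raise ValueError("probes_per_gene must be ≥ 1")


def _switch_probs(spec: RiPanelSpec, mb: np.ndarray) -> np.ndarray:
    """Per-interval strand-switch probabilities with RI map expansion."""
    if spec.fixed_switch_prob is not None:
        return np.full(len(mb) - 1, spec.fixed_switch_prob)
    d_morgan = np.diff(mb) * spec.cm_per_mbp / 100.0
    r = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))  # Haldane
    return 4.0 * r / (1.0 + 6.0 * r)  # sib-mating RI expansion


def simulate_ri_panel(spec: RiPanelSpec) -> GenotypeMatrix:
    """Simulate an RI genotype panel as parental mosaics."""
    rng = np.random.default_rng(spec.seed)
    marker_rows, call_blocks, index = [], [], []
    for name, length, n_markers in spec.chromosomes:
        mb = np.linspace(length / n_markers, length, n_markers)
        cm = mb * spec.cm_per_mbp
        probs = _switch_probs(spec, mb)
        # first marker ±1 with prob 1/2; cumulated switches flip the strand
        start = rng.choice([-1.0, 1.0], size=spec.n_lines)
        switches = rng.random((spec.n_lines, n_markers - 1)) < probs
        flips = np.cumprod(
            np.hstack([np.ones((spec.n_lines, 1)), np.where(switches, -1.0, 1.0)]),
            axis=1,
        )
        calls = start[:, None] * flips  # lines × markers
        if spec.missing_rate > 0:
            miss = rng.random(calls.shape) < spec.missing_rate
            calls = np.where(miss, np.nan, calls)
        for i in range(n_markers):
            index.append(f"{name}_m{i + 1}")
            marker_rows.append({"chrom": name, "cM": float(cm[i]), "Mb": float(mb[i])})
        call_blocks.append(calls.T)  # markers × lines
    strains = [f"RIL{i + 1:03d}" for i in range(spec.n_lines)]
    markers = pd.DataFrame(marker_rows, index=pd.Index(index, name="locus"))
    calls = pd.DataFrame(np.vstack(call_blocks), index=markers.index, columns=strains)
    return GenotypeMatrix(markers, calls)


def simulate_strain_trait(
    geno: GenotypeMatrix, plant: QtlPlantSpec, seed: int = 0
) -> TraitTable:
    """Simulate a strain-mean trait with one planted additive QTL.

    The residual sd is σ = |a|·sqrt((1−h²)/h²) (unit genotype variance);
    h² = 1 gives a noise-free trait.  A null trait (a = 0, h² = 0) uses unit
    residual sd.  Lines with a missing genotype at the planted marker are
    omitted.
    """
    if plant.marker not in geno.markers.index:
        raise ValueError(f"planted marker {plant.marker} not in panel")
    rng = np.random.default_rng(seed)
    x = geno.calls.loc[plant.marker]
    x = x[~x.isna()]
    if plant.effect == 0.0:
        sigma = 1.0
    elif plant.h2 == 1.0:
        sigma = 0.0
    else:
        sigma = abs(plant.effect) * np.sqrt((1.0 - plant.h2) / plant.h2)
    noise = rng.normal(0.0, 1.0, size=len(x)) * sigma
    values = plant.mean + plant.effect * x.to_numpy(dtype=float) + noise
    return TraitTable(
        trait_id=f"synthetic:{plant.marker}",
        values=pd.Series(values, index=x.index),
        metadata=f"planted a={plant.effect} h2={plant.h2}",
    )


def _ar_correlation(n: int, rho: float) -> np.ndarray:
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_gwas_region(
    spec: GwasSimSpec, gene_set: GeneSet | None = None
) -> tuple[GwasSnpTable, LdStore]:
    """Simulate per-gene GWAS Z-scores under autoregressive LD.

    Per gene, Z ~ MVN(mean = non-centrality vector, Σ = AR(ρ)); p-values are
    two-sided normal tails.  The store records the exact pairwise r² = Σ²_ij
    used, so downstream tests see the true LD.  SNP positions are placed
    inside the gene's span when a gene set is supplied, else sequentially.
    """
    rng = np.random.default_rng(spec.seed)
    spans: dict[str, tuple[str, int, int]] = {}
    if gene_set is not None:
        for _, g in gene_set.genes.iterrows():
            spans[g["gene_id"]] = (str(g["chrom"]), int(g["start"]), int(g["end"]))
    store = LdStore()
    rows = []
    cursor = 1
    for gene, n_snps in spec.genes:
        sigma = _ar_correlation(n_snps, spec.rho)
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError as exc:
            raise ValueError("requested correlation is not positive definite") from exc
        mean = np.broadcast_to(
            np.asarray(spec.ncp.get(gene, 0.0), dtype=float), (n_snps,)
        )
        z = mean + chol @ rng.standard_normal(n_snps)
        p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny)
        if gene in spans:
            chrom, start, end = spans[gene]
            if end - start + 1 < n_snps:
                raise ValueError(f"gene {gene} span too short for {n_snps} SNPs")
            pos = np.linspace(start, end, n_snps).round().astype(int)
            pos = np.maximum.accumulate(pos)  # keep order under rounding
        else:
            chrom = "chrSim"
            pos = cursor + np.arange(n_snps)
            cursor = int(pos[-1]) + 1000
        ids = [f"rs_{gene}_{k + 1}" for k in range(n_snps)]
        for k in range(n_snps):
            rows.append({"snp": ids[k], "chrom": chrom, "bp": int(pos[k]), "p": float(p[k])})
        for i in range(n_snps):
            for j in range(i + 1, n_snps):
                store.set(ids[i], ids[j], float(sigma[i, j] ** 2))
    table = GwasSnpTable(pd.DataFrame(rows, columns=["snp", "chrom", "bp", "p"]))
    return table, store


def simulate_annotation(
    regions: list[tuple[str, float, float]],
    genes_per_region: int,
    homolog_rate: float,
    seed: int = 0,
    gene_fill: float = 0.6,
) -> tuple[GeneSet, GeneSet, HomologyMap]:
    """Tile non-overlapping genes across regions and pair them with homologs.

    ``regions`` are (chromosome, start Mbp, end Mbp).  Each region is cut
    into ``genes_per_region`` equal slots; a gene occupies the central
    ``gene_fill`` fraction of its slot.  Each mouse gene gets a human
    partner with probability ``homolog_rate`` (one-to-one).  Human genes are
    tiled on a parallel assembly with the same layout.
    """
    if not (0.0 <= homolog_rate <= 1.0):
        raise ValueError("homolog_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mouse_rows, human_rows = [], []
    hmap = HomologyMap()
    gidx = 0
    for chrom, start_mb, end_mb in regions:
        span_bp = (end_mb - start_mb) * 1e6
        slot = span_bp / genes_per_region
        gene_len = slot * gene_fill
        if gene_len < 1.0:
            raise ValueError(
                f"cannot tile {genes_per_region} non-overlapping genes in "
                f"{chrom}:{start_mb}-{end_mb}"
            )
        for k in range(genes_per_region):
            gidx += 1
            lo = start_mb * 1e6 + k * slot + (slot - gene_len) / 2.0
            mstart, mend = int(round(lo)) + 1, int(round(lo + gene_len))
            mouse_id, human_id = f"Mg{gidx}", f"HG{gidx}"
            mouse_rows.append(
                {"gene_id": mouse_id, "symbol": mouse_id, "chrom": chrom,
                 "start": mstart, "end": mend, "strand": "+"}
            )
            if rng.random() < homolog_rate:
                human_rows.append(
                    {"gene_id": human_id, "symbol": human_id, "chrom": f"h{chrom}",
                     "start": mstart, "end": mend, "strand": "+"}
                )
                hmap.add(mouse_id, human_id)
    cols = ["gene_id", "symbol", "chrom", "start", "end", "strand"]
    return (
        GeneSet(pd.DataFrame(mouse_rows, columns=cols)),
        GeneSet(pd.DataFrame(human_rows, columns=cols)),
        hmap,
    )


def simulate_expression(spec: ExprSimSpec) -> tuple[ExpressionMatrix, ConditionMatrix]:
    """Simulate probe-level expression and binary condition up-calls.

    Probe value = loading·factor(strain) + gene noise + probe noise, with
    one standard-normal latent factor per module and strain.  Condition
    calls threshold simulated log2 fold changes (loading·module activity +
    unit noise) at two-fold (log2 fc ≥ 1).
    """
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.modules)
    factors = sorted(set(spec.modules.values()))
    strains = [f"RIL{i + 1:03d}" for i in range(spec.n_strains)]
    factor_vals = {f: rng.standard_normal(spec.n_strains) for f in factors}
    probe_rows, ann_rows, probe_ids = [], [], []
    for gene in genes:
        load = float(spec.loading.get(gene, 1.0))
        gene_signal = load * factor_vals[spec.modules[gene]] + rng.standard_normal(
            spec.n_strains
        ) * spec.gene_noise_sd
        for k in range(spec.probes_per_gene):
            probe = f"{gene}_p{k + 1}"
            probe_ids.append(probe)
            probe_rows.append(
                gene_signal + rng.standard_normal(spec.n_strains) * spec.probe_noise_sd
            )
            ann_rows.append({"gene_id": gene, "region_type": "exon"})
    values = pd.DataFrame(probe_rows, index=pd.Index(probe_ids, name="probe"),
                          columns=strains)
    annotation = pd.DataFrame(ann_rows, index=values.index)
    expr = ExpressionMatrix(values, annotation)

    # condition-level module activity drives joint two-fold up-calls
    activity = {f: rng.standard_normal(spec.n_conditions) for f in factors}
    lfc_rows = []
    for gene in genes:
        load = float(spec.loading.get(gene, 1.0))
        lfc = load * activity[spec.modules[gene]] + rng.standard_normal(spec.n_conditions)
        lfc_rows.append(lfc)
    lfc = np.vstack(lfc_rows)
    calls = pd.DataFrame(
        (lfc >= 1.0).astype(int),
        index=pd.Index(genes, name="gene"),
        columns=[f"cond{i + 1}" for i in range(spec.n_conditions)],
    )
    return expr, ConditionMatrix(calls)
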