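"""LD-aware gene-based association tests on GWAS SNP summary statistics.

Two tests convert per-SNP p-values plus pairwise LD into a per-gene p-value:

* **GATES** — an extended Simes procedure.  With the gene's SNP p-values
  sorted ascending, P = min_j [ Me · p(j) / me(j) ], where Me is the
  effective number of independent tests among all M SNPs and me(j) the same
  quantity for the top j SNPs.  The effective number for a correlation
  matrix with eigenvalues λ_i is  M − Σ_i I(λ_i > 1)(λ_i − 1): M under
  independence, 1 under perfect correlation.
* **HYST** — a hybrid set-based test: SNPs are partitioned into LD blocks,
  each block is summarized by its GATES p-value, and the block p-values are
  combined with a scaled chi-square (correlated-Fisher) statistic whose
  variance uses Brown's covariance approximation between block key SNPs.

The mapping from LD r² to the correlation of the p-values is pluggable
(default: ρ_p = r², exact at 0 and 1 and monotone in between).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSet, GwasSnpTable, LdStore

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSnpSet",
    "GeneAssociation",
    "pvalue_correlation",
    "effective_tests",
    "gates",
    "ld_blocks",
    "hyst",
    "assign_snps_to_genes",
    "gene_association",
]

_TINY_P = np.finfo(float).tiny


def pvalue_correlation(r2: float) -> float:
    """Approximate correlation between two SNPs' p-values from their LD r².

    The identity ρ_p = r² is exact at r² ∈ {0, 1} and monotone; callers that
    want the published polynomial refinement can pass their own mapping to
    :func:`gene_association`.
    """
    if not (0.0 <= r2 <= 1.0):
        raise ValueError(f"r² out of [0, 1]: {r2}")
    return float(r2)


@dataclass
class GeneSnpSet:
    """SNPs assigned to one gene, with their p-value correlation matrix."""

    gene_id: str
    snps: pd.DataFrame  # columns snp, bp, p; position-sorted
    corr: np.ndarray  # p-value correlation, same order as snps

    def __post_init__(self) -> None:
        if len(self.snps) < 1:
            raise ValueError("GeneSnpSet requires ≥ 1 SNP")
        m = len(self.snps)
        if self.corr.shape != (m, m):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(self.corr, self.corr.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.corr), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any((self.corr < 0) | (self.corr > 1)):
            raise ValueError("correlation entries must lie in [0, 1]")


@dataclass
class GeneAssociation:
    """Per-gene association result with audit metadata."""

    gene_id: str
    n_snps: int
    p_gates: float
    key_snp: str
    p_hyst: float
    n_blocks: int
    block_key_snps: list[str]
    me_full: float  # Me over all SNPs
    hyst_stat: float = np.nan  # T = −2 Σ ln p_block
    hyst_scale: float = np.nan  # c
    hyst_df: float = np.nan  # f

    def __post_init__(self) -> None:
        for p in (self.p_gates, self.p_hyst):
            if not (0.0 < p <= 1.0):
                raise ValueError("gene p-values must lie in (0, 1]")
        if not (1.0 - 1e-9 <= self.me_full <= self.n_snps + 1e-9):
            raise ValueError("Me must lie in [1, n_snps]")

    @property
    def min_p(self) -> float:
        return min(self.p_gates, self.p_hyst)

    @property
    def winning_test(self) -> str:
        return "GATES" if self.p_gates <= self.p_hyst else "HYST"


def effective_tests(corr: np.ndarray) -> float:
    """Effective number of independent tests among correlated p-values."""
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T):
        raise ValueError("correlation matrix must be symmetric")
    m = corr.shape[0]
    lam = np.linalg.eigvalsh(corr)
    me = m - float(np.sum(np.clip(lam - 1.0, 0.0, None)))
    return float(np.clip(me, 1.0, m))


def gates(snps: GeneSnpSet) -> tuple[float, str]:
    """GATES gene p-value and the key SNP achieving the minimum term.

    Ties in p are broken by position order (the input is position-sorted and
    the sort is stable); ties in the minimized term go to the smallest j.
    """
    p = snps.snps["p"].to_numpy(dtype=float)
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    corr_sorted = snps.corr[np.ix_(order, order)]
    m = len(p_sorted)
    me_full = effective_tests(corr_sorted)
    terms = np.empty(m)
    for j in range(1, m + 1):
        me_j = effective_tests(corr_sorted[:j, :j]) if j > 1 else 1.0
        terms[j - 1] = me_full * p_sorted[j - 1] / me_j
    j_min = int(np.argmin(terms))  # argmin returns the first (smallest j) on ties
    p_gene = float(min(terms[j_min], 1.0))
    key = str(snps.snps["snp"].to_numpy()[order][j_min])
    return p_gene, key


def ld_blocks(snps: pd.DataFrame, ldstore: LdStore, r2_join: float = 0.8) -> list[list[int]]:
    """Greedy left-to-right LD-block partition of position-sorted SNPs.

    A SNP joins the current block iff its r² with the block's last member is
    ≥ ``r2_join``; otherwise it starts a new block.  Returns row-index lists.
    """
    ids = snps["snp"].tolist()
    blocks: list[list[int]] = [[0]]
    for i in range(1, len(ids)):
        last = blocks[-1][-1]
        if ldstore.get(ids[last], ids[i]) >= r2_join:
            blocks[-1].append(i)
        else:
            blocks.append([i])
    return blocks


def hyst(block_ps: np.ndarray, key_rho: np.ndarray) -> tuple[float, float, float, float]:
    """Scaled chi-square combination of per-block GATES p-values.

    T = −2 Σ ln p_k has mean E = 2K and, with Brown's approximation for the
    covariance between correlated −2 ln p terms, variance
    Var = 4K + 2 Σ_{i<j} ρ̂(3.25 + 0.75 ρ̂) with ρ̂ = max(ρ_ij, 0).
    The p-value is the upper tail of a chi-square with f = 2E²/Var degrees
    of freedom evaluated at T/c, c = Var/(2E).

    Returns (p, T, c, f).
    """
    block_ps = np.asarray(block_ps, dtype=float)
    k = block_ps.size
    if k < 1:
        raise ValueError("need ≥ 1 block")
    if np.any(block_ps <= 0):
        logger.warning("block p-value of 0 clamped to smallest positive float")
        block_ps = np.maximum(block_ps, _TINY_P)
    t = float(-2.0 * np.sum(np.log(block_ps)))
    e = 2.0 * k
    rho = np.clip(np.asarray(key_rho, dtype=float), 0.0, None)
    iu = np.triu_indices(k, 1)
    cov_sum = float(np.sum(rho[iu] * (3.25 + 0.75 * rho[iu])))
    var = 4.0 * k + 2.0 * cov_sum
    c = var / (2.0 * e)
    f = 2.0 * e**2 / var
    p = float(stats.chi2.sf(t / c, f))
    return min(max(p, _TINY_P), 1.0), t, c, f


def assign_snps_to_genes(
    gwas: GwasSnpTable,
    genes: GeneSet,
    ldstore: LdStore,
    flank_kb: float = 0.0,
    rho_fn: Callable[[float], float] = pvalue_correlation,
) -> tuple[dict[str, GeneSnpSet], list[str]]:
    """Assign SNPs to every gene whose (flanked) span contains them.

    A SNP inside two overlapping genes is assigned to both.  Returns the
    per-gene :class:`GeneSnpSet` map and the list of untested gene ids
    (genes with zero assigned SNPs).
    """
    flank = int(round(flank_kb * 1000))
    rec = gwas.records
    sets: dict[str, GeneSnpSet] = {}
    untested: list[str] = []
    for _, g in genes.genes.iterrows():
        lo, hi = g["start"] - flank, g["end"] + flank
        sel = (rec["chrom"].astype(str) == str(g["chrom"])) & (rec["bp"] >= lo) & (rec["bp"] <= hi)
        sub = rec.loc[sel, ["snp", "bp", "p"]].sort_values("bp", kind="stable").reset_index(drop=True)
        if len(sub) == 0:
            untested.append(g["gene_id"])
            continue
        ids = sub["snp"].tolist()
        m = len(ids)
        corr = np.eye(m)
        for i in range(m):
            for j in range(i + 1, m):
                corr[i, j] = corr[j, i] = rho_fn(ldstore.get(ids[i], ids[j]))
        sets[g["gene_id"]] = GeneSnpSet(g["gene_id"], sub, corr)
    return sets, untested


def gene_association(
    snp_set: GeneSnpSet, ldstore: LdStore, r2_join: float = 0.8,
    rho_fn: Callable[[float], float] = pvalue_correlation,
) -> GeneAssociation:
    """Full GATES + HYST evaluation of one gene."""
    p_gates, key_snp = gates(snp_set)
    blocks = ld_blocks(snp_set.snps, ldstore, r2_join=r2_join)
    block_ps, block_keys = [], []
    for rows in blocks:
        sub = GeneSnpSet(
            snp_set.gene_id,
            snp_set.snps.iloc[rows].reset_index(drop=True),
            snp_set.corr[np.ix_(rows, rows)],
        )
        bp, bkey = gates(sub)
        block_ps.append(bp)
        block_keys.append(bkey)
    k = len(blocks)
    key_rho = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            key_rho[i, j] = key_rho[j, i] = rho_fn(ldstore.get(block_keys[i], block_keys[j]))
    p_hyst, t, c, f = hyst(np.array(block_ps), key_rho)
    return GeneAssociation(
        gene_id=snp_set.gene_id,
        n_snps=len(snp_set.snps),
        p_gates=p_gates,
        key_snp=key_snp,
        p_hyst=p_hyst,
        n_blocks=k,
        block_key_snps=block_keys,
        me_full=effective_tests(snp_set.corr),
        hyst_stat=t,
        hyst_scale=c,
        hyst_df=f,
    )
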