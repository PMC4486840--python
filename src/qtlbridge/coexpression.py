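"""Coexpression and guilt-by-association screens.

Covers the downstream prioritization evidence: Pearson correlation matrices
with probe-count-adjusted significance, conditional (condition-wise)
coexpression values, probe-consistency and phenotype screens,
over-representation analysis with Benjamini–Hochberg adjustment, and PC1
synthetic traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ConditionMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "CoexpressionCallSet",
    "ConditionCoexpr",
    "EnrichmentResult",
    "PcaResult",
    "correlation_matrix",
    "coexpression_calls",
    "r_threshold",
    "consistent_probes",
    "phenotype_screen",
    "conditional_coexpression",
    "ora_enrichment",
    "pc1_trait",
]


@dataclass
class CorrelationResult:
    """Pairwise Pearson correlations with two-sided t-test p-values."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame  # samples per pair (pairwise-complete)
    flagged: list[str] = field(default_factory=list)  # zero-variance items


@dataclass
class CoexpressionCallSet:
    """Boolean coexpression calls under the conjunction rule.

    A pair is called iff |r| ≥ ``r_min`` and p ≤ ``adjusted_alpha`` with
    adjusted_alpha = alpha / n_probes (Bonferroni on the family alpha).
    """

    adjusted_alpha: float
    r_min: float
    r_threshold_at_n: float  # |r| implied by the adjusted alpha at the modal n
    calls: pd.DataFrame


@dataclass
class ConditionCoexpr:
    """Conditional coexpression of every gene with one target gene."""

    target: str
    n_target_up: int
    values: pd.Series  # gene -> joint-up fraction among target-up conditions
    p: pd.Series  # one-sided binomial upper tail
    joint_up: pd.Series
    defined: bool = True

    def common_set(self, value_min: float = 0.50, alpha: float = 0.05) -> list[str]:
        """Genes commonly coexpressed with the target (value and p gates)."""
        if not self.defined:
            return []
        sel = (self.values >= value_min) & (self.p <= alpha)
        return [g for g in self.values.index[sel] if g != self.target]


@dataclass
class EnrichmentResult:
    term: str
    universe_size: int
    term_size: int
    list_size: int
    overlap: int
    p: float
    q: float

    def __post_init__(self) -> None:
        if self.overlap > min(self.term_size, self.list_size):
            raise ValueError("overlap exceeds term/list size")
        if self.q < self.p - 1e-12:
            raise ValueError("BH q must be ≥ p")


@dataclass
class PcaResult:
    scores: pd.Series  # PC1 score per sample
    variance_fraction: float
    loadings: pd.Series  # unit-norm, oriented so the loading sum is ≥ 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.variance_fraction <= 1.0 + 1e-12):
            raise ValueError("variance fraction must lie in [0, 1]")


def correlation_matrix(values: pd.DataFrame) -> CorrelationResult:
    """Pairwise-complete Pearson correlations of items × samples data.

    p-values come from the t transform with pair-specific n; pairs with
    fewer than 3 shared samples, and items with zero variance, give NaN
    (zero-variance items are additionally flagged).
    """
    items = list(values.index)
    X = values.to_numpy(dtype=float)
    mask = ~np.isnan(X)
    m = len(items)
    r = np.full((m, m), np.nan)
    n = np.zeros((m, m), dtype=int)
    flagged = []
    for i in range(m):
        var_i = np.nanvar(X[i])
        if var_i == 0 or np.isnan(var_i):
            flagged.append(items[i])
    for i in range(m):
        r[i, i] = 1.0
        n[i, i] = int(mask[i].sum())
        for j in range(i + 1, m):
            shared = mask[i] & mask[j]
            nij = int(shared.sum())
            n[i, j] = n[j, i] = nij
            if nij < 3:
                continue
            xi, xj = X[i, shared], X[j, shared]
            si, sj = xi.std(), xj.std()
            if si == 0 or sj == 0:
                continue
            r[i, j] = r[j, i] = float(np.corrcoef(xi, xj)[0, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = np.clip(r, -1.0, 1.0)
        df = n - 2
        t = rr * np.sqrt(df / (1.0 - rr**2))
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
        p = np.where(np.isclose(np.abs(rr), 1.0), 0.0, p)
    np.fill_diagonal(p, 0.0)
    idx = pd.Index(items)
    return CorrelationResult(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
        flagged=flagged,
    )


def r_threshold(adjusted_alpha: float, n: int) -> float:
    """|r| needed to reach two-sided significance ``adjusted_alpha`` at n samples."""
    if n < 3:
        raise ValueError("need n ≥ 3")
    t_crit = stats.t.ppf(1.0 - adjusted_alpha / 2.0, n - 2)
    return float(t_crit / np.sqrt(n - 2 + t_crit**2))


def coexpression_calls(
    corr: CorrelationResult, alpha: float = 0.05, n_probes: int = 1, r_min: float = 0.5
) -> CoexpressionCallSet:
    """Call coexpressing pairs: |r| ≥ r_min and p ≤ alpha/n_probes."""
    if n_probes < 1:
        raise ValueError("n_probes must be ≥ 1")
    adjusted = alpha / n_probes
    calls = (corr.r.abs() >= r_min) & (corr.p <= adjusted)
    for item in corr.r.index:
        calls.loc[item, item] = False
    n_mode = int(pd.Series(corr.n.to_numpy()[np.triu_indices(len(corr.n), 1)]).mode().iloc[0]) if len(corr.n) > 1 else 0
    r_at_n = r_threshold(adjusted, n_mode) if n_mode >= 3 else float("nan")
    return CoexpressionCallSet(adjusted, r_min, r_at_n, calls)


def consistent_probes(
    expr: ExpressionMatrix, gene: str, r_min: float = 0.5, alpha: float = 0.05
) -> list[str]:
    """Probes of a gene that correlate (r ≥ r_min, p ≤ alpha) with ≥ 1 sibling.

    Exon probes are preferred; intron probes are used only when a gene has
    no exon probes.  Single-probe genes keep their probe with a logged caveat.
    """
    probes = expr.probes_for(gene, "exon") or expr.probes_for(gene, "intron")
    if not probes:
        raise ValueError(f"gene {gene} has no probes")
    if len(probes) == 1:
        logger.warning("gene %s has a single probe; consistency unverifiable", gene)
        return probes
    corr = correlation_matrix(expr.values.loc[probes])
    keep = []
    for probe in probes:
        others = [q for q in probes if q != probe]
        ok = (corr.r.loc[probe, others] >= r_min) & (corr.p.loc[probe, others] <= alpha)
        if ok.any():
            keep.append(probe)
    return keep


def phenotype_screen(
    probe_values: pd.DataFrame,
    phenotypes: pd.DataFrame,
    r_min: float = 0.5,
    alpha: float = 0.05,
) -> list[str]:
    """Phenotypes correlating with EVERY probe, with a consistent sign.

    ``probe_values`` is probes × strains, ``phenotypes`` is traits × strains
    (shared strain columns are used).  A phenotype is retained iff, against
    every probe, |r| ≥ r_min and p ≤ alpha, and all correlations share one
    sign.
    """
    if len(probe_values) < 1:
        raise ValueError("need ≥ 1 probe")
    shared = probe_values.columns.intersection(phenotypes.columns)
    kept = []
    for pheno in phenotypes.index:
        combined = pd.concat(
            [probe_values[shared], phenotypes.loc[[pheno], shared]], axis=0
        )
        corr = correlation_matrix(combined)
        rs = corr.r.loc[pheno, probe_values.index]
        ps = corr.p.loc[pheno, probe_values.index]
        if rs.isna().any():
            continue
        if ((rs.abs() >= r_min) & (ps <= alpha)).all() and (
            (rs > 0).all() or (rs < 0).all()
        ):
            kept.append(pheno)
    return kept


def conditional_coexpression(conds: ConditionMatrix, target: str) -> ConditionCoexpr:
    """Condition-wise coexpression of every gene with a target gene.

    The value for gene g is the fraction of the target's up-regulated
    conditions in which g is also up-regulated; its p-value is the one-sided
    binomial upper tail of the joint-up count at g's marginal up-frequency.
    """
    calls = conds.calls.astype(bool)
    if target not in calls.index:
        raise ValueError(f"target gene {target} not in condition matrix")
    target_up = calls.loc[target]
    n_t = int(target_up.sum())
    genes = calls.index
    if n_t == 0:
        logger.warning("target %s never up-regulated; values undefined", target)
        nan = pd.Series(np.nan, index=genes)
        return ConditionCoexpr(target, 0, nan, nan, nan, defined=False)
    joint = calls.loc[:, target_up].sum(axis=1)
    values = joint / n_t
    marginal = calls.mean(axis=1)
    p = pd.Series(
        stats.binom.sf(joint.to_numpy() - 1, n_t, marginal.to_numpy()), index=genes
    )
    return ConditionCoexpr(target, n_t, values.astype(float), p, joint, defined=True)


def ora_enrichment(
    gene_list: list[str], term_sets: dict[str, set[str]], universe: set[str]
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation analysis with BH adjustment.

    The p-value per term is P[X ≥ overlap] drawing ``len(gene_list)`` genes
    from the universe; q-values are Benjamini–Hochberg across all supplied
    terms; results are sorted by q then p.
    """
    gene_set = set(gene_list)
    if not gene_set:
        raise ValueError("empty gene list")
    if not gene_set <= universe:
        raise ValueError("gene list must be a subset of the universe")
    big_n, n_draw = len(universe), len(gene_set)
    names, ps, meta = [], [], []
    for term, members in term_sets.items():
        members = members & universe
        k_term = len(members)
        overlap = len(gene_set & members)
        p = float(stats.hypergeom.sf(overlap - 1, big_n, k_term, n_draw))
        names.append(term)
        ps.append(min(p, 1.0))
        meta.append((k_term, overlap))
    _, qs, _, _ = multipletests(ps, method="fdr_bh")
    results = [
        EnrichmentResult(term, big_n, k_term, n_draw, overlap, p, float(q))
        for term, p, q, (k_term, overlap) in zip(names, ps, qs, meta)
    ]
    results.sort(key=lambda r: (r.q, r.p))
    return results


def pc1_trait(values: pd.DataFrame, standardize: bool = True) -> PcaResult:
    """First principal component of samples × traits data as a synthetic trait.

    Columns are centered (and unit-scaled when ``standardize``, the default:
    traits are typically on heterogeneous scales).  The orientation is fixed
    so the loading sum is ≥ 0, making the score sign reproducible.
    """
    if values.shape[1] < 2:
        raise ValueError("need ≥ 2 traits")
    if values.shape[0] < 3:
        raise ValueError("need ≥ 3 samples")
    X = values.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = values.columns[np.flatnonzero(sd == 0)[0]]
            raise ValueError(f"constant column {bad!r} cannot be standardized")
        X = X / sd
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    loadings = vt[0]
    if loadings.sum() < 0:
        loadings = -loadings
    scores = X @ loadings
    var_frac = float(s[0] ** 2 / np.sum(s**2))
    return PcaResult(
        scores=pd.Series(scores, index=values.index),
        variance_fraction=var_frac,
        loadings=pd.Series(loadings, index=values.columns),
    )
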