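"""Cross-species candidate-gene prioritization.

Mouse QTL regions are intersected with a gene annotation and a one-to-one
homology map to define the set of human genes to test.  Each region gets its
own Bonferroni threshold, alpha / (n_homologs × n_tests) with n_tests = 2
(GATES and HYST), and a human gene is called a candidate when its better
gene-based p-value passes its region's threshold.

The homolog count n includes genes without any assigned SNP (untested genes
still count toward the correction), matching the convention of deriving the
threshold from the annotated homolog count rather than the tested-gene count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .assoc import GeneAssociation
from .containers import GeneSet, HomologyMap
from .qtl import QtlRegion

logger = logging.getLogger(__name__)

__all__ = [
    "RegionGeneSet",
    "CandidateCall",
    "homologs_in_region",
    "region_threshold",
    "call_candidates",
]


@dataclass
class RegionGeneSet:
    """Mouse genes under one QTL region and their human homologs."""

    region: QtlRegion
    mouse_gene_ids: list[str]
    human_gene_ids: list[str]
    gene_span_mb: tuple[float, float] | None  # min start, max end of the mouse genes

    @property
    def n(self) -> int:
        return len(self.human_gene_ids)


@dataclass
class CandidateCall:
    """One gene × region significance decision."""

    human_gene_id: str
    region_chrom: str
    threshold: float
    winning_test: str
    winning_p: float
    passed: bool

    def __post_init__(self) -> None:
        if self.passed != (self.winning_p <= self.threshold):
            raise ValueError("pass flag inconsistent with p vs threshold")


def homologs_in_region(
    region: QtlRegion, mouse_genes: GeneSet, homology: HomologyMap
) -> RegionGeneSet:
    """Collect mouse genes overlapping a region and map them to human ids.

    Any 1-bp overlap with the region span counts.  The gene-span (min start,
    max end of the overlapping mouse genes, in Mbp) is recorded for
    reporting — printed region bounds conventionally use gene positions
    rather than marker positions.
    """
    lo = region.start_mb * 1e6
    hi = region.end_mb * 1e6
    g = mouse_genes.genes
    sel = (g["chrom"].astype(str) == str(region.chrom)) & (g["start"] <= hi) & (g["end"] >= lo)
    hit = g.loc[sel]
    mouse_ids = hit["gene_id"].tolist()
    human_ids = [homology.mouse_to_human[m] for m in mouse_ids if m in homology]
    span = None
    if len(hit) > 0:
        span = (float(hit["start"].min()) / 1e6, float(hit["end"].max()) / 1e6)
    return RegionGeneSet(region, mouse_ids, human_ids, span)


def region_threshold(alpha: float, n_genes: int, n_tests: int = 2) -> float:
    """Region-specific Bonferroni threshold: alpha / (n_genes × n_tests)."""
    if n_genes < 1:
        raise ValueError("no testable genes in region")
    if n_tests < 1:
        raise ValueError("n_tests must be ≥ 1")
    return alpha / (n_genes * n_tests)


def call_candidates(
    region_sets: list[RegionGeneSet],
    associations: dict[str, GeneAssociation],
    alpha: float = 0.05,
    n_tests: int = 2,
) -> tuple[list[CandidateCall], list[str]]:
    """Apply region-specific thresholds and call candidate genes.

    Per region the threshold is alpha/(n × n_tests) with n the homolog
    count; a gene passes iff min(GATES p, HYST p) ≤ threshold.  A gene that
    appears in several regions (e.g. a parent region and its sub-region) is
    reported once per region against each region's own threshold.  Homologs
    without an association record count toward n but cannot pass (logged).

    Returns (all calls, sorted distinct passing gene ids).
    """
    calls: list[CandidateCall] = []
    candidates: set[str] = set()
    for rset in region_sets:
        if rset.n == 0:
            logger.warning("region %s has no homologous genes; skipped",
                           rset.region.chrom)
            continue
        thr = region_threshold(alpha, rset.n, n_tests)
        for gene in rset.human_gene_ids:
            assoc = associations.get(gene)
            if assoc is None:
                logger.info("homolog %s untested (no SNPs); counted toward n", gene)
                continue
            passed = bool(assoc.min_p <= thr)
            calls.append(
                CandidateCall(
                    human_gene_id=gene,
                    region_chrom=rset.region.chrom,
                    threshold=thr,
                    winning_test=assoc.winning_test,
                    winning_p=assoc.min_p,
                    passed=passed,
                )
            )
            if passed:
                candidates.add(gene)
    return calls, sorted(candidates)
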