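"""QTL mapping on recombinant-inbred strain means.

Single-marker regression of a strain-mean trait on the biallelic genotype
code x ∈ {-1, +1} ({B, D}) yields, per marker, a likelihood-ratio statistic

    LRS = n · ln(RSS₀ / RSS₁)

with RSS₀ the residual sum of squares of the intercept-only fit and RSS₁
that of the genotype fit, together with the additive coefficient
a = (mean_D − mean_B)/2 (so a < 0 means the B allele increases the trait).
LOD = LRS/4.61 is available as a derived view.

Genome-wide significance is assessed by permutation: trait values are
shuffled across strains, the genome is rescanned, and the maximum LRS of
each permutation is recorded; the threshold is an order statistic of these
maxima and a marker is significant iff its observed LRS strictly exceeds it.
Runs of significant markers become QTL regions, with nearby runs merged
into a parent region carrying the runs as sub-regions (the two-peak
structure often seen in dense RI scans).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, TraitTable

logger = logging.getLogger(__name__)

__all__ = [
    "QtlScan",
    "GenomeWideThreshold",
    "QtlRegion",
    "lrs_scan",
    "permutation_threshold",
    "significant_intervals",
    "consensus_regions",
    "filter_traits",
]

#: LRS → LOD conversion divisor (2·ln 10 ≈ 4.61, GeneNetwork convention)
LRS_PER_LOD = 4.61

#: RSS₁ floor as a fraction of RSS₀, to cap LRS at perfect fits
_RSS_FLOOR = 1e-12


@dataclass
class QtlScan:
    """Per-marker scan result for one trait."""

    trait_id: str
    table: pd.DataFrame  # index marker; columns chrom, Mb, lrs, additive, n_used

    @property
    def lod(self) -> pd.Series:
        return self.table["lrs"] / LRS_PER_LOD

    @property
    def max_lrs(self) -> float:
        return float(np.nanmax(self.table["lrs"].to_numpy()))


@dataclass
class GenomeWideThreshold:
    """Permutation-derived genome-wide LRS threshold."""

    alpha: float
    n_perm: int
    threshold: float
    max_lrs_sample: np.ndarray  # retained for audit
    seed: int

    def __post_init__(self) -> None:
        k = math.ceil((1.0 - self.alpha) * self.n_perm)
        expected = float(np.sort(self.max_lrs_sample)[k - 1])
        if not np.isclose(self.threshold, expected):
            raise ValueError("threshold does not match the stated order statistic")


@dataclass
class QtlRegion:
    """A significant QTL interval (marker-span convention, Mbp)."""

    chrom: str
    start_mb: float
    end_mb: float
    peak_marker: str
    peak_lrs: float
    peak_mb: float
    sub_regions: list["QtlRegion"] = field(default_factory=list)
    support: int = 1

    def __post_init__(self) -> None:
        if not (self.start_mb <= self.peak_mb <= self.end_mb):
            raise ValueError("peak position must lie within the region span")


def _aligned_arrays(geno: GenotypeMatrix, trait: TraitTable) -> tuple[np.ndarray, np.ndarray, list[str]]:
    shared = [s for s in geno.strains if s in trait.values.index]
    if len(shared) < 8:
        raise ValueError(f"need ≥ 8 shared strains for mapping, got {len(shared)}")
    X = geno.calls[shared].to_numpy(dtype=float)  # markers × strains
    y = trait.values[shared].to_numpy(dtype=float)
    return X, y, shared

def _scan_stats(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-marker regression of each column of Y on each row of X.

    X is markers × strains with entries in {-1, +1, NaN}; Y is strains × k.
    Returns (LRS, slope, n_used) each of shape markers × k.  Markers where a
    single allele class remains among non-missing strains give NaN.
    """
    mask = ~np.isnan(X)
    Xz = np.where(mask, X, 0.0)
    M = mask.astype(float)
    n = M @ np.ones((Y.shape[0], 1))  # markers × 1
    s1 = M @ Y                        # Σ y over non-missing strains
    s2 = M @ (Y**2)
    sx = Xz.sum(axis=1, keepdims=True)  # Σ x  (x² = 1 where present)
    sxy = Xz @ Y
    syy = s2 - s1**2 / n
    sxx = n - sx**2 / n
    sxy_c = sxy - sx * s1 / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rss1 = syy - sxy_c**2 / sxx
        slope = sxy_c / sxx
    # degenerate markers: all lines one allele class
    degenerate = (sxx <= 0) | (n < 2)
    rss0 = syy
    # zero trait variance -> all-zero scan
    zerovar = rss0 <= 0
    rss1 = np.maximum(rss1, _RSS_FLOOR * rss0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lrs = n * np.log(rss0 / rss1)
    lrs = np.where(zerovar, 0.0, lrs)
    slope = np.where(zerovar, 0.0, slope)
    lrs = np.where(degenerate, np.nan, lrs)
    slope = np.where(degenerate, np.nan, slope)
    return lrs, slope, np.broadcast_to(n, lrs.shape).copy()


def lrs_scan(geno: GenotypeMatrix, trait: TraitTable) -> QtlScan:
    """Scan every marker for linkage with a strain-mean trait."""
    X, y, shared = _aligned_arrays(geno, trait)
    if np.var(y) == 0:
        logger.warning("trait %s has zero variance; scan is all-zero", trait.trait_id)
    lrs, slope, n_used = _scan_stats(X, y[:, None])
    table = pd.DataFrame(
        {
            "chrom": geno.markers["chrom"],
            "Mb": geno.markers["Mb"],
            "lrs": lrs[:, 0],
            "additive": slope[:, 0],
            "n_used": n_used[:, 0].astype(int),
        },
        index=geno.markers.index,
    )
    return QtlScan(trait.trait_id, table)


def permutation_threshold(
    geno: GenotypeMatrix,
    trait: TraitTable,
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
    batch: int = 1000,
) -> GenomeWideThreshold:
    """Genome-wide LRS threshold from trait-value permutations.

    Each permutation shuffles trait values across strains (one shared
    shuffled order per genome scan) and records the genome-wide maximum LRS;
    the threshold is the k-th smallest of the maxima, k = ceil((1−alpha)·n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be ≥ 100")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    X, y, _ = _aligned_arrays(geno, trait)
    if len(np.unique(y)) < 2:
        raise ValueError("trait must take at least 2 distinct values")
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    done = 0
    while done < n_perm:
        k = min(batch, n_perm - done)
        Y = np.empty((len(y), k))
        for j in range(k):
            Y[:, j] = rng.permutation(y)
        lrs, _, _ = _scan_stats(X, Y)
        maxima[done : done + k] = np.nanmax(lrs, axis=0)
        done += k
    k_stat = math.ceil((1.0 - alpha) * n_perm)
    threshold = float(np.sort(maxima)[k_stat - 1])
    return GenomeWideThreshold(alpha, n_perm, threshold, maxima, seed)


def _run_to_region(scan: QtlScan, idx: np.ndarray) -> QtlRegion:
    sub = scan.table.iloc[idx]
    peak_pos = int(np.argmax(sub["lrs"].to_numpy()))
    peak = sub.iloc[peak_pos]
    return QtlRegion(
        chrom=str(peak["chrom"]),
        start_mb=float(sub["Mb"].iloc[0]),
        end_mb=float(sub["Mb"].iloc[-1]),
        peak_marker=str(sub.index[peak_pos]),
        peak_lrs=float(peak["lrs"]),
        peak_mb=float(peak["Mb"]),
    )


def significant_intervals(
    scan: QtlScan, threshold: float, max_gap_markers: int = 0
) -> list[QtlRegion]:
    """Extract QTL regions as maximal runs of markers with LRS > threshold.

    Two runs on the same chromosome separated by at most ``max_gap_markers``
    sub-threshold markers merge into one parent region that carries both runs
    as sub-regions (each with its own peak).
    """
    regions: list[QtlRegion] = []
    table = scan.table
    for chrom in table["chrom"].unique():
        pos = np.flatnonzero((table["chrom"] == chrom).to_numpy())
        lrs = table["lrs"].to_numpy()[pos]
        sig = np.flatnonzero(np.nan_to_num(lrs, nan=-np.inf) > threshold)
        if sig.size == 0:
            continue
        # maximal runs of consecutive significant markers (chromosome-local idx)
        runs: list[np.ndarray] = []
        start = 0
        for i in range(1, sig.size + 1):
            if i == sig.size or sig[i] != sig[i - 1] + 1:
                runs.append(sig[start:i])
                start = i
        # merge runs separated by <= max_gap_markers sub-threshold markers
        groups: list[list[np.ndarray]] = [[runs[0]]]
        for run in runs[1:]:
            gap = run[0] - groups[-1][-1][-1] - 1
            if gap <= max_gap_markers:
                groups[-1].append(run)
            else:
                groups.append([run])
        for group in groups:
            subs = [_run_to_region(scan, pos[r]) for r in group]
            if len(subs) == 1:
                regions.append(subs[0])
            else:
                best = max(subs, key=lambda r: r.peak_lrs)
                regions.append(
                    QtlRegion(
                        chrom=subs[0].chrom,
                        start_mb=subs[0].start_mb,
                        end_mb=subs[-1].end_mb,
                        peak_marker=best.peak_marker,
                        peak_lrs=best.peak_lrs,
                        peak_mb=best.peak_mb,
                        sub_regions=subs,
                    )
                )
    return regions


def consensus_regions(per_trait_regions: list[list[QtlRegion]]) -> list[QtlRegion]:
    """Union-merge overlapping regions across traits on the same chromosome.

    The consensus span is (min start, max end) over the merged regions; the
    ``support`` field counts contributing trait-level regions.
    """
    flat = [r for regions in per_trait_regions for r in regions]
    out: list[QtlRegion] = []
    by_chrom: dict[str, list[QtlRegion]] = {}
    for r in flat:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, regs in by_chrom.items():
        regs.sort(key=lambda r: (r.start_mb, r.end_mb))
        current: list[QtlRegion] = []
        for r in regs:
            if current and r.start_mb <= max(c.end_mb for c in current):
                current.append(r)
            else:
                if current:
                    out.append(_merge_group(chrom, current))
                current = [r]
        if current:
            out.append(_merge_group(chrom, current))
    return out


def _merge_group(chrom: str, group: list[QtlRegion]) -> QtlRegion:
    best = max(group, key=lambda r: r.peak_lrs)
    return QtlRegion(
        chrom=chrom,
        start_mb=min(r.start_mb for r in group),
        end_mb=max(r.end_mb for r in group),
        peak_marker=best.peak_marker,
        peak_lrs=best.peak_lrs,
        peak_mb=best.peak_mb,
        support=len(group),
    )


def filter_traits(
    traits: list[TraitTable],
    scans: list[QtlScan],
    thresholds: list[GenomeWideThreshold],
) -> list[TraitTable]:
    """Keep traits with ≥ 1 marker exceeding their own genome-wide threshold."""
    if not (len(traits) == len(scans) == len(thresholds)):
        raise ValueError("traits, scans and thresholds must align")
    kept = []
    for trait, scan, thr in zip(traits, scans, thresholds):
        lrs = np.nan_to_num(scan.table["lrs"].to_numpy(), nan=-np.inf)
        if np.any(lrs > thr.threshold):
            kept.append(trait)
    return kept
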