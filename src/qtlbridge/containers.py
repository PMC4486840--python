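"""In-memory data model shared across the pipeline stages.

Conventions used throughout the package:

* Genotype calls for a recombinant-inbred (RI) panel are coded numerically as
  -1 for the B parental homozygote, +1 for the D parental homozygote, and NaN
  for missing (heterozygous or unknown calls collapse to missing — RI lines
  are expected homozygous).
* All genomic coordinates are 1-based inclusive internally.  The only place a
  0-based convention appears is the BED reader/writer in :mod:`qtlbridge.io`.
* QTL region spans are expressed in Mbp; gene coordinates in bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "TraitTable",
    "GwasSnpTable",
    "LdStore",
    "GeneSet",
    "HomologyMap",
    "ExpressionMatrix",
    "ConditionMatrix",
]

#: numeric codes for the two parental allele states
B_CODE = -1.0
D_CODE = 1.0


@dataclass
class GenotypeMatrix:
    """RI strains × markers genotype table.

    Parameters
    ----------
    markers : pandas.DataFrame
        Indexed by marker (locus) id, with columns ``chrom`` (str), ``cM``
        (float, genetic position) and ``Mb`` (float, physical position).
        Markers appear in map order, positions strictly increasing within a
        chromosome.
    calls : pandas.DataFrame
        Markers × strains; entries in {-1.0, +1.0, NaN} (B / D / missing).
    """

    markers: pd.DataFrame
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.markers.index.equals(self.calls.index):
            raise ValueError("markers and calls must share the same marker index")
        if self.calls.columns.duplicated().any():
            raise ValueError("duplicate strain ids")
        if self.markers.index.duplicated().any():
            raise ValueError("duplicate marker ids")
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            pos = sub["Mb"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"marker positions not strictly increasing on chromosome {chrom}"
                )
        vals = self.calls.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == B_CODE) | (vals == D_CODE)
        if not ok.all():
            raise ValueError("genotype codes must be -1, +1 or NaN")

    @property
    def strains(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def chromosome(self, chrom: str) -> "GenotypeMatrix":
        """Sub-matrix restricted to one chromosome."""
        keep = self.markers["chrom"] == chrom
        return GenotypeMatrix(self.markers.loc[keep], self.calls.loc[keep])


@dataclass
class TraitTable:
    """A strain-mean quantitative trait (one value per RI line)."""

    trait_id: str
    values: pd.Series  # strain -> trait value
    metadata: str = ""

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate strain ids in trait table")
        self.values = self.values.astype(float)


@dataclass
class GwasSnpTable:
    """GWAS SNP summary statistics: one p-value per SNP.

    ``records`` has columns ``snp`` (unique id), ``chrom``, ``bp`` (1-based
    position) and ``p``.  ``n_dropped`` counts input rows discarded for
    out-of-range p-values.
    """

    records: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        req = {"snp", "chrom", "bp", "p"}
        if not req.issubset(self.records.columns):
            raise ValueError(f"GwasSnpTable requires columns {sorted(req)}")
        if self.records["snp"].duplicated().any():
            dup = self.records.loc[self.records["snp"].duplicated(), "snp"].iloc[0]
            raise ValueError(f"duplicated snp id: {dup}")
        p = self.records["p"].to_numpy(dtype=float)
        if np.any((p <= 0) | (p > 1)):
            raise ValueError("p-values must lie in (0, 1]")
        if np.any(self.records["bp"].to_numpy() <= 0):
            raise ValueError("positions must be positive")

    def __len__(self) -> int:
        return len(self.records)


class LdStore:
    """Symmetric store of pairwise LD r² keyed by SNP-id pairs.

    Absent pairs return r² = 0 by contract (public LD dumps omit distant
    pairs; treating them as independent is conservative for GATES).
    """

    def __init__(self) -> None:
        self._r2: dict[frozenset[str], float] = {}

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r² out of [0, 1]: {r2}")
        if a == b:
            return
        self._r2[frozenset((a, b))] = float(r2)

    def get(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    def items(self):
        for key, r2 in self._r2.items():
            a, b = sorted(key)
            yield a, b, r2


@dataclass
class GeneSet:
    """Gene annotation table: id, symbol, chromosome, 1-based inclusive span."""

    genes: pd.DataFrame  # columns: gene_id, symbol, chrom, start, end, strand

    def __post_init__(self) -> None:
        req = {"gene_id", "symbol", "chrom", "start", "end", "strand"}
        if not req.issubset(self.genes.columns):
            raise ValueError(f"GeneSet requires columns {sorted(req)}")
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids")
        bad = self.genes["start"] > self.genes["end"]
        if bad.any():
            gid = self.genes.loc[bad, "gene_id"].iloc[0]
            raise ValueError(f"gene {gid} has start > end")

    def __len__(self) -> int:
        return len(self.genes)


class HomologyMap:
    """One-to-one mouse ↔ human gene-id mapping (injective both ways)."""

    def __init__(self) -> None:
        self.mouse_to_human: dict[str, str] = {}
        self.human_to_mouse: dict[str, str] = {}

    def add(self, mouse_id: str, human_id: str) -> None:
        if mouse_id in self.mouse_to_human or human_id in self.human_to_mouse:
            raise ValueError(f"homology map not injective at ({mouse_id}, {human_id})")
        self.mouse_to_human[mouse_id] = human_id
        self.human_to_mouse[human_id] = mouse_id

    def __len__(self) -> int:
        return len(self.mouse_to_human)

    def __contains__(self, mouse_id: str) -> bool:
        return mouse_id in self.mouse_to_human


@dataclass
class ExpressionMatrix:
    """Probe-level expression (log2 intensity scale), probes × strains.

    ``annotation`` maps every probe to a gene and a region type (exon or
    intron); exon probes are preferred downstream, intron probes are used
    when a gene has no exon probes.
    """

    values: pd.DataFrame  # probes × strains
    annotation: pd.DataFrame  # index probe, columns gene_id, region_type

    def __post_init__(self) -> None:
        missing = self.values.index.difference(self.annotation.index)
        if len(missing) > 0:
            raise ValueError(f"probe {missing[0]!r} has no annotation")
        bad = ~self.annotation["region_type"].isin(["exon", "intron"])
        if bad.any():
            raise ValueError("region_type must be 'exon' or 'intron'")

    def probes_for(self, gene_id: str, region_type: str | None = None) -> list[str]:
        ann = self.annotation.loc[self.annotation.index.intersection(self.values.index)]
        sel = ann["gene_id"] == gene_id
        if region_type is not None:
            sel &= ann["region_type"] == region_type
        return list(ann.index[sel])


@dataclass
class ConditionMatrix:
    """Binary gene × condition up-regulation calls (two-fold threshold)."""

    calls: pd.DataFrame  # genes × conditions, values in {0, 1}

    def __post_init__(self) -> None:
        vals = self.calls.to_numpy()
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("condition calls must be 0/1")
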