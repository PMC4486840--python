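"""Readers and writers for the plain-text dialects the pipeline consumes.

Formats: GeneNetwork-style ``.geno`` genotype TSV, two-column strain-mean
trait TSV, whitespace GWAS summary tables, HapMap pairwise-LD text, BED4+,
three-column homology tables, and expression / probe-annotation / condition
TSVs.  All writers emit ``#`` header lines recording the tool version; all
readers validate rather than silently coerce, and count every dropped row.

Coordinates are 1-based inclusive internally; the BED reader/writer is the
only conversion site (BED is 0-based half-open).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    B_CODE,
    D_CODE,
    ConditionMatrix,
    ExpressionMatrix,
    GeneSet,
    GenotypeMatrix,
    GwasSnpTable,
    HomologyMap,
    LdStore,
    TraitTable,
)

logger = logging.getLogger(__name__)

_VERSION_HEADER = "# qtlbridge"

_ALLELE_TO_CODE = {"B": B_CODE, "D": D_CODE, "H": np.nan, "U": np.nan}
_CODE_TO_ALLELE = {B_CODE: "B", D_CODE: "D"}

# accepted header synonyms for GWAS summary tables (case-insensitive)
_GWAS_SYNONYMS = {
    "snp": {"snpid", "snp", "rsid"},
    "chrom": {"chr", "hg18chr", "chrom"},
    "bp": {"bp", "pos", "position"},
    "p": {"pval", "p", "pvalue"},
}


def _header_lines(extra: dict | None = None) -> list[str]:
    lines = [f"{_VERSION_HEADER} 0.1.0"]
    for key, val in (extra or {}).items():
        lines.append(f"# {key}: {val}")
    return lines


# ---------------------------------------------------------------------------
# genotypes (.geno dialect)
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a GeneNetwork-like ``.geno`` TSV.

    Lines starting with ``#`` or ``@`` are skipped.  Columns are
    ``Chr  Locus  cM  Mb`` followed by one column per strain; cells are
    ``B``/``D`` (kept) or ``H``/``U`` (stored as missing).
    """
    rows = []
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("@"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header[:4] != ["Chr", "Locus", "cM", "Mb"]:
                    raise ValueError(
                        f"{path}: expected columns Chr, Locus, cM, Mb; got {header[:4]}"
                    )
                continue
            if len(fields) != len(header):
                raise ValueError(f"{path}:{lineno}: wrong field count")
            rows.append((lineno, fields))
    if header is None:
        raise ValueError(f"{path}: no header line found")
    strains = header[4:]
    marker_rows, call_rows, index = [], [], []
    for lineno, fields in rows:
        chrom, locus = fields[0], fields[1]
        try:
            cm, mb = float(fields[2]), float(fields[3])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed position field") from exc
        codes = []
        for col, cell in zip(strains, fields[4:]):
            if cell not in _ALLELE_TO_CODE:
                raise ValueError(
                    f"{path}:{lineno}: unknown allele code {cell!r} in column {col}"
                )
            codes.append(_ALLELE_TO_CODE[cell])
        index.append(locus)
        marker_rows.append({"chrom": chrom, "cM": cm, "Mb": mb})
        call_rows.append(codes)
    markers = pd.DataFrame(marker_rows, index=pd.Index(index, name="locus"))
    calls = pd.DataFrame(call_rows, index=markers.index, columns=strains, dtype=float)
    return GenotypeMatrix(markers, calls)


def write_genotypes(geno: GenotypeMatrix, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        for line in _header_lines({"seed": seed} if seed is not None else None):
            fh.write(line + "\n")
        fh.write("\t".join(["Chr", "Locus", "cM", "Mb", *geno.strains]) + "\n")
        for locus, row in geno.markers.iterrows():
            cells = [
                _CODE_TO_ALLELE.get(v, "U") if not np.isnan(v) else "U"
                for v in geno.calls.loc[locus].to_numpy(dtype=float)
            ]
            fh.write(
                "\t".join(
                    [str(row["chrom"]), str(locus), repr(float(row["cM"])),
                     repr(float(row["Mb"])), *cells]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# strain-mean traits
# ---------------------------------------------------------------------------

def read_trait(path: str | Path) -> TraitTable:
    """Read a two-column (strain, value) TSV; ``# trait:`` header names it."""
    trait_id, metadata = Path(path).stem, ""
    strains, values = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("#"):
                if line.startswith("# trait:"):
                    trait_id = line.split(":", 1)[1].strip()
                elif line.startswith("# metadata:"):
                    metadata = line.split(":", 1)[1].strip()
                continue
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            try:
                values.append(float(fields[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed value") from exc
            strains.append(fields[0])
    return TraitTable(trait_id, pd.Series(values, index=strains), metadata)


def write_trait(trait: TraitTable, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        for line in _header_lines({"seed": seed} if seed is not None else None):
            fh.write(line + "\n")
        fh.write(f"# trait: {trait.trait_id}\n")
        if trait.metadata:
            fh.write(f"# metadata: {trait.metadata}\n")
        for strain, value in trait.values.items():
            fh.write(f"{strain}\t{value!r}\n")


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def read_gwas_summary(path: str | Path) -> GwasSnpTable:
    """Read a whitespace/tab GWAS summary table.

    Required columns are located case-insensitively among synonyms
    (snpid|snp|rsid, chr|hg18chr, bp|pos, pval|p|pvalue); extra columns are
    ignored.  Rows with p outside (0, 1] are dropped and counted.
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#", dtype=str)
    colmap: dict[str, str] = {}
    lowered = {c.lower(): c for c in df.columns}
    for target, names in _GWAS_SYNONYMS.items():
        found = [lowered[n] for n in names if n in lowered]
        if not found:
            raise ValueError(
                f"{path}: missing required column {target} "
                f"(accepted: {sorted(names)}); found headers {list(df.columns)}"
            )
        colmap[target] = found[0]
    out = pd.DataFrame(
        {
            "snp": df[colmap["snp"]],
            "chrom": df[colmap["chrom"]],
            "bp": pd.to_numeric(df[colmap["bp"]], errors="raise").astype(int),
            "p": pd.to_numeric(df[colmap["p"]], errors="raise").astype(float),
        }
    )
    keep = (out["p"] > 0) & (out["p"] <= 1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: dropped %d rows with p outside (0, 1]", path, n_dropped)
    out = out.loc[keep].reset_index(drop=True)
    return GwasSnpTable(out, n_dropped=n_dropped)


def write_gwas_summary(table: GwasSnpTable, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        for line in _header_lines({"seed": seed} if seed is not None else None):
            fh.write(line + "\n")
        fh.write("snpid\tchr\tbp\tpval\n")
        for _, row in table.records.iterrows():
            fh.write(f"{row['snp']}\t{row['chrom']}\t{int(row['bp'])}\t{row['p']!r}\n")


# ---------------------------------------------------------------------------
# HapMap pairwise LD
# ---------------------------------------------------------------------------

def read_hapmap_ld(path: str | Path) -> LdStore:
    """Read HapMap LD text: pos1 pos2 population rs1 rs2 D' r² LOD fbin.

    Only rs1, rs2 and r² are retained; the store is symmetric and returns 0
    for unseen pairs.
    """
    store = LdStore()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 7:
                raise ValueError(f"{path}:{lineno}: expected ≥ 7 whitespace fields")
            rs1, rs2 = fields[3], fields[4]
            try:
                r2 = float(fields[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed r² field") from exc
            if not (0.0 <= r2 <= 1.0):
                raise ValueError(f"{path}:{lineno}: r² outside [0, 1]: {r2}")
            store.set(rs1, rs2, r2)
    return store


def write_hapmap_ld(store: LdStore, positions: dict[str, int], path: str | Path,
                    population: str = "CEU") -> None:
    """Write the LD store in the HapMap text dialect (D' and LOD are padded)."""
    with open(path, "w") as fh:
        for a, b, r2 in store.items():
            pos_a, pos_b = positions.get(a, 0), positions.get(b, 0)
            fh.write(f"{pos_a} {pos_b} {population} {a} {b} {np.sqrt(r2)!r} {r2!r} 0 0\n")


# ---------------------------------------------------------------------------
# gene annotations (BED) and homology
# ---------------------------------------------------------------------------

def read_gene_bed(path: str | Path, species: str = "mouse") -> GeneSet:
    """Read BED4+ gene annotations, converting to 1-based inclusive."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: BED requires ≥ 4 columns")
            chrom, name = fields[0], fields[3]
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            start, end = start0 + 1, end0  # 0-based half-open -> 1-based inclusive
            if start > end:
                raise ValueError(f"{path}:{lineno}: empty/negative interval")
            strand = fields[5] if len(fields) > 5 else "+"
            symbol = fields[6] if len(fields) > 6 else name
            rows.append(
                {"gene_id": name, "symbol": symbol, "chrom": chrom,
                 "start": start, "end": end, "strand": strand}
            )
    cols = ["gene_id", "symbol", "chrom", "start", "end", "strand"]
    return GeneSet(pd.DataFrame(rows, columns=cols))


def write_gene_bed(genes: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for _, row in genes.genes.iterrows():
            fh.write(
                f"{row['chrom']}\t{row['start'] - 1}\t{row['end']}\t{row['gene_id']}"
                f"\t0\t{row['strand']}\t{row['symbol']}\n"
            )


def read_homology(path: str | Path) -> HomologyMap:
    """Read a 3-column homology table: group id, taxon (mouse|human), gene id.

    Groups with exactly one mouse and one human member become map entries;
    other groups are logged and skipped.
    """
    groups: dict[str, dict[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            group, taxon, gene = fields
            if taxon not in ("mouse", "human"):
                raise ValueError(f"{path}:{lineno}: unknown taxon {taxon!r}")
            groups.setdefault(group, {"mouse": [], "human": []})[taxon].append(gene)
    hmap = HomologyMap()
    n_skipped = 0
    for group, members in groups.items():
        if len(members["mouse"]) == 1 and len(members["human"]) == 1:
            hmap.add(members["mouse"][0], members["human"][0])
        else:
            n_skipped += 1
            logger.info("homology group %s skipped (not 1 mouse + 1 human)", group)
    if n_skipped:
        logger.warning("%s: skipped %d non-1:1 homology groups", path, n_skipped)
    return hmap


def write_homology(hmap: HomologyMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (mouse_id, human_id) in enumerate(sorted(hmap.mouse_to_human.items())):
            fh.write(f"grp{i}\tmouse\t{mouse_id}\n")
            fh.write(f"grp{i}\thuman\t{human_id}\n")


# ---------------------------------------------------------------------------
# expression and condition matrices
# ---------------------------------------------------------------------------

def read_expression(matrix_path: str | Path, annotation_path: str | Path) -> ExpressionMatrix:
    """Join a probes × strains TSV with a probe annotation TSV."""
    values = pd.read_csv(matrix_path, sep="\t", comment="#", index_col=0)
    ann = pd.read_csv(annotation_path, sep="\t", comment="#", index_col=0)
    if not {"gene_id", "region_type"}.issubset(ann.columns):
        raise ValueError(f"{annotation_path}: requires columns gene_id, region_type")
    return ExpressionMatrix(values.astype(float), ann)


def write_expression(expr: ExpressionMatrix, matrix_path: str | Path,
                     annotation_path: str | Path, seed: int | None = None) -> None:
    with open(matrix_path, "w") as fh:
        for line in _header_lines({"seed": seed} if seed is not None else None):
            fh.write(line + "\n")
        expr.values.to_csv(fh, sep="\t", index_label="probe")
    with open(annotation_path, "w") as fh:
        for line in _header_lines():
            fh.write(line + "\n")
        expr.annotation.to_csv(fh, sep="\t", index_label="probe")


def read_conditions(path: str | Path) -> ConditionMatrix:
    calls = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return ConditionMatrix(calls.astype(int))


def write_conditions(conds: ConditionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for line in _header_lines():
            fh.write(line + "\n")
        conds.calls.to_csv(fh, sep="\t", index_label="gene")
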