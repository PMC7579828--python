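"""Readers and writers for the file formats the evaluation touches.

Pedigrees and phenotypes travel as CSV, genotypes as PLINK ``.raw`` text or
VCF, gene annotations as BED or GFF3.  All readers validate strictly and all
coordinates are normalized to a single internal convention: 1-based, closed
intervals (the GFF3 convention); BED's 0-based half-open intervals are
converted on ingest.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

#: Sentinel for an unknown parent after normalization.
UNKNOWN_PARENT = ""

_MISSING_PARENT_CODES = {"", "0", "NA", ".", "nan"}


class PedigreeError(ValueError):
    """Malformed pedigree: duplicate ids, cycles, or undeclared parents."""


class ParseError(ValueError):
    """Malformed genotype/annotation input, carrying a line number."""


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass
class PedigreeTable:
    """Topologically sorted pedigree (parents precede offspring).

    Attributes
    ----------
    table : pandas.DataFrame
        Columns ``animal``, ``sire``, ``dam`` (missing parent = "").
        May carry extra metadata columns (e.g. ``sex``, ``birth_date``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)

    @property
    def animals(self) -> pd.Index:
        return pd.Index(self.table["animal"])

    def __len__(self) -> int:
        return len(self.table)

    def index_of(self) -> dict[str, int]:
        """Map animal id -> row position (also the A-matrix index)."""
        return {a: i for i, a in enumerate(self.table["animal"])}

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Sire/dam row positions (-1 for unknown), in table order."""
        idx = self.index_of()
        sire = np.array([idx.get(s, -1) if s else -1 for s in self.table["sire"]])
        dam = np.array([idx.get(d, -1) if d else -1 for d in self.table["dam"]])
        return sire, dam


def _normalize_parent(value: object) -> str:
    s = "" if value is None else str(value).strip()
    return UNKNOWN_PARENT if s in _MISSING_PARENT_CODES else s


def build_pedigree(df: pd.DataFrame) -> PedigreeTable:
    """Validate and topologically sort an animal/sire/dam frame.

    Raises
    ------
    PedigreeError
        On duplicate animal ids or a parentage cycle (the cycle is named).
    """
    df = df.copy()
    df["animal"] = df["animal"].astype(str).str.strip()
    for col in ("sire", "dam"):
        df[col] = df[col].map(_normalize_parent) if col in df else UNKNOWN_PARENT

    dup = df["animal"][df["animal"].duplicated()]
    if len(dup):
        raise PedigreeError(f"duplicate animal ids: {sorted(set(dup))[:5]}")

    known = set(df["animal"])
    # Parents that never appear as animals get phantom founder rows (closure).
    phantoms = sorted(
        {p for col in ("sire", "dam") for p in df[col] if p and p not in known}
    )
    if phantoms:
        df = pd.concat(
            [pd.DataFrame({"animal": phantoms, "sire": "", "dam": ""}), df],
            ignore_index=True,
        )

    g = nx.DiGraph()
    g.add_nodes_from(df["animal"])
    for _, row in df.iterrows():
        for p in (row["sire"], row["dam"]):
            if p:
                g.add_edge(p, row["animal"])
    try:
        order = list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(g)
        raise PedigreeError(f"pedigree cycle detected: {cycle}") from None
    rank = {a: i for i, a in enumerate(order)}
    df = df.sort_values("animal", kind="stable", key=lambda s: s.map(rank))
    return PedigreeTable(df.reset_index(drop=True))


def read_pedigree(path) -> PedigreeTable:
    """Read an ``animal,sire,dam`` CSV into a validated, sorted pedigree."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"animal", "sire", "dam"}
    if not required.issubset(df.columns):
        raise PedigreeError(f"pedigree CSV must have columns {sorted(required)}")
    return build_pedigree(df)


def write_pedigree(ped: PedigreeTable, path) -> None:
    ped.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Allele-count matrix (animals x SNPs) with marker metadata.

    ``counts`` holds 0/1/2 copies of the counted allele as float, with
    ``numpy.nan`` for missing calls.  ``snps`` has columns ``snp``,
    ``chrom``, ``pos`` (1-based bp), ``a1`` (counted allele), ``a2``.
    """

    animals: pd.Index
    snps: pd.DataFrame
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.animals = pd.Index(self.animals)
        if self.counts.shape != (len(self.animals), len(self.snps)):
            raise ValueError("genotype matrix dimensions inconsistent")
        if (self.snps["pos"].to_numpy() < 0).any():
            raise ValueError("negative SNP positions")

    def subset(self, animal_mask=None, snp_mask=None) -> "GenotypeMatrix":
        am = slice(None) if animal_mask is None else animal_mask
        sm = slice(None) if snp_mask is None else snp_mask
        return GenotypeMatrix(
            self.animals[am],
            self.snps.iloc[sm].reset_index(drop=True)
            if snp_mask is not None
            else self.snps,
            self.counts[am][:, sm],
        )


def read_genotypes(path, format: str = "plink_raw") -> GenotypeMatrix:
    """Read genotypes from PLINK ``.raw`` text or a (plain-text) VCF.

    VCF GT fields "0/1", "1/0" and "0|1" all count 1 copy; missing GT
    becomes NaN.
    """
    if format == "plink_raw":
        return _read_plink_raw(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_plink_raw(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+")
    meta_cols = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if df.columns[: len(meta_cols)].tolist() != meta_cols:
        raise ParseError(
            "line 1: PLINK .raw header must start with "
            "FID IID PAT MAT SEX PHENOTYPE"
        )
    snp_cols = df.columns[len(meta_cols):]
    snp_names, a1 = [], []
    for c in snp_cols:
        name, _, allele = c.rpartition("_")
        if not name:
            raise ParseError(f"SNP column {c!r} lacks the _A1 allele suffix")
        snp_names.append(name)
        a1.append(allele)
    counts = df[snp_cols].to_numpy(dtype=float)
    bad = ~(np.isnan(counts) | np.isin(counts, (0.0, 1.0, 2.0)))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ParseError(f"line {r + 2}: allele count {counts[r, c]} not in 0/1/2")
    snps = pd.DataFrame(
        {"snp": snp_names, "chrom": "0", "pos": np.arange(1, len(snp_names) + 1),
         "a1": a1, "a2": "?"}
    )
    return GenotypeMatrix(pd.Index(df["IID"].astype(str)), snps, counts)


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    animals = pd.Index([str(s) for s in vcf.samples])
    rows, meta = [], []
    for var in vcf:
        counts = np.empty(len(animals))
        for i, g in enumerate(var.genotypes):  # [allele_a, allele_b, phased]
            a, b = g[0], g[1]
            counts[i] = np.nan if (a < 0 or b < 0) else float((a > 0) + (b > 0))
        rows.append(counts)
        meta.append((var.ID or f"{var.CHROM}:{var.POS}", str(var.CHROM), var.POS,
                     var.ALT[0] if var.ALT else ".", var.REF))
    snps = pd.DataFrame(meta, columns=["snp", "chrom", "pos", "a1", "a2"])
    counts = np.array(rows, dtype=float).T if rows else np.empty((len(animals), 0))
    return GenotypeMatrix(animals, snps, counts)


def write_plink_raw(geno: GenotypeMatrix, path) -> None:
    """Write the counterpart of :func:`read_genotypes` (plink_raw)."""
    header = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"] + [
        f"{s}_{a}" for s, a in zip(geno.snps["snp"], geno.snps["a1"])
    ]
    with open(path, "w") as fh:
        fh.write(" ".join(header) + "\n")
        for i, animal in enumerate(geno.animals):
            vals = [
                "NA" if np.isnan(v) else str(int(v)) for v in geno.counts[i]
            ]
            fh.write(" ".join([str(animal), str(animal), "0", "0", "0", "-9"] + vals) + "\n")


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a minimal plain-text VCF with GT fields (unphased)."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = pd.unique(geno.snps["chrom"])
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, geno.animals))
            + "\n"
        )
        for j, row in geno.snps.iterrows():
            gts = [
                "./." if np.isnan(v) else gt_map[v] for v in geno.counts[:, j]
            ]
            ref = row["a2"] if row["a2"] not in (".", "?") else "A"
            alt = row["a1"] if row["a1"] not in (".", "?") else "C"
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['snp']}\t{ref}\t{alt}"
                f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# Gene annotations
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTable:
    """Gene intervals in 1-based closed coordinates."""

    table: pd.DataFrame  # gene_id, chrom, start, end, strand

    def __post_init__(self) -> None:
        t = self.table
        if (t["start"] > t["end"]).any():
            raise ValueError("annotation with start > end after normalization")
        if (t["start"] < 1).any():
            raise ValueError("negative/zero 1-based coordinates")


def read_annotations(path, format: str = "bed") -> AnnotationTable:
    """Read gene annotations; BED (0-based half-open) or GFF3 (1-based closed).

    Both dialects are normalized to 1-based closed coordinates, so a BED line
    ``chr5 99 200 g1`` becomes start=100, end=200.
    """
    if format == "bed":
        rows = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) < 4:
                    raise ParseError(f"line {ln}: BED needs >= 4 columns")
                chrom, start, end, name = parts[:4]
                strand = parts[5] if len(parts) > 5 else "."
                start, end = int(start), int(end)
                if start < 0 or end < 0:
                    raise ParseError(f"line {ln}: negative coordinates")
                rows.append((name, chrom, start + 1, end, strand))
        df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
        return AnnotationTable(df)
    if format == "gff3":
        rows = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise ParseError(f"line {ln}: GFF3 needs 9 columns")
                chrom, _, ftype, start, end, _, strand, _, attrs = parts
                if ftype != "gene":
                    continue
                m = re.search(r"ID=([^;]+)", attrs)
                gene_id = m.group(1) if m else f"{chrom}:{start}-{end}"
                start, end = int(start), int(end)
                if start < 1 or end < 1:
                    raise ParseError(f"line {ln}: non-positive coordinates")
                rows.append((gene_id, chrom, start, end, strand))
        df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
        return AnnotationTable(df)
    raise ValueError(f"unknown annotation format {format!r}")


def write_annotations(ann: AnnotationTable, path, format: str = "bed") -> None:
    if format == "bed":
        with open(path, "w") as fh:
            for _, r in ann.table.iterrows():
                fh.write(
                    f"{r['chrom']}\t{r['start'] - 1}\t{r['end']}\t{r['gene_id']}"
                    f"\t0\t{r['strand']}\n"
                )
    elif format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for _, r in ann.table.iterrows():
                fh.write(
                    f"{r['chrom']}\tshedeval\tgene\t{r['start']}\t{r['end']}\t."
                    f"\t{r['strand']}\t.\tID={r['gene_id']}\n"
                )
    else:
        raise ValueError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# Matrix persistence (indexed upper-triangle TSV)
# ---------------------------------------------------------------------------

def write_matrix_tsv(index: pd.Index, matrix: np.ndarray, path) -> None:
    """Persist a symmetric matrix as (row id, col id, value), upper triangle."""
    iu = np.triu_indices(len(index))
    df = pd.DataFrame(
        {
            "row": np.asarray(index)[iu[0]],
            "col": np.asarray(index)[iu[1]],
            "value": np.asarray(matrix)[iu],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path) -> tuple[pd.Index, np.ndarray]:
    df = pd.read_csv(path, sep="\t", dtype={"row": str, "col": str})
    ids = pd.Index(pd.unique(pd.concat([df["row"], df["col"]])))
    pos = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    m = np.zeros((n, n))
    r = df["row"].map(pos).to_numpy()
    c = df["col"].map(pos).to_numpy()
    m[r, c] = df["value"]
    m[c, r] = df["value"]
    return ids, m
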