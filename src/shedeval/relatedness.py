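"""Pedigree, genomic, and blended (single-step) relationship matrices.

The single-step evaluation needs, in order: the numerator relationship
matrix A (tabular method), its sparse inverse (Henderson's rules with
inbreeding-adjusted Mendelian-sampling variances), the genotyped-subset
block A22, the VanRaden genomic matrix G, the blend
G_w = (1-w) G + w A22, and finally

    H^-1 = A^-1 + [0 0; 0 G_w^-1 - A22^-1]

with the correction scattered onto the genotyped block.  Also here:
genotype quality control (call rate, monomorphic markers, and
opposing-homozygote Mendelian checks that unlink bad parentage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import GenotypeMatrix, PedigreeTable


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix keyed by an ordered animal index."""

    index: pd.Index
    values: np.ndarray | sp.spmatrix
    kind: str  # A, A_inv, A22, A22_inv, G, G_w, G_w_inv, H_inv

    def dense(self) -> np.ndarray:
        v = self.values
        return v.toarray() if sp.issparse(v) else np.asarray(v)


# ---------------------------------------------------------------------------
# Pedigree relationships
# ---------------------------------------------------------------------------

def a_matrix(pedigree: PedigreeTable) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Requires a topologically sorted pedigree (parents before offspring),
    which :func:`shedeval.io_formats.build_pedigree` guarantees.
    """
    sire, dam = pedigree.parent_indices()
    n = len(pedigree)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
            A[i, i] = 1.0 + 0.5 * A[s, d]
        elif s >= 0 or d >= 0:
            p = max(s, d)
            A[i, :i] = 0.5 * A[p, :i]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    return RelationshipMatrix(pedigree.animals, A, "A")


def inbreeding(pedigree: PedigreeTable) -> np.ndarray:
    """Wright's inbreeding coefficients, F = diag(A) - 1."""
    return np.diag(a_matrix(pedigree).dense()) - 1.0


def a_inverse(pedigree: PedigreeTable, f: np.ndarray | None = None) -> RelationshipMatrix:
    """Sparse A-inverse by Henderson's rules with inbreeding adjustment.

    The Mendelian-sampling variance of animal i is
    0.5 - 0.25 (F_s + F_d) with both parents known, 0.75 - 0.25 F_p with
    one, and 1 with none; its reciprocal alpha_i feeds the classic
    (i, s, d) contribution pattern.
    """
    sire, dam = pedigree.parent_indices()
    n = len(pedigree)
    if f is None:
        f = inbreeding(pedigree)
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            msv = 0.5 - 0.25 * (f[s] + f[d])
        elif s >= 0 or d >= 0:
            msv = 0.75 - 0.25 * f[max(s, d)]
        else:
            msv = 1.0
        alpha = 1.0 / msv
        add(i, i, alpha)
        for p in (s, d):
            if p >= 0:
                add(p, i, -0.5 * alpha)
                add(i, p, -0.5 * alpha)
                for q in (s, d):
                    if q >= 0:
                        add(p, q, 0.25 * alpha)
    ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return RelationshipMatrix(pedigree.animals, ainv, "A_inv")


def a22(pedigree: PedigreeTable, genotyped: pd.Index) -> RelationshipMatrix:
    """Pedigree relationships restricted to the genotyped animals."""
    A = a_matrix(pedigree)
    pos = {a: i for i, a in enumerate(A.index)}
    idx = np.array([pos[g] for g in genotyped])
    return RelationshipMatrix(pd.Index(genotyped), A.dense()[np.ix_(idx, idx)], "A22")


# ---------------------------------------------------------------------------
# Genomic relationships
# ---------------------------------------------------------------------------

def vanraden_g(genotypes: GenotypeMatrix, freqs: np.ndarray | None = None) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix, G = ZZ' / (2 sum p(1-p)).

    Z is the allele-count matrix column-centered at 2p, with p the observed
    allele frequency in the genotyped set (unless supplied).  Missing
    genotypes are mean-imputed per SNP before centering, which keeps the
    column means of Z at zero.
    """
    M = genotypes.counts.astype(float).copy()
    if np.isnan(M).all(axis=0).any():
        raise ValueError("SNP with all genotypes missing; run genotype_qc first")
    col_mean = np.nanmean(M, axis=0)
    nan_r, nan_c = np.where(np.isnan(M))
    M[nan_r, nan_c] = col_mean[nan_c]
    p = col_mean / 2.0 if freqs is None else np.asarray(freqs, dtype=float)
    Z = M - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic; G undefined")
    G = (Z @ Z.T) / denom
    return RelationshipMatrix(genotypes.animals, G, "G")


def blend_g(G: RelationshipMatrix, A22m: RelationshipMatrix, weight: float = 0.05) -> RelationshipMatrix:
    """G_w = (1-w) G + w A22; the small pedigree admixture restores full rank."""
    if not G.index.equals(A22m.index):
        raise ValueError("G and A22 animal indices differ")
    Gw = (1.0 - weight) * G.dense() + weight * A22m.dense()
    return RelationshipMatrix(G.index, Gw, "G_w")


def h_inverse(
    a_inv: RelationshipMatrix,
    a22_inv: RelationshipMatrix,
    g_w_inv: RelationshipMatrix,
    genotyped: pd.Index,
) -> RelationshipMatrix:
    """Single-step H-inverse: A-inverse plus the genotyped-block correction."""
    if not (a22_inv.index.equals(g_w_inv.index) and a22_inv.index.equals(pd.Index(genotyped))):
        raise ValueError("genotyped-block indices differ")
    pos = {a: i for i, a in enumerate(a_inv.index)}
    missing = [g for g in genotyped if g not in pos]
    if missing:
        raise ValueError(f"genotyped animals absent from pedigree index: {missing[:5]}")
    idx = np.array([pos[g] for g in genotyped], dtype=int)
    corr = g_w_inv.dense() - a22_inv.dense()
    n = len(a_inv.index)
    scatter = sp.coo_matrix(
        (corr.ravel(), (np.repeat(idx, len(idx)), np.tile(idx, len(idx)))),
        shape=(n, n),
    ).tocsr()
    hinv = (sp.csr_matrix(a_inv.values) if not sp.issparse(a_inv.values) else a_inv.values) + scatter
    return RelationshipMatrix(a_inv.index, hinv, "H_inv")


def inverse_of(rel: RelationshipMatrix, kind: str | None = None) -> RelationshipMatrix:
    """Dense inverse of a (desk-scale) relationship matrix."""
    dense = rel.dense()
    try:
        inv = np.linalg.inv(dense)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            f"{rel.kind} is singular; blend with A22 (weight > 0) first"
        ) from err
    return RelationshipMatrix(rel.index, inv, kind or f"{rel.kind}_inv")


def build_h_inverse(
    pedigree: PedigreeTable,
    genotypes: GenotypeMatrix,
    blend_weight: float = 0.05,
) -> RelationshipMatrix:
    """Convenience path: pedigree + genotypes -> H-inverse."""
    a_inv = a_inverse(pedigree)
    A22m = a22(pedigree, genotypes.animals)
    Gw = blend_g(vanraden_g(genotypes), A22m, blend_weight)
    return h_inverse(a_inv, inverse_of(A22m), inverse_of(Gw), genotypes.animals)


# ---------------------------------------------------------------------------
# Genotype quality control
# ---------------------------------------------------------------------------

@dataclass
class GenotypeQCReport:
    dropped_snps: pd.DataFrame = field(default_factory=pd.DataFrame)
    dropped_animals: pd.DataFrame = field(default_factory=pd.DataFrame)
    unlinked_parents: pd.DataFrame = field(default_factory=pd.DataFrame)


def genotype_qc(
    genotypes: GenotypeMatrix,
    pedigree: PedigreeTable,
    call_rate_min: float = 0.85,
    mendel_max: float = 0.02,
) -> tuple[GenotypeMatrix, GenotypeQCReport, PedigreeTable]:
    """Call-rate, monomorphism, and Mendelian-consistency QC.

    Animals and markers with call rate below ``call_rate_min`` are removed,
    then monomorphic markers.  A genotyped parent-offspring pair whose
    opposing-homozygote rate (child 0 vs parent 2 or vice versa) exceeds
    ``mendel_max`` has that parent link blanked in the returned pedigree.
    """
    M = genotypes.counts
    report = GenotypeQCReport()

    snp_cr = 1.0 - np.isnan(M).mean(axis=0)
    keep_snp = snp_cr >= call_rate_min
    drops = [
        {"snp": s, "reason": "call rate"}
        for s in genotypes.snps.loc[~keep_snp, "snp"]
    ]
    animal_cr = 1.0 - np.isnan(M[:, keep_snp]).mean(axis=1)
    keep_animal = animal_cr >= call_rate_min
    report.dropped_animals = pd.DataFrame(
        {"animal": genotypes.animals[~keep_animal], "reason": "call rate"}
    )
    M2 = M[keep_animal][:, keep_snp]
    mono = np.array([len(np.unique(c[~np.isnan(c)])) <= 1 for c in M2.T])
    drops += [
        {"snp": s, "reason": "monomorphic"}
        for s in genotypes.snps.loc[keep_snp, "snp"][mono]
    ]
    report.dropped_snps = pd.DataFrame(drops, columns=["snp", "reason"])
    keep_snp_idx = np.where(keep_snp)[0][~mono]
    out = genotypes.subset(keep_animal, keep_snp_idx)
    if out.counts.size == 0:
        raise ValueError("no genotypes left after QC")

    # Mendelian check: opposing homozygotes against each listed parent.
    ped = pedigree.table.copy()
    pos = {a: i for i, a in enumerate(out.animals)}
    unlinks = []
    for row in ped.itertuples():
        ci = pos.get(row.animal)
        if ci is None:
            continue
        for which in ("sire", "dam"):
            pid = getattr(row, which)
            pi = pos.get(pid) if pid else None
            if pi is None:
                continue
            c, p = out.counts[ci], out.counts[pi]
            both = ~np.isnan(c) & ~np.isnan(p)
            if both.sum() == 0:
                continue
            opp = ((c == 0) & (p == 2)) | ((c == 2) & (p == 0))
            rate = opp[both].mean()
            if rate > mendel_max:
                unlinks.append(
                    {"animal": row.animal, "parent": pid, "which": which,
                     "error_rate": float(rate)}
                )
                ped.loc[ped["animal"] == row.animal, which] = ""
    report.unlinked_parents = pd.DataFrame(
        unlinks, columns=["animal", "parent", "which", "error_rate"]
    )
    return out, report, PedigreeTable(ped)
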