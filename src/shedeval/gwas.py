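"""Deregressed-EBV genome-wide association with FDR control.

Breeding values from the single-step evaluation are deregressed
(debv = ebv / reliability, with reliability = 1 - PEV/sigma2_a) so each
animal carries one pseudo-phenotype, weighted by that reliability.  A
single-SNP generalized least-squares scan controls family structure
through the VanRaden genomic relationship matrix with heritability
constrained to 0.40; Benjamini-Hochberg q-values flag genome-wide
significance, and genes within 50 kb of significant SNPs are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.linalg import cho_factor, cho_solve
from statsmodels.stats.multitest import multipletests

from .io_formats import AnnotationTable, GenotypeMatrix
from .mme import EBVTable
from .relatedness import RelationshipMatrix


def deregress(
    ebv_table: EBVTable,
    sigma2_a: float,
    reliability_floor: float = 0.0,
    method: str = "reliability",
) -> pd.DataFrame:
    """One deregressed record per animal: debv = ebv / r2, weight = r2.

    r2 = 1 - PEV/sigma2_a, clipped to [0, 1]; animals at or below the
    reliability floor are excluded (an EBV with r2 = 0 carries no data).
    ``method`` is the simple reliability deregression; it is the only one
    implemented (parent-average stripping is a recognized alternative).
    """
    if sigma2_a <= 0:
        raise ValueError("sigma2_a must be positive")
    if method != "reliability":
        raise NotImplementedError(f"deregression method {method!r}")
    t = ebv_table.table
    r2 = np.clip(1.0 - t["pev"].to_numpy(float) / sigma2_a, 0.0, 1.0)
    keep = r2 > reliability_floor
    return pd.DataFrame(
        {
            "animal_id": t["animal"].to_numpy()[keep],
            "debv": t["ebv"].to_numpy(float)[keep] / r2[keep],
            "weight": r2[keep],
        }
    )


@dataclass
class GwasResult:
    table: pd.DataFrame  # snp, chrom, pos, beta, se, p, q
    skipped: pd.DataFrame  # snp, reason


def single_snp_scan(
    debv_records: pd.DataFrame,
    genotypes: GenotypeMatrix,
    grm: RelationshipMatrix,
    h2_fixed: float = 0.40,
) -> GwasResult:
    """GLS single-SNP scan under y = mu + x beta + g + e.

    Var(g) = G sigma2_a, Var(e_i) = sigma2_e / w_i, with the total variance
    taken from the sample variance of the deregressed EBVs and split
    h2_fixed : (1 - h2_fixed).  Wald p-values; BH q-values.
    """
    rec = debv_records.set_index("animal_id")
    common = [a for a in genotypes.animals if a in rec.index and a in set(grm.index)]
    if not common:
        raise ValueError("no animals shared by debv records, genotypes, and GRM")
    gpos = {a: i for i, a in enumerate(genotypes.animals)}
    rpos = {a: i for i, a in enumerate(grm.index)}
    gi = [gpos[a] for a in common]
    ri = [rpos[a] for a in common]
    y = rec.loc[common, "debv"].to_numpy(float)
    w = rec.loc[common, "weight"].to_numpy(float)
    M = genotypes.counts[gi]
    G = grm.dense()[np.ix_(ri, ri)]
    n = len(common)

    tot = float(np.var(y, ddof=1))
    s2a, s2e = h2_fixed * tot, (1.0 - h2_fixed) * tot
    V = s2a * G + s2e * np.diag(1.0 / w)
    cf = cho_factor(V, lower=True, check_finite=False)
    Vi1 = cho_solve(cf, np.ones(n), check_finite=False)
    Viy = cho_solve(cf, y, check_finite=False)

    # Mean-impute residual missingness; flag monomorphic SNPs.
    M = M.copy()
    col_mean = np.nanmean(M, axis=0)
    nr, nc = np.where(np.isnan(M))
    M[nr, nc] = col_mean[nc]
    mono = M.std(axis=0) == 0.0
    skipped = pd.DataFrame(
        {"snp": genotypes.snps.loc[mono, "snp"], "reason": "monomorphic"}
    )
    keep = ~mono
    Mk = M[:, keep]
    ViM = cho_solve(cf, Mk, check_finite=False)
    a11 = float(np.ones(n) @ Vi1)
    a12 = Vi1 @ Mk
    a22 = np.einsum("ij,ij->j", Mk, ViM)
    b1 = float(np.ones(n) @ Viy)
    b2 = y @ ViM
    det = a11 * a22 - a12**2
    beta = (a11 * b2 - a12 * b1) / det
    se = np.sqrt(a11 / det)
    z = beta / se
    p = 2.0 * scipy.stats.norm.sf(np.abs(z))
    q = bh_fdr(p)
    table = genotypes.snps.loc[keep, ["snp", "chrom", "pos"]].reset_index(drop=True)
    table["beta"] = beta
    table["se"] = se
    table["p"] = p
    table["q"] = q
    return GwasResult(table, skipped.reset_index(drop=True))


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def genes_near_hits(
    hits: pd.DataFrame,
    annotations: AnnotationTable,
    window: int = 50_000,
) -> pd.DataFrame:
    """Genes whose span lies within ``window`` bp of each hit SNP.

    Distance is 0 for an overlapping SNP and strand-agnostic; exactly
    ``window`` bp away is included.  Emits one row per (snp, gene) plus a
    deduplicated ``gene_id`` set via ``.drop_duplicates``.
    """
    ann = annotations.table
    hit_chroms = set(hits["chrom"].astype(str))
    ann_chroms = set(ann["chrom"].astype(str))
    unmatched = hit_chroms - ann_chroms
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} hit chromosome(s) absent from annotations: "
            f"{sorted(unmatched)[:5]}"
        )
    rows = []
    for _, h in hits.iterrows():
        sub = ann[ann["chrom"].astype(str) == str(h["chrom"])]
        pos = int(h["pos"])
        dist = np.maximum.reduce(
            [sub["start"].to_numpy() - pos, pos - sub["end"].to_numpy(),
             np.zeros(len(sub), dtype=int)]
        )
        near = dist <= window
        for g, d in zip(sub.loc[near, "gene_id"], dist[near]):
            rows.append({"snp": h["snp"], "gene_id": g, "distance": int(d)})
    return pd.DataFrame(rows, columns=["snp", "gene_id", "distance"])
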