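"""Stage orchestration: simulate -> prep -> relmat -> fit -> validate -> gwas.

Each stage is a plain function from a config dict plus an output directory
to a summary dict; :func:`run_pipeline` wires them in dependency order,
records input/output hashes and seeds in a run manifest, and lets any
stage be toggled off (downstream stages then read whatever files are
already in the output directory).  All of the evaluation's thresholds
surface as named config keys with their operational defaults.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import __version__
from .gwas import deregress, genes_near_hits, single_snp_scan
from .io_formats import (
    read_annotations,
    read_genotypes,
    read_pedigree,
    write_pedigree,
    write_plink_raw,
)
from .lr import run_lr_validation
from .models import ebv_from_fit, fit_univariate, genetic_parameters
from .prep import prepare_records
from .relatedness import (
    RelationshipMatrix,
    a22,
    a_inverse,
    blend_g,
    genotype_qc,
    h_inverse,
    inverse_of,
    vanraden_g,
)
from .reml import REMLFit
from .simulate import SimConfig, simulate_genotypes, simulate_phenotypes, simulate_pedigree, write_truth_tsv

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "stages": ["simulate", "prep", "relmat", "fit", "validate", "gwas"],
    "simulate": {},  # SimConfig overrides
    "call_rate_min": 0.85,
    "mendel_max": 0.02,
    "blend_weight": 0.05,
    "reml_tol": 1e-6,
    "lr_fraction": 0.25,
    "lr_iterations": 10,
    "gwas_h2": 0.40,
    "gene_window": 50_000,
    "annotations": None,  # optional BED/GFF3 path
    "annotation_format": "bed",
}

_STAGE_ORDER = ["simulate", "prep", "relmat", "fit", "validate", "gwas"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineError(RuntimeError):
    pass


def _require(out: Path, name: str, stage: str) -> Path:
    p = out / name
    if not p.exists():
        raise PipelineError(f"stage '{stage}' needs missing upstream artifact {name}")
    return p


def stage_simulate(cfg: dict, out: Path) -> dict:
    sim = SimConfig(seed=cfg["seed"], **cfg.get("simulate", {}))
    ped = simulate_pedigree(sim)
    geno = simulate_genotypes(ped, sim)
    records, truth = simulate_phenotypes(ped, sim)
    write_pedigree(ped, out / "pedigree.csv")
    records.to_csv(out / "phenotypes.csv", index=False)
    write_plink_raw(geno, out / "genotypes.raw")
    geno.snps.to_csv(out / "snp_map.tsv", sep="\t", index=False)
    write_truth_tsv(truth, out / "truth.tsv")
    return {
        "n_animals": len(ped),
        "n_genotyped": len(geno.animals),
        "n_records": len(records),
        "realized_h2": truth.realized_h2,
    }


def stage_prep(cfg: dict, out: Path) -> dict:
    ped = read_pedigree(_require(out, "pedigree.csv", "prep"))
    records = pd.read_csv(_require(out, "phenotypes.csv", "prep"))
    meta = ped.table.rename(columns={"animal": "animal_id"})
    kept, log = prepare_records(records, meta)
    kept.to_csv(out / "prepared.csv", index=False)
    log.to_csv(out / "removal_log.tsv", sep="\t", index=False)
    by_reason = log["reason"].value_counts().to_dict() if len(log) else {}
    return {
        "n_kept": len(kept),
        "n_removed": len(log),
        "removals_by_reason": by_reason,
        "n_contemporary_groups": int(kept["cg_id"].nunique()),
    }


def stage_relmat(cfg: dict, out: Path) -> dict:
    ped = read_pedigree(_require(out, "pedigree.csv", "relmat"))
    geno = read_genotypes(_require(out, "genotypes.raw", "relmat"), "plink_raw")
    snp_map = out / "snp_map.tsv"
    if snp_map.exists():
        geno.snps = pd.read_csv(snp_map, sep="\t", dtype={"chrom": str})
    geno, report, ped_qc = genotype_qc(
        geno, ped, cfg["call_rate_min"], cfg["mendel_max"]
    )
    ainv = a_inverse(ped_qc)
    A22 = a22(ped_qc, geno.animals)
    G = vanraden_g(geno)
    Gw = blend_g(G, A22, cfg["blend_weight"])
    hinv = h_inverse(ainv, inverse_of(A22), inverse_of(Gw), geno.animals)
    sp.save_npz(out / "h_inv.npz", sp.csr_matrix(hinv.values))
    pd.Series(hinv.index).to_csv(out / "h_inv_index.csv", index=False, header=["animal"])
    write_pedigree(ped_qc, out / "pedigree_qc.csv")
    write_plink_raw(geno, out / "genotypes_qc.raw")
    geno.snps.to_csv(out / "snp_map_qc.tsv", sep="\t", index=False)
    return {
        "n_snps_post_qc": len(geno.snps),
        "n_genotyped_post_qc": len(geno.animals),
        "dropped_snps": len(report.dropped_snps),
        "dropped_animals": len(report.dropped_animals),
        "unlinked_parents": len(report.unlinked_parents),
    }


def _load_hinv(out: Path, stage: str) -> RelationshipMatrix:
    values = sp.load_npz(_require(out, "h_inv.npz", stage))
    index = pd.Index(pd.read_csv(_require(out, "h_inv_index.csv", stage))["animal"].astype(str))
    return RelationshipMatrix(index, values, "H_inv")


def _fit_prediction_model(cfg: dict, out: Path, stage: str) -> tuple[REMLFit, pd.DataFrame]:
    records = pd.read_csv(_require(out, "prepared.csv", stage))
    records["animal_id"] = records["animal_id"].astype(str)
    hinv = _load_hinv(out, stage)
    fit = fit_univariate(records, hinv, tol=cfg["reml_tol"])
    return fit, records


def stage_fit(cfg: dict, out: Path) -> dict:
    fit, _ = _fit_prediction_model(cfg, out, "fit")
    gp = genetic_parameters(fit.vc)
    ebv = ebv_from_fit(fit)
    ebv.table.to_csv(out / "ebv.tsv", sep="\t", index=False)
    vc_rows = [
        {"component": "additive", "estimate": fit.vc.group_covs["genetic"][0, 0],
         "se": fit.vc.se(("g", "genetic", 0, 0))},
        {"component": "permanent_environment",
         "estimate": fit.vc.group_covs["pe"][0, 0], "se": fit.vc.se(("g", "pe", 0, 0))},
        {"component": "residual", "estimate": fit.vc.resid_var[0],
         "se": fit.vc.se(("r", 0))},
    ]
    pd.DataFrame(vc_rows).to_csv(out / "variance_components.tsv", sep="\t", index=False)
    params = {
        "h2": gp.h2, "h2_se": gp.h2_se,
        "repeatability": gp.repeatability, "repeatability_se": gp.repeatability_se,
        "logl_reml": fit.vc.logl_reml, "n_iter": fit.vc.n_iter,
    }
    (out / "genetic_parameters.json").write_text(json.dumps(params, indent=2))
    return params


def stage_validate(cfg: dict, out: Path) -> dict:
    fit, records = _fit_prediction_model(cfg, out, "validate")
    res = run_lr_validation(
        records, _load_hinv(out, "validate"),
        n_iter=cfg["lr_iterations"], fraction=cfg["lr_fraction"],
        seed=cfg["seed"], tol=cfg["reml_tol"], whole_fit=fit,
    )
    res.per_iteration.to_csv(out / "lr_iterations.tsv", sep="\t", index=False)
    res.summary.to_csv(out / "lr_summary.tsv", sep="\t", index=False)
    s = res.summary.set_index("statistic")["mean"]
    return {
        "mean_abs_d_val": float(s["abs_d_val"]),
        "mean_b_val": float(s["b_val"]),
        "mean_rho_val": float(s["rho_val"]),
    }


def stage_gwas(cfg: dict, out: Path) -> dict:
    ebv_path = _require(out, "ebv.tsv", "gwas")
    vc = pd.read_csv(_require(out, "variance_components.tsv", "gwas"), sep="\t")
    sigma2_a = float(vc.set_index("component").loc["additive", "estimate"])
    from .mme import EBVTable

    ebv_df = pd.read_csv(ebv_path, sep="\t", dtype={"animal": str})
    geno = read_genotypes(_require(out, "genotypes_qc.raw", "gwas"), "plink_raw")
    snp_map = out / "snp_map_qc.tsv"
    if snp_map.exists():
        geno.snps = pd.read_csv(snp_map, sep="\t", dtype={"chrom": str})
    debv = deregress(EBVTable(ebv_df), sigma2_a)
    grm = vanraden_g(geno)
    result = single_snp_scan(debv, geno, grm, cfg["gwas_h2"])
    result.table.to_csv(out / "gwas.tsv", sep="\t", index=False)
    summary = {
        "n_snps_tested": len(result.table),
        "n_skipped": len(result.skipped),
        "n_hits_q05": int((result.table["q"] < 0.05).sum()),
    }
    if cfg.get("annotations"):
        ann = read_annotations(cfg["annotations"], cfg.get("annotation_format", "bed"))
        hits = result.table[result.table["q"] < 0.05]
        gene_hits = genes_near_hits(hits, ann, cfg["gene_window"])
        gene_hits.to_csv(out / "gene_hits.tsv", sep="\t", index=False)
        summary["n_unique_genes"] = int(gene_hits["gene_id"].nunique())
    return summary


_STAGES = {
    "simulate": stage_simulate,
    "prep": stage_prep,
    "relmat": stage_relmat,
    "fit": stage_fit,
    "validate": stage_validate,
    "gwas": stage_gwas,
}


def run_pipeline(config: dict | None = None, outdir: str | Path = "results") -> dict:
    """Execute the enabled stages in order and write ``manifest.json``.

    The manifest records the package version, the seed, each stage's
    summary, and a SHA-256 per output file, so reruns under an identical
    config are verifiably identical.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    enabled = [s for s in _STAGE_ORDER if s in cfg["stages"]]
    manifest: dict = {"version": __version__, "seed": cfg["seed"], "stages": {}}
    for stage in enabled:
        summary = _STAGES[stage](cfg, out)
        manifest["stages"][stage] = summary
    manifest["outputs"] = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
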