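"""Simulation studies: parameter recovery under the evaluation's truths.

Each study generates replicate synthetic herds whose variance structure is
set to the evaluation's point estimates, runs the corresponding model, and
summarizes the estimates with Monte-Carlo standard errors.  Problem sizes
are desk scale (a thousand-odd pedigree animals per replicate, ten
replicates) so a full study runs in minutes on one CPU; the Monte-Carlo SE
reported alongside each mean is the yardstick the recovered values should
be judged against.

These functions are the single source for both the test suite and the
acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lr import run_lr_validation
from .models import (
    fit_bivariate_fescue,
    fit_fescue_fixed,
    fit_maternal_ww,
    fit_univariate,
    genetic_parameters,
)
from .prep import prepare_records
from .relatedness import a_inverse
from .simulate import (
    SimConfig,
    default_fescue_g0,
    default_maternal_g0,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_phenotypes_bivariate,
    simulate_ww_bivariate,
)

#: Univariate simulation truth: the evaluation's variance-component point
#: estimates (additive, permanent environment, residual) in score units^2.
UNIVARIATE_TRUTH = (0.38, 0.04, 0.53)  # h2 = 0.40, repeatability ~ 0.442


@dataclass
class StudyResult:
    per_replicate: pd.DataFrame
    means: dict[str, float] = field(default_factory=dict)
    mc_se: dict[str, float] = field(default_factory=dict)

    def summarize(self, cols: list[str]) -> None:
        n = len(self.per_replicate)
        for c in cols:
            v = self.per_replicate[c].to_numpy(float)
            self.means[c] = float(np.mean(v))
            self.mc_se[c] = float(np.std(v, ddof=1) / np.sqrt(n))


def _univariate_config(seed: int) -> SimConfig:
    va, vpe, ve = UNIVARIATE_TRUTH
    return SimConfig(
        n_founders=180, n_generations=2, progeny_per_dam=4,
        var_additive=va, var_pe=vpe, var_residual=ve,
        records_min=1, records_max=3, n_farms=5, n_years=3, seed=seed,
    )


def _prepared_univariate(seed: int):
    cfg = _univariate_config(seed)
    ped = simulate_pedigree(cfg)
    records, truth = simulate_phenotypes(ped, cfg)
    meta = ped.table.rename(columns={"animal": "animal_id"})
    kept, _ = prepare_records(records, meta)
    return cfg, ped, kept, truth


def univariate_recovery(n_reps: int = 10, seed: int = 1, tol: float = 1e-6) -> StudyResult:
    """Heritability and repeatability recovery for the prediction model.

    ~1,260 pedigree animals per replicate, ~630 scored cows with 1-3 yearly
    records; truth (0.38, 0.04, 0.53).  Expected: mean h2 near 0.40 and
    mean repeatability near 0.44 within Monte-Carlo error.
    """
    rows = []
    for r in range(n_reps):
        cfg, ped, kept, truth = _prepared_univariate(seed * 1000 + r)
        fit = fit_univariate(kept, a_inverse(ped), tol=tol)
        gp = genetic_parameters(fit.vc)
        rows.append(
            {"replicate": r, "h2": gp.h2, "repeatability": gp.repeatability,
             "realized_h2": truth.realized_h2, "n_records": len(kept),
             "n_iter": fit.vc.n_iter}
        )
    res = StudyResult(pd.DataFrame(rows))
    res.summarize(["h2", "repeatability"])
    return res


def fescue_rg_recovery(n_reps: int = 10, seed: int = 1, tol: float = 1e-6) -> StudyResult:
    """Genetic-correlation recovery for the two-trait fescue model.

    ~700 pedigree animals, ~350 scored cows with 3-4 records each and
    frequent within-cow status switches (cows observed under both statuses
    are what link the traits most directly, as the permanent-environment
    covariance is structurally zero); genetic truth from the evaluation's
    per-status estimates with r_g = 0.93.
    """
    rows = []
    for r in range(n_reps):
        cfg = SimConfig(
            n_founders=100, n_generations=2, progeny_per_dam=4, n_farms=4,
            records_min=3, records_max=4, n_years=4, fescue_switch_prob=0.6,
            seed=seed * 1000 + 500 + r,
        )
        ped = simulate_pedigree(cfg)
        rec, _ = simulate_phenotypes_bivariate(ped, cfg, g0=default_fescue_g0(0.93))
        rec["cg_id"] = rec["farm_id"].astype(str) + "/" + rec["year"].astype(str)
        out = fit_bivariate_fescue(rec, a_inverse(ped), tol=tol)
        rows.append(
            {"replicate": r, "r_g": out.r_g, "n_records": len(rec),
             "n_iter": out.fit.vc.n_iter}
        )
    res = StudyResult(pd.DataFrame(rows))
    res.summarize(["r_g"])
    return res


def maternal_recovery(n_reps: int = 10, seed: int = 1, tol: float = 1e-6) -> StudyResult:
    """Maternal-model genetic-correlation recovery.

    ~240 dams scored over three years with real or dummy calves plus their
    own historical weaning weights; truth r_g(HS, maternal WW) = -0.19,
    r_g(direct WW, maternal WW) = -0.43.
    """
    rows = []
    for r in range(n_reps):
        cfg = SimConfig(
            n_founders=120, n_generations=1, progeny_per_dam=2, n_farms=4,
            seed=seed * 1000 + 700 + r,
        )
        sim = simulate_ww_bivariate(
            simulate_pedigree(cfg), cfg, g0=default_maternal_g0()
        )
        out = fit_maternal_ww(
            sim.hs_records, sim.ww_records, a_inverse(sim.pedigree), tol=tol
        )
        rows.append(
            {"replicate": r, "r_hs_maternal": out.r_g_hs_maternal,
             "r_direct_maternal": out.r_g_direct_maternal,
             "n_iter": out.fit.vc.n_iter}
        )
    res = StudyResult(pd.DataFrame(rows))
    res.summarize(["r_hs_maternal", "r_direct_maternal"])
    return res


def fescue_fixed_recovery(seed: int = 1, tol: float = 1e-6) -> dict[str, float]:
    """Fixed-effect recovery: grazing-status contrast of -0.59 score units.

    One simulation of ~2,000 records; the contemporary group excludes
    status.  Returns the estimated contrast and its model SE.
    """
    cfg = SimConfig(
        n_founders=240, n_generations=2, progeny_per_dam=4, n_farms=5,
        records_min=2, records_max=3, seed=seed * 1000 + 900,
    )
    ped = simulate_pedigree(cfg)
    records, _ = simulate_phenotypes(ped, cfg)
    # Five-part key (status excluded): the status contrast stays estimable.
    records["age_group"] = records["age_days"].map(
        lambda d: str((d + 90) // 365) if (d + 90) // 365 <= 3 else "other"
    )
    records["cg_id"] = (
        records["farm_id"].astype(str) + "/" + records["year"].astype(str)
        + "/" + records["calving_season"] + "/" + records["age_group"]
    )
    out = fit_fescue_fixed(records, a_inverse(ped), tol=tol)
    return {"beta_f": out.beta_f, "se": out.beta_f_se, "n_records": len(records)}


def lr_calibration(
    seed: int = 1, n_iter: int = 10, n_herds: int = 5, tol: float = 1e-6
) -> StudyResult:
    """LR-method calibration under the no-selection simulation.

    Ten 25% masking partitions in each of several independently simulated
    herds; without selection the validation-set mean difference d is
    expected at 0 and the whole-on-partial slope b at 1.  Summaries are
    taken over herd means (partitions within a herd share its whole fit,
    so they are not independent draws of the herd-level noise).
    """
    frames = []
    for h in range(n_herds):
        cfg, ped, kept, _ = _prepared_univariate(seed * 1000 + 300 + h)
        res = run_lr_validation(
            kept, a_inverse(ped), n_iter=n_iter, fraction=0.25,
            seed=seed * 10 + h, tol=tol,
        )
        frames.append(res.per_iteration.assign(herd=h))
    per_iter = pd.concat(frames, ignore_index=True)
    study = StudyResult(per_iter)
    cols = ["d_val", "b_val", "rho_val", "abs_d_val"]
    herd_means = per_iter.groupby("herd")[cols].mean()
    for c in cols:
        study.means[c] = float(herd_means[c].mean())
        study.mc_se[c] = float(herd_means[c].std(ddof=1) / np.sqrt(n_herds))
    return study
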