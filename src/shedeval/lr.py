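"""LR-method validation of breeding values (whole vs partial comparisons).

Phenotypes of a random 25% of scored animals are masked; breeding values
re-estimated from the reduced ("partial") data are compared with those from
all data ("whole") within the validation set (masked animals) and the
reference set.  Per iteration:

* ``d``    mean(whole - partial); its absolute value estimates bias.
           Expectation 0 without selection.
* ``b``    slope of the regression of whole on partial; deviations from 1
           indicate over/under-dispersion.
* ``rho``  Pearson correlation of partial and whole; in the validation set
           this is the prediction-accuracy metric.

Partial fits reuse the whole-data variance components by default (the
standard, much faster practice); set ``reestimate=True`` to rerun REML per
partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import build_univariate, ebv_from_fit, fit_univariate
from .relatedness import RelationshipMatrix
from .reml import REMLFit


@dataclass(frozen=True)
class PartitionScheme:
    iteration: int
    validation: pd.Index  # animals whose phenotypes are masked
    reference: pd.Index
    seed: int
    fraction: float = 0.25


def make_partitions(
    animals: pd.Index, n_iter: int = 10, fraction: float = 0.25, seed: int = 0
) -> list[PartitionScheme]:
    """Independent random 25% validation splits, reproducible by seed."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    animals = pd.Index(animals)
    if len(animals) < 8:
        raise ValueError("need at least 8 phenotyped animals to partition")
    n_val = int(round(len(animals) * fraction))
    out = []
    for it in range(n_iter):
        rng = np.random.default_rng([seed, it])
        val = pd.Index(rng.choice(animals, size=n_val, replace=False))
        ref = animals.difference(val)
        out.append(PartitionScheme(it, val, ref, seed, fraction))
    return out


def lr_stats(
    whole: pd.Series, partial: pd.Series, scheme: PartitionScheme
) -> dict[str, float]:
    """d, b, rho for validation and reference sets.

    ``whole``/``partial`` map animal -> EBV and must cover both sets.
    """
    out: dict[str, float] = {"iteration": scheme.iteration}
    for name, animals in (("val", scheme.validation), ("ref", scheme.reference)):
        w = whole.loc[animals].to_numpy(float)
        p = partial.loc[animals].to_numpy(float)
        d = float(np.mean(w - p))
        vp = float(np.var(p, ddof=1))
        if vp <= 0:
            b = np.nan
            rho = np.nan
        else:
            b = float(np.cov(p, w)[0, 1] / vp)
            rho = float(np.corrcoef(p, w)[0, 1])
        out[f"d_{name}"] = d
        out[f"abs_d_{name}"] = abs(d)
        out[f"b_{name}"] = b
        out[f"rho_{name}"] = rho
    return out


@dataclass
class LRValidationResult:
    per_iteration: pd.DataFrame
    summary: pd.DataFrame  # mean/min/max per statistic
    whole_fit: REMLFit


def run_lr_validation(
    records: pd.DataFrame,
    relinv: RelationshipMatrix,
    n_iter: int = 10,
    fraction: float = 0.25,
    seed: int = 0,
    tol: float = 1e-6,
    reestimate: bool = False,
    whole_fit: REMLFit | None = None,
) -> LRValidationResult:
    """Whole-vs-partial LR assessment of the univariate prediction model."""
    if whole_fit is None:
        whole_fit = fit_univariate(records, relinv, tol=tol)
    whole_ebv = ebv_from_fit(whole_fit).table.set_index("animal")["ebv"]
    animals = pd.Index(pd.unique(records["animal_id"]))
    start = (
        float(whole_fit.vc.group_covs["genetic"][0, 0]),
        float(whole_fit.vc.group_covs["pe"][0, 0]),
        float(whole_fit.vc.resid_var[0]),
    )
    rows = []
    for scheme in make_partitions(animals, n_iter, fraction, seed):
        masked = records[~records["animal_id"].isin(scheme.validation)]
        if reestimate:
            fit = fit_univariate(masked, relinv, start=start, tol=tol)
            sol, system = fit.solutions, fit.system
        else:
            system = build_univariate(masked, relinv, start=start)
            sol = system.solve()
        off, g = system.group_offset("genetic")
        partial = pd.Series(sol[off: off + g.q], index=g.levels)
        rows.append(lr_stats(whole_ebv, partial, scheme))
    per_iter = pd.DataFrame(rows)
    stats = [c for c in per_iter.columns if c != "iteration"]
    summary = per_iter[stats].agg(["mean", "min", "max"]).T.reset_index(names="statistic")
    return LRValidationResult(per_iter, summary, whole_fit)
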