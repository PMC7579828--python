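"""The evaluation models for hair shedding score and weaning weight.

Five model families, all repeated-records animal models solved by the same
MME/AI-REML engine:

1. the univariate prediction model (contemporary group fixed; additive +
   permanent-environment + residual),
2. the age-effect models (age class added as a categorical fixed effect;
   age-in-years, four-class, BIF-class, or null) compared by AIC/LRT,
3. the univariate fescue-status fixed-effect model (beta_f),
4. the bivariate model treating scores recorded while grazing vs not
   grazing toxic fescue as two traits (genetic covariance free,
   permanent-environment covariance fixed at zero),
5. the bivariate maternal model tying a dam's hair shedding score to her
   calf's weaning weight (calf direct WW, dam maternal HS/WW as three
   correlated genetic variates; dam permanent-environment 2x2; residual
   covariance fixed at zero since the two traits are never co-observed on
   one record).

Heritability is sigma2_a / (sigma2_a + sigma2_pe + sigma2_e) and
repeatability (sigma2_a + sigma2_pe) / (same total); standard errors come
from the inverse AI matrix by the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
import statsmodels.api as sm

from .mme import EBVTable, MMESystem, fixed_design, group_from_records
from .relatedness import RelationshipMatrix
from .reml import REMLFit, VarianceComponents, reml_estimate


# ---------------------------------------------------------------------------
# Model assembly helpers
# ---------------------------------------------------------------------------

def _kinv_of(rel: RelationshipMatrix | None) -> tuple[sp.spmatrix | None, pd.Index | None]:
    if rel is None:
        return None, None
    if not rel.kind.endswith("_inv"):
        raise ValueError(f"expected an inverse relationship matrix, got {rel.kind}")
    v = rel.values if sp.issparse(rel.values) else sp.csr_matrix(rel.values)
    return v, rel.index


def build_univariate(
    records: pd.DataFrame,
    relinv: RelationshipMatrix,
    fixed: tuple[str, ...] = ("cg_id",),
    start: tuple[float, float, float] = (0.3, 0.1, 0.5),
) -> MMESystem:
    """Assemble y = Xb (+ optional extra fixed factors) + Zu + Zp + e.

    ``records`` needs ``animal_id``, ``score`` and the fixed-factor columns;
    ``relinv`` supplies H^-1 or A^-1 over every animal in the pedigree.
    """
    kinv, levels = _kinv_of(relinv)
    rec = records.reset_index(drop=True)
    missing = set(rec["animal_id"]) - set(levels)
    if missing:
        raise ValueError(f"records reference animals outside the relationship index: {sorted(missing)[:5]}")
    X, xnames = fixed_design(rec, list(fixed))
    rows = np.arange(len(rec))
    gen = group_from_records(
        "genetic", ("u",), levels, [(rows, 0, rec["animal_id"].to_numpy())],
        kinv, np.array([[start[0]]]),
    )
    pe_levels = pd.Index(pd.unique(rec["animal_id"]))
    pe = group_from_records(
        "pe", ("p",), pe_levels, [(rows, 0, rec["animal_id"].to_numpy())],
        None, np.array([[start[1]]]),
    )
    return MMESystem(
        rec["score"].to_numpy(float), X, [gen, pe], resid_var=start[2],
        xnames=xnames,
    )


def fit_univariate(
    records: pd.DataFrame,
    relinv: RelationshipMatrix,
    fixed: tuple[str, ...] = ("cg_id",),
    start: tuple[float, float, float] = (0.3, 0.1, 0.5),
    tol: float = 1e-8,
    max_iter: int = 200,
) -> REMLFit:
    system = build_univariate(records, relinv, fixed, start)
    return reml_estimate(system, tol=tol, max_iter=max_iter)


def ebv_from_fit(fit: REMLFit, variate: int = 0, group: str = "genetic") -> EBVTable:
    sigma2_a = float(fit.vc.group_covs[group][variate, variate])
    return EBVTable.from_solution(
        fit.system, fit.solutions, fit.cinv, group, variate, sigma2_a
    )


# ---------------------------------------------------------------------------
# Genetic parameters
# ---------------------------------------------------------------------------

@dataclass
class GeneticParameters:
    h2: float
    h2_se: float
    repeatability: float
    repeatability_se: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2 <= self.repeatability <= 1.0 + 1e-9):
            # Sampling noise can nudge ratios slightly out of order; only a
            # real violation is an error.
            if self.h2 > self.repeatability + 1e-6:
                raise ValueError("h2 exceeds repeatability")


def genetic_parameters(vc: VarianceComponents) -> GeneticParameters:
    """h2 and repeatability with delta-method SEs from the AI covariance."""
    keys = [("g", "genetic", 0, 0), ("g", "pe", 0, 0), ("r", 0)]
    a, pe, e = (vc.param_value(k) for k in keys)
    total = a + pe + e
    if total <= 0:
        raise ValueError("zero total variance")
    h2 = a / total
    rep = (a + pe) / total
    cov = vc.subcov(keys)
    grad_h2 = np.array([(total - a), -a, -a]) / total**2
    grad_rep = np.array([e, e, -(a + pe)]) / total**2
    h2_se = float(np.sqrt(max(grad_h2 @ cov @ grad_h2, 0.0)))
    rep_se = float(np.sqrt(max(grad_rep @ cov @ grad_rep, 0.0)))
    return GeneticParameters(h2, h2_se, min(rep, 1.0), rep_se)


def genetic_correlation(
    vc: VarianceComponents, group: str, i: int, j: int
) -> tuple[float, float]:
    """Correlation cov[i,j]/sqrt(cov[i,i] cov[j,j]) with a delta-method SE."""
    G = vc.group_covs[group]
    va, vb, c = G[i, i], G[j, j], G[i, j]
    r = c / np.sqrt(va * vb)
    keys = [("g", group, i, i), ("g", group, j, j),
            ("g", group, min(i, j), max(i, j))]
    try:
        cov = vc.subcov(keys)
        grad = np.array(
            [-c / (2 * va ** 1.5 * vb ** 0.5), -c / (2 * vb ** 1.5 * va ** 0.5),
             1.0 / np.sqrt(va * vb)]
        )
        se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    except ValueError:
        se = np.nan
    return float(r), se


# ---------------------------------------------------------------------------
# Age-effect models and model comparison
# ---------------------------------------------------------------------------

def drop_rare_age_classes(
    records: pd.DataFrame, age_col: str, min_animals: int = 5
) -> pd.DataFrame:
    """Exclude age classifications carried by fewer than five animals."""
    counts = records.groupby(age_col)["animal_id"].nunique()
    keep = counts.index[counts >= min_animals]
    return records[records[age_col].isin(keep)].reset_index(drop=True)


def fit_age_model(
    records: pd.DataFrame,
    relinv: RelationshipMatrix,
    age_col: str | None,
    tol: float = 1e-8,
) -> REMLFit:
    """Repeated-records model with an optional categorical age effect."""
    fixed = ("cg_id",) if age_col is None else ("cg_id", age_col)
    rec = records if age_col is None else drop_rare_age_classes(records, age_col)
    return fit_univariate(rec, relinv, fixed=fixed, tol=tol)


@dataclass
class ModelComparison:
    aic: dict[str, float]
    lrt_stat: float
    lrt_df: int
    lrt_p: float
    neg_log10_p: float


def aic(fit: REMLFit) -> float:
    """AIC = -2 logL + 2k with k = fixed + variance parameters.

    Uses the ML log-likelihood evaluated at the REML estimates, so models
    with different fixed effects are on a comparable scale.
    """
    k = fit.system.n_fixed + fit.vc.n_params
    return -2.0 * fit.vc.logl_ml + 2.0 * k


def compare_models(full: REMLFit, null: REMLFit, names=("full", "null")) -> ModelComparison:
    """AIC plus a likelihood-ratio test of nested models on shared data."""
    if len(full.system.y) != len(null.system.y):
        raise ValueError("LRT requires both models fitted to the same records")
    k_full = full.system.n_fixed + full.vc.n_params
    k_null = null.system.n_fixed + null.vc.n_params
    if k_full < k_null:
        raise ValueError("models are not nested (full model must not drop parameters)")
    stat = max(2.0 * (full.vc.logl_ml - null.vc.logl_ml), 0.0)
    df = k_full - k_null
    if df > 0:
        p = float(scipy.stats.chi2.sf(stat, df))
    else:
        p = 1.0 if stat <= 1e-8 else 0.0
    neg = float(-np.log10(p)) if p > 0 else np.inf
    return ModelComparison(
        {names[0]: aic(full), names[1]: aic(null)}, stat, df, p, neg
    )


# ---------------------------------------------------------------------------
# Fescue-status models
# ---------------------------------------------------------------------------

@dataclass
class FescueFixedResult:
    fit: REMLFit
    effects: dict[str, float]  # status level -> solution (reference = 0)
    beta_f: float  # effect of "no" relative to "yes" (grazing = 0)
    beta_f_se: float


def fit_fescue_fixed(
    records: pd.DataFrame,
    relinv: RelationshipMatrix,
    start: tuple[float, float, float] = (0.3, 0.1, 0.5),
    tol: float = 1e-8,
) -> FescueFixedResult:
    """Univariate model with toxic-fescue grazing status as a fixed effect.

    The contemporary group here excludes status (it is the effect under
    study); ``beta_f`` reports not-grazing relative to grazing, with the
    grazing level pinned at 0.
    """
    fit = fit_univariate(
        records, relinv, fixed=("cg_id", "fescue_status"), start=start, tol=tol
    )
    effects = {}
    for name, val in zip(fit.system.xnames, fit.solutions[: fit.system.n_fixed]):
        if name.startswith("fescue_status:"):
            effects[name.split(":", 1)[1]] = float(val)
    levels = sorted(pd.unique(records["fescue_status"].astype(str)))
    ref = levels[0]
    effects.setdefault(ref, 0.0)
    est_level = next(lv for lv in levels if lv != ref)
    col = fit.system.xnames.index(f"fescue_status:{est_level}")
    se = float(np.sqrt(max(fit.cinv[col, col], 0.0)))
    beta = effects["no"] - effects["yes"]
    return FescueFixedResult(fit, effects, beta, se)


@dataclass
class BivariateFescueResult:
    fit: REMLFit
    r_g: float
    r_g_se: float
    params_by_status: dict[str, GeneticParameters]
    ebv_by_status: dict[str, EBVTable]


def fit_bivariate_fescue(
    records: pd.DataFrame,
    relinv: RelationshipMatrix,
    start_g: np.ndarray | None = None,
    start_pe: tuple[float, float] = (0.1, 0.1),
    start_e: tuple[float, float] = (0.5, 0.5),
    tol: float = 1e-8,
    max_iter: int = 200,
) -> BivariateFescueResult:
    """Bivariate model: scores grazing vs not grazing fescue as two traits.

    Genetic 2x2 covariance free; permanent-environment covariance fixed at
    zero (as is the cross-status residual covariance, which no record
    co-observes).  Statuses map to traits in sorted order ("no"=0, "yes"=1).
    """
    kinv, levels = _kinv_of(relinv)
    rec = records.reset_index(drop=True)
    statuses = sorted(pd.unique(rec["fescue_status"].astype(str)))
    if len(statuses) == 1:
        import warnings

        warnings.warn("only one fescue status present; reduces to univariate")
    trait = rec["fescue_status"].astype(str).map({s: i for i, s in enumerate(statuses)}).to_numpy()
    rec["cg_trait"] = rec["fescue_status"].astype(str) + "/" + rec["cg_id"].astype(str)
    X, xnames = fixed_design(rec, ["cg_trait"])
    k = len(statuses)
    if start_g is None:
        start_g = 0.3 * np.eye(k) + 0.15 * (np.ones((k, k)) - np.eye(k))
    assign_g = [
        (np.where(trait == t)[0], t,
         rec.loc[trait == t, "animal_id"].to_numpy())
        for t in range(k)
    ]
    gen = group_from_records(
        "genetic", tuple(f"u_{s}" for s in statuses), levels, assign_g, kinv,
        start_g,
    )
    pe_levels = pd.Index(pd.unique(rec["animal_id"]))
    pe = group_from_records(
        "pe", tuple(f"p_{s}" for s in statuses), pe_levels, assign_g, None,
        np.diag(np.asarray(start_pe[:k], dtype=float)), free=np.eye(k, dtype=bool),
    )
    system = MMESystem(
        rec["score"].to_numpy(float), X, [gen, pe], trait_of_record=trait,
        resid_var=np.asarray(start_e[:k], dtype=float), xnames=xnames,
    )
    fit = reml_estimate(system, tol=tol, max_iter=max_iter)
    r_g, r_se = genetic_correlation(fit.vc, "genetic", 0, 1)
    params, ebvs = {}, {}
    for t, s in enumerate(statuses):
        G = fit.vc.group_covs
        a = G["genetic"][t, t]
        p = G["pe"][t, t]
        e = fit.vc.resid_var[t]
        total = a + p + e
        params[s] = GeneticParameters(a / total, np.nan, (a + p) / total, np.nan)
        ebvs[s] = EBVTable.from_solution(
            fit.system, fit.solutions, fit.cinv, "genetic", t, float(a)
        )
    return BivariateFescueResult(fit, r_g, r_se, params, ebvs)


# ---------------------------------------------------------------------------
# Maternal weaning-weight model
# ---------------------------------------------------------------------------

@dataclass
class MaternalWWResult:
    fit: REMLFit
    r_g_hs_maternal: float
    r_g_hs_maternal_se: float
    r_g_direct_maternal: float
    r_g_direct_maternal_se: float
    r_g_hs_direct: float


#: Variate order of the maternal model's genetic group.
MATERNAL_VARIATES = ("u_ww", "m_hs", "m_ww")


def _unscale_vc(vc: VarianceComponents, group_scales: dict[str, np.ndarray],
                resid_scales: np.ndarray) -> None:
    """Undo per-trait response standardization on a fitted component set.

    A response divided by c multiplies every covariance touching it by
    1/c^2 (cross-covariances by 1/(c_i c_j)); this restores the original
    scale in place, including the AI sampling covariance.
    """
    factors = []
    for key in vc.param_index:
        if key[0] == "g":
            _, name, i, j = key
            c = group_scales.get(name)
            factors.append(1.0 if c is None else float(c[i] * c[j]))
        else:
            factors.append(float(resid_scales[key[1]] ** 2))
    f = np.asarray(factors)
    for name, c in group_scales.items():
        vc.group_covs[name] *= np.outer(c, c)
    vc.resid_var *= np.asarray(resid_scales) ** 2
    vc.cov_params *= np.outer(f, f)


def fit_maternal_ww(
    hs_records: pd.DataFrame,
    ww_records: pd.DataFrame,
    relinv: RelationshipMatrix,
    start_g: np.ndarray | None = None,
    start_mpe: np.ndarray | None = None,
    start_e: tuple[float, float] = (0.5, 300.0),
    tol: float = 1e-8,
    max_iter: int = 200,
) -> MaternalWWResult:
    """Bivariate maternal model for dam hair shedding and calf weaning weight.

    ``hs_records``: dam-year scores (``animal_id`` = dam, ``score``,
    ``cg_id``).  ``ww_records``: calf weights (``calf_id``, ``dam_id``,
    ``weight`` — NaN for dummy calves — and ``cg_id``).  Hair shedding
    carries a maternal genetic effect only (the calf has no genetic effect
    on its dam's score); weaning weight carries the calf's direct effect
    plus the dam's maternal effect.  The three genetic variates share one
    free 3x3 covariance over the pedigree.  Dummy calves contribute no
    residual row but stay estimable through the relationship matrix.

    The weaning-weight response is standardized internally (its variance
    is ~500x the score variance, which would wreck the conditioning of
    the information matrix); the returned variance components are mapped
    back to kg scale, while ``fit.solutions`` stay on the standardized
    scale.
    """
    kinv, levels = _kinv_of(relinv)
    hs = hs_records.reset_index(drop=True)
    ww = ww_records.dropna(subset=["weight"]).reset_index(drop=True)
    if not len(ww) or not (set(ww["dam_id"]) & set(hs["animal_id"])):
        raise ValueError("no dam-calf links between score and weight records")
    n_hs, n_ww = len(hs), len(ww)
    # Standardize the kg-scale trait so the AI matrix is well conditioned;
    # components are mapped back to the original scale after convergence.
    ww_scale = float(np.std(ww["weight"])) or 1.0
    y = np.concatenate(
        [hs["score"].to_numpy(float), ww["weight"].to_numpy(float) / ww_scale]
    )
    trait = np.concatenate([np.zeros(n_hs, int), np.ones(n_ww, int)])
    fixed_df = pd.DataFrame(
        {
            "cg_trait": np.concatenate(
                ["HS/" + hs["cg_id"].astype(str), "WW/" + ww["cg_id"].astype(str)]
            )
        }
    )
    X, xnames = fixed_design(fixed_df, ["cg_trait"])
    hs_rows = np.arange(n_hs)
    ww_rows = n_hs + np.arange(n_ww)
    if start_g is None:
        start_g = np.diag([200.0, 0.3, 100.0])
    cg = np.array([1.0 / ww_scale, 1.0, 1.0 / ww_scale])  # (u_ww, m_hs, m_ww)
    cm = np.array([1.0, 1.0 / ww_scale])  # (mpe_hs, mpe_ww)
    cr = np.array([1.0, 1.0 / ww_scale])
    start_g = np.asarray(start_g, dtype=float) * np.outer(cg, cg)
    start_mpe_s = (
        np.diag([0.1, 80.0]) if start_mpe is None else np.asarray(start_mpe, float)
    ) * np.outer(cm, cm)
    start_e_s = np.asarray(start_e, dtype=float) * cr**2
    gen = group_from_records(
        "genetic", MATERNAL_VARIATES, levels,
        [
            (ww_rows, 0, ww["calf_id"].to_numpy()),   # calf direct WW
            (hs_rows, 1, hs["animal_id"].to_numpy()),  # dam maternal HS
            (ww_rows, 2, ww["dam_id"].to_numpy()),     # dam maternal WW
        ],
        kinv, start_g,
    )
    dams = pd.Index(pd.unique(np.concatenate([hs["animal_id"], ww["dam_id"]])))
    mpe = group_from_records(
        "mpe", ("mpe_hs", "mpe_ww"), dams,
        [(hs_rows, 0, hs["animal_id"].to_numpy()),
         (ww_rows, 1, ww["dam_id"].to_numpy())],
        None, start_mpe_s,
    )
    system = MMESystem(
        y, X, [gen, mpe], trait_of_record=trait,
        resid_var=start_e_s, xnames=xnames,
    )
    fit = reml_estimate(system, tol=tol, max_iter=max_iter)
    _unscale_vc(
        fit.vc,
        {"genetic": np.array([ww_scale, 1.0, ww_scale]),
         "mpe": np.array([1.0, ww_scale])},
        np.array([1.0, ww_scale]),
    )
    r_hm, se_hm = genetic_correlation(fit.vc, "genetic", 1, 2)
    r_dm, se_dm = genetic_correlation(fit.vc, "genetic", 0, 2)
    r_hd, _ = genetic_correlation(fit.vc, "genetic", 0, 1)
    return MaternalWWResult(fit, r_hm, se_hm, r_dm, se_dm, r_hd)


# ---------------------------------------------------------------------------
# Phenotypic regressions
# ---------------------------------------------------------------------------

def phenotypic_regression(
    dam_scores: np.ndarray, calf_weights: np.ndarray
) -> tuple[float, float]:
    """OLS slope (kg per score unit) of calf weight on dam score, with SE."""
    s = np.asarray(dam_scores, float)
    w = np.asarray(calf_weights, float)
    if len(s) != len(w) or len(s) < 3:
        raise ValueError("need at least 3 paired score/weight observations")
    res = sm.OLS(w, sm.add_constant(s)).fit()
    return float(res.params[1]), float(res.bse[1])
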