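"""Synthetic herds with the statistical structure the evaluation assumes.

The generator emulates a multi-generation Angus-style pedigree scored for
hair shedding (1-5, lower = earlier shedding): random mating without
selection, gene-dropped unlinked SNPs, infinitesimal breeding values
dropped down the pedigree with inbreeding-adjusted Mendelian-sampling
variance, permanent-environment effects, farm-by-year contemporary-group
effects, a U-shaped age-class effect, a fescue grazing-status effect, and
1-3 yearly repeated scores per cow.  Defaults reproduce the variance
structure of the real evaluation: additive 0.38, permanent environment
0.04, residual 0.53 (h2 = 0.40, repeatability ~ 0.44) and a grazing-status
contrast of -0.59 score units (not grazing minus grazing).

Everything is driven by one integer seed; identical configurations give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, PedigreeTable, build_pedigree
from .relatedness import a_matrix

#: Scoring-date offset: cows born ~March 1 are scored ~May 20, so a cow
#: scored k calendar years after birth is 365*k + 80 days old (age class k).
SCORE_DAY_OFFSET = 80
BASE_YEAR = 2010


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic herd.

    Variances are in squared score units; ``fescue_effect`` is the fixed
    contrast of not-grazing relative to grazing toxic fescue.
    """

    n_founders: int = 240
    n_generations: int = 2
    progeny_per_dam: int = 4
    dam_fraction: float = 0.5
    genotyped_fraction: float = 0.5
    n_snps: int = 800
    maf_range: tuple[float, float] = (0.05, 0.5)
    var_additive: float = 0.38
    var_pe: float = 0.04
    var_residual: float = 0.53
    fescue_effect: float = -0.59
    age_class_effects: dict[str, float] = field(
        default_factory=lambda: {"1": 0.20, "2": 0.30, "3": 0.15, "other": 0.0}
    )
    mean_score: float = 3.0
    n_farms: int = 5
    n_years: int = 3
    cg_effect_sd: float = 0.30
    records_min: int = 1
    records_max: int = 3
    fescue_switch_prob: float = 0.2
    discretize: bool = False
    selection: bool = False
    selection_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if min(self.var_additive, self.var_pe, self.var_residual) < 0:
            raise ConfigurationError("variances must be non-negative")
        if self.n_founders < 2 or self.progeny_per_dam < 1:
            raise ConfigurationError("impossible mating structure")
        if not (0.0 <= self.genotyped_fraction <= 1.0):
            raise ConfigurationError("genotyped_fraction must be in [0, 1]")
        if self.records_min < 1 or self.records_max < self.records_min:
            raise ConfigurationError("records_per_animal range invalid")

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic per-stage generator derived from the pipeline seed."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class SimTruth:
    """Ground truth stored alongside simulated phenotypes."""

    true_bv: pd.DataFrame  # animal + one column per genetic variate
    true_pe: pd.DataFrame
    true_fixed: pd.DataFrame  # realized fixed-effect values per record
    realized_h2: float
    realized_repeatability: float


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimConfig) -> PedigreeTable:
    """Random-mating multi-generation pedigree without selection.

    Founders (generation 0) split into dams and sires by ``dam_fraction``
    (deterministically by index parity, so offspring counts follow from the
    mating loop alone).  Each generation, every dam of the previous
    generation produces ``progeny_per_dam`` offspring by a randomly drawn
    sire of that generation; offspring sex alternates F/M.
    """
    rng = config.rng(1)
    rows = []
    n_dams0 = int(round(config.n_founders * config.dam_fraction))
    for i in range(config.n_founders):
        sex = "F" if i < n_dams0 else "M"
        rows.append(("G0_%04d" % i, "", "", sex, 0))
    if n_dams0 == 0 or n_dams0 == config.n_founders:
        if config.n_generations >= 1:
            raise ConfigurationError("need both sexes among founders to breed")
    prev = rows
    for gen in range(1, config.n_generations + 1):
        dams = [r[0] for r in prev if r[3] == "F"]
        sires = [r[0] for r in prev if r[3] == "M"]
        if not dams or not sires:
            raise ConfigurationError(f"generation {gen - 1} lacks one sex")
        new = []
        k = 0
        for dam in dams:
            for _ in range(config.progeny_per_dam):
                sire = sires[int(rng.integers(len(sires)))]
                sex = "F" if k % 2 == 0 else "M"
                new.append((f"G{gen}_%04d" % k, sire, dam, sex, gen))
                k += 1
        rows += new
        prev = new
    df = pd.DataFrame(rows, columns=["animal", "sire", "dam", "sex", "generation"])
    df["birth_year"] = BASE_YEAR + df["generation"]
    return build_pedigree(df)


# ---------------------------------------------------------------------------
# Genotypes (gene dropping, unlinked SNPs)
# ---------------------------------------------------------------------------

def simulate_genotypes(pedigree: PedigreeTable, config: SimConfig) -> GenotypeMatrix:
    """Drop founder haplotypes down the pedigree at unlinked SNPs.

    Founder allele frequencies are uniform on ``maf_range``; each offspring
    receives one uniformly chosen allele per SNP from each parent's pair
    (no linkage), so Mendelian transmission holds exactly.
    """
    rng = config.rng(2)
    n, m = len(pedigree), config.n_snps
    p = rng.uniform(*config.maf_range, size=m)
    hap = np.zeros((n, m, 2), dtype=np.int8)
    sire, dam = pedigree.parent_indices()
    for i in range(n):
        for slot, parent in enumerate((sire[i], dam[i])):
            if parent < 0:
                hap[i, :, slot] = rng.random(m) < p
            else:
                pick = rng.integers(2, size=m)
                hap[i, :, slot] = hap[parent, np.arange(m), pick]
    counts = hap.sum(axis=2).astype(float)
    which = (
        rng.random(n) < config.genotyped_fraction
        if config.genotyped_fraction < 1.0
        else np.ones(n, dtype=bool)
    )
    snps = pd.DataFrame(
        {
            "snp": [f"snp{j + 1}" for j in range(m)],
            "chrom": (np.arange(m) % 29 + 1).astype(str),
            "pos": (np.arange(m) // 29 + 1) * 100_000,
            "a1": "B",
            "a2": "A",
        }
    )
    return GenotypeMatrix(pedigree.animals[which], snps, counts[which])


# ---------------------------------------------------------------------------
# Breeding values (infinitesimal gene dropping)
# ---------------------------------------------------------------------------

def simulate_breeding_values(
    pedigree: PedigreeTable,
    g0: np.ndarray,
    rng: np.random.Generator,
    inbreeding_f: np.ndarray | None = None,
) -> np.ndarray:
    """(n_animals x k) true breeding values dropped down the pedigree.

    Founders draw from N(0, g0); an offspring is the parent average plus
    Mendelian-sampling noise N(0, 0.5 (1 - (F_s + F_d)/2) g0), so the
    covariance of the result is A kron-scaled by g0 and the
    parent-offspring regression slope is 0.5.
    """
    g0 = np.atleast_2d(np.asarray(g0, dtype=float))
    k = g0.shape[0]
    n = len(pedigree)
    L = np.linalg.cholesky(g0 + 1e-12 * np.eye(k))
    f = (
        np.diag(a_matrix(pedigree).dense()) - 1.0
        if inbreeding_f is None
        else inbreeding_f
    )
    sire, dam = pedigree.parent_indices()
    bv = np.zeros((n, k))
    z = rng.standard_normal((n, k))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            ms_var = 0.5 * (1.0 - 0.5 * (f[s] + f[d]))
            bv[i] = 0.5 * (bv[s] + bv[d]) + np.sqrt(ms_var) * (z[i] @ L.T)
        elif s >= 0 or d >= 0:
            p = max(s, d)
            bv[i] = 0.5 * bv[p] + np.sqrt(0.75 - 0.25 * f[p]) * (z[i] @ L.T)
        else:
            bv[i] = z[i] @ L.T
    return bv


# ---------------------------------------------------------------------------
# Phenotypes: univariate hair shedding
# ---------------------------------------------------------------------------

def _score_years(config: SimConfig) -> np.ndarray:
    first = BASE_YEAR + config.n_generations + 1
    return np.arange(first, first + config.n_years)


def _assign_cows(pedigree: PedigreeTable, config: SimConfig, rng) -> pd.DataFrame:
    """Per-cow covariates: farm, calving season, base fescue status."""
    tab = pedigree.table
    cows = tab[tab["sex"] == "F"].copy()
    cows["farm_id"] = np.array(
        [f"farm{j + 1}" for j in rng.integers(config.n_farms, size=len(cows))]
    )
    cows["calving_season"] = np.where(rng.random(len(cows)) < 0.6, "spring", "fall")
    cows["base_fescue"] = np.where(rng.random(len(cows)) < 0.5, "yes", "no")
    return cows


def simulate_phenotypes(
    pedigree: PedigreeTable,
    config: SimConfig,
    bv: np.ndarray | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Repeated yearly hair shedding scores for every female.

    Each record is mean + contemporary-group effect (farm x year,
    N(0, cg_effect_sd^2)) + age-class effect + fescue-status effect +
    breeding value + permanent environment + fresh residual.  Scores stay
    continuous unless ``config.discretize`` clips them to the 1-5 scale.
    """
    if config.var_residual <= 0 and config.var_additive <= 0:
        raise ConfigurationError("missing variance components")
    rng = config.rng(3)
    if bv is None:
        bv = simulate_breeding_values(
            pedigree, np.array([[config.var_additive]]), config.rng(4)
        )
    bv = np.asarray(bv, dtype=float).reshape(len(pedigree), -1)[:, 0]
    idx = pedigree.index_of()
    cows = _assign_cows(pedigree, config, rng)
    pe = rng.normal(0.0, np.sqrt(config.var_pe), size=len(cows))
    years = _score_years(config)
    cg_effects: dict[tuple, float] = {}
    recs = []
    fixed_rows = []
    for (row, pe_i) in zip(cows.itertuples(), pe):
        n_rec = int(rng.integers(config.records_min, config.records_max + 1))
        first = max(years[0], row.birth_year + 1)
        status = row.base_fescue
        switch_at = (
            int(rng.integers(1, n_rec)) if (n_rec > 1 and rng.random() < config.fescue_switch_prob) else -1
        )
        for j in range(n_rec):
            year = first + j
            if year > years[-1]:
                break
            if j == switch_at:
                status = "no" if status == "yes" else "yes"
            k = year - row.birth_year
            age_days = 365 * k + SCORE_DAY_OFFSET
            four = str(k) if k <= 3 else "other"
            cg_key = (row.farm_id, year)
            if cg_key not in cg_effects:
                cg_effects[cg_key] = rng.normal(0.0, config.cg_effect_sd)
            fixed = (
                config.mean_score
                + cg_effects[cg_key]
                + config.age_class_effects.get(four, 0.0)
                + (config.fescue_effect if status == "no" else 0.0)
            )
            resid = rng.normal(0.0, np.sqrt(config.var_residual))
            score = fixed + bv[idx[row.animal]] + pe_i + resid
            if config.discretize:
                score = float(np.clip(np.rint(score), 1, 5))
            recs.append(
                {
                    "animal_id": row.animal,
                    "score": score,
                    "date": f"{year}-05-20",
                    "year": year,
                    "farm_id": row.farm_id,
                    "calving_season": row.calving_season,
                    "fescue_status": status,
                    "sex": "F",
                    "birth_date": f"{row.birth_year}-03-01",
                    "age_days": age_days,
                }
            )
            fixed_rows.append({"animal_id": row.animal, "year": year, "fixed": fixed,
                               "residual": resid})
    records = pd.DataFrame(recs)
    scored = records["animal_id"].unique()
    scored_pos = [idx[a] for a in scored]
    pe_map = dict(zip(cows["animal"], pe))
    var_bv = float(np.var(bv[scored_pos]))
    var_pe_emp = float(np.var([pe_map[a] for a in scored]))
    var_e_emp = float(np.var([r["residual"] for r in fixed_rows]))
    total = var_bv + var_pe_emp + var_e_emp
    truth = SimTruth(
        true_bv=pd.DataFrame({"animal": pedigree.animals, "u": bv}),
        true_pe=pd.DataFrame({"animal": cows["animal"], "p": pe}),
        true_fixed=pd.DataFrame(fixed_rows),
        realized_h2=var_bv / total,
        realized_repeatability=(var_bv + var_pe_emp) / total,
    )
    return records, truth


# ---------------------------------------------------------------------------
# Phenotypes: bivariate fescue (two status-traits)
# ---------------------------------------------------------------------------

def default_fescue_g0(r_g: float = 0.93) -> np.ndarray:
    """2x2 genetic covariance for (not grazing, grazing) status-traits."""
    va_no, va_yes = 0.30, 0.38
    c = r_g * np.sqrt(va_no * va_yes)
    return np.array([[va_no, c], [c, va_yes]])


#: Per-status (not grazing, grazing) permanent-environment and residual
#: variances consistent with the evaluation's phenotypic variances.
FESCUE_PE = (0.023, 0.025)
FESCUE_RESID = (0.627, 0.495)


def simulate_phenotypes_bivariate(
    pedigree: PedigreeTable,
    config: SimConfig,
    g0: np.ndarray | None = None,
    pe_var: tuple[float, float] = FESCUE_PE,
    resid_var: tuple[float, float] = FESCUE_RESID,
) -> tuple[pd.DataFrame, SimTruth]:
    """Scores where grazing status defines the trait (no fixed status effect).

    Trait order is sorted status order ("no"=0, "yes"=1).  Each cow-year
    record expresses the breeding value and permanent-environment effect of
    its status-trait; some cows switch status across years, linking the
    traits at the phenotype level as well as through the pedigree.
    """
    rng = config.rng(5)
    g0 = default_fescue_g0() if g0 is None else np.asarray(g0, dtype=float)
    if np.any(np.linalg.eigvalsh(g0) < -1e-9):
        raise ConfigurationError("genetic covariance not positive semi-definite")
    bv = simulate_breeding_values(pedigree, g0, config.rng(6))
    idx = pedigree.index_of()
    cows = _assign_cows(pedigree, config, rng)
    pe = rng.normal(size=(len(cows), 2)) * np.sqrt(np.asarray(pe_var))
    years = _score_years(config)
    cg_effects: dict[tuple, float] = {}
    recs = []
    for ci, row in enumerate(cows.itertuples()):
        n_rec = int(rng.integers(max(config.records_min, 2), config.records_max + 1))
        first = max(years[0], row.birth_year + 1)
        status = row.base_fescue
        switch_at = (
            int(rng.integers(1, n_rec)) if rng.random() < config.fescue_switch_prob else -1
        )
        for j in range(n_rec):
            year = first + j
            if year > years[-1]:
                break
            if j == switch_at:
                status = "no" if status == "yes" else "yes"
            t = 0 if status == "no" else 1
            k = year - row.birth_year
            cg_key = (row.farm_id, year)
            if cg_key not in cg_effects:
                cg_effects[cg_key] = rng.normal(0.0, config.cg_effect_sd)
            score = (
                config.mean_score
                + cg_effects[cg_key]
                + bv[idx[row.animal], t]
                + pe[ci, t]
                + rng.normal(0.0, np.sqrt(resid_var[t]))
            )
            recs.append(
                {
                    "animal_id": row.animal,
                    "score": score,
                    "year": year,
                    "farm_id": row.farm_id,
                    "calving_season": row.calving_season,
                    "fescue_status": status,
                    "age_days": 365 * k + SCORE_DAY_OFFSET,
                }
            )
    records = pd.DataFrame(recs)
    truth = SimTruth(
        true_bv=pd.DataFrame(
            {"animal": pedigree.animals, "u_no": bv[:, 0], "u_yes": bv[:, 1]}
        ),
        true_pe=pd.DataFrame(
            {"animal": cows["animal"], "p_no": pe[:, 0], "p_yes": pe[:, 1]}
        ),
        true_fixed=pd.DataFrame(),
        realized_h2=np.nan,
        realized_repeatability=np.nan,
    )
    return records, truth


# ---------------------------------------------------------------------------
# Bivariate maternal weaning weight
# ---------------------------------------------------------------------------

def default_maternal_g0(
    r_hs_mww: float = -0.19,
    r_direct_mww: float = -0.43,
    r_hs_direct: float = -0.03,
    var_direct: float = 200.0,
    var_mhs: float = 0.38,
    var_mww: float = 150.0,
) -> np.ndarray:
    """3x3 genetic covariance over (u_ww, m_hs, m_ww)."""
    sd = np.sqrt([var_direct, var_mhs, var_mww])
    corr = np.array(
        [
            [1.0, r_hs_direct, r_direct_mww],
            [r_hs_direct, 1.0, r_hs_mww],
            [r_direct_mww, r_hs_mww, 1.0],
        ]
    )
    return corr * np.outer(sd, sd)


@dataclass
class WWSimResult:
    hs_records: pd.DataFrame
    ww_records: pd.DataFrame
    truth: SimTruth
    pedigree: PedigreeTable  # input pedigree extended with the calves


def simulate_ww_bivariate(
    pedigree: PedigreeTable,
    config: SimConfig,
    g0: np.ndarray | None = None,
    mpe_var: tuple[float, float] = (0.04, 80.0),
    resid_var: tuple[float, float] = (0.53, 300.0),
    mean_ww: float = 220.0,
    calf_prob: float = 0.85,
    n_score_years: int = 3,
) -> WWSimResult:
    """Dam hair shedding paired with calf weaning weight, dam-year by dam-year.

    Every female is scored in ``n_score_years`` consecutive years.  In each
    scored year she weans one calf with probability ``calf_prob``; the calf
    (a new pedigree entry, random sire) expresses its own direct breeding
    value plus the dam's maternal effect.  Otherwise a "dummy calf" with
    unknown sire and missing weight is created, so every dam-year has a calf
    row.  Non-founder animals of the input pedigree additionally carry their
    own historical weaning weight (their dam is known, so her maternal
    effect is attributable); these dam-as-calf records are what anchor the
    direct-maternal covariance.  Weights arrive pre-adjusted (age-of-dam
    and 205-day adjusted), so no age covariates enter the weaning-weight
    side.
    """
    g0 = default_maternal_g0() if g0 is None else np.asarray(g0, dtype=float)
    if np.any(np.linalg.eigvalsh(g0) < -1e-9):
        raise ConfigurationError("genetic covariance not positive semi-definite")
    rng = config.rng(7)
    base = pedigree.table.copy()
    females = base[base["sex"] == "F"]["animal"].tolist()
    males = base[base["sex"] == "M"]["animal"].tolist()
    years = [BASE_YEAR + config.n_generations + 1 + j for j in range(n_score_years)]
    calf_rows = []
    plan = []  # (dam, year, calf_id, real)
    k = 0
    for dam in females:
        for year in years:
            real = bool(rng.random() < calf_prob)
            calf = f"C{year}_%04d" % k
            k += 1
            sire = males[int(rng.integers(len(males)))] if real else ""
            calf_rows.append(
                {"animal": calf, "sire": sire, "dam": dam,
                 "sex": "F" if k % 2 else "M",
                 "generation": config.n_generations + 1, "birth_year": year}
            )
            plan.append((dam, year, calf, real))
    ext = build_pedigree(pd.concat([base, pd.DataFrame(calf_rows)], ignore_index=True))
    bv = simulate_breeding_values(ext, g0, config.rng(8))
    idx = ext.index_of()
    mpe = rng.normal(size=(len(females), 2)) * np.sqrt(np.asarray(mpe_var))
    mpe_of = dict(zip(females, mpe))
    farm_of = {
        f: f"farm{j + 1}" for f, j in zip(females, rng.integers(config.n_farms, size=len(females)))
    }
    cg_effects_hs: dict[tuple, float] = {}
    cg_effects_ww: dict[tuple, float] = {}
    hs_rows, ww_rows = [], []
    # Own historical weaning weights of the input pedigree's non-founders.
    mpe_hist: dict[str, np.ndarray] = {}
    for row in base.itertuples():
        if not row.dam or rng.random() > 0.9:
            continue
        if row.dam not in mpe_hist:
            mpe_hist[row.dam] = (
                mpe_of[row.dam]
                if row.dam in mpe_of
                else rng.normal(size=2) * np.sqrt(np.asarray(mpe_var))
            )
        key = ("ww", "hist", row.birth_year)
        if key not in cg_effects_ww:
            cg_effects_ww[key] = rng.normal(0.0, 10.0)
        weight = (
            mean_ww
            + cg_effects_ww[key]
            + bv[idx[row.animal], 0]
            + bv[idx[row.dam], 2]
            + mpe_hist[row.dam][1]
            + rng.normal(0.0, np.sqrt(resid_var[1]))
        )
        ww_rows.append(
            {"calf_id": row.animal, "dam_id": row.dam, "weight": weight,
             "year": int(row.birth_year), "farm_id": "hist",
             "cg_id": f"hist/{row.birth_year}"}
        )
    for dam, year, calf, real in plan:
        farm = farm_of[dam]
        for key, store, sd in ((("hs", farm, year), cg_effects_hs, config.cg_effect_sd),
                               (("ww", farm, year), cg_effects_ww, 10.0)):
            if key not in store:
                store[key] = rng.normal(0.0, sd)
        score = (
            config.mean_score
            + cg_effects_hs[("hs", farm, year)]
            + bv[idx[dam], 1]
            + mpe_of[dam][0]
            + rng.normal(0.0, np.sqrt(resid_var[0]))
        )
        hs_rows.append(
            {"animal_id": dam, "score": score, "year": year, "farm_id": farm,
             "cg_id": f"{farm}/{year}"}
        )
        weight = np.nan
        if real:
            weight = (
                mean_ww
                + cg_effects_ww[("ww", farm, year)]
                + bv[idx[calf], 0]
                + bv[idx[dam], 2]
                + mpe_of[dam][1]
                + rng.normal(0.0, np.sqrt(resid_var[1]))
            )
        ww_rows.append(
            {"calf_id": calf, "dam_id": dam, "weight": weight, "year": year,
             "farm_id": farm, "cg_id": f"{farm}/{year}"}
        )
    truth = SimTruth(
        true_bv=pd.DataFrame(
            {"animal": ext.animals, "u_ww": bv[:, 0], "m_hs": bv[:, 1],
             "m_ww": bv[:, 2]}
        ),
        true_pe=pd.DataFrame(
            {"animal": females, "mpe_hs": mpe[:, 0], "mpe_ww": mpe[:, 1]}
        ),
        true_fixed=pd.DataFrame(),
        realized_h2=np.nan,
        realized_repeatability=np.nan,
    )
    return WWSimResult(pd.DataFrame(hs_rows), pd.DataFrame(ww_rows), truth, ext)


# ---------------------------------------------------------------------------
# Selection (negative control for validation tests)
# ---------------------------------------------------------------------------

def simulate_selected_population(
    config: SimConfig,
) -> tuple[PedigreeTable, np.ndarray]:
    """Pedigree bred under truncation selection on the trait, with its BVs.

    Each generation, only the top ``selection_fraction`` of candidate dams
    and sires by phenotype (bv + residual-scale noise) become parents.
    Breeding values co-generate with the pedigree (founders N(0, var_a),
    offspring midparent + N(0, var_a/2)); use this to demonstrate the
    dispersion the LR method detects when selection is ignored.
    """
    rng = config.rng(9)
    sd_a = np.sqrt(config.var_additive)
    sd_e = np.sqrt(config.var_residual + config.var_pe)
    rows, bvs = [], []
    n_dams0 = int(round(config.n_founders * config.dam_fraction))
    for i in range(config.n_founders):
        rows.append(("G0_%04d" % i, "", "", "F" if i < n_dams0 else "M", 0))
        bvs.append(rng.normal(0.0, sd_a))
    prev = list(range(config.n_founders))
    for gen in range(1, config.n_generations + 1):
        pheno = np.array([bvs[i] + rng.normal(0.0, sd_e) for i in prev])
        cand_f = [i for i in prev if rows[i][3] == "F"]
        cand_m = [i for i in prev if rows[i][3] == "M"]
        keep_f = max(1, int(len(cand_f) * config.selection_fraction))
        keep_m = max(1, int(len(cand_m) * config.selection_fraction))
        # Lower score is the favorable direction (earlier shedding).
        dams = sorted(cand_f, key=lambda i: pheno[prev.index(i)])[:keep_f]
        sires = sorted(cand_m, key=lambda i: pheno[prev.index(i)])[:keep_m]
        new = []
        k = 0
        for d in dams:
            for _ in range(config.progeny_per_dam):
                s = sires[int(rng.integers(len(sires)))]
                ms = rng.normal(0.0, sd_a * np.sqrt(0.5))
                rows.append(
                    (f"G{gen}_%04d" % k, rows[s][0], rows[d][0],
                     "F" if k % 2 == 0 else "M", gen)
                )
                bvs.append(0.5 * (bvs[s] + bvs[d]) + ms)
                new.append(len(rows) - 1)
                k += 1
        prev = new
    df = pd.DataFrame(rows, columns=["animal", "sire", "dam", "sex", "generation"])
    df["birth_year"] = BASE_YEAR + df["generation"]
    ped = build_pedigree(df)
    order = {a: i for i, a in enumerate(df["animal"])}
    bv_arr = np.array(bvs)[[order[a] for a in ped.animals]]
    return ped, bv_arr


def write_truth_tsv(truth: SimTruth, path) -> None:
    """Persist per-animal true breeding values (long format) for recovery tests."""
    long = truth.true_bv.melt(id_vars="animal", var_name="trait", value_name="true_bv")
    long.to_csv(path, sep="\t", index=False)
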