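"""Mixed-model equations and REML against dense-algebra oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from shedeval.mme import MMESystem, fixed_design, group_from_records
from shedeval.models import (
    aic,
    build_univariate,
    compare_models,
    ebv_from_fit,
    fit_univariate,
    genetic_parameters,
    phenotypic_regression,
)
from shedeval.relatedness import (
    RelationshipMatrix,
    a22,
    a_inverse,
    a_matrix,
    h_inverse,
    inverse_of,
)
from shedeval.reml import VarianceComponents, reml_estimate
from shedeval.simulate import (
    SimConfig,
    simulate_pedigree,
    simulate_phenotypes,
)


def _toy_system(ped, rng, n_rec=12, s2a=0.4, s2pe=0.1, s2e=0.5):
    animals = list(ped.animals)
    rec_animals = rng.choice(animals[2:], size=n_rec)
    y = rng.normal(3, 1, n_rec)
    df = pd.DataFrame({"animal_id": rec_animals, "score": y,
                       "cg": rng.choice(["a", "b"], n_rec)})
    X, names = fixed_design(df, ["cg"])
    rows = np.arange(n_rec)
    A = a_matrix(ped).dense()
    gen = group_from_records(
        "genetic", ("u",), ped.animals, [(rows, 0, rec_animals)],
        sp.csr_matrix(np.linalg.inv(A)), np.array([[s2a]]),
    )
    pe = group_from_records(
        "pe", ("p",), pd.Index(pd.unique(rec_animals)),
        [(rows, 0, rec_animals)], None, np.array([[s2pe]]),
    )
    system = MMESystem(y, X, [gen, pe], resid_var=s2e, xnames=names)
    return system, df, A


class TestMMEAssembly:
    def test_intercept_only_solution_is_mean(self, rng):
        y = rng.normal(5, 1, 20)
        X, _ = fixed_design(pd.DataFrame(index=range(20)), [])
        lev = pd.Index([f"r{i}" for i in range(20)])
        g = group_from_records(
            "pe", ("p",), lev, [(np.arange(20), 0, list(lev))], None,
            np.array([[1e-8]]),  # negligible random effect
        )
        system = MMESystem(y, X, [g], resid_var=1.0)
        sol = system.solve()
        assert sol[0] == pytest.approx(y.mean(), abs=1e-6)

    def test_equation_count_bookkeeping(self, small_pedigree, rng):
        system, df, _ = _toy_system(small_pedigree, rng)
        n_pe = df["animal_id"].nunique()
        assert system.n_eq == 2 + len(small_pedigree) + n_pe

    def test_mme_equals_dense_gls(self, small_pedigree, rng):
        """EBVs from the MME match hat(g) = G0 Z' V^-1 (y - X bhat)."""
        system, df, A = _toy_system(small_pedigree, rng)
        sol = system.solve()
        X = system.X.toarray()
        Z1 = system.groups[0].Z.toarray()
        Z2 = system.groups[1].Z.toarray()
        V = 0.4 * Z1 @ A @ Z1.T + 0.1 * Z2 @ Z2.T + 0.5 * np.eye(len(df))
        Vi = np.linalg.inv(V)
        bhat = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ system.y)
        uhat = 0.4 * A @ Z1.T @ Vi @ (system.y - X @ bhat)
        np.testing.assert_allclose(sol[: X.shape[1]], bhat, atol=1e-8)
        off, g = system.group_offset("genetic")
        np.testing.assert_allclose(sol[off: off + g.q], uhat, atol=1e-8)

    def test_solver_residual_small(self, small_pedigree, rng):
        system, _, _ = _toy_system(small_pedigree, rng)
        sol = system.solve()
        C = system.coefficient_matrix()
        resid = np.abs(C @ sol - system.rhs()).max()
        assert resid < 1e-8 * max(np.abs(system.rhs()).max(), 1.0)

    def test_solution_invariant_to_record_order(self, small_pedigree, rng):
        system, df, _ = _toy_system(small_pedigree, rng)
        sol = system.solve()
        perm = rng.permutation(len(df))
        df2 = df.iloc[perm].reset_index(drop=True)
        X2, _ = fixed_design(df2, ["cg"])
        rows = np.arange(len(df2))
        A = a_matrix(small_pedigree).dense()
        gen2 = group_from_records(
            "genetic", ("u",), small_pedigree.animals,
            [(rows, 0, df2["animal_id"].to_numpy())],
            sp.csr_matrix(np.linalg.inv(A)), np.array([[0.4]]),
        )
        pe_levels = pd.Index(pd.unique(df["animal_id"]))  # same level order
        pe2 = group_from_records(
            "pe", ("p",), pe_levels, [(rows, 0, df2["animal_id"].to_numpy())],
            None, np.array([[0.1]]),
        )
        system2 = MMESystem(df2["score"].to_numpy(), X2, [gen2, pe2], resid_var=0.5)
        np.testing.assert_allclose(system2.solve(), sol, atol=1e-8)

    def test_inverse_diagonal_matches_dense_inverse(self, rng):
        cfg = SimConfig(n_founders=6, n_generations=1, progeny_per_dam=2, seed=2)
        ped = simulate_pedigree(cfg)
        system, _, _ = _toy_system(ped, rng, n_rec=10)
        _, cinv, _ = system.solve_dense()
        C = system.coefficient_matrix().toarray()
        np.testing.assert_allclose(np.diag(cinv), np.diag(np.linalg.inv(C)),
                                   atol=1e-8)


class TestREML:
    def test_balanced_half_sib_matches_anova(self):
        """Closed-form oracle: with balanced one-way data REML equals the
        ANOVA expected-mean-squares estimator exactly."""
        ns, nprog = 50, 20
        rng = np.random.default_rng(42)
        sire_eff = rng.normal(0, np.sqrt(0.2), ns)
        y = np.repeat(sire_eff, nprog) + rng.normal(0, 1.0, ns * nprog)
        sires = np.repeat([f"s{i:02d}" for i in range(ns)], nprog)
        X = sp.csr_matrix(np.ones((len(y), 1)))
        g = group_from_records(
            "genetic", ("s",), pd.Index([f"s{i:02d}" for i in range(ns)]),
            [(np.arange(len(y)), 0, sires)], None, np.array([[0.1]]),
        )
        fit = reml_estimate(MMESystem(y, X, [g], resid_var=1.0), tol=1e-10)
        gm = y.reshape(ns, nprog).mean(axis=1)
        msb = nprog * ((gm - y.mean()) ** 2).sum() / (ns - 1)
        msw = ((y.reshape(ns, nprog) - gm[:, None]) ** 2).sum() / (ns * (nprog - 1))
        assert fit.vc.group_covs["genetic"][0, 0] == pytest.approx(
            (msb - msw) / nprog, abs=1e-6
        )
        assert fit.vc.resid_var[0] == pytest.approx(msw, abs=1e-6)

    def test_null_heritability_recovered(self):
        cfg = SimConfig(n_founders=120, n_generations=2, progeny_per_dam=4,
                        var_additive=0.0, var_pe=0.0, var_residual=0.95, seed=3)
        ped = simulate_pedigree(cfg)
        rec, _ = simulate_phenotypes(ped, cfg)
        rec["cg_id"] = rec["farm_id"].astype(str) + "/" + rec["year"].astype(str)
        fit = fit_univariate(rec, a_inverse(ped), tol=1e-6)
        gp = genetic_parameters(fit.vc)
        assert gp.h2 < 0.05

    def test_rescaling_response_rescales_components(self, small_pedigree, rng):
        """Multiplying y by c multiplies every variance by c^2 and leaves
        the variance ratios (h2, repeatability) unchanged."""
        system, df, A = _toy_system(small_pedigree, rng, n_rec=120)
        fit1 = reml_estimate(system, tol=1e-8)
        c = 3.0
        X, _ = fixed_design(df, ["cg"])
        rows = np.arange(len(df))
        gen = group_from_records(
            "genetic", ("u",), small_pedigree.animals,
            [(rows, 0, df["animal_id"].to_numpy())],
            sp.csr_matrix(np.linalg.inv(A)), np.array([[0.4 * c**2]]),
        )
        pe = group_from_records(
            "pe", ("p",), pd.Index(pd.unique(df["animal_id"])),
            [(rows, 0, df["animal_id"].to_numpy())], None,
            np.array([[0.1 * c**2]]),
        )
        fit2 = reml_estimate(
            MMESystem(c * system.y, X, [gen, pe], resid_var=0.5 * c**2),
            tol=1e-8,
        )
        for name in ("genetic", "pe"):
            np.testing.assert_allclose(
                fit2.vc.group_covs[name], c**2 * fit1.vc.group_covs[name],
                rtol=1e-3, atol=1e-6,
            )
        np.testing.assert_allclose(
            fit2.vc.resid_var, c**2 * fit1.vc.resid_var, rtol=1e-3
        )

    def test_h_equals_a_when_gw_is_a22(self, small_pedigree, rng):
        cfg = SimConfig(n_founders=16, n_generations=2, progeny_per_dam=2, seed=5,
                        records_min=2, records_max=2)
        rec, _ = simulate_phenotypes(small_pedigree, cfg)
        rec["cg_id"] = rec["farm_id"].astype(str) + "/" + rec["year"].astype(str)
        gen_idx = pd.Index(list(small_pedigree.animals))
        A22m = a22(small_pedigree, gen_idx)
        hinv = h_inverse(
            a_inverse(small_pedigree), inverse_of(A22m), inverse_of(A22m), gen_idx
        )
        sys_a = build_univariate(rec, a_inverse(small_pedigree))
        sys_h = build_univariate(rec, hinv)
        np.testing.assert_allclose(sys_h.solve(), sys_a.solve(), atol=1e-8)

    def test_reliability_within_unit_interval(self, small_pedigree, rng):
        cfg = SimConfig(n_founders=16, n_generations=2, progeny_per_dam=2, seed=6)
        rec, _ = simulate_phenotypes(small_pedigree, cfg)
        rec["cg_id"] = rec["farm_id"].astype(str) + "/" + rec["year"].astype(str)
        fit = fit_univariate(rec, a_inverse(small_pedigree), tol=1e-6)
        tab = ebv_from_fit(fit).table
        assert ((tab["reliability"] >= 0) & (tab["reliability"] <= 1)).all()
        assert (tab["pev"] >= 0).all()


class TestGeneticParameters:
    def test_ratio_arithmetic(self):
        vc = _vc(0.38, 0.04, 0.53)
        gp = genetic_parameters(vc)
        assert gp.h2 == pytest.approx(0.40)
        assert gp.repeatability == pytest.approx(0.442, abs=5e-4)

    def test_zero_pe_makes_repeatability_equal_h2(self):
        gp = genetic_parameters(_vc(0.30, 0.0, 0.58))
        assert gp.repeatability == pytest.approx(gp.h2)
        assert gp.h2 == pytest.approx(0.30 / 0.88, abs=1e-6)

    def test_zero_total_variance_raises(self):
        with pytest.raises(ValueError):
            genetic_parameters(_vc(0.0, 0.0, 0.0))


def _vc(a, pe, e):
    return VarianceComponents(
        group_covs={"genetic": np.array([[a]]), "pe": np.array([[pe]])},
        resid_var=np.array([e]),
        param_index=[("g", "genetic", 0, 0), ("g", "pe", 0, 0), ("r", 0)],
        cov_params=np.eye(3) * 1e-4,
        logl_reml=0.0, logl_ml=0.0, n_params=3, converged=True, n_iter=1,
    )


class TestModelComparison:
    def _fit(self, age_effect: float, seed: int):
        effects = {"1": age_effect, "2": age_effect * 0.6,
                   "3": age_effect * 0.25, "other": 0.0}
        cfg = SimConfig(n_founders=80, n_generations=2, progeny_per_dam=4,
                        records_min=2, records_max=3,
                        age_class_effects=effects, seed=seed)
        ped = simulate_pedigree(cfg)
        rec, _ = simulate_phenotypes(ped, cfg)
        rec["cg_id"] = rec["farm_id"].astype(str) + "/" + rec["year"].astype(str)
        rec["age_group"] = rec["age_days"].map(
            lambda d: str((d + 90) // 365) if (d + 90) // 365 <= 3 else "other")
        full = fit_univariate(rec, a_inverse(ped), fixed=("cg_id", "age_group"),
                              tol=1e-6)
        null = fit_univariate(rec, a_inverse(ped), tol=1e-6)
        return full, null

    def test_identical_models_lrt_zero(self):
        full, _ = self._fit(0.0, seed=11)
        cmp_ = compare_models(full, full)
        assert cmp_.lrt_stat == pytest.approx(0.0, abs=1e-6)
        assert cmp_.lrt_p == 1.0

    def test_aic_arithmetic(self):
        full, _ = self._fit(0.0, seed=11)
        k = full.system.n_fixed + full.vc.n_params
        assert aic(full) == pytest.approx(-2 * full.vc.logl_ml + 2 * k)

    def test_age_effect_detected_when_present(self):
        detected = 0
        for seed in (21, 22, 23):
            full, null = self._fit(1.2, seed=seed)
            cmp_ = compare_models(full, null)
            if cmp_.lrt_p < 1e-3:
                detected += 1
        assert detected == 3

    def test_no_detection_without_effect(self):
        full, null = self._fit(0.0, seed=31)
        cmp_ = compare_models(full, null)
        assert cmp_.lrt_p > 1e-3


class TestPhenotypicRegression:
    def test_noiseless_line_recovered(self):
        s = np.array([1.0, 2, 3, 4, 5, 2, 3])
        w = 300.0 - 2.0 * s
        slope, se = phenotypic_regression(s, w)
        assert slope == pytest.approx(-2.0, abs=1e-10)
        assert se == pytest.approx(0.0, abs=1e-8)

    def test_independent_weights_slope_near_zero(self, rng):
        s = rng.integers(1, 6, size=500).astype(float)
        w = rng.normal(250, 20, size=500)
        slope, se = phenotypic_regression(s, w)
        assert abs(slope) < 3 * se + 1e-9

    def test_true_slope_recovered_within_3_se(self, rng):
        n = 2000
        s = rng.uniform(1, 5, n)
        w = 260.0 - 1.45 * s + rng.normal(0, 15, n)
        slope, se = phenotypic_regression(s, w)
        assert abs(slope - (-1.45)) < 3 * se

    def test_too_few_pairs_raise(self):
        with pytest.raises(ValueError):
            phenotypic_regression([1, 2], [3, 4])
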