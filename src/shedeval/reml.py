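"""Average-information REML with EM fallback.

Variance components are estimated by Newton steps on the REML
log-likelihood using the average-information (AI) matrix.  All required
traces come from the dense inverse of the mixed-model coefficient matrix,
the right trade-off at the desk scales this package runs at (a few
thousand equations).

Newton steps are taken in an unconstrained parametrization — the Cholesky
factor of each free covariance block and the log of each residual
variance — so a step can never produce an invalid component; gradient and
AI matrix are computed on the variance scale and mapped through the
Jacobian.  The first iterations use EM (always inside the parameter
space), and EM is also the fallback when an AI step fails numerically or
worsens the likelihood.

For a group with covariance ``cov kron K``, with ``T`` the group's block
of C^-1 and ``uhat`` its solutions laid out (k x q):

* ``U[a,b] = uhat_a' K^-1 uhat_b``
* ``TK[a,b] = tr(T[a,b] K^-1)``

EM updates ``cov[a,b] = (U[a,b] + TK[a,b]) / q``; the REML gradient for
the (i,j) element (symmetric basis E, S = cov^-1 E cov^-1) is

    -0.5 * [ q tr(cov^-1 E) - sum(S * TK) - sum(E * (cov^-1 U cov^-1)) ]

and the AI matrix is built from working variates
f = Z (E cov^-1 kron I) uhat (genetic) and f = ehat/sigma2_t on trait t
(residual), as AI[i,j] = 0.5 f_i' P f_j.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .mme import MMESystem


class REMLError(RuntimeError):
    """Non-convergence; carries the parameter trajectory."""

    def __init__(self, message: str, trajectory: list[np.ndarray]):
        super().__init__(message)
        self.trajectory = trajectory


@dataclass
class VarianceComponents:
    """Estimated (co)variance matrices with approximate sampling covariance."""

    group_covs: dict[str, np.ndarray]
    resid_var: np.ndarray
    param_index: list[tuple]  # ("g", name, i, j) or ("r", t)
    cov_params: np.ndarray  # inverse AI matrix at convergence
    logl_reml: float
    logl_ml: float
    n_params: int
    converged: bool
    n_iter: int

    def se(self, key: tuple) -> float:
        i = self.param_index.index(key)
        return float(np.sqrt(max(self.cov_params[i, i], 0.0)))

    def param_value(self, key: tuple) -> float:
        kind = key[0]
        if kind == "g":
            _, name, i, j = key
            return float(self.group_covs[name][i, j])
        return float(self.resid_var[key[1]])

    def subcov(self, keys: list[tuple]) -> np.ndarray:
        idx = [self.param_index.index(k) for k in keys]
        return self.cov_params[np.ix_(idx, idx)]


@dataclass
class REMLFit:
    """A converged fit: components plus the final solved system."""

    vc: VarianceComponents
    system: MMESystem
    solutions: np.ndarray
    cinv: np.ndarray


# ---------------------------------------------------------------------------
# Parameter bookkeeping
# ---------------------------------------------------------------------------

def _param_list(system: MMESystem) -> list[tuple]:
    params: list[tuple] = []
    for g in system.groups:
        for i in range(g.k):
            for j in range(i, g.k):
                if g.free[i, j]:
                    params.append(("g", g.name, i, j))
    for t in range(system.n_traits):
        params.append(("r", t))
    return params


def _get_theta(system: MMESystem, params: list[tuple]) -> np.ndarray:
    vals = []
    for p in params:
        if p[0] == "g":
            _, name, i, j = p
            g = next(gr for gr in system.groups if gr.name == name)
            vals.append(g.cov[i, j])
        else:
            vals.append(system.resid_var[p[1]])
    return np.array(vals)


def _set_theta(system: MMESystem, params: list[tuple], theta: np.ndarray) -> bool:
    """Write parameters back; returns False if outside the parameter space."""
    for p, v in zip(params, theta):
        if p[0] == "g":
            _, name, i, j = p
            g = next(gr for gr in system.groups if gr.name == name)
            g.cov[i, j] = v
            g.cov[j, i] = v
        else:
            system.resid_var[p[1]] = v
    if np.any(~np.isfinite(theta)) or np.any(system.resid_var <= 0):
        return False
    for g in system.groups:
        ev = np.linalg.eigvalsh(g.cov)
        # Reject indefinite and numerically singular points: the REML
        # surface is evaluated just inside the boundary instead.
        if ev[0] <= 1e-7 * max(ev[-1], 1e-30):
            return False
    return True


class _Transform:
    """Unconstrained parametrization: Cholesky factors + log variances.

    Groups whose free pattern is the full matrix use the lower Cholesky
    factor of the covariance; groups free only on the diagonal use the log
    of each variance.  Residual variances use logs.  Provides phi <-> theta
    maps and the Jacobian d theta / d phi for the chain rule.
    """

    def __init__(self, system: MMESystem, params: list[tuple]):
        self.system = system
        self.params = params
        self.group_mode: dict[str, str] = {}
        for g in system.groups:
            if g.free.all():
                self.group_mode[g.name] = "chol"
            elif (g.free == np.eye(g.k, dtype=bool)).all():
                self.group_mode[g.name] = "logdiag"
            else:
                self.group_mode[g.name] = "theta"  # no transform; EM only
        # phi layout mirrors params order for logdiag/resid; chol groups
        # contribute their lower-triangle entries in (row-major p>=q) order.
        self.phi_index: list[tuple] = []
        for g in system.groups:
            mode = self.group_mode[g.name]
            if mode == "chol":
                for pq in range(g.k):
                    for q_ in range(pq + 1):
                        self.phi_index.append(("L", g.name, pq, q_))
            elif mode == "logdiag":
                for i in range(g.k):
                    self.phi_index.append(("logv", g.name, i))
            else:
                for i in range(g.k):
                    for j in range(i, g.k):
                        if g.free[i, j]:
                            self.phi_index.append(("raw", g.name, i, j))
        for t in range(system.n_traits):
            self.phi_index.append(("logr", t))

    def usable(self) -> bool:
        return all(m != "theta" for m in self.group_mode.values())

    def phi(self) -> np.ndarray:
        vals = []
        for key in self.phi_index:
            if key[0] == "L":
                _, name, p_, q_ = key
                g = next(gr for gr in self.system.groups if gr.name == name)
                L = np.linalg.cholesky(g.cov + 1e-12 * np.eye(g.k))
                vals.append(L[p_, q_])
            elif key[0] == "logv":
                _, name, i = key
                g = next(gr for gr in self.system.groups if gr.name == name)
                vals.append(np.log(max(g.cov[i, i], 1e-12)))
            elif key[0] == "raw":
                _, name, i, j = key
                g = next(gr for gr in self.system.groups if gr.name == name)
                vals.append(g.cov[i, j])
            else:
                vals.append(np.log(max(self.system.resid_var[key[1]], 1e-12)))
        return np.array(vals)

    def theta_of(self, phi: np.ndarray) -> np.ndarray:
        """Map phi to the variance-scale parameter vector (params order)."""
        covs: dict[str, np.ndarray] = {}
        resid = np.empty(self.system.n_traits)
        Ls: dict[str, np.ndarray] = {}
        for key, v in zip(self.phi_index, phi):
            if key[0] == "L":
                _, name, p_, q_ = key
                g = next(gr for gr in self.system.groups if gr.name == name)
                Ls.setdefault(name, np.zeros((g.k, g.k)))[p_, q_] = v
            elif key[0] == "logv":
                _, name, i = key
                g = next(gr for gr in self.system.groups if gr.name == name)
                covs.setdefault(name, np.zeros((g.k, g.k)))[i, i] = np.exp(v)
            elif key[0] == "raw":
                _, name, i, j = key
                g = next(gr for gr in self.system.groups if gr.name == name)
                c = covs.setdefault(name, np.zeros((g.k, g.k)))
                c[i, j] = v
                c[j, i] = v
            else:
                resid[key[1]] = np.exp(v)
        for name, L in Ls.items():
            covs[name] = L @ L.T
        out = []
        for p in self.params:
            if p[0] == "g":
                out.append(covs[p[1]][p[2], p[3]])
            else:
                out.append(resid[p[1]])
        return np.array(out)

    def jacobian(self) -> np.ndarray:
        """J[t, f] = d theta_t / d phi_f at the system's current values."""
        J = np.zeros((len(self.params), len(self.phi_index)))
        Ls = {
            g.name: np.linalg.cholesky(g.cov + 1e-12 * np.eye(g.k))
            for g in self.system.groups
            if self.group_mode[g.name] == "chol"
        }
        for fi, key in enumerate(self.phi_index):
            for ti, p in enumerate(self.params):
                if key[0] == "L" and p[0] == "g" and p[1] == key[1]:
                    _, name, p_, q_ = key
                    _, _, i, j = p
                    L = Ls[name]
                    v = 0.0
                    if i == p_:
                        v += L[j, q_]
                    if j == p_:
                        v += L[i, q_]
                    J[ti, fi] = v
                elif key[0] == "logv" and p[0] == "g" and p[1] == key[1]:
                    if (p[2], p[3]) == (key[2], key[2]):
                        g = next(gr for gr in self.system.groups if gr.name == key[1])
                        J[ti, fi] = g.cov[key[2], key[2]]
                elif key[0] == "raw" and p[0] == "g" and p[1] == key[1]:
                    if (p[2], p[3]) == (key[2], key[3]):
                        J[ti, fi] = 1.0
                elif key[0] == "logr" and p[0] == "r" and p[1] == key[1]:
                    J[ti, fi] = self.system.resid_var[key[1]]
        return J


def _tk_matrix(g, cinv_block: np.ndarray) -> np.ndarray:
    """TK[a,b] = tr(T_block[a,b] @ K^-1) from the sparse K^-1 pattern."""
    kcoo = sp.coo_matrix(g.kinv)
    kr, kc, kv = kcoo.row, kcoo.col, kcoo.data
    q, k = g.q, g.k
    TK = np.empty((k, k))
    for a in range(k):
        for b in range(k):
            Tab = cinv_block[a * q: (a + 1) * q, b * q: (b + 1) * q]
            TK[a, b] = float(np.dot(kv, Tab[kc, kr]))
    return 0.5 * (TK + TK.T)


# ---------------------------------------------------------------------------
# Main driver
# ---------------------------------------------------------------------------

def reml_estimate(
    system: MMESystem,
    tol: float = 1e-8,
    max_iter: int = 200,
    n_em_start: int = 2,
    verbose: bool = False,
) -> REMLFit:
    """Estimate all free variance components of an assembled system.

    Starts with ``n_em_start`` EM iterations, then AI (Newton) steps in the
    unconstrained parametrization, backtracking to shorter steps (and
    finally to EM) whenever the restricted likelihood worsens.  Convergence
    is declared when the largest relative component change drops below
    ``tol``, or when the likelihood has stagnated to machine-level changes
    (an EM crawl along a near-boundary ridge).
    """
    params = _param_list(system)
    m = len(params)
    transform = _Transform(system, params)
    scale = max(float(np.var(system.y)), 1e-12)
    trajectory: list[np.ndarray] = []
    converged = False
    it = 0
    ai = np.eye(m)

    log_r_w = -float(np.sum(np.log(system.w)))
    logdet_gk = sum(g.k * g.logdet_k for g in system.groups)

    def m2ll_current(logdet_c: float, ypy: float) -> float:
        return (
            logdet_c
            + float(np.sum(np.log(system.resid_var[system.trait]))) + log_r_w
            + sum(g.q * np.linalg.slogdet(g.cov)[1] for g in system.groups)
            + logdet_gk
            + ypy
        )

    def m2ll_only() -> float:
        """Likelihood at the system's current parameters (no inverse)."""
        from scipy.linalg import cho_factor, cho_solve

        try:
            C = system.coefficient_matrix().toarray()
            cf = cho_factor(C, lower=True, check_finite=False)
            logdet_c = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
            rhs = system.rhs()
            solv = cho_solve(cf, rhs, check_finite=False)
            ypy = system.ywy() - float(rhs @ solv)
            out = m2ll_current(logdet_c, ypy)
            return out if np.isfinite(out) else np.inf
        except (np.linalg.LinAlgError, ValueError):
            return np.inf

    lam = 1e-4  # Levenberg-Marquardt damping, adapted across iterations
    prev_m2ll = np.inf

    for it in range(1, max_iter + 1):
        theta = _get_theta(system, params)
        trajectory.append(theta.copy())
        sol, cinv, logdet_c = system.solve_dense()
        ehat = system.residuals(sol)
        ypy = system.ywy() - float(system.rhs() @ sol)
        m2ll = m2ll_current(logdet_c, ypy)

        # Per-group summaries.
        group_stats = {}
        for off, g in zip(system.offsets, system.groups):
            uhat = sol[off: off + g.k * g.q].reshape(g.k, g.q)
            U = uhat @ (g.kinv @ uhat.T)
            TK = _tk_matrix(g, cinv[off: off + g.k * g.q, off: off + g.k * g.q])
            group_stats[g.name] = (uhat, U, TK)

        # Residual summaries.
        WC = system.W @ cinv
        qvec = np.asarray(system.W.multiply(WC).sum(axis=1)).ravel()
        sum_we2 = np.zeros(system.n_traits)
        sum_wq = np.zeros(system.n_traits)
        for t in range(system.n_traits):
            mask = system.trait == t
            sum_we2[t] = float(np.sum(system.w[mask] * ehat[mask] ** 2))
            sum_wq[t] = float(np.sum(system.w[mask] * qvec[mask]))

        # Gradient on the variance scale.
        grad = np.empty(m)
        for ix, p in enumerate(params):
            if p[0] == "g":
                _, name, i, j = p
                g = next(gr for gr in system.groups if gr.name == name)
                _, U, TK = group_stats[name]
                E = np.zeros((g.k, g.k))
                E[i, j] = 1.0
                E[j, i] = 1.0
                gi = g.cov_inv()
                S = gi @ E @ gi
                tr_pdv = g.q * float(np.sum(gi * E)) - float(np.sum(S * TK))
                quad = float(np.sum(E * (gi @ U @ gi)))
                grad[ix] = -0.5 * (tr_pdv - quad)
            else:
                t = p[1]
                s2 = system.resid_var[t]
                grad[ix] = -0.5 * (
                    system._nt[t] / s2 - sum_wq[t] / s2**2 - sum_we2[t] / s2**2
                )

        # AI matrix from working variates.
        F = np.zeros((len(system.y), m))
        for ix, p in enumerate(params):
            if p[0] == "g":
                _, name, i, j = p
                g = next(gr for gr in system.groups if gr.name == name)
                uhat, _, _ = group_stats[name]
                E = np.zeros((g.k, g.k))
                E[i, j] = 1.0
                E[j, i] = 1.0
                F[:, ix] = g.Z @ ((E @ g.cov_inv()) @ uhat).ravel()
            else:
                t = p[1]
                mask = system.trait == t
                F[mask, ix] = ehat[mask] / system.resid_var[t]
        rinv = system.r_inv()
        RF = rinv[:, None] * F
        S_ = system.W.T @ RF
        PF = RF - rinv[:, None] * (system.W @ (cinv @ S_))
        ai = 0.5 * (F.T @ PF)
        ai = 0.5 * (ai + ai.T)

        def em_theta() -> np.ndarray:
            vals = []
            for p in params:
                if p[0] == "g":
                    _, name, i, j = p
                    g = next(gr for gr in system.groups if gr.name == name)
                    _, U, TK = group_stats[name]
                    vals.append((U[i, j] + TK[i, j]) / g.q)
                else:
                    t = p[1]
                    vals.append((sum_we2[t] + sum_wq[t]) / system._nt[t])
            return np.array(vals)

        # Damped AI (Levenberg-Marquardt) step in the unconstrained
        # parametrization, accepted only if the likelihood does not worsen;
        # EM (monotone by construction) is the fallback.
        new_theta = None
        if it > n_em_start and transform.usable():
            J = transform.jacobian()
            grad_phi = J.T @ grad
            ai_phi = J.T @ ai @ J
            dscale = np.diag(ai_phi).copy()
            dscale[dscale <= 0] = max(dscale.max(), 1.0)
            phi0 = transform.phi()
            for _trial in range(7):
                try:
                    dphi = np.linalg.solve(
                        ai_phi + lam * np.diag(dscale), grad_phi
                    )
                except np.linalg.LinAlgError:
                    break
                cand = transform.theta_of(phi0 + dphi)
                if _set_theta(system, params, cand) and m2ll_only() <= m2ll + 1e-10 * (
                    1.0 + abs(m2ll)
                ):
                    new_theta = cand
                    lam = max(lam / 3.0, 1e-8)
                    break
                lam *= 10.0
        if new_theta is None:
            new_theta = em_theta()
            for ix, p in enumerate(params):
                if p[0] == "r" or p[2] == p[3]:
                    new_theta[ix] = max(new_theta[ix], 1e-10 * scale)
            ok = False
            for _ in range(60):
                if _set_theta(system, params, new_theta):
                    ok = True
                    break
                for ix, p in enumerate(params):
                    if p[0] == "g" and p[2] != p[3]:
                        new_theta[ix] *= 0.9
            if not ok:  # stay at the previous (valid) point
                new_theta = theta
                _set_theta(system, params, new_theta)

        rel_change = np.max(np.abs(new_theta - theta) / (np.abs(theta) + 1e-4 * scale))
        dll = abs(prev_m2ll - m2ll)
        prev_m2ll = m2ll
        if verbose:
            print(
                f"iter {it}: theta={new_theta}, rel_change={rel_change:.3e}, "
                f"-2logL={m2ll:.6f}, lam={lam:.1e}"
            )
        # Converge on parameter stability, or on likelihood stagnation
        # (a crawl along a flat near-boundary ridge).
        if rel_change < tol or (
            it > n_em_start + 1 and dll < 1e-10 * (1.0 + abs(m2ll))
        ):
            converged = True
            break

    if not converged:
        raise REMLError(
            f"REML did not converge in {max_iter} iterations", trajectory
        )

    # Final solve at the converged parameters.
    sol, cinv, logdet_c = system.solve_dense()
    ypy = system.ywy() - float(system.rhs() @ sol)
    logdet_r = float(np.sum(np.log(system.resid_var[system.trait]))) + log_r_w
    logdet_gstar = logdet_gk + sum(
        g.q * np.linalg.slogdet(g.cov)[1] for g in system.groups
    )
    m2ll_reml = logdet_c + logdet_r + logdet_gstar + ypy

    # ML log-likelihood at the REML estimates (for cross-X model
    # comparison): -2 l_ML = -2 l_REML - log|X' V^-1 X|, and
    # log|X'V^-1X| = log|C| - log|C_zz|.
    C = system.coefficient_matrix().toarray()
    zz = C[system.n_fixed:, system.n_fixed:]
    try:
        Lzz = np.linalg.cholesky(zz)
        logdet_zz = 2.0 * float(np.sum(np.log(np.diag(Lzz))))
        m2ll_ml = m2ll_reml - (logdet_c - logdet_zz)
    except np.linalg.LinAlgError:
        m2ll_ml = np.nan

    try:
        cov_params = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        cov_params = np.full((m, m), np.nan)

    vc = VarianceComponents(
        group_covs={g.name: g.cov.copy() for g in system.groups},
        resid_var=system.resid_var.copy(),
        param_index=params,
        cov_params=cov_params,
        logl_reml=-0.5 * m2ll_reml,
        logl_ml=-0.5 * m2ll_ml,
        n_params=m,
        converged=converged,
        n_iter=it,
    )
    return REMLFit(vc=vc, system=system, solutions=sol, cinv=cinv)
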