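"""Henderson's mixed-model equations for repeated-records animal models.

A model is a response vector plus a sparse fixed-effect design and a list of
:class:`RandomGroup` terms.  Each group holds one or more correlated
*variates* (e.g. direct and maternal genetic effects) over a common set of
levels, with covariance ``cov (k x k) kron K``, where K is supplied through
its sparse inverse (pedigree/H inverse) or is the identity.  Residuals are
independent with per-trait variances and optional record weights
(R_ii = sigma2_trait / w_i).

The coefficient matrix is

    C = W' R^-1 W + blockdiag(0, cov_1^-1 kron K_1^-1, ...)

with W = [X | Z_1 | ... ].  Per-trait cross-products are cached so C can be
reassembled cheaply as variance components change during REML.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.linalg import cho_factor, cho_solve
from scipy.linalg.lapack import dpotri


def fixed_design(
    df: pd.DataFrame, factors: list[str]
) -> tuple[sp.csr_matrix, list[str]]:
    """Sparse fixed-effect design matrix.

    The first factor enters with a full set of indicator columns (it absorbs
    the intercept, the natural choice when it is the contemporary group);
    each later factor drops its first level as the identifiability
    constraint.  With no factors, a lone intercept column is returned.
    """
    n = len(df)
    if not factors:
        return sp.csr_matrix(np.ones((n, 1))), ["intercept"]
    blocks, names = [], []
    for k, f in enumerate(factors):
        codes, levels = pd.factorize(df[f].astype(str), sort=True)
        start = 0 if k == 0 else 1  # drop first level after the first factor
        cols = len(levels) - start
        if cols <= 0:
            continue
        keep = codes >= start
        mat = sp.coo_matrix(
            (np.ones(keep.sum()), (np.where(keep)[0], codes[keep] - start)),
            shape=(n, cols),
        )
        blocks.append(mat)
        names += [f"{f}:{lv}" for lv in levels[start:]]
    return sp.hstack(blocks).tocsr(), names


@dataclass
class RandomGroup:
    """One random term: k correlated variates over q shared levels."""

    name: str
    variates: tuple[str, ...]
    levels: pd.Index
    kinv: sp.spmatrix | None  # None -> identity
    cov: np.ndarray  # current (k x k) covariance, start values on entry
    free: np.ndarray  # bool (k x k), symmetric; which entries are estimated
    rec: np.ndarray  # incidence: record row
    var: np.ndarray  # incidence: variate index
    lev: np.ndarray  # incidence: level index
    coef: np.ndarray  # incidence: coefficient (usually 1)
    Z: sp.csr_matrix = field(init=False)
    logdet_k: float = field(init=False)

    @property
    def k(self) -> int:
        return len(self.variates)

    @property
    def q(self) -> int:
        return len(self.levels)

    def finalize(self, n_records: int) -> None:
        cols = self.var * self.q + self.lev  # variate-major layout
        self.Z = sp.coo_matrix(
            (self.coef, (self.rec, cols)), shape=(n_records, self.k * self.q)
        ).tocsr()
        if self.kinv is None:
            self.kinv = sp.identity(self.q, format="csr")
            self.logdet_k = 0.0
        else:
            self.kinv = sp.csr_matrix(self.kinv)
            lu = spla.splu(self.kinv.tocsc(),
                           diag_pivot_thresh=0, permc_spec="MMD_AT_PLUS_A",
                           options={"SymmetricMode": True})
            # log|K| = -log|K^-1|; K^-1 is SPD so U's diagonal is positive.
            self.logdet_k = -float(np.sum(np.log(np.abs(lu.U.diagonal()))))

    def cov_inv(self) -> np.ndarray:
        return np.linalg.inv(self.cov)


def group_from_records(
    name: str,
    variates: tuple[str, ...],
    levels: pd.Index,
    assignments: list[tuple[np.ndarray, int, np.ndarray]],
    kinv: sp.spmatrix | None,
    cov0: np.ndarray,
    free: np.ndarray | None = None,
) -> RandomGroup:
    """Build a group from (record-rows, variate, level-id array) assignments."""
    pos = {a: i for i, a in enumerate(levels)}
    recs, var_i, lev_i = [], [], []
    for rows, v, ids in assignments:
        recs.append(np.asarray(rows, dtype=int))
        var_i.append(np.full(len(rows), v, dtype=int))
        lev_i.append(np.array([pos[x] for x in ids], dtype=int))
    rec = np.concatenate(recs)
    cov0 = np.atleast_2d(np.asarray(cov0, dtype=float))
    if free is None:
        free = np.ones_like(cov0, dtype=bool)
    return RandomGroup(
        name, tuple(variates), pd.Index(levels), kinv, cov0.copy(),
        np.asarray(free, dtype=bool), rec,
        np.concatenate(var_i), np.concatenate(lev_i),
        np.ones(len(rec)),
    )


class MMESystem:
    """Assembled mixed-model equations with cached cross-products."""

    def __init__(
        self,
        y: np.ndarray,
        X: sp.csr_matrix,
        groups: list[RandomGroup],
        trait_of_record: np.ndarray | None = None,
        weights: np.ndarray | None = None,
        resid_var: np.ndarray | float = 1.0,
        xnames: list[str] | None = None,
    ) -> None:
        self.y = np.asarray(y, dtype=float)
        n = len(self.y)
        self.X = sp.csr_matrix(X)
        self.groups = groups
        for g in groups:
            g.finalize(n)
        self.trait = (
            np.zeros(n, dtype=int)
            if trait_of_record is None
            else np.asarray(trait_of_record, dtype=int)
        )
        self.n_traits = int(self.trait.max()) + 1
        self.w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
        self.resid_var = np.atleast_1d(np.asarray(resid_var, dtype=float)).copy()
        if len(self.resid_var) == 1 and self.n_traits > 1:
            self.resid_var = np.repeat(self.resid_var, self.n_traits)
        self.xnames = xnames or [f"x{i}" for i in range(self.X.shape[1])]

        self.W = sp.hstack([self.X] + [g.Z for g in groups]).tocsr()
        self.n_fixed = self.X.shape[1]
        self.offsets: list[int] = []
        off = self.n_fixed
        for g in groups:
            self.offsets.append(off)
            off += g.k * g.q
        self.n_eq = off

        # Per-trait cached cross-products: M_t = W_t' diag(w) W_t etc.
        self._Mt, self._rhs_t, self._ywy_t, self._nt = [], [], [], []
        for t in range(self.n_traits):
            mask = self.trait == t
            Wt = self.W[mask]
            dw = sp.diags(self.w[mask])
            self._Mt.append((Wt.T @ dw @ Wt).tocsr())
            self._rhs_t.append(Wt.T @ (self.w[mask] * self.y[mask]))
            self._ywy_t.append(float(np.sum(self.w[mask] * self.y[mask] ** 2)))
            self._nt.append(int(mask.sum()))

    # -- assembly -----------------------------------------------------------

    def r_inv(self) -> np.ndarray:
        return self.w / self.resid_var[self.trait]

    def _sigma_block(self) -> sp.csr_matrix:
        """blockdiag(0_fixed, cov_g^-1 kron K_g^-1, ...)."""
        blocks = [sp.csr_matrix((self.n_fixed, self.n_fixed))]
        for g in self.groups:
            blocks.append(sp.kron(g.cov_inv(), g.kinv, format="csr"))
        return sp.block_diag(blocks, format="csr")

    def coefficient_matrix(self) -> sp.csr_matrix:
        C = self._sigma_block()
        for t in range(self.n_traits):
            C = C + self._Mt[t] / self.resid_var[t]
        return C.tocsr()

    def rhs(self) -> np.ndarray:
        out = np.zeros(self.n_eq)
        for t in range(self.n_traits):
            out += self._rhs_t[t] / self.resid_var[t]
        return out

    def ywy(self) -> float:
        return float(
            sum(self._ywy_t[t] / self.resid_var[t] for t in range(self.n_traits))
        )

    # -- solving ------------------------------------------------------------

    def solve(self) -> np.ndarray:
        """Direct sparse factorization solve of the normal equations."""
        C = self.coefficient_matrix().tocsc()
        try:
            lu = spla.splu(C)
        except RuntimeError as err:
            raise np.linalg.LinAlgError(
                f"singular mixed-model equations: {err}"
            ) from err
        return lu.solve(self.rhs())

    def solve_dense(self, ridge: float = 0.0):
        """Dense Cholesky solve returning (solutions, C^-1, logdet C).

        Falls back to a tiny ridge on the fixed block when a fixed level is
        unestimable (no data and no ties), mirroring a zero constraint.
        """
        C = self.coefficient_matrix().toarray()
        if ridge:
            C[: self.n_fixed, : self.n_fixed] += ridge * np.eye(self.n_fixed)
        try:
            cf = cho_factor(C, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            scale = np.mean(np.diag(C)) * 1e-8
            warnings.warn(
                "coefficient matrix singular (unestimable fixed level?); "
                "applying a zero-constraint ridge"
            )
            return self.solve_dense(ridge=scale if ridge == 0.0 else ridge * 100)
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        sol = cho_solve(cf, self.rhs(), check_finite=False)
        cinv, info = dpotri(cf[0], lower=True)
        if info != 0:
            raise np.linalg.LinAlgError("dpotri failed")
        cinv = np.tril(cinv) + np.tril(cinv, -1).T
        return sol, cinv, logdet

    # -- bookkeeping --------------------------------------------------------

    def group_offset(self, name: str) -> tuple[int, "RandomGroup"]:
        for off, g in zip(self.offsets, self.groups):
            if g.name == name:
                return off, g
        raise KeyError(name)

    def solution_block(self, solutions: np.ndarray, name: str) -> np.ndarray:
        """(k x q) array of a group's solutions."""
        off, g = self.group_offset(name)
        return solutions[off: off + g.k * g.q].reshape(g.k, g.q)

    def residuals(self, solutions: np.ndarray) -> np.ndarray:
        return self.y - self.W @ solutions


@dataclass
class EBVTable:
    """Per-animal breeding values with prediction-error variances."""

    table: pd.DataFrame  # animal, ebv, se, pev, reliability

    @classmethod
    def from_solution(
        cls,
        system: MMESystem,
        solutions: np.ndarray,
        cinv: np.ndarray | None,
        group: str,
        variate: int,
        sigma2_a: float,
    ) -> "EBVTable":
        off, g = system.group_offset(group)
        sl = slice(off + variate * g.q, off + (variate + 1) * g.q)
        ebv = solutions[sl]
        if cinv is not None:
            pev = np.diag(cinv)[sl].copy()
            pev = np.clip(pev, 0.0, None)
            rel = np.clip(1.0 - pev / sigma2_a, 0.0, 1.0)
            se = np.sqrt(pev)
        else:
            pev = np.full(g.q, np.nan)
            rel = np.full(g.q, np.nan)
            se = np.full(g.q, np.nan)
        return cls(
            pd.DataFrame(
                {"animal": np.asarray(g.levels), "ebv": ebv, "se": se,
                 "pev": pev, "reliability": rel}
            )
        )
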