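"""REML estimation of the repeatability animal model's variance components.

Univariate fits use average-information REML with EM fallback: AI steps are
Newton-type updates on (sigma2_a, sigma2_pe, sigma2_e) using the average of
observed and expected information, guarded so the restricted log-likelihood
never decreases (a rejected AI step is replaced by an EM step, which cannot
decrease it). All trace terms come from the inverse of the mixed-model
coefficient matrix, so the additive relationship structure K enters only
through its (sparse) inverse.

Multi-trait fits maximize the restricted likelihood directly over
log-Cholesky factors of the additive, permanent-environmental and residual
covariance matrices (quasi-Newton; likelihood evaluated through the sparse
MME), assuming all traits are recorded on the same records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.linalg.lapack import dpotri

from .design import DesignMatrices

__all__ = [
    "VarianceComponents",
    "MultiTraitVarianceComponents",
    "reml_estimate",
    "reml_loglike",
    "reml_estimate_multitrait",
    "multitrait_loglike",
    "heritability",
    "repeatability",
    "genetic_correlation",
    "round_table2",
]


# ----------------------------------------------------------------------
@dataclass
class VarianceComponents:
    """Single-trait variance components with SEs and convergence metadata."""

    sigma2_a: float
    sigma2_pe: float
    sigma2_e: float
    se: dict = field(default_factory=dict)
    loglike: float = np.nan
    converged: bool = False
    n_iter: int = 0
    pinned: dict = field(default_factory=dict)
    pe_identifiable: bool = True
    method: str = "ai-em"
    trait: str = "y"

    @property
    def total(self) -> float:
        return self.sigma2_a + self.sigma2_pe + self.sigma2_e

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "sigma2_a": self.sigma2_a,
                "sigma2_pe": self.sigma2_pe,
                "sigma2_e": self.sigma2_e,
                "h2": heritability(self),
                "repeatability": repeatability(self),
                "loglike": self.loglike,
                "converged": self.converged,
                "n_iter": self.n_iter,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        """Estimate / SE / pinned flag per component, plus convergence rows."""
        rows = [
            {
                "parameter": name,
                "estimate": getattr(self, name),
                "se": self.se.get(name, np.nan),
                "pinned": self.pinned.get(name, False),
            }
            for name in ("sigma2_a", "sigma2_pe", "sigma2_e")
        ]
        rows.append({"parameter": "h2", "estimate": heritability(self),
                     "se": np.nan, "pinned": False})
        rows.append({"parameter": "repeatability", "estimate": repeatability(self),
                     "se": np.nan, "pinned": False})
        out = pd.DataFrame(rows)
        out.attrs["converged"] = self.converged
        return out


def heritability(vc: VarianceComponents, *_args) -> float:
    """h2 = sigma2_a / (sigma2_a + sigma2_pe + sigma2_e)."""
    if vc.total <= 0:
        raise ValueError("zero total variance")
    return vc.sigma2_a / vc.total


def repeatability(vc: VarianceComponents, *_args) -> float:
    """t = (sigma2_a + sigma2_pe) / (sigma2_a + sigma2_pe + sigma2_e)."""
    if vc.total <= 0:
        raise ValueError("zero total variance")
    return (vc.sigma2_a + vc.sigma2_pe) / vc.total


def round_table2(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention of printed ratio tables."""
    factor = 10.0**ndigits
    return np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor


# ----------------------------------------------------------------------
class _MMEWork:
    """Precomputed cross-products for repeated REML factorizations."""

    def __init__(self, design: DesignMatrices, K_inv: sp.spmatrix):
        X = design.X
        Z, W = design.Za.tocsc(), design.Wpe.tocsc()
        self.n, self.p = X.shape
        self.qa, self.qpe = Z.shape[1], W.shape[1]
        if K_inv.shape[0] != self.qa:
            raise ValueError("K_inv dimension does not match pedigree animals")
        self.n_eq = self.p + self.qa + self.qpe
        if self.n_eq > 8000:
            raise MemoryError(
                f"dense REML limited to 8000 equations (got {self.n_eq}); "
                "reduce the pedigree or fit per-trait subsets"
            )
        y = design.y
        self.y = y
        self.yty = float(y @ y)
        self.K_inv = K_inv.tocsr()
        self.Kd = np.asarray(K_inv.todense())
        lu = spla.splu(K_inv.tocsc())
        diag = lu.U.diagonal()
        self.logdet_K = -float(np.sum(np.log(np.abs(diag))))  # ln|K| = -ln|K^-1|
        C0 = np.zeros((self.n_eq, self.n_eq))
        p, qa = self.p, self.qa
        Xs = sp.csr_matrix(X)
        C0[:p, :p] = X.T @ X
        C0[:p, p : p + qa] = (Xs.T @ Z).toarray()
        C0[:p, p + qa :] = (Xs.T @ W).toarray()
        C0[p : p + qa, p : p + qa] = (Z.T @ Z).toarray()
        C0[p : p + qa, p + qa :] = (Z.T @ W).toarray()
        C0[p + qa :, p + qa :] = (W.T @ W).toarray()
        C0[p : p + qa, :p] = C0[:p, p : p + qa].T
        C0[p + qa :, :p] = C0[:p, p + qa :].T
        C0[p + qa :, p : p + qa] = C0[p : p + qa, p + qa :].T
        self.C0 = C0
        self.rhs = np.concatenate([X.T @ y, Z.T @ y, W.T @ y])
        self.record_counts = np.asarray((W.T @ W).diagonal())
        self.design = design
        self.Z, self.W, self.X = Z, W, X

    def factorize(self, theta):
        s2a, s2pe, s2e = theta
        C = self.C0.copy()
        p, qa = self.p, self.qa
        lam_a, lam_pe = s2e / s2a, s2e / s2pe
        C[p : p + qa, p : p + qa] += lam_a * self.Kd
        idx = np.arange(p + qa, self.n_eq)
        C[idx, idx] += lam_pe
        cf = scipy.linalg.cho_factor(C, lower=True, overwrite_a=True, check_finite=False)
        return cf

    def loglike(self, theta, cf=None, sol=None):
        s2a, s2pe, s2e = theta
        if cf is None:
            cf = self.factorize(theta)
        if sol is None:
            sol = scipy.linalg.cho_solve(cf, self.rhs, check_finite=False)
        logdet_C = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        ypy = (self.yty - sol @ self.rhs) / s2e
        neg2l = (
            (self.n - self.n_eq) * np.log(s2e)
            + self.qa * np.log(s2a)
            + self.qpe * np.log(s2pe)
            + self.logdet_K
            + logdet_C
            + ypy
            + (self.n - self.p) * np.log(2.0 * np.pi)
        )
        return -0.5 * neg2l


def reml_loglike(design: DesignMatrices, K_inv: sp.spmatrix, vc) -> float:
    """Restricted log-likelihood of the repeatability model at given components."""
    work = _MMEWork(design, K_inv)
    return work.loglike((vc.sigma2_a, vc.sigma2_pe, vc.sigma2_e))


def reml_estimate(
    design: DesignMatrices,
    K_inv: sp.spmatrix,
    start: tuple[float, float, float] | None = None,
    method: str = "ai-em",
    max_iter: int = 100,
    tol: float = 1e-8,
    trait: str = "y",
    fix_sigma2_pe: float | None = None,
    verbose: bool = False,
) -> VarianceComponents:
    """AI-REML (with EM fallback) estimates of (sigma2_a, sigma2_pe, sigma2_e).

    ``method``: "ai-em" (default), "ai" (no fallback guard), or "em".
    Components are floored at 1e-8 x phenotypic variance and flagged when
    pinned there; with single records per animal sigma2_pe is unidentifiable
    and is pinned with ``pe_identifiable=False``. ``fix_sigma2_pe`` holds the
    permanent-environment variance at a given value (e.g. when it is
    confounded with the additive term).
    """
    if method not in {"ai", "em", "ai-em"}:
        raise ValueError(f"unknown REML method {method!r}")
    work = _MMEWork(design, K_inv)
    vary = float(np.var(design.y))
    floor = 1e-8 * vary
    if start is None:
        theta = np.array([0.2 * vary, 0.2 * vary, 0.6 * vary])
    else:
        theta = np.asarray(start, dtype=float)
        if np.any(theta <= 0):
            raise ValueError("start values must be positive")
    free = np.array([True, True, True])
    pe_identifiable = True
    if fix_sigma2_pe is not None:
        theta[1] = max(fix_sigma2_pe, floor)
        free[1] = False
    elif work.record_counts.max() <= 1:
        warnings.warn(
            "every animal has a single record: sigma2_pe is not identifiable "
            "and is pinned at the boundary",
            stacklevel=2,
        )
        theta[1] = floor
        free[1] = False
        pe_identifiable = False

    prev_ll = -np.inf
    prev_theta = theta.copy()
    last_step_ai = False
    ai_inv = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        cf = work.factorize(theta)
        sol = scipy.linalg.cho_solve(cf, work.rhs, check_finite=False)
        ll = work.loglike(theta, cf, sol)
        if ll < prev_ll - 1e-8 and last_step_ai and method == "ai-em":
            # AI overshot: revert and take the guaranteed EM step instead
            theta = prev_theta.copy()
            cf = work.factorize(theta)
            sol = scipy.linalg.cho_solve(cf, work.rhs, check_finite=False)
            ll = work.loglike(theta, cf, sol)
            force_em = True
        else:
            force_em = False
        s2a, s2pe, s2e = theta
        p, qa, qpe, n = work.p, work.qa, work.qpe, work.n
        a_hat = sol[p : p + qa]
        pe_hat = sol[p + qa :]
        b_hat = sol[:p]
        e_hat = work.y - work.X @ b_hat - work.Z @ a_hat - work.W @ pe_hat
        # inverse of the coefficient matrix for the trace terms
        Cinv, info = dpotri(cf[0], lower=True)
        if info != 0:  # pragma: no cover - LAPACK failure
            raise np.linalg.LinAlgError("dpotri failed")
        # dpotri fills only the lower triangle; the upper holds factor garbage
        Cinv = np.tril(Cinv) + np.tril(Cinv, -1).T
        Caa = Cinv[p : p + qa, p : p + qa]
        tr_Kaa = float(np.sum(work.Kd * Caa))
        tr_Cpp = float(np.trace(Cinv[p + qa :, p + qa :]))
        aKa = float(a_hat @ (work.K_inv @ a_hat))
        pp = float(pe_hat @ pe_hat)
        ee = float(e_hat @ e_hat)
        lam_a, lam_pe = s2e / s2a, s2e / s2pe
        # scores (first derivatives of logL)
        tPa = (qa - lam_a * tr_Kaa) / s2a
        tPpe = (qpe - lam_pe * tr_Cpp) / s2pe
        tP = ((n - p) - s2a * tPa - s2pe * tPpe) / s2e
        score = -0.5 * np.array(
            [tPa - aKa / s2a**2, tPpe - pp / s2pe**2, tP - ee / s2e**2]
        )
        # EM updates (always available; guaranteed ascent)
        em = np.array(
            [
                (aKa + s2e * tr_Kaa) / qa,
                (pp + s2e * tr_Cpp) / qpe,
                (work.yty - sol @ work.rhs) / (n - p),
            ]
        )
        # average-information matrix from one extra solve per parameter
        Fmat = np.column_stack(
            [work.Z @ a_hat / s2a, work.W @ pe_hat / s2pe, e_hat / s2e]
        )
        rhs_F = np.vstack(
            [work.X.T @ Fmat, work.Z.T @ Fmat, work.W.T @ Fmat]
        )
        solF = scipy.linalg.cho_solve(cf, rhs_F, check_finite=False)
        PF = (
            Fmat
            - work.X @ solF[:p]
            - work.Z @ solF[p : p + qa]
            - work.W @ solF[p + qa :]
        ) / s2e
        AI = 0.5 * (Fmat.T @ PF)
        AI = 0.5 * (AI + AI.T)

        if verbose:  # pragma: no cover - debug aid
            print(f"iter {it}: logL={ll:.6f} theta={theta}")
        # convergence on the previous accepted step
        rel = np.max(np.abs(theta - prev_theta) / np.maximum(np.abs(prev_theta), floor))
        if it > 1 and rel < tol:
            converged = True
            fa = free
            ai_inv = np.linalg.inv(AI[np.ix_(fa, fa)])
            prev_ll = ll
            break
        prev_ll, prev_theta = ll, theta.copy()

        use_em = method == "em" or force_em
        new = theta.copy()
        if not use_em:
            fa = free
            try:
                step = np.linalg.solve(AI[np.ix_(fa, fa)], score[fa])
                # step-halving keeps AI's direction when the full Newton
                # step leaves the parameter space
                for frac in (1.0, 0.5, 0.25):
                    cand = theta[fa] + frac * step
                    if np.all(cand > 0) and np.all(cand < 100 * vary):
                        new[fa] = cand
                        last_step_ai = True
                        break
                else:
                    use_em = True
            except np.linalg.LinAlgError:
                use_em = True
        if use_em:
            new[free] = em[free]
            last_step_ai = False
        new = np.maximum(new, floor)
        new[~free] = theta[~free]
        theta = new
        fa = free
        try:
            ai_inv = np.linalg.inv(AI[np.ix_(fa, fa)])
        except np.linalg.LinAlgError:  # pragma: no cover
            ai_inv = None

    se = {}
    if ai_inv is not None:
        names = np.array(["sigma2_a", "sigma2_pe", "sigma2_e"])[free]
        d = np.sqrt(np.maximum(np.diag(ai_inv), 0.0))
        se = dict(zip(names, d))
    pinned = {
        name: bool(theta[k] <= floor * 1.5)
        for k, name in enumerate(["sigma2_a", "sigma2_pe", "sigma2_e"])
    }
    if not converged:
        warnings.warn(f"REML did not converge in {max_iter} iterations", stacklevel=2)
    return VarianceComponents(
        sigma2_a=float(theta[0]),
        sigma2_pe=float(theta[1]),
        sigma2_e=float(theta[2]),
        se=se,
        loglike=float(prev_ll),
        converged=converged,
        n_iter=it,
        pinned=pinned,
        pe_identifiable=pe_identifiable,
        method=method,
        trait=trait,
    )


# ----------------------------------------------------------------------
@dataclass
class MultiTraitVarianceComponents:
    """Covariance matrices of a multi-trait repeatability model."""

    traits: list[str]
    G_a: np.ndarray  # additive covariance, T x T
    G_pe: np.ndarray
    R: np.ndarray
    loglike: float = np.nan
    converged: bool = False
    n_iter: int = 0

    def _ti(self, trait) -> int:
        return self.traits.index(trait) if isinstance(trait, str) else int(trait)

    def univariate(self, trait) -> VarianceComponents:
        i = self._ti(trait)
        return VarianceComponents(
            sigma2_a=float(self.G_a[i, i]),
            sigma2_pe=float(self.G_pe[i, i]),
            sigma2_e=float(self.R[i, i]),
            converged=self.converged,
            trait=self.traits[i],
        )


def genetic_correlation(vc: MultiTraitVarianceComponents, trait_i, trait_j) -> float:
    """r_g = cov_a(i,j) / sqrt(var_a(i) var_a(j)), warning-clipped to [-1, 1]."""
    i, j = vc._ti(trait_i), vc._ti(trait_j)
    vi, vj = vc.G_a[i, i], vc.G_a[j, j]
    if vi <= 0 or vj <= 0:
        raise ValueError("genetic correlation undefined with zero additive variance")
    r = float(vc.G_a[i, j] / np.sqrt(vi * vj))
    if abs(r) > 1.0:
        warnings.warn(f"genetic correlation {r:.3f} outside [-1, 1]; clipping", stacklevel=2)
        r = float(np.clip(r, -1.0, 1.0))
    return r


def _chol_from_params(params: np.ndarray, T: int) -> np.ndarray:
    """Lower-triangular factor with exp-diagonal from a packed parameter vector."""
    L = np.zeros((T, T))
    k = 0
    for i in range(T):
        for j in range(i + 1):
            L[i, j] = np.exp(params[k]) if i == j else params[k]
            k += 1
    return L


def _params_from_cov(M: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(M)
    out = []
    for i in range(L.shape[0]):
        for j in range(i + 1):
            out.append(np.log(L[i, j]) if i == j else L[i, j])
    return np.asarray(out)


class _MultiTraitWork:
    """Precomputed pieces of the stacked multi-trait MME likelihood."""

    def __init__(self, Y: np.ndarray, design: DesignMatrices, K_inv: sp.spmatrix):
        Y = np.asarray(Y, dtype=float)
        self.Y = Y
        self.n, self.T = Y.shape
        X = sp.csr_matrix(design.X)
        Z, W = design.Za.tocsr(), design.Wpe.tocsr()
        self.p, self.qa, self.qpe = X.shape[1], Z.shape[1], W.shape[1]
        Wall = sp.hstack([X, Z, W]).tocsr()
        self.WtW = (Wall.T @ Wall).tocsc()
        self.WtY = np.asarray((Wall.T @ sp.csr_matrix(Y)).todense())
        self.YtY = Y.T @ Y
        K_inv = K_inv.tocsc()
        lu = spla.splu(K_inv)
        self.logdet_K = -float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        p, qa, qpe = self.p, self.qa, self.qpe
        self.Ka = sp.block_diag(
            [sp.csc_matrix((p, p)), K_inv, sp.csc_matrix((qpe, qpe))], format="csc"
        )
        self.Ipe = sp.block_diag(
            [sp.csc_matrix((p, p)), sp.csc_matrix((qa, qa)), sp.eye(qpe)], format="csc"
        )

    def neg2l(self, G0a: np.ndarray, G0pe: np.ndarray, R0: np.ndarray) -> float:
        T, n, p, qa, qpe = self.T, self.n, self.p, self.qa, self.qpe
        sa, la = np.linalg.slogdet(G0a)
        spe_, lpe = np.linalg.slogdet(G0pe)
        sr, lr = np.linalg.slogdet(R0)
        if min(sa, spe_, sr) <= 0:
            return 1e12
        G0a_inv = np.linalg.inv(G0a)
        G0pe_inv = np.linalg.inv(G0pe)
        R0_inv = np.linalg.inv(R0)
        blocks = [
            [
                R0_inv[s, t] * self.WtW
                + G0a_inv[s, t] * self.Ka
                + G0pe_inv[s, t] * self.Ipe
                for t in range(T)
            ]
            for s in range(T)
        ]
        C = sp.bmat(blocks, format="csc")
        rhs = (self.WtY @ R0_inv).T.ravel()
        try:
            lu_c = spla.splu(C)
        except RuntimeError:
            return 1e12
        sol = lu_c.solve(rhs)
        logdet_C = float(np.sum(np.log(np.abs(lu_c.U.diagonal()))))
        yRy = float(np.sum(R0_inv * self.YtY))
        ypy = yRy - float(sol @ rhs)
        return (
            n * lr
            + qa * la
            + qpe * lpe
            + T * self.logdet_K
            + logdet_C
            + ypy
            + (n - p) * T * np.log(2.0 * np.pi)
        )


def multitrait_loglike(
    Y: np.ndarray,
    design: DesignMatrices,
    K_inv: sp.spmatrix,
    G_a: np.ndarray,
    G_pe: np.ndarray,
    R: np.ndarray,
) -> float:
    """Restricted log-likelihood of the multi-trait model at given covariances."""
    work = _MultiTraitWork(Y, design, K_inv)
    return -0.5 * work.neg2l(np.asarray(G_a, float), np.asarray(G_pe, float), np.asarray(R, float))


def reml_estimate_multitrait(
    Y: np.ndarray,
    design: DesignMatrices,
    K_inv: sp.spmatrix,
    traits: list[str] | None = None,
    start: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    max_iter: int = 200,
    verbose: bool = False,
) -> MultiTraitVarianceComponents:
    """Multi-trait REML on equal designs by direct likelihood maximization.

    ``Y`` is records x traits with every trait observed on every record (the
    synthetic world's layout). Covariance matrices are parameterized by
    log-Cholesky factors and optimized by L-BFGS-B on -2 logL evaluated
    through the sparse stacked MME.
    """
    Y = np.asarray(Y, dtype=float)
    n, T = Y.shape
    traits = traits or [f"trait{i + 1}" for i in range(T)]
    work = _MultiTraitWork(Y, design, K_inv)
    npar = T * (T + 1) // 2

    def unpack(params):
        La = _chol_from_params(params[:npar], T)
        Lpe = _chol_from_params(params[npar : 2 * npar], T)
        Lr = _chol_from_params(params[2 * npar :], T)
        return La @ La.T, Lpe @ Lpe.T, Lr @ Lr.T

    def neg2l(params):
        return work.neg2l(*unpack(params))

    if start is None:
        v = np.var(Y, axis=0)
        G0a = np.diag(0.2 * v)
        G0pe = np.diag(0.2 * v)
        R0 = np.diag(0.6 * v)
    else:
        G0a, G0pe, R0 = start
    x0 = np.concatenate(
        [_params_from_cov(G0a), _params_from_cov(G0pe), _params_from_cov(R0)]
    )
    from scipy.optimize import minimize

    res = minimize(
        neg2l, x0, method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8},
    )
    if verbose:  # pragma: no cover
        print(res)
    G0a, G0pe, R0 = unpack(res.x)
    return MultiTraitVarianceComponents(
        traits=list(traits),
        G_a=G0a, G_pe=G0pe, R=R0,
        loglike=-0.5 * float(res.fun),
        converged=bool(res.success),
        n_iter=int(res.nit),
    )
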