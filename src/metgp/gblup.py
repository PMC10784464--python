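"""Joint multi-environment GBLUP with compound-symmetric genetic correlations.

Model for the stacked hybrid x environment adjusted means (environment-
major, hybrid-minor ordering):

    ybar = X b + u_a + u_d + e
    u_a ~ MVN(0, [I_q s2_ua + rho_a s2_ua (J_q - I_q)] kron A)
    u_d ~ MVN(0, [I_q s2_ud + rho_d s2_ud (J_q - I_q)] kron D)
    e   ~ MVN(0, I s2_e)

with A and D the additive and dominance genomic relationship matrices and
b fixed environment effects. Variance components are estimated by REML
(profiled residual variance, bounded quasi-Newton on log-variance-ratio and
logit-correlation transforms). Dropping u_d gives the additive-only model;
a single environment (q = 1, no correlations) gives the within-environment
variant.

For complete hybrid x environment grids the restricted likelihood is
evaluated through a block diagonalization: every compound-symmetry matrix
is diagonalized by the same orthogonal basis (the equal-weights vector and
its complement), so V collapses into q blocks of size p of which q - 1 are
identical. Masked (cross-validation) fits use a dense Cholesky of the
observed-cell covariance instead. The two paths agree to numerical
precision and are cross-checked in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import chi2

from .genotypes import KernelMatrix

__all__ = [
    "VarianceComponents",
    "GeneticParams",
    "LRTResult",
    "ConvergenceError",
    "cs_matrix",
    "cells_from_eblues",
    "build_covariance",
    "reml_fit",
    "fit_within_environment",
    "lrt",
    "genetic_params",
    "heritability_partition",
    "predict_cells",
]


class ConvergenceError(RuntimeError):
    """REML optimisation failed; carries the optimiser trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass
class VarianceComponents:
    """REML estimates for one fitted model."""

    model: str                 # "A" or "AD"
    q: int                     # number of environments in the fit
    sigma2_ua: float
    sigma2_e: float
    sigma2_ud: float | None = None
    rho_a: float | None = None
    rho_d: float | None = None
    logL: float = float("nan")
    converged: bool = False
    n_iter: int = 0
    boundary: bool = False
    message: str = ""
    transformed: np.ndarray | None = None  # optimiser coordinates (warm starts)

    def summary(self) -> pd.DataFrame:
        rows = [("sigma2_ua", self.sigma2_ua)]
        if self.sigma2_ud is not None:
            rows.append(("sigma2_ud", self.sigma2_ud))
        rows.append(("sigma2_e", self.sigma2_e))
        if self.rho_a is not None:
            rows.append(("rho_a", self.rho_a))
        if self.rho_d is not None:
            rows.append(("rho_d", self.rho_d))
        df = pd.DataFrame(rows, columns=["component", "estimate"])
        df["logL"] = self.logL
        df["converged"] = self.converged
        return df


@dataclass
class GeneticParams:
    h2: float
    d2: float
    H2: float


@dataclass
class LRTResult:
    statistic: float
    p_value: float
    significant: bool


# ---------------------------------------------------------------------------
# Covariance assembly
# ---------------------------------------------------------------------------

def cs_matrix(sigma2: float, rho: float, q: int) -> np.ndarray:
    """Compound-symmetry covariance sigma2 [(1 - rho) I_q + rho J_q]."""
    return sigma2 * ((1.0 - rho) * np.eye(q) + rho * np.ones((q, q)))


def _kernel_values(K) -> np.ndarray:
    return K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)


def genetic_covariance(vc: VarianceComponents, A, D=None) -> np.ndarray:
    """Full-grid covariance of u_a (+ u_d): CS kron A (+ CS kron D)."""
    Av = _kernel_values(A)
    q = vc.q
    G = np.kron(cs_matrix(vc.sigma2_ua, vc.rho_a or 0.0, q), Av)
    if vc.sigma2_ud is not None and D is not None:
        G += np.kron(cs_matrix(vc.sigma2_ud, vc.rho_d or 0.0, q), _kernel_values(D))
    return G


def build_covariance(vc: VarianceComponents, A, D=None,
                     obs: np.ndarray | None = None) -> np.ndarray:
    """Phenotypic covariance over observed cells: genetic part + s2_e I.

    ``obs`` is a boolean vector over the environment-major cell ordering;
    omitted rows/columns correspond to unobserved (masked) cells.
    """
    q = vc.q
    if vc.q > 1:
        lo = -1.0 / (q - 1)
        for rho in (vc.rho_a, vc.rho_d):
            if rho is not None and rho <= lo:
                raise ValueError(f"rho={rho} at or below {lo:.4g}: compound "
                                 "symmetry not positive definite")
    V = genetic_covariance(vc, A, D)
    V = V + vc.sigma2_e * np.eye(V.shape[0])
    if obs is not None:
        obs = np.asarray(obs, dtype=bool)
        V = V[np.ix_(obs, obs)]
    return V


def cells_from_eblues(eblues: pd.DataFrame, hybrid_ids, env_ids,
                      trait: str | None = None,
                      mask: pd.DataFrame | None = None,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Stack an eBLUE table into the environment-major cell vector.

    Returns ``(y, obs)`` of length p*q; ``y`` is NaN outside observed
    cells. ``mask`` (hybrids x environments, True = held out) removes cells
    from the observed set on top of missingness in the table.
    """
    df = eblues if trait is None else eblues[eblues["trait"] == trait]
    piv = df.pivot_table(index="hybrid", columns="environment", values="eblue",
                         aggfunc="first")
    piv = piv.reindex(index=hybrid_ids, columns=env_ids)
    y = piv.to_numpy(dtype=float).T.reshape(-1)  # env-major
    obs = ~np.isnan(y)
    if mask is not None:
        m = mask.reindex(index=hybrid_ids, columns=env_ids).fillna(False)
        obs &= ~m.to_numpy(dtype=bool).T.reshape(-1)
    return y, obs


# ---------------------------------------------------------------------------
# REML internals
# ---------------------------------------------------------------------------

def _rho_bounds(q: int) -> float:
    return -1.0 / (q - 1)


def _unpack(x: np.ndarray, model: str, q: int) -> dict:
    lo = _rho_bounds(q) if q > 1 else None
    i = 0
    out = {"ga": float(np.exp(x[i]))}
    i += 1
    if model == "AD":
        out["gd"] = float(np.exp(x[i]))
        i += 1
    else:
        out["gd"] = 0.0
    if q > 1:
        out["ra"] = lo + (1.0 - lo) * float(expit(x[i]))
        i += 1
        if model == "AD":
            out["rd"] = lo + (1.0 - lo) * float(expit(x[i]))
            i += 1
        else:
            out["rd"] = 0.0
    else:
        out["ra"] = out["rd"] = 0.0
    return out


def _pack_start(model: str, q: int, rho0: float = 0.3) -> np.ndarray:
    x = [0.0]
    if model == "AD":
        x.append(0.0)
    if q > 1:
        lo = _rho_bounds(q)
        z = float(logit((rho0 - lo) / (1.0 - lo)))
        x.append(z)
        if model == "AD":
            x.append(z)
    return np.asarray(x)


def _param_bounds(model: str, q: int) -> list[tuple[float, float]]:
    b = [(-14.0, 14.0)]
    if model == "AD":
        b.append((-14.0, 14.0))
    if q > 1:
        b.append((-12.0, 12.0))
        if model == "AD":
            b.append((-12.0, 12.0))
    return b


_BIG = 1e12


class _DenseREML:
    """Profiled restricted likelihood over an arbitrary observed-cell subset."""

    def __init__(self, y, obs, A, D, q):
        obs = np.asarray(obs, dtype=bool)
        p = A.shape[0]
        I_q, J_q = np.eye(q), np.ones((q, q))
        self.KaI = np.kron(I_q, A)[np.ix_(obs, obs)]
        self.KaJ = np.kron(J_q - I_q, A)[np.ix_(obs, obs)]
        if D is not None:
            self.KdI = np.kron(I_q, D)[np.ix_(obs, obs)]
            self.KdJ = np.kron(J_q - I_q, D)[np.ix_(obs, obs)]
        else:
            self.KdI = self.KdJ = None
        X = np.kron(np.eye(q), np.ones((p, 1)))[obs]
        keep = X.sum(axis=0) > 0
        self.X = X[:, keep]
        self.env_cols = np.flatnonzero(keep)
        self.y = y[obs]
        self.n = int(obs.sum())
        self.r = self.n - self.X.shape[1]
        self.q = q

    def _V0(self, prm) -> np.ndarray:
        V = prm["ga"] * (self.KaI + prm["ra"] * self.KaJ)
        if self.KdI is not None and prm["gd"] > 0.0:
            V = V + prm["gd"] * (self.KdI + prm["rd"] * self.KdJ)
        V[np.diag_indices_from(V)] += 1.0
        return V

    def neglik(self, x, model) -> float:
        prm = _unpack(x, model, self.q)
        V0 = self._V0(prm)
        try:
            c = cho_factor(V0, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return _BIG
        logdetV0 = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
        Xy = np.column_stack([self.X, self.y])
        sol = cho_solve(c, Xy, check_finite=False)
        ViX, Viy = sol[:, :-1], sol[:, -1]
        M = self.X.T @ ViX
        try:
            cm = cho_factor(M, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return _BIG
        logdetM = 2.0 * float(np.sum(np.log(np.diag(cm[0]))))
        Xty = self.X.T @ Viy
        beta = cho_solve(cm, Xty, check_finite=False)
        quad = float(self.y @ Viy - Xty @ beta)
        if quad <= 0.0:
            return _BIG
        return 0.5 * (logdetV0 + logdetM + self.r * np.log(quad))

    def finish(self, x, model) -> dict:
        prm = _unpack(x, model, self.q)
        V0 = self._V0(prm)
        c = cho_factor(V0, lower=True, check_finite=False)
        logdetV0 = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
        Xy = np.column_stack([self.X, self.y])
        sol = cho_solve(c, Xy, check_finite=False)
        ViX, Viy = sol[:, :-1], sol[:, -1]
        M = self.X.T @ ViX
        cm = cho_factor(M, lower=True, check_finite=False)
        logdetM = 2.0 * float(np.sum(np.log(np.diag(cm[0]))))
        Xty = self.X.T @ Viy
        beta = cho_solve(cm, Xty, check_finite=False)
        quad = float(self.y @ Viy - Xty @ beta)
        s2e = quad / self.r
        logL = -0.5 * (self.r * np.log(2.0 * np.pi) + self.r
                       + self.r * np.log(s2e) + logdetV0 + logdetM)
        return {"prm": prm, "s2e": s2e, "logL": float(logL)}


def _ones_basis(q: int) -> np.ndarray:
    """Orthogonal q x q basis whose first column is the equal-weights vector."""
    M0 = np.eye(q)
    M0[:, 0] = 1.0
    U, _ = np.linalg.qr(M0)
    if U[0, 0] < 0:
        U = -U
    return U


class _GridSolver:
    """Linear algebra with V0 restricted to the observed cells of a p x q grid.

    Rotating the environment axis by an orthogonal basis containing the
    equal-weights vector turns both compound-symmetry factors into
    diagonals simultaneously, so the full-grid V0 block-diagonalizes into
    one "mean" block (CS eigenvalue 1 + (q-1) rho) and q - 1 identical
    "contrast" blocks (eigenvalue 1 - rho), each of size p. Masked cells
    are handled through the partitioned-inverse identities: with
    K = (V0^-1)[mask, mask],

        V0_obs^-1 b = (V0^-1 b~)_obs - (V0^-1)[obs, mask] K^-1 (V0^-1 b~)_mask
        log det V0_obs = log det V0 + log det K

    (b~ pads b with zeros on the masked cells), so every factorization is
    of size p or n_masked — never of the full observed system.
    """

    def __init__(self, A, D, q, obs=None):
        p = A.shape[0]
        self.A, self.D, self.q, self.p = A, D, q, p
        self.U = _ones_basis(q)
        self.n = p * q
        if obs is None:
            obs = np.ones(self.n, dtype=bool)
        self.obs = np.asarray(obs, dtype=bool)
        self.mask_idx = np.flatnonzero(~self.obs)
        self.obs_idx = np.flatnonzero(self.obs)
        self.n_obs = len(self.obs_idx)
        self._c1 = self._cr = None

    # -- factorization ---------------------------------------------------
    def factor(self, prm) -> None:
        q, p = self.q, self.p
        c1a = 1.0 + (q - 1) * prm["ra"]
        cra = 1.0 - prm["ra"]
        B1 = prm["ga"] * c1a * self.A
        Br = prm["ga"] * cra * self.A
        if self.D is not None and prm["gd"] > 0.0:
            B1 = B1 + prm["gd"] * (1.0 + (q - 1) * prm["rd"]) * self.D
            Br = Br + prm["gd"] * (1.0 - prm["rd"]) * self.D
        B1 = B1 + np.eye(p)
        Br = Br + np.eye(p)
        self._c1 = cho_factor(B1, lower=True, check_finite=False)
        self._cr = cho_factor(Br, lower=True, check_finite=False)
        self.logdet_full = (2.0 * float(np.sum(np.log(np.diag(self._c1[0]))))
                            + (q - 1) * 2.0 * float(np.sum(np.log(np.diag(self._cr[0])))))
        if len(self.mask_idx):
            m = len(self.mask_idx)
            E = np.zeros((self.n, m))
            E[self.mask_idx, np.arange(m)] = 1.0
            S = self._solve_full(E)              # V0^-1 E_mask
            K = S[self.mask_idx]                 # (V0^-1)[mask, mask]
            self._ck = cho_factor(K, lower=True, check_finite=False)
            self._S_obs = S[self.obs_idx]        # (V0^-1)[obs, mask]
            self.logdet_obs = self.logdet_full + \
                2.0 * float(np.sum(np.log(np.diag(self._ck[0]))))
        else:
            self.logdet_obs = self.logdet_full

    def _solve_full(self, B: np.ndarray) -> np.ndarray:
        """V0^-1 B on the complete grid via the block diagonalization."""
        q, p = self.q, self.p
        B = B.reshape(q, p, -1)
        m = B.shape[2]
        Bt = np.einsum("jq,qpm->jpm", self.U.T, B)
        out = np.empty_like(Bt)
        out[0] = cho_solve(self._c1, Bt[0], check_finite=False)
        if q > 1:
            rest = Bt[1:].transpose(1, 0, 2).reshape(p, (q - 1) * m)
            sol = cho_solve(self._cr, rest, check_finite=False)
            out[1:] = sol.reshape(p, q - 1, m).transpose(1, 0, 2)
        Z = np.einsum("qj,jpm->qpm", self.U, out)
        return Z.reshape(self.n, m)

    def solve_obs(self, B: np.ndarray) -> np.ndarray:
        """V0_obs^-1 B for B over observed cells (2-D: n_obs x k)."""
        B = np.atleast_2d(B.T).T if B.ndim == 1 else B
        full = np.zeros((self.n, B.shape[1]))
        full[self.obs_idx] = B
        W = self._solve_full(full)
        if len(self.mask_idx):
            corr = cho_solve(self._ck, W[self.mask_idx], check_finite=False)
            return W[self.obs_idx] - self._S_obs @ corr
        return W[self.obs_idx]


class _StructuredREML:
    """Profiled restricted likelihood on a p x q grid (complete or masked)."""

    def __init__(self, y, obs, A, D, q):
        p = A.shape[0]
        self.solver = _GridSolver(A, D, q, obs)
        X = np.kron(np.eye(q), np.ones((p, 1)))
        self.X = X[self.solver.obs_idx]
        self.y = y[self.solver.obs_idx]
        self.n = self.solver.n_obs
        self.r = self.n - self.X.shape[1]
        self.q = q

    def _core(self, prm):
        self.solver.factor(prm)
        sol = self.solver.solve_obs(np.column_stack([self.X, self.y]))
        ViX, Viy = sol[:, :-1], sol[:, -1]
        M = self.X.T @ ViX
        cm = cho_factor(M, lower=True, check_finite=False)
        logdetM = 2.0 * float(np.sum(np.log(np.diag(cm[0]))))
        Xty = self.X.T @ Viy
        beta = cho_solve(cm, Xty, check_finite=False)
        quad = float(self.y @ Viy - Xty @ beta)
        return self.solver.logdet_obs, logdetM, quad

    def neglik(self, x, model) -> float:
        prm = _unpack(x, model, self.q)
        try:
            logdetV0, logdetM, quad = self._core(prm)
        except np.linalg.LinAlgError:
            return _BIG
        if quad <= 0.0:
            return _BIG
        return 0.5 * (logdetV0 + logdetM + self.r * np.log(quad))

    def finish(self, x, model) -> dict:
        prm = _unpack(x, model, self.q)
        logdetV0, logdetM, quad = self._core(prm)
        s2e = quad / self.r
        logL = -0.5 * (self.r * np.log(2.0 * np.pi) + self.r
                       + self.r * np.log(s2e) + logdetV0 + logdetM)
        return {"prm": prm, "s2e": s2e, "logL": float(logL)}


def _jittered_starts(x0: np.ndarray, n_starts: int) -> list[np.ndarray]:
    starts = [x0]
    signs = [1.0, -1.0, 0.5]
    for k in range(1, n_starts):
        starts.append(x0 + signs[(k - 1) % 3] * 0.8 * np.arange(1, len(x0) + 1)
                      / len(x0))
    return starts


def reml_fit(eblues: pd.DataFrame, A: KernelMatrix, D: KernelMatrix | None = None,
             model: str = "AD", mask: pd.DataFrame | None = None,
             environments=None, trait: str | None = None,
             max_iter: int = 200, n_starts: int = 3, jitter: float = 1e-6,
             rho_start: float = 0.3, start: np.ndarray | None = None,
             dense: bool = False) -> VarianceComponents:
    """REML fit of the joint (or single-environment) GBLUP model.

    Parameters
    ----------
    eblues
        Adjusted-means table with columns hybrid, environment, eblue (and
        optionally trait).
    A, D
        Additive and dominance kernels over the same hybrid ids. ``D`` is
        required for ``model="AD"``.
    model
        ``"A"`` (additive only) or ``"AD"``.
    mask
        Optional hybrids x environments boolean frame, True = hold the cell
        out of the fit (cross-validation masking).
    jitter
        Ridge added to the kernel diagonals before factorisation.

    The optimisation runs on transformed parameters (log variance ratios,
    scaled-logit correlations) with the residual variance profiled out; on
    a failed first start up to ``n_starts`` jittered restarts are tried.
    ``start`` warm-starts the optimiser from a previous fit's transformed
    parameters (``VarianceComponents.transformed``); ``dense=True`` forces
    the dense observed-cell Cholesky path (reference implementation) in
    place of the structured grid solver.
    """
    if model not in ("A", "AD"):
        raise ValueError("model must be 'A' or 'AD'")
    if model == "AD" and D is None:
        raise ValueError("model 'AD' requires a dominance kernel")
    hybrid_ids = list(A.ids)
    if D is not None and list(D.ids) != hybrid_ids:
        D = D.align(hybrid_ids)
    if environments is None:
        environments = list(pd.unique(eblues["environment"]))
    q = len(environments)
    y, obs = cells_from_eblues(eblues, hybrid_ids, environments, trait, mask)
    p = len(hybrid_ids)
    per_env = obs.reshape(q, p).sum(axis=1)
    if (per_env == 0).any():
        missing = [environments[j] for j in np.flatnonzero(per_env == 0)]
        raise ValueError(f"no observed cells in environment(s) {missing}")

    Av = A.values + jitter * np.eye(p)
    Dv = D.values + jitter * np.eye(p) if (D is not None and model == "AD") else None

    if dense:
        core = _DenseREML(y, obs, Av, Dv, q)
    else:
        core = _StructuredREML(np.nan_to_num(y), obs, Av, Dv, q)

    x0 = np.asarray(start, dtype=float) if start is not None \
        else _pack_start(model, q, rho_start)
    bounds = _param_bounds(model, q)
    best, trace = None, []
    for x_start in _jittered_starts(x0, max(1, n_starts)):
        res = minimize(core.neglik, x_start, args=(model,), method="L-BFGS-B",
                       bounds=bounds, options={"maxiter": max_iter})
        trace.append(res)
        if np.isfinite(res.fun) and res.fun < _BIG / 2:
            if best is None or res.fun < best.fun - 1e-9:
                best = res
            if res.success:
                break
    if best is None:
        raise ConvergenceError(
            f"REML failed to converge after {len(trace)} start(s)", trace=trace)

    out = core.finish(best.x, model)
    prm, s2e = out["prm"], out["s2e"]
    eps = 1.0
    at_bound = any(abs(v - b[0]) < eps or abs(v - b[1]) < eps
                   for v, b in zip(best.x, bounds))
    return VarianceComponents(
        model=model, q=q,
        sigma2_ua=prm["ga"] * s2e,
        sigma2_ud=(prm["gd"] * s2e) if model == "AD" else None,
        sigma2_e=s2e,
        rho_a=prm["ra"] if q > 1 else None,
        rho_d=(prm["rd"] if (q > 1 and model == "AD") else None),
        logL=out["logL"], converged=bool(best.success),
        n_iter=int(best.nit), boundary=at_bound,
        message=str(best.message), transformed=np.array(best.x),
    )


def fit_within_environment(eblues: pd.DataFrame, A: KernelMatrix,
                           D: KernelMatrix | None = None,
                           environment: str | None = None,
                           model: str = "AD", **kw) -> VarianceComponents:
    """Single-environment GBLUP (q = 1, no across-environment correlations)."""
    if environment is None:
        raise ValueError("environment id required")
    sub = eblues[eblues["environment"] == environment]
    if sub.empty:
        raise ValueError(f"environment {environment!r} not present")
    return reml_fit(sub, A, D, model=model, environments=[environment], **kw)


# ---------------------------------------------------------------------------
# Inference on fitted components
# ---------------------------------------------------------------------------

def lrt(full: VarianceComponents, reduced: VarianceComponents,
        alpha: float = 0.05, tol: float = 1e-6) -> LRTResult:
    """Likelihood-ratio test, 2 (logL_full - logL_reduced) ~ chi-square(1)."""
    stat = 2.0 * (full.logL - reduced.logL)
    if stat < -tol:
        raise ValueError(
            f"negative LRT statistic ({stat:.3g}): models not nested or fits "
            "not converged")
    stat = max(stat, 0.0)
    p = float(chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return LRTResult(statistic=float(stat), p_value=p, significant=bool(p < alpha))


def heritability_partition(sigma2_ua: float, sigma2_ud: float,
                           sigma2_e: float) -> GeneticParams:
    """Variance-ratio genetic parameters.

    h2 = s2_ua / (s2_ua + s2_ud + s2_e), d2 the dominance share of the same
    denominator, H2 = h2 + d2.
    """
    tot = sigma2_ua + sigma2_ud + sigma2_e
    if tot <= 0.0:
        raise ValueError("all variance components zero; heritability undefined")
    h2 = sigma2_ua / tot
    d2 = sigma2_ud / tot
    return GeneticParams(h2=h2, d2=d2, H2=h2 + d2)


def genetic_params(vc: VarianceComponents) -> GeneticParams:
    """Genetic parameters from a fitted model (s2_ud treated as 0 if absent)."""
    return heritability_partition(vc.sigma2_ua, vc.sigma2_ud or 0.0, vc.sigma2_e)


# ---------------------------------------------------------------------------
# BLUP prediction
# ---------------------------------------------------------------------------

def predict_cells(vc: VarianceComponents, eblues: pd.DataFrame,
                  A: KernelMatrix, D: KernelMatrix | None = None,
                  mask: pd.DataFrame | None = None,
                  targets: list[tuple[str, str]] | None = None,
                  environments=None, trait: str | None = None,
                  jitter: float = 1e-6, method: str | None = None,
                  ) -> pd.DataFrame:
    """Conditional-mean predictions for hybrid x environment cells.

    Fixed part by generalized least squares on the observed cells; genetic
    part as Cov(u_target, y_obs) V_obs^{-1} (y_obs - X bhat) assembled from
    the compound-symmetry kron kernel blocks. ``targets`` defaults to every
    cell not in the observed set.
    """
    hybrid_ids = list(A.ids)
    if D is not None and list(D.ids) != hybrid_ids:
        D = D.align(hybrid_ids)
    if environments is None:
        environments = list(pd.unique(eblues["environment"]))
    q = len(environments)
    if q != vc.q:
        raise ValueError("environment count differs from the fitted model")
    p = len(hybrid_ids)
    y, obs = cells_from_eblues(eblues, hybrid_ids, environments, trait, mask)

    Av = A.values + jitter * np.eye(p)
    Dv = D.values + jitter * np.eye(p) if (D is not None and vc.sigma2_ud is not None) else None
    G = genetic_covariance(vc, Av, Dv)
    X = np.kron(np.eye(q), np.ones((p, 1)))
    X_obs = X[obs]
    keep = X_obs.sum(axis=0) > 0
    if not keep.all():
        raise ValueError("observed cells do not span all environments")
    y_obs = y[obs]
    if vc.sigma2_e > 0:
        # solve with V_obs = s2e * V0_obs through the structured grid solver
        solver = _GridSolver(Av, Dv, q, obs)
        solver.factor({"ga": vc.sigma2_ua / vc.sigma2_e,
                       "gd": (vc.sigma2_ud or 0.0) / vc.sigma2_e,
                       "ra": vc.rho_a or 0.0, "rd": vc.rho_d or 0.0})
        sol = solver.solve_obs(np.column_stack([X_obs, y_obs])) / vc.sigma2_e
    else:
        V_obs = (G + 1e-10 * np.eye(p * q))[np.ix_(obs, obs)]
        c = cho_factor(V_obs, lower=True, check_finite=False)
        sol = cho_solve(c, np.column_stack([X_obs, y_obs]), check_finite=False)
    ViX, Viy = sol[:, :-1], sol[:, -1]
    M = X_obs.T @ ViX
    beta = np.linalg.solve(M, X_obs.T @ Viy)
    resid_rot = Viy - ViX @ beta

    if targets is None:
        t_idx = np.flatnonzero(~obs)
    else:
        hpos = {h: i for i, h in enumerate(hybrid_ids)}
        epos = {e: j for j, e in enumerate(environments)}
        t_idx = []
        for h, e in targets:
            if h not in hpos:
                raise KeyError(f"target hybrid {h!r} absent from kernels")
            if e not in epos:
                raise KeyError(f"unknown environment {e!r}")
            t_idx.append(epos[e] * p + hpos[h])
        t_idx = np.asarray(t_idx, dtype=int)

    genetic = G[np.ix_(t_idx, np.flatnonzero(obs))] @ resid_rot
    env_of = t_idx // p
    values = beta[env_of] + genetic
    label = method or ("GBLUP-AD" if vc.model == "AD" else "GBLUP-A")
    return pd.DataFrame({
        "hybrid": [hybrid_ids[i % p] for i in t_idx],
        "environment": [environments[j] for j in env_of],
        "method": label,
        "value": values,
    })
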