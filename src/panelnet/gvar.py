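"""Panel graphical vector autoregression with FIML estimation.

The model decomposes the stacked-wave covariance of a detrended,
standardized panel into

* a between-person network: precision ``K_B`` of the random intercepts,
* a within-person temporal matrix ``B`` (``B[k, j]``: effect of node j at
  wave t on node k at wave t+1), and
* a within-person contemporaneous network: innovation precision ``K_zeta``.

With ``Sigma_W`` the stationary solution of the discrete Lyapunov equation
``Sigma_W = B Sigma_W B' + K_zeta^{-1}`` and ``Sigma_B = K_B^{-1}``, the
implied covariance between waves t and t+d is ``Sigma_B + B^d Sigma_W``
(random-intercept cross-lagged panel structure).  Estimation maximizes the
pattern-wise full-information Gaussian likelihood; model search follows the
significance-prune / score-test step-up scheme at a fixed alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import solve_discrete_lyapunov
from scipy.optimize import minimize
from scipy.stats import chi2, norm

from .fiml import (LOG2PI, PatternStats, SingularPatternError,
                   independence_loglik, mvn_loglik, pattern_stats,
                   saturated_loglik)
from .ggm import precision_to_partial
from .panel_data import PanelDataset

logger = logging.getLogger(__name__)

PENALTY = 1e10
RHO_MAX = 0.97  # spectral rescaling bound inside the optimizer


class StationarityError(ValueError):
    pass


class GvarError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    def __init__(self, msg, best=None):
        super().__init__(msg)
        self.best = best


# ---------------------------------------------------------------------------
# parameters and implied moments
# ---------------------------------------------------------------------------

@dataclass
class GVARParameters:
    """Panel GVAR parameterization with free/fixed masks.

    ``free_*`` masks mark which network parameters are estimated; fixed
    entries are exactly zero.  Diagonals of both precisions are always free.
    """

    mu: np.ndarray                 # T x p cell means
    B: np.ndarray                  # p x p temporal matrix
    K_zeta: np.ndarray             # within contemporaneous precision
    K_B: np.ndarray                # between-person precision
    free_B: np.ndarray | None = None
    free_K_zeta: np.ndarray | None = None   # off-diagonal, symmetric
    free_K_B: np.ndarray | None = None

    def __post_init__(self):
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.B = np.asarray(self.B, dtype=float)
        self.K_zeta = np.asarray(self.K_zeta, dtype=float)
        self.K_B = np.asarray(self.K_B, dtype=float)
        p = self.B.shape[0]
        if self.free_B is None:
            self.free_B = np.ones((p, p), dtype=bool)
        if self.free_K_zeta is None:
            self.free_K_zeta = ~np.eye(p, dtype=bool)
        if self.free_K_B is None:
            self.free_K_B = ~np.eye(p, dtype=bool)
        # precision masks are symmetric by construction
        self.free_K_zeta = self.free_K_zeta | self.free_K_zeta.T
        self.free_K_B = self.free_K_B | self.free_K_B.T
        rho = spectral_radius(self.B)
        if rho >= 1.0:
            raise StationarityError(f"spectral radius {rho:.3f} >= 1")
        for name, K in (("K_zeta", self.K_zeta), ("K_B", self.K_B)):
            if np.linalg.eigvalsh(0.5 * (K + K.T)).min() <= 0:
                raise GvarError(f"{name} must be positive definite")
        for name, M, mask in (("B", self.B, self.free_B),
                              ("K_zeta", self.K_zeta, self.free_K_zeta | np.eye(p, dtype=bool)),
                              ("K_B", self.K_B, self.free_K_B | np.eye(p, dtype=bool))):
            if np.any(M[~mask] != 0.0):
                raise GvarError(f"fixed entries of {name} must be exactly zero")

    @property
    def p(self) -> int:
        return self.B.shape[0]

    @property
    def n_waves(self) -> int:
        return self.mu.shape[0]

    def n_free_params(self) -> int:
        p = self.p
        return int(self.mu.size + self.free_B.sum() + 2 * p
                   + np.triu(self.free_K_zeta, 1).sum()
                   + np.triu(self.free_K_B, 1).sum())

    def temporal(self) -> np.ndarray:
        return self.B.copy()

    def contemporaneous_partials(self) -> np.ndarray:
        return precision_to_partial(self.K_zeta)

    def between_partials(self) -> np.ndarray:
        return precision_to_partial(self.K_B)

    def to_dict(self) -> dict:
        return {"mu": self.mu.tolist(), "B": self.B.tolist(),
                "K_zeta": self.K_zeta.tolist(), "K_B": self.K_B.tolist(),
                "free_B": self.free_B.tolist(),
                "free_K_zeta": self.free_K_zeta.tolist(),
                "free_K_B": self.free_K_B.tolist()}


def spectral_radius(B: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(B)))) if B.size else 0.0


@dataclass
class ImpliedMoments:
    mean: np.ndarray
    cov: np.ndarray
    Sigma_W: np.ndarray
    Sigma_B: np.ndarray


def implied_moments(params: GVARParameters, T: int | None = None) -> ImpliedMoments:
    """Stacked-wave mean vector and covariance implied by the parameters."""
    T = T or params.n_waves
    p = params.p
    rho = spectral_radius(params.B)
    if rho >= 1.0:
        raise StationarityError(f"spectral radius {rho:.3f} >= 1")
    Q = np.linalg.inv(params.K_zeta)
    Sigma_W = solve_discrete_lyapunov(params.B, Q)
    Sigma_W = 0.5 * (Sigma_W + Sigma_W.T)
    Sigma_B = np.linalg.inv(params.K_B)
    cov = np.empty((T * p, T * p))
    Bpow = [np.eye(p)]
    for _ in range(T - 1):
        Bpow.append(Bpow[-1] @ params.B)
    for t2 in range(T):
        for t1 in range(t2 + 1):
            block = Sigma_B + Bpow[t2 - t1] @ Sigma_W
            cov[t2 * p:(t2 + 1) * p, t1 * p:(t1 + 1) * p] = block
            if t1 != t2:
                cov[t1 * p:(t1 + 1) * p, t2 * p:(t2 + 1) * p] = block.T
    mean = np.broadcast_to(params.mu, (T, p)).ravel().copy() \
        if params.mu.shape[0] != T else params.mu.ravel().copy()
    return ImpliedMoments(mean=mean, cov=0.5 * (cov + cov.T),
                          Sigma_W=Sigma_W, Sigma_B=Sigma_B)


def fiml_loglik(params: GVARParameters, panel) -> float:
    """Pattern-wise FIML log-likelihood of a (detrended) panel."""
    stats = _as_stats(panel)
    mom = implied_moments(params, T=len(stats[0].mask) // params.p)
    return mvn_loglik(stats, mom.mean, mom.cov)


def _as_stats(panel) -> list[PatternStats]:
    if isinstance(panel, PanelDataset):
        return pattern_stats(panel.stacked())
    if isinstance(panel, list) and panel and isinstance(panel[0], PatternStats):
        return panel
    return pattern_stats(np.asarray(panel, dtype=float))


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    loglik: float
    n_params: int
    chi2: float
    df: int
    rmsea: float
    cfi: float
    tli: float
    pvalue: float = float("nan")
    rmsea_undefined: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("loglik", "n_params", "chi2", "df", "rmsea", "cfi", "tli",
                 "pvalue")}


def fit_indices(model_loglik: float, model_params: int, panel) -> ModelFit:
    """Chi-square, RMSEA, CFI and TLI against the saturated Gaussian model.

    The saturated model (free mean and unstructured covariance of the stacked
    waves) is fitted by EM under the same missingness; the baseline is the
    independence model (free means and variances, zero covariances).
    """
    stats = _as_stats(panel)
    k = len(stats[0].mask)
    n = sum(st.n for st in stats)
    ll_sat, _, _ = saturated_loglik(stats)
    sat_params = k + k * (k + 1) // 2
    ll_indep, indep_params = independence_loglik(stats)
    chi2_m = max(0.0, 2.0 * (ll_sat - model_loglik))
    df_m = sat_params - model_params
    chi2_b = max(0.0, 2.0 * (ll_sat - ll_indep))
    df_b = sat_params - indep_params
    if df_m < 0:
        raise GvarError("model has more parameters than the saturated model")
    rmsea_undefined = df_m == 0
    rmsea = 0.0 if rmsea_undefined else float(
        np.sqrt(max(0.0, (chi2_m - df_m) / (df_m * n))))
    denom = max(chi2_b - df_b, 0.0)
    num = max(chi2_m - df_m, 0.0)
    cfi = 1.0 if denom == 0 and num == 0 else (
        0.0 if denom == 0 else min(1.0, max(0.0, 1.0 - num / denom)))
    if df_m > 0 and df_b > 0 and chi2_b / df_b != 1.0:
        tli = min(1.0, ((chi2_b / df_b) - (chi2_m / df_m))
                  / ((chi2_b / df_b) - 1.0))
    else:
        tli = 1.0
    pval = float(chi2.sf(chi2_m, df_m)) if df_m > 0 else float("nan")
    return ModelFit(loglik=model_loglik, n_params=model_params, chi2=chi2_m,
                    df=df_m, rmsea=rmsea, cfi=cfi, tli=tli, pvalue=pval,
                    rmsea_undefined=rmsea_undefined)


# ---------------------------------------------------------------------------
# optimization machinery
# ---------------------------------------------------------------------------

class _Parameterization:
    """Direct parameter vector <-> (mu, B, K_zeta, K_B) with masks."""

    def __init__(self, p: int, T: int, free_B: np.ndarray,
                 free_Kz: np.ndarray, free_KB: np.ndarray):
        self.p, self.T = p, T
        self.free_B = free_B.astype(bool)
        self.free_Kz = free_Kz.astype(bool)
        self.free_KB = free_KB.astype(bool)
        self.iu_z = [(i, j) for i in range(p) for j in range(i + 1, p)
                     if self.free_Kz[i, j]]
        self.iu_b = [(i, j) for i in range(p) for j in range(i + 1, p)
                     if self.free_KB[i, j]]
        self.idx_B = np.argwhere(self.free_B)
        self.n_mu = T * p
        self.n_params = (self.n_mu + len(self.idx_B) + p + len(self.iu_z)
                         + p + len(self.iu_b))
        # labels for network parameters (used by prune/step-up traces)
        self.labels: list[str] = [f"mu[{t},{v}]" for t in range(T) for v in range(p)]
        self.labels += [f"B[{i},{j}]" for i, j in self.idx_B]
        self.labels += [f"Kz[{i},{i}]" for i in range(p)]
        self.labels += [f"Kz[{i},{j}]" for i, j in self.iu_z]
        self.labels += [f"KB[{i},{i}]" for i in range(p)]
        self.labels += [f"KB[{i},{j}]" for i, j in self.iu_b]

    def pack(self, params: GVARParameters) -> np.ndarray:
        p = self.p
        theta = [params.mu.ravel()]
        theta.append(params.B[self.free_B])
        theta.append(np.diag(params.K_zeta))
        theta.append(np.array([params.K_zeta[i, j] for i, j in self.iu_z]))
        theta.append(np.diag(params.K_B))
        theta.append(np.array([params.K_B[i, j] for i, j in self.iu_b]))
        return np.concatenate(theta)

    def unpack(self, theta: np.ndarray):
        p, T = self.p, self.T
        pos = 0

        def take(k):
            nonlocal pos
            out = theta[pos:pos + k]
            pos += k
            return out

        mu = take(T * p).reshape(T, p)
        B = np.zeros((p, p))
        B[self.free_B] = take(len(self.idx_B))
        Kz = np.diag(take(p).copy())
        for v, (i, j) in zip(take(len(self.iu_z)), self.iu_z):
            Kz[i, j] = Kz[j, i] = v
        KB = np.diag(take(p).copy())
        for v, (i, j) in zip(take(len(self.iu_b)), self.iu_b):
            KB[i, j] = KB[j, i] = v
        return mu, B, Kz, KB

    def network_indices(self) -> list[int]:
        """Parameter-vector indices of the network parameters (prune targets)."""
        out = list(range(self.n_mu, self.n_mu + len(self.idx_B)))
        base = self.n_mu + len(self.idx_B) + self.p
        out += list(range(base, base + len(self.iu_z)))
        base += len(self.iu_z) + self.p
        out += list(range(base, base + len(self.iu_b)))
        return out


def _negloglik_factory(par: _Parameterization, stats: list[PatternStats]):
    f = _negloglik_grad_factory(par, stats)

    def negloglik(theta: np.ndarray) -> float:
        return f(theta)[0]

    return negloglik


def _sym_contract(par_pairs: list[tuple[int, int]], M: np.ndarray,
                  p: int) -> tuple[np.ndarray, np.ndarray]:
    """Gradient of a matrix functional wrt diagonal + symmetric-pair entries."""
    diag = np.diag(M).copy()
    off = np.array([M[i, j] + M[j, i] for i, j in par_pairs])
    return diag, off


def _negloglik_grad_factory(par: _Parameterization, stats: list[PatternStats]):
    """Objective returning (value, gradient) with an analytic gradient.

    The gradient chains the pattern-wise Gaussian derivatives dL/d(mu, Sigma)
    through the implied-moment map; the within-covariance sensitivity uses
    one adjoint discrete-Lyapunov solve instead of differentiating the
    Lyapunov solution per parameter.
    """
    p, T = par.p, par.T
    k = T * p
    pattern_idx = [np.nonzero(st.mask)[0] for st in stats]

    def value_and_grad(theta: np.ndarray):
        mu, B, Kz, KB = par.unpack(theta)
        grad = np.zeros_like(theta)
        n_mu, nB = par.n_mu, len(par.idx_B)
        sl_B = slice(n_mu, n_mu + nB)
        sl_zd = slice(sl_B.stop, sl_B.stop + p)
        sl_zo = slice(sl_zd.stop, sl_zd.stop + len(par.iu_z))
        sl_bd = slice(sl_zo.stop, sl_zo.stop + p)
        sl_bo = slice(sl_bd.stop, sl_bd.stop + len(par.iu_b))

        # ---- infeasible regions: penalty with a push-back gradient -------
        pen = 0.0
        for K, sd, so in ((Kz, sl_zd, sl_zo), (KB, sl_bd, sl_bo)):
            w, V = np.linalg.eigh(K)
            if w[0] <= 1e-8:
                pen += 1.0 + max(0.0, -w[0])
                v = V[:, 0]
                M = -np.outer(v, v)  # d(-eigmin)/dK
                pairs = par.iu_z if sd is sl_zd else par.iu_b
                d, o = _sym_contract(pairs, M, p)
                grad[sd] += PENALTY * d
                grad[so] += PENALTY * o
        rho = spectral_radius(B)
        if rho >= RHO_MAX:
            pen += 1.0 + (rho - RHO_MAX)
            lam, U = np.linalg.eig(B)
            i = int(np.argmax(np.abs(lam)))
            lamw, W = np.linalg.eig(B.T)
            jw = int(np.argmin(np.abs(lamw - lam[i])))
            u, w_vec = U[:, i], W[:, jw]
            denom = w_vec @ u
            if abs(denom) > 1e-12:
                dlam = np.outer(w_vec, u) / denom
                drho = np.real(np.conj(lam[i]) / abs(lam[i]) * dlam)
                grad[sl_B] += PENALTY * drho[par.free_B]
        if pen > 0:
            return PENALTY * pen, grad

        try:
            Q = np.linalg.inv(Kz)
            Sigma_W = solve_discrete_lyapunov(B, Q)
            Sigma_W = 0.5 * (Sigma_W + Sigma_W.T)
            Sigma_B = np.linalg.inv(KB)
            Bpow = [np.eye(p)]
            for _ in range(T - 1):
                Bpow.append(Bpow[-1] @ B)
            cov = np.empty((k, k))
            for t2 in range(T):
                for t1 in range(t2 + 1):
                    blk = Sigma_B + Bpow[t2 - t1] @ Sigma_W
                    cov[t2 * p:(t2 + 1) * p, t1 * p:(t1 + 1) * p] = blk
                    if t1 != t2:
                        cov[t1 * p:(t1 + 1) * p, t2 * p:(t2 + 1) * p] = blk.T
            cov = 0.5 * (cov + cov.T)
            mu_vec = mu.ravel()

            # pattern-wise log-likelihood, dL/dmu and dL/dSigma
            loglik = 0.0
            G = np.zeros((k, k))
            g_mu = np.zeros(k)
            for st, idx in zip(stats, pattern_idx):
                so = cov[np.ix_(idx, idx)]
                d = st.mean - mu_vec[idx]
                L = np.linalg.cholesky(so)
                logdet = 2.0 * np.log(np.diag(L)).sum()
                so_inv = np.linalg.inv(so)
                M = st.scatter + np.outer(d, d)
                loglik += -0.5 * st.n * (
                    len(idx) * LOG2PI + logdet + np.sum(so_inv * M))
                G[np.ix_(idx, idx)] += 0.5 * st.n * (
                    so_inv @ M @ so_inv - so_inv)
                g_mu[idx] += st.n * (so_inv @ d)
        except (np.linalg.LinAlgError, SingularPatternError):
            return PENALTY, np.zeros_like(theta)

        # ---- chain rule through the implied moments ----------------------
        blocksG = [[G[t2 * p:(t2 + 1) * p, t1 * p:(t1 + 1) * p]
                    for t1 in range(T)] for t2 in range(T)]
        SumB = np.zeros((p, p))
        for t2 in range(T):
            for t1 in range(T):
                SumB += blocksG[t2][t1]
        M_KB = -Sigma_B @ SumB @ Sigma_B

        A = np.zeros((p, p))
        for t in range(T):
            A += blocksG[t][t]
        dB = np.zeros((p, p))
        for t2 in range(T):
            for t1 in range(t2):
                delta = t2 - t1
                Gb = blocksG[t2][t1]
                A += Bpow[delta].T @ Gb + Gb.T @ Bpow[delta]
                for a in range(delta):
                    b = delta - 1 - a
                    dB += 2.0 * Bpow[a].T @ Gb @ Sigma_W @ Bpow[b].T
        A_tilde = solve_discrete_lyapunov(B.T, A)
        M_Kz = -Q @ A_tilde @ Q
        dB += (A_tilde + A_tilde.T) @ B @ Sigma_W

        grad[:n_mu] = -g_mu
        grad[sl_B] = -dB[par.free_B]
        dz, oz = _sym_contract(par.iu_z, M_Kz, p)
        grad[sl_zd], grad[sl_zo] = -dz, -oz
        db_, ob = _sym_contract(par.iu_b, M_KB, p)
        grad[sl_bd], grad[sl_bo] = -db_, -ob
        return -loglik, grad

    return value_and_grad


def _hessian_from_grad(grad_f, x: np.ndarray, rel_eps: float = 1e-5
                       ) -> np.ndarray:
    """Hessian as the symmetrized Jacobian of an analytic gradient."""
    m = x.size
    H = np.empty((m, m))
    for i in range(m):
        h = rel_eps * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        H[i] = (grad_f(xp)[1] - grad_f(xm)[1]) / (2 * h)
    return 0.5 * (H + H.T)


def _numerical_gradient(f, x: np.ndarray, rel_eps: float = 1e-5) -> np.ndarray:
    g = np.empty_like(x)
    for i in range(x.size):
        h = rel_eps * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2 * h)
    return g


@dataclass
class GVARFit:
    """A fitted panel GVAR: parameters, likelihood and bookkeeping."""

    params: GVARParameters
    loglik: float
    converged: bool
    n_params: int
    theta: np.ndarray
    parameterization: _Parameterization
    stats: list[PatternStats]
    fit: ModelFit | None = None
    se: np.ndarray | None = None

    @property
    def n(self) -> int:
        return sum(st.n for st in self.stats)

    def with_fit_indices(self) -> "GVARFit":
        return replace(self, fit=fit_indices(self.loglik, self.n_params, self.stats))


def _moment_start(stats: list[PatternStats], p: int, T: int):
    """Data-driven starting values from the EM-saturated moments."""
    from .fiml import em_mvn

    mu_hat, S_hat = em_mvn(stats, max_iter=50, tol=1e-6)
    blocks0 = [S_hat[t * p:(t + 1) * p, t * p:(t + 1) * p] for t in range(T)]
    S0 = sum(blocks0) / T
    S1 = sum(S_hat[(t + 1) * p:(t + 2) * p, t * p:(t + 1) * p]
             for t in range(T - 1)) / max(1, T - 1)
    if T >= 3:
        SB = S_hat[2 * p:3 * p, 0:p]
    else:
        SB = 0.5 * S1
    SB = _project_pd(0.5 * (SB + SB.T), 0.02 * np.diag(S0).mean())
    SW = _project_pd(S0 - SB, 0.05 * np.diag(S0).mean())
    B0 = (S1 - SB) @ np.linalg.inv(SW)
    rho = spectral_radius(B0)
    if rho > 0.7:
        B0 *= 0.7 / rho
    Q0 = _project_pd(SW - B0 @ SW @ B0.T, 0.05 * np.diag(SW).mean())
    return mu_hat.reshape(T, p), B0, np.linalg.inv(Q0), np.linalg.inv(SB)


def _project_pd(M: np.ndarray, min_eig: float) -> np.ndarray:
    w, V = np.linalg.eigh(0.5 * (M + M.T))
    return (V * np.clip(w, min_eig, None)) @ V.T


def _optimize(par: _Parameterization, stats, theta0_list, gtol=1e-5,
              maxiter=2000):
    vg = _negloglik_grad_factory(par, stats)
    best = None
    for theta0 in theta0_list:
        res = minimize(vg, theta0, method="L-BFGS-B", jac=True,
                       options={"gtol": gtol, "ftol": 1e-11,
                                "maxiter": maxiter, "maxcor": 30})
        if best is None or res.fun < best.fun:
            best = res
    return best, vg


def fit_gvar(panel, T: int | None = None,
             free_B: np.ndarray | None = None,
             free_K_zeta: np.ndarray | None = None,
             free_K_B: np.ndarray | None = None,
             n_starts: int = 3, seed: int = 0,
             start: GVARParameters | None = None,
             gtol: float = 1e-5) -> GVARFit:
    """Fit a panel GVAR (saturated by default) by pattern-wise FIML.

    Multi-start L-BFGS from a moment-informed start plus seeded
    perturbations; positive definiteness is maintained by a penalty guard and
    stationarity by spectral rescaling inside the objective.
    """
    stats = _as_stats(panel)
    k = len(stats[0].mask)
    if isinstance(panel, PanelDataset):
        T = T or panel.n_waves
    if T is None:
        raise GvarError("T (number of waves) required for matrix input")
    p = k // T
    n = sum(st.n for st in stats)
    if n < 10 * p:
        logger.warning("small sample: n=%d < 10 p=%d", n, 10 * p)
    free_B = np.ones((p, p), dtype=bool) if free_B is None else free_B.astype(bool)
    free_Kz = ~np.eye(p, dtype=bool) if free_K_zeta is None else free_K_zeta.astype(bool)
    free_KB = ~np.eye(p, dtype=bool) if free_K_B is None else free_K_B.astype(bool)
    par = _Parameterization(p, T, free_B, free_Kz, free_KB)
    rng = np.random.default_rng(seed)
    if start is not None:
        theta0 = par.pack(start)
    else:
        mu0, B0, Kz0, KB0 = _moment_start(stats, p, T)
        B0 = np.where(free_B, B0, 0.0)
        Kz0 = np.where(free_Kz | np.eye(p, dtype=bool), Kz0, 0.0)
        KB0 = np.where(free_KB | np.eye(p, dtype=bool), KB0, 0.0)
        theta0 = par.pack(GVARParameters(
            mu=mu0, B=B0,
            K_zeta=_mask_pd(Kz0, free_Kz), K_B=_mask_pd(KB0, free_KB),
            free_B=free_B, free_K_zeta=free_Kz, free_K_B=free_KB))
    starts = [theta0]
    for _ in range(max(0, n_starts - 1)):
        starts.append(theta0 + rng.normal(scale=0.05, size=theta0.size)
                      * np.maximum(1.0, np.abs(theta0)))
    res, nll = _optimize(par, stats, starts, gtol=gtol)
    if res is None or res.fun >= PENALTY:
        raise ConvergenceError("panel GVAR optimization failed", best=res)
    mu, B, Kz, KB = par.unpack(res.x)
    rho = spectral_radius(B)
    if rho >= RHO_MAX:
        B = B * ((RHO_MAX - 0.005) / rho)
    params = GVARParameters(mu=mu, B=B, K_zeta=Kz, K_B=KB, free_B=free_B,
                            free_K_zeta=free_Kz, free_K_B=free_KB)
    return GVARFit(params=params, loglik=-float(res.fun),
                   converged=bool(res.success), n_params=par.n_params,
                   theta=res.x.copy(), parameterization=par, stats=stats)


def _mask_pd(K: np.ndarray, free_off: np.ndarray) -> np.ndarray:
    """Masked precision, shrunk toward its diagonal until PD."""
    p = K.shape[0]
    M = np.where(free_off | np.eye(p, dtype=bool), K, 0.0)
    M = 0.5 * (M + M.T)
    for _ in range(30):
        if np.linalg.eigvalsh(M).min() > 1e-6:
            return M
        off = M - np.diag(np.diag(M))
        M = np.diag(np.diag(M)) + 0.7 * off
    return np.diag(np.maximum(np.diag(K), 1e-3))


def fit_saturated_gvar(panel, T: int | None = None, n_starts: int = 3,
                       seed: int = 0, gtol: float = 1e-5) -> GVARFit:
    """Saturated panel GVAR (all temporal and precision entries free)."""
    return fit_gvar(panel, T=T, n_starts=n_starts, seed=seed, gtol=gtol)


# ---------------------------------------------------------------------------
# prune + step-up model search
# ---------------------------------------------------------------------------

def wald_tests(fit: GVARFit) -> dict[str, tuple[float, float, float]]:
    """Observed-information Wald tests: label -> (estimate, SE, p)."""
    par = fit.parameterization
    vg = _negloglik_grad_factory(par, fit.stats)
    H = _hessian_from_grad(vg, fit.theta)
    cov = _safe_inv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    out = {}
    for i, label in enumerate(par.labels):
        est = fit.theta[i]
        s = se[i]
        pval = 2 * norm.sf(abs(est) / s) if s > 0 else 0.0
        out[label] = (float(est), float(s), float(pval))
    return out


def _safe_inv(H: np.ndarray) -> np.ndarray:
    try:
        w = np.linalg.eigvalsh(0.5 * (H + H.T))
        if w.min() > 0:
            return np.linalg.inv(0.5 * (H + H.T))
    except np.linalg.LinAlgError:
        pass
    return np.linalg.pinv(0.5 * (H + H.T), rcond=1e-10)


def _label_to_mask_entry(label: str):
    kind, rest = label.split("[")
    i, j = (int(x) for x in rest.rstrip("]").split(","))
    return kind, i, j


def prune_stepup(fit: GVARFit, alpha: float = 0.05, max_stepup: int = 30,
                 stepup_correction: str = "bonferroni"
                 ) -> tuple[GVARFit, list[dict]]:
    """Significance prune then score-test step-up search on network parameters.

    Prune: every free network parameter (temporal entries and off-diagonal
    precision entries) with a Wald p >= alpha is fixed to zero, then the
    model is refitted.  Step-up: the fixed parameter with the largest
    score-test (modification-index) improvement is freed while it is
    significant at alpha, refitting after each addition; because the search
    takes the maximum over all fixed candidates, the default Bonferroni
    correction divides alpha by the candidate count so the step does not
    reintroduce the false positives the prune removed
    (``stepup_correction="none"`` tests at raw alpha).  A parameter removed
    and re-added twice terminates the loop (oscillation guard).  Returns the
    final fit and a trace of every decision.
    """
    par = fit.parameterization
    p, T = par.p, par.T
    trace: list[dict] = []
    current = fit
    if alpha < 1.0:
        tests = wald_tests(current)
        net_idx = set(par.network_indices())
        to_fix = []
        for i, label in enumerate(par.labels):
            if i in net_idx:
                est, se, pval = tests[label]
                if pval >= alpha:
                    to_fix.append(label)
                    trace.append({"step": "prune", "param": label,
                                  "estimate": est, "se": se, "p": pval})
        if to_fix:
            current = _refit_without(current, to_fix)
    else:
        return current, trace

    readd_count: dict[str, int] = {}
    for _ in range(max_stepup):
        cand = _stepup_candidates(current)
        if not cand:
            break
        full_par = _Parameterization(p, T, np.ones((p, p), bool),
                                     ~np.eye(p, dtype=bool), ~np.eye(p, dtype=bool))
        theta_full = full_par.pack(replace(
            current.params, free_B=np.ones((p, p), bool),
            free_K_zeta=~np.eye(p, dtype=bool), free_K_B=~np.eye(p, dtype=bool)))
        vg_full = _negloglik_grad_factory(full_par, current.stats)
        g = -vg_full(theta_full)[1]
        H = _hessian_from_grad(vg_full, theta_full)
        cov = _safe_inv(H)
        best_label, best_stat = None, 0.0
        for label in sorted(cand):
            j = full_par.labels.index(label)
            v = cov[j, j]
            if v <= 0:
                continue
            stat = g[j] ** 2 * v
            if stat > best_stat + 1e-12:
                best_label, best_stat = label, stat
        if best_label is None:
            break
        pval = float(chi2.sf(best_stat, 1))
        threshold = alpha / len(cand) if stepup_correction == "bonferroni" \
            else alpha
        if pval >= threshold:
            break
        readd_count[best_label] = readd_count.get(best_label, 0) + 1
        trace.append({"step": "step-up", "param": best_label,
                      "score_stat": float(best_stat), "p": pval})
        if readd_count[best_label] > 2:
            logger.warning("oscillation guard triggered at %s", best_label)
            trace.append({"step": "oscillation-stop", "param": best_label})
            break
        current = _refit_with(current, best_label)
    return current, trace


def _stepup_candidates(fit: GVARFit) -> list[str]:
    par = fit.parameterization
    p = par.p
    cand = [f"B[{i},{j}]" for i in range(p) for j in range(p)
            if not par.free_B[i, j]]
    cand += [f"Kz[{i},{j}]" for i in range(p) for j in range(i + 1, p)
             if not par.free_Kz[i, j]]
    cand += [f"KB[{i},{j}]" for i in range(p) for j in range(i + 1, p)
             if not par.free_KB[i, j]]
    return cand


def _masks_from_fit(fit: GVARFit):
    par = fit.parameterization
    return (par.free_B.copy(), par.free_Kz.copy(), par.free_KB.copy())


def _refit_masks(fit: GVARFit, free_B, free_Kz, free_KB) -> GVARFit:
    params = fit.params
    start = GVARParameters(
        mu=params.mu,
        B=np.where(free_B, params.B, 0.0),
        K_zeta=_mask_pd(params.K_zeta, free_Kz),
        K_B=_mask_pd(params.K_B, free_KB),
        free_B=free_B, free_K_zeta=free_Kz, free_K_B=free_KB)
    return fit_gvar(fit.stats, T=fit.parameterization.T, free_B=free_B,
                    free_K_zeta=free_Kz, free_K_B=free_KB, n_starts=1,
                    start=start)


def _refit_without(fit: GVARFit, labels: list[str]) -> GVARFit:
    free_B, free_Kz, free_KB = _masks_from_fit(fit)
    for label in labels:
        kind, i, j = _label_to_mask_entry(label)
        if kind == "B":
            free_B[i, j] = False
        elif kind == "Kz":
            free_Kz[i, j] = free_Kz[j, i] = False
        else:
            free_KB[i, j] = free_KB[j, i] = False
    return _refit_masks(fit, free_B, free_Kz, free_KB)


def _refit_with(fit: GVARFit, label: str) -> GVARFit:
    free_B, free_Kz, free_KB = _masks_from_fit(fit)
    kind, i, j = _label_to_mask_entry(label)
    if kind == "B":
        free_B[i, j] = True
    elif kind == "Kz":
        free_Kz[i, j] = free_Kz[j, i] = True
    else:
        free_KB[i, j] = free_KB[j, i] = True
    return _refit_masks(fit, free_B, free_Kz, free_KB)
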