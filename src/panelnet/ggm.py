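"""Cross-sectional Gaussian graphical models with EBIC model selection.

A wave's partial-correlation network is estimated by the graphical lasso
along a descending penalty path, selecting the path member that minimizes
the extended Bayesian information criterion (EBIC) with hyperparameter
``gamma`` (0.5 by default, favouring sparser graphs and fewer spurious
edges).  The glasso subproblem is solved by scikit-learn; the path and EBIC
selection live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.covariance import graphical_lasso

from .panel_data import PanelDataset

EDGE_TOL = 1e-8  # below this a precision off-diagonal counts as absent


class GgmError(ValueError):
    pass


class GlassoConvergenceError(RuntimeError):
    pass


@dataclass
class GGM:
    """Selected Gaussian graphical model for one cross-section."""

    partial_corr: np.ndarray
    precision: np.ndarray
    lambda_selected: float
    ebic_gamma: float
    n: int = 0
    node_names: list[str] = field(default_factory=list)
    path_lambdas: np.ndarray | None = None
    path_ebic: np.ndarray | None = None

    @property
    def adjacency(self) -> np.ndarray:
        return np.abs(self.partial_corr) > EDGE_TOL

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())

    def edge_list(self):
        import pandas as pd

        p = self.partial_corr.shape[0]
        names = self.node_names or [f"V{j + 1}" for j in range(p)]
        rows = [
            {"node1": names[i], "node2": names[j],
             "partial_corr": self.partial_corr[i, j]}
            for i in range(p) for j in range(i + 1, p)
            if abs(self.partial_corr[i, j]) > EDGE_TOL
        ]
        return pd.DataFrame(rows, columns=["node1", "node2", "partial_corr"])


def precision_to_partial(K: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(K))
    P = -K / np.outer(d, d)
    np.fill_diagonal(P, 0.0)
    return 0.5 * (P + P.T)


def glasso_fit(S: np.ndarray, lam: float, tol: float = 1e-5,
               max_iter: int = 200) -> np.ndarray:
    """L1-penalized precision estimate for sample covariance S.

    Maximizes ``log det K - tr(SK) - lam * sum_offdiag |K_ij|``.  The
    unpenalized limit returns the exact inverse.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise GgmError("S must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise GgmError("S must be symmetric")
    if lam < 0:
        raise GgmError("penalty must be >= 0")
    if lam == 0:
        return np.linalg.inv(S)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, K = graphical_lasso(S, alpha=lam, tol=tol, max_iter=max_iter)
    except FloatingPointError as err:
        raise GlassoConvergenceError(
            f"graphical lasso failed to converge at lam={lam:.4g}: {err}"
        ) from err
    return 0.5 * (K + K.T)


def ebic_score(K: np.ndarray, S: np.ndarray, n: int, gamma: float = 0.5) -> float:
    """Extended BIC of a Gaussian graphical model; lower is better.

    ``-n (log det K - tr(SK)) + E log n + 4 E gamma log p`` with E the number
    of off-diagonal upper-triangle edges.  ``gamma = 0`` reduces to the BIC.
    """
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        raise GgmError("precision must be positive definite")
    E = int((np.abs(np.triu(K, 1)) > EDGE_TOL).sum())
    p = K.shape[0]
    ll_term = -n * (logdet - np.trace(S @ K))
    return float(ll_term + E * np.log(n) + 4.0 * E * gamma * np.log(p))


def constrained_ml_precision(S: np.ndarray, support: np.ndarray,
                             gtol: float = 1e-9) -> np.ndarray:
    """Gaussian ML precision with off-diagonal zeros outside ``support``.

    Maximizes ``log det K - tr(SK)`` over the free entries (diagonal plus the
    supported symmetric pairs) by quasi-Newton ascent; the gradient is
    ``(K^{-1} - S)`` restricted to the free entries.
    """
    from scipy.optimize import minimize

    p = S.shape[0]
    support = np.asarray(support, dtype=bool)
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)
             if support[i, j] or support[j, i]]

    def build(theta):
        K = np.diag(theta[:p])
        for v, (i, j) in zip(theta[p:], pairs):
            K[i, j] = K[j, i] = v
        return K

    def objective(theta):
        K = build(theta)
        w, V = np.linalg.eigh(K)
        if w[0] <= 1e-10:
            v = V[:, 0]
            g = np.zeros_like(theta)
            M = -np.outer(v, v)
            g[:p] = 1e8 * np.diag(M)
            g[p:] = 1e8 * 2 * np.array([M[i, j] for i, j in pairs])
            return 1e8 * (1.0 - w[0]), g
        Sigma = (V / w) @ V.T
        val = -(np.log(w).sum() - np.sum(S * K))
        G = -(Sigma - S)
        g = np.empty_like(theta)
        g[:p] = np.diag(G)
        g[p:] = 2 * np.array([G[i, j] for i, j in pairs])
        return val, g

    theta0 = np.concatenate([1.0 / np.diag(S), np.zeros(len(pairs))])
    res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                   options={"gtol": gtol, "ftol": 1e-14})
    K = build(res.x)
    return 0.5 * (K + K.T)


def wave_complete_cases(panel: PanelDataset, wave: int) -> np.ndarray:
    """All-variable complete cases at a (1-based) wave."""
    M = panel.values[:, wave - 1, :]
    keep = ~np.isnan(M).any(axis=1)
    return M[keep].copy()


def estimate_ggm(wave_data: np.ndarray, gamma: float = 0.5,
                 path_length: int = 100, min_ratio: float = 0.01,
                 method: str = "pearson", refit: bool = True,
                 node_names: list[str] | None = None) -> GGM:
    """EBIC-selected graphical lasso on one cross-section (n x p matrix).

    The penalty path is log-spaced from the smallest penalty giving an empty
    graph (``max |r_ij|``) down to ``min_ratio`` times it; the correlation
    matrix is the default moment input so the graph is scale-invariant.  By
    default each distinct support on the path is scored by the EBIC of its
    constrained ML refit (the lasso selects the support, maximum likelihood
    scores and reports it); ``refit=False`` scores and returns the penalized
    path members instead.  Ties in EBIC are broken toward the sparser
    (larger-penalty) model.
    """
    X = np.asarray(wave_data, dtype=float)
    if np.isnan(X).any():
        raise GgmError("wave data must be complete cases (drop NaN rows first)")
    n, p = X.shape
    if method == "spearman":
        X = np.apply_along_axis(rankdata, 0, X)
    sd = X.std(axis=0)
    if (sd < 1e-12).any():
        raise GgmError("degenerate (constant) variable in wave data")
    S = np.corrcoef(X, rowvar=False)
    lmax = np.abs(S - np.eye(p)).max()
    if lmax <= 0:
        lmax = 1e-4
    lambdas = np.geomspace(lmax, min_ratio * lmax, path_length)
    best = None
    ebics = np.full(path_length, np.nan)
    seen: dict[bytes, float] = {}
    for i, lam in enumerate(lambdas):
        try:
            K_pen = glasso_fit(S, lam)
        except GlassoConvergenceError:
            continue
        support = np.abs(K_pen) > EDGE_TOL
        np.fill_diagonal(support, True)
        key = support.tobytes()
        if refit:
            if key in seen:
                ebics[i] = seen[key]
                continue
            K = constrained_ml_precision(S, support)
            K = np.where(support, K, 0.0)
        else:
            K = K_pen
        ebics[i] = ebic_score(K, S, n, gamma)
        seen[key] = ebics[i]
        if best is None or ebics[i] < best[0] - 1e-12:
            best = (ebics[i], lam, K)
    if best is None:
        raise GlassoConvergenceError("no path member converged")
    _, lam_sel, K_sel = best
    diag = np.diag(K_sel).copy()
    K_sel = np.where(np.abs(K_sel) > EDGE_TOL, K_sel, 0.0)
    np.fill_diagonal(K_sel, diag)
    return GGM(partial_corr=precision_to_partial(K_sel), precision=K_sel,
               lambda_selected=float(lam_sel), ebic_gamma=gamma, n=n,
               node_names=node_names or [], path_lambdas=lambdas,
               path_ebic=ebics)


def estimate_wave_ggm(panel: PanelDataset, wave: int, gamma: float = 0.5,
                      **kwargs) -> GGM:
    """Convenience: complete cases of one panel wave -> EBIC-glasso GGM."""
    data = wave_complete_cases(panel, wave)
    if data.shape[0] <= panel.n_variables:
        raise GgmError(f"too few complete cases at wave {wave}")
    return estimate_ggm(data, gamma=gamma,
                        node_names=panel.variable_names, **kwargs)
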