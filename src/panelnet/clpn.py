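"""Cross-lagged panel networks via node-wise LASSO regression.

For a pair of consecutive waves (s, t), every node measured at wave t is
regressed on all p nodes measured at wave s with an L1 penalty, the penalty
chosen per node by k-fold cross-validation (10 folds by default).  The
resulting directed p x p weight matrix conflates within- and between-person
effects by design — it answers a prediction question, not a within-person
mechanism question.

The penalized objective is the standard ``(1/2n)||y - b0 - X b||^2 +
lam ||b||_1``; fitting is delegated to scikit-learn's coordinate descent,
with the unpenalized limit computed by least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Lasso, lasso_path

from .panel_data import PanelDataset, wave_pair_complete_cases


class ClpnError(ValueError):
    pass


@dataclass
class CVResult:
    """k-fold cross-validation trace for one node-wise LASSO."""

    lambda_grid: np.ndarray          # descending penalties
    fold_mse: np.ndarray             # grid x fold out-of-fold MSE
    selected: int                    # index into lambda_grid
    rule: str                        # "min" or "1se"
    seed: int

    @property
    def lambda_selected(self) -> float:
        return float(self.lambda_grid[self.selected])

    @property
    def mean_mse(self) -> np.ndarray:
        return self.fold_mse.mean(axis=1)


@dataclass
class CrossLaggedNetwork:
    """Directed lag-1 network for one wave pair.

    ``weights[j, k]`` is the regression coefficient of predictor node j
    (wave s) in the model for outcome node k (wave t); the diagonal holds the
    autoregressive effects.  Coefficients shrunk to zero are exact zeros.
    """

    weights: np.ndarray
    wave_pair: tuple[int, int]
    lambdas: np.ndarray              # per-outcome selected penalty
    n_used: int
    node_names: list[str] = field(default_factory=list)
    cv_results: list[CVResult] = field(default_factory=list)

    def edge_list(self):
        import pandas as pd

        rows = []
        p = self.weights.shape[0]
        names = self.node_names or [f"V{j + 1}" for j in range(p)]
        for j in range(p):
            for k in range(p):
                if self.weights[j, k] != 0.0:
                    rows.append({
                        "from": names[j], "to": names[k],
                        "weight": self.weights[j, k],
                        "wave_pair": f"{self.wave_pair[0]}-{self.wave_pair[1]}",
                    })
        return pd.DataFrame(rows, columns=["from", "to", "weight", "wave_pair"])


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ClpnError("X must be n x p with y of length n")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ClpnError("non-finite values in regression inputs")
    return X, y


def fit_node_lasso(X: np.ndarray, y: np.ndarray, lam: float,
                   tol: float = 1e-10) -> tuple[np.ndarray, float]:
    """L1-penalized regression of one outcome on standardized predictors.

    Returns ``(coefficients, intercept)`` minimizing
    ``(1/2n)||y - b0 - X b||^2 + lam ||b||_1``.  With ``lam = 0`` the exact
    least-squares solution is returned.
    """
    X, y = _validate_xy(X, y)
    if lam < 0:
        raise ClpnError(f"penalty must be >= 0, got {lam}")
    if X.shape[0] <= 2:
        raise ClpnError("need n > 2 observations")
    if lam == 0.0:
        xm, ym = X.mean(axis=0), y.mean()
        coef, *_ = np.linalg.lstsq(X - xm, y - ym, rcond=None)
        return coef, float(ym - xm @ coef)
    model = Lasso(alpha=lam, fit_intercept=True, tol=tol, max_iter=100_000)
    model.fit(X, y)
    return model.coef_.copy(), float(model.intercept_)


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which every coefficient is zero."""
    X, y = _validate_xy(X, y)
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    return float(np.abs(Xc.T @ (y - y.mean())).max() / n)


def default_grid(X: np.ndarray, y: np.ndarray, length: int = 100,
                 min_ratio: float = 1e-3) -> np.ndarray:
    lmax = lambda_max(X, y)
    if lmax <= 0:
        lmax = 1e-8
    return np.geomspace(lmax, min_ratio * lmax, length)


def select_lambda_cv(X: np.ndarray, y: np.ndarray, k: int = 10,
                     grid: np.ndarray | None = None, rule: str = "min",
                     seed: int = 20230101) -> CVResult:
    """k-fold cross-validated penalty selection over a descending grid.

    Folds are a seeded random partition into k near-equal blocks.  ``min``
    picks the penalty with the lowest mean out-of-fold MSE (ties toward the
    sparser model); ``1se`` picks the largest penalty within one standard
    error of that minimum.
    """
    X, y = _validate_xy(X, y)
    n = X.shape[0]
    if not 2 <= k <= n:
        raise ClpnError(f"need 2 <= k <= n, got k={k}, n={n}")
    if rule not in ("min", "1se"):
        raise ClpnError("rule must be 'min' or '1se'")
    if grid is None:
        grid = default_grid(X, y)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or (grid <= 0).any():
        raise ClpnError("penalty grid must be non-empty and positive")
    grid = np.sort(grid)[::-1]
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), k)
    fold_mse = np.empty((grid.size, k))
    for f, test_idx in enumerate(folds):
        train = np.setdiff1d(np.arange(n), test_idx)
        Xtr, ytr = X[train], y[train]
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        _, coefs, _ = lasso_path(Xtr - xm, ytr - ym, alphas=grid,
                                 tol=1e-8, max_iter=100_000)
        pred = (X[test_idx] - xm) @ coefs + ym  # n_test x n_alphas
        fold_mse[:, f] = np.mean((y[test_idx, None] - pred) ** 2, axis=0)
    mean_mse = fold_mse.mean(axis=1)
    i_min = int(np.argmin(mean_mse))  # first minimum = largest lambda = sparsest
    if rule == "min":
        selected = i_min
    else:
        se = fold_mse[i_min].std(ddof=1) / np.sqrt(k)
        within = np.nonzero(mean_mse <= mean_mse[i_min] + se)[0]
        selected = int(within.min())
    return CVResult(lambda_grid=grid, fold_mse=fold_mse, selected=selected,
                    rule=rule, seed=seed)


def estimate_clpn(panel: PanelDataset, s: int, t: int, k: int = 10,
                  rule: str = "min", seed: int = 20230101,
                  grid_length: int = 100,
                  standardize_outcome: bool = True) -> CrossLaggedNetwork:
    """Estimate the cross-lagged network between consecutive waves s and t.

    Complete cases for the wave pair are used; predictors (and, by default,
    outcomes) are z-scored on that sample so edge weights are comparable
    across the network.  Each outcome node gets its own cross-validated
    penalty.
    """
    if t != s + 1:
        raise ClpnError("cross-lagged networks are estimated between "
                        "consecutive waves")
    Xw, Yw, _ = wave_pair_complete_cases(panel, s, t)
    n, p = Xw.shape

    def zscore(M):
        sd = M.std(axis=0)
        if (sd == 0).any():
            raise ClpnError("constant variable in wave-pair sample")
        return (M - M.mean(axis=0)) / sd

    X = zscore(Xw)
    Y = zscore(Yw) if standardize_outcome else Yw - Yw.mean(axis=0)
    weights = np.zeros((p, p))
    lambdas = np.empty(p)
    cv_results = []
    for node in range(p):
        y = Y[:, node]
        grid = default_grid(X, y, length=grid_length)
        # one fold partition for every outcome keeps the estimator
        # equivariant to node relabeling
        cv = select_lambda_cv(X, y, k=k, grid=grid, rule=rule, seed=seed)
        coef, _ = fit_node_lasso(X, y, cv.lambda_selected)
        weights[:, node] = coef
        lambdas[node] = cv.lambda_selected
        cv_results.append(cv)
    return CrossLaggedNetwork(weights=weights, wave_pair=(s, t),
                              lambdas=lambdas, n_used=n,
                              node_names=panel.variable_names,
                              cv_results=cv_results)
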