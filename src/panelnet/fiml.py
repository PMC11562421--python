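"""Full-information maximum likelihood utilities for the multivariate normal.

Missing data are handled pattern-wise: persons sharing an observed-cell mask
contribute through the marginal Gaussian density over their observed cells
only.  Because the density depends on the data only through each pattern's
count, mean and scatter, log-likelihoods are evaluated from precomputed
sufficient statistics — cost independent of the sample size.

Also provides the EM algorithm for the unstructured (saturated) Gaussian
model under missingness, used as the reference model for chi-square fit
statistics and for FIML regressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LOG2PI = float(np.log(2.0 * np.pi))


class SingularPatternError(np.linalg.LinAlgError):
    """Observed-cell submatrix of the implied covariance is singular."""


@dataclass
class PatternStats:
    """Sufficient statistics of one missingness pattern."""

    mask: np.ndarray      # bool, length k (observed cells)
    n: int
    mean: np.ndarray      # observed-cell sample mean
    scatter: np.ndarray   # observed-cell second central moment (divisor n)


def pattern_stats(data: np.ndarray) -> list[PatternStats]:
    """Sufficient statistics per missingness pattern of an n x k matrix.

    Rows with zero observed cells are dropped.
    """
    data = np.asarray(data, dtype=float)
    masks = ~np.isnan(data)
    groups: dict[bytes, list[int]] = {}
    for i in range(data.shape[0]):
        if masks[i].any():
            groups.setdefault(masks[i].tobytes(), []).append(i)
    stats = []
    for key, rows in groups.items():
        mask = np.frombuffer(key, dtype=bool).copy()
        block = data[np.asarray(rows)][:, mask]
        mean = block.mean(axis=0)
        centred = block - mean
        scatter = centred.T @ centred / block.shape[0]
        stats.append(PatternStats(mask, block.shape[0], mean, scatter))
    return stats


def mvn_loglik(stats: list[PatternStats], mu: np.ndarray, sigma: np.ndarray) -> float:
    """Gaussian log-likelihood over missingness patterns.

    Equals the complete-data Gaussian log-likelihood when a single all-observed
    pattern is present.  Raises :class:`SingularPatternError` when an observed
    submatrix of ``sigma`` is not positive definite.
    """
    total = 0.0
    for st in stats:
        idx = np.nonzero(st.mask)[0]
        so = sigma[np.ix_(idx, idx)]
        d = st.mean - mu[idx]
        try:
            L = np.linalg.cholesky(so)
        except np.linalg.LinAlgError as err:
            raise SingularPatternError(
                f"implied covariance singular on pattern with cells {idx.tolist()}"
            ) from err
        logdet = 2.0 * np.log(np.diag(L)).sum()
        sol_d = np.linalg.solve(L, d)
        sol_S = np.linalg.solve(L, np.linalg.solve(L, st.scatter).T)
        total += -0.5 * st.n * (
            len(idx) * LOG2PI + logdet + np.trace(sol_S) + sol_d @ sol_d
        )
    return float(total)


def saturated_loglik(stats: list[PatternStats]) -> tuple[float, np.ndarray, np.ndarray]:
    """FIML log-likelihood, mean and covariance of the saturated Gaussian model.

    Fitted by EM from the pattern sufficient statistics (complete data: one EM
    step already lands on the closed-form MLE).
    """
    mu, sigma = em_mvn(stats)
    return mvn_loglik(stats, mu, sigma), mu, sigma


def em_mvn(stats_or_data, max_iter: int = 500, tol: float = 1e-9,
           ridge: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """EM estimate of (mu, Sigma) for an unstructured MVN with missing cells.

    Accepts a data matrix or precomputed :func:`pattern_stats`.  Standard
    sweep: E-step imputes conditional means and adds conditional covariances,
    M-step re-estimates the moments.  Deterministic.
    """
    stats = stats_or_data if isinstance(stats_or_data, list) else pattern_stats(stats_or_data)
    k = len(stats[0].mask)
    n_total = sum(st.n for st in stats)
    # start from available-case moments
    mu = np.zeros(k)
    counts = np.zeros(k)
    for st in stats:
        idx = np.nonzero(st.mask)[0]
        mu[idx] += st.n * st.mean
        counts[idx] += st.n
    mu = mu / np.maximum(counts, 1)
    sigma = np.eye(k)
    for st in stats:
        idx = np.nonzero(st.mask)[0]
        d = st.mean - mu[idx]
        sigma[np.ix_(idx, idx)] += st.n * (st.scatter + np.outer(d, d))
    sigma = sigma / n_total + ridge * np.eye(k)
    sigma = 0.5 * (sigma + sigma.T)

    prev = -np.inf
    for _ in range(max_iter):
        sum_x = np.zeros(k)
        sum_xx = np.zeros((k, k))
        for st in stats:
            o = np.nonzero(st.mask)[0]
            m = np.nonzero(~st.mask)[0]
            Soo = sigma[np.ix_(o, o)]
            x_o = st.mean
            Eo = st.scatter + np.outer(x_o, x_o)  # E[y_o y_o'] (empirical)
            if m.size == 0:
                sum_x[o] += st.n * x_o
                sum_xx[np.ix_(o, o)] += st.n * Eo
                continue
            Smo = sigma[np.ix_(m, o)]
            B = np.linalg.solve(Soo, Smo.T).T          # regression of m on o
            cond_cov = sigma[np.ix_(m, m)] - B @ Smo.T
            mean_m = mu[m] + B @ (x_o - mu[o])
            # E[y_m] averaged over the pattern; cross moments via linearity
            sum_x[o] += st.n * x_o
            sum_x[m] += st.n * mean_m
            sum_xx[np.ix_(o, o)] += st.n * Eo
            cross = st.n * (np.outer(mu[m] - B @ mu[o], x_o) + B @ Eo)
            sum_xx[np.ix_(m, o)] += cross
            sum_xx[np.ix_(o, m)] += cross.T
            Emm = (
                np.outer(mu[m] - B @ mu[o], mu[m] - B @ mu[o])
                + np.outer(mu[m] - B @ mu[o], B @ x_o)
                + np.outer(B @ x_o, mu[m] - B @ mu[o])
                + B @ Eo @ B.T
            )
            sum_xx[np.ix_(m, m)] += st.n * (Emm + cond_cov)
        mu_new = sum_x / n_total
        sigma_new = sum_xx / n_total - np.outer(mu_new, mu_new)
        sigma_new = 0.5 * (sigma_new + sigma_new.T) + ridge * np.eye(k)
        mu, sigma = mu_new, sigma_new
        ll = mvn_loglik(stats, mu, sigma)
        if abs(ll - prev) < tol * (1.0 + abs(ll)):
            break
        prev = ll
    return mu, sigma


def independence_loglik(stats: list[PatternStats]) -> tuple[float, int]:
    """FIML log-likelihood and parameter count of the diagonal-covariance model.

    With a diagonal covariance the likelihood factorizes over cells, so each
    cell's MLE mean/variance come from its own observed values.
    """
    k = len(stats[0].mask)
    # accumulate per-cell observed moments
    n_c = np.zeros(k)
    s1 = np.zeros(k)
    s2 = np.zeros(k)
    for st in stats:
        idx = np.nonzero(st.mask)[0]
        n_c[idx] += st.n
        s1[idx] += st.n * st.mean
        s2[idx] += st.n * (np.diag(st.scatter) + st.mean ** 2)
    mean = s1 / np.maximum(n_c, 1)
    var = s2 / np.maximum(n_c, 1) - mean ** 2
    sigma = np.diag(np.maximum(var, 1e-12))
    return mvn_loglik(stats, mean, sigma), 2 * k
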