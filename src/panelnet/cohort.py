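"""Synthetic adolescent-cohort generator.

Emulates a three-wave longitudinal panel of 10 internalizing/externalizing
symptom scales (ages ~11/13/16, N≈2,170) with

* a between-person (random intercept) covariance — stable trait differences,
* lag-1 within-person dynamics ``w_{t+1} = B w_t + zeta_t`` with innovation
  precision ``K_zeta`` (the contemporaneous network),
* linear + quadratic group-level time trends fitted through the published
  wave means of each scale,
* monotone attrition (96% / 76% participation at waves 2/3), optionally
  missing-at-random on baseline symptom level, and
* weak executive-functioning covariates measured at wave 1 only.

The generative model is the random-intercept form a panel graphical VAR
assumes: ``y_it = mu + b1*t + b2*t^2 + s * (b_i + w_it)`` with
``b_i ~ N(0, Sigma_B)`` and the within-process started from its stationary
distribution.  Everything is deterministic given the cohort seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_discrete_lyapunov
from scipy.optimize import brentq
from scipy.special import expit

from .panel_data import PanelDataset, VariableMeta

# Published three-wave descriptives (mean per wave, wave-1 SD) for the ten
# symptom scales; used by the trails_like template to place means, trends and
# observation scales of realistic magnitude.
TRAILS_DESCRIPTIVES: dict[str, tuple[tuple[float, float, float], float, str]] = {
    "Depr":     ((0.29, 0.27, 0.30), 0.25, "internalizing"),
    "Somat":    ((0.46, 0.32, 0.26), 0.33, "internalizing"),
    "GenAnx":   ((0.66, 0.48, 0.52), 0.45, "internalizing"),
    "SocPhob":  ((0.78, 0.68, 0.73), 0.43, "internalizing"),
    "SepAnx":   ((0.37, 0.24, 0.22), 0.35, "internalizing"),
    "Panic":    ((0.43, 0.30, 0.28), 0.36, "internalizing"),
    "OCD":      ((0.60, 0.34, 0.29), 0.44, "internalizing"),
    "AttHyper": ((0.59, 0.67, 0.68), 0.36, "externalizing"),
    "Oppos":    ((0.45, 0.46, 0.46), 0.35, "externalizing"),
    "Conduct":  ((0.23, 0.23, 0.24), 0.20, "externalizing"),
}

EF_MEASURES = (
    "fluct_tempo", "fluct_errors", "resinhib_rt", "resinhib_err",
    "cogflex_rt", "cogflex_err", "wm_rt", "wm_err",
)

#: Standardized latent-propensity effects on each EF measure.  The emulated
#: regime is "weak": the only clearly nonzero effect sits on fluctuation in
#: tempo (sustained attention), at the upper edge of the small-effect band.
DEFAULT_EF_BETAS: dict[str, float] = {
    "fluct_tempo": 0.07, "fluct_errors": 0.03, "resinhib_rt": 0.05,
    "resinhib_err": 0.02, "cogflex_rt": 0.02, "cogflex_err": 0.01,
    "wm_rt": 0.02, "wm_err": 0.0,
}

FEMALE_FRACTION = 0.5092  # wave-1 female share of the emulated cohort


class GroundTruthError(ValueError):
    pass


@dataclass
class GroundTruth:
    """Generative parameters of the cohort on the standardized latent scale.

    ``B[k, j]`` is the lag-1 effect of node j at wave t on node k at wave
    t+1 (rows = targets).  ``K_zeta`` is the within-person innovation
    precision (its inverse is the innovation covariance); ``Sigma_B`` the
    between-person trait covariance (positive semi-definite; exactly zero is
    the no-trait degenerate case).  ``mu + trend_lin*t + trend_quad*t^2``
    is the group-level mean path on the observed scale and ``scale`` maps the
    unit-variance latent process to observed units.
    """

    B: np.ndarray
    K_zeta: np.ndarray
    Sigma_B: np.ndarray
    trend_lin: np.ndarray
    trend_quad: np.ndarray
    mu: np.ndarray
    scale: np.ndarray | None = None
    variables: list[VariableMeta] = field(default_factory=list)

    def __post_init__(self):
        self.B = np.asarray(self.B, dtype=float)
        self.K_zeta = np.asarray(self.K_zeta, dtype=float)
        self.Sigma_B = np.asarray(self.Sigma_B, dtype=float)
        p = self.B.shape[0]
        for name in ("trend_lin", "trend_quad", "mu"):
            setattr(self, name, np.broadcast_to(
                np.asarray(getattr(self, name), dtype=float), (p,)).copy())
        if self.scale is None:
            self.scale = np.ones(p)
        self.scale = np.broadcast_to(np.asarray(self.scale, dtype=float), (p,)).copy()
        if not self.variables:
            self.variables = [VariableMeta(f"V{j + 1}") for j in range(p)]
        if self.spectral_radius >= 1.0:
            raise GroundTruthError(
                f"temporal matrix unstable (spectral radius "
                f"{self.spectral_radius:.3f} >= 1)")
        for name, M in (("K_zeta", self.K_zeta),):
            if np.linalg.eigvalsh(0.5 * (M + M.T)).min() <= 0:
                raise GroundTruthError(f"{name} must be positive definite")
        if np.linalg.eigvalsh(0.5 * (self.Sigma_B + self.Sigma_B.T)).min() < -1e-10:
            raise GroundTruthError("Sigma_B must be positive semi-definite")

    @property
    def p(self) -> int:
        return self.B.shape[0]

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.B))))

    def stationary_within_cov(self) -> np.ndarray:
        """Sigma_W solving Sigma_W = B Sigma_W B' + K_zeta^{-1}."""
        Q = np.linalg.inv(self.K_zeta)
        S = solve_discrete_lyapunov(self.B, Q)
        return 0.5 * (S + S.T)

    def contemporaneous_partials(self) -> np.ndarray:
        return _precision_to_partials(self.K_zeta)

    def to_dict(self) -> dict:
        return {
            "B": self.B.tolist(), "K_zeta": self.K_zeta.tolist(),
            "Sigma_B": self.Sigma_B.tolist(),
            "trend_lin": self.trend_lin.tolist(),
            "trend_quad": self.trend_quad.tolist(), "mu": self.mu.tolist(),
            "scale": self.scale.tolist(),
            "variables": [(v.name, v.community) for v in self.variables],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            B=d["B"], K_zeta=d["K_zeta"], Sigma_B=d["Sigma_B"],
            trend_lin=d["trend_lin"], trend_quad=d["trend_quad"], mu=d["mu"],
            scale=d.get("scale"),
            variables=[VariableMeta(n, c) for n, c in d.get("variables", [])],
        )


@dataclass
class CohortSpec:
    """Design knobs of the synthetic cohort (defaults emulate the study design)."""

    n_persons: int = 2170
    n_waves: int = 3
    p: int = 10
    retention: tuple[float, ...] = (1.0, 0.96, 0.76)
    attrition_mechanism: str = "MAR_baseline"
    mar_strength: float = 0.3
    ef_betas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EF_BETAS))
    bounded_scale: bool = False
    seed: int = 0

    def __post_init__(self):
        r = tuple(float(x) for x in self.retention)
        if len(r) != self.n_waves:
            raise GroundTruthError("retention must have one entry per wave")
        if r[0] != 1.0 or any(b > a for a, b in zip(r, r[1:])):
            raise GroundTruthError(
                "retention must start at 1 and be non-increasing")
        if self.attrition_mechanism not in ("MCAR", "MAR_baseline"):
            raise GroundTruthError("attrition_mechanism must be MCAR or MAR_baseline")
        self.retention = r


def _precision_to_partials(K: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(K))
    P = -K / np.outer(d, d)
    np.fill_diagonal(P, 0.0)
    return P


def _partials_to_precision(P: np.ndarray, min_eig: float = 1e-3) -> np.ndarray:
    """Unit-diagonal precision with prescribed partial correlations."""
    K = -np.asarray(P, dtype=float).copy()
    np.fill_diagonal(K, 1.0)
    if np.linalg.eigvalsh(K).min() < min_eig:
        raise GroundTruthError(
            "requested partial-correlation pattern is not positive definite; "
            "use smaller partial correlations")
    return K


def _rng(spec: CohortSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), stream]))


def make_ground_truth(spec: CohortSpec, template: str = "trails_like") -> GroundTruth:
    """Construct generative parameters for a cohort.

    ``trails_like`` places two symptom communities (7 internalizing-like and
    3 externalizing-like nodes at p=10) with positive within-community
    contemporaneous partials, a depressive-problems hub with the highest
    temporal out-strength, and reciprocal lag-1 pairs (panic–somatic,
    ADHD–oppositional feedback loops).  ``random_sparse`` draws a seeded
    sparse stable system for recovery experiments.
    """
    p = spec.p
    if p < 2:
        raise GroundTruthError("need p >= 2")
    rng = _rng(spec, 0)
    if template == "trails_like":
        return _trails_like_truth(spec)
    if template != "random_sparse":
        raise GroundTruthError(f"unknown template {template!r}")
    # random sparse stable temporal matrix
    B = np.diag(rng.uniform(0.1, 0.35, size=p))
    n_edges = max(1, int(0.15 * p * (p - 1)))
    offdiag = [(i, j) for i in range(p) for j in range(p) if i != j]
    for idx in rng.choice(len(offdiag), size=n_edges, replace=False):
        i, j = offdiag[idx]
        B[i, j] = rng.uniform(0.1, 0.3) * rng.choice([-1.0, 1.0])
    rho = np.max(np.abs(np.linalg.eigvals(B)))
    if rho >= 0.6:
        B *= 0.6 / rho
    # sparse partial-correlation structure, shrunk until PD
    P = np.zeros((p, p))
    for idx in rng.choice(len(offdiag), size=n_edges, replace=False):
        i, j = offdiag[idx]
        v = rng.uniform(0.1, 0.25) * rng.choice([-1.0, 1.0])
        P[i, j] = P[j, i] = v
    for _ in range(20):
        try:
            K = _partials_to_precision(P)
            break
        except GroundTruthError:
            P *= 0.8
    else:  # pragma: no cover - shrinkage always terminates above
        K = np.eye(p)
    # between-person network: trait covariance in symptom panels is strong,
    # and the between structure carries the least information per person, so
    # its partials are denser and larger than the within ones
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    n_edges_b = min(len(pairs), max(2, round(0.4 * len(pairs))))
    PB = np.zeros((p, p))
    for idx in rng.choice(len(pairs), size=n_edges_b, replace=False):
        i, j = pairs[idx]
        v = rng.uniform(0.25, 0.4) * rng.choice([-1.0, 1.0])
        PB[i, j] = PB[j, i] = v
    for _ in range(20):
        try:
            KB = _partials_to_precision(PB)
            break
        except GroundTruthError:
            PB *= 0.8
    SB = np.linalg.inv(KB)
    d = 1.0 / np.sqrt(np.diag(SB))
    Sigma_B = 0.7 * (SB * np.outer(d, d))  # trait share ~ half the variance
    return GroundTruth(B=B, K_zeta=K, Sigma_B=Sigma_B,
                       trend_lin=np.zeros(p), trend_quad=np.zeros(p),
                       mu=np.zeros(p))


def _trails_like_truth(spec: CohortSpec) -> GroundTruth:
    p = spec.p
    names = list(TRAILS_DESCRIPTIVES)
    if p == 10:
        variables = [VariableMeta(n, TRAILS_DESCRIPTIVES[n][2]) for n in names]
    else:
        n_ext = max(1, round(0.3 * p))
        variables = [VariableMeta(f"Int{j + 1}", "internalizing")
                     for j in range(p - n_ext)]
        variables += [VariableMeta(f"Ext{j + 1}", "externalizing")
                      for j in range(n_ext)]
    comm = np.array([v.community for v in variables])
    internal = np.nonzero(comm == "internalizing")[0]
    external = np.nonzero(comm == "externalizing")[0]
    hub = internal[0]  # depressive problems at p=10

    # temporal matrix: AR diagonal, hub spraying onto other internalizing
    # nodes, and two reciprocal pairs (feedback loops)
    B = np.eye(p) * 0.22
    for k in internal:
        if k != hub:
            B[k, hub] = 0.15
    if len(internal) >= 3:
        a, b = internal[1], internal[-2]  # Somat, Panic at p=10
        B[a, b] = B[b, a] = 0.12
    if len(external) >= 2:
        a, b = external[0], external[1]  # AttHyper, Oppos at p=10
        B[a, b] = B[b, a] = 0.12
    rho = np.max(np.abs(np.linalg.eigvals(B)))
    if rho >= 0.9:  # pragma: no cover - template values are well inside
        B *= 0.85 / rho
    # guarantee the hub is the strict out-strength maximum
    out = np.abs(B).sum(axis=0) - np.abs(np.diag(B))
    assert out[hub] == out.max()

    # contemporaneous partials: positive within communities, a depressive
    # bridge to the externalizing side, one negative cross edge
    P = np.zeros((p, p))
    for grp, val in ((internal, 0.14), (external, 0.20)):
        for ii, i in enumerate(grp):
            for j in grp[ii + 1:]:
                P[i, j] = P[j, i] = val
    if len(external) >= 1:
        P[hub, external[0]] = P[external[0], hub] = 0.10
    if len(external) >= 3 and len(internal) >= 4:
        soc = internal[3]  # SocPhob at p=10
        P[soc, external[2]] = P[external[2], soc] = -0.08
    K_zeta = _partials_to_precision(P)

    # between-person: community-structured trait covariance, ICC ~ 0.4
    R = np.full((p, p), 0.15)
    for grp in (internal, external):
        R[np.ix_(grp, grp)] = 0.45
    np.fill_diagonal(R, 1.0)
    Sigma_B = 0.4 * R

    # rescale innovations so the stationary within-variance averages 0.6
    Q = np.linalg.inv(K_zeta)
    S = solve_discrete_lyapunov(B, Q)
    K_zeta = K_zeta * (np.diag(S).mean() / 0.6)

    # observed-scale means/trends/SDs from the published descriptives
    if p == 10:
        means = np.array([TRAILS_DESCRIPTIVES[n][0] for n in names])
        sds = np.array([TRAILS_DESCRIPTIVES[n][1] for n in names])
    else:
        means = np.tile(np.array([[0.4, 0.35, 0.33]]), (p, 1))
        sds = np.full(p, 0.3)
    # exact quadratic through the three wave means at t = 1, 2, 3
    D = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 4.0], [1.0, 3.0, 9.0]])
    coef = np.linalg.solve(D, means.T).T  # rows: (mu, lin, quad)
    return GroundTruth(B=B, K_zeta=K_zeta, Sigma_B=Sigma_B,
                       trend_lin=coef[:, 1], trend_quad=coef[:, 2],
                       mu=coef[:, 0], scale=sds, variables=variables)


def _psd_factor(S: np.ndarray) -> np.ndarray:
    """Matrix square root valid for PSD (possibly singular) covariances."""
    w, V = np.linalg.eigh(0.5 * (S + S.T))
    return V * np.sqrt(np.clip(w, 0.0, None))


def simulate_panel(truth: GroundTruth, spec: CohortSpec) -> PanelDataset:
    """Draw a complete panel from the generative model.

    The returned dataset carries the simulated random intercepts in the
    ``random_intercepts`` attribute (n x p, latent scale) so that downstream
    covariate simulation can condition on the person-level trait.
    """
    n, T, p = spec.n_persons, spec.n_waves, truth.p
    rng = _rng(spec, 1)
    Sigma_W = truth.stationary_within_cov()
    Q = np.linalg.inv(truth.K_zeta)
    Lb = _psd_factor(truth.Sigma_B)
    Lw = _psd_factor(Sigma_W)
    Lq = _psd_factor(Q)
    b = rng.standard_normal((n, p)) @ Lb.T
    w = np.empty((n, T, p))
    w[:, 0, :] = rng.standard_normal((n, p)) @ Lw.T
    for t in range(1, T):
        w[:, t, :] = w[:, t - 1, :] @ truth.B.T + rng.standard_normal((n, p)) @ Lq.T
    t_codes = np.arange(1, T + 1, dtype=float)
    trend = (truth.mu[None, :] + np.outer(t_codes, truth.trend_lin)
             + np.outer(t_codes ** 2, truth.trend_quad))  # T x p
    y = trend[None, :, :] + truth.scale[None, None, :] * (b[:, None, :] + w)
    if spec.bounded_scale:
        y = np.clip(y, 0.0, 2.0)
    panel = PanelDataset(
        values=y,
        person_ids=np.arange(1, n + 1),
        wave_times=t_codes,
        variables=list(truth.variables),
    )
    panel.random_intercepts = b
    return panel


def apply_attrition(panel: PanelDataset, spec: CohortSpec) -> PanelDataset:
    """Impose monotone wave-level dropout per the retention schedule.

    Under ``MAR_baseline`` the per-person dropout hazard increases with the
    standardized baseline (wave-1) mean symptom score via a logistic link
    with slope ``mar_strength``; the intercept is solved so the realized
    participation matches the target fractions in expectation.  Once a person
    drops out, all later waves are missing.
    """
    if all(r == 1.0 for r in spec.retention):
        out = panel.copy_with(panel.values)
        if hasattr(panel, "random_intercepts"):
            out.random_intercepts = panel.random_intercepts
        return out
    rng = _rng(spec, 2)
    n, T, p = panel.values.shape
    values = panel.values.copy()
    base = np.nanmean(panel.values[:, 0, :], axis=1)
    z = (base - np.nanmean(base)) / (np.nanstd(base) if np.nanstd(base) > 0 else 1.0)
    present = np.ones(n, dtype=bool)
    for t in range(1, T):
        cond = spec.retention[t] / spec.retention[t - 1]
        drop_target = 1.0 - cond
        zi = z[present]
        if spec.attrition_mechanism == "MCAR" or spec.mar_strength == 0.0:
            p_drop = np.full(zi.shape, drop_target)
        elif drop_target <= 0.0:
            p_drop = np.zeros(zi.shape)
        else:
            def gap(c):
                return expit(c + spec.mar_strength * zi).mean() - drop_target
            c = brentq(gap, -30.0, 30.0)
            p_drop = expit(c + spec.mar_strength * zi)
        drops = rng.random(zi.shape) < p_drop
        idx = np.nonzero(present)[0][drops]
        values[idx, t:, :] = np.nan
        present[idx] = False
    out = panel.copy_with(values)
    if hasattr(panel, "random_intercepts"):
        out.random_intercepts = panel.random_intercepts
    return out


def simulate_ef(panel: PanelDataset, truth: GroundTruth, spec: CohortSpec
                ) -> pd.DataFrame:
    """Simulate wave-1 executive-functioning measures and sex.

    Each EF measure is ``beta * propensity + sqrt(1 - beta^2) * noise`` with
    the propensity the standardized person-level trait (mean random
    intercept); measures have unit variance and higher = worse performance.
    Sex is Bernoulli with the cohort's female fraction (1 = female).
    """
    rng = _rng(spec, 3)
    n = panel.n_persons
    b = getattr(panel, "random_intercepts", None)
    if b is not None:
        prop = b.mean(axis=1)
    else:  # observed-data fallback: standardized wave-1 mean symptom level
        prop = np.nanmean(panel.values[:, 0, :], axis=1)
    sd = prop.std()
    prop = (prop - prop.mean()) / sd if sd > 0 else np.zeros(n)
    out = {"person_id": panel.person_ids}
    for m in EF_MEASURES:
        beta = float(spec.ef_betas.get(m, 0.0))
        noise = rng.standard_normal(n)
        out[m] = beta * prop + np.sqrt(max(0.0, 1.0 - beta ** 2)) * noise
    out["sex"] = (rng.random(n) < FEMALE_FRACTION).astype(int)
    return pd.DataFrame(out)


def simulate_cohort(spec: CohortSpec, template: str = "trails_like"
                    ) -> tuple[GroundTruth, PanelDataset, pd.DataFrame]:
    """Convenience wrapper: truth -> complete panel -> attrition -> EF table."""
    truth = make_ground_truth(spec, template)
    panel = simulate_panel(truth, spec)
    panel = apply_attrition(panel, spec)
    ef = simulate_ef(panel, truth, spec)
    return truth, panel, ef
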