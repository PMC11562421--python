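"""Executive-functioning scores and hierarchical FIML regressions.

Derives the eight task measures used as wave-1 covariates — fluctuation in
tempo and error percentage from a sustained-attention task, response
inhibition and cognitive flexibility difference scores from a set-shifting
task, and working-memory load difference scores — applies the |z| >= 4
between-person outlier rule, and fits the two-step hierarchical regressions
(previous-wave broadband symptoms + sex, then + all EF measures) under
full-information maximum likelihood.

Higher values mean worse performance on every EF measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fiml import em_mvn, pattern_stats
from .panel_data import PanelDataset
from scipy.stats import norm

EF_COLUMNS = ("fluct_tempo", "fluct_errors", "resinhib_rt", "resinhib_err",
              "cogflex_rt", "cogflex_err", "wm_rt", "wm_err")

#: Step-2 predictor order as the hierarchical models list them.
MODEL2_EF_ORDER = ("wm_rt", "wm_err", "resinhib_err", "resinhib_rt",
                   "fluct_tempo", "fluct_errors", "cogflex_rt", "cogflex_err")


class EfError(ValueError):
    pass


# ---------------------------------------------------------------------------
# score derivation
# ---------------------------------------------------------------------------

def derive_ef_scores(dots: pd.DataFrame, shifting: pd.DataFrame,
                     memory: pd.DataFrame) -> pd.DataFrame:
    """Per-person EF measures from task summaries.

    ``dots``: one row per (person_id, series) with ``mean_rt`` (ms) and
    ``pct_errors``; fluctuation in tempo is the sample SD (n-1) of the
    per-series mean RTs, fluctuation errors the mean error percentage.
    ``shifting``/``memory``: one row per (person_id, part) with ``mean_rt``
    and ``pct_errors``; response inhibition is part 2 - part 1, cognitive
    flexibility and working memory are part 3 - part 1.
    """
    out = {}
    series_counts = dots.groupby("person_id")["mean_rt"].count()
    if (series_counts < 2).any():
        bad = series_counts[series_counts < 2].index[0]
        raise EfError(f"person {bad!r} has fewer than 2 series; SD undefined")
    g = dots.groupby("person_id")
    out["fluct_tempo"] = g["mean_rt"].std(ddof=1)
    out["fluct_errors"] = g["pct_errors"].mean()

    def part_diff(df, hi, name_rt, name_err):
        wide_rt = df.pivot_table(index="person_id", columns="part",
                                 values="mean_rt", aggfunc="first")
        wide_er = df.pivot_table(index="person_id", columns="part",
                                 values="pct_errors", aggfunc="first")
        out[name_rt] = wide_rt[hi] - wide_rt[1]
        out[name_err] = wide_er[hi] - wide_er[1]

    part_diff(shifting, 2, "resinhib_rt", "resinhib_err")
    part_diff(shifting, 3, "cogflex_rt", "cogflex_err")
    part_diff(memory, 3, "wm_rt", "wm_err")
    df = pd.DataFrame(out)
    df.index.name = "person_id"
    return df.reset_index()


def zscore_outlier_filter(values, threshold: float = 4.0
                          ) -> tuple[np.ndarray, int]:
    """Set values with between-person |z| >= threshold to missing (one pass).

    z-scores use the sample mean and SD (n-1) of the non-missing values.
    Returns the filtered copy and the number of values removed; a
    zero-variance input is returned unchanged with a warning.
    """
    arr = np.asarray(values, dtype=float).copy()
    obs = ~np.isnan(arr)
    if obs.sum() < 3:
        raise EfError("need at least 3 non-missing values")
    sd = arr[obs].std(ddof=1)
    if sd == 0:
        warnings.warn("zero variance: outlier filter is a no-op")
        return arr, 0
    z = (arr - arr[obs].mean()) / sd
    with np.errstate(invalid="ignore"):
        out_mask = obs & (np.abs(z) >= threshold)
    arr[out_mask] = np.nan
    return arr, int(out_mask.sum())


def filter_ef_table(ef: pd.DataFrame, threshold: float = 4.0) -> pd.DataFrame:
    """Apply the outlier rule to every EF measure column of a table."""
    out = ef.copy()
    for col in EF_COLUMNS:
        if col in out.columns:
            out[col], _ = zscore_outlier_filter(out[col].to_numpy(), threshold)
    return out


# ---------------------------------------------------------------------------
# FIML regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    terms: list[str]
    coefficients: pd.DataFrame   # term, estimate, std_estimate, se, z, p
    r2: float
    n: int
    intercept: float
    mu: np.ndarray
    sigma: np.ndarray


def fit_fiml_regression(data: pd.DataFrame, outcome: str,
                        predictors: list[str],
                        standardize_terms: list[str] | None = None
                        ) -> RegressionResult:
    """Linear regression under a joint-Gaussian FIML model.

    The joint distribution of (outcome, predictors) is estimated by EM over
    missingness patterns; slopes, R^2 and asymptotic standard errors are
    derived from the implied covariance.  On complete data this equals the
    least-squares solution.  ``std_estimate`` rescales slopes of the listed
    terms (default: all) to the standardized metric.
    """
    cols = [outcome] + list(predictors)
    M = data[cols].to_numpy(dtype=float)
    M = M[~np.isnan(M).all(axis=1)]
    n = M.shape[0]
    if n < len(cols) + 2:
        raise EfError("too few observations for the requested model")
    stats = pattern_stats(M)
    mu, sigma = em_mvn(stats)
    syy = sigma[0, 0]
    sxy = sigma[1:, 0]
    Sxx = sigma[1:, 1:]
    cond = np.linalg.cond(Sxx)
    if cond > 1e10:
        raise EfError(f"predictor covariance is singular (cond={cond:.2g})")
    beta = np.linalg.solve(Sxx, sxy)
    r2 = float(sxy @ beta / syy)
    s2_res = max(syy - sxy @ beta, 1e-12)
    cov_beta = s2_res * np.linalg.inv(Sxx) / n
    se = np.sqrt(np.diag(cov_beta))
    z = beta / se
    pvals = 2 * norm.sf(np.abs(z))
    sd_x = np.sqrt(np.diag(Sxx))
    sd_y = np.sqrt(syy)
    std_set = set(standardize_terms if standardize_terms is not None
                  else predictors)
    std_beta = np.array([
        beta[j] * sd_x[j] / sd_y if predictors[j] in std_set else beta[j]
        for j in range(len(predictors))
    ])
    table = pd.DataFrame({
        "term": predictors, "estimate": beta, "std_estimate": std_beta,
        "se": se, "z": z, "p": pvals,
    })
    return RegressionResult(terms=list(predictors), coefficients=table,
                            r2=r2, n=n,
                            intercept=float(mu[0] - mu[1:] @ beta),
                            mu=mu, sigma=sigma)


# ---------------------------------------------------------------------------
# hierarchical comparison
# ---------------------------------------------------------------------------

@dataclass
class HierarchicalComparison:
    target: str
    wave: int
    step1: RegressionResult
    step2: RegressionResult
    delta_r2: float
    n_effective: int


def broadband_aggregates(panel: PanelDataset) -> pd.DataFrame:
    """Per-person broadband internalizing/externalizing means per wave."""
    comm = np.array([v.community for v in panel.variables])
    out = {"person_id": panel.person_ids}
    for label in ("internalizing", "externalizing"):
        idx = np.nonzero(comm == label)[0]
        if idx.size == 0:
            raise EfError(f"no variables in community {label!r}")
        for t in range(panel.n_waves):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out[f"{label}_w{t + 1}"] = np.nanmean(
                    panel.values[:, t, idx], axis=1)
    return pd.DataFrame(out)


def hierarchical_compare(symptoms: pd.DataFrame, ef: pd.DataFrame,
                         target: str = "internalizing", wave: int = 2,
                         sex_column: str = "sex") -> HierarchicalComparison:
    """Two-step hierarchical regression of a broadband symptom outcome.

    Step 1 regresses the wave-``wave`` aggregate on sex and both previous-wave
    aggregates; step 2 adds all eight EF measures in the published predictor
    order.  Continuous predictors are reported in both raw and standardized
    metrics; sex stays raw.
    """
    if target not in ("internalizing", "externalizing"):
        raise EfError("target must be internalizing or externalizing")
    if wave < 2:
        raise EfError("outcome wave must have a previous wave")
    missing = [c for c in MODEL2_EF_ORDER if c not in ef.columns]
    if missing:
        raise EfError(f"EF table lacks measures: {missing}")
    data = symptoms.merge(ef, on="person_id", how="inner")
    outcome = f"{target}_w{wave}"
    prev = wave - 1
    step1_terms = [sex_column, f"internalizing_w{prev}", f"externalizing_w{prev}"]
    step2_terms = step1_terms + list(MODEL2_EF_ORDER)
    continuous = [t for t in step2_terms if t != sex_column]
    step1 = fit_fiml_regression(data, outcome, step1_terms,
                                standardize_terms=[t for t in step1_terms
                                                   if t != sex_column])
    step2 = fit_fiml_regression(data, outcome, step2_terms,
                                standardize_terms=continuous)
    return HierarchicalComparison(target=target, wave=wave, step1=step1,
                                  step2=step2,
                                  delta_r2=step2.r2 - step1.r2,
                                  n_effective=step2.n)
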