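"""Panel data containers, scale scoring and GVAR preprocessing.

The central container is :class:`PanelDataset`: a persons x waves x variables
array of continuous scale scores with missing values encoded as NaN.  Waves
are repeated assessments of the same variables (here: symptom scales) at
increasing time codes.  The module also provides

* questionnaire scale scoring (mean of items with a minimum-coverage rule),
* the detrend-and-standardize preprocessing required before fitting a
  stationary graphical VAR to few-wave panel data,
* complete-case extraction for consecutive wave pairs (cross-lagged
  regressions need complete predictor/outcome rows), and
* missingness-pattern grouping (pattern-wise full-information likelihood).

Long and wide CSV readers/writers round-trip the container.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COMMUNITIES = ("internalizing", "externalizing", "attention", "other")


class PanelDataError(ValueError):
    """Invalid panel data or scale input."""


class InsufficientDataError(PanelDataError):
    """Too few complete cases for the requested operation."""


class DegenerateVariableError(PanelDataError):
    """A variable has (near-)zero residual variance."""


@dataclass(frozen=True)
class VariableMeta:
    """Metadata for one node: short label, symptom community, instrument."""

    name: str
    community: str = "other"
    instrument: str = ""

    def __post_init__(self):
        if self.community not in COMMUNITIES:
            raise PanelDataError(
                f"community {self.community!r} not one of {COMMUNITIES}"
            )


@dataclass(frozen=True)
class ScaleDefinition:
    """How to score a questionnaire scale from its items.

    ``min_coverage`` is the fraction of non-missing items required before a
    mean score is computed; below it the score is missing.
    """

    item_columns: tuple[str, ...]
    item_min: float = 0.0
    item_max: float = 2.0
    min_coverage: float = 0.75

    def __post_init__(self):
        if not self.item_min < self.item_max:
            raise PanelDataError("item_min must be < item_max")
        if not 0.0 < self.min_coverage <= 1.0:
            raise PanelDataError("min_coverage must be in (0, 1]")


@dataclass
class PanelDataset:
    """Persons x waves x variables array of continuous scores.

    Missing cells are NaN.  ``wave_times`` are the numeric time codes used by
    the detrending regression (wave index 1..T by default; mean ages are an
    alternative).
    """

    values: np.ndarray
    person_ids: np.ndarray
    wave_times: np.ndarray
    variables: list[VariableMeta] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.person_ids = np.asarray(self.person_ids)
        self.wave_times = np.asarray(self.wave_times, dtype=float)
        if self.values.ndim != 3:
            raise PanelDataError("values must be 3-dimensional (n, T, p)")
        n, T, p = self.values.shape
        if not self.variables:
            self.variables = [VariableMeta(f"V{j + 1}") for j in range(p)]
        if len(self.person_ids) != n:
            raise PanelDataError("person_ids length mismatch")
        if len(self.wave_times) != T:
            raise PanelDataError("wave_times length mismatch")
        if len(self.variables) != p:
            raise PanelDataError("variables length mismatch")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise PanelDataError("variable names must be unique")
        if np.any(np.diff(self.wave_times) <= 0):
            raise PanelDataError("wave_times must be strictly increasing")
        if n and np.all(np.isnan(self.values[:, 0, :]), axis=1).any():
            bad = self.person_ids[np.all(np.isnan(self.values[:, 0, :]), axis=1)]
            raise PanelDataError(
                f"persons with all-missing wave-1 data violate the entry "
                f"criterion: {list(bad[:5])}"
            )

    # -- convenience -------------------------------------------------------
    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_waves(self) -> int:
        return self.values.shape[1]

    @property
    def n_variables(self) -> int:
        return self.values.shape[2]

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def communities(self) -> dict[str, str]:
        return {v.name: v.community for v in self.variables}

    def stacked(self) -> np.ndarray:
        """n x (T*p) wave-major matrix: cell (t, v) at column t*p + v."""
        n, T, p = self.values.shape
        return self.values.reshape(n, T * p)

    def copy_with(self, values: np.ndarray) -> "PanelDataset":
        return replace(self, values=np.array(values, dtype=float))

    # -- I/O ---------------------------------------------------------------
    def to_long(self) -> pd.DataFrame:
        n, T, p = self.values.shape
        rows = {
            "person_id": np.repeat(self.person_ids, T * p),
            "wave": np.tile(np.repeat(np.arange(1, T + 1), p), n),
            "variable": np.tile(self.variable_names, n * T),
            "value": self.values.ravel(),
        }
        return pd.DataFrame(rows)

    def to_wide(self) -> pd.DataFrame:
        n, T, p = self.values.shape
        cols = {"person_id": self.person_ids}
        for t in range(T):
            for j, name in enumerate(self.variable_names):
                cols[f"{name}_w{t + 1}"] = self.values[:, t, j]
        return pd.DataFrame(cols)

    def write_csv(self, path, format: str = "long") -> None:
        df = self.to_long() if format == "long" else self.to_wide()
        df.to_csv(path, index=False)


def read_long_csv(path_or_df, variables: list[VariableMeta] | None = None,
                  wave_times: np.ndarray | None = None) -> PanelDataset:
    """Build a PanelDataset from a long table (person_id, wave, variable, value)."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    waves = np.sort(df["wave"].unique())
    if variables is not None:
        var_names = [v.name for v in variables]
    else:
        var_names = list(pd.unique(df["variable"]))
        variables = [VariableMeta(v) for v in var_names]
    persons = list(pd.unique(df["person_id"]))
    pivot = df.pivot_table(index="person_id", columns=["wave", "variable"],
                           values="value", dropna=False, aggfunc="first")
    pivot = pivot.reindex(persons)
    n, T, p = len(persons), len(waves), len(var_names)
    values = np.full((n, T, p), np.nan)
    for ti, w in enumerate(waves):
        for j, v in enumerate(var_names):
            if (w, v) in pivot.columns:
                values[:, ti, j] = pivot[(w, v)].to_numpy()
    if wave_times is None:
        wave_times = waves.astype(float)
    return PanelDataset(values, np.asarray(persons), wave_times, variables)


def read_wide_csv(path_or_df, variables: list[VariableMeta] | None = None,
                  wave_times: np.ndarray | None = None) -> PanelDataset:
    """Build a PanelDataset from a wide table (person_id, <var>_w<t> columns)."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    cells = []
    for c in df.columns:
        if c == "person_id":
            continue
        name, _, w = c.rpartition("_w")
        cells.append((name, int(w)))
    var_names = list(dict.fromkeys(name for name, _ in cells))
    waves = sorted({w for _, w in cells})
    if variables is None:
        variables = [VariableMeta(v) for v in var_names]
    n, T, p = len(df), len(waves), len(var_names)
    values = np.full((n, T, p), np.nan)
    for ti, w in enumerate(waves):
        for j, v in enumerate(var_names):
            col = f"{v}_w{w}"
            if col in df.columns:
                values[:, ti, j] = df[col].to_numpy(dtype=float)
    if wave_times is None:
        wave_times = np.asarray(waves, dtype=float)
    return PanelDataset(values, df["person_id"].to_numpy(), wave_times, variables)


# -- scale scoring ---------------------------------------------------------

def score_scale(items, definition: ScaleDefinition) -> np.ndarray:
    """Mean-score a scale from a persons x items matrix.

    Items outside ``[item_min, item_max]`` raise a validation error naming the
    offending person (row) and item (column).  A person's score is the mean of
    their non-missing items when the observed fraction reaches
    ``min_coverage``, otherwise NaN.
    """
    if isinstance(items, pd.DataFrame):
        arr = items[list(definition.item_columns)].to_numpy(dtype=float)
        index = list(items.index)
    else:
        arr = np.asarray(items, dtype=float)
        index = list(range(arr.shape[0]))
    if arr.ndim != 2:
        raise PanelDataError("items must be 2-dimensional (persons x items)")
    with np.errstate(invalid="ignore"):
        bad = (arr < definition.item_min) | (arr > definition.item_max)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise PanelDataError(
            f"item value {arr[i, j]!r} out of bounds "
            f"[{definition.item_min}, {definition.item_max}] for person "
            f"{index[i]!r}, item {definition.item_columns[j] if definition.item_columns else j!r}"
        )
    observed = ~np.isnan(arr)
    coverage = observed.mean(axis=1)
    score = np.full(arr.shape[0], np.nan)
    any_obs = observed.any(axis=1)
    score[any_obs] = np.nansum(arr[any_obs], axis=1) / observed[any_obs].sum(axis=1)
    score[coverage < definition.min_coverage] = np.nan
    return score


def load_variable_config(path_or_dict) -> tuple[list[VariableMeta], dict[str, ScaleDefinition]]:
    """Variable metadata and scale definitions from a YAML/JSON config.

    Expected layout::

        variables:
          - {name: Depr, community: internalizing, instrument: YSR}
        scales:
          Depr:
            items: [ysr_q1, ysr_q2]
            item_min: 0
            item_max: 2
            min_coverage: 0.75
    """
    import yaml

    if isinstance(path_or_dict, dict):
        cfg = path_or_dict
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh) or {}
    variables = [
        VariableMeta(v["name"], v.get("community", "other"),
                     v.get("instrument", ""))
        for v in cfg.get("variables", [])
    ]
    scales = {
        name: ScaleDefinition(
            tuple(s["items"]),
            item_min=float(s.get("item_min", 0.0)),
            item_max=float(s.get("item_max", 2.0)),
            min_coverage=float(s.get("min_coverage", 0.75)))
        for name, s in (cfg.get("scales") or {}).items()
    }
    return variables, scales


# -- preprocessing ---------------------------------------------------------

def detrend_and_standardize(panel: PanelDataset, per_wave: bool = False,
                            tol: float = 1e-12) -> PanelDataset:
    """Remove pooled linear+quadratic time trends and scale to pooled unit SD.

    For each variable, one regression of score on (1, t, t^2) is fitted over
    all non-missing person-wave cells (t = wave time code); residuals are then
    divided by their pooled standard deviation.  After the transform every
    variable has pooled mean 0 and pooled SD 1 over all observed cells, which
    the stationary GVAR parameterization assumes.  ``per_wave=True`` instead
    z-scores within each wave separately (off by default).
    """
    n, T, p = panel.values.shape
    t = panel.wave_times
    out = panel.values.copy()
    if per_wave:
        for ti in range(T):
            for j in range(p):
                col = out[:, ti, j]
                obs = ~np.isnan(col)
                sd = np.std(col[obs]) if obs.any() else 0.0
                if sd < tol:
                    raise DegenerateVariableError(
                        f"variable {panel.variable_names[j]!r} degenerate at wave {ti + 1}"
                    )
                out[:, ti, j] = (col - np.mean(col[obs])) / sd
        return panel.copy_with(out)
    design = np.column_stack([np.ones(T), t, t ** 2])  # per-wave design rows
    for j in range(p):
        vals = out[:, :, j]
        obs = ~np.isnan(vals)
        X = np.repeat(design[None, :, :], n, axis=0)[obs]
        y = vals[obs]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sd = np.sqrt(np.mean(resid ** 2))
        if sd < tol:
            raise DegenerateVariableError(
                f"variable {panel.variable_names[j]!r} has zero residual "
                f"variance after detrending"
            )
        vals[obs] = resid / sd
    return panel.copy_with(out)


def wave_pair_complete_cases(panel: PanelDataset, s: int, t: int
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Complete-case predictor/outcome matrices for the wave pair (s, t).

    Waves are 1-based.  Returns ``(X, Y, person_ids)`` restricted to persons
    with no missing value at either wave, in stable person order.
    """
    if not 1 <= s < t <= panel.n_waves:
        raise PanelDataError(f"need 1 <= s < t <= {panel.n_waves}, got ({s}, {t})")
    Xw = panel.values[:, s - 1, :]
    Yw = panel.values[:, t - 1, :]
    keep = ~np.isnan(Xw).any(axis=1) & ~np.isnan(Yw).any(axis=1)
    n_complete = int(keep.sum())
    if n_complete < panel.n_variables + 2:
        raise InsufficientDataError(
            f"only {n_complete} complete cases for wave pair ({s}, {t}); "
            f"need at least {panel.n_variables + 2}"
        )
    return Xw[keep].copy(), Yw[keep].copy(), panel.person_ids[keep].copy()


def missingness_patterns(panel_or_matrix) -> list[dict]:
    """Group persons by identical observed-cell masks over the stacked vector.

    Accepts a PanelDataset (stacked wave-major) or an n x k matrix.  Persons
    with zero observed cells are excluded with a logged warning.  Returns a
    list of ``{"mask": bool array, "rows": index array}`` groups that
    partition the remaining persons.
    """
    data = panel_or_matrix.stacked() if isinstance(panel_or_matrix, PanelDataset) else np.asarray(panel_or_matrix, dtype=float)
    masks = ~np.isnan(data)
    empty = ~masks.any(axis=1)
    if empty.any():
        logger.warning("excluding %d person(s) with zero observed cells",
                       int(empty.sum()))
    groups: dict[bytes, list[int]] = {}
    for i in np.nonzero(~empty)[0]:
        groups.setdefault(masks[i].tobytes(), []).append(i)
    return [
        {"mask": np.frombuffer(key, dtype=bool).copy(), "rows": np.asarray(rows)}
        for key, rows in groups.items()
    ]
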