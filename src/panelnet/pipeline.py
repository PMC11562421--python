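"""Config-driven orchestration of the full panel-network analysis.

A single :func:`run_pipeline` call reproduces the complete analysis graph on
synthetic or user data: per-wave contemporaneous networks (EBIC glasso),
cross-lagged networks per consecutive wave pair, a pruned panel GVAR on the
detrended panel, centrality and bridge tables, a case-dropping stability
report, and the four hierarchical EF regressions.  All outputs are plain
CSV/JSON (optionally GraphML for network viewers); the run manifest records
every stage, seed and runtime so a run is reproducible from config + seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clpn import estimate_clpn
from .cohort import CohortSpec, simulate_cohort
from .ef import broadband_aggregates, filter_ef_table, hierarchical_compare
from .ggm import estimate_wave_ggm
from .gvar import fit_indices, fit_saturated_gvar, prune_stepup
from .metrics import bridge_strength, case_drop_bootstrap, strength_in_out
from .panel_data import (PanelDataset, detrend_and_standardize, read_long_csv,
                         read_wide_csv)

logger = logging.getLogger(__name__)

ALL_STAGES = ("ggm", "clpn", "gvar", "metrics", "stability", "ef_regression")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """What to run, on what input, with which per-stage parameters."""

    source: dict = field(default_factory=lambda: {"synthetic": {}})
    stages: tuple[str, ...] = ALL_STAGES
    params: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "panelnet_output"

    def __post_init__(self):
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ConfigError(f"unknown stages: {unknown}")
        if "metrics" in self.stages and not (
                {"clpn", "gvar", "ggm"} & set(self.stages)):
            raise ConfigError("metrics stage requires an estimated network "
                              "(enable clpn, gvar or ggm)")
        if "stability" in self.stages and "clpn" not in self.stages:
            raise ConfigError("stability stage requires the clpn stage")
        if not ({"synthetic", "file"} & set(self.source)):
            raise ConfigError("source must contain 'synthetic' or 'file'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(
                source=raw.get("source", {"synthetic": {}}),
                stages=tuple(raw.get("stages", ALL_STAGES)),
                params=raw.get("params", {}),
                seed=int(raw.get("seed", 0)),
                outdir=raw.get("outdir", "panelnet_output"),
            )
        except (TypeError, ValueError) as err:
            raise ConfigError(str(err)) from err


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not serializable: {type(o)}")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True,
                               default=_json_default) + "\n")


def _load_input(config: PipelineConfig):
    if "synthetic" in config.source:
        spec_kwargs = dict(config.source.get("synthetic") or {})
        if "retention" in spec_kwargs:
            spec_kwargs["retention"] = tuple(spec_kwargs["retention"])
        spec_kwargs.setdefault("seed", config.seed)
        template = config.source.get("template", "trails_like")
        truth, panel, ef = simulate_cohort(CohortSpec(**spec_kwargs), template)
        return truth, panel, ef
    path = config.source["file"]
    fmt = config.source.get("format", "wide")
    panel = read_wide_csv(path) if fmt == "wide" else read_long_csv(path)
    ef = None
    if config.source.get("ef_file"):
        ef = pd.read_csv(config.source["ef_file"])
    return None, panel, ef


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": {}, "config": {
                          "stages": list(config.stages),
                          "params": config.params,
                          "source": {k: v for k, v in config.source.items()
                                     if k != "synthetic"} |
                                    ({"synthetic": dict(config.source["synthetic"] or {})}
                                     if "synthetic" in config.source else {})}}
    state: dict = {}
    t0 = time.perf_counter()
    truth, panel, ef = _load_input(config)
    state.update(truth=truth, panel=panel, ef=ef)
    panel.write_csv(outdir / "panel_wide.csv", format="wide")
    if ef is not None:
        ef.to_csv(outdir / "ef_wave1.csv", index=False)
    if truth is not None:
        _write_json(outdir / "ground_truth.json", truth.to_dict())
    manifest["stages"]["input"] = {
        "n_persons": panel.n_persons, "n_waves": panel.n_waves,
        "n_variables": panel.n_variables,
        "runtime_s": round(time.perf_counter() - t0, 3),
        "outputs": ["panel_wide.csv"]}
    for stage in config.stages:
        t0 = time.perf_counter()
        try:
            outputs = _STAGE_FUNCS[stage](config, state, outdir)
        except Exception:
            manifest["failed_stage"] = stage
            _write_json(outdir / "manifest.json", manifest)
            raise
        manifest["stages"][stage] = {
            "runtime_s": round(time.perf_counter() - t0, 3),
            "outputs": outputs}
        logger.info("stage %s done in %.1fs", stage,
                    manifest["stages"][stage]["runtime_s"])
    _write_json(outdir / "manifest.json", manifest)
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_ggm(config, state, outdir: Path):
    panel: PanelDataset = state["panel"]
    prm = config.params.get("ggm", {})
    gamma = prm.get("gamma", 0.5)
    outputs = []
    state["ggms"] = {}
    for wave in range(1, panel.n_waves + 1):
        g = estimate_wave_ggm(panel, wave, gamma=gamma)
        state["ggms"][wave] = g
        name = f"ggm_w{wave}"
        g.edge_list().to_csv(outdir / f"{name}_edges.csv", index=False)
        _write_json(outdir / f"{name}.json", {
            "partial_corr": g.partial_corr, "lambda": g.lambda_selected,
            "ebic_gamma": g.ebic_gamma, "n": g.n, "nodes": g.node_names})
        outputs += [f"{name}_edges.csv", f"{name}.json"]
        if prm.get("graphml"):
            _write_graphml(outdir / f"{name}.graphml", g.partial_corr,
                           g.node_names)
            outputs.append(f"{name}.graphml")
    return outputs


def _stage_clpn(config, state, outdir: Path):
    panel: PanelDataset = state["panel"]
    prm = config.params.get("clpn", {})
    outputs = []
    state["clpns"] = {}
    for s in range(1, panel.n_waves):
        net = estimate_clpn(panel, s, s + 1, k=prm.get("folds", 10),
                            rule=prm.get("rule", "min"),
                            seed=prm.get("seed", config.seed + 100 + s))
        state["clpns"][(s, s + 1)] = net
        name = f"clpn_w{s}{s + 1}"
        net.edge_list().to_csv(outdir / f"{name}_edges.csv", index=False)
        _write_json(outdir / f"{name}.json", {
            "weights": net.weights, "lambdas": net.lambdas,
            "n_used": net.n_used, "nodes": net.node_names})
        outputs += [f"{name}_edges.csv", f"{name}.json"]
    return outputs


def _stage_gvar(config, state, outdir: Path):
    panel: PanelDataset = state["panel"]
    prm = config.params.get("gvar", {})
    detrended = detrend_and_standardize(panel)
    state["detrended"] = detrended
    sat = fit_saturated_gvar(detrended, n_starts=prm.get("starts", 3),
                             seed=config.seed)
    pruned, trace = prune_stepup(sat, alpha=prm.get("alpha", 0.05))
    fit = fit_indices(pruned.loglik, pruned.n_params, pruned.stats)
    state["gvar"] = pruned
    state["gvar_fit"] = fit
    _write_json(outdir / "gvar_model.json", {
        "B": pruned.params.B,
        "contemporaneous_partials": pruned.params.contemporaneous_partials(),
        "between_partials": pruned.params.between_partials(),
        "free_B": pruned.params.free_B,
        "free_K_zeta": pruned.params.free_K_zeta,
        "free_K_B": pruned.params.free_K_B,
        "fit_indices": fit.to_dict(), "prune_trace": trace,
        "saturated_loglik": sat.loglik, "nodes": panel.variable_names})
    return ["gvar_model.json"]


def _stage_metrics(config, state, outdir: Path):
    panel: PanelDataset = state["panel"]
    comm = panel.communities
    outputs = []
    for (s, t), net in state.get("clpns", {}).items():
        tab = strength_in_out(net.weights, node_names=net.node_names)
        tab.table.to_csv(outdir / f"centrality_clpn_w{s}{t}.csv", index=False)
        outputs.append(f"centrality_clpn_w{s}{t}.csv")
    for wave, g in state.get("ggms", {}).items():
        tab = bridge_strength(g.partial_corr, comm, node_names=g.node_names)
        tab.table.to_csv(outdir / f"bridge_ggm_w{wave}.csv", index=False)
        outputs.append(f"bridge_ggm_w{wave}.csv")
    if "gvar" in state:
        gv = state["gvar"]
        tab = strength_in_out(gv.params.B.T,
                              node_names=panel.variable_names)
        tab.table.to_csv(outdir / "centrality_gvar_temporal.csv", index=False)
        outputs.append("centrality_gvar_temporal.csv")
    return outputs


def _stage_stability(config, state, outdir: Path):
    panel: PanelDataset = state["panel"]
    prm = config.params.get("stability", {})
    s, t = prm.get("wave_pair", (1, 2))
    folds = config.params.get("clpn", {}).get("folds", 10)

    def estimator(sub):
        return estimate_clpn(sub, s, t, k=folds, seed=config.seed + 100 + s)

    def metric(net):
        tab = strength_in_out(net.weights)
        return np.concatenate([tab["in_strength"], tab["out_strength"]])

    res = case_drop_bootstrap(
        panel, estimator, metric,
        proportions=tuple(prm.get("proportions", (0.1, 0.2, 0.3))),
        n_boot=prm.get("n_boot", 50), seed=config.seed + 7)
    _write_json(outdir / "stability.json", {
        "cs_coefficient": res.cs_coefficient,
        "drop_proportions": res.drop_proportions,
        "mean_correlation": {str(q): float(np.mean(r)) if r.size else None
                             for q, r in res.correlations.items()},
        "n_boot": res.n_boot, "failures": res.failures})
    return ["stability.json"]


def _stage_ef_regression(config, state, outdir: Path):
    panel: PanelDataset = state["panel"]
    ef = state.get("ef")
    if ef is None:
        raise ConfigError("ef_regression stage needs an EF table "
                          "(synthetic source or ef_file)")
    prm = config.params.get("ef_regression", {})
    ef = filter_ef_table(ef, threshold=prm.get("z_threshold", 4.0))
    symptoms = broadband_aggregates(panel)
    outputs = []
    summary = {}
    for target in ("internalizing", "externalizing"):
        for wave in (2, 3):
            comp = hierarchical_compare(symptoms, ef, target=target, wave=wave)
            name = f"efreg_{target}_w{wave}"
            comp.step2.coefficients.to_csv(outdir / f"{name}_step2.csv",
                                           index=False)
            outputs.append(f"{name}_step2.csv")
            summary[name] = {"r2_step1": comp.step1.r2,
                             "r2_step2": comp.step2.r2,
                             "delta_r2": comp.delta_r2,
                             "n": comp.n_effective}
    _write_json(outdir / "efreg_summary.json", summary)
    state["efreg"] = summary
    return outputs + ["efreg_summary.json"]


def _write_graphml(path: Path, matrix: np.ndarray, names: list[str]) -> None:
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(names)
    p = len(names)
    for i in range(p):
        for j in range(i + 1, p):
            if matrix[i, j] != 0:
                G.add_edge(names[i], names[j], weight=float(matrix[i, j]))
    nx.write_graphml(G, path)


_STAGE_FUNCS = {
    "ggm": _stage_ggm,
    "clpn": _stage_clpn,
    "gvar": _stage_gvar,
    "metrics": _stage_metrics,
    "stability": _stage_stability,
    "ef_regression": _stage_ef_regression,
}
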