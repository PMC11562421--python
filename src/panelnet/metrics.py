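"""Centrality and case-dropping bootstrap stability for estimated networks.

Strength centralities use absolute edge weights by default so that positive
and negative edges do not cancel (a signed variant is available).  Stability
follows the case-dropping bootstrap: re-estimate the network on person
subsamples of decreasing size and summarize, per drop proportion, how well
the subsample centrality vector correlates with the full-sample one.  The
CS-coefficient is the largest drop proportion at which at least 95% of
bootstraps still correlate >= 0.7.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_data import PanelDataset

logger = logging.getLogger(__name__)

DEFAULT_PROPORTIONS = tuple(np.round(np.arange(0.05, 0.76, 0.05), 2))


class MetricsError(ValueError):
    pass


class StabilityError(RuntimeError):
    pass


@dataclass
class CentralityTable:
    nodes: list[str]
    table: pd.DataFrame
    communities: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, column: str) -> np.ndarray:
        return self.table[column].to_numpy()


def strength_in_out(net: np.ndarray, include_self: bool = False,
                    node_names: list[str] | None = None,
                    signed: bool = False) -> CentralityTable:
    """In-/out-strength of a directed weighted network.

    ``out_strength(j) = sum_k |w(j -> k)|`` over outgoing edges and
    ``in_strength(k) = sum_j |w(j -> k)|`` over incoming ones; ``net[j, k]``
    is the edge j -> k.  Self-loops are excluded unless ``include_self``.
    """
    W = np.asarray(net, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise MetricsError(f"network matrix must be square, got {W.shape}")
    p = W.shape[0]
    A = W if signed else np.abs(W)
    if not include_self:
        A = A - np.diag(np.diag(A))
    names = node_names or [f"V{j + 1}" for j in range(p)]
    df = pd.DataFrame({
        "node": names,
        "out_strength": A.sum(axis=1),
        "in_strength": A.sum(axis=0),
    })
    return CentralityTable(nodes=names, table=df)


def strength_undirected(net: np.ndarray, node_names: list[str] | None = None,
                        signed: bool = False) -> CentralityTable:
    """Node strength of a symmetric network (sum of absolute edge weights)."""
    W = np.asarray(net, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise MetricsError("network matrix must be square")
    A = W if signed else np.abs(W)
    A = A - np.diag(np.diag(A))
    names = node_names or [f"V{j + 1}" for j in range(W.shape[0])]
    df = pd.DataFrame({"node": names, "strength": A.sum(axis=1)})
    return CentralityTable(nodes=names, table=df)


def bridge_strength(net: np.ndarray, communities: dict[str, str] | list[str],
                    node_names: list[str] | None = None,
                    signed: bool = False) -> CentralityTable:
    """Bridge strength: a node's summed edge weight to other communities.

    Quantifies how strongly a symptom connects to symptoms outside its own
    cluster (e.g. an internalizing node's edges into the externalizing
    cluster); every node must carry exactly one community label.
    """
    W = np.asarray(net, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise MetricsError("network matrix must be square")
    p = W.shape[0]
    names = node_names or [f"V{j + 1}" for j in range(p)]
    if isinstance(communities, dict):
        try:
            labels = [communities[n] for n in names]
        except KeyError as err:
            raise MetricsError(f"node {err.args[0]!r} has no community label")
    else:
        labels = list(communities)
        if len(labels) != p:
            raise MetricsError("one community label per node required")
    A = W if signed else np.abs(W)
    A = A - np.diag(np.diag(A))
    labels_arr = np.asarray(labels)
    bridge = np.array([
        A[j, labels_arr != labels_arr[j]].sum() for j in range(p)
    ])
    df = pd.DataFrame({"node": names, "bridge_strength": bridge,
                       "community": labels})
    return CentralityTable(nodes=names, table=df,
                           communities=dict(zip(names, labels)))


@dataclass
class StabilityResult:
    drop_proportions: np.ndarray
    correlations: dict[float, np.ndarray]   # per proportion, per-bootstrap r
    cs_coefficient: float
    n_boot: int
    failures: dict[float, int] = field(default_factory=dict)
    threshold: float = 0.7
    coverage: float = 0.95

    def cs_at(self, threshold: float) -> float:
        """CS-coefficient recomputed at another correlation threshold."""
        return _cs_from_correlations(self.drop_proportions, self.correlations,
                                     threshold, self.coverage)


def _metric_correlation(full: np.ndarray, sub: np.ndarray) -> float:
    full = np.asarray(full, dtype=float)
    sub = np.asarray(sub, dtype=float)
    if full.std() == 0 or sub.std() == 0:
        return 1.0 if np.allclose(full, sub) else 0.0
    return float(np.corrcoef(full, sub)[0, 1])


def _cs_from_correlations(props, correlations, threshold, coverage):
    passing = [float(q) for q in props
               if correlations[float(q)].size
               and np.mean(correlations[float(q)] >= threshold) >= coverage]
    return max(passing, default=0.0)


def case_drop_bootstrap(panel: PanelDataset, estimator, metric,
                        proportions=DEFAULT_PROPORTIONS, n_boot: int = 200,
                        seed: int = 0, threshold: float = 0.7,
                        coverage: float = 0.95,
                        max_failure_rate: float = 0.2) -> StabilityResult:
    """Case-dropping bootstrap stability of a network centrality metric.

    ``estimator(panel) -> network-like`` and ``metric(result) -> vector``
    together map data to the centrality vector under study.  For each drop
    proportion q, ``n_boot`` seeded subsamples of ``ceil((1 - q) n)`` persons
    are re-estimated; estimator failures are logged and skipped, but more
    than ``max_failure_rate`` failures at any proportion aborts.
    """
    n = panel.n_persons
    full_metric = np.asarray(metric(estimator(panel)), dtype=float)
    rng = np.random.default_rng(seed)
    correlations: dict[float, np.ndarray] = {}
    failures: dict[float, int] = {}
    for q in proportions:
        keep = int(np.ceil((1.0 - q) * n))
        rs = []
        fail = 0
        for _ in range(n_boot):
            idx = np.sort(rng.choice(n, size=keep, replace=False))
            sub = PanelDataset(panel.values[idx], panel.person_ids[idx],
                               panel.wave_times, list(panel.variables))
            try:
                rs.append(_metric_correlation(full_metric,
                                              metric(estimator(sub))))
            except Exception as err:  # estimator failure on a subsample
                fail += 1
                logger.debug("estimator failed at q=%.2f: %s", q, err)
        failures[float(q)] = fail
        if fail > max_failure_rate * n_boot:
            raise StabilityError(
                f"{fail}/{n_boot} estimator failures at drop proportion {q}")
        correlations[float(q)] = np.asarray(rs)
    cs = _cs_from_correlations(proportions, correlations, threshold, coverage)
    return StabilityResult(drop_proportions=np.asarray(proportions, dtype=float),
                           correlations=correlations, cs_coefficient=cs,
                           n_boot=n_boot, failures=failures,
                           threshold=threshold, coverage=coverage)
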