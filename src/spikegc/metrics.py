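"""Global network metrics, RT-aligned time courses, and group comparisons.

Causal density is the fraction of ordered node pairs carrying a
statistically significant causal connection,

    Cd = Num_GC / (N (N-1)),

bounded in [0, 1]. Global efficiency averages inverse shortest-path
lengths over ordered pairs,

    E = 1/(N(N-1)) * sum_{i != j} 1 / L_ij,

on the directed pruned graph with edge length = 1 / connection strength;
unreachable pairs contribute 0. Per-trial time courses of both metrics
are aligned to the trial's reference time (RT); the scalar used for group
comparisons is the mean of the metric over the windows within +-0.25 s of
its per-trial peak, and groups are compared by a two-sample Welch t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .granger import GCNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "MetricTimecourse",
    "GroupComparison",
    "causal_density",
    "global_efficiency",
    "metric_timecourse",
    "peak_window_stats",
    "compare_groups",
]


@dataclass
class MetricTimecourse:
    """Per-window Cd and E for one trial, times relative to RT (s)."""

    trial_id: int | str
    space_tag: str
    times: np.ndarray
    cd: np.ndarray
    eff: np.ndarray
    label: str

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.cd = np.asarray(self.cd, dtype=float)
        self.eff = np.asarray(self.eff, dtype=float)
        if not (len(self.times) == len(self.cd) == len(self.eff)):
            raise ValueError("times, cd, eff must have equal length")
        if self.cd.size and (self.cd.min() < 0 or self.cd.max() > 1):
            raise ValueError("causal density must lie in [0, 1]")


@dataclass
class GroupComparison:
    group_a_values: np.ndarray
    group_b_values: np.ndarray
    statistic: float
    pvalue: float
    effect_direction: str  # "a>b" | "b>a" | "none"


def causal_density(net: GCNetwork) -> float:
    """Fraction of ordered pairs with a surviving (significant) edge."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("causal density undefined for fewer than 2 nodes")
    if net.sig_mask is None:
        raise ValueError("network not yet pruned by significance_filter")
    num = int(net.sig_mask.sum())
    return num / (n * (n - 1))


def global_efficiency(net: GCNetwork, use_significant_only: bool = True) -> float:
    """Mean inverse directed shortest-path length, edge length = 1/strength."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("global efficiency undefined for fewer than 2 nodes")
    if use_significant_only:
        if net.sig_mask is None:
            raise ValueError("network not yet pruned by significance_filter")
        weights = np.where(net.sig_mask, net.F, 0.0)
    else:
        weights = net.F
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    rows, cols = np.nonzero(weights)
    for i, j in zip(rows, cols):  # F[i, j] is the edge j -> i
        g.add_edge(j, i, length=1.0 / weights[i, j])
    total = 0.0
    for src, dists in nx.all_pairs_dijkstra_path_length(g, weight="length"):
        for dst, d in dists.items():
            if dst != src and d > 0:
                total += 1.0 / d
    return total / (n * (n - 1))


def metric_timecourse(
    networks: list[GCNetwork],
    label: str,
    trial_id: int | str = 0,
    use_significant_only: bool = True,
) -> MetricTimecourse:
    """Window-by-window Cd and E, sorted by window center.

    Skipped windows are simply absent (gaps); nothing is interpolated.
    """
    if not networks:
        raise ValueError("need at least one network")
    nets = sorted(networks, key=lambda nw: nw.window_center)
    times = np.array([nw.window_center for nw in nets])
    cd = np.array([causal_density(nw) for nw in nets])
    eff = np.array([global_efficiency(nw, use_significant_only) for nw in nets])
    return MetricTimecourse(trial_id, nets[0].space_tag, times, cd, eff, label)


def peak_window_stats(
    tc: MetricTimecourse,
    metric: str = "cd",
    pre: float = 0.25,
    post: float = 0.25,
) -> float:
    """Mean of the metric over windows within [peak - pre, peak + post].

    The peak is the metric's own per-trial maximum; ties break toward the
    earliest window (argmax convention).
    """
    values = tc.cd if metric == "cd" else tc.eff
    if values.size == 0:
        raise ValueError(f"trial {tc.trial_id}: empty timecourse, excluded")
    t_peak = tc.times[int(np.argmax(values))]
    sel = (tc.times >= t_peak - pre - 1e-12) & (tc.times <= t_peak + post + 1e-12)
    return float(values[sel].mean())


def compare_groups(a, b) -> GroupComparison:
    """Two-sample Welch t-test (two-sided) between per-trial scalars."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return GroupComparison(a, b, 0.0, 1.0, "none")
        # degenerate but separated groups: report infinite evidence
        direction = "a>b" if a.mean() > b.mean() else "b>a"
        return GroupComparison(a, b, np.inf if a.mean() > b.mean() else -np.inf, 0.0, direction)
    stat, pval = stats.ttest_ind(a, b, equal_var=False)
    if a.mean() > b.mean():
        direction = "a>b"
    elif a.mean() < b.mean():
        direction = "b>a"
    else:
        direction = "none"
    return GroupComparison(a, b, float(stat), float(pval), direction)
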