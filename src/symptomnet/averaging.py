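"""Bootstrap model averaging of learned networks.

A network is learned on each of B nonparametric bootstrap resamples; each
unordered node pair accumulates a *strength* (fraction of resampled
networks containing an edge between the two nodes, either direction) and a
*direction* split (fraction of those favouring each orientation).  The
averaged network keeps the pairs whose strength clears a threshold —
either a fixed proportion or the L1-optimal significance threshold of the
arc-strength literature — oriented by majority, with a deterministic
cycle repair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .dag import Arc, Dag
from .data import MixedDataset
from .search import default_blacklist, hill_climb
from .variables import VariableSpec


def bootstrap_networks(data: MixedDataset, B: int, seed: int = 0,
                       learner: Callable[[MixedDataset], Dag] | None = None,
                       resampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
                       ) -> list[Dag]:
    """Learn one network per bootstrap resample (n records with
    replacement, deterministic given ``seed`` and the replicate index).

    ``learner`` maps a dataset to a Dag; the default is hill climbing with
    the standard continuous-into-discrete blacklist.  ``resampler`` is a
    test hook overriding index generation.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if learner is None:
        bl = default_blacklist(data.specs)

        def learner(d: MixedDataset) -> Dag:  # noqa: F811
            return hill_climb(d, blacklist=bl)[0]

    dags = []
    for b in range(B):
        rng = np.random.default_rng(np.random.SeedSequence([seed, b]))
        idx = resampler(rng, data.n) if resampler is not None else \
            rng.integers(0, data.n, size=data.n)
        try:
            dags.append(learner(data.take_rows(idx)))
        except Exception as exc:
            raise RuntimeError(f"bootstrap replicate {b} failed: {exc}") from exc
    return dags


@dataclass
class ArcConfidence:
    nodes: tuple[str, ...]
    B: int
    strength: dict[frozenset, float] = field(default_factory=dict)
    direction: dict[Arc, float] = field(default_factory=dict)

    def strength_of(self, u: str, v: str) -> float:
        return self.strength.get(frozenset((u, v)), 0.0)

    def direction_of(self, u: str, v: str) -> float:
        return self.direction.get((u, v), 0.0)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, u in enumerate(self.nodes):
            for v in self.nodes[i + 1:]:
                s = self.strength_of(u, v)
                rows.append({"node_a": u, "node_b": v, "strength": s,
                             "direction_a_to_b": self.direction_of(u, v),
                             "direction_b_to_a": self.direction_of(v, u)})
        return pd.DataFrame(rows)


def arc_confidence(dags: Sequence[Dag]) -> ArcConfidence:
    """Exact edge and orientation frequencies across learned networks."""
    if not dags:
        raise ValueError("need at least one network")
    nodes = dags[0].nodes
    node_set = set(nodes)
    for d in dags:
        if set(d.nodes) != node_set:
            raise ValueError("networks have inconsistent node sets")
    B = len(dags)
    pair_counts: dict[frozenset, int] = {}
    dir_counts: dict[Arc, int] = {}
    for d in dags:
        for u, v in d.arcs:
            pair_counts[frozenset((u, v))] = pair_counts.get(frozenset((u, v)), 0) + 1
            dir_counts[(u, v)] = dir_counts.get((u, v), 0) + 1
    conf = ArcConfidence(nodes=nodes, B=B)
    for pair, c in pair_counts.items():
        conf.strength[pair] = c / B
        u, v = sorted(pair)
        present = c
        conf.direction[(u, v)] = dir_counts.get((u, v), 0) / present
        conf.direction[(v, u)] = dir_counts.get((v, u), 0) / present
    return conf


def significance_threshold(conf: ArcConfidence) -> float:
    """L1-optimal strength threshold.

    The strengths of all candidate pairs are modelled as a mixture of a
    noise atom near 0 and a signal atom near 1; the estimated noise mass
    ``p`` minimizes the L1 distance between the empirical strength CDF and
    the constant-``p`` step function, and the threshold is the empirical
    ``p``-quantile of the strengths.  Pairs *strictly above* the returned
    value are significant.
    """
    strengths = []
    for i, u in enumerate(conf.nodes):
        for v in conf.nodes[i + 1:]:
            strengths.append(conf.strength_of(u, v))
    s = np.sort(np.asarray(strengths))
    if s.size == 0:
        return 1.0
    support, counts = np.unique(s, return_counts=True)
    cdf = np.cumsum(counts) / s.size
    # piecewise-constant empirical CDF over [0, 1]: value 0 before the
    # first support point, cdf[i] on [support[i], support[i+1])
    breaks = np.concatenate([[0.0], support, [1.0]])
    seg_widths = np.diff(breaks)
    seg_vals = np.concatenate([[0.0], cdf])
    best_p, best_l1 = 0.0, np.inf
    for p in np.unique(seg_vals):
        l1 = float(np.sum(seg_widths * np.abs(seg_vals - p)))
        if l1 < best_l1 - 1e-15:
            best_l1, best_p = l1, float(p)
    # p-quantile of the strengths
    idx = int(np.ceil(best_p * s.size)) - 1
    idx = min(max(idx, 0), s.size - 1)
    return float(s[idx])


def averaged_network(conf: ArcConfidence, threshold: float | str = "auto",
                     blacklist: Iterable[Arc] | None = None) -> Dag:
    """Threshold strengths into a consensus DAG.

    Numeric thresholds include pairs with ``strength >= threshold``;
    ``"auto"`` includes pairs strictly above the estimated significance
    threshold.  Orientation follows the majority direction (exact ties
    break to the lexicographically smaller orientation, never into the
    blacklist); any residual directed cycle is repaired by dropping its
    weakest-strength arc.
    """
    bl = {tuple(a) for a in (blacklist or ())}
    if threshold == "auto":
        t = significance_threshold(conf)
        selected = [pair for pair, s in conf.strength.items() if s > t]
    else:
        t = float(threshold)
        if not (0.0 <= t <= 1.0):
            raise ValueError("threshold must lie in [0, 1]")
        selected = [pair for pair, s in conf.strength.items() if s >= t]
    arcs: list[Arc] = []
    for pair in selected:
        u, v = sorted(pair)
        f_uv, f_vu = conf.direction_of(u, v), conf.direction_of(v, u)
        if f_uv > f_vu:
            arc = (u, v)
        elif f_vu > f_uv:
            arc = (v, u)
        else:
            arc = (u, v)  # lexicographic tie-break
        if arc in bl:
            arc = (arc[1], arc[0])
        arcs.append(arc)
    # cycle repair: drop the weakest arc of each remaining cycle
    import networkx as nx
    g = nx.DiGraph()
    g.add_nodes_from(conf.nodes)
    g.add_edges_from(arcs)
    while not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        drop = min(cycle, key=lambda e: (conf.strength_of(e[0], e[1]), e[0], e[1]))
        g.remove_edge(*drop)
    return Dag(conf.nodes, list(g.edges()))


@dataclass
class EdgeComparison:
    shared: int
    unique_to_first: int
    unique_to_second: int


def compare_edges(a: Dag, b: Dag, ignore_direction: bool = False) -> EdgeComparison:
    """Shared / unique edge counts between two networks on one node set."""
    if set(a.nodes) != set(b.nodes):
        raise ValueError("node sets differ")
    ea = a.skeleton() if ignore_direction else set(a.arcs)
    eb = b.skeleton() if ignore_direction else set(b.arcs)
    return EdgeComparison(shared=len(ea & eb),
                          unique_to_first=len(ea - eb),
                          unique_to_second=len(eb - ea))
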