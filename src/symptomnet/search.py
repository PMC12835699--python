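"""Score-based DAG search: greedy hill climbing and a Tabu variant.

Both searches start from the arcless graph and move through single-arc
additions, deletions and reversals, maximizing the decomposable BIC
network score.  Candidate moves are enumerated in a fixed lexicographic
order — ties among equal score deltas resolve to the first candidate by
``(operator, parent, child)`` — so results are platform-independent.
Family scores are memoized in a :class:`~symptomnet.clg.CLGScorer`, and
every move's delta touches only the affected families (score
decomposability), which is what makes bootstrap averaging affordable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .clg import CLGScorer
from .dag import Arc, Dag
from .data import MixedDataset
from .variables import VariableSpec

_TOL = 1e-9


def default_blacklist(specs: Sequence[VariableSpec]) -> set[Arc]:
    """All arcs from a continuous variable into a discrete one — the
    structural constraint of the CLG family (demographics cannot be child
    nodes of clinical scale scores)."""
    cont = [s.name for s in specs if s.is_continuous]
    disc = [s.name for s in specs if s.is_discrete]
    return {(c, d) for c in cont for d in disc}


@dataclass
class SearchTrace:
    iterations: list[tuple[str, Arc, float]] = field(default_factory=list)
    final_score: float = float("-inf")
    converged: bool = False

    def to_jsonl(self, path: str | Path) -> None:
        lines = [json.dumps({"operator": op, "parent": a[0], "child": a[1],
                             "score_delta": d})
                 for op, a, d in self.iterations]
        lines.append(json.dumps({"final_score": self.final_score,
                                 "converged": self.converged}))
        Path(path).write_text("\n".join(lines) + "\n")


class _SearchState:
    """Mutable parent-set representation with incremental scoring."""

    def __init__(self, data: MixedDataset, specs: Sequence[VariableSpec],
                 blacklist: Iterable[Arc]):
        self.specs = list(specs)
        self.names = [s.name for s in self.specs]
        self.kind = {s.name: s.kind for s in self.specs}
        self.blacklist = {tuple(a) for a in blacklist}
        self.scorer = CLGScorer(data, self.specs)
        self.parents: dict[str, frozenset[str]] = {n: frozenset() for n in self.names}
        self.fscore: dict[str, float] = {
            n: self.scorer.family_score(n, frozenset()) for n in self.names}

    # -- structure helpers ----------------------------------------------
    def arcs(self) -> set[Arc]:
        return {(u, v) for v, ps in self.parents.items() for u in ps}

    def has_arc(self, u: str, v: str) -> bool:
        return u in self.parents[v]

    def has_path(self, src: str, dst: str, skip_arc: Arc | None = None) -> bool:
        """Directed reachability src -> dst (DFS over current arcs)."""
        stack, seen = [src], {src}
        children: dict[str, list[str]] = {n: [] for n in self.names}
        for v, ps in self.parents.items():
            for u in ps:
                if skip_arc is not None and (u, v) == skip_arc:
                    continue
                children[u].append(v)
        while stack:
            node = stack.pop()
            if node == dst:
                return True
            for c in children[node]:
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return False

    def addable(self, u: str, v: str) -> bool:
        if u == v or self.has_arc(u, v) or (u, v) in self.blacklist:
            return False
        if self.kind[u] == "continuous" and self.kind[v] == "discrete":
            return False  # structurally outside the CLG family
        return not self.has_path(v, u)

    def reversible(self, u: str, v: str) -> bool:
        if not self.has_arc(u, v) or (v, u) in self.blacklist:
            return False
        if self.kind[v] == "continuous" and self.kind[u] == "discrete":
            return False
        # cycle iff another directed path u -> v survives removing (u, v)
        return not self.has_path(u, v, skip_arc=(u, v))

    # -- move deltas ----------------------------------------------------
    def delta(self, op: str, u: str, v: str) -> float:
        fs = self.scorer.family_score
        if op == "add":
            return fs(v, self.parents[v] | {u}) - self.fscore[v]
        if op == "delete":
            return fs(v, self.parents[v] - {u}) - self.fscore[v]
        if op == "reverse":
            return (fs(v, self.parents[v] - {u}) - self.fscore[v]
                    + fs(u, self.parents[u] | {v}) - self.fscore[u])
        raise ValueError(op)

    def candidate_moves(self):
        """Legal moves in deterministic (operator, parent, child) order."""
        moves: list[tuple[str, str, str]] = []
        for u in self.names:
            for v in self.names:
                if u == v:
                    continue
                if self.has_arc(u, v):
                    moves.append(("delete", u, v))
                    if self.reversible(u, v):
                        moves.append(("reverse", u, v))
                elif self.addable(u, v):
                    moves.append(("add", u, v))
        moves.sort()
        return moves

    def apply(self, op: str, u: str, v: str) -> None:
        if op == "add":
            self.parents[v] = self.parents[v] | {u}
        elif op == "delete":
            self.parents[v] = self.parents[v] - {u}
        elif op == "reverse":
            self.parents[v] = self.parents[v] - {u}
            self.parents[u] = self.parents[u] | {v}
            self.fscore[u] = self.scorer.family_score(u, self.parents[u])
        else:
            raise ValueError(op)
        self.fscore[v] = self.scorer.family_score(v, self.parents[v])

    def total_score(self) -> float:
        return float(sum(self.fscore.values()))

    def to_dag(self) -> Dag:
        return Dag(self.names, self.arcs())


def hill_climb(data: MixedDataset, specs: Sequence[VariableSpec] | None = None,
               blacklist: Iterable[Arc] | None = None, seed: int = 0,
               restarts: int = 0, tol: float = _TOL,
               _state: _SearchState | None = None) -> tuple[Dag, SearchTrace]:
    """Greedy BIC hill climbing from the empty network.

    Applies the single legal add/delete/reverse move with the largest
    positive score delta until none improves; the result is certified a
    local optimum.  ``seed`` only matters when ``restarts > 0`` (random
    restarts perturb the start by random arc additions; the base algorithm
    is deterministic and restarts default to 0).
    """
    specs = list(specs) if specs is not None else list(data.specs)
    if blacklist is None:
        blacklist = default_blacklist(specs)
    state = _state or _SearchState(data, specs, blacklist)
    trace = SearchTrace()
    guard = 4 * len(specs) ** 2 + 50
    for _ in range(guard):
        best = None
        best_delta = tol
        for op, u, v in state.candidate_moves():
            d = state.delta(op, u, v)
            if d > best_delta:
                best, best_delta = (op, u, v), d
        if best is None:
            trace.converged = True
            break
        state.apply(*best)
        trace.iterations.append((best[0], (best[1], best[2]), best_delta))
    trace.final_score = state.total_score()
    dag = state.to_dag()
    if restarts > 0:
        import numpy as np
        rng = np.random.default_rng(seed)
        best_dag, best_trace = dag, trace
        for _ in range(restarts):
            st = _SearchState(data, specs, blacklist)
            # random warm start: a few random legal additions
            for _k in range(rng.integers(1, len(specs))):
                adds = [m for m in st.candidate_moves() if m[0] == "add"]
                if not adds:
                    break
                st.apply(*adds[rng.integers(0, len(adds))])
            d2, t2 = hill_climb(data, specs, blacklist, _state=st)
            if t2.final_score > best_trace.final_score + tol:
                best_dag, best_trace = d2, t2
        return best_dag, best_trace
    return dag, trace


def tabu_search(data: MixedDataset, specs: Sequence[VariableSpec] | None = None,
                blacklist: Iterable[Arc] | None = None, tabu_length: int = 10,
                max_worsening_moves: int = 20, seed: int = 0,
                tol: float = _TOL) -> tuple[Dag, SearchTrace]:
    """Hill climbing with a tabu list of recently visited structures.

    The best non-tabu move is taken even when it worsens the score, for up
    to ``max_worsening_moves`` consecutive non-improving steps; the
    best-scoring structure visited is returned.  With
    ``max_worsening_moves=0`` this degenerates to plain hill climbing.
    """
    del seed  # deterministic; kept for interface symmetry
    if tabu_length < 1:
        raise ValueError("tabu_length must be >= 1")
    specs = list(specs) if specs is not None else list(data.specs)
    if blacklist is None:
        blacklist = default_blacklist(specs)
    state = _SearchState(data, specs, blacklist)
    trace = SearchTrace()
    tabu: list[frozenset[Arc]] = [frozenset()]
    best_arcs = frozenset()
    best_score = state.total_score()
    worsening_used = 0
    guard = 4 * len(specs) ** 2 + 50 + max_worsening_moves
    for _ in range(guard):
        current_arcs = frozenset(state.arcs())
        best_move = None
        best_delta = float("-inf")
        for op, u, v in state.candidate_moves():
            if op == "add":
                nxt = current_arcs | {(u, v)}
            elif op == "delete":
                nxt = current_arcs - {(u, v)}
            else:
                nxt = (current_arcs - {(u, v)}) | {(v, u)}
            if nxt in tabu:
                continue
            d = state.delta(op, u, v)
            if d > best_delta + tol:
                best_move, best_delta = (op, u, v), d
        if best_move is None:
            break
        if best_delta <= tol and worsening_used >= max_worsening_moves:
            trace.converged = True
            break
        state.apply(*best_move)
        trace.iterations.append((best_move[0], (best_move[1], best_move[2]),
                                 best_delta))
        tabu.append(frozenset(state.arcs()))
        if len(tabu) > tabu_length:
            tabu.pop(0)
        score = state.total_score()
        if score > best_score + tol:
            best_score = score
            best_arcs = frozenset(state.arcs())
            worsening_used = 0
        else:
            worsening_used += 1
    else:
        trace.converged = False
    trace.final_score = best_score
    return Dag(state.names, best_arcs), trace
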