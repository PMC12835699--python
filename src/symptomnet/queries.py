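"""Conditional-probability queries on a fitted CLG network.

Events are median splits for continuous variables (``<`` / ``>`` the
sample median, strict: ties fall in neither event) or level equality for
discrete variables.  Probabilities are estimated by logic (rejection)
sampling: draw ancestral samples from the fitted network, discard those
violating the evidence, and report the fraction of survivors satisfying
the event with its Monte-Carlo standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .clg import CLGParameters, ContinuousFamily, DiscreteFamily, _config_codes
from .dag import Dag
from .data import MixedDataset

Clause = tuple[str, str, object]  # (variable, relation, reference)


def median_thresholds(data: MixedDataset) -> dict[str, object]:
    """Sample median per continuous variable (mean of the middle two for
    even n); modal level per discrete variable (ties break to level order)."""
    if not data.is_complete():
        raise ValueError("median_thresholds requires complete data")
    out: dict[str, object] = {}
    for s in data.specs:
        col = data.frame[s.name]
        if s.is_continuous:
            out[s.name] = float(np.median(col.to_numpy(dtype=float)))
        else:
            counts = col.value_counts()
            best = max(s.levels, key=lambda lev: (counts.get(lev, 0),
                                                  -s.levels.index(lev)))
            out[s.name] = best
    return out


@dataclass
class QuerySpec:
    event: Clause
    evidence: list[Clause] = field(default_factory=list)
    n_samples: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1000:
            raise ValueError("n_samples must be >= 1000")
        ev_vars = {c[0] for c in self.evidence}
        if self.event[0] in ev_vars:
            raise ValueError("event variable cannot appear in the evidence")
        for var, rel, _ in [self.event, *self.evidence]:
            if rel not in ("<", ">", "="):
                raise ValueError(f"unknown relation {rel!r} for {var!r}")


@dataclass
class QueryResult:
    probability: float
    mc_standard_error: float
    n_effective: int


def _sample_raw(dag: Dag, params: CLGParameters, n: int,
                rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Vectorized ancestral sampling to raw arrays (codes / floats)."""
    disc: dict[str, np.ndarray] = {}
    cont: dict[str, np.ndarray] = {}
    for node in dag.topological_order():
        fam = params[node]
        if isinstance(fam, DiscreteFamily):
            cfg = _config_codes([disc[p] for p in fam.parents],
                                list(fam.parent_levels)) if fam.parents \
                else np.zeros(n, dtype=np.int64)
            u = rng.random(n)
            cum = np.cumsum(fam.cpt, axis=1)
            disc[node] = (u[:, None] > cum[cfg]).sum(axis=1).astype(np.int64)
        else:
            cfg = _config_codes([disc[p] for p in fam.discrete_parents],
                                list(fam.parent_levels)) if fam.discrete_parents \
                else np.zeros(n, dtype=np.int64)
            mu = fam.intercept[cfg].copy()
            for j, p in enumerate(fam.continuous_parents):
                mu += fam.slopes[cfg, j] * cont[p]
            cont[node] = mu + fam.sd[cfg] * rng.standard_normal(n)
    out: dict[str, np.ndarray] = {}
    out.update(cont)
    out.update(disc)
    return out


def _clause_mask(values: dict[str, np.ndarray], params: CLGParameters,
                 clause: Clause) -> np.ndarray:
    var, rel, ref = clause
    fam = params[var]
    x = values[var]
    if rel == "=":
        if not isinstance(fam, DiscreteFamily):
            raise ValueError(f"'=' queries require a discrete variable ({var!r})")
        code = fam.levels.index(ref)
        return x == code
    if isinstance(fam, DiscreteFamily):
        raise ValueError(f"ordinal relation {rel!r} requires a continuous "
                         f"variable ({var!r})")
    return x < float(ref) if rel == "<" else x > float(ref)


def conditional_query(params: CLGParameters, dag: Dag,
                      query: QuerySpec,
                      rng: np.random.Generator | None = None) -> QueryResult:
    """Monte-Carlo estimate of P(event | evidence) by rejection sampling."""
    rng = rng or np.random.default_rng(query.seed)
    values = _sample_raw(dag, params, query.n_samples, rng)
    keep = np.ones(query.n_samples, dtype=bool)
    for clause in query.evidence:
        keep &= _clause_mask(values, params, clause)
    n_eff = int(keep.sum())
    if n_eff == 0:
        raise ValueError("evidence never satisfied: incompatible evidence "
                         "or too few samples")
    event_mask = _clause_mask(values, params, query.event)
    prob = float(event_mask[keep].mean())
    se = float(np.sqrt(prob * (1.0 - prob) / n_eff))
    return QueryResult(probability=prob, mc_standard_error=se, n_effective=n_eff)


def query_battery(params: CLGParameters, dag: Dag, data: MixedDataset,
                  pairs: Sequence[tuple[str, str, str, str]],
                  n_samples: int = 1_000_000, seed: int = 0) -> pd.DataFrame:
    """Run P(variable2 sign2 median | variable1 sign1 median) per pair.

    Signs are ``<`` / ``>`` (continuous, median reference) or ``=``
    (discrete; the reference is the modal level unless given explicitly as
    ``"=level"``).  Medians come from the supplied analysis dataset.
    """
    thresholds = median_thresholds(data)

    def clause(var: str, sign: str) -> Clause:
        if sign.startswith("=") and len(sign) > 1:
            return (var, "=", sign[1:])
        return (var, sign, thresholds[var])

    rows = []
    for i, (v1, s1, v2, s2) in enumerate(pairs):
        if v1 == v2:
            raise ValueError(f"self-pair {v1!r} is not a valid query")
        q = QuerySpec(event=clause(v2, s2), evidence=[clause(v1, s1)],
                      n_samples=n_samples, seed=seed)
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        res = conditional_query(params, dag, q, rng=rng)
        rows.append({"variable1": v1, "sign1": s1, "variable2": v2,
                     "sign2": s2, "probability": res.probability,
                     "mc_standard_error": res.mc_standard_error,
                     "n_effective": res.n_effective})
    return pd.DataFrame(rows)
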