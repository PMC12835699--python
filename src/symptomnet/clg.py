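"""Conditional linear Gaussian (CLG) Bayesian networks.

The joint density factorizes over a DAG: discrete nodes carry multinomial
conditional probability tables indexed by their (discrete) parents'
configurations; each continuous node carries, per discrete-parent
configuration, an ordinary linear regression on its continuous parents with
Gaussian residuals.  Continuous parents of discrete nodes are outside the
family and rejected.

This module provides maximum-likelihood parameter fitting, the joint
log-likelihood, the decomposable BIC network score (log-likelihood scale,
``log L - d/2 * log n``, higher is better), exhaustive DAG enumeration for
small oracles, and vectorized ancestral sampling.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .dag import Arc, Dag
from .data import MixedDataset
from .variables import VariableSpec

_SD_FLOOR = 1e-6
_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class DiscreteFamily:
    """Multinomial CPT of one discrete node given its discrete parents.

    ``cpt`` has shape ``(n_configs, n_levels)``; configuration index is the
    mixed-radix code of the parents' level indices (first parent most
    significant).  Rows sum to one; parent configurations never observed
    get the uniform row.
    """

    parents: tuple[str, ...]
    parent_levels: tuple[int, ...]
    levels: tuple[str, ...]
    cpt: np.ndarray

    def __post_init__(self) -> None:
        self.cpt = np.asarray(self.cpt, dtype=float)
        if self.cpt.shape != (int(np.prod(self.parent_levels, dtype=int)), len(self.levels)):
            raise ValueError("CPT shape mismatch")
        if not np.allclose(self.cpt.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("CPT rows must sum to 1")


@dataclass
class ContinuousFamily:
    """Per-configuration linear-Gaussian family of one continuous node.

    For discrete-parent configuration ``g``:
    ``child = intercept[g] + slopes[g] @ continuous_parents + N(0, sd[g]^2)``.
    """

    discrete_parents: tuple[str, ...]
    parent_levels: tuple[int, ...]
    continuous_parents: tuple[str, ...]
    intercept: np.ndarray
    slopes: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        ncfg = int(np.prod(self.parent_levels, dtype=int))
        self.intercept = np.asarray(self.intercept, dtype=float).reshape(ncfg)
        self.slopes = np.asarray(self.slopes, dtype=float).reshape(
            ncfg, len(self.continuous_parents))
        self.sd = np.asarray(self.sd, dtype=float).reshape(ncfg)
        if np.any(self.sd <= 0):
            raise ValueError("residual sd must be positive")


@dataclass
class CLGParameters:
    """Full parameter set of a CLG network: one family per node."""

    families: dict[str, DiscreteFamily | ContinuousFamily] = field(default_factory=dict)

    def __getitem__(self, node: str):
        return self.families[node]

    def to_json(self) -> str:
        payload = {}
        for node, fam in self.families.items():
            if isinstance(fam, DiscreteFamily):
                payload[node] = {
                    "kind": "discrete",
                    "parents": list(fam.parents),
                    "levels": list(fam.levels),
                    "cpt": fam.cpt.tolist(),
                }
            else:
                payload[node] = {
                    "kind": "continuous",
                    "discrete_parents": list(fam.discrete_parents),
                    "continuous_parents": list(fam.continuous_parents),
                    "intercept": fam.intercept.tolist(),
                    "slopes": fam.slopes.tolist(),
                    "sd": fam.sd.tolist(),
                }
        return json.dumps(payload, indent=2)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


# ---------------------------------------------------------------------------
# encoded data + scoring engine
# ---------------------------------------------------------------------------

def _config_codes(codes: Sequence[np.ndarray], radices: Sequence[int]) -> np.ndarray:
    """Mixed-radix configuration index (first array most significant)."""
    if not codes:
        return np.zeros(0, dtype=np.int64)
    out = np.zeros_like(codes[0], dtype=np.int64)
    for c, r in zip(codes, radices):
        out = out * r + c
    return out


class CLGScorer:
    """Cached per-family log-likelihood / BIC scores for one dataset.

    Encodes the dataset once (discrete columns to integer codes, continuous
    to float arrays) and memoizes family scores keyed by
    ``(child, frozenset(parents))`` — the workhorse behind both
    :func:`bic_score` and the structure search, where the same families are
    re-scored across thousands of candidate moves.
    """

    def __init__(self, data: MixedDataset, specs: Sequence[VariableSpec] | None = None):
        if not data.is_complete():
            raise ValueError("scoring requires complete data (impute first)")
        self.specs = {s.name: s for s in (specs or data.specs)}
        self.n = data.n
        self._log_n = math.log(self.n)
        self._disc: dict[str, np.ndarray] = {}
        self._nlev: dict[str, int] = {}
        self._cont: dict[str, np.ndarray] = {}
        for name, s in self.specs.items():
            col = data.frame[name]
            if s.is_discrete:
                idx = {lev: i for i, lev in enumerate(s.levels)}
                self._disc[name] = np.array([idx[v] for v in col], dtype=np.int64)
                self._nlev[name] = s.n_levels
            else:
                self._cont[name] = col.to_numpy(dtype=float)
        self._cache: dict[tuple[str, frozenset[str]], tuple[float, int]] = {}

    # -- family decomposition -------------------------------------------
    def split_parents(self, parents: Iterable[str]) -> tuple[list[str], list[str]]:
        dpar = sorted(p for p in parents if self.specs[p].is_discrete)
        cpar = sorted(p for p in parents if self.specs[p].is_continuous)
        return dpar, cpar

    def family_loglik_dof(self, child: str, parents: frozenset[str]) -> tuple[float, int]:
        key = (child, parents)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        dpar, cpar = self.split_parents(parents)
        if self.specs[child].is_discrete:
            if cpar:
                raise ValueError(
                    f"discrete node {child!r} cannot have continuous parents")
            out = self._discrete_family(child, dpar)
        else:
            out = self._continuous_family(child, dpar, cpar)
        self._cache[key] = out
        return out

    def family_score(self, child: str, parents: frozenset[str]) -> float:
        ll, dof = self.family_loglik_dof(child, parents)
        return ll - 0.5 * dof * self._log_n

    def _discrete_family(self, child: str, dpar: list[str]) -> tuple[float, int]:
        levels = self._nlev[child]
        radices = [self._nlev[p] for p in dpar]
        ncfg = int(np.prod(radices, dtype=int)) if dpar else 1
        cfg = _config_codes([self._disc[p] for p in dpar], radices) if dpar else \
            np.zeros(self.n, dtype=np.int64)
        counts = np.bincount(cfg * levels + self._disc[child],
                             minlength=ncfg * levels).reshape(ncfg, levels)
        row = counts.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = np.log(counts / row[:, None])
        mask = counts > 0
        ll = float((counts[mask] * logp[mask]).sum())
        dof = (levels - 1) * ncfg
        return ll, dof

    def _continuous_family(self, child: str, dpar: list[str],
                           cpar: list[str]) -> tuple[float, int]:
        y = self._cont[child]
        radices = [self._nlev[p] for p in dpar]
        ncfg = int(np.prod(radices, dtype=int)) if dpar else 1
        k = len(cpar)
        dof = ncfg * (k + 2)  # intercept + slopes + variance per config
        if dpar:
            cfg = _config_codes([self._disc[p] for p in dpar], radices)
        else:
            cfg = np.zeros(self.n, dtype=np.int64)
        X = np.empty((self.n, k + 1))
        X[:, 0] = 1.0
        for j, p in enumerate(cpar):
            X[:, j + 1] = self._cont[p]
        ll = 0.0
        if ncfg == 1:
            ll = _gauss_family_ll(X, y)
        else:
            order = np.argsort(cfg, kind="stable")
            cfg_sorted = cfg[order]
            bounds = np.searchsorted(cfg_sorted, np.arange(ncfg + 1))
            for g in range(ncfg):
                rows = order[bounds[g]:bounds[g + 1]]
                if rows.size == 0:
                    continue  # empty configuration: no data term, dof still counted
                ll += _gauss_family_ll(X[rows], y[rows])
        return ll, dof


def _gauss_family_ll(X: np.ndarray, y: np.ndarray) -> float:
    """ML Gaussian regression log-likelihood of one configuration block."""
    m = y.size
    if m == 0:
        return 0.0
    xtx = X.T @ X
    xty = X.T @ y
    try:
        beta = np.linalg.solve(xtx, xty)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ beta
    sigma2 = max(float(resid @ resid) / m, _SD_FLOOR ** 2)
    return -0.5 * m * (_LOG2PI + math.log(sigma2)) - float(resid @ resid) / (2 * sigma2)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def fit_parameters(dag: Dag, data: MixedDataset) -> CLGParameters:
    """Maximum-likelihood CLG parameters of ``dag`` on complete data.

    Discrete nodes: empirical conditional frequencies (zero smoothing);
    never-observed parent configurations get the uniform row.  Continuous
    nodes: per discrete-parent configuration, ordinary least squares on the
    continuous parents with ML residual variance (denominator = block
    count); a singular design raises.
    """
    if not data.is_complete():
        raise ValueError("fit_parameters requires complete data")
    specs = {s.name: s for s in data.specs}
    for node in dag.nodes:
        if node not in specs:
            raise ValueError(f"dag node {node!r} absent from data")
    scorer = CLGScorer(data)
    params = CLGParameters()
    psets = dag.parent_sets()
    for node in dag.nodes:
        s = specs[node]
        dpar, cpar = scorer.split_parents(psets[node])
        radices = tuple(scorer._nlev[p] for p in dpar)
        ncfg = int(np.prod(radices, dtype=int)) if dpar else 1
        if dpar:
            cfg = _config_codes([scorer._disc[p] for p in dpar], list(radices))
        else:
            cfg = np.zeros(data.n, dtype=np.int64)
        if s.is_discrete:
            if cpar:
                raise ValueError(f"discrete node {node!r} has continuous parents")
            L = s.n_levels
            counts = np.bincount(cfg * L + scorer._disc[node],
                                 minlength=ncfg * L).reshape(ncfg, L).astype(float)
            row = counts.sum(axis=1)
            cpt = np.full((ncfg, L), 1.0 / L)
            seen = row > 0
            cpt[seen] = counts[seen] / row[seen, None]
            params.families[node] = DiscreteFamily(tuple(dpar), radices, s.levels, cpt)
        else:
            k = len(cpar)
            X = np.empty((data.n, k + 1))
            X[:, 0] = 1.0
            for j, p in enumerate(cpar):
                X[:, j + 1] = scorer._cont[p]
            y = scorer._cont[node]
            # collinear continuous parents are a degenerate design
            if np.linalg.matrix_rank(X.T @ X) < k + 1:
                raise np.linalg.LinAlgError(
                    f"singular regression design for node {node!r} "
                    f"(collinear parents)")
            intercept = np.zeros(ncfg)
            slopes = np.zeros((ncfg, k))
            sd = np.ones(ncfg)
            for g in range(ncfg):
                rows = np.flatnonzero(cfg == g)
                if rows.size == 0:
                    continue  # uniform fallback: N(0, 1), slopes 0
                Xg, yg = X[rows], y[rows]
                xtx = Xg.T @ Xg
                if rows.size <= k or np.linalg.matrix_rank(xtx) < k + 1:
                    # sparse configuration: minimum-norm least squares
                    beta = np.linalg.lstsq(Xg, yg, rcond=None)[0]
                else:
                    beta = np.linalg.solve(xtx, Xg.T @ yg)
                resid = yg - Xg @ beta
                sigma2 = float(resid @ resid) / rows.size
                if sigma2 < _SD_FLOOR ** 2:
                    warnings.warn(
                        f"residual sd of {node!r} floored at {_SD_FLOOR}",
                        RuntimeWarning, stacklevel=2)
                    sigma2 = _SD_FLOOR ** 2
                intercept[g] = beta[0]
                slopes[g] = beta[1:]
                sd[g] = math.sqrt(sigma2)
            params.families[node] = ContinuousFamily(
                tuple(dpar), radices, tuple(cpar), intercept, slopes, sd)
    return params


def log_likelihood(params: CLGParameters, dag: Dag, data: MixedDataset) -> float:
    """Joint log-likelihood of complete data under the CLG factorization.

    Returns ``-inf`` as soon as any record lands on a zero-probability CPT
    cell.
    """
    if not data.is_complete():
        raise ValueError("log_likelihood requires complete data")
    specs = {s.name: s for s in data.specs}
    total = 0.0
    psets = dag.parent_sets()
    for node in dag.nodes:
        fam = params[node]
        if isinstance(fam, DiscreteFamily):
            idx = {lev: i for i, lev in enumerate(fam.levels)}
            codes = np.array([idx[v] for v in data.frame[node]], dtype=np.int64)
            pcodes = []
            for p in fam.parents:
                plev = {lev: i for i, lev in enumerate(specs[p].levels)}
                pcodes.append(np.array([plev[v] for v in data.frame[p]], dtype=np.int64))
            cfg = _config_codes(pcodes, list(fam.parent_levels)) if fam.parents \
                else np.zeros(data.n, dtype=np.int64)
            probs = fam.cpt[cfg, codes]
            if np.any(probs <= 0):
                return float("-inf")
            total += float(np.log(probs).sum())
        else:
            y = data.frame[node].to_numpy(dtype=float)
            pcodes = []
            for p in fam.discrete_parents:
                plev = {lev: i for i, lev in enumerate(specs[p].levels)}
                pcodes.append(np.array([plev[v] for v in data.frame[p]], dtype=np.int64))
            cfg = _config_codes(pcodes, list(fam.parent_levels)) if fam.discrete_parents \
                else np.zeros(data.n, dtype=np.int64)
            mu = fam.intercept[cfg]
            for j, p in enumerate(fam.continuous_parents):
                mu = mu + fam.slopes[cfg, j] * data.frame[p].to_numpy(dtype=float)
            sd = fam.sd[cfg]
            z = (y - mu) / sd
            total += float((-0.5 * z * z - np.log(sd) - 0.5 * _LOG2PI).sum())
    del psets
    return total


@dataclass
class NetworkScore:
    total: float
    per_node: dict[str, float]


def bic_score(dag: Dag, data: MixedDataset,
              scorer: CLGScorer | None = None) -> NetworkScore:
    """Decomposable BIC network score, ``log L - d/2 log n`` (maximized)."""
    if data.n < 2:
        raise ValueError("BIC requires n >= 2")
    scorer = scorer or CLGScorer(data)
    per_node = {}
    for node, parents in dag.parent_sets().items():
        per_node[node] = scorer.family_score(node, parents)
    return NetworkScore(total=float(sum(per_node.values())), per_node=per_node)


def enumerate_dags(specs: Sequence[VariableSpec],
                   blacklist: Iterable[Arc] = ()) -> Iterator[Dag]:
    """Yield every labelled DAG on the given nodes avoiding blacklisted arcs.

    Exhaustive (3^(p choose 2) orientation assignments filtered for
    acyclicity); guarded to at most 6 nodes.
    """
    names = [s.name for s in specs]
    if len(names) > 6:
        raise ValueError("enumerate_dags is limited to 6 nodes")
    bl = {tuple(a) for a in blacklist}
    pairs = list(itertools.combinations(names, 2))
    # per-pair admissible states: absent / forward / backward
    states = []
    for u, v in pairs:
        opts: list[tuple[Arc, ...]] = [()]
        if (u, v) not in bl:
            opts.append(((u, v),))
        if (v, u) not in bl:
            opts.append(((v, u),))
        states.append(opts)
    for combo in itertools.product(*states):
        arcs = [a for opt in combo for a in opt]
        try:
            yield Dag(names, arcs)
        except ValueError:
            continue


# ---------------------------------------------------------------------------
# ancestral sampling
# ---------------------------------------------------------------------------

def ancestral_sample(dag: Dag, params: CLGParameters,
                     specs: Sequence[VariableSpec], n: int,
                     rng: np.random.Generator) -> MixedDataset:
    """Draw ``n`` joint samples by forward sampling in topological order."""
    import pandas as pd

    if n < 1:
        raise ValueError("n must be >= 1")
    spec_map = {s.name: s for s in specs}
    order = dag.topological_order()  # raises on cycles via Dag invariant
    disc_codes: dict[str, np.ndarray] = {}
    cont_vals: dict[str, np.ndarray] = {}
    for node in order:
        fam = params[node]
        if isinstance(fam, DiscreteFamily):
            cfg = _config_codes([disc_codes[p] for p in fam.parents],
                                list(fam.parent_levels)) if fam.parents \
                else np.zeros(n, dtype=np.int64)
            u = rng.random(n)
            cum = np.cumsum(fam.cpt, axis=1)
            disc_codes[node] = (u[:, None] > cum[cfg]).sum(axis=1).astype(np.int64)
        else:
            cfg = _config_codes([disc_codes[p] for p in fam.discrete_parents],
                                list(fam.parent_levels)) if fam.discrete_parents \
                else np.zeros(n, dtype=np.int64)
            mu = fam.intercept[cfg].copy()
            for j, p in enumerate(fam.continuous_parents):
                mu += fam.slopes[cfg, j] * cont_vals[p]
            cont_vals[node] = mu + fam.sd[cfg] * rng.standard_normal(n)
    cols = {}
    for s in specs:
        if s.name in disc_codes:
            levels = np.array(spec_map[s.name].levels, dtype=object)
            cols[s.name] = levels[disc_codes[s.name]]
        else:
            cols[s.name] = cont_vals[s.name]
    return MixedDataset(pd.DataFrame(cols, columns=[s.name for s in specs]),
                        list(specs))
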