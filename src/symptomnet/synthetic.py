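"""Synthetic CATIE-like data generation from a known CLG ground truth.

The generator emulates the structure of the CATIE schizophrenia baseline
sample: 21 variables (six discrete demographics, fifteen continuous scale
scores), n on the order of 1450, roughly 2.4% missing cells plus a handful
of rows with more than half their cells missing.  The ground-truth DAG and
standardized coefficients mirror the published symptom network (processing
speed driving the other cognitive domains, negative symptoms and quality of
life; PANSS general driving negative and positive subscales; employment,
depression, drug attitude and illness severity feeding quality of life).

Continuous variables are generated on a standardized scale: residual
variances are solved so that every continuous node has unit marginal
variance at ``effect_scale=1``, which makes each arc's annotated
coefficient equal the population standardized regression coefficient —
the property the parameter-recovery tests rely on.  Discrete parents act
on continuous children through unit-variance centred level scores, so the
same equality holds for integer-coded discrete predictors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .clg import (CLGParameters, ContinuousFamily, DiscreteFamily,
                  ancestral_sample)
from .dag import Arc, Dag
from .data import MixedDataset
from .variables import VariableSpec, catie_roster


@dataclass
class GroundTruthNetwork:
    dag: Dag
    params: CLGParameters
    specs: list[VariableSpec]
    coefficient_annotations: dict[Arc, float] = field(default_factory=dict)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.dag.write_graphml(directory / "truth.graphml")
        self.params.save(directory / "truth_params.json")
        (directory / "truth_annotations.json").write_text(json.dumps(
            {f"{u}->{v}": b for (u, v), b in sorted(self.coefficient_annotations.items())},
            indent=2))


@dataclass
class GeneratorConfig:
    """Synthetic study conditions.

    Defaults mirror the emulated study: 1450 analyzable participants,
    2.4% missing cells, ten rows with more than half their cells missing
    (the rows the row filter is meant to remove), unit effect scale.
    """

    n: int = 1450
    seed: int = 0
    missing_rate: float = 0.024
    n_bad_rows: int = 10
    effect_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        if not (0.0 <= self.missing_rate < 0.5):
            raise ValueError("missing_rate must lie in [0, 0.5)")
        if not (0 <= self.n_bad_rows < self.n):
            raise ValueError("n_bad_rows must be in [0, n)")
        if self.effect_scale < 0:
            raise ValueError("effect_scale must be nonnegative")


# ---------------------------------------------------------------------------
# ground-truth construction
# ---------------------------------------------------------------------------

# Root / conditional level probabilities for the six demographics.
# Marginals track the published sample: 74.4% male, 60.2/34.9/2.3% racial
# identification, 59.6% never married, 84.9% not working, age distribution
# implied by mean 40.5 (s.d. 11.1) cut at 30 and 45 years.
_CPTS: dict[str, tuple[tuple[str, ...], list[list[float]]]] = {
    "age_category": ((), [[0.17, 0.49, 0.34]]),
    "sex": ((), [[0.744, 0.256]]),
    "race": ((), [[0.602, 0.349, 0.023, 0.026]]),
    "marital_status": (("sex",), [[0.64, 0.36],
                                  [0.47, 0.53]]),
    "education": (("race",), [[0.26, 0.45, 0.29],
                              [0.36, 0.46, 0.18],
                              [0.25, 0.40, 0.35],
                              [0.33, 0.44, 0.23]]),
    "employment": ((), [[0.151, 0.849]]),
}

# Standardized ground-truth path coefficients (parent, child) -> beta.
# Published values where the source reports them; remaining supports chosen
# once to keep the network connected and the effect sizes clinically
# plausible (see docs/methods.md).
_COEFFS: dict[Arc, float] = {
    ("matrics_processing_speed", "matrics_verbal"): 0.50,
    ("matrics_processing_speed", "matrics_vigilance"): 0.55,
    ("matrics_processing_speed", "matrics_reasoning"): 0.45,
    ("matrics_processing_speed", "matrics_working_memory"): 0.55,
    ("matrics_working_memory", "matrics_vigilance"): 0.20,
    ("matrics_working_memory", "matrics_reasoning"): 0.25,
    ("matrics_processing_speed", "panss_negative"): -0.25,
    ("matrics_working_memory", "panss_general"): -0.14,
    ("panss_general", "panss_negative"): 0.61,
    ("panss_general", "panss_positive"): 0.64,
    ("cdss_total", "panss_general"): 0.35,
    ("cdss_total", "panss_negative"): -0.14,
    ("panss_positive", "cgi_severity"): 0.45,
    ("cdss_total", "cgi_drug"): 0.20,
    ("panss_positive", "cgi_drug"): 0.15,
    ("cgi_alcohol", "panss_negative"): -0.10,
    ("dai_total", "itaq_total"): 0.30,
    ("dai_total", "qol_total"): 0.10,
    ("cdss_total", "qol_total"): -0.10,
    ("cgi_severity", "qol_total"): -0.12,
    ("panss_negative", "qol_total"): -0.33,
    ("matrics_processing_speed", "qol_total"): 0.12,
    ("employment", "qol_total"): -0.32,
    ("age_category", "matrics_processing_speed"): -0.15,
    ("education", "matrics_working_memory"): 0.15,
}

_DISCRETE_ARCS: tuple[Arc, ...] = (("sex", "marital_status"), ("race", "education"))


def _discrete_marginals(specs: Mapping[str, VariableSpec]) -> dict[str, np.ndarray]:
    """Exact level marginals of the discrete layer.

    Valid because every discrete node here has at most one discrete parent
    and parents of distinct nodes are independent.
    """
    marg: dict[str, np.ndarray] = {}
    pending = dict(_CPTS)
    while pending:
        for name in list(pending):
            parents, rows = pending[name]
            if all(p in marg for p in parents):
                cpt = np.asarray(rows, dtype=float)
                if parents:
                    w = marg[parents[0]]
                    marg[name] = w @ cpt
                else:
                    marg[name] = cpt[0]
                del pending[name]
    return marg


def _level_zscores(probs: np.ndarray) -> np.ndarray:
    """Centred unit-variance scores of integer level codes 0..L-1."""
    codes = np.arange(len(probs), dtype=float)
    mu = float(probs @ codes)
    var = float(probs @ codes ** 2) - mu ** 2
    return (codes - mu) / math.sqrt(var)


def make_catie_like_truth(seed: int = 0, effect_scale: float = 1.0) -> GroundTruthNetwork:
    """Build the 21-node CATIE-like ground-truth CLG network.

    ``effect_scale`` multiplies every ground-truth coefficient (continuous
    slopes and discrete-level effects alike); residual standard deviations
    are solved at unit scale and kept fixed, so scale 0 yields independent
    standard-normal continuous variables.  ``seed`` is accepted for
    interface symmetry; the truth itself is deterministic.
    """
    del seed  # the ground truth is a fixed population model
    if effect_scale < 0:
        raise ValueError("effect_scale must be nonnegative")
    specs = catie_roster()
    spec_map = {s.name: s for s in specs}
    arcs = list(_COEFFS.keys()) + list(_DISCRETE_ARCS)
    dag = Dag([s.name for s in specs], arcs)
    for u, v in dag.arcs:  # blacklist invariant
        if spec_map[u].is_continuous and spec_map[v].is_discrete:
            raise AssertionError("ground truth violates the blacklist")

    marginals = _discrete_marginals(spec_map)
    zscores = {name: _level_zscores(m) for name, m in marginals.items()}

    # Exact covariance of the predictor set at unit effect scale, treating
    # each discrete parent's level score as an exogenous unit-variance
    # variable independent of the others (true for this layout: the
    # discrete variables feeding continuous nodes have independent
    # ancestries).
    params = CLGParameters()
    for name, (parents, rows) in _CPTS.items():
        plev = tuple(spec_map[p].n_levels for p in parents)
        params.families[name] = DiscreteFamily(
            parents, plev, spec_map[name].levels, np.asarray(rows, dtype=float))

    cont_nodes = [s.name for s in specs if s.is_continuous]
    predictors: list[str] = []  # continuous node names and "z:<discrete>" labels
    cov: dict[tuple[str, str], float] = {}

    def get_cov(a: str, b: str) -> float:
        return cov.get((a, b), cov.get((b, a), 0.0))

    def add_predictor(label: str, parent_terms: list[tuple[str, float]]) -> float:
        """Register a predictor as a linear blend + residual; returns the
        residual variance solving for unit marginal variance."""
        explained = 0.0
        for (pa, ba) in parent_terms:
            for (pb, bb) in parent_terms:
                explained += ba * bb * get_cov(pa, pb)
        resid = 1.0 - explained
        if resid <= 0:
            raise ValueError(f"ground-truth coefficients of {label} imply "
                             f"non-positive residual variance ({resid:.3f})")
        for other in predictors:
            c = sum(b * get_cov(p, other) for p, b in parent_terms)
            cov[(label, other)] = c
        cov[(label, label)] = 1.0
        predictors.append(label)
        return resid

    # discrete z-predictors are exogenous unit-variance
    for dname in ("age_category", "education", "employment"):
        cov[(f"z:{dname}", f"z:{dname}")] = 1.0
        predictors.append(f"z:{dname}")

    order = dag.topological_order()
    resid_var: dict[str, float] = {}
    for node in order:
        if node not in cont_nodes:
            continue
        terms = []
        for (u, v), b in _COEFFS.items():
            if v != node:
                continue
            label = f"z:{u}" if spec_map[u].is_discrete else u
            terms.append((label, b))
        resid_var[node] = add_predictor(node, terms)

    annotations: dict[Arc, float] = {}
    for node in cont_nodes:
        dpar = sorted(u for (u, v) in _COEFFS if v == node and spec_map[u].is_discrete)
        cpar = sorted(u for (u, v) in _COEFFS if v == node and spec_map[u].is_continuous)
        plev = tuple(spec_map[p].n_levels for p in dpar)
        ncfg = int(np.prod(plev, dtype=int)) if dpar else 1
        intercept = np.zeros(ncfg)
        if dpar:
            grids = np.meshgrid(*[np.arange(L) for L in plev], indexing="ij")
            flat = [g.ravel() for g in grids]
            for j, p in enumerate(dpar):
                beta = _COEFFS[(p, node)] * effect_scale
                intercept += beta * zscores[p][flat[j]]
        slopes = np.array([[_COEFFS[(p, node)] * effect_scale for p in cpar]] * ncfg)
        slopes = slopes.reshape(ncfg, len(cpar))
        sd = np.full(ncfg, math.sqrt(resid_var[node]))
        params.families[node] = ContinuousFamily(
            tuple(dpar), plev, tuple(cpar), intercept, slopes, sd)
        for p in dpar + cpar:
            annotations[(p, node)] = _COEFFS[(p, node)] * effect_scale
    return GroundTruthNetwork(dag=dag, params=params, specs=specs,
                              coefficient_annotations=annotations)


# ---------------------------------------------------------------------------
# sampling and missingness
# ---------------------------------------------------------------------------

def sample_dataset(net: GroundTruthNetwork, n: int, seed: int = 0) -> MixedDataset:
    """Ancestral sampling of ``n`` complete records from the ground truth."""
    rng = np.random.default_rng(seed)
    return ancestral_sample(net.dag, net.params, net.specs, n, rng)


def inject_missingness(data: MixedDataset, config: GeneratorConfig) -> MixedDataset:
    """Plant MCAR missingness plus ``n_bad_rows`` heavily incomplete rows.

    Ordinary rows lose cells independently at ``missing_rate``; each
    designated bad row loses strictly more than half of its cells (so the
    row-missingness filter removes exactly those rows).  Deterministic
    given ``config.seed``.
    """
    if not data.is_complete():
        raise ValueError("inject_missingness expects complete data")
    out = data.copy()
    n, p = out.n, len(out.columns)
    if config.missing_rate == 0.0 and config.n_bad_rows == 0:
        return out
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 911]))
    bad_rows = rng.choice(n, size=config.n_bad_rows, replace=False) if config.n_bad_rows else np.array([], dtype=int)
    bad_set = set(bad_rows.tolist())
    mask = rng.random((n, p)) < config.missing_rate
    mask[list(bad_set), :] = False
    lo = p // 2 + 1  # strictly more than half
    for r in bad_rows:
        k = int(rng.integers(lo, min(p, lo + 5) + 1))
        cols = rng.choice(p, size=k, replace=False)
        mask[r, cols] = True
    frame = out.frame.copy()
    for j, name in enumerate(out.columns):
        col_mask = mask[:, j]
        if col_mask.any():
            frame.loc[frame.index[col_mask], name] = np.nan
    return MixedDataset(frame, list(out.specs))


def generate(config: GeneratorConfig,
             truth: GroundTruthNetwork | None = None) -> tuple[MixedDataset, GroundTruthNetwork]:
    """Convenience: build the default truth, sample, inject missingness."""
    truth = truth or make_catie_like_truth(seed=config.seed,
                                           effect_scale=config.effect_scale)
    complete = sample_dataset(truth, config.n, seed=config.seed)
    return inject_missingness(complete, config), truth
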