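import numpy as np
import pandas as pd
import pytest

from symptomnet import (Dag, GeneratorConfig, MixedDataset, VariableSpec,
                        make_catie_like_truth, sample_dataset)
from symptomnet.clg import CLGParameters, ContinuousFamily, DiscreteFamily


@pytest.fixture(scope="session")
def truth():
    return make_catie_like_truth(seed=0, effect_scale=1.0)


@pytest.fixture(scope="session")
def catie_sample(truth):
    """One complete CATIE-like sample at the emulated study size."""
    return sample_dataset(truth, 1450, seed=42)


def continuous_specs(*names):
    return [VariableSpec(n, "continuous") for n in names]


def gaussian_chain_net(slopes=(0.8, 0.8), sds=(1.0, 0.6, 0.6)):
    """X -> Y -> Z linear-Gaussian chain."""
    specs = continuous_specs("X", "Y", "Z")
    dag = Dag(["X", "Y", "Z"], [("X", "Y"), ("Y", "Z")])
    params = CLGParameters()
    params.families["X"] = ContinuousFamily((), (), (), [0.0], [[]], [sds[0]])
    params.families["Y"] = ContinuousFamily((), (), ("X",), [0.0],
                                            [[slopes[0]]], [sds[1]])
    params.families["Z"] = ContinuousFamily((), (), ("Y",), [0.0],
                                            [[slopes[1]]], [sds[2]])
    return dag, params, specs


def bivariate_net(rho):
    """X -> Y with standard-normal marginals and correlation rho."""
    specs = continuous_specs("X", "Y")
    dag = Dag(["X", "Y"], [("X", "Y")] if rho != 0 else [])
    params = CLGParameters()
    params.families["X"] = ContinuousFamily((), (), (), [0.0], [[]], [1.0])
    if rho != 0:
        params.families["Y"] = ContinuousFamily(
            (), (), ("X",), [0.0], [[rho]], [np.sqrt(1 - rho ** 2)])
    else:
        params.families["Y"] = ContinuousFamily((), (), (), [0.0], [[]], [1.0])
    return dag, params, specs


def chain_dataset(n=2000, seed=0, slopes=(0.8, 0.8)):
    from symptomnet.clg import ancestral_sample
    dag, params, specs = gaussian_chain_net(slopes=slopes)
    rng = np.random.default_rng(seed)
    return ancestral_sample(dag, params, specs, n, rng), specs


def independent_dataset(n=2000, seed=0, names=("A", "B", "C", "D")):
    rng = np.random.default_rng(seed)
    specs = continuous_specs(*names)
    frame = pd.DataFrame({nm: rng.standard_normal(n) for nm in names})
    return MixedDataset(frame, specs), specs


def random_clg_problem(seed, n_disc=2, n_cont=2):
    """A random small mixed CLG ground truth for search oracles."""
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_disc):
        specs.append(VariableSpec(f"D{i}", "discrete", ("a", "b")))
    for i in range(n_cont):
        specs.append(VariableSpec(f"C{i}", "continuous"))
    names = [s.name for s in specs]
    kind = {s.name: s.kind for s in specs}
    arcs = []
    for i, u in enumerate(names):
        for v in names[i + 1:]:
            if kind[u] == "continuous" and kind[v] == "discrete":
                continue
            if rng.random() < 0.5:
                arcs.append((u, v))
    dag = Dag(names, arcs)
    params = CLGParameters()
    psets = dag.parent_sets()
    for s in specs:
        dpar = tuple(sorted(p for p in psets[s.name] if kind[p] == "discrete"))
        cpar = tuple(sorted(p for p in psets[s.name] if kind[p] == "continuous"))
        plev = tuple(2 for _ in dpar)
        ncfg = int(np.prod(plev)) if dpar else 1
        if s.is_discrete:
            probs = rng.uniform(0.2, 0.8, size=ncfg)
            cpt = np.column_stack([probs, 1 - probs])
            params.families[s.name] = DiscreteFamily(dpar, plev, s.levels, cpt)
        else:
            coef = rng.uniform(0.4, 0.9, size=len(cpar)) * rng.choice([-1, 1], len(cpar))
            intercept = rng.uniform(-0.5, 0.5, size=ncfg)
            slopes = np.tile(coef, (ncfg, 1)).reshape(ncfg, len(cpar))
            sd = np.full(ncfg, 1.0)
            params.families[s.name] = ContinuousFamily(dpar, plev, cpar,
                                                       intercept, slopes, sd)
    return dag, params, specs
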