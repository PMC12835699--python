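"""CLG parameter MLE, log-likelihood, BIC score, DAG enumeration."""

import math

import numpy as np
import pandas as pd
import pytest

from symptomnet import (Dag, MixedDataset, VariableSpec, bic_score,
                        enumerate_dags, fit_parameters, log_likelihood)
from symptomnet.clg import CLGScorer, ancestral_sample

from conftest import bivariate_net, continuous_specs, independent_dataset


class TestFitParameters:
    def test_root_binary_cpt_is_empirical_frequency(self):
        specs = [VariableSpec("g", "discrete", ("a", "b"))]
        frame = pd.DataFrame({"g": ["a"] * 744 + ["b"] * 256})
        params = fit_parameters(Dag(["g"]), MixedDataset(frame, specs))
        np.testing.assert_allclose(params["g"].cpt, [[0.744, 0.256]])

    def test_root_continuous_mean_and_ml_sd(self):
        specs = continuous_specs("x")
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        params = fit_parameters(Dag(["x"]),
                                MixedDataset(pd.DataFrame({"x": vals}), specs))
        fam = params["x"]
        assert fam.intercept[0] == pytest.approx(vals.mean())
        assert fam.sd[0] == pytest.approx(vals.std(ddof=0))

    def test_slope_recovery(self):
        dag, params, specs = bivariate_net(0.5)
        rng = np.random.default_rng(31)
        d = ancestral_sample(dag, params, specs, 50_000, rng)
        fit = fit_parameters(Dag(["X", "Y"], [("X", "Y")]), d)
        assert fit["Y"].slopes[0, 0] == pytest.approx(0.5, abs=0.02)

    def test_missing_data_rejected(self):
        specs = continuous_specs("x")
        ds = MixedDataset(pd.DataFrame({"x": [1.0, np.nan]}), specs)
        with pytest.raises(ValueError):
            fit_parameters(Dag(["x"]), ds)

    def test_collinear_parents_raise(self):
        specs = continuous_specs("a", "b", "y")
        rng = np.random.default_rng(32)
        a = rng.standard_normal(100)
        frame = pd.DataFrame({"a": a, "b": 2 * a, "y": rng.standard_normal(100)})
        dag = Dag(["a", "b", "y"], [("a", "y"), ("b", "y")])
        with pytest.raises(np.linalg.LinAlgError):
            fit_parameters(dag, MixedDataset(frame, specs))


class TestLogLikelihood:
    def test_standard_normal_closed_form(self):
        specs = continuous_specs("x")
        ds = MixedDataset(pd.DataFrame({"x": [0.0, 1.0]}), specs)
        dag = Dag(["x"])
        from symptomnet.clg import CLGParameters, ContinuousFamily
        params = CLGParameters()
        params.families["x"] = ContinuousFamily((), (), (), [0.0], [[]], [1.0])
        one = MixedDataset(pd.DataFrame({"x": [0.0]}), specs)
        assert log_likelihood(params, dag, one) == pytest.approx(
            -0.5 * math.log(2 * math.pi))

    def test_factorization_identity(self, truth, catie_sample):
        """Joint log-likelihood equals the sum of per-node family terms."""
        params = fit_parameters(truth.dag, catie_sample)
        total = log_likelihood(params, truth.dag, catie_sample)
        scorer = CLGScorer(catie_sample)
        by_family = sum(
            scorer.family_loglik_dof(node, ps)[0]
            for node, ps in truth.dag.parent_sets().items())
        assert total == pytest.approx(by_family, rel=1e-9)

    def test_complete_discrete_graph_matches_saturated_table(self):
        rng = np.random.default_rng(33)
        specs = [VariableSpec("u", "discrete", ("a", "b")),
                 VariableSpec("v", "discrete", ("c", "d"))]
        frame = pd.DataFrame({
            "u": rng.choice(["a", "b"], 500),
            "v": rng.choice(["c", "d"], 500)})
        ds = MixedDataset(frame, specs)
        dag = Dag(["u", "v"], [("u", "v")])
        params = fit_parameters(dag, ds)
        ll = log_likelihood(params, dag, ds)
        # saturated empirical log-likelihood of the 2x2 contingency table
        counts = pd.crosstab(frame["u"], frame["v"]).to_numpy().ravel()
        saturated = float(sum(c * math.log(c / 500) for c in counts if c))
        assert ll == pytest.approx(saturated, rel=1e-10)


class TestBicScore:
    def test_empty_graph_is_sum_of_marginals(self, catie_sample):
        dag = Dag([s.name for s in catie_sample.specs])
        score = bic_score(dag, catie_sample)
        scorer = CLGScorer(catie_sample)
        expected = sum(scorer.family_score(s.name, frozenset())
                       for s in catie_sample.specs)
        assert score.total == pytest.approx(expected, abs=1e-8)
        assert score.total == pytest.approx(sum(score.per_node.values()), abs=1e-8)

    def test_adding_arc_changes_only_child_family(self, catie_sample):
        nodes = [s.name for s in catie_sample.specs]
        empty = Dag(nodes)
        one = Dag(nodes, [("cdss_total", "qol_total")])
        s0 = bic_score(empty, catie_sample)
        s1 = bic_score(one, catie_sample)
        for node in nodes:
            if node != "qol_total":
                assert s1.per_node[node] == pytest.approx(s0.per_node[node],
                                                          abs=1e-10)

    def test_true_arc_beats_empty_graph(self):
        dag, params, specs = bivariate_net(0.8)
        rng = np.random.default_rng(34)
        d = ancestral_sample(dag, params, specs, 2000, rng)
        with_arc = bic_score(Dag(["X", "Y"], [("X", "Y")]), d).total
        empty = bic_score(Dag(["X", "Y"]), d).total
        assert with_arc > empty

    def test_true_graph_beats_empty_across_seeds(self):
        """BIC consistency: the generating structure wins at n=2000."""
        wins = 0
        for seed in range(20):
            dag, params, specs = bivariate_net(0.5)
            rng = np.random.default_rng(1000 + seed)
            d = ancestral_sample(dag, params, specs, 2000, rng)
            if bic_score(dag, d).total > bic_score(Dag(["X", "Y"]), d).total:
                wins += 1
        assert wins >= 19


class TestEnumerateDags:
    @pytest.mark.parametrize("n_nodes,expected", [(2, 3), (3, 25)])
    def test_labelled_dag_counts(self, n_nodes, expected):
        specs = continuous_specs(*[f"v{i}" for i in range(n_nodes)])
        assert sum(1 for _ in enumerate_dags(specs)) == expected

    def test_blacklist_respected(self):
        specs = [VariableSpec("D", "discrete", ("a", "b")),
                 VariableSpec("C", "continuous")]
        dags = list(enumerate_dags(specs, blacklist={("C", "D")}))
        assert len(dags) == 2
        for d in dags:
            assert ("C", "D") not in d.arcs

    def test_guard_against_large_spaces(self):
        specs = continuous_specs(*[f"v{i}" for i in range(7)])
        with pytest.raises(ValueError):
            next(enumerate_dags(specs))

    def test_complete_dag_maximizes_unpenalized_likelihood(self):
        d, _ = independent_dataset(n=200, seed=35, names=("A", "B", "C"))
        scorer = CLGScorer(d)

        def loglik(dag):
            return sum(scorer.family_loglik_dof(v, ps)[0]
                       for v, ps in dag.parent_sets().items())

        best = max(loglik(g) for g in enumerate_dags(d.specs))
        complete = Dag(["A", "B", "C"], [("A", "B"), ("A", "C"), ("B", "C")])
        assert loglik(complete) == pytest.approx(best, abs=1e-6)
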