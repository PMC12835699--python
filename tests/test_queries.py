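"""Median thresholds and Monte-Carlo conditional probability queries."""

import numpy as np
import pandas as pd
import pytest

from symptomnet import (Dag, MixedDataset, QuerySpec, VariableSpec,
                        conditional_query, fit_parameters, median_thresholds,
                        query_battery)

from conftest import bivariate_net


class TestMedianThresholds:
    def test_even_n_mean_of_middle_two(self):
        specs = [VariableSpec("x", "continuous")]
        ds = MixedDataset(pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]}), specs)
        assert median_thresholds(ds)["x"] == 2.5

    def test_single_value(self):
        specs = [VariableSpec("x", "continuous")]
        ds = MixedDataset(pd.DataFrame({"x": [5.0]}), specs)
        assert median_thresholds(ds)["x"] == 5.0

    def test_odd_n_middle_order_statistic(self):
        rng = np.random.default_rng(90)
        vals = rng.standard_normal(101)
        specs = [VariableSpec("x", "continuous")]
        ds = MixedDataset(pd.DataFrame({"x": vals}), specs)
        assert median_thresholds(ds)["x"] == float(np.sort(vals)[50])

    def test_discrete_mode(self):
        specs = [VariableSpec("g", "discrete", ("a", "b"))]
        ds = MixedDataset(pd.DataFrame({"g": ["b", "b", "a"]}), specs)
        assert median_thresholds(ds)["g"] == "b"


class TestConditionalQuery:
    def test_symmetric_root_above_median(self):
        dag, params, _ = bivariate_net(0.0)
        q = QuerySpec(event=("X", ">", 0.0), n_samples=100_000, seed=1)
        res = conditional_query(params, dag, q)
        assert abs(res.probability - 0.5) < 3 * res.mc_standard_error + 1e-9

    def test_independent_pair_is_uninformative(self):
        dag, params, _ = bivariate_net(0.0)
        q = QuerySpec(event=("Y", ">", 0.0), evidence=[("X", ">", 0.0)],
                      n_samples=200_000, seed=2)
        res = conditional_query(params, dag, q)
        assert abs(res.probability - 0.5) < 3 * res.mc_standard_error + 1e-9

    def test_orthant_probability_closed_form(self):
        """P(Y > 0 | X > 0) = 1/2 + arcsin(rho)/pi for a bivariate normal."""
        dag, params, _ = bivariate_net(0.5)
        q = QuerySpec(event=("Y", ">", 0.0), evidence=[("X", ">", 0.0)],
                      n_samples=400_000, seed=3)
        res = conditional_query(params, dag, q)
        target = 0.5 + np.arcsin(0.5) / np.pi
        assert abs(res.probability - target) < 3 * res.mc_standard_error

    def test_complementarity(self):
        dag, params, _ = bivariate_net(0.4)
        kwargs = dict(evidence=[("X", "<", 0.0)], n_samples=100_000)
        up = conditional_query(params, dag,
                               QuerySpec(event=("Y", ">", 0.0), seed=4, **kwargs))
        down = conditional_query(params, dag,
                                 QuerySpec(event=("Y", "<", 0.0), seed=4, **kwargs))
        assert up.probability + down.probability == pytest.approx(
            1.0, abs=2 * up.mc_standard_error + 1e-12)

    def test_deterministic_given_seed(self):
        dag, params, _ = bivariate_net(0.3)
        q = QuerySpec(event=("Y", ">", 0.0), evidence=[("X", ">", 0.0)],
                      n_samples=50_000, seed=5)
        assert conditional_query(params, dag, q).probability == \
            conditional_query(params, dag, q).probability

    def test_error_scaling_with_sample_size(self):
        """Doubling the sample count shrinks the RMS error roughly by sqrt 2."""
        dag, params, _ = bivariate_net(0.5)
        target = 0.5 + np.arcsin(0.5) / np.pi
        errs = {}
        for n_samples in (20_000, 40_000):
            sq = []
            for seed in range(10):
                q = QuerySpec(event=("Y", ">", 0.0), evidence=[("X", ">", 0.0)],
                              n_samples=n_samples, seed=600 + seed)
                sq.append((conditional_query(params, dag, q).probability
                           - target) ** 2)
            errs[n_samples] = np.sqrt(np.mean(sq))
        ratio = errs[20_000] / errs[40_000]
        assert 0.8 < ratio < 2.5

    def test_incompatible_evidence_errors(self):
        dag, params, _ = bivariate_net(0.0)
        q = QuerySpec(event=("Y", ">", 0.0), evidence=[("X", ">", 1e9)],
                      n_samples=1000, seed=6)
        with pytest.raises(ValueError, match="evidence"):
            conditional_query(params, dag, q)

    def test_event_variable_cannot_be_evidence(self):
        with pytest.raises(ValueError):
            QuerySpec(event=("X", ">", 0.0), evidence=[("X", "<", 0.0)])


class TestQueryBattery:
    def test_positive_path_implies_quadrant_dependence(self, truth, catie_sample):
        params = fit_parameters(truth.dag, catie_sample)
        table = query_battery(
            params, truth.dag, catie_sample,
            [("matrics_processing_speed", "<", "matrics_working_memory", "<")],
            n_samples=100_000, seed=7)
        assert table["probability"].iloc[0] > 0.5

    def test_discrete_evidence_clause(self, truth, catie_sample):
        params = fit_parameters(truth.dag, catie_sample)
        table = query_battery(
            params, truth.dag, catie_sample,
            [("employment", "=working", "qol_total", ">")],
            n_samples=100_000, seed=8)
        # employment lowers QOL for the non-working majority, so the
        # employed minority sits above the median more often than not
        assert table["probability"].iloc[0] > 0.55

    def test_self_pair_rejected(self, truth, catie_sample):
        params = fit_parameters(truth.dag, catie_sample)
        with pytest.raises(ValueError, match="self-pair"):
            query_battery(params, truth.dag, catie_sample,
                          [("qol_total", ">", "qol_total", "<")],
                          n_samples=10_000)
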