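"""Path-model SEM: coding, coefficient recovery, fit indices, Holm."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from symptomnet import (Dag, MixedDataset, VariableSpec, encode_for_sem,
                        fit_indices, fit_path_model, holm_adjust,
                        sample_dataset)

from conftest import bivariate_net
from symptomnet.clg import ancestral_sample


class TestEncoding:
    def test_binary_ordinal_dummy_coding(self, catie_sample):
        sem = encode_for_sem(catie_sample)
        assert sem.column_map["sex"] == ["sex"]
        assert set(np.unique(sem.frame["sex"])) <= {0.0, 1.0}
        assert sem.column_map["age_category"] == ["age_category"]
        assert set(np.unique(sem.frame["age_category"])) <= {0.0, 1.0, 2.0}
        assert len(sem.column_map["race"]) == 3  # 4 levels, first = reference
        assert sem.coding_report["race"]["reference"] == "white"

    def test_single_observed_level_rejected(self):
        specs = [VariableSpec("g", "discrete", ("a", "b")),
                 VariableSpec("x", "continuous")]
        frame = pd.DataFrame({"g": ["a", "a", "a"], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="single"):
            encode_for_sem(MixedDataset(frame, specs))


class TestPathModel:
    def test_saturated_model_has_zero_chi_square(self, catie_sample):
        cont = [s.name for s in catie_sample.specs if s.is_continuous]
        sub = MixedDataset(catie_sample.frame[cont[:5]],
                           [catie_sample.spec_of(c) for c in cont[:5]])
        complete = Dag(cont[:5], [(cont[i], cont[j])
                                  for i in range(5) for j in range(i + 1, 5)])
        fit = fit_path_model(complete, encode_for_sem(sub))
        assert fit.degrees_of_freedom == 0
        assert fit.chi_square == pytest.approx(0.0, abs=1e-6)
        assert fit.cfi == 1.0 and fit.rmsea == 0.0

    def test_single_arc_beta_equals_correlation(self):
        dag, params, specs = bivariate_net(0.6)
        d = ancestral_sample(dag, params, specs, 500,
                             np.random.default_rng(70))
        fit = fit_path_model(Dag(["X", "Y"], [("X", "Y")]), encode_for_sem(d))
        r = np.corrcoef(d.frame["X"], d.frame["Y"])[0, 1]
        assert fit.arcs["beta"].iloc[0] == pytest.approx(r, abs=1e-10)

    def test_known_path_model_recovery(self, truth):
        d = sample_dataset(truth, 5000, seed=71)
        fit = fit_path_model(truth.dag, encode_for_sem(d))
        for (u, v), beta in truth.coefficient_annotations.items():
            row = fit.arcs[(fit.arcs.parent == u) & (fit.arcs.child == v)]
            assert float(row["beta"].iloc[0]) == pytest.approx(beta, abs=0.05)

    def test_estimates_invariant_to_node_order(self, truth):
        d = sample_dataset(truth, 800, seed=72)
        fit_a = fit_path_model(truth.dag, encode_for_sem(d))
        reordered = Dag(tuple(reversed(truth.dag.nodes)), set(truth.dag.arcs))
        fit_b = fit_path_model(reordered, encode_for_sem(d))
        a = fit_a.arcs.set_index(["parent", "child", "parent_col"])["beta"]
        b = fit_b.arcs.set_index(["parent", "child", "parent_col"])["beta"]
        for key, val in a.items():
            assert b[key] == pytest.approx(val, abs=1e-10)

    def test_r_squared_within_unit_interval(self, truth, catie_sample):
        fit = fit_path_model(truth.dag, encode_for_sem(catie_sample))
        assert all(0.0 <= v <= 1.0 for v in fit.r_squared.values())

    def test_information_criteria_prefer_true_arcs(self, truth):
        """BIC drops when a real arc joins the model, rises for a noise arc."""
        true_hits = null_hits = 0
        reduced_arcs = set(truth.dag.arcs) - {("panss_general", "panss_negative")}
        reduced = Dag(truth.dag.nodes, reduced_arcs)
        # null arc into an endogenous child keeps the exogenous block fixed,
        # so the comparison isolates the one extra path parameter
        null_aug = Dag(truth.dag.nodes,
                       set(truth.dag.arcs) | {("cgi_alcohol", "matrics_verbal")})
        for seed in range(5):
            d = sample_dataset(truth, 1450, seed=200 + seed)
            sem = encode_for_sem(d)
            bic_true = fit_path_model(truth.dag, sem).bic
            if fit_path_model(reduced, sem).bic > bic_true:
                true_hits += 1
            if fit_path_model(null_aug, sem).bic > bic_true:
                null_hits += 1
        assert true_hits >= 4 and null_hits >= 4


class TestFitIndices:
    def test_perfect_fit(self):
        cfi, tli, rmsea = fit_indices(10.0, 10, 500.0, 45, 1000)
        assert cfi == 1.0 and rmsea == 0.0

    def test_no_improvement_over_null(self):
        cfi, _, _ = fit_indices(500.0, 45, 500.0, 45, 1000)
        assert cfi == 0.0

    def test_null_df_zero_rejected(self):
        with pytest.raises(ValueError):
            fit_indices(1.0, 0, 1.0, 0, 100)

    def test_true_model_rmsea_small(self, truth):
        """Central chi-square under the generating model keeps RMSEA < 0.05."""
        hits = 0
        for seed in range(20):
            d = sample_dataset(truth, 5000, seed=300 + seed)
            fit = fit_path_model(truth.dag, encode_for_sem(d))
            if fit.rmsea < 0.05:
                hits += 1
        assert hits >= 18


class TestHolm:
    def test_singleton_identity(self):
        assert holm_adjust([0.04]) == [0.04]

    def test_step_down_with_running_maximum(self):
        assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])

    def test_cap_at_one_propagates(self):
        assert holm_adjust([0.5, 0.9]) == pytest.approx([1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])

    def test_dominates_raw_p_and_matches_statsmodels(self):
        rng = np.random.default_rng(73)
        for _ in range(50):
            m = int(rng.integers(1, 20))
            p = rng.random(m)
            ours = np.array(holm_adjust(p))
            assert np.all(ours >= p - 1e-15)
            reference = multipletests(p, method="holm")[1]
            np.testing.assert_allclose(ours, reference, atol=1e-12)
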