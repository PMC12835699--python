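"""Row filtering, missForest-style imputation, age binning, standardization."""

import numpy as np
import pandas as pd
import pytest

from symptomnet import (GeneratorConfig, MixedDataset, VariableSpec,
                        categorize_age, filter_rows_by_missingness,
                        impute_random_forest, inject_missingness,
                        sample_dataset, standardize_columns)


def _dataset_with_row_missingness(n_missing, p=21):
    specs = [VariableSpec(f"x{i}", "continuous") for i in range(p)]
    full = {f"x{i}": [1.0, 2.0] for i in range(p)}
    frame = pd.DataFrame(full)
    for i in range(n_missing):
        frame.loc[0, f"x{i}"] = np.nan
    return MixedDataset(frame, specs)


class TestRowFilter:
    def test_strictly_above_half_removed(self):
        ds = _dataset_with_row_missingness(11)  # 11/21 = 0.524
        kept, removed = filter_rows_by_missingness(ds, 0.5)
        assert removed == 1 and kept.n == 1

    def test_exactly_half_retained(self):
        specs = [VariableSpec(f"x{i}", "continuous") for i in range(4)]
        frame = pd.DataFrame({f"x{i}": [1.0] for i in range(4)})
        frame.loc[0, ["x0", "x1"]] = np.nan  # exactly 50%
        kept, removed = filter_rows_by_missingness(MixedDataset(frame, specs), 0.5)
        assert removed == 0 and kept.n == 1

    def test_generator_bad_rows_all_caught(self, truth):
        d = sample_dataset(truth, 1460, seed=21)
        cfg = GeneratorConfig(n=1460, seed=21, missing_rate=0.024, n_bad_rows=10)
        kept, removed = filter_rows_by_missingness(inject_missingness(d, cfg), 0.5)
        assert removed == 10 and kept.n == 1450

    def test_all_rows_removed_errors(self):
        ds = _dataset_with_row_missingness(21)
        ds.frame.iloc[1, :] = np.nan
        ds = MixedDataset(ds.frame, ds.specs)
        with pytest.raises(ValueError):
            filter_rows_by_missingness(ds, 0.5)


class TestImputation:
    def test_complete_data_unchanged(self, truth):
        d = sample_dataset(truth, 50, seed=22)
        out, report = impute_random_forest(d, seed=1)
        assert out.frame.equals(d.frame)
        assert report.n_iterations == 1
        assert report.cell_missing_fraction == 0.0

    def test_beats_mean_imputation_on_strong_predictor(self):
        rng = np.random.default_rng(23)
        n = 600
        x = rng.standard_normal(n)
        y = x + 0.1 * rng.standard_normal(n)
        mask = rng.random(n) < 0.1
        specs = [VariableSpec("x", "continuous"), VariableSpec("y", "continuous")]
        y_obs = y.copy()
        y_obs[mask] = np.nan
        ds = MixedDataset(pd.DataFrame({"x": x, "y": y_obs}), specs)
        out, _ = impute_random_forest(ds, n_trees=50, seed=2)
        rf_err = np.sqrt(((out.frame["y"].to_numpy()[mask] - y[mask]) ** 2).mean())
        mean_err = np.sqrt(((y[~mask].mean() - y[mask]) ** 2).mean())
        assert rf_err < mean_err

    def test_reports_cell_missing_fraction(self, truth):
        d = sample_dataset(truth, 800, seed=24)
        cfg = GeneratorConfig(n=800, seed=24, missing_rate=0.024, n_bad_rows=0)
        dm = inject_missingness(d, cfg)
        _, report = impute_random_forest(dm, n_trees=20, seed=3)
        assert report.cell_missing_fraction == pytest.approx(0.024, abs=0.006)

    def test_observed_cells_untouched_and_complete(self, truth):
        d = sample_dataset(truth, 300, seed=25)
        cfg = GeneratorConfig(n=300, seed=25, missing_rate=0.05, n_bad_rows=0)
        dm = inject_missingness(d, cfg)
        out, _ = impute_random_forest(dm, n_trees=20, seed=4)
        assert out.is_complete()
        mask = dm.missing_mask()
        for c in dm.columns:
            obs = ~mask[c]
            assert out.frame.loc[obs, c].equals(dm.frame.loc[obs, c])

    def test_deterministic_given_seed(self, truth):
        d = sample_dataset(truth, 250, seed=26)
        cfg = GeneratorConfig(n=250, seed=26, missing_rate=0.05, n_bad_rows=0)
        dm = inject_missingness(d, cfg)
        a, _ = impute_random_forest(dm, n_trees=15, seed=5)
        b, _ = impute_random_forest(dm, n_trees=15, seed=5)
        assert a.frame.equals(b.frame)

    def test_fully_missing_column_errors(self):
        specs = [VariableSpec("x", "continuous"), VariableSpec("y", "continuous")]
        frame = pd.DataFrame({"x": [1.0, 2.0], "y": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="fully missing"):
            impute_random_forest(MixedDataset(frame, specs))

    def test_max_iter_validation(self, truth):
        d = sample_dataset(truth, 50, seed=27)
        with pytest.raises(ValueError):
            impute_random_forest(d, max_iter=0)


class TestAgeBinning:
    @pytest.mark.parametrize("age,expected", [
        (29, "<30"), (30, "<30"), (31, "31-45"), (45, "31-45"), (46, ">45"),
        (44.6, "31-45"),  # rounds to 45
    ])
    def test_band_assignment(self, age, expected):
        assert categorize_age([age]) == [expected]

    def test_nonpositive_age_errors(self):
        with pytest.raises(ValueError):
            categorize_age([-1.0])


class TestStandardize:
    def test_closed_form(self):
        specs = [VariableSpec("x", "continuous")]
        ds = MixedDataset(pd.DataFrame({"x": [1.0, 2.0, 3.0]}), specs)
        out = standardize_columns(ds, ["x"])
        np.testing.assert_allclose(out.frame["x"], [-1.0, 0.0, 1.0])

    def test_idempotent(self, truth):
        d = sample_dataset(truth, 500, seed=28)
        cols = ["matrics_verbal", "qol_total"]
        once = standardize_columns(d, cols)
        twice = standardize_columns(once, cols)
        np.testing.assert_allclose(once.frame[cols], twice.frame[cols], atol=1e-12)

    def test_zero_variance_errors(self):
        specs = [VariableSpec("x", "continuous")]
        ds = MixedDataset(pd.DataFrame({"x": [2.0, 2.0]}), specs)
        with pytest.raises(ValueError, match="zero variance"):
            standardize_columns(ds, ["x"])
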