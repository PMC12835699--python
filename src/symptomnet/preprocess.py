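"""Data diagnosis: row filtering, iterative random-forest imputation,
age categorization and standardization.

The imputation follows the missForest scheme of Stekhoven & Buhlmann:
initialize missing cells with the column mean (continuous) or mode
(discrete), then cycle over variables in order of increasing missingness,
fitting a random forest of each variable on all others and predicting its
missing cells, until the iteration-over-iteration difference criterion
rises for both variable kinds (or the only kind present), returning the
matrix from the iteration before the rise.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import json
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .data import MixedDataset


@dataclass
class ImputationReport:
    n_rows_removed: int
    cell_missing_fraction: float
    n_iterations: int
    final_difference_continuous: float
    final_difference_discrete: float
    iteration_log: list[dict]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def filter_rows_by_missingness(data: MixedDataset,
                               threshold: float = 0.5) -> tuple[MixedDataset, int]:
    """Drop rows whose missing-cell fraction is *strictly* greater than
    ``threshold``; survivors keep their original order."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    frac = data.missing_mask().to_numpy().mean(axis=1)
    keep = frac <= threshold
    removed = int((~keep).sum())
    if removed == data.n:
        raise ValueError("row filter removed every record")
    return data.take_rows(np.flatnonzero(keep)), removed


def _mode_code(codes: np.ndarray, n_levels: int) -> int:
    counts = np.bincount(codes, minlength=n_levels)
    return int(counts.argmax())  # ties -> lowest code (level order)


def impute_random_forest(data: MixedDataset, max_iter: int = 10,
                         n_trees: int = 100,
                         seed: int = 0) -> tuple[MixedDataset, ImputationReport]:
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    mask = data.missing_mask().to_numpy()
    if mask.all(axis=0).any():
        bad = [c for c, m in zip(data.columns, mask.all(axis=0)) if m]
        raise ValueError(f"column(s) fully missing: {bad}")
    frac_missing = float(mask.mean())
    specs = data.specs
    p = len(specs)
    n = data.n

    # integer-coded working matrix (float, NaN = missing)
    work = np.empty((n, p))
    level_maps = []
    for j, s in enumerate(specs):
        col = data.frame[s.name]
        if s.is_continuous:
            work[:, j] = col.to_numpy(dtype=float)
            level_maps.append(None)
        else:
            idx = {lev: i for i, lev in enumerate(s.levels)}
            work[:, j] = np.array(
                [idx[v] if isinstance(v, str) else np.nan for v in col])
            level_maps.append(s.levels)

    if not mask.any():
        report = ImputationReport(0, 0.0, 1, 0.0, 0.0, [])
        return data.copy(), report

    # initialization: mean / mode
    for j, s in enumerate(specs):
        mj = mask[:, j]
        if not mj.any():
            continue
        obs = work[~mj, j]
        if s.is_continuous:
            work[mj, j] = obs.mean()
        else:
            work[mj, j] = _mode_code(obs.astype(int), s.n_levels)

    miss_cols = [j for j in range(p) if mask[:, j].any()]
    miss_cols.sort(key=lambda j: (mask[:, j].sum(), j))  # ascending missingness
    cont_cells = [(j, mask[:, j]) for j in miss_cols if specs[j].is_continuous]
    disc_cells = [(j, mask[:, j]) for j in miss_cols if specs[j].is_discrete]

    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    prev = work.copy()
    best = work.copy()
    prev_dc = prev_dd = np.inf
    log: list[dict] = []
    n_iterations = 0
    final_dc = final_dd = 0.0

    for it in range(1, max_iter + 1):
        n_iterations = it
        for j in miss_cols:
            s = specs[j]
            mj = mask[:, j]
            others = [k for k in range(p) if k != j]
            X = work[:, others]
            y = work[:, j]
            rf_seed = int(rng.integers(0, 2 ** 31 - 1))
            if s.is_continuous:
                model = RandomForestRegressor(
                    n_estimators=n_trees, max_features=1.0 / 3.0,
                    random_state=rf_seed, n_jobs=1)
                model.fit(X[~mj], y[~mj])
                work[mj, j] = model.predict(X[mj])
            else:
                model = RandomForestClassifier(
                    n_estimators=n_trees, max_features="sqrt",
                    random_state=rf_seed, n_jobs=1)
                model.fit(X[~mj], y[~mj].astype(int))
                work[mj, j] = model.predict(X[mj])
        # difference criteria over imputed cells
        dc = 0.0
        if cont_cells:
            num = sum(float(((work[mj, j] - prev[mj, j]) ** 2).sum())
                      for j, mj in cont_cells)
            den = sum(float((work[mj, j] ** 2).sum()) for j, mj in cont_cells)
            dc = num / den if den > 0 else 0.0
        dd = 0.0
        if disc_cells:
            changed = sum(int((work[mj, j] != prev[mj, j]).sum())
                          for j, mj in disc_cells)
            total = sum(int(mj.sum()) for j, mj in disc_cells)
            dd = changed / total
        log.append({"iteration": it, "difference_continuous": dc,
                    "difference_discrete": dd})
        rose_c = dc > prev_dc
        rose_d = dd > prev_dd
        stop = (rose_c and rose_d) if (cont_cells and disc_cells) else \
            (rose_c if cont_cells else rose_d)
        if stop:
            work = best  # matrix from the last iteration before the rise
            n_iterations = it
            final_dc, final_dd = prev_dc if cont_cells else 0.0, \
                prev_dd if disc_cells else 0.0
            break
        best = work.copy()
        prev = work.copy()
        prev_dc, prev_dd = dc, dd
        final_dc, final_dd = dc, dd

    # decode back to a MixedDataset
    frame = data.frame.copy()
    for j, s in enumerate(specs):
        mj = mask[:, j]
        if not mj.any():
            continue
        if s.is_continuous:
            col = frame[s.name].to_numpy(dtype=float)
            col[mj] = work[mj, j]
            frame[s.name] = col
        else:
            levels = np.array(s.levels, dtype=object)
            vals = frame[s.name].to_numpy(dtype=object)
            vals[mj] = levels[work[mj, j].astype(int)]
            frame[s.name] = vals
    out = MixedDataset(frame, list(specs))
    report = ImputationReport(
        n_rows_removed=0,
        cell_missing_fraction=frac_missing,
        n_iterations=n_iterations,
        final_difference_continuous=float(final_dc if np.isfinite(final_dc) else 0.0),
        final_difference_discrete=float(final_dd if np.isfinite(final_dd) else 0.0),
        iteration_log=log,
    )
    return out, report


_AGE_LEVELS = ("<30", "31-45", ">45")


def categorize_age(values: Sequence[float],
                   breaks: tuple[float, float] = (30.0, 45.0)) -> list[str]:
    """Bin ages (years) into three bands: <=30, (30, 45], >45.

    Ages are rounded to integer years first; the published band labels
    leave exact 30 unassigned, so 30 joins the youngest band and 45 the
    middle one (exhaustive, order-preserving).
    """
    lo, hi = breaks
    out = []
    for v in values:
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"nonpositive or non-finite age {v!r}")
        r = round(float(v))
        if r <= lo:
            out.append(_AGE_LEVELS[0])
        elif r <= hi:
            out.append(_AGE_LEVELS[1])
        else:
            out.append(_AGE_LEVELS[2])
    return out


def standardize_columns(data: MixedDataset, columns: Sequence[str]) -> MixedDataset:
    """Rescale the named continuous columns to sample mean 0, sd 1 (n-1)."""
    frame = data.frame.copy()
    for name in columns:
        s = data.spec_of(name)
        if not s.is_continuous:
            raise ValueError(f"column {name!r} is not continuous")
        col = frame[name].to_numpy(dtype=float)
        sd = col.std(ddof=1)
        if not np.isfinite(sd) or sd <= 0:
            raise ValueError(f"column {name!r} has zero variance")
        frame[name] = (col - col.mean()) / sd
    return MixedDataset(frame, list(data.specs))
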