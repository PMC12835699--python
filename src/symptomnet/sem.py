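"""Recursive path-model SEM on a learned DAG.

The learned network is refit as a recursive linear system: every
endogenous variable is regressed on its parents (with uncorrelated errors
this equation-wise least-squares fit is the ML fit), yielding raw and
standardized coefficients, normal-reference p-values with Holm adjustment,
per-node variance explained, and global fit statistics from the
model-implied covariance matrix: chi-square ``T = (n-1) F_ML``, CFI, TLI,
RMSEA, AIC and BIC.

Discrete variables enter through an explicit numeric coding (0/1 for
binary, integer codes for ordered bands, reference dummies for nominal
multi-level variables); the coding report makes every mapping auditable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dag import Dag
from .data import MixedDataset


@dataclass
class SemData:
    """Numerically coded dataset plus the variable -> column mapping."""

    frame: pd.DataFrame
    column_map: dict[str, list[str]]
    coding_report: dict[str, dict]

    @property
    def n(self) -> int:
        return len(self.frame)


def encode_for_sem(data: MixedDataset) -> SemData:
    """Code discrete variables numerically for the path model.

    Binary variables become a 0/1 indicator of the second level; ordered
    discrete variables become integer codes in level order; nominal
    multi-level variables become first-level-reference dummies; continuous
    variables pass through unchanged.
    """
    if not data.is_complete():
        raise ValueError("encode_for_sem requires complete data")
    cols: dict[str, np.ndarray] = {}
    column_map: dict[str, list[str]] = {}
    report: dict[str, dict] = {}
    for s in data.specs:
        raw = data.frame[s.name]
        if s.is_continuous:
            cols[s.name] = raw.to_numpy(dtype=float)
            column_map[s.name] = [s.name]
            report[s.name] = {"coding": "continuous"}
            continue
        observed = sorted(set(raw))
        if len(observed) < 2:
            raise ValueError(f"discrete variable {s.name!r} has a single "
                             f"observed level")
        codes = {lev: i for i, lev in enumerate(s.levels)}
        code_col = np.array([codes[v] for v in raw], dtype=float)
        if s.n_levels == 2 or s.ordered:
            cols[s.name] = code_col
            column_map[s.name] = [s.name]
            report[s.name] = {"coding": "binary" if s.n_levels == 2 else "ordinal",
                              "levels": {lev: i for lev, i in codes.items()}}
        else:
            names = []
            for lev in s.levels[1:]:
                cname = f"{s.name}__{lev}"
                cols[cname] = (np.asarray(raw) == lev).astype(float)
                names.append(cname)
            column_map[s.name] = names
            report[s.name] = {"coding": "dummy", "reference": s.levels[0],
                              "columns": names}
    order = [c for s in data.specs for c in column_map[s.name]]
    return SemData(pd.DataFrame(cols)[order], column_map, report)


@dataclass
class PathFit:
    arcs: pd.DataFrame          # parent, child, parent_col, child_col, b, beta, se, z, p, p_holm
    r_squared: dict[str, float]  # per endogenous encoded column
    chi_square: float
    degrees_of_freedom: int
    model_p: float
    cfi: float
    tli: float
    rmsea: float
    aic: float
    bic: float
    n: int
    n_free_parameters: int = 0
    extras: dict = field(default_factory=dict)

    def global_block(self) -> dict:
        return {"chi_square": self.chi_square, "df": self.degrees_of_freedom,
                "p": self.model_p, "cfi": self.cfi, "tli": self.tli,
                "rmsea": self.rmsea, "aic": self.aic, "bic": self.bic,
                "n": self.n}

    def save(self, csv_path: str | Path, json_path: str | Path) -> None:
        self.arcs.to_csv(csv_path, index=False)
        payload = dict(self.global_block())
        payload["r_squared"] = self.r_squared
        Path(json_path).write_text(json.dumps(payload, indent=2))


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down familywise adjustment.

    Sort ascending, multiply the i-th smallest of m by (m - i), enforce the
    running maximum, cap at 1, return in original order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = min((m - rank) * p[idx], 1.0)
        running = max(running, val)
        adj[idx] = running
    return adj.tolist()


def fit_indices(chi_square: float, df: int, chi_square_null: float,
                df_null: int, n: int) -> tuple[float, float, float]:
    """CFI, TLI and RMSEA from model and independence-baseline chi-squares.

    CFI = 1 - max(T-df, 0)/max(T0-df0, T-df, 0); TLI from the relative
    chi-square ratio, defined as 1 for a saturated model; RMSEA =
    sqrt(max(T-df, 0) / (df (n-1))).  CFI and TLI are capped at 1.
    """
    if df_null == 0:
        raise ValueError("independence model must have df > 0")
    if df < 0 or df_null < df or n < 2:
        raise ValueError("invalid degrees of freedom / sample size")
    t, t0 = float(chi_square), float(chi_square_null)
    num = max(t - df, 0.0)
    den = max(t0 - df_null, t - df, 0.0)
    cfi = 1.0 if den == 0.0 else 1.0 - num / den
    if df == 0:
        tli = 1.0
    else:
        ratio0 = t0 / df_null
        if ratio0 <= 1.0:
            tli = 1.0
        else:
            tli = (ratio0 - t / df) / (ratio0 - 1.0)
    tli = min(tli, 1.0)
    cfi = min(max(cfi, 0.0), 1.0)
    rmsea = 0.0 if df == 0 else math.sqrt(max(t - df, 0.0) / (df * (n - 1)))
    return cfi, tli, rmsea


def _ml_discrepancy(sample: np.ndarray, implied: np.ndarray) -> float:
    p = sample.shape[0]
    sign_i, logdet_i = np.linalg.slogdet(implied)
    sign_s, logdet_s = np.linalg.slogdet(sample)
    if sign_i <= 0 or sign_s <= 0:
        raise np.linalg.LinAlgError("covariance matrix not positive definite")
    return float(logdet_i + np.trace(sample @ np.linalg.inv(implied))
                 - logdet_s - p)


def fit_path_model(dag: Dag, sem: SemData, n: int | None = None) -> PathFit:
    """Fit the recursive path model implied by ``dag`` on coded data."""
    n = n if n is not None else sem.n
    cols = list(sem.frame.columns)
    col_idx = {c: i for i, c in enumerate(cols)}
    X = sem.frame.to_numpy(dtype=float)
    p = len(cols)
    S = np.cov(X, rowvar=False, ddof=1)
    sds = np.sqrt(np.diag(S))

    psets = dag.parent_sets()
    endo_vars = [v for v in dag.nodes if psets[v]]
    exo_vars = [v for v in dag.nodes if not psets[v]]
    endo_cols = [c for v in endo_vars for c in sem.column_map[v]]
    exo_cols = [c for v in exo_vars for c in sem.column_map[v]]

    B = np.zeros((p, p))
    resid_var: dict[str, float] = {}
    rows = []
    r2: dict[str, float] = {}
    for child in endo_vars:
        parents = sorted(psets[child], key=dag.nodes.index)
        pcols = [c for par in parents for c in sem.column_map[par]]
        pmap = [(par, c) for par in parents for c in sem.column_map[par]]
        Xp = X[:, [col_idx[c] for c in pcols]]
        k = Xp.shape[1]
        if n <= k + 1:
            raise ValueError(f"too few records to fit node {child!r}")
        design = np.column_stack([np.ones(n), Xp])
        for ccol in sem.column_map[child]:
            y = X[:, col_idx[ccol]]
            xtx = design.T @ design
            if np.linalg.matrix_rank(xtx) < k + 1:
                raise ValueError(f"singular design for node {child!r}")
            xtx_inv = np.linalg.inv(xtx)
            beta_hat = xtx_inv @ design.T @ y
            resid = y - design @ beta_hat
            rss = float(resid @ resid)
            dof_resid = max(n - k - 1, 1)
            se = np.sqrt(np.diag(xtx_inv) * rss / dof_resid)
            var_y = float(S[col_idx[ccol], col_idx[ccol]])
            resid_var[ccol] = rss / (n - 1)
            r2[ccol] = max(0.0, min(1.0, 1.0 - resid_var[ccol] / var_y))
            for j, (par, pcol) in enumerate(pmap):
                b = float(beta_hat[j + 1])
                sej = float(se[j + 1])
                z = b / sej if sej > 0 else np.inf
                pval = float(2.0 * stats.norm.sf(abs(z)))
                beta_std = b * sds[col_idx[pcol]] / sds[col_idx[ccol]]
                B[col_idx[ccol], col_idx[pcol]] = b
                rows.append({"parent": par, "child": child,
                             "parent_col": pcol, "child_col": ccol,
                             "b": b, "beta": float(beta_std), "se": sej,
                             "z": z, "p": pval})

    arcs = pd.DataFrame(rows, columns=["parent", "child", "parent_col",
                                       "child_col", "b", "beta", "se", "z", "p"])
    arcs["p_holm"] = holm_adjust(arcs["p"].tolist()) if len(arcs) else []

    # model-implied covariance: exogenous block fixed at the sample
    # covariance, endogenous residuals diagonal
    psi = np.zeros((p, p))
    exo_idx = [col_idx[c] for c in exo_cols]
    psi[np.ix_(exo_idx, exo_idx)] = S[np.ix_(exo_idx, exo_idx)]
    for c in endo_cols:
        psi[col_idx[c], col_idx[c]] = resid_var[c]
    A = np.linalg.inv(np.eye(p) - B)
    implied = A @ psi @ A.T

    n_paths = len(arcs)
    pe = len(exo_cols)
    q = n_paths + len(endo_cols) + pe * (pe + 1) // 2
    df = p * (p + 1) // 2 - q
    f_ml = max(_ml_discrepancy(S, implied), 0.0)
    t = (n - 1) * f_ml
    if df == 0 and t < 1e-6:
        t = 0.0
    model_p = 1.0 if df <= 0 else float(stats.chi2.sf(t, df))

    # independence baseline
    implied0 = np.diag(np.diag(S))
    t0 = (n - 1) * max(_ml_discrepancy(S, implied0), 0.0)
    df0 = p * (p + 1) // 2 - p
    cfi, tli, rmsea = fit_indices(t, max(df, 0), t0, df0, n)

    # Gaussian log-likelihood based information criteria
    S_ml = np.cov(X, rowvar=False, ddof=0)
    sign, logdet = np.linalg.slogdet(implied)
    loglik = -0.5 * n * (p * math.log(2 * math.pi) + logdet
                         + float(np.trace(S_ml @ np.linalg.inv(implied))))
    aic = -2 * loglik + 2 * q
    bic = -2 * loglik + q * math.log(n)

    return PathFit(arcs=arcs, r_squared=r2, chi_square=float(t),
                   degrees_of_freedom=int(df), model_p=model_p, cfi=cfi,
                   tli=tli, rmsea=rmsea, aic=float(aic), bic=float(bic),
                   n=int(n), n_free_parameters=int(q))
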