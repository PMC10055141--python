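"""Predictor analysis of transition cost.

Each target state is characterised by summary features of its map
(mean, SD, network variance, rank correlations with nodal
architecture), and those features are related to the mean energy
required to reach the state, via partial rank correlations and
dominance analysis (an all-subsets decomposition of the regression
R^2 into per-predictor contributions).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .energy import TransitionEnergyMatrix
from .graph import (
    Connectome,
    effective_resistance,
    map_to_distribution,
    network_variance,
    node_predictors,
)

__all__ = [
    "partial_spearman",
    "dominance_analysis",
    "build_predictor_table",
]


def _rank(v: np.ndarray) -> np.ndarray:
    r = sps.rankdata(v)
    if np.all(r == r[0]):
        raise ValueError("variable is constant after ranking")
    return r


def partial_spearman(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Spearman correlation of x and y after removing covariates.

    All variables are rank-transformed; x and y are residualized on
    the (ranked) covariates by least squares and the Pearson
    correlation of the residuals is returned with a t-based two-sided
    p-value (df = n - 2 - n_covariates). With no covariates this is
    the plain Spearman correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 observations")
    rx, ry = _rank(x), _rank(y)
    if covariates is None:
        design = np.ones((n, 1))
        k = 0
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        rc = np.column_stack([sps.rankdata(cov[:, j]) for j in range(cov.shape[1])])
        design = np.column_stack([np.ones(n), rc])
        k = cov.shape[1]
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("covariates are rank deficient")
    beta_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ beta_x
    ey = ry - design @ beta_y
    # residuals that are pure round-off mean the variable is fully
    # explained by the covariates: the partial correlation is 0
    tiny_x = np.linalg.norm(ex) < 1e-8 * np.linalg.norm(rx - rx.mean())
    tiny_y = np.linalg.norm(ey) < 1e-8 * np.linalg.norm(ry - ry.mean())
    if tiny_x or tiny_y:
        return 0.0, 1.0
    denom = np.linalg.norm(ex) * np.linalg.norm(ey)
    r = float(ex @ ey / denom)
    df = n - 2 - k
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p


def _r2(x: np.ndarray, y: np.ndarray, cols: tuple[int, ...]) -> float:
    design = np.column_stack([np.ones(len(y)), x[:, cols]])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = np.sum((y - y.mean()) ** 2)
    return float(1.0 - np.sum(resid**2) / tss)


def dominance_analysis(
    predictors: pd.DataFrame | np.ndarray,
    response: np.ndarray,
    averaging: str = "size",
    adjusted: bool = False,
) -> pd.DataFrame:
    """Decompose regression R^2 into per-predictor dominance.

    Fits ordinary least squares on every non-empty predictor subset.
    The general dominance of predictor k averages its incremental R^2
    over subsets, stratified by model size (``averaging='size'``,
    default) or uniformly over all subsets (``averaging='uniform'``).
    With size-stratified averaging the dominances sum exactly to the
    full-model (unadjusted) R^2. ``adjusted=True`` additionally
    reports the full model's adjusted R^2 for display; the exact sum
    identity applies to the unadjusted value.
    """
    if isinstance(predictors, pd.DataFrame):
        names = list(predictors.columns)
        x = predictors.to_numpy(dtype=float)
    else:
        x = np.asarray(predictors, dtype=float)
        names = [f"x{j}" for j in range(x.shape[1])]
    y = np.asarray(response, dtype=float)
    n, p = x.shape
    if p > 8:
        raise ValueError("at most 8 predictors (2^p - 1 submodels fitted)")
    if n <= p + 2:
        raise ValueError("need more observations than predictors + 2")
    xs = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    cond = np.linalg.cond(np.column_stack([np.ones(n), xs]))
    if cond > 1e10:
        raise ValueError(
            f"predictors are (near-)collinear: design condition number {cond:.3e}"
        )
    r2 = {(): 0.0}
    for size in range(1, p + 1):
        for cols in combinations(range(p), size):
            r2[cols] = _r2(x, y, cols)
    dominance = np.zeros(p)
    for k in range(p):
        others = [j for j in range(p) if j != k]
        if averaging == "size":
            level_means = []
            for size in range(p):
                incs = [
                    r2[tuple(sorted(s + (k,)))] - r2[s]
                    for s in combinations(others, size)
                ]
                level_means.append(np.mean(incs))
            dominance[k] = float(np.mean(level_means))
        elif averaging == "uniform":
            incs = [
                r2[tuple(sorted(s + (k,)))] - r2[s]
                for size in range(p)
                for s in combinations(others, size)
            ]
            dominance[k] = float(np.mean(incs))
        else:
            raise ValueError("averaging must be 'size' or 'uniform'")
    full = r2[tuple(range(p))]
    out = pd.DataFrame(
        {
            "dominance": dominance,
            "percent_of_r2": 100.0 * dominance / full if full > 0 else np.nan,
        },
        index=pd.Index(names, name="predictor"),
    )
    out.attrs["full_r2"] = full
    if adjusted:
        out.attrs["full_r2_adjusted"] = 1.0 - (1.0 - full) * (n - 1) / (n - p - 1)
    return out


def build_predictor_table(
    states: pd.DataFrame,
    connectome: Connectome,
    tem: TransitionEnergyMatrix,
    module_assignment: np.ndarray,
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-state predictor table against mean energy-to-reach.

    For each state (term) the response is the mean transition energy
    to reach it from every other state; predictors are the map's mean
    and SD, its network variance under effective-resistance distance,
    and its Spearman correlation with each nodal architecture measure
    (degree, strength, participation, plus any annotation columns).
    """
    if list(states.columns) != list(tem.term_labels):
        raise ValueError("states and transition matrix must share term order")
    res = effective_resistance(connectome)
    nodal = node_predictors(connectome, module_assignment, annotations)
    nodal = nodal.drop(columns=[c for c in ("isolated",) if c in nodal])
    e = tem.energies
    k = e.shape[0]
    response = (e.sum(axis=0) - np.diag(e)) / (k - 1)
    rows = []
    for j, term in enumerate(states.columns):
        v = states[term].to_numpy(dtype=float)
        row = {
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)),
            "network_variance": network_variance(res, map_to_distribution(v)),
        }
        for col in nodal.columns:
            rho = sps.spearmanr(v, nodal[col].to_numpy(dtype=float)).statistic
            row[f"corr_{col}"] = float(rho)
        row["mean_energy_to_reach"] = float(response[j])
        rows.append(row)
    table = pd.DataFrame(rows, index=pd.Index(states.columns, name="term"))
    if table.isna().any().any():
        bad = table.columns[table.isna().any()].tolist()
        raise ValueError(f"predictor table has undefined entries in {bad}")
    return table
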