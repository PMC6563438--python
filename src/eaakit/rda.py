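"""Redundancy analysis of group membership on environment and geography.

RDA asks how much of a multivariate response — here the accessions'
membership probabilities in the K genetic groups (the Q matrix) — is
explained by a predictor set (agroclimatic variables, geographic variables).
The machinery:

* ``rda_fit``: Y projected on the column space of X; R² is the explained
  share of total variance, adjusted by Ezekiel's formula,
* ``partial_rda``: classic variance partitioning over two predictor sets
  (unique X, unique Z, common), built from adjusted R² of the nested models
  so the partition identity holds exactly,
* ``permutation_test``: anova-like permutation of (residualized) response
  rows against the pseudo-F statistic,
* ``forward_select``: greedy selection by adjusted-R² gain with the
  dummy-variable stopping report (how many real variables enter before a
  spatially correlated dummy would be the best addition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RdaResult",
    "rda_fit",
    "partial_rda",
    "permutation_test",
    "forward_select",
    "adjusted_r2",
]


def _as_matrix(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    return a[:, None] if a.ndim == 1 else a


def _center(y: np.ndarray) -> np.ndarray:
    return y - y.mean(axis=0)


def _fit_r2(Y: np.ndarray, X: np.ndarray | None):
    """Explained sum of squares fraction of centered Y on centered X
    (pseudo-inverse projection; None/empty X explains nothing).
    Returns (R2, rank, Yhat)."""
    ssy = (Y ** 2).sum()
    if X is None or X.shape[1] == 0:
        return 0.0, 0, np.zeros_like(Y)
    Xc = _center(X)
    beta, _, rank, _ = np.linalg.lstsq(Xc, Y, rcond=None)
    if rank < Xc.shape[1]:
        warnings.warn("collinear predictors; using pseudo-inverse projection",
                      stacklevel=3)
    yhat = Xc @ beta
    r2 = (yhat ** 2).sum() / ssy if ssy > 0 else 0.0
    return float(r2), int(rank), yhat


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel's adjustment, 1 - (1-R2)(n-1)/(n-p-1); may be negative."""
    if n - p - 1 <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


@dataclass
class RdaResult:
    r2: float
    adj_r2: float
    rank: int
    site_scores: pd.DataFrame | None = None
    axis_variance: np.ndarray | None = None
    permutation_p: float | None = None
    partition: dict = field(default_factory=dict)


def rda_fit(Y, X, axes: bool = True) -> RdaResult:
    """Redundancy analysis of (centered) Y on X.

    R² = trace of the fitted variance over trace of the response variance;
    canonical axes are the principal components of the fitted values.
    """
    Ym = _center(_as_matrix(Y))
    Xm = _as_matrix(X)
    if Ym.shape[0] != Xm.shape[0]:
        raise ValueError("Y and X row counts differ")
    n = Ym.shape[0]
    r2, rank, yhat = _fit_r2(Ym, Xm)
    res = RdaResult(r2=r2, adj_r2=adjusted_r2(r2, n, rank), rank=rank)
    if axes:
        u, s, _ = np.linalg.svd(yhat, full_matrices=False)
        keep = s > (s[0] * 1e-9 if s.size and s[0] > 0 else 1.0)
        names = [f"RDA{i + 1}" for i in range(int(keep.sum()))]
        idx = Y.index if isinstance(Y, pd.DataFrame) else range(n)
        res.site_scores = pd.DataFrame((u[:, keep] * s[keep]), index=idx,
                                       columns=names)
        res.axis_variance = (s[keep] ** 2) / (Ym ** 2).sum()
    return res


def partial_rda(Y, X, Z=None) -> RdaResult:
    """Variance partitioning of Y over predictor sets X and Z.

    ``unique_X`` = adjR²(X∪Z) − adjR²(Z), ``unique_Z`` symmetric,
    ``common`` = adjR²(X) + adjR²(Z) − adjR²(X∪Z); the three terms sum to
    adjR²(X∪Z) exactly.  The returned R²/adjR² are the semipartial values
    for X given Z.
    """
    Ym = _center(_as_matrix(Y))
    Xm = _as_matrix(X)
    n = Ym.shape[0]
    if Z is None or _as_matrix(Z).shape[1] == 0:
        base = rda_fit(Y, X, axes=False)
        base.partition = {"unique_X": base.adj_r2, "unique_Z": 0.0,
                          "common": 0.0, "total": base.adj_r2}
        return base
    Zm = _as_matrix(Z)
    xz = np.column_stack([Xm, Zm])
    r2_x, rank_x, _ = _fit_r2(Ym, Xm)
    r2_z, rank_z, _ = _fit_r2(Ym, Zm)
    r2_xz, rank_xz, _ = _fit_r2(Ym, xz)
    adj_x = adjusted_r2(r2_x, n, rank_x)
    adj_z = adjusted_r2(r2_z, n, rank_z)
    adj_xz = adjusted_r2(r2_xz, n, rank_xz)
    unique_x = adj_xz - adj_z
    unique_z = adj_xz - adj_x
    common = adj_x + adj_z - adj_xz
    if rank_xz <= max(rank_x, rank_z):
        warnings.warn("conditioning set spans the predictors; unique "
                      "fraction is zero by construction", stacklevel=2)
    return RdaResult(r2=r2_xz - r2_z, adj_r2=unique_x, rank=rank_xz,
                     partition={"unique_X": unique_x, "unique_Z": unique_z,
                                "common": common, "total": adj_xz})


def _pseudo_f(Y: np.ndarray, X: np.ndarray):
    r2, rank, _ = _fit_r2(Y, X)
    n = Y.shape[0]
    df_res = n - rank - 1
    if rank == 0 or df_res <= 0 or r2 >= 1.0:
        return np.inf if r2 >= 1.0 else 0.0
    return (r2 / rank) / ((1.0 - r2) / df_res)


def permutation_test(Y, X, Z=None, n_perm: int = 999, seed: int = 0) -> float:
    """Permutational anova-like significance test of X (given Z).

    Residualizes Y (and X) on Z, permutes the rows of the residualized
    response, and compares pseudo-F values:
    ``p = (1 + #{F_perm >= F_obs}) / (n_perm + 1)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    Ym = _center(_as_matrix(Y))
    Xm = _center(_as_matrix(X))
    if Z is not None and _as_matrix(Z).shape[1] > 0:
        Zm = _center(_as_matrix(Z))
        bz, *_ = np.linalg.lstsq(Zm, Ym, rcond=None)
        Ym = Ym - Zm @ bz
        bx, *_ = np.linalg.lstsq(Zm, Xm, rcond=None)
        Xm = Xm - Zm @ bx
    f_obs = _pseudo_f(Ym, Xm)
    rng = np.random.default_rng(seed)
    count = 0
    n = Ym.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _pseudo_f(Ym[perm], Xm) >= f_obs:
            count += 1
    return (1 + count) / (n_perm + 1)


def forward_select(Y, candidates: pd.DataFrame, dummy_names=(),
                   max_steps: int | None = None):
    """Greedy forward selection by added adjusted R², with dummy stop.

    Candidates are added one at a time by largest adjusted-R² gain;
    selection stops when the best next candidate is one of the flagged
    dummy variables (or when no candidate improves adjusted R²).
    Returns ``(selected_names, stop_index, history)`` where ``stop_index``
    is the number of real variables entered before the first dummy ranked
    best and ``history`` records the adjusted R² after each entry.
    Deterministic: no randomness is involved.
    """
    Ym = _center(_as_matrix(Y))
    n = Ym.shape[0]
    dummy_names = set(dummy_names)
    remaining = list(candidates.columns)
    selected: list = []
    history: list = []
    current_adj = 0.0
    max_steps = max_steps or len(remaining)
    while remaining and len(selected) < max_steps:
        gains = {}
        for name in remaining:
            cols = candidates[selected + [name]].to_numpy(dtype=float)
            r2, rank, _ = _fit_r2(Ym, cols)
            gains[name] = adjusted_r2(r2, n, rank)
        best = max(gains, key=lambda k: (gains[k], k))
        if gains[best] <= current_adj:
            break
        if best in dummy_names:
            break
        selected.append(best)
        remaining.remove(best)
        current_adj = gains[best]
        history.append(current_adj)
    return selected, len(selected), history
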