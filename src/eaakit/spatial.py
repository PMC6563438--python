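"""Spatially correlated dummy variables by unconditional Gaussian simulation.

Environmental surfaces are spatially smooth, so testing association
statistics against *uncorrelated* random noise understates the false-positive
rate.  This module builds the honest null: zero-mean unit-variance Gaussian
random fields whose spatial covariance follows a chosen semivariogram model
(spherical, exponential or gaussian), simulated on a grid and sampled at the
collection sites.  A weighted-least-squares semivariogram fit lets the dummy
smoothness be matched to that of a real climatic surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = [
    "SemivariogramModel",
    "GridSpec",
    "GridField",
    "simulate_field",
    "fit_semivariogram",
    "empirical_semivariogram",
    "make_dummies",
]


def _corr(model_type: str, h, rng: float):
    """Normalized correlation function (1 at h=0, ->0 at large h).
    ``rng`` is the practical range for exponential/gaussian."""
    h = np.asarray(h, dtype=float)
    if model_type == "spherical":
        x = np.minimum(h / rng, 1.0)
        return 1.0 - (1.5 * x - 0.5 * x ** 3)
    if model_type == "exponential":
        return np.exp(-3.0 * h / rng)
    if model_type == "gaussian":
        return np.exp(-3.0 * (h / rng) ** 2)
    raise ValueError(f"unknown semivariogram model {model_type!r}")


@dataclass
class SemivariogramModel:
    """gamma(h) = nugget + partial_sill * (1 - corr(h)); range in km."""

    model_type: str = "gaussian"
    nugget: float = 0.0
    partial_sill: float = 1.0
    range_km: float = 100.0

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial_sill must be >= 0")
        if self.range_km <= 0:
            raise ValueError("range must be > 0")
        _corr(self.model_type, 0.0, self.range_km)  # validates family

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def gamma(self, h):
        return self.nugget + self.partial_sill * (
            1.0 - _corr(self.model_type, h, self.range_km))

    def covariance(self, h):
        """Covariance of the implied field (sill-normalized to variance 1)."""
        h = np.asarray(h, dtype=float)
        c = self.partial_sill * _corr(self.model_type, h, self.range_km)
        c = np.where(h == 0.0, self.sill, c)
        return c / self.sill if self.sill > 0 else c


@dataclass
class GridSpec:
    rows: int = 20
    cols: int = 20
    cell_size_km: float = 25.0
    origin: tuple = (0.0, 0.0)

    def coordinates(self) -> np.ndarray:
        """Cell-centre coordinates, shape (rows*cols, 2), row-major."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.cols) + 0.5) * self.cell_size_km
        ys = y0 + (np.arange(self.rows) + 0.5) * self.cell_size_km
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass
class GridField:
    grid: GridSpec
    values: np.ndarray
    model: SemivariogramModel
    seed: int


def simulate_field(grid: GridSpec, model: SemivariogramModel,
                   seed: int) -> GridField:
    """Unconditional Gaussian simulation on the grid.

    Draws a zero-mean, unit-variance Gaussian field whose covariance is the
    (sill-normalized) semivariogram-implied covariance, via Cholesky of the
    dense grid covariance.
    """
    coords = grid.coordinates()
    if len(coords) < 4:
        raise ValueError("need at least 4 grid cells")
    cov = model.covariance(squareform(pdist(coords)))
    np.fill_diagonal(cov, cov.diagonal() + 1e-10)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("implied covariance is not positive definite") \
            from exc
    rng = np.random.default_rng(seed)
    z = chol @ rng.standard_normal(len(coords))
    return GridField(grid=grid, values=z, model=model, seed=seed)


def empirical_semivariogram(coords, values, n_bins: int = 15,
                            max_dist: float | None = None):
    """Binned empirical semivariogram.

    Returns ``(lag_centres, gamma_hat, pair_counts)`` for pairs up to
    ``max_dist`` (default: half the maximum separation).
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    d = pdist(coords)
    dv2 = pdist(values[:, None], metric="sqeuclidean") / 2.0
    if max_dist is None:
        max_dist = d.max() / 2.0
    edges = np.linspace(0.0, max_dist, n_bins + 1)
    idx = np.digitize(d, edges) - 1
    keep = (idx >= 0) & (idx < n_bins)
    counts = np.bincount(idx[keep], minlength=n_bins)
    sums = np.bincount(idx[keep], weights=dv2[keep], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        gamma = sums / counts
    centres = (edges[:-1] + edges[1:]) / 2.0
    ok = counts > 0
    return centres[ok], gamma[ok], counts[ok]


def fit_semivariogram(coords, values, model_type: str = "gaussian",
                      n_bins: int = 15,
                      max_dist: float | None = None) -> SemivariogramModel:
    """Weighted-least-squares fit of a semivariogram model.

    Weights are pair counts over squared model semivariance (gstat's
    default weighting).  Constant inputs return a degenerate zero model
    with a warning.  The fit is invariant to adding a constant to the
    values (the semivariogram only sees differences).
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(values) < 30:
        raise ValueError("need >= 30 points to fit a semivariogram")
    if np.allclose(values, values[0]):
        warnings.warn("all values equal; returning degenerate model",
                      stacklevel=2)
        return SemivariogramModel(model_type, nugget=0.0, partial_sill=0.0,
                                  range_km=1.0)
    lags, gamma, counts = empirical_semivariogram(coords, values, n_bins,
                                                  max_dist)
    var = values.var(ddof=1)
    span = lags.max()

    def resid(theta):
        nugget, psill, rng_ = np.exp(theta)
        g = nugget + psill * (1.0 - _corr(model_type, lags, rng_))
        return np.sqrt(counts) * (gamma - g) / np.maximum(g, 1e-8)

    x0 = np.log([max(0.05 * var, 1e-6), max(var, 1e-6), span / 2.0])
    sol = least_squares(resid, x0, method="lm", max_nfev=2000)
    nugget, psill, rng_ = np.exp(sol.x)
    # guard against a pure-nugget process dressed up as structure at an
    # implausibly long range: keep the spatial component only if it beats
    # the flat (nugget-only) model
    flat = np.average(gamma, weights=counts)
    sse_fit = float((resid(sol.x) ** 2).sum())
    sse_flat = float(((np.sqrt(counts) * (gamma - flat) / flat) ** 2).sum())
    if psill < 1e-6 * max(nugget, var) or sse_fit > 0.99 * sse_flat:
        return SemivariogramModel(model_type, nugget=float(flat),
                                  partial_sill=0.0, range_km=1.0)
    return SemivariogramModel(model_type, nugget=float(nugget),
                              partial_sill=float(psill),
                              range_km=float(min(rng_, 10 * span)))


def make_dummies(sites: pd.DataFrame, grid: GridSpec,
                 model: SemivariogramModel, seed: int,
                 n: int = 12) -> pd.DataFrame:
    """``n`` standardized dummy columns sampled at the collection sites.

    Each column is an independent simulated field (seeds spawned from
    ``seed``) read off at the nearest grid cell of each site; sites outside
    the grid bounding box fall back to the nearest cell with a warning.
    Columns are standardized over sites (mean 0, sd 1).
    """
    coords = grid.coordinates()
    pts = sites[["lon", "lat"]].to_numpy(dtype=float)
    x0, y0 = grid.origin
    bbox_ok = ((pts[:, 0] >= x0) & (pts[:, 0] <= x0 + grid.cols * grid.cell_size_km)
               & (pts[:, 1] >= y0) & (pts[:, 1] <= y0 + grid.rows * grid.cell_size_km))
    if not bbox_ok.all():
        warnings.warn(f"{(~bbox_ok).sum()} site(s) outside the grid bounding "
                      "box; using nearest cell", stacklevel=2)
    nearest = cdist(pts, coords).argmin(axis=1)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(seed).spawn(n)]
    cols = {}
    for j, s in enumerate(seeds, start=1):
        field = simulate_field(grid, model, s)
        v = field.values[nearest]
        sd = v.std(ddof=0)
        cols[f"dummy{j:02d}"] = (v - v.mean()) / sd if sd > 0 else v * 0.0
    return pd.DataFrame(cols, index=sites["id"].to_numpy()
                        if "id" in sites.columns else sites.index)
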