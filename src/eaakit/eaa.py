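"""SNP x environment association with and without structure correction.

The association model treats each accession as a population of haploid
sample size one (so the "population frequency" is the 0/1 call itself) and
places the vector of standardized allele frequencies under a Gaussian
hierarchical model around an ancestral frequency ``eps`` with covariance
``eps(1-eps) Ω``:

    null:        y ~ N(eps * 1,           eps(1-eps) Ω)
    alternative: y ~ N(eps * 1 + beta e,  eps(1-eps) Ω)

with ``e`` the standardized environmental variable and ``beta`` integrated
over a symmetric uniform prior.  The Bayes factor is the marginal-likelihood
ratio; with Ω = I this is the structure-uncorrected "null model" analysis,
with the estimated genotype-covariance Ω the structure-corrected
"covariance model".  Five seeded runs supply the median BF / median rho and
the per-run top-1 % consensus rule; the 12 spatially correlated dummy
variables supply the empirical 99.99-percentile BF threshold.

A latent-factor association (ridge-LFMM style: truncated randomized SVD of
the centered genotype matrix as confounders) provides the complementary
individual-level analysis, with Fisher-Stouffer combination across runs and
per-variable Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.utils.extmath import randomized_svd
from statsmodels.stats.multitest import multipletests

from .popdiff import CovarianceMatrix

__all__ = [
    "BfModelConfig",
    "standardize_env",
    "write_environfile",
    "read_environfile",
    "bayes_factor_run",
    "spearman_env",
    "run_association",
    "consensus_hits",
    "dummy_threshold",
    "latent_factor_assoc",
    "combine_fisher_stouffer",
    "genomic_control",
    "bh_fdr",
    "bf_xtx_correlation",
]


@dataclass
class BfModelConfig:
    """Configuration of the Bayes-factor integration.

    ``beta_prior_halfwidth`` is the half-width of the uniform prior on the
    environmental effect (standardized-frequency units per 1 SD of
    environment); ``n_beta_draws`` Monte Carlo draws per run integrate over
    it (``method="grid"`` uses a deterministic 61-point grid instead).
    ``n_iterations`` is kept for interface parity with MCMC samplers and
    bounds the draw count.
    """

    n_iterations: int = 100_000
    n_runs: int = 5
    beta_prior_halfwidth: float = 0.3
    n_beta_draws: int = 400
    n_freq_draws: int = 32
    n_grid: int = 61
    method: str = "mc"            # "mc" (seeded) or "grid" (deterministic)
    rho_method: str = "observed"  # "observed" (exact) or "posterior" (drawn)
    ridge: float = 1e-6
    seeds: tuple = ()

    def __post_init__(self) -> None:
        if self.n_iterations < 1000:
            raise ValueError("n_iterations must be >= 1000")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.beta_prior_halfwidth <= 0:
            raise ValueError("beta prior half-width must be > 0")
        self.n_beta_draws = min(self.n_beta_draws, self.n_iterations)

    def run_seeds(self, seed_base: int = 0):
        if self.seeds:
            return list(self.seeds)[:self.n_runs]
        return [int(s.generate_state(1)[0] % (2 ** 31))
                for s in np.random.SeedSequence(seed_base).spawn(self.n_runs)]


# ---------------------------------------------------------------------------
# environment matrix
# ---------------------------------------------------------------------------

def standardize_env(env: pd.DataFrame) -> pd.DataFrame:
    """Column-wise (x - mean)/sd (population sd); errors on constants."""
    sd = env.std(ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant environmental column(s): {constant}")
    out = (env - env.mean()) / sd
    out.attrs["standardized"] = True
    return out


def write_environfile(env: pd.DataFrame, path) -> None:
    """bayenv environfile dialect: one tab-separated row per variable, one
    column per population/accession."""
    env.T.to_csv(path, sep="\t", header=False, float_format="%.6f")


def read_environfile(path, accession_ids=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, index_col=0).T
    if accession_ids is not None:
        df.index = accession_ids
    df.columns.name = None
    return df.reset_index(drop=True) if accession_ids is None else df


# ---------------------------------------------------------------------------
# Bayes factor
# ---------------------------------------------------------------------------

def _locus_stats(G: pd.DataFrame, omega, ridge: float):
    """Shared per-locus quantities: A = (Ω + ridge I)^-1, GLS ancestral
    frequency, residuals (missing calls held at the ancestral estimate, so
    they carry no information), and the variance scale eps(1-eps)."""
    cov = np.asarray(omega.omega if isinstance(omega, CovarianceMatrix)
                     else omega, dtype=float)
    P = cov.shape[0]
    a = np.linalg.inv(cov + ridge * np.eye(P))
    y = G.to_numpy(dtype=float)                      # P x L (acc x loci)
    one = np.ones(P)
    a1 = a @ one
    obs = ~np.isnan(y)
    eps_simple = np.nanmean(y, axis=0)
    y_fill = np.where(obs, y, eps_simple)
    eps = (y_fill.T @ a1) / (one @ a1)
    eps = np.clip(eps, 1e-6, 1 - 1e-6)
    resid = y_fill - eps                             # P x L
    s = eps * (1.0 - eps)
    return a, resid, s, eps


def bayes_factor_run(G: pd.DataFrame, env: pd.DataFrame,
                     omega, config: BfModelConfig | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """One run of Bayes factors for every locus x variable.

    Under the Gaussian model the likelihood ratio at a fixed effect size is
    ``exp(beta * u - beta^2 v / 2)`` with ``u = e' Σ^-1 r`` and
    ``v = e' Σ^-1 e``; the BF integrates this over the uniform prior on
    beta, by seeded Monte Carlo (default) or on a fixed grid.  Monomorphic
    loci get BF = 1.  Returns loci x variables.
    """
    config = config or BfModelConfig()
    a, resid, s, eps = _locus_stats(G, omega, config.ridge)
    w = config.beta_prior_halfwidth
    rng = np.random.default_rng(seed)
    if config.method == "grid":
        betas = np.linspace(-w, w, config.n_grid)
    else:
        betas = rng.uniform(-w, w, config.n_beta_draws)
    ar = a @ resid                                   # P x L
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-NaN columns are caught below
        mono = np.nanstd(G.to_numpy(dtype=float), axis=0) == 0
    out = {}
    for var in env.columns:
        e = env[var].to_numpy(dtype=float)
        u = (e @ ar) / s                             # L
        v = float(e @ a @ e) / s                     # L
        # log mean over beta draws of exp(beta*u - beta^2*v/2)
        expo = betas[None, :] * u[:, None] \
            - 0.5 * (betas ** 2)[None, :] * v[:, None]
        m = expo.max(axis=1)
        logbf = m + np.log(np.exp(expo - m[:, None]).mean(axis=1))
        bf = np.exp(np.clip(logbf, -700.0, 700.0))
        bf[mono] = 1.0
        out[var] = bf
    return pd.DataFrame(out, index=G.columns)


# ---------------------------------------------------------------------------
# Spearman rho
# ---------------------------------------------------------------------------

def spearman_env(freqs, env) -> float:
    """Spearman rank correlation (average ranks on ties) between a locus's
    standardized frequencies and an environmental variable."""
    x = np.asarray(freqs, dtype=float)
    y = np.asarray(env, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def _spearman_matrix(calls: np.ndarray, env: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho of every locus against every variable, vectorized via
    rank transform + Pearson (complete matrices only)."""
    rg = stats.rankdata(calls, axis=0)
    re = stats.rankdata(env.to_numpy(dtype=float), axis=0)
    rg = (rg - rg.mean(axis=0)) / np.maximum(rg.std(axis=0), 1e-12)
    re = (re - re.mean(axis=0)) / np.maximum(re.std(axis=0), 1e-12)
    rho = rg.T @ re / rg.shape[0]
    mono = np.ptp(calls, axis=0) == 0
    rho[mono] = np.nan
    return rho


def run_association(G: pd.DataFrame, env: pd.DataFrame, omega,
                    config: BfModelConfig | None = None,
                    seed_base: int = 0) -> list:
    """The full multi-run association: per run, Bayes factors for every
    locus x variable plus Spearman rho computed on a seeded draw of the
    per-accession frequency posterior (Jeffreys Beta posterior of a
    haploid call), mirroring posterior-sample correlations of MCMC
    samplers.  Returns a list of per-run DataFrames indexed by locus with
    MultiIndex columns (statistic, variable).
    """
    config = config or BfModelConfig()
    seeds = config.run_seeds(seed_base)
    calls = G.to_numpy(dtype=float)
    eps = np.nanmean(calls, axis=0)
    tables = []
    for r, seed in enumerate(seeds):
        bf = bayes_factor_run(G, env, omega, config, seed=seed)
        filled = np.where(np.isnan(calls), eps, calls)
        if config.rho_method == "posterior":
            # posterior-mean frequency behind each haploid call from seeded
            # Beta (Jeffreys) draws: adds MCMC-like run-to-run variation
            rng = np.random.default_rng(seed + 1)
            freqs = np.mean([rng.beta(filled + 0.5, 1.5 - filled)
                             for _ in range(config.n_freq_draws)], axis=0)
        else:
            # haploid calls give the accession-level frequencies exactly, so
            # the rank correlation carries no Monte Carlo uncertainty
            freqs = filled
        rho = _spearman_matrix(freqs, env)
        tab = pd.concat({"bf": bf,
                         "rho": pd.DataFrame(rho, index=G.columns,
                                             columns=env.columns)}, axis=1)
        tab.attrs["seed"] = seed
        tables.append(tab)
    return tables


# ---------------------------------------------------------------------------
# thresholding rules
# ---------------------------------------------------------------------------

def median_over_runs(run_tables, statistic: str) -> pd.DataFrame:
    return pd.concat([t[statistic] for t in run_tables]) \
        .groupby(level=0).median() \
        .reindex(run_tables[0][statistic].index)


def consensus_hits(run_tables, variables=None, bf_quantile: float = 0.99,
                   rho_quantile: float = 0.99) -> set:
    """The 5-run consensus rule.

    A (locus, variable) pair is a hit iff its median-over-runs BF lies in
    the top ``1 - bf_quantile`` of the distribution pooled over all listed
    variables, AND its |rho| lies in the per-run pooled top
    ``1 - rho_quantile`` in *every* run.
    """
    shapes = {t["bf"].shape for t in run_tables}
    if len(shapes) != 1:
        raise ValueError("run tables have mismatching shapes")
    variables = list(variables) if variables is not None \
        else list(run_tables[0]["bf"].columns)
    med_bf = median_over_runs(run_tables, "bf")[variables]
    bf_thr = float(np.nanquantile(med_bf.to_numpy().ravel(), bf_quantile))
    bf_ok = med_bf >= bf_thr
    rho_ok = None
    for t in run_tables:
        rho = t["rho"][variables].abs()
        thr = float(np.nanquantile(rho.to_numpy().ravel(), rho_quantile))
        ok = rho >= thr
        rho_ok = ok if rho_ok is None else (rho_ok & ok)
    hits = bf_ok & rho_ok
    stacked = hits.stack()
    return set(stacked[stacked].index)


def dummy_threshold(dummy_bf_values, percentile: float = 99.99) -> float:
    """Empirical percentile of the BF null distribution built from the
    spatially correlated dummy variables."""
    vals = np.asarray(dummy_bf_values, dtype=float).ravel()
    vals = vals[~np.isnan(vals)]
    if vals.size < 10_000:
        warnings.warn(
            f"only {vals.size} dummy BF values; the {percentile} percentile "
            "has a wide confidence interval", stacklevel=2)
    return float(np.percentile(vals, percentile))


# ---------------------------------------------------------------------------
# latent-factor association
# ---------------------------------------------------------------------------

def latent_factor_assoc(G: pd.DataFrame, env, K: int = 6, n_runs: int = 5,
                        seed_base: int = 0) -> np.ndarray:
    """Per-locus environmental-effect z-scores adjusted for K latent factors.

    Each run estimates the factors as the top-K left singular vectors of
    the centered (complete, imputed) genotype matrix via seeded randomized
    SVD, then regresses every locus on [1, factors, env]; the z-score of
    the env coefficient is returned, shape (loci, n_runs).  ``K = 0``
    reduces to the simple per-locus regression.
    """
    calls = G.to_numpy(dtype=float)
    if np.isnan(calls).any():
        raise ValueError("latent-factor association needs a complete "
                         "(imputed) matrix")
    n, L = calls.shape
    if K >= n:
        raise ValueError("K must be smaller than the accession count")
    e = np.asarray(env, dtype=float)
    centered = calls - calls.mean(axis=0)
    zmat = np.empty((L, n_runs))
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(seed_base).spawn(n_runs)]
    for r, seed in enumerate(seeds):
        if K > 0:
            u, _, _ = randomized_svd(centered, n_components=K,
                                     random_state=seed)
            design = np.column_stack([np.ones(n), u, e])
        else:
            design = np.column_stack([np.ones(n), e])
        p = design.shape[1]
        xtx_inv = np.linalg.inv(design.T @ design)
        beta = xtx_inv @ design.T @ calls             # p x L
        resid = calls - design @ beta
        dof = n - p
        sigma2 = (resid ** 2).sum(axis=0) / dof
        se = np.sqrt(np.maximum(sigma2 * xtx_inv[-1, -1], 1e-300))
        t = beta[-1] / se
        # map t to a standard-normal z through matching tail probability
        zmat[:, r] = stats.norm.isf(stats.t.sf(t, dof)) if dof < 200 else t
    return zmat


def combine_fisher_stouffer(z_runs) -> tuple:
    """Stouffer combination across runs: z = sum(z_i)/sqrt(m), two-sided
    normal p.  Accepts (L, m) arrays or 1-D per-locus vectors."""
    z = np.atleast_2d(np.asarray(z_runs, dtype=float))
    m = z.shape[1]
    comb = z.sum(axis=1) / np.sqrt(m)
    p = 2.0 * stats.norm.sf(np.abs(comb))
    if np.ndim(z_runs) == 1:
        return float(comb[0]), float(p[0])
    return comb, p


def genomic_control(z) -> tuple:
    """Genomic-inflation adjustment of combined z-scores.

    Runs combined by Stouffer are strongly dependent (they share the data
    and differ only in solver starts), which inflates the combined z by up
    to sqrt(m); the standard latent-factor recalibration divides the
    squared scores by the inflation factor
    ``lambda = median(z^2) / qchisq(0.5, 1)`` so that the bulk of (null)
    loci is standard normal.  Returns (adjusted z, two-sided p).
    """
    z = np.asarray(z, dtype=float)
    lam = np.median(z ** 2) / stats.chi2.ppf(0.5, 1)
    adj = z / np.sqrt(max(lam, 1e-12))
    return adj, 2.0 * stats.norm.sf(np.abs(adj))


def bh_fdr(pvalues, q: float = 0.01) -> tuple:
    """Benjamini-Hochberg step-up: returns (qvalues, significance mask)."""
    p = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(p)
    qvals = np.full_like(p, np.nan)
    mask = np.zeros_like(p, dtype=bool)
    if ok.sum():
        rej, qv, *_ = multipletests(p[ok], alpha=q, method="fdr_bh")
        qvals[ok] = qv
        mask[ok] = rej
    return qvals, mask


def bf_xtx_correlation(bf, xtx_values) -> float:
    """Pearson correlation between per-locus BF and XtX (the diagnostic
    linking association strength to group differentiation)."""
    x = np.asarray(bf, dtype=float)
    y = np.asarray(xtx_values, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
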