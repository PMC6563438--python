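"""Population-differentiation statistics for haploid-coded panels.

Implements the drift-aware differentiation machinery:

* expected heterozygosity (gene diversity) ``H = 2p(1-p)``,
* a Weir-Cockerham-type Fst estimator adapted to haploid calls
  (one-way ANOVA on allele indicators, ratio-of-sums across loci),
* the among-population covariance matrix Ω of standardized allele
  frequencies — the drift null that both the association Bayes factor and
  XtX are judged against,
* XtX, a covariance-aware analogue of Fst: the Mahalanobis distance of the
  per-population frequency vector from its ancestral estimate under Ω, with
  neutral expectation equal to the number of populations,
* a pseudo-observed-data (POD) simulation that calibrates XtX significance
  thresholds from Ω and the observed frequency spectrum,
* 4 cM sliding-window summaries with the percentile reference lines used in
  genome-scan figures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "expected_het",
    "group_frequencies",
    "fst_weir_cockerham",
    "fst_pairwise",
    "estimate_omega",
    "null_omega",
    "read_omega",
    "write_omega",
    "xtx",
    "pod_threshold",
    "sliding_windows",
    "DiffScanResult",
    "differentiation_scan",
]


def expected_het(p):
    """Gene diversity of a biallelic locus: H = 2p(1-p)."""
    p = np.asarray(p, dtype=float)
    h = 2.0 * p * (1.0 - p)
    return float(h) if h.ndim == 0 else h


def group_frequencies(G: pd.DataFrame, labels) -> pd.DataFrame:
    """Per-group allele-1 frequencies (groups x loci), missing ignored."""
    labels = pd.Series(np.asarray(labels), index=G.index)
    return G.groupby(labels, observed=True).mean()


def _wc_components(G: pd.DataFrame, labels):
    """Per-locus between/within variance components of the haploid
    Weir-Cockerham ANOVA. Returns (a, b): numerator and extra denominator
    such that theta = sum(a) / sum(a + b)."""
    labels = pd.Series(np.asarray(labels), index=G.index)
    grouped = G.groupby(labels, observed=True)
    p_i = grouped.mean()                       # groups x loci
    n_i = grouped.count().to_numpy(dtype=float)
    r = p_i.shape[0]
    n = n_i.sum(axis=0)
    nbar = n / r
    nc = (n - (n_i ** 2).sum(axis=0) / n) / (r - 1)
    pbar = (n_i * p_i.to_numpy()).sum(axis=0) / n
    msp = (n_i * (p_i.to_numpy() - pbar) ** 2).sum(axis=0) / (r - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        msg = (n_i * p_i.to_numpy() * (1 - p_i.to_numpy())).sum(axis=0) \
            / (n - r)
        a = (msp - msg) / nc
    return a, msg, nbar


def fst_weir_cockerham(G: pd.DataFrame, labels) -> float:
    """Multi-locus Weir-Cockerham Fst (ratio of sums) for haploid calls."""
    a, msg, _ = _wc_components(G, labels)
    num = np.nansum(a)
    den = np.nansum(a + msg)
    return float(num / den) if den > 0 else float("nan")


def fst_pairwise(G: pd.DataFrame, labels,
                 diagonal: str = "heterozygosity") -> pd.DataFrame:
    """K x K matrix: pairwise multi-locus Fst off the diagonal; on the
    diagonal the within-group mean expected heterozygosity (all loci
    polymorphic in the full panel are included)."""
    labels = pd.Series(np.asarray(labels), index=G.index)
    groups = list(pd.unique(labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out = pd.DataFrame(np.nan, index=groups, columns=groups)
    freqs = group_frequencies(G, labels)
    poly = G.std(ddof=0) > 0
    for gi in groups:
        h = expected_het(freqs.loc[gi, poly].to_numpy())
        out.loc[gi, gi] = float(np.nanmean(h)) if diagonal == "heterozygosity" \
            else np.nan
    for i, gi in enumerate(groups):
        for gj in groups[i + 1:]:
            sub = labels.isin([gi, gj])
            f = fst_weir_cockerham(G.loc[sub.to_numpy()],
                                   labels[sub].to_numpy())
            out.loc[gi, gj] = out.loc[gj, gi] = f
    return out


# ---------------------------------------------------------------------------
# covariance matrix Ω
# ---------------------------------------------------------------------------

@dataclass
class CovarianceMatrix:
    """Among-population covariance of standardized allele frequencies."""

    omega: pd.DataFrame
    n_runs: int = 1
    seed: int | None = None
    n_markers: int = 0
    meta: dict = field(default_factory=dict)

    def to_numpy(self) -> np.ndarray:
        return self.omega.to_numpy()


def _psd_project(m: np.ndarray) -> np.ndarray:
    m = (m + m.T) / 2.0
    w, v = np.linalg.eigh(m)
    w = np.maximum(w, 0.0)
    return (v * w) @ v.T


def _moment_omega(freqs: np.ndarray) -> np.ndarray:
    """Moment estimate from a (P x L) frequency matrix: covariance across
    populations of (p_j - pbar)/sqrt(pbar(1-pbar)), averaged over loci."""
    pbar = freqs.mean(axis=0)
    scale = np.sqrt(np.maximum(pbar * (1.0 - pbar), 1e-12))
    informative = (pbar > 0) & (pbar < 1)
    x = (freqs[:, informative] - pbar[informative]) / scale[informative]
    return x @ x.T / x.shape[1]


def estimate_omega(G: pd.DataFrame, labels=None, n_runs: int = 10,
                   seed: int = 0) -> CovarianceMatrix:
    """Estimate Ω from a (shortlisted, low-LD) marker set.

    ``labels`` assigns accessions to populations; by default every accession
    is its own population (sample size one), matching the association
    usage.  ``n_runs`` seeded bootstrap replicates over loci are averaged
    element-wise and the mean is projected onto the PSD cone — emulating the
    average-of-runs covariance matrix of MCMC samplers while remaining
    deterministic per seed.
    """
    if labels is None:
        labels = pd.Series(G.index, index=G.index)
        pops = list(G.index)
    else:
        labels = pd.Series(np.asarray(labels), index=G.index)
        pops = list(pd.unique(labels))
    freqs = group_frequencies(G, labels).loc[pops]
    arr = np.nan_to_num(freqs.to_numpy(),
                        nan=np.nanmean(freqs.to_numpy(), axis=0,
                                       keepdims=True))
    n_loci = arr.shape[1]
    if n_loci < 30:
        warnings.warn(f"only {n_loci} markers; Ω estimate will be unstable",
                      stacklevel=2)
    if n_runs <= 1:
        omega = _moment_omega(arr)
    else:
        rng = np.random.default_rng(seed)
        acc = np.zeros((arr.shape[0], arr.shape[0]))
        for _ in range(n_runs):
            pick = rng.integers(0, n_loci, n_loci)
            acc += _moment_omega(arr[:, pick])
        omega = acc / n_runs
    omega = _psd_project(omega)
    return CovarianceMatrix(
        omega=pd.DataFrame(omega, index=pops, columns=pops),
        n_runs=n_runs, seed=seed, n_markers=n_loci)


def null_omega(P: int, pops=None) -> CovarianceMatrix:
    """Identity covariance: the structure-uncorrected 'null model'."""
    if P < 1:
        raise ValueError("P must be >= 1")
    pops = list(pops) if pops is not None else list(range(P))
    return CovarianceMatrix(omega=pd.DataFrame(np.eye(P), index=pops,
                                               columns=pops),
                            meta={"null": True})


def write_omega(cov: CovarianceMatrix, path) -> None:
    """Whitespace-separated square matrix (the bayenv matrix dialect)."""
    np.savetxt(path, cov.to_numpy(), fmt="%.10g", delimiter="\t")


def read_omega(path, pops=None) -> CovarianceMatrix:
    arr = np.loadtxt(path)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("omega file is not a square matrix")
    pops = list(pops) if pops is not None else list(range(arr.shape[0]))
    return CovarianceMatrix(omega=pd.DataFrame(arr, index=pops, columns=pops))


# ---------------------------------------------------------------------------
# XtX
# ---------------------------------------------------------------------------

def xtx(freqs, omega, ridge: float = 1e-6) -> np.ndarray:
    """Covariance-aware differentiation statistic per locus.

    ``freqs`` is a (L x P) or (P,) matrix of per-population allele
    frequencies; Ω is regularized with ``ridge``·I before inversion.  The
    ancestral frequency is the GLS (Ω-weighted) estimate; the statistic is
    the Mahalanobis quadratic form scaled by P/(P-1) so that its neutral
    expectation is P (the GLS estimate consumes one degree of freedom).
    Loci whose ancestral estimate is fixed (0 or 1) return NaN.
    """
    omega = np.asarray(omega.omega if isinstance(omega, CovarianceMatrix)
                       else omega, dtype=float)
    theta = np.atleast_2d(np.asarray(freqs, dtype=float))
    P = omega.shape[0]
    a = np.linalg.inv(omega + ridge * np.eye(P))
    one = np.ones(P)
    a1 = a @ one
    eps = theta @ a1 / (one @ a1)
    resid = theta - eps[:, None]
    qform = np.einsum("lp,pq,lq->l", resid, a, resid)
    denom = eps * (1.0 - eps)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = qform / denom * (P / (P - 1.0))
    out[(eps <= 0.0) | (eps >= 1.0)] = np.nan
    return out if np.ndim(freqs) == 2 else float(out[0])


def pod_threshold(omega, eps_spectrum, n_sim: int = 10000,
                  percentile: float = 99.0, seed: int = 0,
                  n_per_pop=None) -> float:
    """XtX significance threshold from pseudo-observed neutral data.

    Simulates ``n_sim`` neutral loci: an ancestral frequency resampled from
    the observed spectrum, population frequencies drawn from
    ``N(eps, eps(1-eps) Ω)`` truncated to [0, 1] (optionally followed by
    binomial sampling of ``n_per_pop`` haploid calls per population), and
    returns the requested percentile of their XtX values.
    """
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000")
    cov = omega.to_numpy() if isinstance(omega, CovarianceMatrix) \
        else np.asarray(omega, dtype=float)
    P = cov.shape[0]
    rng = np.random.default_rng(seed)
    spectrum = np.clip(np.asarray(eps_spectrum, dtype=float), 0.01, 0.99)
    eps = rng.choice(spectrum, size=n_sim, replace=True)
    w, v = np.linalg.eigh((cov + cov.T) / 2.0)
    chol_like = v * np.sqrt(np.maximum(w, 0.0))
    z = rng.standard_normal((n_sim, P))
    theta = eps[:, None] + np.sqrt(eps * (1 - eps))[:, None] * (z @ chol_like.T)
    theta = np.clip(theta, 1e-6, 1 - 1e-6)
    if n_per_pop is not None:
        n_vec = np.broadcast_to(np.asarray(n_per_pop), (P,))
        theta = rng.binomial(n_vec, theta) / n_vec
        theta = np.clip(theta, 1e-6, 1 - 1e-6)
    vals = xtx(theta, cov)
    return float(np.nanpercentile(vals, percentile))


# ---------------------------------------------------------------------------
# sliding windows & scan assembly
# ---------------------------------------------------------------------------

def sliding_windows(values, ccm, width_cM: float = 4.0) -> np.ndarray:
    """Centered sliding-window means: at every marker position ``c`` the
    mean of all loci whose cumulative cM lies in the half-open window
    ``[c - width/2, c + width/2)``.  NaN values are excluded; windows with
    no finite member are NaN."""
    values = np.asarray(values, dtype=float)
    ccm = np.asarray(ccm, dtype=float)
    order = np.argsort(ccm, kind="stable")
    v, c = values[order], ccm[order]
    half = width_cM / 2.0
    lo = np.searchsorted(c, c - half, side="left")
    hi = np.searchsorted(c, c + half, side="left")
    finite = np.isfinite(v)
    cs = np.concatenate([[0.0], np.cumsum(np.where(finite, v, 0.0))])
    cn = np.concatenate([[0], np.cumsum(finite.astype(int))])
    sums = cs[hi] - cs[lo]
    counts = cn[hi] - cn[lo]
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    out = np.empty_like(means)
    out[order] = means
    return out


@dataclass
class DiffScanResult:
    """Per-locus differentiation scan with windowed values and the
    percentile reference thresholds of the genome-scan figure."""

    table: pd.DataFrame            # locus, chrom, ccM, XtX, H, rS2 + windows
    thresholds: dict


def differentiation_scan(G: pd.DataFrame, labels, mmap: pd.DataFrame,
                         Q=None, omega: CovarianceMatrix | None = None,
                         width_cM: float = 4.0, n_pod: int = 10000,
                         pod_percentile: float = 99.0,
                         seed: int = 0) -> DiffScanResult:
    """Assemble the genome differentiation scan: per-SNP XtX (against the
    group-level Ω), overall expected heterozygosity, structure-corrected
    neighbourhood LD, their 4 cM sliding windows, and the reference lines
    (POD XtX threshold; window percentiles 95/5; single-SNP 99/1)."""
    from .genodata import neighbor_ld_profile

    mmap = mmap[mmap["locus"].isin(G.columns)].sort_values(
        "ccM", kind="stable").reset_index(drop=True)
    G = G[mmap["locus"].tolist()]
    freqs = group_frequencies(G, labels)
    overall = G.mean(axis=0, skipna=True).to_numpy()
    h = expected_het(overall)
    omega = omega if omega is not None else estimate_omega(
        G, labels=pd.Series(np.asarray(labels), index=G.index),
        n_runs=1, seed=seed)
    xtx_vals = xtx(freqs.to_numpy().T, omega)
    rs2 = neighbor_ld_profile(G, mmap, n_side=4, Q=Q).to_numpy()
    ccm = mmap["ccM"].to_numpy()
    tab = pd.DataFrame({
        "locus": mmap["locus"], "chrom": mmap["chrom"], "ccM": ccm,
        "XtX": xtx_vals, "H": h, "rS2": rs2,
        "XtX_win": sliding_windows(xtx_vals, ccm, width_cM),
        "H_win": sliding_windows(h, ccm, width_cM),
        "rS2_win": sliding_windows(rs2, ccm, width_cM),
    })
    eps = overall[(overall > 0) & (overall < 1)]
    thresholds = {
        "xtx_significance": pod_threshold(omega, eps, n_sim=n_pod,
                                          percentile=pod_percentile,
                                          seed=seed),
        "xtx_win_p95": float(np.nanpercentile(tab["XtX_win"], 95)),
        "h_win_p5": float(np.nanpercentile(tab["H_win"], 5)),
        "rs2_win_p95": float(np.nanpercentile(tab["rS2_win"], 95)),
        "h_snp_p1": float(np.nanpercentile(tab["H"], 1)),
        "rs2_snp_p99": float(np.nanpercentile(tab["rS2"], 99)),
    }
    return DiffScanResult(table=tab, thresholds=thresholds)
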