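"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Everything downstream of raw data — agroclimatic indices, structure-aware
association, differentiation scans, RDA — is exercised on data produced here,
with known truth labels:

* daily weather on a coarse grid of sites with latitude and altitude
  gradients (seasonal sinusoid + AR(1) noise for temperature, a
  Bernoulli-gamma mixture for precipitation, a smooth seasonal reference
  evapotranspiration curve),
* inbred (haploid-coded) accessions in a few subpopulations under the
  Balding-Nichols model, parameterized directly by per-group Fst,
* a handful of causal loci whose allele frequencies follow an environmental
  cline of stated effect size (logit-scale shift per 1 SD of environment).

All generators are reproducible bit-for-bit given a seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .agroclim import SeasonSpec, build_catalogue

__all__ = [
    "WeatherGenParams",
    "SyntheticTruth",
    "GenotypeBundle",
    "FixtureBundle",
    "gen_daily_weather",
    "gen_structured_genotypes",
    "plant_env_clines",
    "end_to_end_fixture",
    "make_sites",
]


@dataclass
class WeatherGenParams:
    """Parameters of the daily weather generator.

    Temperature: a seasonal sinusoid for the daily mean (peak around late
    July), plus AR(1) Gaussian noise; the diurnal range is constant with
    optional Gaussian jitter.  Altitude cools at ``lapse_rate`` °C/km and a
    linear latitude gradient mimics the north-south contrast.  Precipitation
    is a per-month Bernoulli occurrence times a gamma amount.  ET0 is a
    smooth seasonal curve (it is consumed, not modelled, downstream).
    """

    n_years: int = 30
    start_year: int = 1981
    grid_dims: tuple = (8, 8)
    cell_size_km: float = 50.0
    tmin_mean: float = 6.0          # sea-level annual means, °C
    tmax_mean: float = 16.0
    seasonal_amplitude: float = 8.0  # °C, on the daily mean
    lapse_rate: float = 6.5          # °C per km altitude
    lat_gradient: float = -0.005     # °C per km northward
    temp_noise_sd: float = 2.0
    range_noise_sd: float = 1.0
    ar1_coefficient: float = 0.7
    precip_occurrence_prob: tuple = (0.35, 0.32, 0.30, 0.30, 0.25, 0.15,
                                     0.08, 0.08, 0.20, 0.30, 0.35, 0.38)
    precip_lat_gradient: float = 0.0004  # occurrence prob per km northward
    precip_shape: float = 0.8            # gamma, mm
    precip_scale: float = 6.0
    et0_mean: float = 3.4                # mm/day
    et0_amplitude: float = 2.6
    et0_alt_coeff: float = 8e-5          # fractional loss per m altitude
    et0_lat_coeff: float = 2e-4          # fractional loss per km northward
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        if min(self.grid_dims) < 1 or self.cell_size_km <= 0:
            raise ValueError("invalid grid specification")
        if self.tmax_mean < self.tmin_mean:
            raise ValueError("tmax_mean must be >= tmin_mean")
        if not 0 <= self.ar1_coefficient < 1:
            raise ValueError("ar1_coefficient must be in [0, 1)")
        if any(not 0 <= p <= 1 for p in self.precip_occurrence_prob):
            raise ValueError("precipitation probabilities must be in [0, 1]")
        if self.precip_shape <= 0 or self.precip_scale <= 0:
            raise ValueError("gamma shape/scale must be > 0")


def _seasonal(doy: np.ndarray, mean: float, amplitude: float) -> np.ndarray:
    # peak on DOY 202 (late July), trough in winter
    return mean + amplitude * np.cos(2.0 * np.pi * (doy - 202) / 365.25)


def gen_daily_weather(params: WeatherGenParams,
                      sites: pd.DataFrame) -> pd.DataFrame:
    """Generate a complete daily series per site.

    ``sites`` needs columns id, lon, lat (projected km) and alt (m).
    Returns a long frame (site, date, tmin, tmax, pcp, et0) with no calendar
    gaps, ``tmax >= tmin`` every day and non-negative pcp/et0.
    """
    if len(sites) < 1:
        raise ValueError("need at least one site")
    dates = pd.date_range(f"{params.start_year}-01-01",
                          f"{params.start_year + params.n_years - 1}-12-31",
                          freq="D")
    doy = dates.dayofyear.to_numpy()
    month = dates.month.to_numpy()
    nd = len(dates)
    range_mean = params.tmax_mean - params.tmin_mean
    tmed_mean = (params.tmax_mean + params.tmin_mean) / 2.0
    p_occ_base = np.asarray(params.precip_occurrence_prob)[month - 1]
    et0_base = np.maximum(
        0.0, _seasonal(doy, params.et0_mean, params.et0_amplitude))

    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(params.seed).spawn(len(sites))]
    frames = []
    for (_, site), rng in zip(sites.iterrows(), streams):
        shift = (-params.lapse_rate * site["alt"] / 1000.0
                 + params.lat_gradient * site["lat"])
        eps = rng.normal(0.0, params.temp_noise_sd, nd)
        noise = lfilter([1.0], [1.0, -params.ar1_coefficient], eps)
        tmed = _seasonal(doy, tmed_mean, params.seasonal_amplitude) \
            + shift + noise
        rng_day = range_mean + rng.normal(0.0, params.range_noise_sd, nd)
        rng_day = np.maximum(rng_day, 0.0)
        tmin = tmed - rng_day / 2.0
        tmax = tmed + rng_day / 2.0
        p_occ = np.clip(
            p_occ_base + params.precip_lat_gradient * site["lat"],
            0.01 if params.precip_lat_gradient else 0.0, 0.95)
        wet = rng.random(nd) < p_occ
        amount = rng.gamma(params.precip_shape, params.precip_scale, nd)
        pcp = np.where(wet, amount, 0.0)
        et0_factor = max(0.0, 1.0 - params.et0_alt_coeff * site["alt"]
                         - params.et0_lat_coeff * site["lat"])
        frames.append(pd.DataFrame({
            "site": site["id"], "date": dates,
            "tmin": tmin, "tmax": tmax, "pcp": pcp,
            "et0": et0_base * et0_factor,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# structured genotypes
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Truth labels of a synthetic data set, for recovery tests."""

    causal_locus_ids: list
    causal_variable_names: list
    effect_sizes: dict                  # locus id -> logit shift per 1 SD env
    group_assignments: pd.Series        # accession -> group label
    group_fst: dict                     # group label -> F in (0, 1)
    causal_variable_of: dict = field(default_factory=dict)  # locus -> variable

    def __post_init__(self) -> None:
        for b in self.effect_sizes.values():
            if not np.isfinite(b):
                raise ValueError("effect sizes must be finite")
        for f in self.group_fst.values():
            if not 0 < f < 1:
                raise ValueError("group Fst must be in (0, 1)")


@dataclass
class GenotypeBundle:
    """Haploid-coded genotype matrix with its structure objects."""

    calls: pd.DataFrame        # accessions x loci, {0.0, 1.0, NaN}
    q_matrix: pd.DataFrame     # accessions x K
    marker_map: pd.DataFrame   # locus id, chrom, cM, bp, ccM
    group_assignments: pd.Series
    group_freqs: pd.DataFrame  # groups x loci, Balding-Nichols frequencies
    ancestral_freqs: pd.Series


def _build_marker_map(locus_ids, n_chrom: int, rng) -> pd.DataFrame:
    n_loci = len(locus_ids)
    chroms = np.array_split(np.arange(n_loci), n_chrom)
    rows = []
    ccm_offset = 0.0
    for c, idx in enumerate(chroms, start=1):
        cm = np.sort(rng.uniform(0.0, 150.0, len(idx)))
        # strictly increasing cM within chromosome (unique positions)
        cm = cm + np.arange(len(idx)) * 1e-6
        bp = (cm * 4e6).astype(np.int64) + 1
        for j, i in enumerate(idx):
            rows.append((locus_ids[i], f"{c}H", cm[j], bp[j],
                         ccm_offset + cm[j]))
        ccm_offset += 160.0
    return pd.DataFrame(rows, columns=["locus", "chrom", "cM", "bp", "ccM"])


def gen_structured_genotypes(n_acc: int, n_loci: int, group_sizes,
                             fst, seed: int, n_chrom: int = 7,
                             missing_rate: float = 0.0) -> GenotypeBundle:
    """Balding-Nichols haploid genotypes in K subpopulations.

    Per-group locus frequencies are drawn from
    ``Beta(p (1-F)/F, (1-p) (1-F)/F)`` around a uniform ancestral frequency
    ``p``; accession calls are Bernoulli draws.  ``fst`` may be a scalar or
    one value per group.  Missing data are injected uniformly at random at
    ``missing_rate`` (NaN calls).
    """
    group_sizes = list(group_sizes)
    k = len(group_sizes)
    if sum(group_sizes) != n_acc:
        raise ValueError(f"group sizes {group_sizes} do not sum to {n_acc}")
    if n_acc < k or k < 1:
        raise ValueError("need n_acc >= K >= 1")
    fst_vec = np.broadcast_to(np.asarray(fst, dtype=float), (k,)).copy()
    if np.any(fst_vec <= 0) or np.any(fst_vec >= 1):
        raise ValueError("fst must be in (0, 1)")
    rng = np.random.default_rng(seed)
    anc = rng.uniform(0.1, 0.9, n_loci)
    group_freqs = np.empty((k, n_loci))
    for g in range(k):
        c = (1.0 - fst_vec[g]) / fst_vec[g]
        group_freqs[g] = rng.beta(np.maximum(c * anc, 1e-12),
                                  np.maximum(c * (1.0 - anc), 1e-12))
    labels = np.repeat([f"G{g + 1}" for g in range(k)], group_sizes)
    calls = np.empty((n_acc, n_loci))
    start = 0
    for g, size in enumerate(group_sizes):
        calls[start:start + size] = (
            rng.random((size, n_loci)) < group_freqs[g]).astype(float)
        start += size
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = np.nan
    acc_ids = [f"acc{i + 1:03d}" for i in range(n_acc)]
    locus_ids = [f"snp{i + 1:05d}" for i in range(n_loci)]
    q = pd.DataFrame(0.0, index=acc_ids,
                     columns=[f"Q{g + 1}" for g in range(k)])
    for i, lab in enumerate(labels):
        q.iloc[i, int(lab[1:]) - 1] = 1.0
    mmap = _build_marker_map(locus_ids, min(n_chrom, n_loci), rng)
    return GenotypeBundle(
        calls=pd.DataFrame(calls, index=acc_ids, columns=locus_ids),
        q_matrix=q,
        marker_map=mmap,
        group_assignments=pd.Series(labels, index=acc_ids, name="group"),
        group_freqs=pd.DataFrame(group_freqs,
                                 index=[f"G{g + 1}" for g in range(k)],
                                 columns=locus_ids),
        ancestral_freqs=pd.Series(anc, index=locus_ids),
    )


def _logit(p):
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1.0 - p))


def plant_env_clines(bundle: GenotypeBundle, env, causal_ids, beta: float,
                     seed: int):
    """Re-draw causal loci with an environmental cline.

    At each causal locus the allele probability of accession *i* becomes
    ``logistic(logit(p_group(i)) + beta * env_i)`` with ``env`` standardized;
    non-causal loci are untouched.  Returns ``(GenotypeBundle,
    SyntheticTruth)``.
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    causal_ids = list(causal_ids)
    unknown = set(causal_ids) - set(bundle.calls.columns)
    if unknown:
        raise ValueError(f"causal ids not in the genotype matrix: {unknown}")
    env = np.asarray(env, dtype=float)
    calls = bundle.calls.copy()
    rng = np.random.default_rng(seed)
    if causal_ids:
        base = bundle.group_freqs.loc[
            bundle.group_assignments.to_numpy(), causal_ids].to_numpy()
        prob = 1.0 / (1.0 + np.exp(-(_logit(base) + beta * env[:, None])))
        new = (rng.random(prob.shape) < prob).astype(float)
        missing = calls[causal_ids].isna().to_numpy()
        new[missing] = np.nan
        calls[causal_ids] = new
    truth = SyntheticTruth(
        causal_locus_ids=causal_ids,
        causal_variable_names=[],
        effect_sizes={lid: beta for lid in causal_ids},
        group_assignments=bundle.group_assignments,
        group_fst={},
    )
    out = GenotypeBundle(calls=calls, q_matrix=bundle.q_matrix,
                         marker_map=bundle.marker_map,
                         group_assignments=bundle.group_assignments,
                         group_freqs=bundle.group_freqs,
                         ancestral_freqs=bundle.ancestral_freqs)
    return out, truth


# ---------------------------------------------------------------------------
# end-to-end fixture
# ---------------------------------------------------------------------------

def make_sites(n_sites: int, group_labels, params: WeatherGenParams,
               seed: int) -> pd.DataFrame:
    """Collection sites on the weather grid, one per accession.

    Groups are placed around distinct geographic centres (so that group
    membership, geography and climate are genuinely entangled, as in real
    landrace collections), with within-group scatter and a broad altitude
    range.
    """
    rng = np.random.default_rng(seed)
    rows, cols = params.grid_dims
    extent_x = cols * params.cell_size_km
    extent_y = rows * params.cell_size_km
    groups = pd.unique(np.asarray(group_labels))
    centres = {g: (rng.uniform(0.2, 0.8) * extent_x,
                   rng.uniform(0.2, 0.8) * extent_y) for g in groups}
    recs = []
    for i, g in enumerate(group_labels):
        cx, cy = centres[g]
        lon = np.clip(cx + rng.normal(0, 0.18 * extent_x), 0, extent_x)
        lat = np.clip(cy + rng.normal(0, 0.18 * extent_y), 0, extent_y)
        alt = np.clip(rng.gamma(2.0, 250.0) + 0.4 * lat, 0, 2200)
        recs.append((f"site{i + 1:03d}", lon, lat, alt))
    return pd.DataFrame(recs, columns=["id", "lon", "lat", "alt"])


@dataclass
class FixtureBundle:
    """Self-consistent synthetic inputs for the whole pipeline."""

    sites: pd.DataFrame
    weather: pd.DataFrame           # long daily climate
    catalogue: object               # AcvCatalogue
    env: pd.DataFrame               # accessions x selected variables (raw)
    genotypes: GenotypeBundle
    truth: SyntheticTruth
    seed: int

    def checksum(self) -> str:
        h = hashlib.sha256()
        for arr in (self.env.to_numpy(),
                    np.nan_to_num(self.genotypes.calls.to_numpy(), nan=-1.0),
                    self.genotypes.q_matrix.to_numpy()):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()


DEFAULT_GROUP_SIZES = (13, 9, 43, 55)          # scaled 15/10/48/62 panel
DEFAULT_GROUP_FST = (0.25, 0.35, 0.20, 0.22)   # realistic landrace range


def end_to_end_fixture(seed: int, n_acc: int = 120, n_loci: int = 3000,
                       n_causal: int = 20, beta: float = 2.0,
                       n_years: int = 15,
                       causal_variables=("pfrost", "bal_jun"),
                       group_sizes=None, group_fst=None,
                       missing_rate: float = 0.05) -> FixtureBundle:
    """Generate the full synthetic study: weather, ACVs, genotypes, truth.

    Defaults emulate the study conditions at CI scale: ~120 inbred
    accessions in 4 subpopulations (sizes proportional to the real panel),
    3,000 biallelic SNPs, 15 years of daily weather, 20 causal loci with a
    logit-scale cline of ``beta`` per 1 SD of environment, split evenly
    over the causal variables.
    """
    ss = np.random.SeedSequence(seed)
    s_geno, s_sites, s_weather, s_cline, s_missing = [
        int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(5)]
    if group_sizes is None:
        group_sizes = [round(g * n_acc / sum(DEFAULT_GROUP_SIZES))
                       for g in DEFAULT_GROUP_SIZES]
        group_sizes[-1] += n_acc - sum(group_sizes)
    if group_fst is None:
        group_fst = DEFAULT_GROUP_FST[:len(group_sizes)]
    geno = gen_structured_genotypes(n_acc, n_loci, group_sizes, group_fst,
                                    seed=s_geno)
    params = WeatherGenParams(n_years=n_years, seed=s_weather)
    sites = make_sites(n_acc, geno.group_assignments.to_numpy(), params,
                       seed=s_sites)
    weather = gen_daily_weather(params, sites)
    series_by_site = {sid: g.drop(columns="site")
                      for sid, g in weather.groupby("site", sort=False)}
    catalogue = build_catalogue(series_by_site, sites, SeasonSpec())
    env = catalogue.selected()
    env.index = geno.calls.index  # site i collected accession i

    rng = np.random.default_rng(s_cline)
    causal_variables = list(causal_variables)
    causal_ids = [f"snp{i + 1:05d}"
                  for i in sorted(rng.choice(n_loci, n_causal, replace=False))]
    var_of = {}
    calls = geno.calls
    truth_effects = {}
    for j, block in enumerate(np.array_split(np.arange(n_causal),
                                             len(causal_variables))):
        var = causal_variables[j]
        ids = [causal_ids[i] for i in block]
        e = env[var].to_numpy()
        sd = e.std(ddof=0)
        e_std = (e - e.mean()) / sd if sd > 0 else np.zeros_like(e)
        geno, _ = plant_env_clines(geno, e_std, ids, beta,
                                   seed=s_cline + j + 1)
        for lid in ids:
            var_of[lid] = var
            truth_effects[lid] = beta
    if missing_rate > 0:
        m_rng = np.random.default_rng(s_missing)
        arr = geno.calls.to_numpy()
        arr[m_rng.random(arr.shape) < missing_rate] = np.nan
        geno.calls.loc[:, :] = arr
    truth = SyntheticTruth(
        causal_locus_ids=causal_ids,
        causal_variable_names=causal_variables,
        effect_sizes=truth_effects,
        group_assignments=geno.group_assignments,
        group_fst=dict(zip([f"G{i+1}" for i in range(len(group_sizes))],
                           group_fst)),
        causal_variable_of=var_of,
    )
    return FixtureBundle(sites=sites, weather=weather, catalogue=catalogue,
                         env=env, genotypes=geno, truth=truth, seed=seed)
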