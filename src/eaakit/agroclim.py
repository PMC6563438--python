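"""Agroclimatic variables for winter cereals from daily climate series.

Computes the catalogue of agroclimatic variables (ACVs) used to describe
landrace collection sites: temporal aggregates of precipitation, temperature,
thermal amplitude, frost-day counts, reference evapotranspiration and the
climatic water balance, plus two phenology-motivated indices:

* *potential vernalization* — the climatically effective exposure to cold
  that a winter cereal sown in autumn would accumulate, computed daily from
  ``tmin``/``tmax`` assuming a within-day sine temperature curve
  (CERES-Wheat style) and a piecewise-linear effectiveness response, and
* *pfrost* — the first day of year at which the late-frost probability drops
  to a one-in-ten-year return period.

The default catalogue holds exactly 147 agroclimatic variables; an
``analysis_subset`` view drops the summer aggregates and the July-October
months, which have no bearing on an autumn-sown crop, and named multi-month
composites (``pcp_mar_apr`` etc.) can be derived on top.

Variable clustering (Ward D2 on standardized variables) and a PCA of the
standardized catalogue support the selection of a non-redundant subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "SeasonSpec",
    "AcvCatalogue",
    "EnvPcaResult",
    "vern_effectiveness",
    "diurnal_sine",
    "daily_vernalization",
    "verna_nd",
    "pfrost",
    "aggregate",
    "build_catalogue",
    "composite_variable",
    "cluster_variables",
    "pca_env",
    "SELECTED_VARIABLES",
    "read_daily_climate",
    "validate_daily_series",
]

MONTH_ABBR = ["jan", "feb", "mar", "apr", "may", "jun",
              "jul", "aug", "sep", "oct", "nov", "dec"]

#: families aggregated by summation within a period (then averaged over years)
SUM_FAMILIES = frozenset({"pcp", "ET_0", "verna", "frost", "bal"})
#: families aggregated by (day-weighted) averaging within a period
MEAN_FAMILIES = frozenset({"tmed", "tmax", "tmin", "tamp"})

#: the representative low-redundancy variable preset (17 agroclimatic + 3
#: geographic), one or two variables per Ward cluster, matched to barley
#: growth phases
SELECTED_VARIABLES = [
    "lon", "lat", "alt",
    "pcp_aut", "pcp_win", "pcp_mar_apr", "pcp_may_jun",
    "ET_0_spr",
    "bal_aut", "bal_win", "bal_mar_apr_may", "bal_jun",
    "tamp_win", "tamp_spr",
    "verna_30d", "verna_jan_feb", "verna_mar_apr",
    "frost_jan_feb", "frost_apr_may",
    "pfrost",
]


@dataclass
class SeasonSpec:
    """Season definitions and sowing assumptions for the catalogue.

    ``months`` maps season suffix to calendar month numbers.  The default
    uses meteorological seasons (win=DJF, spr=MAM, aut=SON, summer=JJA);
    a two-month spring (Mar-Apr) can be configured instead.
    """

    months: dict = field(default_factory=lambda: {
        "win": (12, 1, 2),
        "spr": (3, 4, 5),
        "summer": (6, 7, 8),
        "aut": (9, 10, 11),
    })
    sowing_month: int = 11
    sowing_day: int = 15
    imbibition_days: int = 5
    verna_targets: tuple = (10, 20, 30, 40)

    def __post_init__(self) -> None:
        if not 1 <= self.sowing_month <= 12 or not 1 <= self.sowing_day <= 28:
            raise ValueError("invalid sowing date")
        for name, ms in self.months.items():
            if any(m < 1 or m > 12 for m in ms):
                raise ValueError(f"season {name!r} has invalid months")


# ---------------------------------------------------------------------------
# vernalization model
# ---------------------------------------------------------------------------

def vern_effectiveness(temp):
    """Vernalization effectiveness of a temperature, in [0, 1].

    Effective cold starts at 0 °C, ramps linearly to full effect at 4 °C,
    stays fully effective up to 8 °C, then declines linearly to zero at
    15 °C (thresholds calibrated for barley).
    """
    t = np.asarray(temp, dtype=float)
    eff = np.minimum(np.minimum(t / 4.0, (15.0 - t) / 7.0), 1.0)
    out = np.clip(eff, 0.0, 1.0)
    return out if out.ndim else float(out)


def diurnal_sine(tmin, tmax, n_steps: int = 24):
    """Within-day temperature samples along a sine curve.

    Samples ``T(h) = (tmax+tmin)/2 + (tmax-tmin)/2 * sin(2*pi*h/24 - pi/2)``
    at ``n_steps`` equally spaced points over the 24 h cycle, so the samples
    attain ``tmin`` and ``tmax`` exactly and average to their midpoint.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    tmin = float(tmin)
    tmax = float(tmax)
    if tmax < tmin:
        raise ValueError("tmax must be >= tmin")
    h = np.arange(n_steps) * (24.0 / n_steps)
    return (tmax + tmin) / 2.0 + (tmax - tmin) / 2.0 * np.sin(
        2.0 * np.pi * h / 24.0 - np.pi / 2.0)


_DEFAULT_VERN_STEPS = 240
_DIURNAL_PHASE = np.sin(
    2.0 * np.pi * np.arange(_DEFAULT_VERN_STEPS) / _DEFAULT_VERN_STEPS
    - np.pi / 2.0)


def daily_vernalization(tmin, tmax, n_steps: int = _DEFAULT_VERN_STEPS):
    """Vernalization-day fraction contributed by one day, in [0, 1].

    Mean of :func:`vern_effectiveness` over the diurnal sine curve, sampled
    densely enough (240 steps) that the piecewise-linear kinks of the
    response contribute less than 1e-3 discretization error.  Accepts
    scalars or equally shaped arrays (vectorized over days).
    """
    tmin_a = np.atleast_1d(np.asarray(tmin, dtype=float))
    tmax_a = np.atleast_1d(np.asarray(tmax, dtype=float))
    if np.any(tmax_a < tmin_a):
        raise ValueError("tmax must be >= tmin")
    if n_steps == _DEFAULT_VERN_STEPS:
        phase = _DIURNAL_PHASE
    else:
        if n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        phase = np.sin(2.0 * np.pi * np.arange(n_steps) / n_steps - np.pi / 2.0)
    mid = (tmax_a + tmin_a) / 2.0
    amp = (tmax_a - tmin_a) / 2.0
    temps = mid[..., None] + amp[..., None] * phase
    frac = vern_effectiveness(temps).mean(axis=-1)
    return float(frac[0]) if np.isscalar(tmin) or np.ndim(tmin) == 0 else frac


# ---------------------------------------------------------------------------
# daily series handling
# ---------------------------------------------------------------------------

def validate_daily_series(df: pd.DataFrame) -> pd.DataFrame:
    """Check a single-site daily series: complete calendar, tmax>=tmin,
    non-negative pcp/et0. Returns the frame sorted by date."""
    df = df.sort_values("date").reset_index(drop=True)
    dates = pd.DatetimeIndex(df["date"])
    expected = pd.date_range(dates[0], dates[-1], freq="D")
    if len(dates) != len(expected) or not (dates == expected).all():
        raise ValueError("daily series has calendar gaps or duplicates")
    if (df["tmax"] < df["tmin"]).any():
        raise ValueError("tmax < tmin in daily series")
    if (df["pcp"] < 0).any() or (df["et0"] < 0).any():
        raise ValueError("negative pcp or et0 in daily series")
    return df


def read_daily_climate(path) -> pd.DataFrame:
    """Read a long-format daily climate CSV (site,date,tmin,tmax,pcp,et0)."""
    df = pd.read_csv(path, parse_dates=["date"])
    required = {"site", "date", "tmin", "tmax", "pcp", "et0"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"climate table missing columns: {sorted(missing)}")
    return df


def _prepare(series: pd.DataFrame) -> pd.DataFrame:
    """Add derived daily columns to a validated single-site series."""
    df = validate_daily_series(series)
    df = df.assign(
        tmed=(df["tmin"] + df["tmax"]) / 2.0,
        tamp=df["tmax"] - df["tmin"],
        frost=(df["tmin"] < 0).astype(float),
        verna=daily_vernalization(df["tmin"].to_numpy(), df["tmax"].to_numpy()),
        year=pd.DatetimeIndex(df["date"]).year,
        month=pd.DatetimeIndex(df["date"]).month,
        doy=pd.DatetimeIndex(df["date"]).dayofyear,
    )
    return df


def _monthly_climatology(daily: pd.DataFrame) -> pd.DataFrame:
    """Per calendar month: across-year average of monthly sums (sum families)
    and means (mean families). Index = month 1..12."""
    bym = daily.groupby(["year", "month"])
    sums = bym[["pcp", "et0", "verna", "frost"]].sum()
    means = bym[["tmed", "tmax", "tmin", "tamp"]].mean()
    ndays = bym.size().rename("ndays")
    monthly = pd.concat([sums, means, ndays], axis=1).reset_index()
    clim = monthly.groupby("month").mean().drop(columns="year")
    clim["bal"] = clim["pcp"] - clim["et0"]
    return clim


def aggregate(series: pd.DataFrame, variable: str, period,
              spec: SeasonSpec | None = None) -> float:
    """Aggregate one variable of a single-site daily series over a period.

    ``variable`` is one of pcp, tmed, tmax, tmin, tamp, frost, verna, ET_0,
    bal; ``period`` a month number, a month abbreviation, a season suffix
    from ``spec.months``, or "annual".  Sum families are summed within the
    period and averaged across years; mean families are day-weighted means.
    """
    spec = spec or SeasonSpec()
    colmap = {"ET_0": "et0"}
    col = colmap.get(variable, variable)
    valid = SUM_FAMILIES | MEAN_FAMILIES
    if variable not in valid:
        raise ValueError(f"unknown variable {variable!r}")
    clim = _monthly_climatology(_prepare(series))
    months = _period_months(period, spec)
    sub = clim.loc[list(months)]
    if variable in SUM_FAMILIES:
        return float(sub[col].sum())
    return float(np.average(sub[col], weights=sub["ndays"]))


def _period_months(period, spec: SeasonSpec):
    if isinstance(period, int):
        if not 1 <= period <= 12:
            raise ValueError(f"invalid month {period}")
        return (period,)
    if period in MONTH_ABBR:
        return (MONTH_ABBR.index(period) + 1,)
    if period == "annual":
        return tuple(range(1, 13))
    if period in spec.months:
        return tuple(spec.months[period])
    raise ValueError(f"unknown period {period!r}")


# ---------------------------------------------------------------------------
# phenology indices
# ---------------------------------------------------------------------------

def verna_nd(series: pd.DataFrame, n_target: int,
             spec: SeasonSpec | None = None) -> float:
    """Mean days from sowing to accumulate ``n_target`` vernalization days.

    Counts calendar days from the sowing date (day 1) of each season-year;
    vernalization starts accruing only after the imbibition lag.  Years in
    which the target is never reached before the following 30 June are
    excluded with a warning; NaN if no year reaches it.
    """
    return _verna_nd_prepared(_prepare(series), n_target, spec)


def _verna_nd_prepared(daily: pd.DataFrame, n_target: int,
                       spec: SeasonSpec | None = None) -> float:
    spec = spec or SeasonSpec()
    if n_target not in spec.verna_targets:
        warnings.warn(
            f"verna_Nd target {n_target} outside the standard set "
            f"{spec.verna_targets}", stacklevel=2)
    if n_target <= 0:
        raise ValueError("n_target must be positive")
    by_date = daily.set_index("date")
    years = sorted(daily["year"].unique())
    counts = []
    n_failed = 0
    for y in years:
        sowing = pd.Timestamp(y, spec.sowing_month, spec.sowing_day)
        end = pd.Timestamp(y + 1, 6, 30)
        if sowing < by_date.index[0] or end > by_date.index[-1]:
            continue  # incomplete season-year
        window = by_date.loc[sowing:end, "verna"].to_numpy(copy=True)
        window[:spec.imbibition_days] = 0.0  # seed imbibition lag
        cum = np.cumsum(window)
        hit = np.nonzero(cum >= n_target)[0]
        if hit.size == 0:
            n_failed += 1
            continue
        counts.append(hit[0] + 1)  # day 1 = sowing date
    if n_failed:
        warnings.warn(
            f"verna_{n_target}d: target never reached in {n_failed} "
            "season-year(s); excluded from the average", stacklevel=2)
    if not counts:
        return float("nan")
    return float(np.mean(counts))


def pfrost(series: pd.DataFrame, threshold: float = 0.10,
           window_end_doy: int = 181, min_years: int = 10,
           pointwise: bool = False) -> float:
    """First day of year at which late-frost probability drops to <= 10 %.

    With ``q(d)`` = fraction of years having at least one day with
    ``tmin < 0`` on day-of-year >= ``d`` (within the Jan 1 - Jun 30 search
    window), returns ``min{d : q(d) <= threshold}`` — the return-period
    reading of "P(tmin<0) <= 0.10".  ``pointwise=True`` instead thresholds
    the per-day frost frequency smoothed over the remaining season.
    """
    return _pfrost_prepared(_prepare(series), threshold, window_end_doy,
                            min_years, pointwise)


def _pfrost_prepared(daily: pd.DataFrame, threshold: float = 0.10,
                     window_end_doy: int = 181, min_years: int = 10,
                     pointwise: bool = False) -> float:
    if window_end_doy < 1:
        raise ValueError("empty search window")
    years = sorted(daily["year"].unique())
    complete = [y for y in years
                if (daily["year"] == y).sum() >= 365]
    if len(complete) < min_years:
        raise ValueError(
            f"pfrost needs >= {min_years} complete years, got {len(complete)}")
    sub = daily[daily["year"].isin(complete) & (daily["doy"] <= window_end_doy)]
    if pointwise:
        freq = (sub.groupby("doy")["frost"].mean()
                .reindex(range(1, window_end_doy + 1), fill_value=0.0))
        ok = freq[freq <= threshold]
        return float(ok.index[0]) if len(ok) else float(window_end_doy + 1)
    # last frost DOY per year (0 if no frost that year)
    last = (sub[sub["frost"] > 0].groupby("year")["doy"].max()
            .reindex(complete, fill_value=0))
    n = len(complete)
    for d in range(1, window_end_doy + 2):
        q = float((last >= d).sum()) / n
        if q <= threshold:
            return float(d)
    return float(window_end_doy + 1)  # unreachable; q(end+1)=0


# ---------------------------------------------------------------------------
# catalogue construction
# ---------------------------------------------------------------------------

@dataclass
class AcvCatalogue:
    """Site x agroclimatic-variable matrix plus geographic columns."""

    data: pd.DataFrame           # sites x (ACVs + lon/lat/alt)
    agroclimatic: list           # the ACV column names (147 by default)
    spec: SeasonSpec

    @property
    def geo(self):
        return [c for c in ("lon", "lat", "alt") if c in self.data.columns]

    def analysis_subset(self, composites: dict | None = None,
                        drop_months=("jul", "aug", "sep", "oct"),
                        drop_seasons=("summer",)) -> pd.DataFrame:
        """Catalogue view excluding summer aggregates and Jul-Oct months,
        optionally extended with named multi-month composites
        (``{"pcp_mar_apr": ("pcp", ["mar", "apr"]), ...}``)."""
        drop = [c for c in self.agroclimatic
                if any(c.endswith(f"_{m}") for m in drop_months)
                or any(c.endswith(f"_{s}") for s in drop_seasons)]
        out = self.data.drop(columns=drop)
        if composites:
            extra = {name: composite_variable(self.data, family, months)
                     for name, (family, months) in composites.items()}
            out = pd.concat([out, pd.DataFrame(extra, index=out.index)], axis=1)
        return out

    def selected(self, names=None) -> pd.DataFrame:
        """The representative variable preset (defaults to the shipped
        20-name list), deriving multi-month composites as needed."""
        names = list(names) if names is not None else list(SELECTED_VARIABLES)
        cols = {}
        for name in names:
            if name in self.data.columns:
                cols[name] = self.data[name]
            else:
                family, months = _parse_composite(name)
                cols[name] = composite_variable(self.data, family, months)
        return pd.DataFrame(cols, index=self.data.index)


def _parse_composite(name: str):
    """Split e.g. 'pcp_mar_apr' -> ('pcp', ['mar','apr'])."""
    for family in sorted(SUM_FAMILIES | MEAN_FAMILIES, key=len, reverse=True):
        if name.startswith(family + "_"):
            toks = name[len(family) + 1:].split("_")
            if toks and all(t in MONTH_ABBR for t in toks):
                return family, toks
    raise KeyError(f"cannot derive variable {name!r}")


def composite_variable(catalogue: pd.DataFrame, family: str, months) -> pd.Series:
    """Multi-month composite: sum of monthly columns for sum families
    (pcp, bal, ET_0, verna, frost), mean for temperature families."""
    cols = [f"{family}_{m}" for m in months]
    block = catalogue[cols]
    if family in SUM_FAMILIES:
        return block.sum(axis=1)
    return block.mean(axis=1)


def build_catalogue(series_by_site: dict, sites: pd.DataFrame | None = None,
                    spec: SeasonSpec | None = None) -> AcvCatalogue:
    """Compute the full ACV catalogue for a set of sites.

    ``series_by_site`` maps site id to a daily climate frame;
    ``sites`` optionally supplies lon/lat/alt columns indexed by site id.
    The default SeasonSpec yields exactly 147 agroclimatic columns:
    6 families x (12 months + 4 seasons) + 12 monthly verna + 4 verna_Nd
    + pfrost + 17 ET_0 + 17 bal.
    """
    spec = spec or SeasonSpec()
    season_names = list(spec.months)
    periods = MONTH_ABBR + season_names          # month+season families
    rows = {}
    spans = set()
    for site_id, series in series_by_site.items():
        daily = _prepare(series)
        spans.add((daily["date"].iloc[0], daily["date"].iloc[-1]))
        clim = _monthly_climatology(daily).reindex(range(1, 13))
        arrays = {c: clim[c].to_numpy() for c in clim.columns}
        ndays = arrays["ndays"]
        midx = {per: np.array(_period_months(per, spec)) - 1
                for per in periods + ["annual"]}

        def agg(col, family, per):
            ix = midx[per]
            if family in SUM_FAMILIES:
                return float(arrays[col][ix].sum())
            return float(np.average(arrays[col][ix], weights=ndays[ix]))

        row = {}
        for family, col in [("pcp", "pcp"), ("tmed", "tmed"), ("tmax", "tmax"),
                            ("tmin", "tmin"), ("tamp", "tamp"),
                            ("frost", "frost")]:
            for per in periods:
                row[f"{family}_{per}"] = agg(col, family, per)
        for m_idx, m in enumerate(MONTH_ABBR):
            row[f"verna_{m}"] = float(arrays["verna"][m_idx])
        for n in spec.verna_targets:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                row[f"verna_{n}d"] = _verna_nd_prepared(daily, n, spec)
        row["pfrost"] = _pfrost_prepared(daily)
        for family, col in [("ET_0", "et0"), ("bal", "bal")]:
            for per in periods + ["annual"]:
                row[f"{family}_{per}"] = agg(col, family, per)
        rows[site_id] = row
    if len(spans) > 1:
        raise ValueError("sites do not share the same climatology period")
    data = pd.DataFrame.from_dict(rows, orient="index")
    acv_names = list(data.columns)
    if sites is not None:
        geo = sites.set_index("id") if "id" in sites.columns else sites
        for col in ("lon", "lat", "alt"):
            if col in geo.columns:
                data[col] = geo.loc[data.index, col].to_numpy()
    return AcvCatalogue(data=data, agroclimatic=acv_names, spec=spec)


def _agg_from_clim(clim: pd.DataFrame, col: str, family: str, period,
                   spec: SeasonSpec) -> float:
    months = _period_months(period, spec)
    sub = clim.loc[list(months)]
    if family in SUM_FAMILIES:
        return float(sub[col].sum())
    return float(np.average(sub[col], weights=sub["ndays"]))


# ---------------------------------------------------------------------------
# variable clustering and PCA
# ---------------------------------------------------------------------------

def _standardize_columns(df: pd.DataFrame, on_constant: str = "drop"):
    sd = df.std(ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        if on_constant == "error":
            raise ValueError(f"constant column(s): {constant}")
        warnings.warn(f"dropping constant variable(s): {constant}",
                      stacklevel=3)
        df = df.drop(columns=constant)
        sd = sd.drop(index=constant)
    return (df - df.mean()) / sd


def cluster_variables(catalogue: pd.DataFrame, k: int = 10):
    """Ward-D2 clustering of standardized variables.

    Variables are standardized across sites, then agglomerated on Euclidean
    distances between variable vectors; the dendrogram is cut into ``k``
    clusters.  Returns ``(labels: Series, linkage_matrix)``.
    """
    z = _standardize_columns(catalogue)
    if z.shape[1] < k:
        raise ValueError(f"need >= {k} non-constant variables, "
                         f"got {z.shape[1]}")
    lk = linkage(z.to_numpy().T, method="ward")
    labels = fcluster(lk, t=k, criterion="maxclust")
    return pd.Series(labels, index=z.columns, name="cluster"), lk


@dataclass
class EnvPcaResult:
    scores: pd.DataFrame        # sites x components
    loadings: pd.DataFrame      # variables x components
    variance_fraction: np.ndarray


def pca_env(catalogue: pd.DataFrame) -> EnvPcaResult:
    """PCA of the covariance matrix of scaled-and-centred variables
    (i.e. the correlation structure).  Rank-deficient inputs are truncated
    to the positive singular values."""
    if catalogue.shape[1] < 1 or catalogue.shape[0] < 2:
        raise ValueError("need >=1 variable and >=2 sites")
    z = _standardize_columns(catalogue).to_numpy()
    n = z.shape[0]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    keep = s > s[0] * 1e-12 if s.size and s[0] > 0 else np.zeros(0, bool)
    u, s, vt = u[:, keep], s[keep], vt[keep]
    var = s ** 2 / (n - 1)
    total = z.var(axis=0, ddof=1).sum()
    names = [f"PC{i + 1}" for i in range(len(s))]
    cols = _standardize_columns(catalogue).columns
    return EnvPcaResult(
        scores=pd.DataFrame(u * s, index=catalogue.index, columns=names),
        loadings=pd.DataFrame(vt.T, index=cols, columns=names),
        variance_fraction=var / total,
    )
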