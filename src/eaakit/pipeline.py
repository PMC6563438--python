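"""End-to-end orchestration: climate → ACVs → dummies → genotype filters →
structure inputs → association → differentiation scan → RDA → report.

``run_pipeline`` drives the full analysis from a :class:`PipelineConfig`
(paths or in-memory synthetic fixture), with per-stage provenance records
and simple stage caching; ``candidate_regions`` maps significant SNPs to
±1 Mb genome windows and counts the annotation features they overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agroclim, eaa, genodata, popdiff, rda, spatial
from .agroclim import SeasonSpec

logger = logging.getLogger("eaakit")

__all__ = [
    "PipelineConfig",
    "CandidateRegion",
    "run_pipeline",
    "candidate_regions",
    "read_annotation",
]


@dataclass
class PipelineConfig:
    """All inputs and thresholds of a pipeline run.

    Paths may be None when the corresponding object is passed in memory to
    :func:`run_pipeline` (the synthetic-fixture route).
    """

    climate_path: str | None = None
    sites_path: str | None = None
    genotype_path: str | None = None
    marker_map_path: str | None = None
    q_matrix_path: str | None = None
    group_labels_path: str | None = None
    out_dir: str | None = None

    max_missing: float = 0.10
    min_maf: float = 0.05
    ld_r2_max: float = 0.2
    shortlist_n_side: int = 5
    bf_quantile: float = 0.99
    rho_quantile: float = 0.99
    dummy_percentile: float = 99.99
    fdr_q: float = 0.01
    xtx_percentile: float = 99.0
    window_cm: float = 4.0
    n_dummies: int = 12
    lfmm_k: int = 6
    n_runs: int = 5
    n_beta_draws: int = 400
    omega_runs: int = 10
    n_pod: int = 10000
    seed: int = 0
    selected_variables: list = field(
        default_factory=lambda: list(agroclim.SELECTED_VARIABLES))

    def __post_init__(self) -> None:
        for name in ("max_missing", "min_maf", "ld_r2_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("bf_quantile", "rho_quantile"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def check_paths(self) -> None:
        for name in ("climate_path", "sites_path", "genotype_path",
                     "marker_map_path", "q_matrix_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")


def _stage(cache: dict, log: list, name: str, fn, **params):
    if name in cache:
        return cache[name]
    logger.info("stage %s: %s", name, params)
    try:
        result = fn()
    except Exception as exc:
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    cache[name] = result
    log.append({"stage": name, "params": params})
    return result


def run_pipeline(config: PipelineConfig, fixture=None,
                 cache: dict | None = None) -> dict:
    """Run the full analysis; returns a result dict plus provenance log.

    ``fixture`` (a :class:`eaakit.synthetic.FixtureBundle`) short-circuits
    file loading; otherwise the configured paths are read.  Deterministic
    given ``config.seed``.
    """
    config.check_paths()
    cache = {} if cache is None else cache
    log: list = []
    rng_seed = config.seed

    def load_inputs():
        if fixture is not None:
            sites = fixture.sites
            env_raw = fixture.env
            catalogue = fixture.catalogue
            calls = fixture.genotypes.calls
            mmap = fixture.genotypes.marker_map
            q = fixture.genotypes.q_matrix
            groups = fixture.genotypes.group_assignments
        else:
            climate = agroclim.read_daily_climate(config.climate_path)
            sites = pd.read_csv(config.sites_path)
            series = {sid: g.drop(columns="site")
                      for sid, g in climate.groupby("site", sort=False)}
            catalogue = agroclim.build_catalogue(series, sites, SeasonSpec())
            env_raw = catalogue.selected(config.selected_variables)
            calls = genodata.read_genotype_tsv(config.genotype_path)
            mmap = genodata.read_marker_map(config.marker_map_path)
            q = genodata.read_q_matrix(config.q_matrix_path)
            groups = pd.Series(q.to_numpy().argmax(axis=1), index=q.index) \
                .map(lambda i: f"G{i + 1}")
            env_raw.index = calls.index
        return sites, catalogue, env_raw, calls, mmap, q, groups

    sites, catalogue, env_raw, calls, mmap, q, groups = _stage(
        cache, log, "load", load_inputs)

    env_std = _stage(cache, log, "standardize_env",
                     lambda: eaa.standardize_env(env_raw))

    def make_dummy_block():
        coords = sites[["lon", "lat"]].to_numpy()
        span = max(np.ptp(coords[:, 0]), np.ptp(coords[:, 1]), 1.0)
        grid = spatial.GridSpec(rows=16, cols=16, cell_size_km=span / 14,
                                origin=(coords[:, 0].min() - span / 14,
                                        coords[:, 1].min() - span / 14))
        ref = config.selected_variables[3] \
            if len(config.selected_variables) > 3 else env_raw.columns[0]
        model = spatial.fit_semivariogram(coords, env_raw[ref].to_numpy(),
                                          model_type="gaussian")
        if model.partial_sill == 0:
            model = spatial.SemivariogramModel("gaussian", 0.1, 1.0,
                                               span / 3)
        dum = spatial.make_dummies(sites, grid, model, seed=rng_seed,
                                   n=config.n_dummies)
        dum.index = env_raw.index
        return dum

    dummies = _stage(cache, log, "dummies", make_dummy_block,
                     n=config.n_dummies)

    def filter_geno():
        g1 = genodata.filter_missing(calls, config.max_missing)
        g2 = genodata.maf_filter(g1, config.min_maf)
        return g2

    geno = _stage(cache, log, "filter_genotypes", filter_geno,
                  max_missing=config.max_missing, min_maf=config.min_maf)

    shortlist = _stage(
        cache, log, "shortlist",
        lambda: genodata.shortlist_nonredundant(
            geno, mmap, config.ld_r2_max, config.shortlist_n_side),
        r2_max=config.ld_r2_max)

    omega_acc = _stage(
        cache, log, "omega_accessions",
        lambda: popdiff.estimate_omega(geno[shortlist],
                                       n_runs=config.omega_runs,
                                       seed=rng_seed),
        n_markers=len(shortlist))
    omega_null = popdiff.null_omega(geno.shape[0], pops=list(geno.index))

    env_all = pd.concat([env_std, dummies], axis=1)
    bf_config = eaa.BfModelConfig(n_runs=config.n_runs,
                                  n_beta_draws=config.n_beta_draws)

    assoc = {}
    for model_name, om in [("null", omega_null), ("covariance", omega_acc)]:
        runs = _stage(
            cache, log, f"association_{model_name}",
            lambda om=om: eaa.run_association(geno, env_all, om, bf_config,
                                              seed_base=rng_seed),
            model=model_name, n_runs=config.n_runs)
        med_bf = eaa.median_over_runs(runs, "bf")
        med_rho = eaa.median_over_runs(runs, "rho")
        agro_vars = [v for v in env_std.columns]
        hits = eaa.consensus_hits(runs, variables=agro_vars,
                                  bf_quantile=config.bf_quantile,
                                  rho_quantile=config.rho_quantile)
        dum_thr = eaa.dummy_threshold(
            med_bf[dummies.columns].to_numpy(),
            percentile=config.dummy_percentile)
        assoc[model_name] = {
            "runs": runs, "median_bf": med_bf, "median_rho": med_rho,
            "consensus_hits": hits, "dummy_threshold": dum_thr,
            "dummy9999_hits": {
                (lid, var)
                for var in agro_vars
                for lid in med_bf.index[med_bf[var] > dum_thr]},
        }

    def lfmm_stage():
        complete = genodata.impute_knn(geno)
        z_by_var = {}
        qvals = {}
        masks = {}
        for var in env_std.columns:
            z = eaa.latent_factor_assoc(complete, env_std[var],
                                        K=config.lfmm_k,
                                        n_runs=config.n_runs,
                                        seed_base=rng_seed)
            zc, p = eaa.combine_fisher_stouffer(z)
            zc, p = eaa.genomic_control(zc)
            qv, mask = eaa.bh_fdr(p, config.fdr_q)
            z_by_var[var], qvals[var], masks[var] = zc, qv, mask
        return (pd.DataFrame(z_by_var, index=geno.columns),
                pd.DataFrame(qvals, index=geno.columns),
                pd.DataFrame(masks, index=geno.columns))

    lfmm_z, lfmm_q, lfmm_mask = _stage(cache, log, "latent_factor",
                                       lfmm_stage, K=config.lfmm_k)

    def scan_stage():
        omega_groups = popdiff.estimate_omega(
            geno[shortlist], labels=groups, n_runs=config.omega_runs,
            seed=rng_seed)
        return popdiff.differentiation_scan(
            geno, groups, mmap, Q=q, omega=omega_groups,
            width_cM=config.window_cm, n_pod=config.n_pod,
            pod_percentile=config.xtx_percentile, seed=rng_seed)

    scan = _stage(cache, log, "differentiation_scan", scan_stage,
                  width_cM=config.window_cm)

    def rda_stage():
        agro = [v for v in env_std.columns if v not in ("lon", "lat", "alt")]
        geo = [v for v in ("lon", "lat", "alt") if v in env_std.columns]
        fit = rda.rda_fit(q, env_std[agro])
        fit.permutation_p = rda.permutation_test(q, env_std[agro],
                                                 n_perm=499, seed=rng_seed)
        part = rda.partial_rda(q, env_std[agro],
                               env_std[geo] if geo else None)
        sel, stop, hist = rda.forward_select(
            q, pd.concat([env_std[agro], dummies], axis=1),
            dummy_names=list(dummies.columns))
        return {"fit": fit, "partition": part,
                "forward_selection": {"selected": sel, "stop_index": stop,
                                      "history": hist}}

    rda_res = _stage(cache, log, "rda", rda_stage)

    fst = _stage(cache, log, "fst",
                 lambda: popdiff.fst_pairwise(geno, groups))

    results = {
        "catalogue": catalogue, "env": env_std, "dummies": dummies,
        "genotypes": geno, "shortlist": shortlist,
        "omega": omega_acc, "association": assoc,
        "lfmm": {"z": lfmm_z, "q": lfmm_q, "significant": lfmm_mask},
        "scan": scan, "rda": rda_res, "fst": fst,
        "provenance": log, "seed": rng_seed,
    }
    if config.out_dir:
        _write_outputs(results, Path(config.out_dir))
    return results


def _write_outputs(results: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    results["catalogue"].data.to_csv(out / "acv_catalogue.tsv", sep="\t")
    results["env"].to_csv(out / "env_standardized.tsv", sep="\t")
    results["dummies"].to_csv(out / "dummies.tsv", sep="\t")
    popdiff.write_omega(results["omega"], out / "omega_mean.txt")
    results["scan"].table.to_csv(out / "diff_scan.tsv", sep="\t",
                                 index=False)
    for model, res in results["association"].items():
        res["median_bf"].to_csv(out / f"bf_median_{model}.tsv", sep="\t")
        res["median_rho"].to_csv(out / f"rho_median_{model}.tsv", sep="\t")
    results["fst"].to_csv(out / "fst_pairwise.tsv", sep="\t")


# ---------------------------------------------------------------------------
# candidate regions
# ---------------------------------------------------------------------------

@dataclass
class CandidateRegion:
    locus: str
    chrom: str
    bp: int
    window: tuple                  # [start, end) half-open, clipped
    class_counts: dict
    gene_hits: list


def read_annotation(path) -> pd.DataFrame:
    """Minimal GFF3 reader: returns chrom, start, end (half-open),
    feature id and confidence class (from a ``confidence=`` attribute, else
    'NA')."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";")
                         if "=" in kv)
            rows.append({
                "chrom": parts[0], "feature": parts[2],
                "start": int(parts[3]), "end": int(parts[4]) + 1,
                "id": attrs.get("ID", "."),
                "confidence": attrs.get("confidence", "NA"),
            })
    return pd.DataFrame(rows, columns=["chrom", "feature", "start", "end",
                                       "id", "confidence"])


def candidate_regions(hit_loci, mmap: pd.DataFrame,
                      annotation: pd.DataFrame, flank: int = 1_000_000,
                      chrom_lengths: dict | None = None) -> list:
    """±``flank`` windows around significant SNPs with feature overlaps.

    Overlap is half-open on [bp - flank, bp + flank); a feature containing
    the SNP position itself is reported as a gene hit.  Loci missing from
    the map (no bp) are skipped with a warning.
    """
    import warnings as _warnings

    pos = mmap.set_index("locus")
    regions = []
    for lid in hit_loci:
        if lid not in pos.index or pd.isna(pos.loc[lid, "bp"]):
            _warnings.warn(f"locus {lid} has no physical position; skipped",
                           stacklevel=2)
            continue
        bp = int(pos.loc[lid, "bp"])
        chrom = pos.loc[lid, "chrom"]
        lo = max(0, bp - flank)
        hi = bp + flank
        if chrom_lengths and chrom in chrom_lengths:
            hi = min(hi, chrom_lengths[chrom])
        if len(annotation):
            sub = annotation[(annotation["chrom"] == chrom)
                             & (annotation["start"] < hi)
                             & (annotation["end"] > lo)]
            counts = sub["confidence"].value_counts().to_dict()
            genes = sub[(sub["start"] <= bp) & (bp < sub["end"])]["id"] \
                .tolist()
        else:
            counts, genes = {}, []
        regions.append(CandidateRegion(locus=lid, chrom=chrom, bp=bp,
                                       window=(lo, hi), class_counts=counts,
                                       gene_hits=genes))
    return regions
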