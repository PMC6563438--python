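"""Genotype data handling for haploid-coded inbred panels.

The in-memory genotype container is a pandas DataFrame of accessions x loci
with calls in {0.0, 1.0, NaN} (count of allele 1 per accession; inbred lines
are scored as haploids).  Supported external formats:

* the two-line allele-counts "snpsfile" (bayenv convention: each SNP is two
  rows, counts of allele 1 then allele 2 per accession; 0/0 means missing),
* plain genotype/marker-map/Q-matrix TSVs,
* VCF ingestion with GT collapsed to haploid calls (heterozygotes treated
  as missing).

Filtering follows the study defaults (drop loci with >10 % missing, MAF
threshold 0.05), imputation is kNN-majority over genotypic similarity, and
linkage disequilibrium is available both as plain r² and as the
structure-corrected r_S² of Mangin et al. (squared correlation of the
residuals after projecting the two loci on the population-membership Q
matrix), which feeds the non-redundant marker shortlist and the
neighbourhood LD profile.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "read_snpsfile",
    "write_snpsfile",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_marker_map",
    "read_q_matrix",
    "validate_q_matrix",
    "read_vcf_haploid",
    "filter_missing",
    "maf_filter",
    "minor_allele_freq",
    "impute_knn",
    "ld_r2",
    "ld_rs2",
    "neighbor_ld_profile",
    "shortlist_nonredundant",
]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_snpsfile(path, locus_ids=None, accession_ids=None) -> pd.DataFrame:
    """Parse a two-line-per-SNP allele-counts file into a genotype matrix.

    Line 2k holds the per-accession counts of allele 1 of SNP k, line 2k+1
    the counts of allele 2; with haploid coding each count is 0 or 1 and a
    0/0 column means missing.  Returns accessions x loci.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) % 2:
        raise ValueError("snpsfile has an odd number of lines")
    n_snps = len(lines) // 2
    calls = []
    n_acc = None
    for k in range(n_snps):
        a1 = np.array(lines[2 * k].split(), dtype=float)
        a2 = np.array(lines[2 * k + 1].split(), dtype=float)
        if len(a1) != len(a2):
            raise ValueError(
                f"SNP {k}: allele-1 and allele-2 lines have different "
                f"column counts ({len(a1)} vs {len(a2)})")
        if n_acc is None:
            n_acc = len(a1)
        elif len(a1) != n_acc:
            raise ValueError(f"SNP {k}: inconsistent accession count")
        col = np.where(a1 + a2 == 0, np.nan, a1)
        calls.append(col)
    mat = np.array(calls).T if calls else np.empty((0, 0))
    locus_ids = locus_ids or [f"snp{k + 1:05d}" for k in range(n_snps)]
    accession_ids = accession_ids or [f"acc{i + 1:03d}" for i in range(n_acc or 0)]
    return pd.DataFrame(mat, index=accession_ids, columns=locus_ids)


def write_snpsfile(G: pd.DataFrame, path) -> None:
    """Write the two-line allele-counts dialect (tab-separated integers).
    Missing calls are written as 0/0; write(read(f)) is byte-identical for
    canonical files."""
    with open(path, "w") as fh:
        arr = G.to_numpy()
        for k in range(arr.shape[1]):
            col = arr[:, k]
            a1 = np.where(np.isnan(col), 0, col).astype(int)
            a2 = np.where(np.isnan(col), 0, 1 - col).astype(int)
            fh.write("\t".join(map(str, a1)) + "\n")
            fh.write("\t".join(map(str, a2)) + "\n")


def read_genotype_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_genotype_tsv(G: pd.DataFrame, path) -> None:
    G.to_csv(path, sep="\t", na_rep="NA")


def read_marker_map(path) -> pd.DataFrame:
    """Marker map TSV (locus, chrom, cM, bp[, ccM]); adds cumulative cM over
    the concatenated genome if absent."""
    mmap = pd.read_csv(path, sep="\t")
    required = {"locus", "chrom", "cM", "bp"}
    if required - set(mmap.columns):
        raise ValueError(f"marker map needs columns {sorted(required)}")
    if "ccM" not in mmap.columns:
        mmap = add_cumulative_cm(mmap)
    return mmap


def add_cumulative_cm(mmap: pd.DataFrame) -> pd.DataFrame:
    mmap = mmap.sort_values(["chrom", "cM"], kind="stable").reset_index(drop=True)
    offset, ccm = 0.0, []
    for _, grp in mmap.groupby("chrom", sort=False):
        ccm.extend(offset + grp["cM"].to_numpy())
        offset += grp["cM"].max() + 10.0
    return mmap.assign(ccM=ccm)


def validate_q_matrix(q: pd.DataFrame, tol: float = 1e-6) -> pd.DataFrame:
    arr = q.to_numpy(dtype=float)
    if (arr < -tol).any() or (arr > 1 + tol).any():
        raise ValueError("Q entries must be in [0, 1]")
    if not np.allclose(arr.sum(axis=1), 1.0, atol=tol):
        raise ValueError("Q rows must sum to 1")
    return q


def read_q_matrix(path) -> pd.DataFrame:
    return validate_q_matrix(pd.read_csv(path, sep="\t", index_col=0))


def read_vcf_haploid(path) -> pd.DataFrame:
    """Minimal VCF ingestion: biallelic records only, GT collapsed to a
    haploid call (0/0 -> 0, 1/1 -> 1, heterozygous or missing -> NaN)."""
    loci, rows, samples = [], [], None
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.rstrip("\n").split("\t")[9:]
                continue
            parts = line.rstrip("\n").split("\t")
            if samples is None or len(parts) < 10:
                continue
            ref, alt = parts[3], parts[4]
            if "," in alt:        # multiallelic
                continue
            vid = parts[2] if parts[2] != "." else f"{parts[0]}:{parts[1]}"
            fmt = parts[8].split(":")
            gt_i = fmt.index("GT")
            calls = []
            for smp in parts[9:]:
                gt = smp.split(":")[gt_i].replace("|", "/")
                alleles = set(gt.split("/")) - {"."}
                if alleles == {"0"}:
                    calls.append(0.0)
                elif alleles == {"1"}:
                    calls.append(1.0)
                else:
                    calls.append(np.nan)
            loci.append(vid)
            rows.append(calls)
    return pd.DataFrame(np.array(rows).T if rows else np.empty((0, 0)),
                        index=samples or [], columns=loci)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_missing(G: pd.DataFrame, max_frac: float = 0.10) -> pd.DataFrame:
    """Drop loci with missing fraction strictly above ``max_frac``."""
    frac = G.isna().mean(axis=0)
    return G.loc[:, frac <= max_frac]


def minor_allele_freq(G: pd.DataFrame) -> pd.Series:
    p = G.mean(axis=0, skipna=True)
    return np.minimum(p, 1.0 - p)


def maf_filter(G: pd.DataFrame, min_maf: float = 0.05,
               strict: bool = True) -> pd.DataFrame:
    """Keep loci with MAF > ``min_maf`` (strict, the study's wording) or
    >= with ``strict=False``. MAF is computed on non-missing calls."""
    maf = minor_allele_freq(G)
    keep = maf > min_maf if strict else maf >= min_maf
    return G.loc[:, keep.fillna(False)]


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def _similarity(arr: np.ndarray) -> np.ndarray:
    """Pairwise fraction of agreeing calls over mutually observed loci."""
    obs = ~np.isnan(arr)
    x = np.nan_to_num(arr)
    ones = x * obs
    zeros = (1.0 - x) * obs
    agree = ones @ ones.T + zeros @ zeros.T
    shared = obs.astype(float) @ obs.astype(float).T
    with np.errstate(invalid="ignore"):
        sim = agree / shared
    sim[shared == 0] = 0.0
    np.fill_diagonal(sim, -1.0)  # an accession never imputes itself
    return sim


def impute_knn(G: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Fill each missing call with the majority allele among the ``k`` most
    genotypically similar accessions observed at that locus; ties (including
    no informative neighbour) fall back to the locus's major allele, ties
    there to allele 1.  Deterministic."""
    arr = G.to_numpy(dtype=float).copy()
    if np.isnan(arr).all(axis=0).any():
        raise ValueError("cannot impute an all-missing locus")
    if not np.isnan(arr).any():
        return G.copy()
    sim = _similarity(arr)
    p = np.nanmean(arr, axis=0)
    global_major = (p >= 0.5).astype(float)
    order = np.argsort(-sim, axis=1, kind="stable")
    miss_i, miss_l = np.nonzero(np.isnan(arr))
    for i, l in zip(miss_i, miss_l):
        donors = order[i][~np.isnan(arr[order[i], l])][:k]
        if donors.size == 0:
            arr[i, l] = global_major[l]
            continue
        votes = arr[donors, l]
        n1 = votes.sum()
        if n1 * 2 > len(votes):
            arr[i, l] = 1.0
        elif n1 * 2 < len(votes):
            arr[i, l] = 0.0
        else:
            arr[i, l] = global_major[l]
    return pd.DataFrame(arr, index=G.index, columns=G.columns)


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(x, y) -> float:
    """Squared Pearson correlation of two haploid call vectors over shared
    non-missing accessions; NaN if either is monomorphic there."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _residualize_on_q(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def ld_rs2(x, y, Q) -> float:
    """Structure-corrected LD: squared correlation of the residuals of the
    two call vectors after projection on span{1, Q columns}.  With a single
    population (K=1) this reduces exactly to :func:`ld_r2`."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    q = np.asarray(Q, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y, q = x[ok], y[ok], q[ok]
    if len(x) < 3 or x.std() == 0 or y.std() == 0:
        return float("nan")
    design = np.column_stack([np.ones(len(x)), q])
    rx = _residualize_on_q(x, design)
    ry = _residualize_on_q(y, design)
    if rx.std() < 1e-12 * max(1.0, x.std()) or \
            ry.std() < 1e-12 * max(1.0, y.std()):
        return float("nan")
    r = np.corrcoef(rx, ry)[0, 1]
    return float(r * r)


def _pair_ld(G_arr, i, j, q) -> float:
    if q is None:
        return ld_r2(G_arr[:, i], G_arr[:, j])
    return ld_rs2(G_arr[:, i], G_arr[:, j], q)


def neighbor_ld_profile(G: pd.DataFrame, mmap: pd.DataFrame,
                        n_side: int = 4, Q=None) -> pd.Series:
    """Per-locus mean LD with up to ``n_side`` markers to each side on the
    same chromosome (r_S² when a Q matrix is given, plain r² otherwise).
    Edge loci average over the neighbours available."""
    mmap = mmap.sort_values(["chrom", "ccM"], kind="stable")
    arr = G.to_numpy(dtype=float)
    col_of = {lid: k for k, lid in enumerate(G.columns)}
    q = np.asarray(Q, dtype=float) if Q is not None else None
    out = {}
    for _, grp in mmap.groupby("chrom", sort=False):
        loci = [lid for lid in grp["locus"] if lid in col_of]
        for pos, lid in enumerate(loci):
            lo = max(0, pos - n_side)
            vals = [_pair_ld(arr, col_of[lid], col_of[loci[p]], q)
                    for p in range(lo, min(len(loci), pos + n_side + 1))
                    if p != pos]
            vals = [v for v in vals if not np.isnan(v)]
            out[lid] = float(np.mean(vals)) if vals else float("nan")
    return pd.Series(out).reindex(G.columns)


def shortlist_nonredundant(G: pd.DataFrame, mmap: pd.DataFrame,
                           r2_max: float = 0.2, n_side: int = 5,
                           Q=None) -> list:
    """Greedy left-to-right shortlist of low-LD markers at unique genetic
    positions.

    Scanning loci in cumulative-cM order, a locus is kept iff its LD r²
    (r_S² when ``Q`` is given) with each of the last ``n_side`` kept loci is
    below ``r2_max`` and its cM position differs from every kept locus on
    the same chromosome (first kept wins on exact ties).  Deterministic and
    order-stable.
    """
    mmap = mmap[mmap["locus"].isin(G.columns)].sort_values(
        "ccM", kind="stable")
    arr = G.to_numpy(dtype=float)
    col_of = {lid: k for k, lid in enumerate(G.columns)}
    q = np.asarray(Q, dtype=float) if Q is not None else None
    kept: list = []
    kept_pos: set = set()
    for lid, chrom, cm in mmap[["locus", "chrom", "cM"]].itertuples(
            index=False):
        if (chrom, cm) in kept_pos:
            continue
        window = kept[-n_side:]
        redundant = False
        for other in window:
            r2 = _pair_ld(arr, col_of[lid], col_of[other], q)
            if not np.isnan(r2) and r2 >= r2_max:
                redundant = True
                break
        if redundant:
            continue
        kept.append(lid)
        kept_pos.add((chrom, cm))
    return kept
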