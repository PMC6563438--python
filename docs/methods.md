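# Methods

`eaakit` reimplements, as a tested pipeline on synthetic data with known
truth, the statistical machinery of a landrace environment-association
study: agroclimatic indices from daily climate, spatially correlated null
variables, allele-frequency/environment Bayes factors with and without
population-covariance correction, differentiation scans (H, Fst, XtX,
structure-corrected LD) and redundancy-analysis variance partitioning.
This note records the models, the parameter choices that matter, and the
limits of what the synthetic tests demonstrate.

## Agroclimatic variables

Daily input is a per-site series of `tmin`, `tmax` (°C), `pcp` and
reference evapotranspiration `et0` (mm/day); `et0` is consumed, never
computed (Penman-Monteith is upstream of this package's scope).

**Aggregation.** Monthly climatologies are computed first (per calendar
month: across-year mean of monthly sums for the cumulative families
`pcp`, `ET_0`, `verna`, `frost`, `bal`; of monthly means for `tmed`,
`tmax`, `tmin`, `tamp`). Seasonal and annual values are then sums (or
day-weighted means) of the monthly climatologies, which makes aggregation
exactly additive: `bal_win = bal_dec + bal_jan + bal_feb`. Seasons default
to meteorological conventions (win = DJF, spr = MAM, aut = SON,
summer = JJA) and are configurable through `SeasonSpec`. The default
catalogue enumerates exactly 147 agroclimatic variables: 6 families x
(12 months + 4 seasons) + 12 monthly vernalization values + 4
`verna_Nd` targets + `pfrost` + 17 `ET_0` + 17 `bal` entries, plus
lon/lat/alt as geographic columns.

**Potential vernalization.** Within-day temperature follows a sine curve
between `tmin` and `tmax` (the CERES-Wheat convention); vernalization
effectiveness is piecewise linear — zero at or below 0 °C, rising to full
effect at 4 °C, full up to 8 °C, declining to zero at 15 °C (barley
thresholds). The daily vernalization fraction is the mean effectiveness
over the diurnal curve, integrated at 240 samples per day: the
effectiveness curve has kinks, so the discretization error is O(1/n) and
240 steps keep it near 1e-4, comfortably inside the 1e-3 contract against
a dense quadrature oracle. `verna_Nd` counts calendar days from a November
15 sowing (day 1) until N vernalization days have accumulated, with
accrual starting only after a 5-day imbibition lag; season-years that
never reach the target are excluded from the across-year average with a
warning.

**pfrost.** The late-frost index is read as a return period: with
`q(d)` = fraction of years having at least one `tmin < 0` day on
day-of-year >= `d` (search window January-June), `pfrost` is the smallest
`d` with `q(d) <= 0.10` — one damaging frost in ten years. A pointwise
per-day frequency variant is available behind a flag; the return-period
reading is the default because it is the one that matches the
"mean return period of one in ten years" interpretation.

**Variable selection.** Ward-D2 clustering (scipy's `ward` linkage on
standardized variable vectors) cuts the catalogue into 10 clusters; the
shipped 20-name preset (17 agroclimatic + lon/lat/alt) picks one or two
representatives per cluster aligned to barley growth phases, with
multi-month composites (`pcp_mar_apr` etc.) derived by the family's own
rule (sum for cumulative families, mean for temperatures). PCA operates on
the correlation structure (covariance of scaled variables) with rank
truncation.

## Synthetic data: what it emulates and what it does not

The weather generator produces a seasonal sinusoid for daily mean
temperature (peak near late July) with AR(1) Gaussian noise
(coefficient 0.7, innovation sd 2 °C), a constant diurnal range with
Gaussian jitter, a 6.5 °C/km lapse rate and a linear latitude gradient;
precipitation is per-month Bernoulli occurrence (wet winters, dry
summers) times Gamma(0.8, 6 mm) amounts; `et0` is a smooth seasonal curve
scaled down with altitude and latitude. This is the minimal structure
that exercises every index: it does not emulate weather fronts, spatial
correlation of daily anomalies between sites, drizzle autocorrelation or
extreme-value behaviour — so passing tests demonstrate correctness of the
index arithmetic, not meteorological realism.

Genotypes follow the Balding-Nichols model: per-group allele frequencies
`Beta(p(1-F)/F, (1-p)(1-F)/F)` around a Uniform(0.1, 0.9) ancestral
frequency, haploid Bernoulli calls (inbred lines scored 0/1), missing
data injected uniformly at random (default 5% in the fixture). The
default fixture uses ~120 accessions in 4 groups sized proportionally to
the real panel (15/10/48/62 scaled) with per-group F of
0.25/0.35/0.20/0.22 — the upper half of the realistic landrace range —
3,000 biallelic SNPs on 7 chromosomes, and 15 years of daily weather at
one collection site per accession, with group geographic centres drawn on
the grid so that structure, geography and climate are genuinely
entangled. Environmental clines are planted by redrawing causal calls
from `logistic(logit(p_group) + beta * env)` with standardized `env`;
the fixture default is beta = 2 (logit shift per 1 SD of environment)
at 20 causal loci split over `pfrost` and `bal_jun`. No attempt is made
to mimic real LD decay (loci are exchangeable given structure) or the
real allele-frequency spectrum.

## Spatially correlated dummies

Dummy variables are zero-mean unit-variance Gaussian random fields
simulated unconditionally on a grid by Cholesky factorization of the
semivariogram-implied covariance (spherical, exponential or gaussian
families; ranges are "practical" ranges at 95% of the sill), sampled at
the collection sites by nearest-cell lookup and standardized. The
semivariogram fit is weighted least squares on binned lags (weights
counts/gamma^2, the gstat convention), with a nugget-only fallback when
the spatial component does not beat the flat model — otherwise white
noise masquerades as structure at an implausibly long range. A single
realization's empirical semivariogram is itself noisy; range-recovery
checks therefore average the fitted range over a few independent fields.

## Genotype handling

The two-line allele-counts format ("snpsfile": counts of allele 1 then
allele 2 per SNP, 0/0 = missing) round-trips byte-identically. Filters
follow the study defaults — drop loci with more than 10% missing calls,
then MAF strictly greater than 0.05 (the comparator is configurable).
Imputation is kNN-majority: similarity is the fraction of agreeing calls
over mutually observed loci, each missing call takes the majority allele
among the k = 5 most similar accessions observed there, ties fall back to
the locus's major allele (then to allele 1); fully deterministic.
Structure-corrected LD `r_S²` is the squared correlation of the two call
vectors' residuals after projection on span{1, Q}; with K = 1 it equals
plain r² exactly. The non-redundant shortlist scans loci in cumulative-cM
order and keeps a locus iff its LD with each of the last five kept loci is
below r² = 0.2 and its cM position is new on that chromosome (first kept
wins ties) — greedy, order-stable, deterministic.

## Population differentiation

Fst is a Weir-Cockerham-type estimator adapted to haploid calls (one-way
ANOVA on allele indicators; multi-locus value by ratio of sums). The
pairwise matrix reports within-group mean gene diversity `2p(1-p)` on the
diagonal (over loci polymorphic in the full panel).

**Ω.** The among-population covariance of standardized allele frequencies
`(p_j - pbar)/sqrt(pbar(1-pbar))` is estimated by the method of moments
over a low-LD marker shortlist, averaged element-wise over seeded
bootstrap-over-loci replicates (emulating the average-over-runs matrix of
MCMC samplers while staying deterministic per seed) and projected onto
the PSD cone. For association, every accession is its own population of
haploid sample size one, so Ω is effectively the genotype covariance
among accessions; for XtX, the four groups are the populations.

**XtX.** With `A = (Ω + 1e-6 I)^-1` and the GLS ancestral estimate
`eps = (1'A theta)/(1'A 1)`, the statistic is the Mahalanobis form
`(theta - eps1)' A (theta - eps1) / (eps(1-eps))`, scaled by `P/(P-1)`.
The scaling is a degrees-of-freedom correction: estimating `eps`
consumes one dimension, leaving the raw form with neutral expectation
P-1; the corrected statistic has neutral expectation P, which the tests
verify to ±0.2 at 5,000 loci. Significance thresholds come from
pseudo-observed data: neutral loci simulated from Ω and the observed
frequency spectrum (Gaussian frequencies truncated to [0,1], optional
binomial sampling), thresholded at the requested percentile.

Sliding windows are centred at every marker over half-open ±2 cM
intervals of cumulative cM; scan outputs carry the reference lines
(window percentiles 95/5, single-SNP percentiles 99/1, POD threshold)
as numbers.

## Association

Each accession is one haploid observation, so the "population frequency"
is the call itself. The hierarchical model places the frequency vector
`y` under `N(eps 1, eps(1-eps) Ω)` (null) versus
`N(eps 1 + beta e, eps(1-eps) Ω)` (alternative) with `e` the standardized
environmental variable. Given this Gaussian form, the likelihood ratio at
fixed beta is `exp(beta u - beta² v/2)` with `u = e'Σ⁻¹r`, `v = e'Σ⁻¹e`;
the Bayes factor integrates it over a uniform prior on beta with
half-width 0.3 (standardized scale), either by seeded Monte Carlo draws
(default 400 per run — the source of honest run-to-run variation for the
five-run consensus) or on a deterministic 61-point grid. Missing calls
are held at the ancestral estimate and carry no information; monomorphic
loci report BF = 1. With Ω = I this is the structure-uncorrected "null
model"; with the accession-covariance Ω the "covariance model".

Spearman rho per run is computed on the observed accession-level
frequencies by default — haploid calls give them exactly, so the rank
correlation has no sampling uncertainty; a "posterior" mode instead
correlates seeded Beta-posterior frequency draws for MCMC-like run
variation (an early single-draw version attenuated |rho| by ~40% and
destroyed the power of the all-runs consensus condition, which is why
the exact computation is the default).

Thresholding rules: (i) the consensus rule — median-over-runs BF in the
pooled (all agroclimatic variables) top 1% AND |rho| in the per-run
pooled top 1% in every run; (ii) the empirical 99.99 percentile of the
BF values of the 12 spatially correlated dummies; (iii) for the
latent-factor analysis, per-variable Benjamini-Hochberg FDR at Q = 0.01.

The latent-factor association is a ridge-LFMM-style closed form: K
factors (default 6; the structured-null calibration tests use the true
group count) are the top left singular vectors of the centered imputed
genotype matrix via seeded randomized SVD — the seeded solver start is
the run-to-run variation — and each locus is regressed on
[1, factors, env]. Combined z-scores use Fisher-Stouffer
(`z = Σz_i/√m`); because the runs share the data and differ only in
solver starts they are strongly dependent, inflating the combined score
by up to √m, so the combined z is recalibrated by the genomic inflation
factor `lambda = median(z²)/qchisq(0.5, 1)` before two-sided p-values
and FDR. Under a structured null with K set to the true group count the
adjusted p-values are uniform (KS-tested).

One calibration subtlety: under the structure-uncorrected model the BF
scale of a single null variable depends on how that variable happens to
align with genotype group structure, so permutation-vs-dummy
distributional checks compare ensembles (several permutations against
several iid dummies) at moderate sample size rather than single draws at
full locus count. This alignment sensitivity is precisely why the
spatially correlated dummy threshold, not a parametric cutoff, guards the
null-model results.

## Redundancy analysis

Y is the centered Q matrix (its columns sum to one; the induced
collinearity is handled by pseudo-inverse projection), X a standardized
predictor set. R² is the explained-variance trace; the adjustment is
Ezekiel's `1 - (1-R²)(n-1)/(n-p-1)` with p the rank of the predictor
block, reported as-is even when negative. Variance partitioning uses the
classic difference-of-adjusted-R² construction (`unique_X =
adjR²(X∪Z) - adjR²(Z)`, `common = adjR²(X) + adjR²(Z) - adjR²(X∪Z)`),
so the partition identity holds exactly by construction. The permutation
test residualizes response and predictors on the conditioning set,
permutes residualized response rows and compares pseudo-F values with
the `(1 + #{F* >= F})/(n_perm + 1)` rule. Forward selection adds
candidates greedily by adjusted-R² gain (ties broken lexicographically,
no randomness) and stops when the best next candidate is a flagged dummy
or no candidate improves; the stop index — how many real variables enter
before the first dummy would — is the reported guard against
overfitting, mirroring the two-real-variables-before-first-dummy
behaviour on constructed designs in >= 90% of seeds.

## Problem sizes and determinism

Test and acceptance runs use CI-scale sizes chosen to keep Monte Carlo
error well inside each tolerance: 2,000 loci for Fst recovery (binomial
SE ~0.01 against a ±0.05 band), 5,000 loci for the neutral XtX mean
(±0.2 band), 8,000 POD simulations for thresholds, 20 fixture seeds x 20
causal loci for consensus power, 40x40 grids for variogram round trips,
50 seeds for the forward-selection stop. Every random stage takes an
explicit seed; sub-seeds are spawned with `numpy.random.SeedSequence`,
so all results are bit-reproducible given the top-level seed. The full
pipeline (`run_pipeline`) is deterministic for a fixed config seed and
logs every stage with its parameters.

## Known limitations

* The Bayes factor is a Gaussian-model integral, not an MCMC replication
  of the original samplers; only rank- and threshold-level behaviour is
  claimed, never numerical equality of BF values.
* Ω's optional MCMC refinement is a hook only; the moment estimator is
  the implementation.
* Group membership (the Q matrix) is an input; no admixture-model
  clustering ships with the package (the synthetic generator's one-hot Q
  is a light surrogate used in tests).
* `pfrost` probabilities are not smoothed across day-of-year before
  thresholding; with 10-30 years the empirical q(d) is a step function
  and the index is integer-valued.
* Candidate-region reporting counts annotation features and flags gene
  hits; it makes no biological claims about candidates.
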