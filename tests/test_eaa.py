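"""Association core: Bayes factors, rho, consensus/dummy thresholds,
latent factors, combination and FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eaakit.eaa import (BfModelConfig, bayes_factor_run, bf_xtx_correlation,
                        bh_fdr, combine_fisher_stouffer, consensus_hits,
                        dummy_threshold, genomic_control, latent_factor_assoc,
                        median_over_runs, read_environfile, run_association,
                        spearman_env, standardize_env, write_environfile)
from eaakit.popdiff import null_omega
from eaakit.synthetic import gen_structured_genotypes


class TestStandardizeEnv:
    def test_closed_form_three_values(self):
        out = standardize_env(pd.DataFrame({"v": [1.0, 2.0, 3.0]}))
        assert np.allclose(out["v"], [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_idempotent_within_tolerance(self, rng):
        df = pd.DataFrame(rng.normal(2.0, 3.0, size=(50, 3)),
                          columns=list("abc"))
        once = standardize_env(df)
        twice = standardize_env(once)
        assert np.allclose(once, twice, atol=1e-8)

    def test_identical_columns_identical_outputs(self, rng):
        x = rng.normal(size=30)
        out = standardize_env(pd.DataFrame({"a": x, "b": x}))
        assert np.allclose(out["a"], out["b"])

    def test_constant_column_error_names_column(self):
        with pytest.raises(ValueError, match="flat"):
            standardize_env(pd.DataFrame({"ok": [1.0, 2.0],
                                          "flat": [5.0, 5.0]}))

    def test_environfile_round_trip(self, tmp_path, rng):
        env = standardize_env(pd.DataFrame(
            rng.normal(size=(10, 3)), columns=["a", "b", "c"],
            index=[f"acc{i}" for i in range(10)]))
        p = tmp_path / "envfile.tsv"
        write_environfile(env, p)
        back = read_environfile(p, accession_ids=env.index)
        assert np.allclose(back.to_numpy(), env.to_numpy(), atol=1e-6)


@pytest.fixture(scope="module")
def assoc_setup():
    b = gen_structured_genotypes(100, 400, [100], 0.2, seed=21)
    rng = np.random.default_rng(1)
    env = pd.DataFrame({"e1": rng.normal(size=100),
                        "e2": rng.normal(size=100)})
    env = standardize_env(env)
    om = null_omega(100, pops=list(b.calls.index))
    return b, env, om


class TestBayesFactor:
    def test_uninformative_env_gives_bf_near_one(self, assoc_setup):
        b, env, om = assoc_setup
        # an env with (numerically) no variance information: tiny values
        tiny = pd.DataFrame({"z": np.full(100, 0.0)})
        cfg = BfModelConfig(n_beta_draws=2000)
        bf = bayes_factor_run(b.calls, tiny, om, cfg, seed=0)
        assert np.allclose(bf["z"], 1.0, atol=1e-6)

    def test_monomorphic_locus_flagged_neutral(self, assoc_setup):
        b, env, om = assoc_setup
        g = b.calls.copy()
        g.iloc[:, 0] = 1.0
        bf = bayes_factor_run(g, env, om)
        assert bf.iloc[0, 0] == 1.0

    def test_bf_increases_with_planted_effect(self, assoc_setup):
        b, env, om = assoc_setup
        rng = np.random.default_rng(3)
        g = b.calls.copy()
        e = env["e1"].to_numpy()
        meds = []
        for k, beta in enumerate((0.0, 1.0, 2.5)):
            prob = 1.0 / (1.0 + np.exp(-(beta * e)))
            cols = g.columns[k * 20:(k + 1) * 20]
            g[cols] = (rng.random((100, 20)) < prob[:, None]).astype(float)
            bf = bayes_factor_run(g[cols], env, om,
                                  BfModelConfig(n_beta_draws=500), seed=1)
            meds.append(np.median(np.log(bf["e1"])))
        assert meds[0] < meds[1] < meds[2]

    def test_grid_method_deterministic(self, assoc_setup):
        b, env, om = assoc_setup
        cfg = BfModelConfig(method="grid")
        a = bayes_factor_run(b.calls, env, om, cfg, seed=1)
        c = bayes_factor_run(b.calls, env, om, cfg, seed=999)
        pd.testing.assert_frame_equal(a, c)

    def test_permuted_env_matches_dummy_distribution(self, assoc_setup):
        """Permuting the environment across accessions must produce the same
        BF distribution as independent (dummy) variables."""
        b, env, om = assoc_setup
        rng = np.random.default_rng(5)
        perm = pd.DataFrame(
            {"p": env["e1"].to_numpy()[rng.permutation(100)]})
        dummy = standardize_env(pd.DataFrame({"d": rng.normal(size=100)}))
        # grid integration: compares the statistic's distribution itself,
        # not Monte Carlo jitter of the beta integral
        cfg = BfModelConfig(method="grid")
        bf_perm = bayes_factor_run(b.calls, perm, om, cfg)["p"]
        bf_dum = bayes_factor_run(b.calls, dummy, om, cfg)["d"]
        ks = stats.ks_2samp(np.log(bf_perm), np.log(bf_dum))
        assert ks.pvalue > 0.01


class TestSpearman:
    def test_monotone_pairs(self):
        assert spearman_env([1, 2, 3, 4], [10, 20, 30, 40]) == 1.0
        assert spearman_env([1, 2, 3, 4], [40, 30, 20, 10]) == -1.0

    def test_hand_ranked_example(self):
        assert spearman_env([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_all_tied_is_nan(self):
        assert np.isnan(spearman_env([1, 1, 1], [1, 2, 3]))


def _run_table(bf: dict, rho: dict, loci, variables):
    return pd.concat({
        "bf": pd.DataFrame(bf, index=loci, columns=variables),
        "rho": pd.DataFrame(rho, index=loci, columns=variables)}, axis=1)


class TestConsensusHits:
    def _tables(self, n=100):
        loci = [f"l{i}" for i in range(n)]
        rng = np.random.default_rng(0)
        tables = []
        for _ in range(5):
            bf = {"v": np.concatenate([[1000.0], rng.uniform(0, 1, n - 1)])}
            rho = {"v": np.concatenate([[0.99], rng.uniform(0, 0.2, n - 1)])}
            tables.append(_run_table(bf, rho, loci, ["v"]))
        return loci, tables

    def test_dominant_pair_is_sole_hit(self):
        loci, tables = self._tables()
        assert consensus_hits(tables) == {("l0", "v")}

    def test_four_of_five_runs_is_not_a_hit(self):
        loci, tables = self._tables()
        # knock the winner out of the top 1% of |rho| in one single run
        tables[2].loc["l0", ("rho", "v")] = 0.0
        assert ("l0", "v") not in consensus_hits(tables)

    def test_empty_intersection_no_error(self):
        loci = [f"l{i}" for i in range(50)]
        rng = np.random.default_rng(1)
        tables = []
        for r in range(5):
            # the top-BF locus differs per run and never tops |rho|
            bf = {"v": rng.permutation(50).astype(float)}
            rho = {"v": rng.uniform(0, 1, 50) * (1 - bf["v"] / 50)}
            tables.append(_run_table(bf, rho, loci, ["v"]))
        assert isinstance(consensus_hits(tables), set)

    def test_hits_contained_in_per_run_top_sets(self, assoc_setup):
        b, env, om = assoc_setup
        runs = run_association(b.calls, env, om,
                               BfModelConfig(n_beta_draws=300), seed_base=4)
        hits = consensus_hits(runs)
        for t in runs:
            rho = t["rho"].abs()
            thr = np.nanquantile(rho.to_numpy().ravel(), 0.99)
            for locus, var in hits:
                assert rho.loc[locus, var] >= thr

    def test_shape_mismatch_errors(self):
        loci, tables = self._tables()
        with pytest.raises(ValueError):
            consensus_hits(tables[:1] + [tables[1].iloc[:10]])


class TestDummyThreshold:
    def test_degenerate_all_ones(self):
        with pytest.warns(UserWarning):
            assert dummy_threshold(np.ones(100)) == 1.0

    def test_monotone_in_percentile(self, rng):
        vals = rng.lognormal(size=20_000)
        assert dummy_threshold(vals, 99.99) >= dummy_threshold(vals, 99.0)

    def test_wide_interval_warns_on_few_values(self, rng):
        with pytest.warns(UserWarning):
            dummy_threshold(rng.lognormal(size=100))


class TestLatentFactors:
    def test_k_zero_equals_simple_regression(self, rng):
        calls = (rng.random((60, 100)) < 0.4).astype(float)
        env = rng.normal(size=60)
        z = latent_factor_assoc(pd.DataFrame(calls), env, K=0, n_runs=1)
        # oracle: per-locus OLS t of env coefficient
        x = np.column_stack([np.ones(60), env])
        xtxi = np.linalg.inv(x.T @ x)
        beta = xtxi @ x.T @ calls
        resid = calls - x @ beta
        s2 = (resid ** 2).sum(axis=0) / 58
        t = beta[1] / np.sqrt(s2 * xtxi[1, 1])
        z_oracle = stats.norm.isf(stats.t.sf(t, 58))
        assert np.allclose(z[:, 0], z_oracle, atol=1e-8)

    def test_structured_null_calibrated_after_adjustment(self):
        b = gen_structured_genotypes(120, 1200, [30, 30, 30, 30], 0.25,
                                     seed=31)
        rng = np.random.default_rng(2)
        env = b.q_matrix.to_numpy() @ np.array([1.0, -1.0, 0.5, -0.5]) \
            + rng.normal(0, 1, 120)
        env = (env - env.mean()) / env.std()
        z = latent_factor_assoc(b.calls, env, K=4, n_runs=5, seed_base=3)
        zc, _ = combine_fisher_stouffer(z)
        _, p = genomic_control(zc)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_structure_absorbs_confounded_signal(self):
        # a cline aligned with group membership: adjusting for the true
        # number of factors shrinks |z| at the causal loci
        b = gen_structured_genotypes(120, 400, [60, 60], 0.3, seed=32)
        env = np.repeat([1.0, -1.0], 60)
        env = (env - env.mean()) / env.std()
        rng = np.random.default_rng(4)
        g = b.calls.copy()
        prob = 1.0 / (1.0 + np.exp(-1.5 * env))
        causal = g.columns[:30]
        g[causal] = (rng.random((120, 30)) < prob[:, None]).astype(float)
        z0 = latent_factor_assoc(g, env, K=0, n_runs=1)
        z2 = latent_factor_assoc(g, env, K=2, n_runs=1)
        assert np.abs(z0[:30]).mean() > np.abs(z2[:30]).mean()

    def test_k_too_large_errors(self, rng):
        calls = pd.DataFrame((rng.random((20, 50)) < 0.5).astype(float))
        with pytest.raises(ValueError):
            latent_factor_assoc(calls, rng.normal(size=20), K=20)

    def test_missing_data_rejected(self, rng):
        calls = pd.DataFrame(np.full((10, 5), np.nan))
        with pytest.raises(ValueError):
            latent_factor_assoc(calls, rng.normal(size=10), K=2)


class TestCombination:
    def test_identical_runs_preserve_z(self):
        z, p = combine_fisher_stouffer(np.array([2.0, 2.0, 2.0, 2.0]))
        assert z == pytest.approx(2.0 * 4 / np.sqrt(4))

    def test_opposite_signs_cancel(self):
        z, p = combine_fisher_stouffer(np.array([2.0, -2.0]))
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form_example(self):
        z, _ = combine_fisher_stouffer(np.array([1.0, 2.0, 3.0]))
        assert z == pytest.approx(6.0 / np.sqrt(3.0), abs=1e-4)

    def test_matrix_input_shape(self, rng):
        z, p = combine_fisher_stouffer(rng.normal(size=(50, 5)))
        assert z.shape == (50,) and p.shape == (50,)


class TestBhFdr:
    def test_all_ones_no_hits(self):
        _, mask = bh_fdr(np.ones(10), q=0.01)
        assert not mask.any()

    def test_step_up_by_hand(self):
        # p=(0.001, 0.5, 0.9), m=3, Q=0.01: only the first passes
        # 0.001 <= 1/3 * 0.01
        qv, mask = bh_fdr(np.array([0.001, 0.5, 0.9]), q=0.01)
        assert list(mask) == [True, False, False]

    def test_mask_monotone_in_q(self, rng):
        p = rng.uniform(size=200) ** 3
        _, loose = bh_fdr(p, q=0.10)
        _, tight = bh_fdr(p, q=0.01)
        assert (tight <= loose).all()


class TestBfXtxCorrelation:
    def test_proportional_vectors(self, rng):
        x = rng.lognormal(size=100)
        assert bf_xtx_correlation(3 * x, x) == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self, rng):
        assert abs(bf_xtx_correlation(rng.lognormal(size=5000),
                                      rng.lognormal(size=5000))) < 0.05

    def test_zero_variance_nan(self):
        assert np.isnan(bf_xtx_correlation(np.ones(10), np.arange(10.0)))

    def test_dummy_baseline_near_zero_on_panel(self, assoc_setup):
        b, env, om = assoc_setup
        rng = np.random.default_rng(9)
        cfg = BfModelConfig(n_beta_draws=300)
        xtx_like = rng.lognormal(size=b.calls.shape[1])  # unrelated scan
        rs = []
        for d in range(6):
            dummy = standardize_env(
                pd.DataFrame({"d": rng.normal(size=100)}))
            bf = bayes_factor_run(b.calls, dummy, om, cfg, seed=d)["d"]
            rs.append(bf_xtx_correlation(bf, xtx_like))
        assert abs(np.mean(rs)) < 3 * (np.std(rs) + 1e-3)


class TestMedianOverRuns:
    def test_median_of_five_runs(self, assoc_setup):
        b, env, om = assoc_setup
        runs = run_association(b.calls.iloc[:, :50], env, om,
                               BfModelConfig(n_beta_draws=200), seed_base=6)
        med = median_over_runs(runs, "bf")
        stacked = np.stack([t["bf"].to_numpy() for t in runs])
        assert np.allclose(med.to_numpy(), np.median(stacked, axis=0))
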