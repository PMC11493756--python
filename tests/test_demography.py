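"""Model registry, SFS construction/folding, composite likelihood and
fitting contracts."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

from refugia import demography as dm
from refugia import synthpool

from conftest import make_poolcounts

EXPECTED_K = {
    "bottleneck_growth_both": 10,
    "bottleneck_growth_invaded": 8,
    "bottleneck_both": 8,
    "bottleneck_invaded": 7,
    "split_uneven_mig": 5,
    "split_even_mig": 4,
    "split_no_mig": 3,
}


class TestRegistry:
    def test_free_parameter_counts(self):
        for name, k in EXPECTED_K.items():
            assert dm.MODEL_REGISTRY[name].k == k, name

    def test_default_set_is_the_seven(self):
        assert set(dm.DEFAULT_MODELS) == set(EXPECTED_K)

    def test_untested_alternative_behind_flag(self):
        alt = dm.MODEL_REGISTRY["bottleneck_both_growth_invaded"]
        assert not alt.in_default_set
        assert alt.k == 9

    def test_theta_free_exactly_for_bottleneck_models(self):
        for m in dm.MODEL_REGISTRY.values():
            assert ("theta" in m.param_names) == m.has_bottleneck


class TestFolding:
    def test_fold_merges_complements(self):
        M = np.zeros((5, 5))
        M[1, 0] = 3.0
        M[3, 4] = 2.0   # complement of (1, 0)
        F = dm.fold_matrix(M, 4, 4)
        assert F[1, 0] == 5.0
        assert F[3, 4] == 0.0

    def test_fold_idempotent(self):
        rng = np.random.default_rng(1)
        M = rng.uniform(size=(7, 9))
        F = dm.fold_matrix(M, 6, 8)
        assert np.allclose(dm.fold_matrix(F, 6, 8), F)

    def test_mask_covers_corners_and_low_counts(self):
        m = dm.default_mask(8, 8, mask_max=3)
        assert m[0, 0] and m[8, 8]
        i, j = np.meshgrid(range(9), range(9), indexing="ij")
        assert np.all(m[(i + j) <= 3])

    def test_mask_and_fold_commute(self):
        rng = np.random.default_rng(2)
        M = rng.uniform(size=(9, 9))
        mask = dm.default_mask(8, 8)
        a = np.where(~mask, dm.fold_matrix(M, 8, 8), 0.0)
        b = dm.fold_matrix(np.where(~dm.fold_mask(8, 8), M, M), 8, 8)
        assert np.allclose(np.where(~mask, b, 0.0), a)


class TestEffectiveLength:
    def test_identity_when_all_snps_used(self):
        assert dm.effective_length(1e9, 500, 500) == 1e9

    def test_stated_example(self):
        assert dm.effective_length(1e9, 10**6, 2 * 10**7) == 5e7

    def test_linear_in_snps_used(self):
        a = dm.effective_length(1e8, 1000, 10_000)
        assert dm.effective_length(1e8, 2000, 10_000) == pytest.approx(2 * a)


class TestBuildSfs:
    def _pc(self, seed=3, L=4000):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.0, 1.0, size=(L, 2))
        p[:200] = 0.0       # fixed reference in both pools
        return synthpool.simulate_pool_reads(p, coverage_mean=30,
                                             error_rate=0.0, seed=seed)

    def test_fixed_sites_never_appear_unmasked(self):
        pc = self._pc()
        obs = dm.build_sfs(pc, (0, 1), n1=10, n2=10, coverage_band=False,
                           seed=4)
        assert obs.mask[0, 0] and obs.counts[0, 0] == 0

    def test_projection_matches_multinomial_expectation(self):
        """Projected SFS agrees with the direct binomial-projection
        expectation computed by an independent per-SNP pmf sum."""
        pc = self._pc(seed=5, L=20_000)
        n1 = n2 = 8
        obs = dm.build_sfs(pc, (0, 1), n1=n1, n2=n2, coverage_band=False,
                           mask_max=0, seed=6)
        p = pc.alt_freq()
        exp = np.zeros((n1 + 1, n2 + 1))
        k = np.arange(n1 + 1)
        pm1 = stats.binom.pmf(k[None, :], n1, p[:, 0][:, None])
        pm2 = stats.binom.pmf(k[None, :], n2, p[:, 1][:, None])
        for l in range(pc.n_sites):
            exp += np.outer(pm1[l], pm2[l])
        exp = dm.fold_matrix(exp, n1, n2)
        sel = ~obs.mask & (exp > 30)
        rel = (obs.counts[sel] - exp[sel]) / np.sqrt(exp[sel])
        assert np.mean(np.abs(rel) < 4) > 0.95

    def test_metadata_and_exclusion(self):
        pc = self._pc()
        obs = dm.build_sfs(pc, (0, 1), n1=10, n2=10,
                           exclude=set(range(1000)), coverage_band=False,
                           seed=7)
        assert obs.snps_total == pc.n_sites
        assert obs.snps_used <= pc.n_sites - 1000 + 200
        assert obs.total_length == pytest.approx(pc.pos.max() - pc.pos.min() + 1)
        assert obs.l_eff == pytest.approx(
            obs.total_length * obs.snps_used / obs.snps_total)


class TestCompositeLoglik:
    def _toy_obs(self):
        counts = np.array([[0.0, 5, 3, 0],
                           [4, 2, 1, 0],
                           [0, 0, 0, 0]])
        mask = np.zeros((3, 4), dtype=bool)
        mask[0, 0] = mask[2, 3] = True
        mask[0, 3] = mask[2, 0] = True
        return dm.Folded2DSFS(counts=counts, n1=2, n2=3, mask=mask,
                              total_length=1e4, snps_used=15, snps_total=20)

    def test_saturated_model_attains_poisson_maximum(self):
        obs = self._toy_obs()
        ll, _ = dm.composite_loglik(obs, obs.counts)
        k = obs.counts[~obs.mask]
        kp = k[k > 0]
        direct = float(np.sum(kp * np.log(kp) - kp - gammaln(kp + 1)))
        assert ll == pytest.approx(direct, rel=1e-12)

    def test_masked_cells_ignored(self):
        obs = self._toy_obs()
        m1 = obs.counts + 0.5
        m2 = m1.copy()
        m2[0, 0] = 99.0
        assert dm.composite_loglik(obs, m1)[0] == dm.composite_loglik(obs, m2)[0]

    def test_zero_model_with_positive_count_is_minus_inf(self):
        obs = self._toy_obs()
        m = obs.counts.copy()
        m[0, 1] = 0.0
        ll, _ = dm.composite_loglik(obs, m)
        assert ll == -np.inf

    def test_profiled_theta_is_stationary(self):
        obs = self._toy_obs()
        model = obs.counts * 0.37 + 0.05
        ll, scale = dm.composite_loglik(obs, model, profile_theta=True)
        for eps in (0.99, 1.01):
            ll2, _ = dm.composite_loglik(obs, model * scale * eps)
            assert ll2 < ll


class TestExpectedSfs:
    def test_bit_identical_under_fixed_seed(self):
        m = dm.MODEL_REGISTRY["split_uneven_mig"]
        p = dict(nu1=1.0, nu2=0.5, T_S=0.5, m_IR=1.0, m_RI=0.1)
        a = dm.expected_branch_lengths(m, p, 10, 10, n_reps=2000, seed=9)
        b = dm.expected_branch_lengths(m, p, 10, 10, n_reps=2000, seed=9)
        assert np.array_equal(a, b)

    def test_linear_in_theta(self):
        m = dm.MODEL_REGISTRY["split_no_mig"]
        p = dict(nu1=1.0, nu2=1.0, T_S=0.2)
        a = dm.expected_sfs(m, p, 6, 6, n_reps=2000, seed=10, theta=100.0)
        b = dm.expected_sfs(m, p, 6, 6, n_reps=2000, seed=10, theta=200.0)
        assert np.allclose(2.0 * a, b)

    def test_parameter_validation(self):
        m = dm.MODEL_REGISTRY["split_no_mig"]
        with pytest.raises(ValueError):
            dm.expected_branch_lengths(m, dict(nu1=-1, nu2=1, T_S=0.1), 4, 4)
        with pytest.raises(ValueError):
            dm.expected_branch_lengths(m, dict(nu1=np.nan, nu2=1, T_S=0.1), 4, 4)
        mb = dm.MODEL_REGISTRY["bottleneck_invaded"]
        with pytest.raises(ValueError):
            # bottleneck placement requires the effective length
            dm.expected_branch_lengths(
                mb, dict(nu1=1, nu1B=0.1, nu2=1, T_S=0.5, m_IR=1, m_RI=1,
                         theta=100.0), 4, 4)

    def test_symmetric_island_fst_matches_msprime(self):
        """F_ST from the expected SFS of a symmetric two-deme equilibrium
        agrees with msprime's branch-mode joint spectrum (independent
        coalescent implementation)."""
        msprime = pytest.importorskip("msprime")
        M = 2.0
        m = dm.MODEL_REGISTRY["split_even_mig"]
        p = dict(nu1=1.0, nu2=1.0, T_S=8.0, m_sym=M)
        n1 = n2 = 6
        T = dm.expected_branch_lengths(m, p, n1, n2, n_reps=100_000, seed=11)

        # haploid msprime populations of size nu give pairwise coalescence
        # rate 1/nu per unit time, matching the engine's 2*N_ref time units
        demog = msprime.Demography()
        demog.add_population(name="A", initial_size=1.0)
        demog.add_population(name="B", initial_size=1.0)
        demog.add_population(name="anc", initial_size=1.0)
        demog.add_population_split(time=8.0, derived=["A", "B"],
                                   ancestral="anc")
        demog.set_migration_rate("A", "B", M / 2)
        demog.set_migration_rate("B", "A", M / 2)

        def fst_from_sfs(S):
            # Hudson-style from expected heterozygosities
            i = np.arange(n1 + 1)[:, None] / n1
            j = np.arange(n2 + 1)[None, :] / n2
            hw = (S * (i * (1 - i) + j * (1 - j))).sum() / 2
            hb = (S * (i * (1 - j) + j * (1 - i))).sum() / 2
            return 1 - hw / hb

        # batch means give the oracle's Monte-Carlo SE for the 3-SE band
        n_batches, reps = 10, 500
        batch_fst, acc = [], np.zeros((n1 + 1, n2 + 1))
        it = msprime.sim_ancestry(
            samples={"A": n1, "B": n2}, demography=demog, ploidy=1,
            num_replicates=n_batches * reps, random_seed=12)
        for r, ts in enumerate(it, start=1):
            acc += ts.allele_frequency_spectrum(
                sample_sets=[list(range(n1)), list(range(n1, n1 + n2))],
                mode="branch", polarised=True, span_normalise=False)
            if r % reps == 0:
                batch_fst.append(fst_from_sfs(acc))
                acc = np.zeros((n1 + 1, n2 + 1))
        f_ref = float(np.mean(batch_fst))
        se = float(np.std(batch_fst, ddof=1)) / np.sqrt(n_batches)
        assert fst_from_sfs(T) == pytest.approx(f_ref, abs=3 * se)


class TestGeneFlowAndRanking:
    def test_classification_boundaries(self):
        assert dm.classify_gene_flow(0.04) == "negligible"
        assert dm.classify_gene_flow(0.05) == "low"
        assert dm.classify_gene_flow(5.5) == "low"
        assert dm.classify_gene_flow(5.51) == "high"

    def test_tie_reported_and_order_invariant(self):
        f1 = dm.FitResult(model="split_no_mig", params={}, loglik=-100.0)
        f2 = dm.FitResult(model="split_even_mig", params={}, loglik=-100.0)
        f3 = dm.FitResult(model="split_uneven_mig", params={}, loglik=-90.0)
        a = dm.compare_models([f1, f2, f3])
        b = dm.compare_models([f3, f2, f1])
        assert a["model"].tolist() == b["model"].tolist()
        assert a.iloc[0]["model"] == "split_uneven_mig"
        assert not a.iloc[0]["tied"]
        assert a.iloc[1]["tied"] and a.iloc[2]["tied"]
        assert a["rank"].tolist() == [1, 2, 2]

    def test_scaled_migration_uses_recipient_present_size(self):
        m = dm.MODEL_REGISTRY["bottleneck_invaded"]
        p = dict(nu1=1.0, nu1B=0.1, nu2=2.0, T_S=0.5, m_IR=3.0, m_RI=0.5,
                 theta=100.0)
        tn = dm.scaled_migration(m, p)
        assert tn["into_invaded"] == pytest.approx(3.0 * 0.1)
        assert tn["into_refuge"] == pytest.approx(0.5 * 2.0)


class TestBlockBootstrap:
    def _small_case(self):
        rng = np.random.default_rng(20)
        p = rng.uniform(0.1, 0.9, size=(3000, 2))
        pc = synthpool.simulate_pool_reads(p, coverage_mean=30,
                                           error_rate=0.0, seed=21,
                                           spacing=600)
        obs = dm.build_sfs(pc, (0, 1), n1=6, n2=6, coverage_band=False,
                           seed=22)
        fit = dm.fit_model(obs, "split_no_mig", n_reps=1500, seed=23,
                           max_runs=1, converge_runs=1, nm_maxiter=60,
                           n_scan=16, polish_reps=1500)
        return pc, fit

    def test_too_few_chunks_rejected(self):
        pc, fit = self._small_case()
        with pytest.raises(ValueError, match="chunks"):
            dm.block_bootstrap(pc, (0, 1), "split_no_mig", fit,
                               chunk=10**9, n_boot=2)

    def test_degenerate_single_bootstrap(self):
        pc, fit = self._small_case()
        build = dict(n1=6, n2=6, coverage_band=False)
        ci = dm.block_bootstrap(pc, (0, 1), "split_no_mig", fit,
                                chunk=100_000, n_boot=1, seed=24,
                                build_kwargs=build,
                                fit_kwargs=dict(n_reps=1500, n_scan=8,
                                                nm_maxiter=40,
                                                polish_reps=1500))
        for lo_hi in ci.values():
            assert lo_hi[0] == pytest.approx(lo_hi[1])
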