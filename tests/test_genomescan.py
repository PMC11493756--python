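"""Omega estimation, differentiation/association statistics, recalibration,
q-values and candidate filtering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from refugia import genomescan as gs
from refugia import synthpool

from conftest import make_poolcounts


def toy_pc(phat, depth=200, n=80):
    """PoolCounts whose read frequencies are (approximately) ``phat``."""
    phat = np.atleast_2d(np.asarray(phat, dtype=float))
    alt = np.round(phat * depth).astype(int)
    return make_poolcounts(depth - alt, alt, pool_haploids=n)


class TestEstimateOmega:
    def test_matches_brute_force_outer_product(self):
        rng = np.random.default_rng(1)
        pc = toy_pc(rng.uniform(0.2, 0.8, size=(10, 4)))
        om = gs.estimate_omega(pc)
        p = pc.alt_freq()
        acc = np.zeros((4, 4))
        for l in range(10):
            pbar = p[l].mean()
            x = (p[l] - pbar) / np.sqrt(pbar * (1 - pbar))
            acc += np.outer(x, x)
        acc /= 10
        assert np.allclose(om.omega - om.ridge_eps * np.eye(4), acc, atol=1e-12)

    def test_monomorphic_snps_excluded(self):
        rng = np.random.default_rng(2)
        ph = rng.uniform(0.3, 0.7, size=(30, 3))
        ph[:5] = 0.0   # pbar = 0 rows must not contribute
        pc = toy_pc(ph)
        om = gs.estimate_omega(pc)
        assert om.n_snps_used == 25
        assert om.n_snps_excluded == 5

    def test_cluster_sign_structure(self):
        """Two migration clusters with clear divergence: positive
        allele-frequency covariance within clusters, negative between
        (clusters are demes 0-5 vs 6-11)."""
        cfg = synthpool.SimConfig(n_loci=5000, p_selected=0.0, split_gen=500,
                                  deme_size=200, m_between=0.002,
                                  bottleneck_demes=(), seed=41)
        freqs, _ = synthpool.simulate_metapopulation(cfg)
        pc = synthpool.simulate_pool_reads(freqs, seed=42)
        from refugia import poolio
        pcf, _ = poolio.filter_snps(pc)
        om = gs.estimate_omega(pcf).omega
        within, between = [], []
        for i in range(12):
            for j in range(i + 1, 12):
                (within if (i < 6) == (j < 6) else between).append(om[i, j])
        assert np.mean(within) > 0 and np.mean(np.array(within) > 0) > 0.9
        assert np.mean(between) < 0 and np.mean(np.array(between) < 0) > 0.9

    def test_requires_enough_snps(self):
        pc = toy_pc(np.full((2, 4), 0.5))
        with pytest.raises(ValueError):
            gs.estimate_omega(pc)


class TestXtxScan:
    def test_zero_deviation_vector_is_low_tail(self):
        ph = np.vstack([np.full((5, 3), 0.5), [[0.2, 0.5, 0.8]] * 5])
        pc = toy_pc(ph)
        om = gs.estimate_omega(pc)
        res = gs.xtx_scan(pc, om)
        assert res.statistic[0] == pytest.approx(0.0, abs=1e-12)
        assert res.p_raw[0] == pytest.approx(0.0, abs=1e-12)
        assert res["tail"][0] == "low"

    def test_identity_omega_reduces_to_sum_of_squares(self):
        """3-population toy with Omega = I: XtX equals the plain sum of
        squared standardized deviations (hand-checkable)."""
        pc = toy_pc([[0.2, 0.5, 0.8]])
        om = gs.OmegaMatrix(omega=np.eye(3))
        res = gs.xtx_scan(pc, om)
        p = pc.alt_freq()[0]
        pbar = p.mean()
        x = (p - pbar) / np.sqrt(pbar * (1 - pbar))
        assert res.statistic[0] == pytest.approx(np.sum(x ** 2), rel=1e-9)

    def test_ref_alt_swap_invariance(self, neutral_scan_data):
        _, pcf = neutral_scan_data
        pc = pcf.take(np.arange(500))
        om = gs.estimate_omega(pcf)
        a = gs.xtx_scan(pc, om)
        swapped = pc.take(np.arange(500))
        swapped.ref_count, swapped.alt_count = (swapped.alt_count.copy(),
                                                swapped.ref_count.copy())
        b = gs.xtx_scan(swapped, om)
        assert np.allclose(a.statistic.to_numpy(), b.statistic.to_numpy(),
                           equal_nan=True)

    def test_planted_outlier_ranks_top(self, neutral_scan_data):
        """A SNP at 0.9 in one cluster and 0.1 in the other on a neutral
        background lands in the top 0.1% of the scan."""
        _, pcf = neutral_scan_data
        planted = np.array([[0.9] * 6 + [0.1] * 6], dtype=float)
        alt = np.round(planted * 200).astype(int)
        pc2 = pcf.take(np.arange(pcf.n_sites))
        pc2.ref_count = np.vstack([pcf.ref_count, 200 - alt])
        pc2.alt_count = np.vstack([pcf.alt_count, alt])
        pc2.chrom = np.append(pcf.chrom, "scaf_1")
        pc2.pos = np.append(pcf.pos, pcf.pos.max() + 100)
        pc2.ref_base = np.append(pcf.ref_base, "A")
        pc2.alt_base = np.append(pcf.alt_base, "C")
        pc2.multiallelic = np.append(pcf.multiallelic, False)
        pc2.del_count = np.vstack([pc2.del_count, np.zeros((1, 12), dtype=int)])
        om = gs.estimate_omega(pc2)
        res = gs.xtx_scan(pc2, om)
        rank = (res.statistic > res.statistic.iloc[-1]).mean()
        assert rank < 0.001

    def test_singular_omega_raises_with_guidance(self):
        pc = toy_pc(np.random.default_rng(3).uniform(0.3, 0.7, (10, 3)))
        om = gs.OmegaMatrix(omega=np.ones((3, 3)))
        with pytest.raises(np.linalg.LinAlgError, match="regulariz"):
            gs.xtx_scan(pc, om)


class TestC2Scan:
    def test_orthogonal_deviation_gives_zero(self):
        # contrast (+,+,-,-): deviations symmetric within groups -> c'x = 0
        pc = toy_pc([[0.3, 0.7, 0.3, 0.7]])
        om = gs.OmegaMatrix(omega=np.eye(4))
        res = gs.c2_scan(pc, om, [1, 1, 0, 0])
        assert res.statistic[0] == pytest.approx(0.0, abs=1e-12)
        assert res.p_raw[0] == pytest.approx(1.0)

    def test_group_relabel_flips_sign_only(self, neutral_scan_data):
        cfg, pcf = neutral_scan_data
        pc = pcf.take(np.arange(300))
        om = gs.estimate_omega(pcf)
        g = np.array(cfg.env_goby)
        a = gs.c2_scan(pc, om, g)
        b = gs.c2_scan(pc, om, 1 - g)
        assert np.allclose(a.statistic, b.statistic, equal_nan=True)
        assert np.array_equal(a.effect_sign.to_numpy(),
                              -b.effect_sign.to_numpy())

    def test_constant_contrast_rejected(self):
        pc = toy_pc([[0.3, 0.5, 0.7]])
        om = gs.OmegaMatrix(omega=np.eye(3))
        with pytest.raises(ValueError):
            gs.c2_scan(pc, om, [1, 1, 1])


class TestOmegaRegression:
    def test_constant_covariable_rejected(self, neutral_scan_data):
        _, pcf = neutral_scan_data
        om = gs.estimate_omega(pcf)
        with pytest.raises(ValueError):
            gs.omega_regression(pcf, om, np.ones(12))

    def test_identity_omega_hand_check(self):
        """3 populations, Omega = I, k standardized: z^2 = (k'x)^2 / (k'k)."""
        pc = toy_pc([[0.2, 0.5, 0.8]])
        om = gs.OmegaMatrix(omega=np.eye(3))
        covar = np.array([-1.0, 0.0, 1.0])
        res = gs.omega_regression(pc, om, covar)
        p = pc.alt_freq()[0]
        pbar = p.mean()
        x = (p - pbar) / np.sqrt(pbar * (1 - pbar))
        k = (covar - covar.mean()) / covar.std()
        assert res.statistic[0] == pytest.approx((k @ x) ** 2 / (k @ k), rel=1e-9)
        assert res.effect_sign[0] == 1


class TestQuasibinomialScan:
    def test_flat_frequencies_give_null_slope(self):
        pc = toy_pc(np.full((20, 6), 0.4))
        res = gs.quasibinomial_scan(pc, [0, 0, 0, 1, 1, 1])
        assert np.all(np.abs(res.statistic[res.converged]) < 1e-6)
        assert np.all(res.p_raw[res.converged] > 0.99)

    def test_complete_separation_finite_via_add_one(self):
        ph = np.vstack([np.tile([0.0, 0.0, 0.0, 1.0, 1.0, 1.0], (1, 1)),
                        np.full((30, 6), 0.5) + np.linspace(-0.1, 0.1, 6)])
        pc = toy_pc(ph)
        res = gs.quasibinomial_scan(pc, [0, 0, 0, 1, 1, 1])
        assert np.isfinite(res.p_raw[0])
        assert res.p_raw[0] == res.p_raw.min()

    def test_matches_statsmodels_quasibinomial(self, neutral_scan_data):
        """Slope and dispersion agree with an independent IRLS (statsmodels
        GLM with binomial family and Pearson-chi2 scale) on a SNP sample."""
        sm = pytest.importorskip("statsmodels.api")
        cfg, pcf = neutral_scan_data
        g = np.array(cfg.env_goby, dtype=float)
        res = gs.quasibinomial_scan(pcf, g)
        from refugia.poolio import effective_sample_size
        xdes = sm.add_constant((g - g.mean()) / g.std())
        rng = np.random.default_rng(0)
        for snp in rng.choice(pcf.n_sites, 12, replace=False):
            depth = pcf.depth[snp].astype(float)
            phat = pcf.alt_count[snp] / depth
            neff = effective_sample_size(pcf.pool_haploids, depth)
            ya = phat * neff
            yr = (1 - phat) * neff
            ya = np.where(ya == 0, 1.0, ya)
            yr = np.where(yr == 0, 1.0, yr)
            w = ya + yr
            fit = sm.GLM(ya / w, xdes, family=sm.families.Binomial(),
                         var_weights=w).fit(scale="X2")
            t_ours = np.sqrt(res.statistic[snp]) * res.effect_sign[snp]
            t_sm = fit.params[1] / fit.bse[1]
            assert t_ours == pytest.approx(t_sm, rel=1e-4, abs=1e-6)


class TestGenomicControl:
    def test_uniform_grid_is_identity(self):
        p = np.linspace(0.0005, 0.9995, 2001)
        res = gs.genomic_control(p)
        assert res.lam == pytest.approx(1.0, abs=0.01)
        assert np.allclose(res.p_recal, p, atol=0.01)

    def test_recovers_twofold_inflation(self):
        rng = np.random.default_rng(4)
        z2 = 2.0 * stats.chi2.rvs(1, size=20_000, random_state=rng)
        res = gs.genomic_control(stats.chi2.sf(z2, 1))
        assert res.lam == pytest.approx(2.0, abs=0.08)

    def test_deflated_null_recalibrates_monotonically(self):
        rng = np.random.default_rng(5)
        z2 = 0.85 * stats.chi2.rvs(1, size=20_000, random_state=rng)
        p_raw = stats.chi2.sf(z2, 1)
        res = gs.genomic_control(p_raw)
        assert res.lam < 1.0
        small = p_raw < 0.01
        assert np.all(res.p_recal[small] < p_raw[small])
        order = np.argsort(p_raw)
        assert np.all(np.diff(res.p_recal[order]) >= 0)

    def test_rejects_zero_pvalues(self):
        with pytest.raises(ValueError):
            gs.genomic_control(np.array([0.0, 0.5]))

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning):
            gs.genomic_control(np.linspace(0.1, 0.9, 50))


class TestStoreyQvalues:
    def test_all_ones(self):
        assert np.all(gs.storey_qvalues(np.ones(10)) == 1.0)

    def test_pi0_one_equals_benjamini_hochberg(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(6)
        p = rng.uniform(size=1000)
        q = gs.storey_qvalues(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, bh, atol=1e-12)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=500)
        q = gs.storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestCandidateIntersection:
    def _frame(self, snps, sig, signs, with_q=True):
        n = max(snps) + 1
        df = pd.DataFrame({"snp": np.arange(n), "significant": False,
                           "effect_sign": 0,
                           "q": np.ones(n)})
        df.loc[list(sig), "significant"] = True
        if with_q:
            df.loc[list(sig), "q"] = 0.0001
        for s, sg in signs.items():
            df.loc[s, "effect_sign"] = sg
        return df

    def setup_method(self, method):
        # 6 pops; SNPs 0/1 separate cleanly by group, SNP 2 does not
        ph = np.array([
            [0.1, 0.1, 0.1, 0.9, 0.9, 0.9],
            [0.9, 0.9, 0.9, 0.1, 0.1, 0.1],
            [0.5, 0.1, 0.9, 0.5, 0.9, 0.1],
            [0.1, 0.2, 0.1, 0.8, 0.9, 0.9],
        ])
        self.pc = toy_pc(ph)
        self.groups = {"calcium": np.array([0, 0, 0, 1, 1, 1]),
                       "goby": np.array([0, 0, 0, 1, 1, 1])}

    def test_disjoint_sets_empty(self):
        om = {"calcium": self._frame([0, 1, 2, 3], {0}, {0: 1}),
              "goby": self._frame([0, 1, 2, 3], set(), {})}
        gl = {"calcium": self._frame([0, 1, 2, 3], {1}, {1: -1}),
              "goby": self._frame([0, 1, 2, 3], set(), {})}
        out = gs.candidate_intersection(self.pc, om, gl, self.groups)
        assert out["calcium"].snp_ids.size == 0

    def test_shared_snp_excluded_from_both(self):
        om = {"calcium": self._frame([0, 1, 2, 3], {0}, {0: 1}),
              "goby": self._frame([0, 1, 2, 3], {0}, {0: 1})}
        gl = {"calcium": self._frame([0, 1, 2, 3], {0}, {0: 1}),
              "goby": self._frame([0, 1, 2, 3], {0}, {0: 1})}
        out = gs.candidate_intersection(self.pc, om, gl, self.groups)
        assert out["calcium"].snp_ids.size == 0
        assert out["goby"].snp_ids.size == 0
        assert out["calcium"].n_removed_shared == 1

    def test_direction_rules(self):
        # SNP 0: clean separation, agreeing signs -> kept
        # SNP 1: methods disagree in sign -> dropped
        # SNP 2: scrambled frequencies -> fails group separation
        om = {"calcium": self._frame([0, 1, 2, 3], {0, 1, 2}, {0: 1, 1: 1, 2: 1}),
              "goby": self._frame([0, 1, 2, 3], set(), {})}
        gl = {"calcium": self._frame([0, 1, 2, 3], {0, 1, 2}, {0: 1, 1: -1, 2: 1}),
              "goby": self._frame([0, 1, 2, 3], set(), {})}
        out = gs.candidate_intersection(self.pc, om, gl, self.groups)
        assert list(out["calcium"].snp_ids) == [0]
        assert out["calcium"].n_removed_direction == 2
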