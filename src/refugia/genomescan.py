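"""Outlier and genotype-environment association scans for pool-seq data.

All scans share the scaled covariance matrix Omega of standardized
population allele-frequency deviations, which absorbs demographic history so
that differentiation statistics are not confounded by population structure:

* ``xtx_scan``      - SNP-specific differentiation (Omega-corrected squared
                      Mahalanobis length), chi2(J) under neutrality, bilateral
                      test (low tail = balancing-selection-like).
* ``c2_scan``       - squared standardized group contrast for a binary
                      covariable, chi2(1) under neutrality.
* ``omega_regression`` - generalized-least-squares slope of standardized
                      frequencies on a standardized continuous covariable
                      (deterministic evaluation of the same regression model
                      family that Bayesian association scans sample).
* ``quasibinomial_scan`` - per-SNP GLM of allele frequency on a binary
                      covariable with binomial variance and free dispersion,
                      on counts rescaled to the pool-seq effective sample
                      size; recalibrated against the empirical null via the
                      genomic inflation factor.

Candidates are SNPs significant in both an Omega-based scan and the GLM
scan, uniquely associated with one covariable, and direction-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .poolio import PoolCounts, effective_sample_size

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549364...


@dataclass
class OmegaMatrix:
    """J x J scaled covariance of standardized population allele frequencies."""

    omega: np.ndarray
    n_snps_used: int = 0
    n_snps_excluded: int = 0
    ridge_eps: float = 0.0

    @property
    def n_pops(self) -> int:
        return self.omega.shape[0]

    def inverse(self) -> np.ndarray:
        try:
            return np.linalg.inv(self.omega)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "Omega is singular; re-estimate with ridge regularization "
                "(estimate_omega applies it automatically)") from err


@dataclass
class RecalibrationResult:
    """Genomic-control recalibration: inflation factor and recalibrated p."""

    lam: float
    p_recal: np.ndarray


@dataclass
class CandidateSet:
    """Candidate SNPs for one covariable after intersection, uniqueness and
    direction-consistency filtering."""

    covariable: str
    snp_ids: np.ndarray
    n_intersection: int = 0
    n_removed_shared: int = 0
    n_removed_direction: int = 0


def standardized_deviations(pc: PoolCounts):
    """Per-SNP standardized deviation vectors x_lj = (p_lj - pbar_l)/sqrt(pbar(1-pbar)).

    Returns (x, valid) where ``valid`` marks SNPs usable for Omega/XtX (full
    depth in every population and 0 < pbar < 1); x rows for invalid SNPs are 0.
    """
    p = pc.alt_freq()
    valid = ~np.any(np.isnan(p), axis=1)
    pbar = np.nanmean(p, axis=1)
    valid &= (pbar > 0.0) & (pbar < 1.0)
    x = np.zeros_like(p)
    den = np.sqrt(np.clip(pbar * (1.0 - pbar), 1e-300, None))
    x[valid] = (p[valid] - pbar[valid, None]) / den[valid, None]
    return x, valid


def estimate_omega(pc: PoolCounts, ridge_factor: float = 1e-6) -> OmegaMatrix:
    """Moment estimate Omega = (1/L) sum_l x_l x_l^T over usable SNPs,
    ridge-regularized (eps added to the diagonal, doubling until positive
    definite)."""
    if pc.n_pops < 2:
        raise ValueError("need at least 2 populations")
    x, valid = standardized_deviations(pc)
    L = int(valid.sum())
    if L < pc.n_pops:
        raise ValueError(f"need at least J={pc.n_pops} usable SNPs, got {L}")
    xv = x[valid]
    omega = xv.T @ xv / L
    # sample-mean centering leaves the ones-vector in the null space, so the
    # raw moment estimate is always rank-deficient; ridge until the smallest
    # eigenvalue is meaningfully positive.  The deviations x are orthogonal
    # to the ridged direction, so downstream quadratic forms are unaffected.
    eps = ridge_factor * np.trace(omega) / pc.n_pops
    eps = max(eps, 1e-12)
    total = 0.0
    while True:
        ev = np.linalg.eigvalsh(omega + total * np.eye(pc.n_pops))
        if ev[0] > 1e-10 * max(ev[-1], 1e-300):
            break
        total = eps if total == 0.0 else total * 2.0
    omega = omega + total * np.eye(pc.n_pops)
    return OmegaMatrix(omega=omega, n_snps_used=L,
                       n_snps_excluded=pc.n_sites - L, ridge_eps=total)


def _assoc_frame(n, method, covariable):
    return pd.DataFrame({
        "snp": np.arange(n),
        "method": method,
        "covariable": covariable,
        "statistic": np.nan,
        "p_raw": np.nan,
        "p_recal": np.nan,
        "q": np.nan,
        "effect_sign": 0,
    })


def xtx_scan(pc: PoolCounts, omega: OmegaMatrix, p_threshold: float = 0.001,
             df: int = None) -> pd.DataFrame:
    """XtX_l = x_l' Omega^-1 x_l with a bilateral chi2 test.

    p = 2*min(F(XtX), 1-F(XtX)); the high tail flags positive-selection-like
    differentiation, the low tail balancing-selection-like homogeneity.

    The default reference is chi2(J-1): standardizing against the sample
    mean across populations removes one degree of freedom (the deviations
    sum to zero), so the neutral null of this deterministic estimator has
    J-1 df.  Hierarchical Bayesian implementations that infer a latent
    ancestral frequency quote J df for the analogous statistic; pass
    ``df=J`` to reproduce that reference against an externally supplied
    Omega.
    """
    oinv = omega.inverse()
    x, valid = standardized_deviations(pc)
    xtx = np.einsum("lj,jk,lk->l", x, oinv, x)
    J = pc.n_pops
    if df is None:
        df = J - 1
    cdf = stats.chi2.cdf(xtx, df)
    p = 2.0 * np.minimum(cdf, 1.0 - cdf)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = _assoc_frame(pc.n_sites, "xtx", "none")
    out["statistic"] = np.where(valid, xtx, np.nan)
    out["p_raw"] = np.where(valid, p, np.nan)
    out["tail"] = np.where(cdf >= 0.5, "high", "low")
    out["outlier"] = valid & (p < p_threshold)
    return out


def _contrast_vector(groups: np.ndarray) -> np.ndarray:
    """Mean-zero +/-1-coded group contrast."""
    g = np.asarray(groups)
    if np.unique(g).size != 2:
        raise ValueError("binary contrast must have exactly two levels present")
    c = np.where(g == np.max(g), 1.0, -1.0)
    return c - c.mean()


def c2_scan(pc: PoolCounts, omega: OmegaMatrix, contrast, fdr: float = 0.01) -> pd.DataFrame:
    """C2_l = (c' x_l)^2 / (c' Omega c), chi2(1) under neutrality; q-values
    attached for FDR control."""
    c = _contrast_vector(contrast)
    x, valid = standardized_deviations(pc)
    num = x @ c
    den = float(c @ omega.omega @ c)
    c2 = num ** 2 / den
    p = stats.chi2.sf(c2, 1)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = _assoc_frame(pc.n_sites, "c2", "binary")
    out["statistic"] = np.where(valid, c2, np.nan)
    out["p_raw"] = np.where(valid, p, np.nan)
    out.loc[valid, "q"] = storey_qvalues(p[valid])
    out["effect_sign"] = np.where(valid, np.sign(num).astype(int), 0)
    out["significant"] = valid & (out["q"].to_numpy() < fdr)
    return out


def omega_regression(pc: PoolCounts, omega: OmegaMatrix, covar,
                     q_threshold: float = 0.001) -> pd.DataFrame:
    """GLS regression of x_l on a standardized covariable k.

    beta_l = (k' Omega^-1 x_l) / (k' Omega^-1 k), Var(beta) = 1/(k' Omega^-1 k),
    z^2 = beta^2 * (k' Omega^-1 k) ~ chi2(1) under the null.  The default
    stringency (q < 0.001 on genomic-control-recalibrated p) emulates a
    "decisive evidence" cut-off.
    """
    k = np.asarray(covar, dtype=float)
    if np.std(k) == 0:
        raise ValueError("covariable has zero variance")
    k = (k - k.mean()) / k.std()
    oinv = omega.inverse()
    x, valid = standardized_deviations(pc)
    koi = oinv @ k
    den = float(k @ koi)
    beta = (x @ koi) / den
    z2 = beta ** 2 * den
    p = stats.chi2.sf(z2, 1)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = _assoc_frame(pc.n_sites, "omega_reg", "continuous")
    out["statistic"] = np.where(valid, z2, np.nan)
    out["p_raw"] = np.where(valid, p, np.nan)
    recal = genomic_control(p[valid])
    out.loc[valid, "p_recal"] = recal.p_recal
    out.loc[valid, "q"] = storey_qvalues(recal.p_recal)
    out["effect_sign"] = np.where(valid, np.sign(beta).astype(int), 0)
    out["significant"] = valid & (out["q"].to_numpy() < q_threshold)
    out.attrs["lambda_gc"] = recal.lam
    return out


def quasibinomial_scan(pc: PoolCounts, covar, rescale: bool = True,
                       add_one: bool = True, max_iter: int = 50,
                       tol: float = 1e-8) -> pd.DataFrame:
    """Per-SNP quasibinomial GLM of allele frequency on a binary covariable.

    Counts are rescaled to the effective sample size n_eff (the information
    content of pooled reads), one is added to zero cells, and a logit-link
    IRLS fit with binomial variance is run per SNP (vectorized across SNPs).
    The slope is tested against a t reference with J-2 df using the Pearson
    dispersion estimate; p-values are raw (recalibrate with
    :func:`genomic_control`).
    """
    J = pc.n_pops
    if J < 3:
        raise ValueError("need at least 3 populations")
    g = np.asarray(covar, dtype=float)
    if np.unique(g).size < 2:
        raise ValueError("covariable must vary")
    xdes = np.column_stack([np.ones(J), (g - g.mean()) / g.std()])

    depth = pc.depth.astype(float)
    valid = np.all(depth > 0, axis=1)
    p_hat = np.where(depth > 0, pc.alt_count / np.maximum(depth, 1), 0.0)
    if rescale:
        neff = np.where(depth > 0,
                        effective_sample_size(pc.pool_haploids[None, :],
                                              np.maximum(depth, 1)), 1.0)
    else:
        neff = depth
    y_alt = p_hat * neff
    y_ref = (1.0 - p_hat) * neff
    if add_one:
        y_alt = np.where(y_alt == 0.0, 1.0, y_alt)
        y_ref = np.where(y_ref == 0.0, 1.0, y_ref)
    w = y_alt + y_ref          # (L, J) prior weights
    y = y_alt / w              # observed proportions

    L = pc.n_sites
    beta = np.zeros((L, 2))
    pbar = np.clip(y.mean(axis=1), 1e-6, 1 - 1e-6)
    beta[:, 0] = np.log(pbar / (1 - pbar))
    converged = np.zeros(L, dtype=bool)
    active = valid.copy()
    for _ in range(max_iter):
        if not active.any():
            break
        eta = beta[:, 0:1] + beta[:, 1:2] * xdes[:, 1][None, :]
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        W = w * mu * (1.0 - mu)                      # IRLS weights
        z = (y - mu)                                 # working residual * mu'(eta)^-1 folded in
        # normal equations with design [1, x]: solve 2x2 per SNP
        Sw = W.sum(axis=1)
        Swx = (W * xdes[:, 1]).sum(axis=1)
        Swxx = (W * xdes[:, 1] ** 2).sum(axis=1)
        r0 = (w * z).sum(axis=1)
        r1 = (w * z * xdes[:, 1]).sum(axis=1)
        det = Sw * Swxx - Swx ** 2
        ok = active & (det > 1e-300)
        d0 = np.zeros(L)
        d1 = np.zeros(L)
        d0[ok] = (Swxx[ok] * r0[ok] - Swx[ok] * r1[ok]) / det[ok]
        d1[ok] = (Sw[ok] * r1[ok] - Swx[ok] * r0[ok]) / det[ok]
        beta[:, 0] += np.where(ok, d0, 0.0)
        beta[:, 1] += np.where(ok, d1, 0.0)
        done = ok & (np.abs(d0) < tol) & (np.abs(d1) < tol)
        converged |= done
        active &= ~done
        active &= ok | ~active

    eta = beta[:, 0:1] + beta[:, 1:2] * xdes[:, 1][None, :]
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    pearson = w * (y - mu) ** 2 / np.clip(mu * (1.0 - mu), 1e-12, None)
    phi = pearson.sum(axis=1) / (J - 2)
    W = w * mu * (1.0 - mu)
    Sw = W.sum(axis=1)
    Swx = (W * xdes[:, 1]).sum(axis=1)
    Swxx = (W * xdes[:, 1] ** 2).sum(axis=1)
    det = Sw * Swxx - Swx ** 2
    var_slope = np.where(det > 1e-300, phi * Sw / np.clip(det, 1e-300, None), np.nan)
    tstat = beta[:, 1] / np.sqrt(np.clip(var_slope, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(tstat), J - 2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    usable = valid & converged
    out = _assoc_frame(L, "qb_glm", "binary")
    out["statistic"] = np.where(usable, tstat ** 2, np.nan)
    out["p_raw"] = np.where(usable, p, np.nan)
    out["effect_sign"] = np.where(usable, np.sign(beta[:, 1]).astype(int), 0)
    out["converged"] = usable
    return out


def genomic_control(p_raw) -> RecalibrationResult:
    """Empirical-null recalibration via the genomic inflation factor.

    p-values are mapped to chi2(1) deviates; lambda = median(z^2) / median of
    chi2(1); recalibrated p = upper chi2(1) tail of z^2 / lambda.  lambda > 1
    flags inflation (residual structure), lambda < 1 deflation.
    """
    p = np.asarray(p_raw, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    if p.size < 100:
        import warnings
        warnings.warn("fewer than 100 p-values: the median (and lambda) is unstable")
    z2 = stats.chi2.isf(p, 1)
    lam = float(np.median(z2) / CHI2_1_MEDIAN)
    p_recal = stats.chi2.sf(z2 / lam, 1)
    p_recal = np.clip(p_recal, np.finfo(float).tiny, 1.0)
    return RecalibrationResult(lam=lam, p_recal=p_recal)


def storey_qvalues(p, pi0: float = None) -> np.ndarray:
    """Storey q-values with the fixed-threshold pi0 estimate
    pi0 = min(1, #{p > 0.5} / (0.5 m)); with pi0 forced to 1 this reduces to
    Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = min(1.0, float(np.sum(p > 0.5)) / (0.5 * m))
        pi0 = max(pi0, 1.0 / m)  # guard against pi0 = 0 on tiny inputs
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def direction_consistent(pc: PoolCounts, snp_idx: int, groups, sign: int,
                         min_fraction: float = 5.0 / 6.0) -> bool:
    """Declared convention for the qualitative "consistent allele frequency
    association" rule: with effect sign ``sign`` for the high/1 group, at
    least ceil(min_fraction * group size) populations in EACH group must lie
    on the model-implied side of the across-population mean frequency."""
    g = np.asarray(groups)
    p = pc.alt_freq()[snp_idx]
    if np.any(np.isnan(p)) or sign == 0:
        return False
    pbar = p.mean()
    dev = p - pbar
    hi = g == np.max(g)
    lo = ~hi
    need_hi = int(np.ceil(min_fraction * hi.sum()))
    need_lo = int(np.ceil(min_fraction * lo.sum()))
    ok_hi = int(np.sum(sign * dev[hi] > 0))
    ok_lo = int(np.sum(sign * dev[lo] < 0))
    return ok_hi >= need_hi and ok_lo >= need_lo


def candidate_intersection(pc: PoolCounts, omega_results: dict, glm_results: dict,
                           groups: dict, glm_fdr: float = 0.01) -> dict:
    """Intersect the Omega-based and GLM significant sets per covariable,
    enforce uniqueness across covariables, then drop direction-inconsistent
    SNPs (method effect signs disagree, or the group-separation rule fails).

    ``omega_results``/``glm_results`` map covariable name -> scan DataFrame;
    ``groups`` maps covariable name -> binary per-population group vector
    used by the direction rule (continuous covariables are split at their
    median upstream).
    """
    inter = {}
    signs_omega, signs_glm = {}, {}
    for cov in omega_results:
        om = omega_results[cov]
        gl = glm_results[cov]
        om_sig = set(om.loc[om["significant"], "snp"].tolist())
        if "q" not in gl or gl["q"].isna().all():
            raise ValueError("GLM results must carry q-values on recalibrated p")
        gl_sig = set(gl.loc[gl["q"] < glm_fdr, "snp"].tolist())
        inter[cov] = om_sig & gl_sig
        signs_omega[cov] = dict(zip(om["snp"], om["effect_sign"]))
        signs_glm[cov] = dict(zip(gl["snp"], gl["effect_sign"]))

    covs = list(omega_results)
    shared = set.intersection(*[inter[c] for c in covs]) if len(covs) > 1 else set()

    out = {}
    for cov in covs:
        kept, n_dir = [], 0
        for snp in sorted(inter[cov] - shared):
            so, sg = signs_omega[cov].get(snp, 0), signs_glm[cov].get(snp, 0)
            if so == 0 or so != sg:
                n_dir += 1
                continue
            if not direction_consistent(pc, snp, groups[cov], so):
                n_dir += 1
                continue
            kept.append(snp)
        out[cov] = CandidateSet(
            covariable=cov, snp_ids=np.array(kept, dtype=int),
            n_intersection=len(inter[cov]),
            n_removed_shared=len(inter[cov] & shared),
            n_removed_direction=n_dir,
        )
    return out
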