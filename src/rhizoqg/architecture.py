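"""MAF-dependent genetic architecture: LD pruning and the BayesS sampler.

The BayesS model is a spike-slab whole-genome regression
y = 1*mu + X beta + e in which a SNP has a non-zero effect with probability
pi and, when non-zero, beta_j ~ N(0, sigma_b^2 * [2 p_j (1-p_j)]^S).  The
sign of S couples effect size to minor allele frequency: S < 0 (larger
effects at rarer alleles) is the signature of purifying selection, S > 0 of
positive selection, S ~ 0 of neutrality.  S is sampled by random-walk
Metropolis on its conditional given the current non-zero effects, with the
step size adapted during burn-in to a 20-40% acceptance rate and then
frozen.  The Gibbs kernel is compiled with numba and is bit-reproducible
under a fixed seed in single-threaded execution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numba
import numpy as np
import pandas as pd

from rhizoqg.io_formats import GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = [
    "BayesSResult",
    "ld_prune",
    "bayess_fit",
    "s_significance",
    "maf_effect_plot_data",
]


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def ld_prune(
    geno: GenotypeMatrix,
    window_kb: float = 100.0,
    step_snps: int = 100,
    r2_max: float = 0.1,
    maf_min: float = 0.01,
) -> GenotypeMatrix:
    """Greedy windowed LD pruning.

    After a MAF filter, windows of ``window_kb`` (advanced by ``step_snps``
    SNPs) are scanned per chromosome; within a window, while any surviving
    pair has r^2 >= ``r2_max`` the lower-MAF SNP of the worst pair is
    removed (ties: the larger position goes).
    """
    keep_maf = geno.snp_map["maf"].to_numpy() >= maf_min
    geno = geno.subset_snps(keep_maf)
    X = geno.imputed()
    sm = geno.snp_map
    removed = np.zeros(geno.n_snps, dtype=bool)
    span = window_kb * 1000.0
    for chrom, sub in sm.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy(float)
        maf = sub["maf"].to_numpy()
        for s in range(0, len(idx), step_snps):
            in_win = np.nonzero((pos >= pos[s]) & (pos - pos[s] <= span))[0]
            in_win = in_win[in_win >= s]
            while True:
                alive = in_win[~removed[idx[in_win]]]
                if len(alive) < 2:
                    break
                sub_X = X[:, idx[alive]]
                with np.errstate(invalid="ignore"):
                    r2 = np.corrcoef(sub_X.T) ** 2
                np.fill_diagonal(r2, 0.0)
                i, j = np.unravel_index(np.nanargmax(r2), r2.shape)
                if not (r2[i, j] >= r2_max):
                    break
                a, b = alive[i], alive[j]
                if maf[a] < maf[b]:
                    victim = a
                elif maf[b] < maf[a]:
                    victim = b
                else:
                    victim = a if pos[a] > pos[b] else b
                removed[idx[victim]] = True
    return geno.subset_snps(~removed)


# ---------------------------------------------------------------------------
# BayesS Gibbs sampler
# ---------------------------------------------------------------------------


@dataclass
class BayesSResult:
    """Posterior summaries and samples from the BayesS sampler."""

    S_mean: float
    S_sd: float
    S_ci: tuple
    pi_mean: float
    pi_ci: tuple
    sigma_b2_mean: float
    sigma_e2_mean: float
    nnz_mean: float
    pip: np.ndarray
    beta_mean: np.ndarray
    samples: dict  # name -> 1-D posterior sample arrays
    acceptance_rate: float
    config: dict = dc_field(default_factory=dict)


@numba.njit(cache=True)
def _bayess_kernel(
    Xt, y, logh, chain_length, burnin, thin,
    pi_a, pi_b, nu, s2b_scale, s2e_scale,
    s_prior_sd, s_bound, rw_step0, seed,
):  # pragma: no cover - exercised through bayess_fit
    np.random.seed(seed)
    m, n = Xt.shape
    c = np.empty(m)
    for j in range(m):
        c[j] = np.dot(Xt[j], Xt[j])

    beta = np.zeros(m)
    mu = 0.0
    e = y.copy()
    sigma_b2 = s2b_scale
    sigma_e2 = s2e_scale
    S = 0.0
    pi = pi_a / (pi_a + pi_b)

    n_keep = (chain_length - burnin) // thin
    out_S = np.empty(n_keep)
    out_pi = np.empty(n_keep)
    out_s2b = np.empty(n_keep)
    out_s2e = np.empty(n_keep)
    out_nnz = np.empty(n_keep)
    pip = np.zeros(m)
    beta_mean = np.zeros(m)

    rw_step = rw_step0
    acc_win = 0
    tries_win = 0
    acc_total = 0
    tries_total = 0
    kept = 0

    for it in range(chain_length):
        # intercept
        for i in range(n):
            e[i] += mu
        ssum = 0.0
        for i in range(n):
            ssum += e[i]
        mu = ssum / n + np.sqrt(sigma_e2 / n) * np.random.normal()
        for i in range(n):
            e[i] -= mu

        # spike-slab per-SNP updates with residual maintenance
        log_pi_odds = np.log(pi) - np.log(1.0 - pi)
        m_nz = 0
        ssq_scaled = 0.0  # sum beta_j^2 / v_j over non-zero
        for j in range(m):
            bj = beta[j]
            r = bj * c[j] + np.dot(Xt[j], e)
            v_j = np.exp(S * logh[j])
            tau = sigma_b2 * v_j
            var0 = sigma_e2 * c[j]
            var1 = tau * c[j] * c[j] + var0
            log_odds = (
                log_pi_odds
                + 0.5 * (np.log(var0) - np.log(var1))
                + 0.5 * r * r * (1.0 / var0 - 1.0 / var1)
            )
            if log_odds > 35.0:
                p_inc = 1.0
            elif log_odds < -35.0:
                p_inc = 0.0
            else:
                p_inc = 1.0 / (1.0 + np.exp(-log_odds))
            if np.random.random() < p_inc:
                denom = c[j] + sigma_e2 / tau
                post_var = sigma_e2 / denom
                post_mean = r / denom
                bnew = post_mean + np.sqrt(post_var) * np.random.normal()
                m_nz += 1
                ssq_scaled += bnew * bnew / v_j
            else:
                bnew = 0.0
            diff = bnew - bj
            if diff != 0.0:
                e -= Xt[j] * diff
                beta[j] = bnew

        # pi (conjugate beta)
        pi = np.random.beta(pi_a + m_nz, pi_b + m - m_nz)
        if pi < 1e-12:
            pi = 1e-12
        if pi > 1.0 - 1e-12:
            pi = 1.0 - 1e-12

        # sigma_b2 (scaled-inv-chi2)
        sigma_b2 = (nu * s2b_scale + ssq_scaled) / np.random.chisquare(nu + m_nz)

        # sigma_e2
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        sigma_e2 = (nu * s2e_scale + sse) / np.random.chisquare(nu + n)

        # S random-walk Metropolis on its conditional given non-zero betas
        S_prop = S + rw_step * np.random.normal()
        tries_win += 1
        tries_total += 1
        if -s_bound <= S_prop <= s_bound:
            ll_cur = -0.5 * S * S / (s_prior_sd * s_prior_sd)
            ll_prop = -0.5 * S_prop * S_prop / (s_prior_sd * s_prior_sd)
            for j in range(m):
                if beta[j] != 0.0:
                    b2 = beta[j] * beta[j] / sigma_b2
                    ll_cur += -0.5 * (S * logh[j] + b2 * np.exp(-S * logh[j]))
                    ll_prop += -0.5 * (S_prop * logh[j] + b2 * np.exp(-S_prop * logh[j]))
            if np.log(np.random.random()) < ll_prop - ll_cur:
                S = S_prop
                acc_win += 1
                acc_total += 1

        # adapt the step during burn-in only, in windows of 100 proposals
        if it < burnin and tries_win >= 100:
            rate = acc_win / tries_win
            if rate > 0.4:
                rw_step *= 1.2
            elif rate < 0.2:
                rw_step *= 0.8
            acc_win = 0
            tries_win = 0
        if it == burnin - 1:
            acc_total = 0
            tries_total = 0

        if it >= burnin and (it - burnin) % thin == 0 and kept < n_keep:
            out_S[kept] = S
            out_pi[kept] = pi
            out_s2b[kept] = sigma_b2
            out_s2e[kept] = sigma_e2
            out_nnz[kept] = m_nz
            for j in range(m):
                if beta[j] != 0.0:
                    pip[j] += 1.0
                    beta_mean[j] += beta[j]
            kept += 1

    for j in range(m):
        if pip[j] > 0:
            beta_mean[j] /= pip[j]
        pip[j] /= kept
    acc_rate = acc_total / tries_total if tries_total > 0 else 0.0
    return out_S, out_pi, out_s2b, out_s2e, out_nnz, pip, beta_mean, acc_rate


def bayess_fit(
    y,
    geno: GenotypeMatrix,
    chain_length: int = 25000,
    burnin: int = 5000,
    thin: int = 10,
    priors: dict | None = None,
    seed: int = 0,
    sample_s: bool = True,
) -> BayesSResult:
    """Fit the BayesS spike-slab model by Gibbs sampling.

    ``y`` holds one value per individual (typically genotype BLUPs);
    dosages are mean-imputed and column-centered internally.  Defaults are
    a desk-scale chain of 25,000 with 5,000 burn-in; longer chains for
    cluster runs go through ``chain_length``/``burnin``.  ``sample_s=False``
    pins S at 0, reducing the model to a standard spike-slab.
    """
    if chain_length <= burnin:
        raise ValueError("chain_length must exceed burnin")
    y = np.asarray(y, float)
    if len(y) != geno.n_individuals:
        raise ValueError("y length must match number of individuals")
    X = geno.imputed()
    X = np.ascontiguousarray((X - X.mean(axis=0)).T)  # (m, n)
    yc = y - y.mean()
    m = geno.n_snps
    p = geno.snp_map["maf"].to_numpy()
    # centering log(2pq) decorrelates S from the slab variance scale; the
    # model is unchanged (the shift is absorbed into sigma_b^2)
    logh = np.log(2.0 * p * (1.0 - p))
    logh = logh - logh.mean()
    vy = float(np.var(yc))
    if vy <= 0:
        raise ValueError("y has zero variance")

    pr = {
        "pi_a": 1.0,
        "pi_b": max(m / 25.0, 1.0),
        "nu": 4.0,
        "s_prior_sd": 1.0,
        "s_bound": 5.0,
        "rw_step": 0.3,
    }
    if priors:
        pr.update(priors)
    exp_nnz = m * pr["pi_a"] / (pr["pi_a"] + pr["pi_b"])
    s2b_scale = 0.5 * vy / max(exp_nnz * float(np.mean(np.exp(logh))), 1e-12)
    s2e_scale = 0.5 * vy

    out = _bayess_kernel(
        X, yc, logh, int(chain_length), int(burnin), int(thin),
        float(pr["pi_a"]), float(pr["pi_b"]), float(pr["nu"]),
        float(s2b_scale), float(s2e_scale),
        float(pr["s_prior_sd"]), float(pr["s_bound"]) if sample_s else 0.0,
        float(pr["rw_step"]) if sample_s else 0.0,
        int(seed) % (2 ** 31 - 1),
    )
    S_s, pi_s, s2b_s, s2e_s, nnz_s, pip, beta_mean, acc = out
    if not np.isfinite(S_s).all() or not np.isfinite(s2e_s).all():
        raise RuntimeError(f"non-finite sampler state; last draws: S={S_s[-5:]}, "
                           f"sigma_e2={s2e_s[-5:]}")
    ci = tuple(np.percentile(S_s, [2.5, 97.5]))
    result = BayesSResult(
        S_mean=float(S_s.mean()), S_sd=float(S_s.std()), S_ci=ci,
        pi_mean=float(pi_s.mean()), pi_ci=tuple(np.percentile(pi_s, [2.5, 97.5])),
        sigma_b2_mean=float(s2b_s.mean()), sigma_e2_mean=float(s2e_s.mean()),
        nnz_mean=float(nnz_s.mean()), pip=pip, beta_mean=beta_mean,
        samples={"S": S_s, "pi": pi_s, "sigma_b2": s2b_s,
                 "sigma_e2": s2e_s, "nnz": nnz_s},
        acceptance_rate=float(acc),
        config={"chain_length": chain_length, "burnin": burnin, "thin": thin,
                "seed": seed, "priors": pr, "sample_s": sample_s},
    )
    log.info("BayesS: S=%.3f (%.3f, %.3f), nnz=%.1f, S-acceptance=%.2f",
             result.S_mean, ci[0], ci[1], result.nnz_mean, acc)
    return result


def s_significance(result: BayesSResult, level: float = 0.95) -> str:
    """Classify the selection signature from the posterior of S.

    'purifying' if the credible interval lies entirely below 0, 'positive'
    if entirely above, else 'neutral'.
    """
    lo, hi = np.percentile(result.samples["S"], [50 * (1 - level), 50 * (1 + level)])
    if hi < 0:
        return "purifying"
    if lo > 0:
        return "positive"
    return "neutral"


def maf_effect_plot_data(
    result: BayesSResult, geno: GenotypeMatrix, pip_min: float = 0.5
) -> pd.DataFrame:
    """Per-SNP (maf, |effect|, allele-1 frequency) for SNPs with posterior
    inclusion probability >= ``pip_min``, plus a frequency-skew statistic.

    Allele 1 is the major allele (frequency 1 - maf); purifying selection
    (effects at low MAF) shows up as negative skew of the allele-1
    frequency among the retained SNPs.
    """
    from scipy.stats import skew

    keep = result.pip >= pip_min
    maf = geno.snp_map["maf"].to_numpy()[keep]
    df = pd.DataFrame({
        "snp": geno.snp_map.index[keep],
        "maf": maf,
        "abs_effect": np.abs(result.beta_mean[keep]),
        "allele1_freq": 1.0 - maf,
        "pip": result.pip[keep],
    })
    if len(df) == 0:
        log.warning("no SNPs pass pip >= %g", pip_min)
        df.attrs["freq_skew"] = np.nan
    else:
        df.attrs["freq_skew"] = float(skew(df["allele1_freq"])) if len(df) > 2 else np.nan
    return df
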