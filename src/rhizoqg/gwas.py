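"""Linear-mixed-model GWAS, effective-SNP Bonferroni thresholds, MAPL
hotspot windows, gene annotation and allele stratification.

The association scan uses the P3D/EMMAX approximation by default: the
kinship matrix is eigendecomposed once, the variance ratio
delta = sigma_e^2 / sigma_g^2 is estimated by REML under the null model
(intercept + principal components) and then fixed for every per-SNP
generalized-least-squares Wald test.  An exact mode that re-optimizes delta
per SNP is available for cross-checking.  Significant SNP-trait
associations are tallied into fixed, non-overlapping 10-kb genomic windows;
windows with at least ``min_signals`` associations are the reported
microbe-associated plant loci (MAPLs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from rhizoqg.io_formats import GeneAnnotation, GenotypeMatrix
from rhizoqg.mixed_models import KinshipMatrix

log = logging.getLogger(__name__)

__all__ = [
    "GwasResult",
    "lmm_gwas",
    "effective_snp_number",
    "significance_threshold",
    "call_mapls",
    "annotate_genes",
    "allele_stratified_comparison",
    "ld_r2_matrix",
]


@dataclass
class GwasResult:
    trait: str
    treatment: str
    table: pd.DataFrame  # snp, chrom, pos, beta, se, neglog10p
    delta: float
    lambda_gc: float
    n_skipped: int = 0


def _null_delta(yt: np.ndarray, Ct: np.ndarray, xi: np.ndarray) -> float:
    """REML estimate of delta = sigma_e^2/sigma_g^2 on the rotated data."""
    n, p = Ct.shape

    def neg2_reml(log_delta: float) -> float:
        d = xi + np.exp(log_delta)
        w = 1.0 / d
        CtW = Ct * w[:, None]
        A = CtW.T @ Ct
        b = CtW.T @ yt
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return 1e12
        r = yt - Ct @ beta
        ypy = float(np.sum(w * r * r))
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0 or ypy <= 0:
            return 1e12
        return (n - p) * np.log(ypy / (n - p)) + float(np.sum(np.log(d))) + logdetA

    grid = np.linspace(-8.0, 8.0, 49)
    vals = [neg2_reml(g) for g in grid]
    k = int(np.argmin(vals))
    lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg2_reml, bounds=(lo, hi), method="bounded")
    return float(np.exp(res.x))


def lmm_gwas(
    y: pd.Series,
    geno: GenotypeMatrix,
    K: KinshipMatrix,
    n_pcs: int = 3,
    mode: str = "p3d",
    trait: str = "trait",
    treatment: str = "",
) -> GwasResult:
    """Mixed-model association scan of one trait against all SNPs.

    ``y`` holds one value per individual (BLUPs), indexed by individual id;
    covariates are an intercept plus the top ``n_pcs`` principal components
    of the kinship matrix.  ``mode='p3d'`` fixes the null-model variance
    ratio for all SNPs; ``mode='exact'`` re-optimizes it per SNP.
    """
    ids = pd.Index(y.index)
    if not ids.equals(geno.individual_ids) or not ids.equals(K.values.index):
        geno = geno.subset_individuals(ids)
        K = KinshipMatrix(K.values.loc[ids, ids], K.method)
    yv = y.to_numpy(float)
    n = len(yv)

    Kv = (K.values.to_numpy() + K.values.to_numpy().T) / 2.0
    xi, U = np.linalg.eigh(Kv)
    if xi.min() < 1e-8:
        n_clip = int((xi < 1e-8).sum())
        if xi.min() < -1e-8:
            log.warning("clipping %d kinship eigenvalues at 1e-8", n_clip)
        xi = np.maximum(xi, 1e-8)
    order = np.argsort(xi)[::-1]
    xi, U = xi[order], U[:, order]

    C = np.ones((n, 1))
    if n_pcs > 0:
        pcs = U[:, :n_pcs] * np.sqrt(xi[:n_pcs])
        C = np.hstack([C, pcs])
    yt = U.T @ yv
    Ct = U.T @ C

    X = geno.imputed()
    sd = X.std(axis=0)
    mono = sd == 0
    n_skipped = int(mono.sum())
    Gt = U.T @ X

    delta = _null_delta(yt, Ct, xi)
    sm = geno.snp_map
    p_cov = Ct.shape[1]
    df = n - p_cov - 1

    if mode == "p3d":
        w = 1.0 / (xi + delta)
        sw = np.sqrt(w)
        ys = sw * yt
        Cs = Ct * sw[:, None]
        Gs = Gt * sw[:, None]
        Q, _ = np.linalg.qr(Cs)
        ry = ys - Q @ (Q.T @ ys)
        RG = Gs - Q @ (Q.T @ Gs)
        gg = np.sum(RG * RG, axis=0)
        gy = RG.T @ ry
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = gy / gg
            rss = float(ry @ ry) - beta * gy
            sigma2 = rss / df
            se = np.sqrt(sigma2 / gg)
            tstat = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
        beta[mono] = np.nan
        se[mono] = np.nan
        pvals[mono] = np.nan
        deltas = np.full(len(sm), delta)
    elif mode == "exact":
        beta = np.full(len(sm), np.nan)
        se = np.full(len(sm), np.nan)
        pvals = np.full(len(sm), np.nan)
        deltas = np.full(len(sm), np.nan)
        for j in range(len(sm)):
            if mono[j]:
                continue
            Cj = np.hstack([Ct, Gt[:, j:j + 1]])
            dj = _null_delta(yt, Cj, xi)
            w = 1.0 / (xi + dj)
            CW = Cj * w[:, None]
            A = CW.T @ Cj
            b = CW.T @ yt
            coef = np.linalg.solve(A, b)
            r = yt - Cj @ coef
            sigma2 = float(np.sum(w * r * r)) / df
            cov = np.linalg.inv(A) * sigma2
            beta[j] = coef[-1]
            se[j] = np.sqrt(cov[-1, -1])
            tj = beta[j] / se[j]
            pvals[j] = 2.0 * stats.t.sf(abs(tj), df)
            deltas[j] = dj
    else:
        raise ValueError(f"unknown mode {mode!r}")

    chi2 = stats.chi2.isf(pvals[~np.isnan(pvals)], 1)
    lam = float(np.median(chi2) / stats.chi2.isf(0.5, 1)) if len(chi2) else np.nan
    with np.errstate(divide="ignore"):
        neglog = -np.log10(np.maximum(pvals, 1e-300))
    table = pd.DataFrame({
        "snp": sm.index,
        "chrom": sm["chrom"].to_numpy(),
        "pos": sm["pos"].to_numpy(),
        "maf": sm["maf"].to_numpy(),
        "beta": beta,
        "se": se,
        "p": pvals,
        "neglog10p": neglog,
    })
    return GwasResult(trait=trait, treatment=treatment, table=table,
                      delta=delta, lambda_gc=lam, n_skipped=n_skipped)


def effective_snp_number(
    geno: GenotypeMatrix | None,
    method: str = "liji",
    block_size: int = 200,
    meff: int | None = None,
) -> float:
    """Effective number of independent SNPs for Bonferroni correction.

    ``liji`` sums, chromosome-wise over blocks of ``block_size`` SNPs, the
    Li & Ji eigenvalue summary f(lam) = I(lam >= 1) + (lam - floor(lam)) of
    the SNP correlation matrix.  ``user_supplied`` passes ``meff`` through.
    """
    if method == "user_supplied":
        if meff is None:
            raise ValueError("user_supplied requires meff")
        return float(meff)
    if method != "liji":
        raise ValueError(f"unknown method {method!r}")
    X = geno.imputed()
    total = 0.0
    for _, sub in geno.snp_map.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        for s in range(0, len(idx), block_size):
            block = idx[s:s + block_size]
            if len(block) == 1:
                total += 1.0
                continue
            R = np.corrcoef(X[:, block].T)
            # rounding keeps numerically-integer eigenvalues (duplicate
            # SNPs give exactly 2) on the right side of the floor
            lam = np.round(np.abs(np.linalg.eigvalsh(R)), 8)
            total += float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))
    return total


def significance_threshold(alpha: float = 0.05, meff: float = 1.0) -> float:
    """-log10(alpha / Meff) genome-wide significance threshold."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if meff < 1:
        raise ValueError("meff must be >= 1")
    return float(-np.log10(alpha / meff))


def call_mapls(
    gwas_results,
    window_bp: int = 10000,
    threshold: float = 7.2,
    min_signals: int = 1,
) -> pd.DataFrame:
    """Tally significant SNP-trait associations into fixed genomic windows.

    Windows are non-overlapping, 0-based half-open
    [k*window_bp, (k+1)*window_bp) anchored at 0 per chromosome; each
    significant SNP-trait-treatment association contributes one signal
    (the same SNP significant for two traits counts twice).  Windows with
    signal count >= ``min_signals`` are returned; the output is invariant
    to the order of the supplied results.
    """
    hits = []
    for res in gwas_results:
        t = res.table
        sig = t[t["neglog10p"] >= threshold]
        for _, r in sig.iterrows():
            hits.append((str(r["chrom"]), int(r["pos"]), res.trait, res.treatment))
    cols = ["chrom", "window", "start", "end", "n_signals", "traits", "treatments"]
    if not hits:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(hits, columns=["chrom", "pos", "trait", "treatment"])
    df["window"] = df["pos"] // window_bp
    rows = []
    for (chrom, win), sub in df.groupby(["chrom", "window"]):
        rows.append({
            "chrom": chrom,
            "window": int(win),
            "start": int(win) * window_bp,
            "end": (int(win) + 1) * window_bp,
            "n_signals": len(sub),
            "traits": ";".join(sorted(sub["trait"].unique())),
            "treatments": ";".join(sorted({str(t) for t in sub["treatment"]})),
        })
    out = pd.DataFrame(rows, columns=cols)
    out = out[out["n_signals"] >= min_signals]
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def annotate_genes(
    mapls: pd.DataFrame, annotation: GeneAnnotation, flank: int = 10000
) -> pd.DataFrame:
    """Attach genes whose transcribed span is completely contained within
    +/- ``flank`` of each MAPL window; partial overlaps are excluded."""
    genes = annotation.genes
    if len(mapls) and not set(mapls["chrom"]).intersection(set(genes["chrom"])):
        log.warning(
            "no shared chromosome names between MAPLs (%s) and annotation (%s)",
            sorted(set(mapls["chrom"]))[:5], sorted(set(genes["chrom"]))[:5],
        )
    out = mapls.copy()
    gene_lists, n_genes = [], []
    for _, r in mapls.iterrows():
        lo = r["start"] - flank + 1  # 1-based inclusive bounds of the flanked window
        hi = r["end"] + flank
        hit = genes[
            (genes["chrom"] == r["chrom"])
            & (genes["start"] >= lo)
            & (genes["end"] <= hi)
        ]
        gene_lists.append(";".join(hit["gene_id"]))
        n_genes.append(len(hit))
    out["genes"] = gene_lists
    out["n_genes"] = n_genes
    return out


def allele_stratified_comparison(
    geno: GenotypeMatrix,
    snp_index: int,
    values: pd.DataFrame | pd.Series,
    het_policy: str = "minor",
) -> pd.DataFrame:
    """Compare trait values between genotypes carrying the major vs the
    minor allele at one SNP (Welch t-test).

    ``values`` holds one row per genotype (id-indexed).  Heterozygotes join
    the minor-carrier group by default (inbred panels have few hets); set
    ``het_policy='major'`` to flip.  Groups with < 3 genotypes report means
    but a suppressed p.
    """
    if isinstance(values, pd.Series):
        values = values.to_frame()
    dos = pd.Series(geno.imputed()[:, snp_index], index=geno.individual_ids)
    dos = dos.loc[values.index]
    if dos.nunique() < 2:
        raise ValueError("monomorphic SNP in the analyzed genotypes")
    cutoff = 0.5 if het_policy == "minor" else 1.5
    is_minor = dos > cutoff
    rows = []
    for col in values.columns:
        a = values.loc[~is_minor, col].dropna()  # major group
        b = values.loc[is_minor, col].dropna()
        if len(a) >= 3 and len(b) >= 3:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        else:
            t, p = np.nan, np.nan
        rows.append({
            "variable": col,
            "mean_major": a.mean(), "mean_minor": b.mean(),
            "n_major": len(a), "n_minor": len(b),
            "t": t, "p": p,
        })
    return pd.DataFrame(rows).set_index("variable")


def ld_r2_matrix(geno: GenotypeMatrix, chrom=None, start=None, end=None) -> pd.DataFrame:
    """Pairwise r^2 between SNPs (optionally within a region) for plotting."""
    sm = geno.snp_map
    mask = np.ones(len(sm), dtype=bool)
    if chrom is not None:
        mask &= (sm["chrom"] == str(chrom)).to_numpy()
    if start is not None:
        mask &= (sm["pos"] >= start).to_numpy()
    if end is not None:
        mask &= (sm["pos"] <= end).to_numpy()
    X = geno.imputed()[:, mask]
    r2 = np.corrcoef(X.T) ** 2
    labels = sm.loc[mask, "pos"].to_numpy()
    return pd.DataFrame(r2, index=labels, columns=labels)
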