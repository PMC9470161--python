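"""REML variance components, heritability, BLUPs, kinship and genotype PCA.

The heritability statistic is the repeatability-style line-mean form
h2 = Vg / (Vg + Ve/n) with n the number of samples per genotype-treatment
(6 in the emulated design: 2 replicate plots x 3 samples per plot), with a
permutation null built by shuffling genotype labels.  The one-way REML fit
uses the balanced closed form (identical to the ANOVA estimator truncated
at the boundary) when group sizes are equal and a profiled numerical
optimum otherwise; multi-term models (the BLUP model with genotype, block,
split plot and split-plot block) are fitted by REML on the equivalent
low-dimensional system obtained via the Woodbury identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import optimize

from rhizoqg.io_formats import GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = [
    "HeritabilityResult",
    "BlupTable",
    "KinshipMatrix",
    "fit_variance_components",
    "heritability",
    "permutation_heritability",
    "fit_blup",
    "grm",
    "genotype_pca",
    "heritability_table",
]


@dataclass
class HeritabilityResult:
    trait: str
    treatment: str
    Vg: float
    Ve: float
    n: int
    h2: float
    p: float | None = None
    B: int | None = None


@dataclass
class BlupTable:
    """Genotype BLUPs plus the variance components of the fitted model."""

    blups: pd.Series  # indexed by genotype
    components: dict  # term name -> variance
    fixed_intercept: float


@dataclass
class KinshipMatrix:
    values: pd.DataFrame  # genotype x genotype
    method: str = "vanraden"

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.allclose(arr, arr.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")
        w = np.linalg.eigvalsh((arr + arr.T) / 2)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise ValueError("kinship matrix not PSD within tolerance")


# ---------------------------------------------------------------------------
# REML engines
# ---------------------------------------------------------------------------


def _reml_oneway(y: np.ndarray, codes: np.ndarray) -> tuple[float, float]:
    """REML (Vg, Ve) for y = mu + genotype + e, variances constrained >= 0.

    Balanced designs use the exact closed form (ANOVA estimator with
    boundary truncation, which coincides with REML); unbalanced designs
    fall back to a profiled 1-D optimization over the variance ratio.
    """
    y = np.asarray(y, float)
    n_tot = len(y)
    n_grp = codes.max() + 1
    counts = np.bincount(codes, minlength=n_grp).astype(float)
    sums = np.bincount(codes, weights=y, minlength=n_grp)
    means = sums / counts
    ssw = float(np.sum(y * y) - np.sum(sums * means))
    gm = y.mean()
    ssb = float(np.sum(counts * (means - gm) ** 2))
    if ssw + ssb <= 1e-300:
        return 0.0, 0.0

    if np.all(counts == counts[0]):
        n = counts[0]
        msw = ssw / (n_tot - n_grp)
        msb = ssb / (n_grp - 1)
        if msb >= msw:
            return (msb - msw) / n, msw
        return 0.0, (ssw + ssb) / (n_tot - 1)

    # unbalanced: profile Ve out, optimize the ratio gamma = Vg/Ve
    def neg2_reml(log_gamma: float) -> float:
        g = np.exp(log_gamma)
        d = 1.0 + g * counts  # per-group |I + g J| factor; V = Ve*(I + g ZZ')
        # y'V0^-1 y etc. with V0 = I + g ZZ'
        yv_y = np.sum(y * y) - np.sum(g * counts ** 2 * means ** 2 / d)
        ov_o = np.sum(counts / d)
        ov_y = np.sum(counts * means / d)
        ypy = yv_y - ov_y ** 2 / ov_o
        ve = ypy / (n_tot - 1)
        logdet = float(np.sum(np.log(d)))
        return (n_tot - 1) * np.log(ve) + logdet + np.log(ov_o)

    res = optimize.minimize_scalar(neg2_reml, bounds=(-12.0, 12.0), method="bounded")
    g = float(np.exp(res.x))
    # boundary check against gamma = 0
    if neg2_reml(-30.0) <= res.fun + 1e-10:
        return 0.0, (ssw + ssb) / (n_tot - 1)
    d = 1.0 + g * counts
    yv_y = np.sum(y * y) - np.sum(g * counts ** 2 * means ** 2 / d)
    ov_o = np.sum(counts / d)
    ov_y = np.sum(counts * means / d)
    ve = (yv_y - ov_y ** 2 / ov_o) / (n_tot - 1)
    return g * ve, ve


class _MultiTermREML:
    """REML for y = 1*mu + sum_k Z_k u_k + e via q x q Woodbury algebra."""

    def __init__(self, y: np.ndarray, term_codes: dict[str, np.ndarray]):
        self.y = np.asarray(y, float)
        self.n = len(self.y)
        self.names = list(term_codes)
        self.sizes = []
        cols = []
        for name in self.names:
            codes = np.asarray(term_codes[name])
            q_k = codes.max() + 1
            Z = np.zeros((self.n, q_k))
            Z[np.arange(self.n), codes] = 1.0
            cols.append(Z)
            self.sizes.append(q_k)
        self.Z = np.hstack(cols)
        self.q = self.Z.shape[1]
        self.ZtZ = self.Z.T @ self.Z
        self.Zty = self.Z.T @ self.y
        self.Zt1 = self.Z.sum(axis=0)
        self.yty = float(self.y @ self.y)
        self.oty = float(self.y.sum())

    def _gamma(self, sigmas: np.ndarray, sigma_e: float) -> np.ndarray:
        # floor keeps 1/gamma finite when a component collapses to zero
        return np.maximum(np.repeat(sigmas, self.sizes) / sigma_e, 1e-300)

    def neg2_reml(self, log_params: np.ndarray) -> float:
        from scipy.linalg import solve_triangular

        sig = np.exp(log_params)
        sigmas, sigma_e = sig[:-1], sig[-1]
        gam = self._gamma(sigmas, sigma_e)
        A = self.ZtZ + np.diag(1.0 / gam)
        try:
            L = np.linalg.cholesky(A)
        except np.linalg.LinAlgError:
            return 1e12
        logdetA = 2.0 * np.sum(np.log(np.diag(L)))
        logdetV = self.n * np.log(sigma_e) + logdetA + np.sum(np.log(gam))

        S = solve_triangular(
            L, np.column_stack([self.Zty, self.Zt1]), lower=True,
            check_finite=False,
        )
        yvy = (self.yty - S[:, 0] @ S[:, 0]) / sigma_e
        ovo = (self.n - S[:, 1] @ S[:, 1]) / sigma_e
        ovy = (self.oty - S[:, 0] @ S[:, 1]) / sigma_e
        if ovo <= 0:
            return 1e12
        ypy = yvy - ovy ** 2 / ovo
        return logdetV + np.log(ovo) + ypy

    def fit(self, max_iter: int = 2000, x0: np.ndarray | None = None):
        vy = max(self.y.var(), 1e-12)
        k = len(self.names)
        if x0 is None:
            x0 = np.log(np.full(k + 1, vy / (k + 1)))
        res = optimize.minimize(
            self.neg2_reml, x0, method="Nelder-Mead",
            options={"maxiter": max_iter, "xatol": 1e-8, "fatol": 1e-10},
        )
        if not res.success and res.fun >= 1e12:
            raise RuntimeError(f"REML did not converge: {res.message}\n{res}")
        sig = np.exp(res.x)
        floor = 1e-8 * vy
        comps = {name: (0.0 if s < floor else float(s))
                 for name, s in zip(self.names, sig[:-1])}
        sigma_e = float(sig[-1])
        return comps, sigma_e, res

    def blups(self, comps: dict, sigma_e: float) -> tuple[dict[str, np.ndarray], float]:
        sigmas = np.array([comps[n] for n in self.names])
        gam = self._gamma(np.maximum(sigmas, 1e-12), sigma_e)
        A = self.ZtZ + np.diag(1.0 / gam)
        Ainv = np.linalg.inv(A)
        # GLS intercept
        def vinv_vec(za, a_minus):  # returns V^-1 a given Z'a and raw a
            return (a_minus - self.Z @ (Ainv @ za)) / sigma_e
        v1 = vinv_vec(self.Zt1, np.ones(self.n))
        vy = vinv_vec(self.Zty, self.y)
        mu = float(self.y @ v1) / float(np.ones(self.n) @ v1)
        r = self.y - mu
        u = Ainv @ (self.Z.T @ r)
        out, off = {}, 0
        for name, q_k, s in zip(self.names, self.sizes, sigmas):
            out[name] = u[off:off + q_k] if s > 0 else np.zeros(q_k)
            off += q_k
        return out, mu


def fit_variance_components(y, genotype, extra_random: dict | None = None):
    """REML variance components for a random-intercept model.

    With no extra terms fits y = mu + genotype + e and returns
    ``(Vg, Ve, {})``; with ``extra_random`` (mapping term name -> labels)
    fits the multi-term model and returns ``(Vg, Ve, extras)``.  All
    variance estimates are constrained to be non-negative.
    """
    y = np.asarray(y, float)
    codes, levels = pd.factorize(pd.Series(genotype))
    if len(levels) < 2:
        raise ValueError("need >= 2 genotypes")
    if np.bincount(codes).max() < 2:
        raise ValueError("need >= 2 observations for at least one genotype")
    if not extra_random:
        vg, ve = _reml_oneway(y, codes)
        return float(vg), float(ve), {}
    terms = {"genotype": codes}
    for name, labels in extra_random.items():
        terms[name] = pd.factorize(pd.Series(labels))[0]
    eng = _MultiTermREML(y, terms)
    comps, sigma_e, _ = eng.fit()
    extras = {k: v for k, v in comps.items() if k != "genotype"}
    return float(comps["genotype"]), float(sigma_e), extras


def heritability(Vg: float, Ve: float, n: int = 6) -> float:
    """h2 = Vg / (Vg + Ve/n); 0 when Vg = Ve = 0."""
    if Vg < 0 or Ve < 0:
        raise ValueError("variance components must be non-negative")
    denom = Vg + Ve / n
    return 0.0 if denom == 0 else Vg / denom


def permutation_heritability(
    y, genotype, B: int = 1000, seed: int = 0, n: int = 6
) -> tuple[float, float]:
    """Permutation p-value for h2 by shuffling genotype labels.

    Returns (h2_observed, p) with p = (#{h2_perm >= h2_obs} + 1) / (B + 1).
    """
    if B < 99:
        log.warning("B=%d gives coarse permutation p resolution", B)
    y = np.asarray(y, float)
    codes, _ = pd.factorize(pd.Series(genotype))
    vg, ve = _reml_oneway(y, codes)
    h_obs = heritability(vg, ve, n=n)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(B):
        yp = rng.permutation(y)
        vg_p, ve_p = _reml_oneway(yp, codes)
        if heritability(vg_p, ve_p, n=n) >= h_obs - 1e-12:
            count += 1
    return h_obs, (count + 1) / (B + 1)


def fit_blup(y, design: pd.DataFrame, x0: np.ndarray | None = None) -> BlupTable:
    """BLUPs from y ~ (1|genotype) + (1|block) + (1|split_plot) +
    (1|split_plot_block) + error, fitted by REML.

    ``design`` must carry the four design columns aligned with ``y``.
    Raises on a design where a factor aliases genotype.
    """
    required = ("genotype", "block", "split_plot", "split_plot_block")
    missing = [c for c in required if c not in design.columns]
    if missing:
        raise ValueError(f"design missing columns: {missing}")
    geno = design["genotype"]
    if geno.nunique() < 2:
        raise ValueError("need >= 2 genotypes")
    for col in required[1:]:
        pairs = design[["genotype", col]].drop_duplicates()
        if (
            len(pairs) == geno.nunique()
            and design[col].nunique() == geno.nunique()
        ):
            raise ValueError(f"factor {col!r} aliases genotype")
    y = np.asarray(y, float)
    terms = {c: pd.factorize(design[c])[0] for c in required}
    eng = _MultiTermREML(y, terms)
    comps, sigma_e, res = eng.fit(x0=x0)
    u, mu = eng.blups(comps, sigma_e)
    levels = pd.factorize(design["genotype"])[1]
    blups = pd.Series(u["genotype"], index=levels, name="blup").sort_index()
    comps["error"] = sigma_e
    bt = BlupTable(blups=blups, components=comps, fixed_intercept=mu)
    bt.opt_x = res.x  # warm start for the next trait on the same design
    return bt


# ---------------------------------------------------------------------------
# kinship and PCA
# ---------------------------------------------------------------------------


def grm(geno: GenotypeMatrix) -> KinshipMatrix:
    """Centered (VanRaden) genomic relationship matrix.

    K = W W' / (2 * sum_j p_j (1 - p_j)) with W the column-centered
    (mean-imputed) dosage matrix; mean diagonal ~ 1 under HWE.
    """
    X = geno.imputed()
    p = X.mean(axis=0) / 2.0
    W = X - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    K = W @ W.T / denom
    df = pd.DataFrame(K, index=geno.individual_ids, columns=geno.individual_ids)
    return KinshipMatrix(values=df, method="vanraden")


def genotype_pca(geno: GenotypeMatrix, k: int = 3) -> pd.DataFrame:
    """Top-k genotype principal components (eigenvectors of the GRM scaled
    by sqrt(eigenvalue))."""
    n = geno.n_individuals
    if k > n - 1:
        raise ValueError(f"k={k} exceeds n-1={n - 1}")
    K = grm(geno).values.to_numpy()
    eigval, eigvec = np.linalg.eigh(K)
    order = np.argsort(eigval)[::-1][:k]
    pcs = eigvec[:, order] * np.sqrt(np.maximum(eigval[order], 0.0))
    return pd.DataFrame(
        pcs, index=geno.individual_ids, columns=[f"PC{i + 1}" for i in range(k)]
    )


# ---------------------------------------------------------------------------
# per-trait driver
# ---------------------------------------------------------------------------


def heritability_table(
    values: pd.DataFrame,
    sample_meta: pd.DataFrame,
    n: int = 6,
    B: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-trait, per-treatment heritability with permutation p-values.

    ``values`` is a samples x traits matrix; rows are matched to
    ``sample_meta`` (genotype, treatment).
    """
    rng = np.random.default_rng(seed)
    meta = sample_meta.loc[values.index]
    rows = []
    for treatment, idx in meta.groupby("treatment").groups.items():
        sub = values.loc[idx]
        geno = meta.loc[idx, "genotype"]
        for trait in sub.columns:
            y = sub[trait].to_numpy(float)
            codes, _ = pd.factorize(geno)
            vg, ve = _reml_oneway(y, codes)
            h2 = heritability(vg, ve, n=n)
            _, p = permutation_heritability(
                y, geno, B=B, seed=int(rng.integers(2 ** 31 - 1)), n=n
            )
            rows.append({
                "trait": trait, "treatment": treatment,
                "Vg": vg, "Ve": ve, "n": n, "h2": h2, "p": p, "B": B,
            })
    return pd.DataFrame(rows)
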