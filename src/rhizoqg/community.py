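"""Community-level analyses: dissimilarity, ordination, PERMANOVA.

Bray-Curtis and weighted UniFrac dissimilarities are computed on relative
abundances (UniFrac through scikit-bio against a supplied tree).  PCoA is
classical metric MDS by double centering; negative eigenvalues are reported
uncorrected.  CAP is distance-based RDA: PCoA coordinates regressed on the
design factors, with the fitted values eigen-decomposed into constrained
axes.  PERMANOVA uses Anderson's pseudo-F with seeded label permutations
(optionally within strata, or full enumeration on tiny designs).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from rhizoqg.io_formats import AsvCountTable

log = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "bray_curtis",
    "weighted_unifrac",
    "pcoa",
    "cap",
    "permanova",
]


@dataclass
class DistanceMatrix:
    """Symmetric sample dissimilarity matrix with its metric name."""

    data: pd.DataFrame
    metric: str

    def __post_init__(self) -> None:
        arr = self.data.to_numpy(float)
        if arr.shape[0] != arr.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(arr, arr.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(arr)).max() > 1e-12:
            raise ValueError("distance matrix diagonal must be zero")
        if arr.min() < -1e-12:
            raise ValueError("distances must be non-negative")

    @property
    def ids(self) -> pd.Index:
        return self.data.index

    def values(self) -> np.ndarray:
        return self.data.to_numpy(float)


def bray_curtis(table: AsvCountTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on relative abundances."""
    from scipy.spatial.distance import pdist, squareform

    rel = table.relative_abundance().fillna(0.0)
    d = squareform(pdist(rel.to_numpy(), metric="braycurtis"))
    return DistanceMatrix(pd.DataFrame(d, index=rel.index, columns=rel.index), "braycurtis")


def weighted_unifrac(table: AsvCountTable, tree, normalized: bool = True) -> DistanceMatrix:
    """Weighted (by default normalized) UniFrac against a phylogenetic tree.

    ``tree`` is an skbio TreeNode (or a path to / string of newick).  Every
    ASV in the table must be a tip of the tree.
    """
    import skbio
    from skbio.diversity import beta_diversity

    if not isinstance(tree, skbio.TreeNode):
        tree = skbio.TreeNode.read(str(tree)) if hasattr(tree, "read") or isinstance(tree, str) else tree
    tips = {t.name for t in tree.tips()}
    missing = [a for a in table.asv_ids if a not in tips]
    if missing:
        raise ValueError(f"ASVs absent from tree: {missing[:10]}")
    # skbio works on integer counts and converts to relative abundance
    # internally (it truncates float input)
    counts = table.counts
    dm = beta_diversity(
        "weighted_unifrac", counts.to_numpy(), ids=list(counts.index),
        taxa=list(counts.columns), tree=tree, normalized=normalized,
    )
    return DistanceMatrix(dm.to_data_frame(), "weighted_unifrac")


def pcoa(dist: DistanceMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal coordinates by double centering.

    Returns (coordinates from the non-negative eigenvalues, all eigenvalues
    in decreasing order including negative ones).  Satisfies the Gower
    identity: sum of eigenvalues equals the total centered squared-distance
    sum / n.
    """
    D = dist.values()
    n = D.shape[0]
    A = -0.5 * D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-10
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=dist.ids, columns=cols), eigval


def _design_matrix(factors: pd.DataFrame) -> np.ndarray:
    mats = [np.ones((len(factors), 1))]
    for col in factors.columns:
        d = pd.get_dummies(factors[col].astype("category"), drop_first=True)
        mats.append(d.to_numpy(float))
    return np.hstack(mats)


def cap(
    dist: DistanceMatrix,
    factors: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Constrained ordination (distance-based RDA) on design factors.

    PCoA coordinates are regressed on the one-hot design; constrained axes
    are the principal axes of the fitted values, residual axes those of the
    residuals.  Per-factor significance is a PERMANOVA on the same distance
    matrix.  Returns a dict with constrained coordinates, eigenvalues,
    residual eigenvalues, and a per-factor table (pseudo-F, p).
    """
    factors = factors.loc[dist.ids]
    Y, _ = pcoa(dist)
    Yv = Y.to_numpy()
    M = _design_matrix(factors)
    coef, *_ = np.linalg.lstsq(M, Yv, rcond=None)
    fitted = M @ coef
    fitted -= fitted.mean(axis=0)
    resid = Yv - M @ coef

    def _axes(Z, prefix):
        u, s, vt = np.linalg.svd(Z, full_matrices=False)
        eig = s ** 2 / 1.0
        keep = eig > 1e-10
        axes = u[:, keep] * s[keep]
        cols = [f"{prefix}{i + 1}" for i in range(axes.shape[1])]
        return pd.DataFrame(axes, index=dist.ids, columns=cols), eig[keep]

    cap_coords, cap_eig = _axes(fitted, "CAP")
    _, res_eig = _axes(resid - resid.mean(axis=0), "MDS")

    rows = []
    for col in factors.columns:
        res = permanova(dist, factors[col], n_perm=n_perm, seed=seed)
        rows.append({"factor": col, "pseudo_F": res["F"], "p": res["p"]})
    return {
        "coordinates": cap_coords,
        "eigenvalues": cap_eig,
        "residual_eigenvalues": res_eig,
        "factor_tests": pd.DataFrame(rows).set_index("factor"),
    }


def _pseudo_f(D2: np.ndarray, codes: np.ndarray, n_levels: int) -> float:
    """Anderson's pseudo-F from squared distances and integer group codes."""
    n = D2.shape[0]
    sst = D2.sum() / (2.0 * n)
    ssw = 0.0
    for g in range(n_levels):
        idx = np.nonzero(codes == g)[0]
        if len(idx) < 1:
            continue
        ssw += D2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ssa = sst - ssw
    df_a, df_w = n_levels - 1, n - n_levels
    if ssw <= 1e-300:
        raise ValueError("zero within-group variation; pseudo-F undefined")
    return (ssa / df_a) / (ssw / df_w)


def permanova(
    dist: DistanceMatrix,
    factor: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
    strata: pd.Series | None = None,
    exhaustive: bool = False,
) -> dict:
    """PERMANOVA of one factor on a distance matrix.

    p = (#{F_perm >= F_obs} + 1) / (n_perm + 1), permuting factor labels
    (within strata when given).  ``exhaustive=True`` enumerates all distinct
    label permutations instead (only feasible for tiny n; strata ignored
    there must be None).
    """
    factor = pd.Series(factor).loc[dist.ids]
    codes, levels = pd.factorize(factor)
    if len(levels) < 2:
        raise ValueError("factor needs >= 2 levels")
    if n_perm < 99 and not exhaustive:
        log.warning("n_perm=%d gives coarse p-value resolution", n_perm)
    D2 = dist.values() ** 2
    f_obs = _pseudo_f(D2, codes, len(levels))

    if exhaustive:
        if strata is not None:
            raise ValueError("exhaustive enumeration does not support strata")
        perms = set(itertools.permutations(codes))
        f_null = np.array([_pseudo_f(D2, np.array(p), len(levels)) for p in perms])
        p = float((f_null >= f_obs - 1e-12).mean())
        return {"F": f_obs, "p": p, "n_perm": len(perms), "method": "exhaustive"}

    rng = np.random.default_rng(seed)
    count = 0
    perm = codes.copy()
    if strata is not None:
        strata = pd.Series(strata).loc[dist.ids]
        strata_idx = [np.nonzero((strata == s).to_numpy())[0] for s in strata.unique()]
    for _ in range(n_perm):
        if strata is None:
            perm = rng.permutation(codes)
        else:
            perm = codes.copy()
            for idx in strata_idx:
                perm[idx] = perm[rng.permutation(idx)]
        if _pseudo_f(D2, perm, len(levels)) >= f_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return {"F": f_obs, "p": p, "n_perm": n_perm, "method": "monte-carlo"}
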