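"""Linear and quadratic selection differentials from a smoothed fitness
function.

Relative fitness (canopy coverage / its mean) is regressed on each
standardized trait with a penalized cubic regression spline (P-spline:
uniform knots, third-order difference penalty, so linear and quadratic
trends sit in the unpenalized null space), with the smoothing parameter
chosen by restricted maximum likelihood.  The linear differential s is the
average first derivative of the fitted function over the observed trait
values and the quadratic differential c the average second derivative
(function-valued analogues of the Lande-Arnold differentials for
standardized traits).  A second-derivative penalty would shrink the
quadratic differential itself; keeping quadratics unpenalized leaves both
differentials estimable while still smoothing higher-order wiggle.
Significance comes from a genotype-level bootstrap with a two-sided
sign-crossing p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

log = logging.getLogger(__name__)

__all__ = [
    "SelectionEstimate",
    "relative_fitness",
    "standardize",
    "fit_fitness_function",
    "selection_differentials",
    "bootstrap_selection",
    "selection_table",
]


@dataclass
class SelectionEstimate:
    trait: str
    treatment: str
    s: float
    c: float
    p_s: float | None = None
    p_c: float | None = None
    B: int | None = None


def relative_fitness(cc: pd.Series) -> pd.Series:
    """w = CC / mean(CC); mean(w) = 1 exactly."""
    cc = pd.Series(cc).astype(float)
    m = cc.mean()
    if m == 0:
        raise ValueError("all fitness-proxy values are zero")
    return (cc / m).rename("w")


def standardize(x: pd.Series) -> pd.Series:
    """(x - mean) / sd.  Zero-variance input raises (caller excludes trait)."""
    x = pd.Series(x).astype(float)
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero-variance trait cannot be standardized")
    return (x - x.mean()) / sd


def _pspline_basis(z: np.ndarray, basis_df: int):
    """Uniform-knot cubic B-spline design matrix and knot vector."""
    lo, hi = z.min(), z.max()
    n_inner = max(basis_df - 3, 1)
    step = (hi - lo) / n_inner
    # pad the span slightly so boundary points are strictly interior
    knots = np.concatenate([
        lo + step * np.arange(-3, 0) - 1e-9,
        np.linspace(lo - 1e-9, hi + 1e-9, n_inner + 1),
        hi + step * np.arange(1, 4) + 1e-9,
    ])
    n_coef = len(knots) - 4
    design = np.empty((len(z), n_coef))
    for k in range(n_coef):
        coef = np.zeros(n_coef)
        coef[k] = 1.0
        design[:, k] = BSpline(knots, coef, 3)(z)
    return design, knots


def fit_fitness_function(z, w, basis_df: int = 12, lam: float | None = None):
    """Penalized cubic regression spline of relative fitness on one trait.

    Cubic B-splines on uniform knots with a third-order difference penalty
    on the coefficients (P-spline); on uniform knots the penalty null space
    is the quadratic polynomials, so exactly linear or quadratic data are
    reproduced for any penalty strength.  The smoothing parameter is chosen
    by restricted maximum likelihood when ``lam`` is None (REML profiles
    are far better behaved than GCV when the fitness surface is nearly
    polynomial, where GCV goes flat and undersmooths).  The basis is
    reduced with a warning when there are fewer points than ``basis_df``.
    Returns the fitted spline (callable; use ``.derivative(k)``).
    """
    z = np.asarray(z, float)
    w = np.asarray(w, float)
    n_distinct = len(np.unique(z))
    if n_distinct < 5:
        raise ValueError("need >= 5 distinct trait values to fit the spline")
    if n_distinct < basis_df:
        log.warning("reducing spline basis from %d to %d", basis_df, n_distinct - 1)
        basis_df = n_distinct - 1
    basis_df = max(basis_df, 4)
    B, knots = _pspline_basis(z, basis_df)
    n_coef = B.shape[1]
    D = np.diff(np.eye(n_coef), n=3, axis=0)
    P = D.T @ D
    BtB = B.T @ B
    Btw = B.T @ w
    # numerical ridge: keeps the solve well posed if boundary basis
    # functions lose support in a bootstrap resample, without visible bias
    ridge = 1e-10 * (np.trace(BtB) / n_coef) * np.eye(n_coef)
    n = len(z)
    p_null = 3  # dim of the unpenalized (quadratic) null space
    rank = n_coef - p_null

    def fit_at(l):
        A = BtB + l * P + ridge
        coef = np.linalg.solve(A, Btw)
        return coef, A

    if lam is None:
        # floor the profiled variance so numerically-exact fits tie and the
        # tie resolves toward the smoothest model
        s2_floor = 1e-13 * max(1.0, float(w @ w) / n)
        best = (np.inf, None)
        for l in np.logspace(8, -6, 29):
            coef, A = fit_at(l)
            resid = w - B @ coef
            s2 = (float(resid @ resid) + l * float(coef @ P @ coef)) / (n - p_null)
            _, logdetA = np.linalg.slogdet(A)
            reml = (n - p_null) * np.log(max(s2, s2_floor)) + logdetA - rank * np.log(l)
            if reml < best[0] - 1e-9:
                best = (reml, l)
        lam = best[1]
    coef, _ = fit_at(lam)
    return BSpline(knots, coef, 3)


def selection_differentials(spline, z) -> tuple[float, float]:
    """Average-derivative estimators over the observed z sample.

    s = mean_i f'(z_i), c = mean_i f''(z_i).
    """
    z = np.asarray(z, float)
    s = float(spline.derivative(1)(z).mean())
    c = float(spline.derivative(2)(z).mean())
    return s, c


def _estimate(z: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    spline = fit_fitness_function(z, w)
    return selection_differentials(spline, z)


def bootstrap_selection(
    z, w, B: int = 1000, seed: int = 0, max_redraws: int = 100
) -> dict:
    """Genotype-level bootstrap of the selection differentials.

    Rows of (z, w) are resampled with replacement; degenerate resamples
    (zero trait variance) are redrawn with a logged count.  Two-sided
    sign-crossing p-values with the +1/(B+1) correction.
    """
    z = np.asarray(z, float)
    w = np.asarray(w, float)
    n = len(z)
    s_obs, c_obs = _estimate(z, w)
    rng = np.random.default_rng(seed)
    s_b = np.empty(B)
    c_b = np.empty(B)
    n_redrawn = 0
    for b in range(B):
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(z[idx])) >= 5:
                break
            n_redrawn += 1
        s_b[b], c_b[b] = _estimate(z[idx], w[idx])
    if n_redrawn:
        log.info("redrew %d degenerate bootstrap resamples", n_redrawn)

    def two_sided(stat_b):
        lo = (np.sum(stat_b <= 0) + 1) / (B + 1)
        hi = (np.sum(stat_b >= 0) + 1) / (B + 1)
        return min(1.0, 2.0 * min(lo, hi))

    return {
        "s": s_obs, "c": c_obs,
        "p_s": two_sided(s_b), "p_c": two_sided(c_b),
        "s_boot": s_b, "c_boot": c_b,
        "ci_s": tuple(np.percentile(s_b, [2.5, 97.5])),
        "ci_c": tuple(np.percentile(c_b, [2.5, 97.5])),
        "B": B,
    }


def selection_table(
    blups: pd.DataFrame,
    fitness: pd.Series,
    treatment: str,
    B: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-trait selection differentials for one treatment.

    ``blups`` is a genotype x trait matrix; ``fitness`` is the fitness
    proxy (e.g. canopy coverage) per genotype.  Zero-variance traits are
    excluded with a warning.
    """
    rng = np.random.default_rng(seed)
    common = blups.index.intersection(fitness.index)
    w = relative_fitness(fitness.loc[common])
    rows = []
    for trait in blups.columns:
        try:
            z = standardize(blups.loc[common, trait])
        except ValueError:
            log.warning("excluding zero-variance trait %s", trait)
            continue
        res = bootstrap_selection(
            z.to_numpy(), w.to_numpy(), B=B, seed=int(rng.integers(2 ** 31 - 1))
        )
        rows.append({
            "trait": trait, "treatment": treatment,
            "s": res["s"], "c": res["c"], "p_s": res["p_s"], "p_c": res["p_c"],
            "ci_s_lo": res["ci_s"][0], "ci_s_hi": res["ci_s"][1],
            "ci_c_lo": res["ci_c"][0], "ci_c_hi": res["ci_c"][1],
            "B": B,
        })
    return pd.DataFrame(rows)
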