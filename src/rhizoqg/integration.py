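"""Microbe-phenotype integration.

Correlates genotype-level microbial-trait BLUPs with plant-trait values
(per treatment), tests whether more groups are significantly correlated
than expected by chance via a genotype-label permutation null, relates
per-group heritability to the strength of the canopy-coverage correlation,
compares expression of MAPL genes against all other genes per tissue, and
assembles the per-group summary ledger joining every analysis.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "correlate",
    "count_significant_permutation",
    "heritability_correlation_relation",
    "expression_set_test",
    "build_summary",
]


def correlate(
    blups: pd.DataFrame,
    plant: pd.DataFrame | pd.Series,
    treatment: str = "",
    method: str = "pearson",
) -> pd.DataFrame:
    """Pearson correlation of each microbial trait with each plant trait.

    Both inputs are genotype-indexed; pairs are matched on genotype and
    missing pairs dropped.  Records with n < 3 after matching are
    suppressed with a flag.
    """
    if method != "pearson":
        raise ValueError("only pearson supported")
    if isinstance(plant, pd.Series):
        plant = plant.to_frame()
    rows = []
    for pt in plant.columns:
        pv = plant[pt]
        for mt in blups.columns:
            pair = pd.concat([blups[mt], pv], axis=1, join="inner").dropna()
            if len(pair) < 3:
                rows.append({"microbial_trait": mt, "plant_trait": pt,
                             "treatment": treatment, "r": np.nan, "p": np.nan,
                             "n": len(pair), "suppressed": True})
                continue
            r, p = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            rows.append({"microbial_trait": mt, "plant_trait": pt,
                         "treatment": treatment, "r": r, "p": p,
                         "n": len(pair), "suppressed": False})
    return pd.DataFrame(rows)


def count_significant_permutation(
    blups: pd.DataFrame,
    plant: pd.Series,
    p_cut: float = 0.01,
    B: int = 1000,
    seed: int = 0,
) -> dict:
    """Is the number of microbial groups significantly correlated with the
    plant trait more than expected by chance?

    Genotype labels of the plant trait are shuffled B times; each
    permutation recomputes all correlations and counts groups with
    p < ``p_cut``.  p = (#{count_perm >= count_obs} + 1) / (B + 1).
    """
    common = blups.index.intersection(plant.index)
    Z = blups.loc[common].to_numpy(float)
    x = plant.loc[common].to_numpy(float)
    n = len(common)

    def n_sig(xv: np.ndarray) -> int:
        xc = xv - xv.mean()
        Zc = Z - Z.mean(axis=0)
        r = (Zc.T @ xc) / np.sqrt((Zc ** 2).sum(axis=0) * (xc ** 2).sum())
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r ** 2))
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
        return int(np.sum(p < p_cut))

    obs = n_sig(x)
    rng = np.random.default_rng(seed)
    null = np.array([n_sig(rng.permutation(x)) for _ in range(B)])
    p = (int(np.sum(null >= obs)) + 1) / (B + 1)
    return {"observed": obs, "null": null, "p": p, "B": B}


def heritability_correlation_relation(
    h2_table: pd.DataFrame, corr_table: pd.DataFrame
) -> pd.DataFrame:
    """Per-treatment Pearson correlation between group heritability and the
    group's (signed) correlation with the plant trait.

    ``h2_table`` needs columns trait, treatment, h2; ``corr_table`` needs
    microbial_trait, treatment, r.  Constant vectors are suppressed.
    """
    rows = []
    for treatment in sorted(h2_table["treatment"].unique()):
        h = h2_table[h2_table["treatment"] == treatment].set_index("trait")["h2"]
        c = corr_table[corr_table["treatment"] == treatment].set_index(
            "microbial_trait")["r"]
        pair = pd.concat([h, c], axis=1, join="inner").dropna()
        if len(pair) < 3 or pair.iloc[:, 0].std() == 0 or pair.iloc[:, 1].std() == 0:
            rows.append({"treatment": treatment, "r": np.nan, "p": np.nan,
                         "n": len(pair), "suppressed": True})
            continue
        r, p = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
        rows.append({"treatment": treatment, "r": r, "p": p, "n": len(pair),
                     "suppressed": False})
    return pd.DataFrame(rows)


def expression_set_test(
    expression: pd.DataFrame, mapl_genes, log_transform: bool = False
) -> pd.DataFrame:
    """Mann-Whitney U of MAPL-gene vs other-gene expression per tissue.

    ``expression`` is genes x tissues on a log scale (set ``log_transform``
    to apply log2(x+1) to raw values).  Effect is the difference in mean
    log expression (MAPL minus others).
    """
    mapl_genes = pd.Index(mapl_genes)
    if len(mapl_genes) == 0:
        raise ValueError("empty MAPL gene set")
    in_set = expression.index.isin(mapl_genes)
    if in_set.all():
        raise ValueError("gene sets must be disjoint: every gene is in the MAPL set")
    expr = np.log2(expression + 1.0) if log_transform else expression
    rows = []
    for tissue in expr.columns:
        a = expr.loc[in_set, tissue].dropna()
        b = expr.loc[~in_set, tissue].dropna()
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"tissue": tissue, "effect": a.mean() - b.mean(),
                     "U": u, "p": p, "n_set": len(a), "n_other": len(b)})
    return pd.DataFrame(rows).set_index("tissue")


def build_summary(
    h2_table: pd.DataFrame,
    selection_table: pd.DataFrame,
    mapls: pd.DataFrame,
    corr_table: pd.DataFrame,
    alpha_h2: float = 0.05,
    alpha_sel: float = 0.05,
    alpha_corr: float = 0.01,
) -> pd.DataFrame:
    """One row per microbial group joining every analysis.

    Flags are re-derived from the source tables: heritable under +N/-N
    (permutation p), selection class (bootstrap p on s), MAPL membership
    (windows listing the group), and sign/significance of the correlation
    with the plant performance trait per treatment.
    """
    groups = pd.Index(sorted(h2_table["trait"].unique()), name="group")
    orphans = set(selection_table["trait"]) - set(groups)
    orphans |= set(corr_table["microbial_trait"]) - set(groups)
    if orphans:
        raise ValueError(f"traits absent from the heritability table: {sorted(orphans)[:10]}")

    out = pd.DataFrame(index=groups)
    for treatment in sorted(h2_table["treatment"].unique()):
        h = h2_table[h2_table["treatment"] == treatment].set_index("trait")
        out[f"h2_{treatment}"] = h["h2"].reindex(groups)
        out[f"heritable_{treatment}"] = (h["p"] < alpha_h2).reindex(groups).fillna(False)
        s = selection_table[selection_table["treatment"] == treatment].set_index("trait")
        out[f"s_{treatment}"] = s["s"].reindex(groups)
        sig_lin = (s["p_s"] < alpha_sel).reindex(groups).fillna(False)
        out[f"selected_{treatment}"] = sig_lin
        c = corr_table[corr_table["treatment"] == treatment].set_index("microbial_trait")
        out[f"cc_r_{treatment}"] = c["r"].reindex(groups)
        out[f"cc_sig_{treatment}"] = (c["p"] < alpha_corr).reindex(groups).fillna(False)

    mapl_of = {g: [] for g in groups}
    for _, r in mapls.iterrows():
        for t in str(r["traits"]).split(";"):
            if t in mapl_of:
                mapl_of[t].append(f"{r['chrom']}:{r['start']}-{r['end']}")
    out["mapls"] = [";".join(mapl_of[g]) for g in groups]
    out["n_mapls"] = [len(mapl_of[g]) for g in groups]

    her_cols = [c for c in out.columns if c.startswith("heritable_")]
    sel_cols = [c for c in out.columns if c.startswith("selected_")]
    sig_cols = [c for c in out.columns if c.startswith("cc_sig_")]
    out["heritable_any"] = out[her_cols].any(axis=1)
    out["selected_any"] = out[sel_cols].any(axis=1)
    out["cc_correlated_any"] = out[sig_cols].any(axis=1)
    out["has_mapl"] = out["n_mapls"] > 0
    out["overlap_all"] = (
        out["heritable_any"] & out["selected_any"]
        & out["cc_correlated_any"] & out["has_mapl"]
    )
    return out
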