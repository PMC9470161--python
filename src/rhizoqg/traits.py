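"""Rhizobiome trait construction.

Turns a curated ASV count table into a matrix of group-level traits on the
ln-relative-abundance scale: abundance/prevalence filtering reproducible
across years, taxonomy-driven clustering of ASVs into microbial groups
(with optional splitting of taxa whose members respond to N treatment in
opposite directions), the ln(group count / sample total) transform, and the
per-group differential-abundance classification between N treatments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from rhizoqg.io_formats import AsvCountTable, TREATMENT_LEVELS

log = logging.getLogger(__name__)

__all__ = [
    "GroupTraitMatrix",
    "filter_asvs",
    "cluster_asvs",
    "transform_abundance",
    "differential_abundance",
]

N_RESPONSE_CLASSES = ("plusN_enriched", "minusN_enriched", "ns")


@dataclass
class GroupTraitMatrix:
    """Samples x groups ln-relative-abundance values with group metadata."""

    values: pd.DataFrame  # samples x groups
    group_map: pd.Series  # ASV id -> group id
    group_meta: pd.DataFrame  # indexed by group id: label, n_asvs, (n_response)

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("trait values must be finite")


def filter_asvs(
    table: AsvCountTable,
    min_mean_rel_abund: float = 1e-4,
    min_prevalence: float = 0.1,
    require_groups: str = "year",
    min_per_group_prevalence: float | None = None,
) -> AsvCountTable:
    """Keep ASVs that are abundant and repeatedly observed in every level
    of ``require_groups`` (by default: reproducible across years).

    An ASV survives iff, within EVERY level of the grouping column, its mean
    relative abundance is >= ``min_mean_rel_abund`` and its prevalence
    (fraction of samples with a non-zero count) is >= the prevalence
    threshold.
    """
    prev_thresh = (
        min_prevalence if min_per_group_prevalence is None else min_per_group_prevalence
    )
    rel = table.relative_abundance().fillna(0.0)
    levels = table.sample_meta.loc[table.sample_ids, require_groups]
    keep = pd.Series(True, index=table.asv_ids)
    for _, samples in levels.groupby(levels):
        sub_rel = rel.loc[samples.index]
        sub_cnt = table.counts.loc[samples.index]
        keep &= sub_rel.mean(axis=0) >= min_mean_rel_abund
        keep &= (sub_cnt > 0).mean(axis=0) >= prev_thresh
    n_before, n_after = len(keep), int(keep.sum())
    log.info("filter_asvs: %d -> %d ASVs", n_before, n_after)
    if n_after == 0:
        raise ValueError(
            "all ASVs removed by filtering; lower min_mean_rel_abund "
            f"(={min_mean_rel_abund}) or the prevalence threshold (={prev_thresh})"
        )
    return table.subset_asvs(keep.index[keep])


def _per_asv_t(table: AsvCountTable) -> pd.DataFrame:
    """Welch t of each ASV's ln relative abundance between N treatments."""
    rel = table.relative_abundance().fillna(0.0)
    ln = np.log(rel + 1.0 / table.counts.sum(axis=1).to_numpy()[:, None])
    treat = table.sample_meta.loc[table.sample_ids, "treatment"]
    a = ln[ (treat == TREATMENT_LEVELS[0]).to_numpy() ]
    b = ln[ (treat == TREATMENT_LEVELS[1]).to_numpy() ]
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return pd.DataFrame({"t": t, "p": p}, index=table.asv_ids)


def cluster_asvs(
    table: AsvCountTable,
    rank_priority=("genus", "family"),
    split_by_n_response: bool = False,
    p_split: float = 0.05,
) -> pd.Series:
    """Group ASVs by the finest non-Unknown taxonomic rank available.

    ASVs with an Unknown genus fall back to the family level with labels
    like ``"f_<Family> Unknown Genus"``; fully Unknown ASVs go to a single
    ``"Unclassified"`` group.  When ``split_by_n_response`` is set, a taxon
    whose member ASVs show significantly opposite-signed responses to N
    treatment (per-ASV Welch t on ln relative abundance at ``p_split``) is
    split into numbered subgroups.

    Returns a Series mapping ASV id -> group label (deterministic).
    """
    tax = table.taxonomy
    labels = {}
    for asv in table.asv_ids:
        label = None
        for rank in rank_priority:
            val = tax.at[asv, rank]
            if val != "Unknown":
                label = f"f_{val} Unknown Genus" if rank == "family" else str(val)
                break
        labels[asv] = label if label is not None else "Unclassified"
    group_map = pd.Series(labels, name="group")

    if split_by_n_response:
        asv_t = _per_asv_t(table)
        new_map = {}
        for grp in sorted(group_map.unique()):
            members = group_map.index[group_map == grp]
            sub = asv_t.loc[members]
            sig = sub[sub["p"] < p_split]
            if len(members) >= 2 and (sig["t"] > 0).any() and (sig["t"] < 0).any():
                for asv in members:
                    side = 1 if sub.at[asv, "t"] > 0 else 2
                    new_map[asv] = f"{grp} {side}"
            else:
                for asv in members:
                    new_map[asv] = grp
        group_map = pd.Series(new_map, name="group").loc[group_map.index]
    return group_map


def transform_abundance(
    table: AsvCountTable, group_map: pd.Series, pseudocount: float = 1.0
) -> GroupTraitMatrix:
    """ln((group count + pseudocount) / sample total) per sample and group.

    The pseudocount is added to the summed group count (not per ASV) so the
    transform is exactly ln(group/total) shifted by at most pseudocount.
    Zero-total samples are dropped with a warning.
    """
    asvs = group_map.index.intersection(table.asv_ids)
    counts = table.counts[asvs]
    totals = table.counts.sum(axis=1)
    nonzero = totals > 0
    if not nonzero.all():
        log.warning("dropping %d zero-total samples", int((~nonzero).sum()))
        counts, totals = counts.loc[nonzero], totals.loc[nonzero]
    grouped = counts.T.groupby(group_map.loc[asvs]).sum().T
    values = np.log((grouped + pseudocount).div(totals, axis=0))
    meta = pd.DataFrame({
        "label": grouped.columns,
        "n_asvs": group_map.loc[asvs].value_counts().reindex(grouped.columns).to_numpy(),
    }, index=grouped.columns)
    return GroupTraitMatrix(values=values, group_map=group_map.loc[asvs], group_meta=meta)


def differential_abundance(
    traits: GroupTraitMatrix, sample_meta: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Welch t-test of each group's ln relative abundance between treatments.

    Classes: plusN_enriched (p < alpha, higher mean under +N),
    minusN_enriched (reverse), else ns.  Groups constant in both arms have
    an undefined t and are classed ns with a flag.
    """
    treat = sample_meta.loc[traits.values.index, "treatment"]
    present = set(treat.unique())
    if not set(TREATMENT_LEVELS) <= present:
        raise ValueError(f"both treatment levels required, found {sorted(present)}")
    a = traits.values[(treat == TREATMENT_LEVELS[0]).to_numpy()]
    b = traits.values[(treat == TREATMENT_LEVELS[1]).to_numpy()]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, equal_var=False)
    mean_plus, mean_minus = a.mean(axis=0), b.mean(axis=0)
    out = pd.DataFrame({
        "t": t, "p": p,
        "mean_plusN": mean_plus, "mean_minusN": mean_minus,
    }, index=traits.values.columns)
    degenerate = ~np.isfinite(out["t"])
    cls = np.where(
        (out["p"] < alpha) & (mean_plus > mean_minus), "plusN_enriched",
        np.where((out["p"] < alpha) & (mean_plus < mean_minus), "minusN_enriched", "ns"),
    )
    cls = np.where(degenerate, "ns", cls)
    out["n_response"] = cls
    out["degenerate"] = degenerate.to_numpy()
    return out
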