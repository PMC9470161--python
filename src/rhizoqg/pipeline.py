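"""End-to-end synthetic-to-summary pipeline.

Thin orchestration over the analysis modules, shared by the numbered
analysis scripts, the command-line interface and the acceptance script.
All tunables live in one nested config dict (see :func:`default_config`);
unknown keys are rejected.  Every stage derives its RNG stream from the
master seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from rhizoqg import architecture, community, gwas, integration, mixed_models
from rhizoqg import selection as sel
from rhizoqg import synthetic, traits as traits_mod
from rhizoqg.io_formats import TREATMENT_LEVELS, write_table

log = logging.getLogger(__name__)


def default_config() -> dict:
    """Defaults emulate the field study's scale where desk-feasible."""
    return {
        "simulate": {
            "n_geno": 230,
            "n_snp": 2000,
            "n_chrom": 2,
            "maf_dist": [0.05, 0.5],
            "ld_rho": 0.5,
            "block_len": 25,
            "bp_spacing": 1000,
            "reps_per_treatment": 2,
            "samples_per_plot": 3,
            "n_groups": 50,
            "n_causal": 20,
            "S_true": -1.0,
            "depth": 32000,
            "overdispersion": 25.0,
            "h2_range": [0.0, 0.85],
            "n_sel_traits": 5,
            "sel_s": 0.2,
            "sel_c": -0.05,
            "fitness_noise_sd": 0.3,
            "cc_mean": 50.0,
        },
        "traits": {
            "min_mean_rel_abund": 1e-4,
            "min_prevalence": 0.1,
            "pseudocount": 1.0,
            "split_by_n_response": False,
        },
        "heritability": {"n": 6, "B": 199},
        "selection": {"B": 400},
        "bayess": {
            "chain_length": 25000,
            "burnin": 5000,
            "thin": 10,
            "n_traits": 4,
        },
        "gwas": {
            "n_pcs": 3,
            "maf_min": 0.05,
            "alpha": 0.05,
            "window_bp": 10000,
            "min_signals": 2,
            "flank": 10000,
            "meff_block": 200,
        },
        "integration": {"p_cut": 0.01, "B": 999},
        "community": {"n_perm": 999, "max_samples": 400},
    }


def validate_config(cfg: dict, reference: dict | None = None) -> None:
    """Reject unknown keys anywhere in the nested config."""
    reference = default_config() if reference is None else reference
    for key, val in cfg.items():
        if key not in reference:
            raise KeyError(f"unknown config key: {key!r}")
        if isinstance(reference[key], dict):
            if not isinstance(val, dict):
                raise KeyError(f"config key {key!r} must be a mapping")
            validate_config(val, reference[key])


def merge_config(overrides: dict | None) -> dict:
    cfg = default_config()
    if overrides:
        validate_config(overrides)
        for k, v in overrides.items():
            if isinstance(v, dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    return cfg


def _seeds(master: int, n: int) -> list[int]:
    return [int(s) for s in np.random.default_rng(master).integers(2 ** 31 - 1, size=n)]


def run_simulation(cfg: dict, seed: int) -> dict:
    """Generate genotypes, design, counts, latent traits and fitness."""
    sc = cfg["simulate"]
    s_geno, s_design, s_traits, s_fit_plus, s_fit_minus, s_h2 = _seeds(seed, 6)
    geno = synthetic.simulate_genotypes(
        n_ind=sc["n_geno"], n_snp=sc["n_snp"], maf_dist=tuple(sc["maf_dist"]),
        ld_rho=sc["ld_rho"], block_len=sc["block_len"], seed=s_geno,
        n_chrom=sc["n_chrom"], bp_spacing=sc["bp_spacing"],
    )
    design = synthetic.simulate_design(
        list(geno.individual_ids), reps_per_treatment=sc["reps_per_treatment"],
        samples_per_plot=sc["samples_per_plot"], seed=s_design,
    )
    h2_rng = np.random.default_rng(s_h2)
    h2_targets = h2_rng.uniform(*sc["h2_range"], size=sc["n_groups"])
    table, latent, truth = synthetic.simulate_group_traits(
        geno, design, h2_targets, n_causal=sc["n_causal"], S_true=sc["S_true"],
        overdispersion=sc["overdispersion"], depth=sc["depth"], seed=s_traits,
    )
    # fitness: linear/quadratic selection on the first n_sel standardized
    # true genetic values, independent noise per treatment
    groups = truth.genetic_values.columns
    n_sel = sc["n_sel_traits"]
    s_vec = np.zeros(len(groups))
    c_vec = np.zeros(len(groups))
    s_vec[:n_sel] = sc["sel_s"]
    c_vec[:n_sel] = sc["sel_c"]
    gv = truth.genetic_values
    z_true = (gv - gv.mean()) / gv.std(ddof=1).replace(0, np.nan)
    z_true = z_true.fillna(0.0)
    cc = {}
    for treatment, s_fit in zip(TREATMENT_LEVELS, (s_fit_plus, s_fit_minus)):
        cc_t, _, _ = synthetic.simulate_fitness(
            z_true, s_vec, c_vec, noise_sd=sc["fitness_noise_sd"],
            seed=s_fit, cc_mean=sc["cc_mean"],
        )
        cc[treatment] = cc_t
    truth.s_true = s_vec
    truth.c_true = c_vec
    return {"geno": geno, "design": design, "table": table, "latent": latent,
            "truth": truth, "cc": cc, "seed": seed}


def run_traits(sim: dict, cfg: dict) -> dict:
    tc = cfg["traits"]
    table = traits_mod.filter_asvs(
        sim["table"], min_mean_rel_abund=tc["min_mean_rel_abund"],
        min_prevalence=tc["min_prevalence"], require_groups="treatment",
    )
    group_map = traits_mod.cluster_asvs(
        table, split_by_n_response=tc["split_by_n_response"]
    )
    gtm = traits_mod.transform_abundance(table, group_map, pseudocount=tc["pseudocount"])
    diff = traits_mod.differential_abundance(gtm, table.sample_meta)
    return {"table": table, "group_map": group_map, "gtm": gtm, "diff": diff}


def truth_label_map(truth, est_group_map: pd.Series) -> dict:
    """Map generator group ids to the taxonomy-derived group labels."""
    out = {}
    for asv, grp in truth.group_map.items():
        if asv in est_group_map.index and grp not in out:
            out[grp] = est_group_map[asv]
    return out


def run_heritability(gtm, sample_meta, cfg: dict, seed: int) -> pd.DataFrame:
    hc = cfg["heritability"]
    return mixed_models.heritability_table(
        gtm.values, sample_meta, n=hc["n"], B=hc["B"], seed=seed
    )


def run_blups(gtm, sample_meta) -> dict[str, pd.DataFrame]:
    """Per-treatment genotype x trait BLUP matrices from the four-term model."""
    out = {}
    meta = sample_meta.loc[gtm.values.index]
    for treatment, idx in meta.groupby("treatment").groups.items():
        sub = gtm.values.loc[idx]
        design = meta.loc[idx]
        cols = {}
        x0 = None
        for trait in sub.columns:
            y = sub[trait].to_numpy()
            sd = y.std()
            # variance components scale as sd^2: normalize so the warm
            # start from the previous trait carries over
            bt = mixed_models.fit_blup(y / sd if sd > 0 else y, design, x0=x0)
            x0 = bt.opt_x
            cols[trait] = bt.blups * (sd if sd > 0 else 1.0)
        out[treatment] = pd.DataFrame(cols)
    return out


def run_selection(blups: dict, cc: dict, cfg: dict, seed: int) -> pd.DataFrame:
    tables = []
    for s, (treatment, bl) in zip(_seeds(seed, len(blups)), sorted(blups.items())):
        tables.append(sel.selection_table(
            bl, cc[treatment], treatment, B=cfg["selection"]["B"], seed=s
        ))
    return pd.concat(tables, ignore_index=True)


def run_architecture(blups: dict, geno, cfg: dict, seed: int) -> pd.DataFrame:
    """BayesS on the first n_traits groups per treatment (pruned panel)."""
    bc = cfg["bayess"]
    pruned = architecture.ld_prune(geno)
    rows = []
    seeds = iter(_seeds(seed, 2 * bc["n_traits"] + 4))
    for treatment, bl in sorted(blups.items()):
        for trait in bl.columns[: bc["n_traits"]]:
            y = bl[trait].loc[pruned.individual_ids]
            res = architecture.bayess_fit(
                y.to_numpy(), pruned, chain_length=bc["chain_length"],
                burnin=bc["burnin"], thin=bc["thin"], seed=next(seeds),
            )
            rows.append({
                "trait": trait, "treatment": treatment,
                "S_mean": res.S_mean, "S_ci_lo": res.S_ci[0], "S_ci_hi": res.S_ci[1],
                "pi_mean": res.pi_mean, "nnz_mean": res.nnz_mean,
                "class": architecture.s_significance(res),
                "acceptance": res.acceptance_rate,
            })
    return pd.DataFrame(rows)


def run_gwas_mapl(blups: dict, geno, annotation, cfg: dict) -> dict:
    gc = cfg["gwas"]
    keep = geno.snp_map["maf"].to_numpy() >= gc["maf_min"]
    sub = geno.subset_snps(keep)
    K = mixed_models.grm(sub)
    meff = gwas.effective_snp_number(sub, block_size=gc["meff_block"])
    threshold = gwas.significance_threshold(gc["alpha"], meff)
    results = []
    for treatment, bl in sorted(blups.items()):
        for trait in bl.columns:
            y = bl[trait].loc[sub.individual_ids]
            results.append(gwas.lmm_gwas(
                y, sub, K, n_pcs=gc["n_pcs"], trait=trait, treatment=treatment
            ))
    mapls_all = gwas.call_mapls(results, window_bp=gc["window_bp"],
                                threshold=threshold, min_signals=1)
    mapls = gwas.call_mapls(results, window_bp=gc["window_bp"],
                            threshold=threshold, min_signals=gc["min_signals"])
    if annotation is not None:
        mapls = gwas.annotate_genes(mapls, annotation, flank=gc["flank"])
    return {"results": results, "meff": meff, "threshold": threshold,
            "mapls_all": mapls_all, "mapls": mapls, "kinship": K, "geno": sub}


def run_integration(blups: dict, cc: dict, h2_table, sel_table, mapls,
                    cfg: dict, seed: int) -> dict:
    ic = cfg["integration"]
    corr_tables, perms = [], {}
    for s, treatment in zip(_seeds(seed, len(blups)), sorted(blups)):
        corr_tables.append(integration.correlate(
            blups[treatment], cc[treatment].rename("CC"), treatment=treatment
        ))
        perms[treatment] = integration.count_significant_permutation(
            blups[treatment], cc[treatment], p_cut=ic["p_cut"], B=ic["B"], seed=s
        )
    corr = pd.concat(corr_tables, ignore_index=True)
    h2corr = integration.heritability_correlation_relation(h2_table, corr)
    summary = integration.build_summary(h2_table, sel_table, mapls, corr,
                                        alpha_corr=ic["p_cut"])
    return {"correlations": corr, "permutation": perms,
            "h2_correlation": h2corr, "summary": summary}


def write_outputs(outdir, seed: int, **tables) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        if df is None:
            continue
        write_table(df, outdir / f"{name}.tsv", seed=seed)
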