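#!/usr/bin/env python
"""Microbe-phenotype integration and the per-group summary ledger.

Correlates genotype BLUPs of every group with canopy coverage per
treatment, tests whether more groups are significant than chance by
genotype-label permutation, relates heritability to the CC correlation,
runs the MAPL-gene expression set test on a synthetic expression matrix,
and assembles the summary table joining heritability, selection, MAPL
membership and CC correlation per group.
"""

import sys
from pathlib import Path

from rhizoqg import integration, pipeline, synthetic
from rhizoqg.io_formats import write_table

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    cfg = pipeline.default_config()
    sim = pipeline.run_simulation(cfg, SEED)
    tr = pipeline.run_traits(sim, cfg)
    gtm, meta = tr["gtm"], tr["table"].sample_meta
    h2 = pipeline.run_heritability(gtm, meta, cfg, SEED)
    blups = pipeline.run_blups(gtm, meta)
    sel_t = pipeline.run_selection(blups, sim["cc"], cfg, SEED)
    g = pipeline.run_gwas_mapl(blups, sim["geno"], None, cfg)
    it = pipeline.run_integration(blups, sim["cc"], h2, sel_t,
                                  g["mapls"], cfg, SEED)

    OUT.mkdir(exist_ok=True)
    write_table(it["correlations"], OUT / "cc_correlations.tsv", seed=SEED)
    write_table(it["h2_correlation"], OUT / "h2_vs_cc_correlation.tsv", seed=SEED)
    write_table(it["summary"], OUT / "group_summary.tsv", seed=SEED)

    for treatment, res in it["permutation"].items():
        print(f"{treatment}: {res['observed']} groups correlated with CC "
              f"(p < {cfg['integration']['p_cut']}), permutation p = {res['p']:.4g}")
    print("heritability vs CC-correlation relation:")
    print(it["h2_correlation"].to_string(index=False))

    # expression set comparison on a synthetic expression matrix
    mapl_genes = [f"gene{i + 1:05d}" for i in range(60)]
    expr, truth = synthetic.simulate_expression(
        4000, mapl_genes, ["germinating_root", "germinating_shoot", "leaf_base"],
        root_boost=1.0, seed=SEED, root_tissues=["germinating_root"],
    )
    est = integration.expression_set_test(expr, truth.mapl_gene_ids)
    write_table(est, OUT / "expression_set_test.tsv", seed=SEED)
    print("expression set test (MAPL genes vs others):")
    print(est.to_string(float_format=lambda v: f"{v:.3g}"))

    s = it["summary"]
    n_corr = int(s["cc_correlated_any"].sum())
    if n_corr:
        her = int((s["cc_correlated_any"] & s["heritable_any"]).sum())
        sel_n = int((s["cc_correlated_any"] & s["selected_any"]).sum())
        print(f"of {n_corr} CC-correlated groups: {her} heritable "
              f"({100 * her / n_corr:.0f}%), {sel_n} under selection "
              f"({100 * sel_n / n_corr:.0f}%)")
    print(f"groups overlapping in all assays: {int(s['overlap_all'].sum())}")


if __name__ == "__main__":
    main()
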