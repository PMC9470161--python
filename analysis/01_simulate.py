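#!/usr/bin/env python
"""Generate the synthetic field study.

230 maize genotypes x 2 N treatments x 2 replicate plots x 3 samples per
plot (2,760 rhizosphere samples), a 2,000-SNP panel with block LD, 50
microbial groups whose latent log abundances carry genotype effects with
known heritabilities and MAF-dependent causal architecture (S = -1), and a
canopy-coverage fitness proxy under known linear and quadratic selection on
the first five groups.  Writes counts, design, taxonomy, fitness and the
ground-truth table under results/.
"""

import sys
from pathlib import Path

import pandas as pd

from rhizoqg import pipeline
from rhizoqg.io_formats import write_table

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    cfg = pipeline.default_config()
    sim = pipeline.run_simulation(cfg, SEED)
    table = sim["table"]
    OUT.mkdir(exist_ok=True)
    write_table(table.counts, OUT / "counts.tsv", seed=SEED)
    write_table(table.sample_meta, OUT / "sample_meta.tsv", seed=SEED)
    write_table(table.taxonomy, OUT / "taxonomy.tsv", seed=SEED)
    write_table(pd.DataFrame(sim["cc"]), OUT / "canopy_coverage.tsv", seed=SEED)
    truth = sim["truth"].to_frame()
    truth.index = sim["truth"].genetic_values.columns
    write_table(truth, OUT / "sim_truth.tsv", seed=SEED)
    print(f"samples x ASVs: {table.counts.shape[0]} x {table.counts.shape[1]}")
    print(f"groups: {len(truth)}; mean target h2: {truth['h2_target'].mean():.3f}")
    print(f"wrote counts, design, taxonomy, fitness, truth -> {OUT}")


if __name__ == "__main__":
    main()
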