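import numpy as np
import pandas as pd
import pytest

from rhizoqg import synthetic
from rhizoqg.io_formats import AsvCountTable, TAXONOMY_RANKS


def make_table(counts: np.ndarray, *, treatments=None, years=None,
               genotypes=None, taxonomy=None) -> AsvCountTable:
    """Hand-built AsvCountTable for toy tests."""
    n, m = counts.shape
    samples = [f"s{i}" for i in range(n)]
    asvs = [f"a{j}" for j in range(m)]
    meta = pd.DataFrame({
        "genotype": genotypes if genotypes is not None else [f"g{i % 3}" for i in range(n)],
        "treatment": treatments if treatments is not None
        else ["plusN" if i % 2 == 0 else "minusN" for i in range(n)],
        "year": years if years is not None else [2019] * n,
        "block": ["b0"] * n,
        "split_plot": ["sp0"] * n,
        "split_plot_block": ["spb0"] * n,
        "replicate": list(range(1, n + 1)),
    }, index=pd.Index(samples, name="sample_id"))
    if taxonomy is None:
        taxonomy = pd.DataFrame(
            {r: ["Unknown"] * m for r in TAXONOMY_RANKS},
            index=pd.Index(asvs, name="asv"),
        )
        taxonomy["genus"] = [f"Genus{j}" for j in range(m)]
        taxonomy["family"] = "FamX"
    return AsvCountTable(
        counts=pd.DataFrame(counts.astype(np.int64), index=samples, columns=asvs),
        sample_meta=meta,
        taxonomy=taxonomy,
    )


@pytest.fixture(scope="session")
def small_geno():
    return synthetic.simulate_genotypes(120, 300, ld_rho=0.3, block_len=20,
                                        seed=11, n_chrom=2)


@pytest.fixture(scope="session")
def small_sim(small_geno):
    """Small end-to-end dataset: 120 genotypes, 12 groups, known truth."""
    design = synthetic.simulate_design(list(small_geno.individual_ids), seed=12)
    h2 = np.linspace(0.0, 0.8, 12)
    table, latent, truth = synthetic.simulate_group_traits(
        small_geno, design, h2, n_causal=10, S_true=0.0, seed=13
    )
    return {"geno": small_geno, "design": design, "table": table,
            "latent": latent, "truth": truth}
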