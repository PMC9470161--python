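"""Synthetic genotypes, field design, microbial counts, fitness and expression.

Every generator is a pure function of (parameters, seed) and emits its
ground truth in a :class:`SimTruth`, so each downstream stage has a
parameter-recovery test.  Defaults emulate the field study the pipeline is
modelled on: ~230 maize genotypes x 2 N treatments x 2 replicate plots x 3
samples per plot (n = 6 samples per genotype-treatment), overdispersed
sequencing counts of ~32k reads per sample whose log relative abundances
carry genotype effects of specified heritability, SNP panels with
first-order LD and MAF-dependent causal effect variance proportional to
[2p(1-p)]^S, and a canopy-coverage fitness proxy generated under known
linear/quadratic selection on standardized trait values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from rhizoqg.io_formats import (
    AsvCountTable,
    GenotypeMatrix,
    TAXONOMY_RANKS,
    TREATMENT_LEVELS,
    _reorient_minor,
)

log = logging.getLogger(__name__)

__all__ = [
    "SimTruth",
    "simulate_genotypes",
    "simulate_design",
    "simulate_group_traits",
    "simulate_fitness",
    "simulate_expression",
]


@dataclass
class SimTruth:
    """Ground-truth parameters recorded by the generators."""

    master_seed: int
    h2_target: np.ndarray | None = None  # per group
    h2_realized: np.ndarray | None = None
    Vg: np.ndarray | None = None
    Ve: float | None = None
    Vblock: float | None = None
    Vsp: float | None = None
    Vspb: float | None = None
    n_per_genotype: int | None = None
    S_true: float | None = None
    pi_true: float | None = None
    causal_snps: dict = dc_field(default_factory=dict)  # group -> snp indices
    causal_effects: dict = dc_field(default_factory=dict)  # group -> beta
    treat_effects: np.ndarray | None = None
    genetic_values: pd.DataFrame | None = None  # genotype x group
    latent: pd.DataFrame | None = None  # sample x group latent y
    group_map: pd.Series | None = None  # ASV id -> group id
    s_true: np.ndarray | None = None
    c_true: np.ndarray | None = None
    fitness_noise_sd: float | None = None
    mapl_gene_ids: list | None = None
    root_boost: float | None = None

    def to_frame(self) -> pd.DataFrame:
        """Per-group truth table (for TSV export)."""
        d = {}
        if self.h2_target is not None:
            d["h2_target"] = self.h2_target
            d["h2_realized"] = self.h2_realized
            d["Vg"] = self.Vg
            d["treat_effect"] = self.treat_effects
        if self.s_true is not None:
            d["s_true"] = self.s_true
            d["c_true"] = self.c_true
        return pd.DataFrame(d)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(
    n_ind: int,
    n_snp: int,
    maf_dist=(0.05, 0.5),
    ld_rho: float = 0.0,
    block_len: int = 50,
    seed: int = 0,
    n_chrom: int = 1,
    bp_spacing: int = 1000,
) -> GenotypeMatrix:
    """Simulate diploid dosages with block-wise first-order LD.

    Haplotypes are built SNP by SNP: inside a block of ``block_len`` SNPs
    each haplotype copies its allele at the previous SNP with probability
    ``ld_rho``, otherwise draws Bernoulli(p_j) with p_j sampled uniformly
    from ``maf_dist``; blocks are independent.  Dosage is the sum of two
    haplotypes.  Monomorphic sites are resampled; the dosage returned is
    oriented to the realized cohort minor allele.
    """
    if n_ind < 2:
        raise ValueError("n_ind must be >= 2")
    if not (0 <= ld_rho < 1):
        raise ValueError("ld_rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    lo, hi = maf_dist
    p = rng.uniform(lo, hi, size=n_snp)

    H = np.empty((2 * n_ind, n_snp), dtype=np.int8)
    for j in range(n_snp):
        fresh = rng.random(2 * n_ind) < p[j]
        if j % block_len == 0 or ld_rho == 0.0:
            H[:, j] = fresh
        else:
            copy = rng.random(2 * n_ind) < ld_rho
            H[:, j] = np.where(copy, H[:, j - 1], fresh)

    X = (H[0::2] + H[1::2]).astype(float)
    # resample monomorphic sites (no LD; they are replacements, not copies)
    for _ in range(100):
        mono = (X.std(axis=0) == 0)
        if not mono.any():
            break
        k = int(mono.sum())
        Hm = rng.random((2 * n_ind, k)) < rng.uniform(lo, hi, size=k)
        X[:, mono] = (Hm[0::2] + Hm[1::2]).astype(float)

    per_chrom = int(np.ceil(n_snp / n_chrom))
    chrom = np.array([f"{1 + j // per_chrom}" for j in range(n_snp)])
    pos = np.array([(j % per_chrom + 1) * bp_spacing for j in range(n_snp)])
    sm = pd.DataFrame({
        "chrom": chrom, "pos": pos,
        "allele_major": "A", "allele_minor": "B", "maf": 0.25,
    })
    ids = pd.Index([f"G{i + 1:04d}" for i in range(n_ind)])
    return _reorient_minor(X, sm, ids)


# ---------------------------------------------------------------------------
# field design
# ---------------------------------------------------------------------------


def simulate_design(
    n_geno,
    treatments=TREATMENT_LEVELS,
    reps_per_treatment: int = 2,
    samples_per_plot: int = 3,
    seed: int = 0,
    block_size: int = 24,
    year: int = 2019,
) -> pd.DataFrame:
    """Sample-level skeleton of the split-plot field design.

    Each genotype appears once per quadrant (= treatment x replicate);
    within a quadrant genotypes are laid out in incomplete blocks of
    ``block_size``, each block split into two split plots, each split plot
    into two split-plot blocks.  Returns a sample metadata frame indexed by
    sample id with the design columns the downstream models expect.
    """
    if isinstance(n_geno, int):
        genotypes = [f"G{i + 1:04d}" for i in range(n_geno)]
    else:
        genotypes = list(n_geno)
    rng = np.random.default_rng(seed)
    rows = []
    counter = 0
    for t in treatments:
        for r in range(1, reps_per_treatment + 1):
            quad = f"{t}_q{r}"
            order = rng.permutation(len(genotypes))
            for k, gi in enumerate(order):
                blk = k // block_size
                within = k % block_size
                sp = within // max(1, block_size // 2)
                spb = within // max(1, block_size // 4)
                for s in range(1, samples_per_plot + 1):
                    counter += 1
                    rows.append({
                        "sample_id": f"S{counter:06d}",
                        "genotype": genotypes[gi],
                        "treatment": t,
                        "year": year,
                        "block": f"{quad}_b{blk}",
                        "split_plot": f"{quad}_b{blk}_sp{sp}",
                        "split_plot_block": f"{quad}_b{blk}_spb{spb}",
                        "replicate": s,
                    })
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# microbial group traits and counts
# ---------------------------------------------------------------------------


def _heritability_vg(h2: float, Ve: float, n_per: int) -> float:
    """Vg such that Vg / (Vg + Ve/n) equals the target repeatability h2."""
    if not 0 <= h2 < 1:
        raise ValueError("h2 target must be in [0, 1)")
    return (Ve / n_per) * h2 / (1.0 - h2)


def simulate_group_traits(
    geno: GenotypeMatrix,
    design: pd.DataFrame,
    h2_targets,
    n_causal: int = 20,
    S_true: float = 0.0,
    pi_true: float | None = None,
    treat_effects=None,
    overdispersion: float = 25.0,
    seed: int = 0,
    depth: int = 32000,
    Ve: float = 1.0,
    Vblock: float = 0.10,
    Vsp: float = 0.05,
    Vspb: float = 0.05,
    mean_asvs_per_group: float = 3.0,
) -> tuple[AsvCountTable, pd.DataFrame, SimTruth]:
    """Simulate group-level latent abundances and realize ASV counts.

    Latent sample value: y = mu_g + treatment + u(genotype) + block + sp +
    spb + e, with the genotype effect u built additively from ``n_causal``
    SNPs whose effect variance is proportional to [2p(1-p)]^S_true, and
    scaled so Vg/(Vg + Ve/n) equals the per-group h2 target exactly on the
    realized genotypes.  Counts: each sample's group counts are negative
    binomial around depth * softmax(y) and split multinomially across the
    group's member ASVs.

    Returns (AsvCountTable, latent sample x group matrix, SimTruth).
    """
    rng = np.random.default_rng(seed)
    h2_targets = np.atleast_1d(np.asarray(h2_targets, float))
    n_groups = len(h2_targets)
    if np.any(h2_targets >= 1) or np.any(h2_targets < 0):
        raise ValueError("h2 targets must be in [0, 1)")

    genotypes = pd.Index(sorted(design["genotype"].unique()))
    if not genotypes.isin(geno.individual_ids).all():
        raise ValueError("design genotypes missing from genotype matrix")
    X = geno.imputed()
    X = X - X.mean(axis=0)
    geno_idx = geno.individual_ids.get_indexer(genotypes)
    n_per = int(design.groupby(["genotype", "treatment"]).size().iloc[0])

    p = geno.snp_map["maf"].to_numpy()
    hetero = 2.0 * p * (1.0 - p)
    if pi_true is None:
        pi_true = n_causal / geno.n_snps

    groups = [f"grp{g + 1:03d}" for g in range(n_groups)]
    if treat_effects is None:
        treat_effects = rng.normal(0.0, 0.6, size=n_groups)
    else:
        treat_effects = np.broadcast_to(np.asarray(treat_effects, float), (n_groups,)).copy()

    mu = rng.normal(0.0, 1.0, size=n_groups)
    treat_sign = np.where(design["treatment"].to_numpy() == TREATMENT_LEVELS[0], 0.5, -0.5)
    blocks = design["block"].astype("category").cat.codes.to_numpy()
    sps = design["split_plot"].astype("category").cat.codes.to_numpy()
    spbs = design["split_plot_block"].astype("category").cat.codes.to_numpy()
    geno_codes = genotypes.get_indexer(design["genotype"])

    truth = SimTruth(
        master_seed=seed, h2_target=h2_targets, Ve=Ve, Vblock=Vblock,
        Vsp=Vsp, Vspb=Vspb, n_per_genotype=n_per, S_true=S_true,
        pi_true=pi_true, treat_effects=treat_effects,
    )

    latent = np.empty((len(design), n_groups))
    U = np.empty((len(genotypes), n_groups))
    Vg = np.empty(n_groups)
    h2_real = np.empty(n_groups)
    for g in range(n_groups):
        Vg[g] = _heritability_vg(h2_targets[g], Ve, n_per)
        causal = rng.choice(geno.n_snps, size=min(n_causal, geno.n_snps), replace=False)
        beta = rng.normal(0.0, 1.0, size=len(causal)) * hetero[causal] ** (S_true / 2.0)
        u = X[np.ix_(geno_idx, causal)] @ beta
        sd = u.std()
        if Vg[g] > 0 and sd > 0:
            u = u * np.sqrt(Vg[g]) / sd
        else:
            u = np.zeros_like(u)
            beta = np.zeros_like(beta)
        # scale recorded effects consistently with the standardization
        if sd > 0 and Vg[g] > 0:
            beta = beta * np.sqrt(Vg[g]) / sd
        U[:, g] = u
        truth.causal_snps[groups[g]] = causal
        truth.causal_effects[groups[g]] = beta
        h2_real[g] = u.var() / (u.var() + Ve / n_per) if (u.var() + Ve) > 0 else 0.0

        b_eff = rng.normal(0, np.sqrt(Vblock), size=blocks.max() + 1)
        sp_eff = rng.normal(0, np.sqrt(Vsp), size=sps.max() + 1)
        spb_eff = rng.normal(0, np.sqrt(Vspb), size=spbs.max() + 1)
        e = rng.normal(0, np.sqrt(Ve), size=len(design))
        latent[:, g] = (
            mu[g] + treat_effects[g] * treat_sign + u[geno_codes]
            + b_eff[blocks] + sp_eff[sps] + spb_eff[spbs] + e
        )
    truth.Vg = Vg
    truth.h2_realized = h2_real
    truth.genetic_values = pd.DataFrame(U, index=genotypes, columns=groups)
    latent_df = pd.DataFrame(latent, index=design.index, columns=groups)
    truth.latent = latent_df

    # realize counts: NB around depth * softmax(latent), multinomial ASV split
    w = np.exp(latent - latent.max(axis=1, keepdims=True))
    props = w / w.sum(axis=1, keepdims=True)
    means = depth * props
    r = overdispersion
    group_counts = rng.negative_binomial(r, r / (r + np.maximum(means, 1e-12)))

    n_asvs = np.maximum(1, rng.poisson(mean_asvs_per_group, size=n_groups))
    asv_cols, tax_rows, group_map = [], [], {}
    count_cols = []
    for g in range(n_groups):
        split = rng.dirichlet(np.ones(n_asvs[g]))
        sub = rng.multinomial(group_counts[:, g], split)
        unknown_genus = g % 5 == 4
        family = f"Fam{g + 1:03d}" if unknown_genus else f"Fam{(g // 3) + 1:03d}"
        genus = "Unknown" if unknown_genus else f"Genus{g + 1:03d}"
        for a in range(n_asvs[g]):
            asv = f"ASV{len(asv_cols) + 1:05d}"
            asv_cols.append(asv)
            group_map[asv] = groups[g]
            tax_rows.append({
                "asv": asv, "kingdom": "Bacteria", "phylum": f"Phy{(g // 20) + 1}",
                "class": f"Cls{(g // 10) + 1}", "order": f"Ord{(g // 6) + 1}",
                "family": family, "genus": genus, "species": "Unknown",
            })
        count_cols.append(sub)
    counts = pd.DataFrame(
        np.hstack(count_cols).astype(np.int64), index=design.index, columns=asv_cols
    )
    taxonomy = pd.DataFrame(tax_rows).set_index("asv")[list(TAXONOMY_RANKS)]
    table = AsvCountTable(counts=counts, sample_meta=design.copy(), taxonomy=taxonomy)
    truth.group_map = pd.Series(group_map, name="group")
    return table, latent_df, truth


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------


def simulate_fitness(
    z: pd.DataFrame,
    s_vec,
    c_vec,
    noise_sd: float = 0.3,
    seed: int = 0,
    cc_mean: float = 50.0,
) -> tuple[pd.Series, pd.Series, SimTruth]:
    """Canopy coverage under known linear/quadratic selection.

    Relative fitness w_i = 1 + sum_k s_k z_ik + 0.5 * sum_k c_k z_ik^2 + e_i
    with e ~ N(0, noise_sd^2); CC = w * cc_mean.  ``z`` must be standardized
    per trait so the generated s, c are directly Lande-Arnold differentials.
    Non-positive w are floored at 1e-6 with a logged count.
    """
    rng = np.random.default_rng(seed)
    s_vec = np.broadcast_to(np.asarray(s_vec, float), (z.shape[1],))
    c_vec = np.broadcast_to(np.asarray(c_vec, float), (z.shape[1],))
    Z = z.to_numpy(float)
    w = 1.0 + Z @ s_vec + 0.5 * (Z ** 2) @ c_vec + rng.normal(0, noise_sd, size=len(z))
    n_floor = int((w <= 0).sum())
    if n_floor:
        log.warning("flooring %d non-positive fitness values at 1e-6", n_floor)
        w = np.maximum(w, 1e-6)
    w = pd.Series(w, index=z.index, name="w")
    cc = (w * cc_mean).rename("CC")
    truth = SimTruth(
        master_seed=seed, s_true=s_vec.copy(), c_true=c_vec.copy(),
        fitness_noise_sd=noise_sd,
    )
    return cc, w, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    n_genes: int,
    mapl_gene_ids,
    tissue_list,
    root_boost: float = 1.0,
    seed: int = 0,
    root_tissues=None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Log-normal mean expression per gene per tissue (log2 scale).

    Genes in ``mapl_gene_ids`` are shifted upward by ``root_boost`` (log2
    units) in root tissues only (tissues whose name contains 'root' unless
    ``root_tissues`` is given explicitly).
    """
    if root_boost < 0:
        raise ValueError("root_boost must be >= 0")
    rng = np.random.default_rng(seed)
    mapl_gene_ids = list(mapl_gene_ids)
    genes = [f"gene{i + 1:05d}" for i in range(n_genes)]
    extra = [g for g in mapl_gene_ids if g not in genes]
    genes = genes + extra
    if root_tissues is None:
        root_tissues = [t for t in tissue_list if "root" in t.lower()]
    base = rng.normal(5.0, 1.5, size=len(genes))
    expr = pd.DataFrame(index=pd.Index(genes, name="gene_id"), columns=list(tissue_list),
                        dtype=float)
    for t in tissue_list:
        expr[t] = base + rng.normal(0.0, 0.5, size=len(genes))
    is_mapl = expr.index.isin(mapl_gene_ids)
    for t in root_tissues:
        expr.loc[is_mapl, t] += root_boost
    truth = SimTruth(master_seed=seed, mapl_gene_ids=mapl_gene_ids, root_boost=root_boost)
    return expr, truth
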