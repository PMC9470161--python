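import numpy as np
import pandas as pd
import pytest

from rhizoqg import mixed_models as mm
from rhizoqg import synthetic


def balanced_data(rng, n_geno=40, n=6, vg=0.5, ve=1.0):
    g = np.repeat(np.arange(n_geno), n)
    y = np.repeat(rng.normal(0, np.sqrt(vg), n_geno), n) + rng.normal(0, np.sqrt(ve), n_geno * n)
    return y, g


def anova_estimator(y, g, n):
    n_geno = g.max() + 1
    means = np.array([y[g == i].mean() for i in range(n_geno)])
    msb = n * np.sum((means - y.mean()) ** 2) / (n_geno - 1)
    msw = sum(np.sum((y[g == i] - means[i]) ** 2) for i in range(n_geno)) / (n_geno * (n - 1))
    if msb >= msw:
        return (msb - msw) / n, msw
    return 0.0, np.var(y, ddof=1)


class TestVarianceComponents:
    @pytest.mark.parametrize("seed", range(5))
    def test_balanced_matches_anova_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y, g = balanced_data(rng)
        vg, ve, _ = mm.fit_variance_components(y, g)
        vg0, ve0 = anova_estimator(y, g, 6)
        assert vg == pytest.approx(vg0, abs=1e-6)
        assert ve == pytest.approx(ve0, abs=1e-6)

    def test_constant_y(self):
        vg, ve, _ = mm.fit_variance_components(np.ones(30), np.repeat(np.arange(10), 3))
        assert vg == 0.0 and ve == 0.0

    def test_unbalanced_close_to_truth(self):
        rng = np.random.default_rng(3)
        g = np.concatenate([np.full(2 + i % 5, i) for i in range(80)])
        u = rng.normal(0, 1.0, 80)
        y = u[g] + rng.normal(0, 1.0, len(g))
        vg, ve, _ = mm.fit_variance_components(y, g)
        assert vg == pytest.approx(1.0, abs=0.4)
        assert ve == pytest.approx(1.0, abs=0.3)

    def test_scale_and_shift_equivariance(self):
        rng = np.random.default_rng(4)
        y, g = balanced_data(rng)
        vg, ve, _ = mm.fit_variance_components(y, g)
        vg2, ve2, _ = mm.fit_variance_components(3.0 * y + 7.0, g)
        assert vg2 == pytest.approx(9.0 * vg, rel=1e-6, abs=1e-9)
        assert ve2 == pytest.approx(9.0 * ve, rel=1e-6)

    def test_boundary_fraction_under_pure_noise(self):
        # with no genotype signal, REML hits the Vg=0 boundary roughly half
        # the time (asymptotic 50:50 mixture)
        rng = np.random.default_rng(5)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            y = rng.normal(0, 1, 120)
            g = np.repeat(np.arange(20), 6)
            vg, _, _ = mm.fit_variance_components(y, g)
            hits += vg == 0.0
        assert hits / n_rep == pytest.approx(0.5, abs=0.12)

    def test_needs_replication(self):
        with pytest.raises(ValueError):
            mm.fit_variance_components(np.arange(4.0), np.arange(4))

    def test_multi_term_matches_oneway_when_extras_absent(self):
        rng = np.random.default_rng(6)
        y, g = balanced_data(rng, n_geno=30)
        vg1, ve1, _ = mm.fit_variance_components(y, g)
        block = np.tile(np.arange(6), 30)  # orthogonal dummy term
        vg2, ve2, extras = mm.fit_variance_components(y, g, {"block": block})
        assert vg2 == pytest.approx(vg1, abs=0.05)
        assert ve2 == pytest.approx(ve1, rel=0.1)


class TestHeritability:
    @pytest.mark.parametrize("vg,ve,n,expected", [
        (1.0, 6.0, 6, 0.5),
        (0.0, 2.0, 6, 0.0),
        (0.7, 0.0, 6, 1.0),
        (0.0, 0.0, 6, 0.0),
    ])
    def test_arithmetic(self, vg, ve, n, expected):
        assert mm.heritability(vg, ve, n) == pytest.approx(expected)

    def test_negative_inputs_raise(self):
        with pytest.raises(ValueError):
            mm.heritability(-0.1, 1.0)


class TestPermutationHeritability:
    def test_zero_h2_gives_p_one(self):
        y = np.ones(60)
        g = np.repeat(np.arange(10), 6)
        h2, p = mm.permutation_heritability(y, g, B=99, seed=0)
        assert h2 == 0.0
        assert p == 1.0

    def test_power_at_high_h2(self):
        rng = np.random.default_rng(1)
        hits = 0
        for i in range(10):
            n_geno = 200
            vg = (1.0 / 6) * 0.6 / 0.4
            u = rng.normal(0, np.sqrt(vg), n_geno)
            g = np.repeat(np.arange(n_geno), 6)
            y = u[g] + rng.normal(0, 1, len(g))
            _, p = mm.permutation_heritability(y, g, B=199, seed=i)
            hits += p < 0.05
        assert hits >= 9

    def test_p_in_valid_range(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, 60)
        g = np.repeat(np.arange(10), 6)
        _, p = mm.permutation_heritability(y, g, B=99, seed=3)
        assert 1 / 100 <= p <= 1.0


class TestBlup:
    @pytest.fixture(scope="class")
    def design(self):
        d = synthetic.simulate_design(60, seed=7)
        return d[d["treatment"] == "plusN"]

    def test_no_shrinkage_limit(self, design):
        rng = np.random.default_rng(0)
        genos = sorted(design["genotype"].unique())
        u = dict(zip(genos, rng.normal(0, 1, len(genos))))
        y = np.array([u[g] for g in design["genotype"]]) + rng.normal(0, 1e-3, len(design))
        bt = mm.fit_blup(y, design)
        means = pd.Series(y, index=design["genotype"]).groupby(level=0).mean()
        np.testing.assert_allclose(bt.blups, means - means.mean(), atol=1e-4)

    def test_blups_sum_to_zero_and_shrink(self, design):
        rng = np.random.default_rng(1)
        genos = sorted(design["genotype"].unique())
        u = dict(zip(genos, rng.normal(0, 0.3, len(genos))))
        y = np.array([u[g] for g in design["genotype"]]) + rng.normal(0, 1.0, len(design))
        bt = mm.fit_blup(y, design)
        assert abs(bt.blups.sum()) < 1e-6 * len(y) * np.std(y)
        means = pd.Series(y, index=design["genotype"]).groupby(level=0).mean()
        assert bt.blups.var() <= means.var()

    def test_recovery_improves_with_h2(self, design):
        rng = np.random.default_rng(2)
        genos = sorted(design["genotype"].unique())
        cors = []
        for h2 in (0.2, 0.5, 0.8):
            vg = (1.0 / 6) * h2 / (1 - h2)
            u = rng.normal(0, np.sqrt(vg), len(genos))
            umap = dict(zip(genos, u))
            y = np.array([umap[g] for g in design["genotype"]]) + rng.normal(0, 1, len(design))
            bt = mm.fit_blup(y, design)
            cors.append(np.corrcoef(bt.blups.loc[genos], u)[0, 1])
        assert cors[0] < cors[1] < cors[2]

    def test_single_genotype_raises(self):
        d = pd.DataFrame({
            "genotype": ["g1"] * 6, "block": ["b"] * 6,
            "split_plot": ["sp"] * 6, "split_plot_block": ["spb"] * 6,
        })
        with pytest.raises(ValueError, match="genotype"):
            mm.fit_blup(np.arange(6.0), d)

    def test_aliased_factor_raises(self):
        d = pd.DataFrame({
            "genotype": ["g1"] * 3 + ["g2"] * 3,
            "block": ["b1"] * 3 + ["b2"] * 3,
            "split_plot": ["sp"] * 6, "split_plot_block": ["spb"] * 6,
        })
        with pytest.raises(ValueError, match="aliases"):
            mm.fit_blup(np.arange(6.0), d)


class TestKinshipPca:
    def test_duplicated_individuals(self, small_geno):
        ids = list(small_geno.individual_ids[:30]) + [small_geno.individual_ids[0]]
        dup = small_geno.subset_individuals(ids)
        K = mm.grm(dup).values.to_numpy()
        assert K[0, 30] == pytest.approx(K[0, 0], abs=1e-10)
        assert K[30, 30] == pytest.approx(K[0, 0], abs=1e-10)

    def test_mean_diagonal_near_one(self, small_geno):
        K = mm.grm(small_geno).values.to_numpy()
        assert np.diag(K).mean() == pytest.approx(1.0, abs=0.05)

    def test_pca_separates_subpopulations(self):
        rng = np.random.default_rng(9)
        p1 = rng.uniform(0.1, 0.5, 400)
        p2 = np.clip(p1 + rng.normal(0, 0.2, 400), 0.02, 0.98)
        X1 = rng.binomial(2, p1, size=(60, 400)).astype(float)
        X2 = rng.binomial(2, p2, size=(60, 400)).astype(float)
        from rhizoqg.io_formats import _reorient_minor
        sm = pd.DataFrame({
            "chrom": "1", "pos": np.arange(1, 401) * 100,
            "allele_major": "A", "allele_minor": "B", "maf": 0.25,
        })
        g = _reorient_minor(np.vstack([X1, X2]), sm,
                            pd.Index([f"i{k}" for k in range(120)]))
        pcs = mm.genotype_pca(g, 2)
        lab = np.r_[np.zeros(60), np.ones(60)]
        r = np.corrcoef(pcs.iloc[:, 0], lab)[0, 1]
        assert abs(r) > 0.9

    def test_k_too_large(self, small_geno):
        with pytest.raises(ValueError, match="n-1"):
            mm.genotype_pca(small_geno, small_geno.n_individuals)
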