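import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rhizoqg import gwas, mixed_models as mm, synthetic
from rhizoqg.io_formats import GeneAnnotation
from tests.test_architecture import make_geno


@pytest.fixture(scope="module")
def geno():
    return synthetic.simulate_genotypes(200, 400, ld_rho=0.3, block_len=20,
                                        seed=40, n_chrom=2)


def identity_kinship(ids):
    return mm.KinshipMatrix(
        pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids), "identity"
    )


class TestLmmGwas:
    def test_identity_kinship_equals_ols(self, geno):
        rng = np.random.default_rng(0)
        y = pd.Series(rng.normal(size=200), index=geno.individual_ids)
        res = gwas.lmm_gwas(y, geno, identity_kinship(geno.individual_ids), n_pcs=0)
        X = geno.imputed()
        X = X - X.mean(axis=0)
        yc = y.to_numpy() - y.to_numpy().mean()
        for j in range(0, 400, 37):
            x = X[:, j]
            b = (x @ yc) / (x @ x)
            r = yc - b * x
            s2 = (r @ r) / (200 - 2)
            t = b / np.sqrt(s2 / (x @ x))
            p_ols = 2 * stats.t.sf(abs(t), 200 - 2)
            assert res.table.loc[j, "p"] == pytest.approx(p_ols, abs=1e-8)

    def test_p3d_and_exact_agree(self, geno):
        rng = np.random.default_rng(1)
        K = mm.grm(geno)
        u = rng.multivariate_normal(np.zeros(200), 0.5 * K.values.to_numpy())
        y = pd.Series(u + rng.normal(0, 1, 200), index=geno.individual_ids)
        sub = geno.subset_snps(np.arange(geno.n_snps) < 120)
        r_p3d = gwas.lmm_gwas(y, sub, K, n_pcs=3, mode="p3d")
        r_ex = gwas.lmm_gwas(y, sub, K, n_pcs=3, mode="exact")
        d = np.abs(r_p3d.table["neglog10p"] - r_ex.table["neglog10p"])
        assert (d <= 0.2).mean() >= 0.99

    def test_structured_null_is_calibrated(self):
        # single-replicate genomic-control lambda is noisy (median over
        # correlated SNPs), so calibration is asserted on the mean
        lams, lams_ols = [], []
        for seed in range(4):
            rng = np.random.default_rng(100 + seed)
            p1 = rng.uniform(0.1, 0.5, 800)
            p2 = np.clip(p1 + rng.normal(0, 0.15, 800), 0.02, 0.98)
            X = np.vstack([
                rng.binomial(2, p1, size=(100, 800)),
                rng.binomial(2, p2, size=(100, 800)),
            ]).astype(float)
            g = make_geno(X)
            K = mm.grm(g)
            u = rng.multivariate_normal(np.zeros(200), 0.8 * K.values.to_numpy())
            y = pd.Series(u + rng.normal(0, 1, 200), index=g.individual_ids)
            res = gwas.lmm_gwas(y, g, K, n_pcs=3)
            lams.append(res.lambda_gc)
            # naive OLS on the same data for contrast
            yc = y.to_numpy() - y.to_numpy().mean()
            Xc = g.imputed() - g.imputed().mean(axis=0)
            chi = []
            for j in range(0, 800, 4):
                x = Xc[:, j]
                b = (x @ yc) / (x @ x)
                r = yc - b * x
                t = b / np.sqrt((r @ r) / 198 / (x @ x))
                chi.append(t ** 2)
            lams_ols.append(np.median(chi) / stats.chi2.isf(0.5, 1))
        assert 0.9 <= np.mean(lams) <= 1.1
        assert np.mean(lams_ols) > 1.2

    def test_planted_causal_snp_is_top_hit(self, geno):
        rng = np.random.default_rng(3)
        X = geno.imputed()
        x = X[:, 123] - X[:, 123].mean()
        g_eff = x / x.std() * np.sqrt(0.2)
        y = pd.Series(g_eff + rng.normal(0, np.sqrt(0.8), 200),
                      index=geno.individual_ids)
        res = gwas.lmm_gwas(y, geno, mm.grm(geno), n_pcs=3)
        assert res.table["neglog10p"].idxmax() == 123

    def test_monomorphic_snp_skipped(self):
        rng = np.random.default_rng(4)
        X = rng.binomial(2, 0.3, size=(50, 5)).astype(float)
        X[:, 2] = 1.0
        g = make_geno(X)
        g.snp_map.loc[2, "maf"] = 0.5  # dosage constant but freq 0.5
        y = pd.Series(rng.normal(size=50), index=g.individual_ids)
        res = gwas.lmm_gwas(y, g, identity_kinship(g.individual_ids), n_pcs=0)
        assert res.n_skipped == 1
        assert np.isnan(res.table.loc[2, "p"])


class TestEffectiveSnpNumber:
    def test_user_supplied_passthrough(self):
        assert gwas.effective_snp_number(None, "user_supplied", meff=769690) == 769690

    def test_independent_snps(self):
        g = synthetic.simulate_genotypes(800, 300, ld_rho=0.0, seed=41)
        meff = gwas.effective_snp_number(g, block_size=100)
        assert meff == pytest.approx(300, rel=0.05)

    def test_duplicated_snps_halved(self):
        # pair-sized blocks make the block spectrum exact ({2, 0} per pair);
        # with larger blocks the integer-bracket eigenvalue summary is
        # noise-sensitive exactly at 2 and counts a duplicated pair as ~1.5
        rng = np.random.default_rng(5)
        X0 = rng.binomial(2, rng.uniform(0.1, 0.5, 100), size=(500, 100)).astype(float)
        X = np.repeat(X0, 2, axis=1)  # each SNP duplicated adjacently
        g = make_geno(X)
        meff = gwas.effective_snp_number(g, block_size=2)
        assert meff == pytest.approx(100, rel=0.10)


class TestSignificanceThreshold:
    def test_genomewide_value_to_reported_precision(self):
        assert round(gwas.significance_threshold(0.05, 769690), 1) == 7.2

    @pytest.mark.parametrize("alpha,meff,expected", [
        (0.05, 1, 1.3010),
        (1.0, 1, 0.0),
    ])
    def test_edge_values(self, alpha, meff, expected):
        assert gwas.significance_threshold(alpha, meff) == pytest.approx(expected, abs=1e-4)


def _fake_result(trait, treatment, hits):
    """GwasResult-like object with significant SNPs at given (chrom, pos)."""
    rows = [{"snp": i, "chrom": c, "pos": p, "maf": 0.2, "beta": 1.0, "se": 0.1,
             "p": 1e-9, "neglog10p": 9.0} for i, (c, p) in enumerate(hits)]
    table = pd.DataFrame(rows, columns=["snp", "chrom", "pos", "maf", "beta",
                                        "se", "p", "neglog10p"])
    return gwas.GwasResult(trait=trait, treatment=treatment, table=table,
                           delta=1.0, lambda_gc=1.0)


class TestCallMapls:
    def test_window_arithmetic(self):
        res = _fake_result("t1", "plusN", [("1", 5), ("1", 9999), ("1", 10000)])
        out = gwas.call_mapls([res], threshold=7.2, min_signals=1)
        assert len(out) == 2
        first = out[out["start"] == 0].iloc[0]
        assert first["n_signals"] == 2
        second = out[out["start"] == 10000].iloc[0]
        assert second["n_signals"] == 1
        strict = gwas.call_mapls([res], threshold=7.2, min_signals=2)
        assert len(strict) == 1 and strict.iloc[0]["start"] == 0

    def test_same_snp_two_traits_counts_twice(self):
        r1 = _fake_result("t1", "plusN", [("2", 55555)])
        r2 = _fake_result("t2", "minusN", [("2", 55555)])
        out = gwas.call_mapls([r1, r2], threshold=7.2)
        assert len(out) == 1
        assert out.iloc[0]["n_signals"] == 2
        assert out.iloc[0]["traits"] == "t1;t2"

    def test_empty_when_nothing_significant(self):
        res = _fake_result("t1", "plusN", [])
        out = gwas.call_mapls([res], threshold=7.2)
        assert len(out) == 0

    def test_order_invariance(self):
        rng = np.random.default_rng(6)
        results = [
            _fake_result(f"t{i}", "plusN",
                         [("1", int(p)) for p in rng.integers(1, 100000, 5)])
            for i in range(4)
        ]
        a = gwas.call_mapls(results, threshold=7.2)
        b = gwas.call_mapls(results[::-1], threshold=7.2)
        pd.testing.assert_frame_equal(a, b)

    def test_matches_brute_force_window_tally(self):
        rng = np.random.default_rng(7)
        hits = [("1", int(p)) for p in rng.integers(1, 200000, 40)]
        res = _fake_result("t1", "plusN", hits)
        out = gwas.call_mapls([res], window_bp=10000, threshold=7.2)
        from collections import Counter
        expected = Counter(p // 10000 for _, p in hits)
        got = dict(zip(out["window"], out["n_signals"]))
        assert got == dict(expected)


class TestAnnotateGenes:
    def _ann(self, rows):
        return GeneAnnotation(pd.DataFrame(
            rows, columns=["gene_id", "chrom", "start", "end", "strand"]))

    def test_contained_and_boundary(self):
        ann = self._ann([
            ("gA", "1", 1, 100, "+"),         # inside flank
            ("gB", "1", 15000, 25000, "+"),   # crosses the flank boundary
        ])
        mapls = pd.DataFrame([{"chrom": "1", "window": 0, "start": 0,
                               "end": 10000, "n_signals": 2}])
        out = gwas.annotate_genes(mapls, ann, flank=10000)
        assert out.iloc[0]["genes"] == "gA"
        assert out.iloc[0]["n_genes"] == 1

    def test_matches_brute_force_interval_check(self):
        rng = np.random.default_rng(8)
        genes = [(f"g{i}", "1", int(s), int(s + rng.integers(100, 30000)), "+")
                 for i, s in enumerate(rng.integers(1, 300000, 30))]
        ann = self._ann(genes)
        mapls = pd.DataFrame([
            {"chrom": "1", "window": k, "start": k * 10000,
             "end": (k + 1) * 10000, "n_signals": 1}
            for k in (0, 7, 19)
        ])
        out = gwas.annotate_genes(mapls, ann, flank=10000)
        for _, row in out.iterrows():
            lo, hi = row["start"] - 10000 + 1, row["end"] + 10000
            expect = sorted(g for g, _, s, e, _ in genes if s >= lo and e <= hi)
            got = sorted(row["genes"].split(";")) if row["genes"] else []
            assert got == expect

    def test_chrom_mismatch_warns(self, caplog):
        ann = self._ann([("gA", "chr1", 1, 100, "+")])
        mapls = pd.DataFrame([{"chrom": "1", "window": 0, "start": 0,
                               "end": 10000, "n_signals": 1}])
        with caplog.at_level("WARNING"):
            out = gwas.annotate_genes(mapls, ann)
        assert "no shared chromosome" in caplog.text
        assert out.iloc[0]["n_genes"] == 0


class TestAlleleStratification:
    def test_monomorphic_raises(self):
        X = np.zeros((20, 1))
        X[0, 0] = 1  # polymorphic overall
        g = make_geno(X + 0.0)
        vals = pd.Series(np.arange(10.0), index=g.individual_ids[:10])
        with pytest.raises(ValueError, match="monomorphic"):
            gwas.allele_stratified_comparison(g, 0, vals.iloc[1:])

    def test_planted_allele_effect_detected(self):
        rng = np.random.default_rng(9)
        X = rng.binomial(2, 0.3, size=(200, 3)).astype(float)
        g = make_geno(X)
        shift = (X[:, 1] > 0).astype(float)
        vals = pd.DataFrame({
            "trait": shift * 1.0 + rng.normal(0, 1, 200),
            "CC": rng.normal(50, 5, 200),
        }, index=g.individual_ids)
        out = gwas.allele_stratified_comparison(g, 1, vals)
        assert out.loc["trait", "p"] < 0.01
        assert out.loc["trait", "mean_minor"] > out.loc["trait", "mean_major"]
        assert out.loc["CC", "p"] > 0.01

    def test_small_group_suppresses_p(self):
        X = np.zeros((30, 1))
        X[:2, 0] = 2.0
        g = make_geno(X)
        vals = pd.Series(np.random.default_rng(10).normal(size=30),
                         index=g.individual_ids)
        out = gwas.allele_stratified_comparison(g, 0, vals)
        assert np.isnan(out.loc["w", "p"]) if "w" in out.index else np.isnan(out.iloc[0]["p"])
        assert np.isfinite(out.iloc[0]["mean_major"])
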