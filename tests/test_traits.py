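import numpy as np
import pandas as pd
import pytest

from rhizoqg import traits
from rhizoqg.io_formats import TAXONOMY_RANKS
from tests.conftest import make_table


class TestFilterAsvs:
    def test_zero_thresholds_identity(self):
        t = make_table(np.arange(1, 13).reshape(3, 4))
        out = traits.filter_asvs(t, 0.0, 0.0)
        assert list(out.asv_ids) == list(t.asv_ids)

    def test_year_specific_asv_removed(self):
        counts = np.array([[5, 10], [6, 12], [0, 9], [0, 11]])
        t = make_table(counts, years=[2018, 2018, 2019, 2019])
        out = traits.filter_asvs(t, min_mean_rel_abund=1e-6, min_prevalence=0.5)
        assert list(out.asv_ids) == ["a1"]

    def test_all_removed_raises(self):
        t = make_table(np.ones((3, 2)))
        with pytest.raises(ValueError, match="all ASVs removed"):
            traits.filter_asvs(t, min_mean_rel_abund=0.99, min_prevalence=1.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(0, 30, size=(12, 6))
        counts[rng.random((12, 6)) < 0.4] = 0
        years = [2018] * 6 + [2019] * 6
        t = make_table(counts, years=years)
        thr_a, thr_p = 0.02, 0.4
        out = traits.filter_asvs(t, thr_a, thr_p)
        rel = counts / counts.sum(axis=1, keepdims=True)
        expected = []
        for j, asv in enumerate(t.asv_ids):
            ok = True
            for rows in (slice(0, 6), slice(6, 12)):
                ok &= rel[rows, j].mean() >= thr_a
                ok &= (counts[rows, j] > 0).mean() >= thr_p
            if ok:
                expected.append(asv)
        assert list(out.asv_ids) == expected


def _tax(rows):
    df = pd.DataFrame(rows).set_index("asv")
    for r in TAXONOMY_RANKS:
        if r not in df.columns:
            df[r] = "Unknown"
    return df[list(TAXONOMY_RANKS)]


class TestClusterAsvs:
    def test_two_genera_two_groups(self):
        tax = _tax([
            {"asv": "a0", "family": "F1", "genus": "GenA"},
            {"asv": "a1", "family": "F1", "genus": "GenA"},
            {"asv": "a2", "family": "F2", "genus": "GenB"},
        ])
        t = make_table(np.ones((4, 3)), taxonomy=tax)
        gm = traits.cluster_asvs(t)
        assert gm.nunique() == 2
        assert gm["a0"] == gm["a1"] == "GenA"

    def test_unknown_genus_falls_back_to_family(self):
        tax = _tax([
            {"asv": "a0", "family": "Comamonadaceae", "genus": "Unknown"},
            {"asv": "a1", "family": "Unknown", "genus": "Unknown"},
        ])
        t = make_table(np.ones((4, 2)), taxonomy=tax)
        gm = traits.cluster_asvs(t)
        assert gm["a0"] == "f_Comamonadaceae Unknown Genus"
        assert gm["a1"] == "Unclassified"

    def test_opposite_response_splits_group(self):
        rng = np.random.default_rng(3)
        n = 60
        treat = ["plusN"] * (n // 2) + ["minusN"] * (n // 2)
        base = rng.integers(50, 100, size=(n, 3))
        base[: n // 2, 0] *= 8       # a0 up in +N
        base[n // 2:, 1] *= 8        # a1 up in -N
        tax = _tax([
            {"asv": f"a{j}", "family": "F1", "genus": "GenA"} for j in range(3)
        ])
        t = make_table(base, treatments=treat, taxonomy=tax)
        gm = traits.cluster_asvs(t, split_by_n_response=True, p_split=0.05)
        assert gm["a0"] != gm["a1"]
        assert gm["a0"].startswith("GenA ")
        gm_nosplit = traits.cluster_asvs(t, split_by_n_response=False)
        assert gm_nosplit.nunique() == 1

    def test_generator_round_trip(self, small_sim):
        table, truth = small_sim["table"], small_sim["truth"]
        gm = traits.cluster_asvs(table)
        # recovered grouping must induce the same partition as the truth
        joint = pd.DataFrame({"est": gm, "true": truth.group_map})
        assert joint.groupby("true")["est"].nunique().max() == 1
        assert joint.groupby("est")["true"].nunique().max() == 1


class TestTransformAbundance:
    def test_hand_values(self):
        counts = np.array([[99, 1], [0, 10]])
        tax = _tax([
            {"asv": "a0", "genus": "GenA", "family": "F"},
            {"asv": "a1", "genus": "GenB", "family": "F"},
        ])
        t = make_table(counts, taxonomy=tax)
        gm = traits.cluster_asvs(t)
        out = traits.transform_abundance(t, gm, pseudocount=1)
        # group GenA in sample 0: ln((99+1)/100) = 0
        assert out.values.loc["s0", "GenA"] == pytest.approx(0.0)
        # zero count: ln((0+1)/10)
        assert out.values.loc["s1", "GenA"] == pytest.approx(np.log(1 / 10))
        assert out.values.loc["s1", "GenB"] == pytest.approx(np.log(11 / 10))

    def test_zero_total_sample_dropped(self, caplog):
        counts = np.array([[5, 5], [0, 0]])
        t = make_table(counts)
        gm = traits.cluster_asvs(t)
        with caplog.at_level("WARNING"):
            out = traits.transform_abundance(t, gm)
        assert list(out.values.index) == ["s0"]

    def test_count_conservation(self, small_sim):
        table = small_sim["table"]
        gm = small_sim["truth"].group_map
        out = traits.transform_abundance(table, gm, pseudocount=1)
        totals = table.counts.sum(axis=1).loc[out.values.index]
        recovered = (np.exp(out.values)).mul(totals, axis=0).sum(axis=1)
        n_groups = out.values.shape[1]
        assert (np.abs(recovered - totals) <= n_groups + 1e-6).all()


class TestDifferentialAbundance:
    def test_identical_distributions_ns(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"),
                            index=[f"s{i}" for i in range(40)])
        meta = pd.DataFrame({"treatment": ["plusN", "minusN"] * 20},
                            index=vals.index)
        gtm = traits.GroupTraitMatrix(
            values=vals, group_map=pd.Series(dtype=object),
            group_meta=pd.DataFrame(index=list("abc")),
        )
        # a constant column exercises the degenerate branch
        gtm.values["c"] = 1.0
        out = traits.differential_abundance(gtm, meta)
        assert out.loc["c", "n_response"] == "ns"
        assert out.loc["c", "degenerate"]

    def test_injected_shift_detected(self):
        rng = np.random.default_rng(1)
        n = 600
        treat = ["plusN"] * n + ["minusN"] * n
        vals = pd.DataFrame({
            "shifted": np.r_[rng.normal(2, 1, n), rng.normal(0, 1, n)],
            "flat": rng.normal(0, 1, 2 * n),
        }, index=[f"s{i}" for i in range(2 * n)])
        meta = pd.DataFrame({"treatment": treat}, index=vals.index)
        gtm = traits.GroupTraitMatrix(values=vals, group_map=pd.Series(dtype=object),
                                      group_meta=pd.DataFrame())
        out = traits.differential_abundance(gtm, meta)
        assert out.loc["shifted", "n_response"] == "plusN_enriched"
        assert out.loc["shifted", "p"] < 1e-10

    def test_null_type_one_error(self):
        rng = np.random.default_rng(2)
        n_groups = 400
        vals = pd.DataFrame(rng.normal(size=(200, n_groups)),
                            index=[f"s{i}" for i in range(200)])
        vals.columns = [f"g{j}" for j in range(n_groups)]
        meta = pd.DataFrame({"treatment": ["plusN", "minusN"] * 100}, index=vals.index)
        gtm = traits.GroupTraitMatrix(values=vals, group_map=pd.Series(dtype=object),
                                      group_meta=pd.DataFrame())
        out = traits.differential_abundance(gtm, meta)
        frac_sig = (out["p"] < 0.05).mean()
        assert frac_sig == pytest.approx(0.05, abs=0.03)

    def test_missing_treatment_level_raises(self):
        vals = pd.DataFrame({"a": [1.0, 2.0]}, index=["s0", "s1"])
        meta = pd.DataFrame({"treatment": ["plusN", "plusN"]}, index=vals.index)
        gtm = traits.GroupTraitMatrix(values=vals, group_map=pd.Series(dtype=object),
                                      group_meta=pd.DataFrame())
        with pytest.raises(ValueError, match="treatment"):
            traits.differential_abundance(gtm, meta)
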