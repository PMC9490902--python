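"""LOF curation, differentiation testing and the deleteriousness ratio."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from admixkit import lof
from admixkit import synthgen as sg
from admixkit.core import GenotypeMatrix


def make_matrix(calls):
    calls = np.asarray(calls, dtype=np.int8)
    n, l = calls.shape
    variants = pd.DataFrame({
        "chrom": ["1"] * l, "pos": np.arange(1, l + 1) * 1000,
        "id": [f"v{j}" for j in range(l)], "ref": ["A"] * l, "alt": ["G"] * l})
    return GenotypeMatrix(calls, [f"s{i}" for i in range(n)], variants)


def make_ann(ids, stop=(), curated=(), cadd=None, traits=None):
    return pd.DataFrame({
        "id": list(ids),
        "consequence": ["stop_gained" if i in stop else "intron_variant"
                        for i in ids],
        "cadd": [cadd.get(i, 10.0) if cadd else 10.0 for i in ids],
        "curated_lof": [i in curated for i in ids],
        "traits": [traits.get(i, "") if traits else "" for i in ids]})


class TestCurate:
    def test_union_and_dedup(self):
        ann = make_ann(["a", "b", "c", "d"], stop={"b", "c"}, curated={"a", "b"})
        assert lof.curate_lof(ann) == ["a", "b", "c"]

    def test_empty(self):
        ann = make_ann(["a", "b"])
        assert lof.curate_lof(ann) == []

    def test_restricted_to_genotyped(self):
        ann = make_ann(["a", "b"], stop={"a", "b"})
        assert lof.curate_lof(ann, genotyped_ids=["b"]) == ["b"]

    def test_fixture_of_97(self):
        ids = [f"v{i}" for i in range(500)]
        stop = set(ids[:60])
        curated = set(ids[40:97])  # overlap of 20 with the stop set
        ann = make_ann(ids, stop=stop, curated=curated)
        assert len(lof.curate_lof(ann)) == 97


class TestAllelicChi2:
    def test_equal_frequencies_null(self):
        chi2, p = lof.allelic_chi2(30, 30, 50, 50)
        assert chi2 == 0.0 and p == 1.0

    def test_hand_computed_table(self):
        # cluster (30 A, 10 a) vs rest (20 A, 40 a):
        # chi2 = 100*(30*40-10*20)^2 / (40*60*50*50) = 50/3
        chi2, p = lof.allelic_chi2(30, 10, 20, 40)
        assert chi2 == pytest.approx(50 / 3)
        assert p == pytest.approx(stats.chi2.sf(50 / 3, 1))

    def test_zero_margin(self):
        assert lof.allelic_chi2(0, 10, 0, 20) == (0.0, 1.0)

    def test_matches_fisher_ordering(self):
        # p-value ordering agrees with an exact-test oracle when all
        # expected counts are >= 5
        rng = np.random.default_rng(0)
        ps_chi, ps_fisher = [], []
        while len(ps_chi) < 40:
            a, b, c, d = rng.integers(5, 60, size=4)
            n = a + b + c + d
            exp_min = min((a + b) * (a + c), (a + b) * (b + d),
                          (c + d) * (a + c), (c + d) * (b + d)) / n
            if exp_min < 5:
                continue
            ps_chi.append(lof.allelic_chi2(a, b, c, d)[1])
            ps_fisher.append(stats.fisher_exact([[a, b], [c, d]])[1])
        rho = stats.spearmanr(ps_chi, ps_fisher).statistic
        assert rho > 0.99


class TestClusterDifferentiation:
    def engineered(self):
        rng = np.random.default_rng(1)
        n_per, L = 50, 97
        calls = rng.binomial(2, 0.3, size=(4 * n_per, L)).astype(np.int8)
        # variant v0: AF 0.5 in cluster A, absent elsewhere
        calls[:, 0] = 0
        calls[:n_per, 0] = rng.binomial(2, 0.5, size=n_per)
        clusters = np.repeat(list("ABCD"), n_per)
        return make_matrix(calls), clusters

    def test_private_allele_bonferroni_significant(self):
        G, clusters = self.engineered()
        lof_set = list(G.variants["id"])
        rec = lof.cluster_differentiation(G, clusters, lof_set)
        assert rec.attrs["n_tests"] == 97 * 4
        hit = rec[(rec["id"] == "v0") & (rec["cluster"] == "A")]
        assert hit["significant"].iloc[0]
        assert hit["af_cluster"].iloc[0] > 0.35
        assert hit["af_rest"].iloc[0] == 0.0

    def test_monomorphic_flagged(self):
        calls = np.zeros((40, 3), dtype=np.int8)
        rec = lof.cluster_differentiation(
            make_matrix(calls), ["A"] * 20 + ["B"] * 20, ["v0", "v1", "v2"])
        assert rec["monomorphic"].all()
        assert (rec["p"] == 1.0).all()

    def test_top_differentiated(self):
        G, clusters = self.engineered()
        rec = lof.cluster_differentiation(G, clusters, list(G.variants["id"]))
        top = lof.top_differentiated(rec, n=5)
        assert (top.groupby("cluster").size() == 5).all()


class TestDeleteriousnessRatio:
    def test_uniform_af_gives_one(self):
        df = pd.DataFrame({"cluster": ["A"] * 6 + ["B"] * 6,
                           "cadd": [30, 40, 50, 1, 2, 3] * 2,
                           "af": 0.1})
        for r in lof.deleteriousness_ratio(df):
            assert r.ratio == pytest.approx(1.0)

    def test_median_arithmetic(self):
        df = pd.DataFrame({"cluster": "A",
                           "cadd": [30, 35, 40, 1, 2, 3],
                           "af": [0.01, 0.02, 0.03, 0.1, 0.2, 0.3]})
        (r,) = lof.deleteriousness_ratio(df)
        assert r.ratio == pytest.approx(0.02 / 0.2)

    def test_invariant_to_mid_score_variants(self):
        base = pd.DataFrame({"cluster": "A",
                             "cadd": [30.0, 2.0], "af": [0.05, 0.2]})
        extra = pd.concat([base, pd.DataFrame(
            {"cluster": "A", "cadd": [10.0, 15.0, 20.0], "af": [0.9, 0.8, 0.7]})])
        (r1,) = lof.deleteriousness_ratio(base)
        (r2,) = lof.deleteriousness_ratio(extra)
        assert r1.ratio == r2.ratio

    def test_empty_bin_and_zero_median_flagged(self):
        no_low = pd.DataFrame({"cluster": "A", "cadd": [30.0], "af": [0.1]})
        (r,) = lof.deleteriousness_ratio(no_low)
        assert r.flag == "empty_bin" and np.isnan(r.ratio)
        zero_low = pd.DataFrame({"cluster": "A", "cadd": [30.0, 2.0],
                                 "af": [0.1, 0.0]})
        (r,) = lof.deleteriousness_ratio(zero_low)
        assert r.flag == "zero_low_median" and np.isinf(r.ratio)


class TestGenotypeByCluster:
    def test_identical_distributions_null(self):
        block = np.array([0] * 5 + [1] * 10 + [2] * 5, dtype=np.int8)
        calls = np.concatenate([block, block])[:, None]
        G = make_matrix(calls)
        clusters = ["A"] * 20 + ["B"] * 20
        table, chi2, p, dof, warn = lof.genotype_by_cluster("v0", G, clusters)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_opposite_fixation_significant(self):
        calls = np.array([0] * 25 + [2] * 25, dtype=np.int8)[:, None]
        G = make_matrix(calls)
        clusters = ["A"] * 25 + ["B"] * 25
        table, chi2, p, dof, warn = lof.genotype_by_cluster("v0", G, clusters)
        assert p < 1e-10

    def test_bookkeeping(self):
        rng = np.random.default_rng(2)
        calls = rng.choice([0, 1, 2], size=(60, 1)).astype(np.int8)
        G = make_matrix(calls)
        clusters = np.repeat(list("ABC"), 20)
        table, *_ = lof.genotype_by_cluster("v0", G, clusters)
        assert (table.sum(axis=0) == 20).all()
        assert table.to_numpy().sum() == 60

    def test_absent_variant_rejected(self):
        G = make_matrix(np.zeros((4, 2)))
        with pytest.raises(KeyError):
            lof.genotype_by_cluster("nope", G, ["A", "A", "B", "B"])
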