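"""nSL scan correctness (hand example + brute-force oracle), normalization,
candidate calling and the shared/private partition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from admixkit import selection
from admixkit.core import HaplotypeSet
from admixkit.synthgen import uniform_variant_table

from conftest import neutral_haplotypes


def hapset(hap):
    hap = np.asarray(hap, dtype=np.int8)
    v, _ = uniform_variant_table(hap.shape[1])
    samples = [f"S{i}" for i in range(hap.shape[0] // 2)]
    return HaplotypeSet(hap, samples, v)


class TestScan:
    def test_hand_example(self):
        # focal SNP index 2: derived pair identical over SNPs 1-4 (L=4),
        # ancestral pair identical over SNPs 3-5 only (L=3)
        H = hapset([[0, 0, 1, 0, 0],
                    [0, 0, 1, 0, 1],
                    [0, 0, 0, 1, 1],
                    [0, 1, 0, 1, 1]])
        scores = selection.nsl_scan(H, maf_min=0.05).set_index("id")
        row = scores.loc["rs1_2"]
        assert row["sl_d"] == 4
        assert row["sl_a"] == 3
        assert row["nsl_raw"] == pytest.approx(np.log(3 / 4))

    def test_identical_background_gives_zero(self):
        # all haplotypes identical outside the focal SNP
        base = np.tile([0, 1, 0, 1, 1, 0], (6, 1))
        base[:3, 2] = 1
        base[3:, 2] = 0
        scores = selection.nsl_scan(hapset(base), maf_min=0.05)
        row = scores.set_index("id").loc["rs1_2"]
        assert row["sl_a"] == row["sl_d"] == 6
        assert row["nsl_raw"] == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 15)) * 2
        L = int(rng.integers(20, 60))
        H = neutral_haplotypes(n_hap=n, L=L, seed=seed + 100)
        fast = selection.nsl_scan(H, maf_min=0.05)
        slow = selection.nsl_brute_force(H, maf_min=0.05)
        pd.testing.assert_frame_equal(fast, slow)

    def test_haplotype_order_invariance(self):
        H = neutral_haplotypes(n_hap=12, L=80, seed=5)
        a = selection.nsl_scan(H)
        perm = np.random.default_rng(6).permutation(12)
        Hp = HaplotypeSet(H.haplotypes[perm], H.samples, H.variants.copy())
        b = selection.nsl_scan(Hp)
        pd.testing.assert_frame_equal(a, b)

    def test_focal_label_flip_negates_score(self):
        H = neutral_haplotypes(n_hap=16, L=60, seed=7)
        a = selection.nsl_scan(H, maf_min=0.05).set_index("id")
        x = 30
        flipped = H.haplotypes.copy()
        flipped[:, x] = 1 - flipped[:, x]
        b = selection.nsl_scan(
            HaplotypeSet(flipped, H.samples, H.variants.copy()),
            maf_min=0.05).set_index("id")
        vid = H.variants.at[x, "id"]
        if vid in a.index and vid in b.index:
            assert b.loc[vid, "nsl_raw"] == pytest.approx(-a.loc[vid, "nsl_raw"])
            assert b.loc[vid, "sl_a"] == a.loc[vid, "sl_d"]

    def test_skips_rare_and_monoclass_snps(self):
        hap = np.zeros((8, 5), dtype=np.int8)
        hap[0, 2] = 1   # daf 1/8 < 0.2
        scores = selection.nsl_scan(hapset(hap), maf_min=0.2)
        assert len(scores) == 0


class TestNormalize:
    def test_bins_are_standardized(self):
        H = neutral_haplotypes(n_hap=40, L=600, seed=9)
        scores = selection.nsl_scan(H)
        z = selection.normalize_nsl(scores, n_bins=10)
        for b, sub in z.dropna(subset=["nsl_std"]).groupby("bin"):
            assert abs(sub["nsl_std"].mean()) < 1e-9
            assert abs(sub["nsl_std"].std(ddof=0) - 1) < 1e-9

    def test_single_bin_equals_global_zscore(self):
        H = neutral_haplotypes(n_hap=20, L=200, seed=10)
        scores = selection.nsl_scan(H)
        z = selection.normalize_nsl(scores, n_bins=1)
        raw = scores["nsl_raw"].to_numpy()
        expect = (raw - raw.mean()) / raw.std()
        assert np.allclose(z["nsl_std"].to_numpy(), expect)

    def test_too_few_scores_rejected(self):
        H = neutral_haplotypes(n_hap=10, L=30, seed=11)
        scores = selection.nsl_scan(H)
        with pytest.raises(ValueError):
            selection.normalize_nsl(scores, n_bins=len(scores) + 1)

    def test_zero_variance_bin_flagged(self):
        scores = pd.DataFrame({
            "id": [f"v{i}" for i in range(6)],
            "chrom": ["1"] * 6, "pos": range(6),
            "daf": [0.1, 0.12, 0.9, 0.91, 0.92, 0.93],
            "sl_a": 1.0, "sl_d": 1.0,
            "nsl_raw": [0.5, 0.5, 0.1, 0.2, 0.3, 0.4]})
        z = selection.normalize_nsl(scores, n_bins=2)
        low = z[z["daf"] < 0.5]
        assert low["flagged"].all()
        assert not z[z["daf"] > 0.5]["flagged"].any()


def engineer_sweep(seed, n_hap=40, L=1000, focal=500, span=60, daf=0.4):
    """Neutral background plus one swept variant: derived carriers share an
    identical haplotype over ``span`` SNPs around the focal site.  Returns
    the untouched neutral cohort, the swept cohort, and the swept id."""
    H0 = neutral_haplotypes(n_hap=n_hap, L=L, seed=seed)
    hap = H0.haplotypes.copy()
    rng = np.random.default_rng(seed + 999)
    carriers = rng.choice(n_hap, size=int(daf * n_hap), replace=False)
    hap[:, focal] = 0
    lo, hi = focal - span // 2, focal + span // 2
    hap[carriers, lo:hi] = hap[carriers[0], lo:hi]
    hap[carriers, focal] = 1
    H1 = HaplotypeSet(hap, H0.samples, H0.variants.copy())
    return H0, H1, H0.variants.at[focal, "id"]


class TestCandidates:
    def make_ann(self, ids, traited):
        return pd.DataFrame({
            "id": list(ids),
            "consequence": ["intron_variant"] * len(ids),
            "cadd": [1.0] * len(ids),
            "curated_lof": [False] * len(ids),
            "traits": ["HDL" if i in traited else "" for i in ids]})

    def test_sweep_variant_called(self):
        _, H, swept = engineer_sweep(seed=21)
        scores = selection.normalize_nsl(selection.nsl_scan(H), n_bins=20)
        ann = self.make_ann(scores["id"], {swept})
        cs = selection.call_candidates(scores, ann, cluster="c1")
        assert swept in cs.variants

    def test_empty_annotations_empty_set(self):
        _, H, _ = engineer_sweep(seed=22)
        scores = selection.normalize_nsl(selection.nsl_scan(H), n_bins=20)
        cs = selection.call_candidates(scores, self.make_ann(scores["id"], set()))
        assert cs.variants == set()

    def test_percentile_100_at_most_one(self):
        _, H, _ = engineer_sweep(seed=23)
        scores = selection.normalize_nsl(selection.nsl_scan(H), n_bins=20)
        ann = self.make_ann(scores["id"], set(scores["id"]))
        cs = selection.call_candidates(scores, ann, percentile=100)
        assert len(cs.variants) <= 1

    def test_sweep_exceeds_neutral_99th_percentile(self):
        # enrichment across seeded replicates, against the matched neutral
        # cohort's |nsl_std| distribution
        hits = 0
        for seed in range(20):
            H0, H1, swept = engineer_sweep(seed=300 + seed)
            neutral = selection.normalize_nsl(selection.nsl_scan(H0), n_bins=20)
            cut = np.percentile(neutral["nsl_std"].abs().dropna(), 99)
            scores = selection.normalize_nsl(selection.nsl_scan(H1), n_bins=20)
            row = scores[scores["id"] == swept]
            if len(row) and abs(row["nsl_std"].iloc[0]) >= cut:
                hits += 1
        assert hits >= 18


class TestPartition:
    def cs(self, cluster, ids):
        return selection.CandidateSet(cluster=cluster, variants=set(ids),
                                      traits={i: "t" for i in ids})

    def test_identical_sets_all_shared(self):
        sets = [self.cs(c, ["a", "b"]) for c in "xyz"]
        cells, shared = selection.shared_private_partition(sets)
        assert cells == {frozenset("xyz"): 2}
        assert len(shared) == 2

    def test_disjoint_sets_all_private(self):
        sets = [self.cs("x", ["a"]), self.cs("y", ["b"])]
        cells, shared = selection.shared_private_partition(sets)
        assert cells == {frozenset("x"): 1, frozenset("y"): 1}
        assert shared.empty
        priv = selection.private_by_trait(sets)
        assert len(priv) == 2

    @given(st.lists(st.sets(st.sampled_from("abcdefgh")), min_size=2,
                    max_size=4))
    @settings(max_examples=40, derandomize=True)
    def test_cell_counts_sum_to_union(self, idsets):
        sets = [self.cs(f"c{i}", ids) for i, ids in enumerate(idsets)]
        cells, _ = selection.shared_private_partition(sets)
        union = set().union(*(s.variants for s in sets))
        assert sum(cells.values()) == len(union)
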