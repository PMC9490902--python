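"""QC filter semantics: het outliers, call rate, exact HWE, relatedness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

from admixkit import qc
from admixkit.core import GenotypeMatrix

from conftest import build_cohort


def make_matrix(calls, phased=False):
    calls = np.asarray(calls, dtype=np.int8)
    n, l = calls.shape
    variants = pd.DataFrame({
        "chrom": ["1"] * l, "pos": np.arange(1, l + 1) * 1000,
        "id": [f"v{j}" for j in range(l)], "ref": ["A"] * l, "alt": ["G"] * l})
    return GenotypeMatrix(calls, [f"s{i}" for i in range(n)], variants, phased)


def hwe_enumeration(n_AA, n_Aa, n_aa):
    """Independent oracle: full enumeration over heterozygote counts
    compatible with the observed allele counts, with exact multinomial
    probabilities in log space."""
    n = n_AA + n_Aa + n_aa
    nA = 2 * n_AA + n_Aa
    na = 2 * n_aa + n_Aa
    hets = range(nA % 2, min(nA, na) + 1, 2)
    logprobs = {}
    for het in hets:
        aa = (na - het) // 2
        AA = n - het - aa
        lp = (gammaln(n + 1) - gammaln(AA + 1) - gammaln(het + 1)
              - gammaln(aa + 1) + het * np.log(2)
              - (gammaln(2 * n + 1) - gammaln(nA + 1) - gammaln(na + 1)))
        logprobs[het] = lp
    p_obs = logprobs[n_Aa]
    total = sum(np.exp(lp) for lp in logprobs.values())  # ~1, guards rounding
    return min(1.0, sum(np.exp(lp) for lp in logprobs.values()
                        if lp <= p_obs + 1e-9) / total)


class TestHetOutliers:
    def test_single_hot_site_flagged(self):
        rng = np.random.default_rng(0)
        # 20 sites with het rate near 0.3, one at 0.9
        calls = rng.choice([0, 1, 2], p=[0.35, 0.3, 0.35], size=(50, 21))
        calls[:, 7] = rng.choice([0, 1], p=[0.1, 0.9], size=50)
        flags = qc.site_het_outliers(make_matrix(calls), k_sd=3)
        assert flags[7]
        assert flags.sum() == 1

    def test_uniform_rates_none_flagged(self):
        calls = np.tile([0, 1, 2, 1], (8, 5))  # identical het rate everywhere
        assert not qc.site_het_outliers(make_matrix(calls)).any()

    def test_infinite_k_none_flagged(self):
        rng = np.random.default_rng(1)
        calls = rng.choice([0, 1, 2], size=(30, 40))
        assert not qc.site_het_outliers(make_matrix(calls), k_sd=np.inf).any()

    def test_all_missing_site_flagged(self):
        calls = np.array([[0, -1, 1], [1, -1, 2], [2, -1, 0], [1, -1, 1]])
        flags = qc.site_het_outliers(make_matrix(calls))
        assert flags[1]


class TestCallRate:
    def test_site_above_threshold_removed(self):
        calls = np.zeros((100, 3), dtype=np.int8)
        calls[:2, 1] = -1                       # 2% missing site
        site_keep, sample_keep = qc.call_rate_filter(make_matrix(calls))
        assert site_keep.tolist() == [True, False, True]
        assert sample_keep.all()

    def test_sample_at_exact_boundary_retained(self):
        calls = np.zeros((4, 20), dtype=np.int8)
        calls[0, :1] = -1                       # exactly 5% missing
        # sites are removed first at --geno 0.01, so widen the site threshold
        site_keep, sample_keep = qc.call_rate_filter(
            make_matrix(calls), site_max_missing=1.0, sample_max_missing=0.05)
        assert sample_keep[0]

    def test_fully_observed_unchanged(self):
        calls = np.random.default_rng(2).choice([0, 1, 2], size=(10, 10))
        site_keep, sample_keep = qc.call_rate_filter(make_matrix(calls))
        assert site_keep.all() and sample_keep.all()


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert qc.hwe_exact(10, 0, 0) == 1.0
        assert qc.hwe_exact(0, 0, 7) == 1.0

    def test_small_table_matches_enumeration(self):
        assert qc.hwe_exact(1, 2, 1) == pytest.approx(hwe_enumeration(1, 2, 1))

    @given(st.integers(0, 25), st.integers(0, 25), st.integers(0, 25))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_matches_enumeration_and_symmetry(self, a, h, b):
        if a + h + b == 0:
            return
        p = qc.hwe_exact(a, h, b)
        assert p == pytest.approx(hwe_enumeration(a, h, b), abs=1e-9)
        assert p == pytest.approx(qc.hwe_exact(b, h, a))  # allele-label swap
        assert 0 <= p <= 1

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            qc.hwe_exact(-1, 2, 3)


class TestRelatedness:
    def test_duplicate_sample_flagged(self):
        H, G, *_ = build_cohort(K=1, L=800, N=20, seed=3)
        calls = np.vstack([G.calls, G.calls[5]])  # duplicate of sample 5
        G2 = make_matrix(calls)
        pairs = qc.pairwise_pi_hat(G2)
        dup = pairs[(pairs["sample1"] == "s5") & (pairs["sample2"] == "s20")]
        assert dup["pi_hat"].iloc[0] > 0.95
        flags = qc.relatedness_prune(G2)
        assert flags[5] ^ flags[20]  # exactly one member of the pair

    def test_unrelated_near_zero(self):
        H, G, *_ = build_cohort(K=1, L=2000, N=15, seed=4)
        pairs = qc.pairwise_pi_hat(G)
        assert pairs["pi_hat"].max() < 0.12

    def test_permissive_threshold_flags_none(self):
        H, G, *_ = build_cohort(K=1, L=500, N=10, seed=5)
        assert not qc.relatedness_prune(G, pi_hat_max=1.01).any()


class TestPipeline:
    def test_counts_reconcile_and_idempotent(self):
        H, G, *_ = build_cohort(K=1, L=600, N=40, seed=6)
        rng = np.random.default_rng(7)
        calls = G.calls.copy()
        calls[rng.random(calls.shape) < 0.002] = -1
        G = make_matrix(calls)
        G1, rep = qc.qc_pipeline(G)
        assert len(rep.removed_sites) == G.n_variants - G1.n_variants
        assert len(rep.removed_samples) == G.n_samples - G1.n_samples
        # one primary reason per removed item
        assert rep.removed_sites["id"].is_unique
        assert rep.removed_samples["sample"].is_unique
        G2, rep2 = qc.qc_pipeline(G1)
        assert G2.n_variants == G1.n_variants
        assert G2.n_samples == G1.n_samples
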