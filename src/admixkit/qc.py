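"""Genotype quality control: the four standard array-QC filters.

Filters (applied in this order by :func:`qc_pipeline`): relatedness removal
(method-of-moments PI_HAT), site heterozygosity outliers (one-sided, mean +
k·SD), call-rate filtering (sites before samples, strict inequalities at the
thresholds), and the Hardy–Weinberg exact test.  Every removal is recorded
with a single primary reason in a :class:`QCReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix


@dataclass
class QCReport:
    removed_samples: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample", "reason"]))
    removed_sites: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id", "reason"]))
    thresholds: dict = field(default_factory=dict)

    def add_samples(self, samples, reason: str) -> None:
        if len(samples):
            df = pd.DataFrame({"sample": list(samples), "reason": reason})
            self.removed_samples = pd.concat(
                [self.removed_samples, df], ignore_index=True)

    def add_sites(self, ids, reason: str) -> None:
        if len(ids):
            df = pd.DataFrame({"id": list(ids), "reason": reason})
            self.removed_sites = pd.concat(
                [self.removed_sites, df], ignore_index=True)


def site_het_outliers(G: GenotypeMatrix, k_sd: float = 3.0) -> np.ndarray:
    """Flag sites whose heterozygosity rate exceeds mean + k_sd·SD.

    The rate is heterozygote count / non-missing calls per site; the rule is
    one-sided (only excess heterozygosity flags a site, the classic signature
    of a badly clustering assay).  All-missing sites are excluded from the
    mean/SD and flagged.  Zero SD across sites flags nothing.
    """
    obs = G.calls != MISSING
    n_obs = obs.sum(axis=0)
    het = (G.calls == 1).sum(axis=0)
    all_missing = n_obs == 0
    with np.errstate(invalid="ignore"):
        rate = np.where(all_missing, np.nan, het / np.maximum(n_obs, 1))
    valid = ~all_missing
    if valid.sum() < 2:
        raise ValueError("need at least 2 sites with data")
    mu = float(np.nanmean(rate))
    sd = float(np.nanstd(rate))
    flags = np.zeros(G.n_variants, dtype=bool)
    if np.isfinite(k_sd) and sd > 0:
        flags |= valid & (rate > mu + k_sd * sd)
    flags |= all_missing
    return flags


def call_rate_filter(G: GenotypeMatrix, site_max_missing: float = 0.01,
                     sample_max_missing: float = 0.05
                     ) -> tuple[np.ndarray, np.ndarray]:
    """PLINK-order call-rate filter: sites first, then samples on the
    surviving sites.  A site/sample is removed when its missing fraction is
    strictly above the threshold.  Returns (site_keep, sample_keep) masks."""
    miss = G.missing_mask()
    site_frac = miss.mean(axis=0)
    site_keep = site_frac <= site_max_missing
    sample_frac = (miss[:, site_keep].mean(axis=1) if site_keep.any()
                   else np.zeros(G.n_samples))
    sample_keep = sample_frac <= sample_max_missing
    return site_keep, sample_keep


def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy–Weinberg test p-value.

    Conditions on the observed allele counts and sums, over all heterozygote
    counts with the same parity, the probabilities not larger than that of
    the observed count (two-sided exact test in the Wigginton style,
    evaluated with the standard recurrence).  Monomorphic sites give p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa        # rare-allele count
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    # possible het counts share the parity of the rare allele count
    het_max = min(n_rare, 2 * n - n_rare)
    hets = np.arange(n_rare % 2, het_max + 1, 2)
    probs = np.empty(hets.size)
    # start from the mode region: begin at the largest het count and recurse down
    probs[-1] = 1.0
    for i in range(hets.size - 1, 0, -1):
        het = hets[i]
        rare_hom = (n_rare - het) // 2
        common_hom = n - het - rare_hom
        # P(het-2) / P(het) = het(het-1) / (4(rare_hom+1)(common_hom+1))
        probs[i - 1] = probs[i] * het * (het - 1) / (
            4.0 * (rare_hom + 1) * (common_hom + 1))
        if probs[i - 1] > 1e250:                 # guard against overflow
            probs[: i] /= 1e250
            probs[i - 1] /= 1e250
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_Aa)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_filter(G: GenotypeMatrix, p_min: float = 1e-6) -> np.ndarray:
    """Keep-mask over sites: False where the exact HWE p-value < p_min."""
    keep = np.ones(G.n_variants, dtype=bool)
    for l in range(G.n_variants):
        col = G.calls[:, l]
        col = col[col != MISSING]
        p = hwe_exact(int((col == 0).sum()), int((col == 1).sum()),
                      int((col == 2).sum())) if col.size else 1.0
        keep[l] = p >= p_min
    return keep


def _ibs_expectations(p: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                              np.ndarray, np.ndarray]:
    """Per-site P(IBS=i | IBD=j) under HWE (large-sample formulas)."""
    q = 1.0 - p
    e0_ibd0 = 2 * p**2 * q**2
    e1_ibd0 = 4 * p**3 * q + 4 * p * q**3
    e2_ibd0 = 1.0 - e0_ibd0 - e1_ibd0
    e1_ibd1 = 2 * p**2 * q + 2 * p * q**2
    e2_ibd1 = 1.0 - e1_ibd1
    return e0_ibd0, e1_ibd0, e2_ibd0, e1_ibd1, e2_ibd1


def pairwise_pi_hat(G: GenotypeMatrix) -> pd.DataFrame:
    """Method-of-moments genome-wide IBD proportions for every sample pair.

    PLINK-style estimator: observed IBS0/1/2 counts are combined with their
    HWE expectations given allele frequencies to solve for P(IBD=0,1,2);
    PI_HAT = P(IBD=2) + P(IBD=1)/2, clamped to [0, 1].
    """
    if G.n_samples < 2:
        return pd.DataFrame(columns=["sample1", "sample2", "pi_hat"])
    p = G.allele_freqs()
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    calls = G.calls[:, poly].astype(np.int16)
    e0_0, e1_0, e2_0, e1_1, e2_1 = _ibs_expectations(p[poly])
    obs = calls != MISSING
    rows = []
    for i in range(G.n_samples):
        for j in range(i + 1, G.n_samples):
            use = obs[i] & obs[j]
            if use.sum() < 10:
                continue
            gi, gj = calls[i, use], calls[j, use]
            diff = np.abs(gi - gj)
            ibs0 = float((diff == 2).sum())
            ibs1 = float((diff == 1).sum())
            ibs2 = float((diff == 0).sum())
            s0_0, s1_0 = e0_0[use].sum(), e1_0[use].sum()
            s2_0 = e2_0[use].sum()
            s1_1, s2_1 = e1_1[use].sum(), e2_1[use].sum()
            P0 = ibs0 / s0_0 if s0_0 > 0 else 0.0
            P1 = (ibs1 - P0 * s1_0) / s1_1 if s1_1 > 0 else 0.0
            n_use = float(use.sum())
            P2 = (ibs2 - P0 * s2_0 - P1 * s2_1) / n_use
            pi = min(1.0, max(0.0, P2 + 0.5 * P1))
            rows.append((G.samples[i], G.samples[j], pi))
    return pd.DataFrame(rows, columns=["sample1", "sample2", "pi_hat"])


def relatedness_prune(G: GenotypeMatrix, pi_hat_max: float = 0.185) -> np.ndarray:
    """Flag one member of every pair with PI_HAT above the threshold.

    The member with more missingness is flagged (tie: the later sample).
    Returns a boolean removal mask over samples; a no-op for N < 2.
    """
    flags = np.zeros(G.n_samples, dtype=bool)
    if G.n_samples < 2:
        return flags
    pairs = pairwise_pi_hat(G)
    miss = G.missing_mask().sum(axis=1)
    index = {s: i for i, s in enumerate(G.samples)}
    for _, row in pairs[pairs["pi_hat"] > pi_hat_max].iterrows():
        i, j = index[row["sample1"]], index[row["sample2"]]
        if flags[i] or flags[j]:
            continue
        flags[j if miss[j] >= miss[i] else i] = True
    return flags


def qc_pipeline(G: GenotypeMatrix, het_k_sd: float = 3.0,
                site_max_missing: float = 0.01, sample_max_missing: float = 0.05,
                hwe_p_min: float = 1e-6, pi_hat_max: float = 0.185
                ) -> tuple[GenotypeMatrix, QCReport]:
    """Run all four filters; returns the filtered matrix and an audit report
    whose counts reconcile exactly with the dimension changes."""
    report = QCReport(thresholds={
        "het_k_sd": het_k_sd, "site_max_missing": site_max_missing,
        "sample_max_missing": sample_max_missing, "hwe_p_min": hwe_p_min,
        "pi_hat_max": pi_hat_max})
    rel = relatedness_prune(G, pi_hat_max)
    report.add_samples(np.array(G.samples)[rel], "relatedness")
    G = G.subset(sample_idx=~rel)

    het = site_het_outliers(G, het_k_sd)
    report.add_sites(G.variants.loc[het, "id"], "het_outlier")
    G = G.subset(variant_idx=~het)

    site_keep, sample_keep = call_rate_filter(G, site_max_missing,
                                              sample_max_missing)
    report.add_sites(G.variants.loc[~site_keep, "id"], "call_rate")
    G = G.subset(variant_idx=site_keep)
    report.add_samples(np.array(G.samples)[~sample_keep], "call_rate")
    G = G.subset(sample_idx=sample_keep)

    hwe_keep = hwe_filter(G, hwe_p_min)
    report.add_sites(G.variants.loc[~hwe_keep, "id"], "hwe")
    G = G.subset(variant_idx=hwe_keep)
    return G, report
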