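"""Putative loss-of-function variants: curation, per-cluster frequency
differentiation with Bonferroni control, the CADD-binned deleteriousness
ratio, and genotype-by-cluster contingency tests.

The deleteriousness ratio — median allele frequency of high-scoring LOFs
(score >= 25) over that of low-scoring ones (score <= 5), within a cluster —
contrasts the reach of purifying selection against drift: a low ratio means
selection keeps damaging alleles rare relative to the drift baseline, the
signature of a larger effective population size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


def curate_lof(annotations: pd.DataFrame, genotyped_ids=None) -> list[str]:
    """Union of the curated-LOF list and all stop_gained variants, collapsed
    and restricted to variants present in the genotype data when given."""
    mask = annotations["curated_lof"].astype(bool) | (
        annotations["consequence"] == "stop_gained")
    ids = annotations.loc[mask, "id"].astype(str)
    if genotyped_ids is not None:
        present = set(map(str, genotyped_ids))
        ids = ids[ids.isin(present)]
    return sorted(set(ids))


def allelic_chi2(a_alt: float, a_ref: float, b_alt: float, b_ref: float
                 ) -> tuple[float, float]:
    """1-df chi-square on a 2x2 allele-count table without continuity
    correction (the PLINK --assoc convention).  Returns (chi2, p); a table
    with a zero margin gives (0, 1)."""
    n = a_alt + a_ref + b_alt + b_ref
    r1, r2 = a_alt + a_ref, b_alt + b_ref
    c1, c2 = a_alt + b_alt, a_ref + b_ref
    if min(r1, r2, c1, c2) == 0:
        return 0.0, 1.0
    chi2 = n * (a_alt * b_ref - a_ref * b_alt) ** 2 / (r1 * r2 * c1 * c2)
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def _allele_counts(G: GenotypeMatrix, variant_idx: np.ndarray,
                   sample_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(alt, ref) allele counts per variant within a sample subset; two
    alleles per homozygote, one per het, missing skipped."""
    calls = G.calls[np.ix_(sample_mask, variant_idx)]
    obs = calls != MISSING
    alt = np.where(obs, calls, 0).sum(axis=0).astype(float)
    ref = (2 * obs.sum(axis=0) - alt).astype(float)
    return alt, ref


def cluster_differentiation(G: GenotypeMatrix, clusters, lof_set: list[str],
                            annotations: pd.DataFrame | None = None,
                            alpha: float = 0.05,
                            family: str = "variants_x_clusters") -> pd.DataFrame:
    """One-vs-rest allele-frequency differentiation of every LOF variant.

    For each variant and cluster, a 2x2 allele-count table (cluster vs all
    other clusters) is tested with the allelic chi-square; the Bonferroni
    threshold is alpha / (n_variants * n_clusters) by default
    (``family='variants'`` divides by n_variants only).  Variants
    monomorphic in everyone get p = 1 and a monomorphic flag.
    """
    clusters = np.asarray(clusters)
    labels = [c for c in pd.unique(clusters)]
    if len(labels) < 2:
        raise ValueError("need at least 2 clusters")
    id_to_idx = {v: i for i, v in enumerate(G.variants["id"])}
    vidx = np.array([id_to_idx[v] for v in lof_set], dtype=int)
    n_tests = len(lof_set) * (len(labels) if family == "variants_x_clusters"
                              else 1)
    threshold = alpha / max(n_tests, 1)
    per_cluster = {}
    for lab in labels:
        mask = clusters == lab
        per_cluster[lab] = _allele_counts(G, vidx, mask)
    tot_alt = sum(a for a, _ in per_cluster.values())
    tot_ref = sum(r for _, r in per_cluster.values())
    rows = []
    for lab in labels:
        alt_c, ref_c = per_cluster[lab]
        alt_r, ref_r = tot_alt - alt_c, tot_ref - ref_c
        for k, vid in enumerate(lof_set):
            mono = (tot_alt[k] == 0) or (tot_ref[k] == 0)
            if mono:
                chi2, p = 0.0, 1.0
            else:
                chi2, p = allelic_chi2(alt_c[k], ref_c[k], alt_r[k], ref_r[k])
            af_c = alt_c[k] / max(alt_c[k] + ref_c[k], 1)
            af_r = alt_r[k] / max(alt_r[k] + ref_r[k], 1)
            rows.append((vid, lab, af_c, af_r, chi2, p, bool(mono),
                         p < threshold))
    out = pd.DataFrame(rows, columns=["id", "cluster", "af_cluster", "af_rest",
                                      "chi2", "p", "monomorphic",
                                      "significant"])
    if annotations is not None:
        out = out.merge(
            annotations[["id", "consequence", "cadd", "curated_lof"]],
            on="id", how="left")
    out.attrs["bonferroni_threshold"] = threshold
    out.attrs["n_tests"] = n_tests
    return out


def top_differentiated(records: pd.DataFrame, n: int = 5) -> pd.DataFrame:
    """The n lowest p-values per cluster (the follow-up short-list)."""
    return (records.sort_values("p").groupby("cluster", sort=False)
            .head(n).reset_index(drop=True))


@dataclass
class DeleteriousnessRatio:
    cluster: str
    median_af_high: float
    median_af_low: float
    ratio: float
    flag: str = ""   # "", "empty_bin", "zero_low_median"


def deleteriousness_ratio(lof_af: pd.DataFrame, high_min: float = 25.0,
                          low_max: float = 5.0) -> list[DeleteriousnessRatio]:
    """Per-cluster ratio of median allele frequencies, high-score bin over
    low-score bin.

    ``lof_af`` needs columns cluster, cadd, af.  Scores strictly between
    ``low_max`` and ``high_min`` are excluded (so the ratio is invariant to
    adding mid-score variants).  An empty bin or a zero low-bin median is
    flagged, never silently dropped.
    """
    out = []
    for lab, sub in lof_af.groupby("cluster", sort=False):
        high = sub.loc[sub["cadd"] >= high_min, "af"]
        low = sub.loc[sub["cadd"] <= low_max, "af"]
        if len(high) == 0 or len(low) == 0:
            out.append(DeleteriousnessRatio(lab, np.nan, np.nan, np.nan,
                                            "empty_bin"))
            continue
        mh, ml = float(high.median()), float(low.median())
        if ml == 0:
            out.append(DeleteriousnessRatio(lab, mh, ml, np.inf,
                                            "zero_low_median"))
        else:
            out.append(DeleteriousnessRatio(lab, mh, ml, mh / ml))
    return out


def cluster_allele_freqs(G: GenotypeMatrix, clusters, lof_set: list[str],
                         annotations: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-cluster allele-frequency table for the LOF set (input to
    :func:`deleteriousness_ratio`)."""
    clusters = np.asarray(clusters)
    id_to_idx = {v: i for i, v in enumerate(G.variants["id"])}
    vidx = np.array([id_to_idx[v] for v in lof_set], dtype=int)
    ann = annotations.set_index("id")
    rows = []
    for lab in pd.unique(clusters):
        alt, ref = _allele_counts(G, vidx, clusters == lab)
        with np.errstate(invalid="ignore"):
            af = alt / np.maximum(alt + ref, 1)
        for k, vid in enumerate(lof_set):
            rows.append((lab, vid, float(ann.at[vid, "cadd"]), float(af[k])))
    return pd.DataFrame(rows, columns=["cluster", "id", "cadd", "af"])


def genotype_by_cluster(variant_id: str, G: GenotypeMatrix, clusters
                        ) -> tuple[pd.DataFrame, float, float, int, bool]:
    """Genotype x cluster contingency table with a chi-square test.

    Returns (table, chi2, p, dof, low_expected) where ``low_expected`` warns
    that some expected cell count is below 5 (chi-square approximation
    suspect).  Genotype rows with zero total are dropped before testing.
    """
    ids = G.variants["id"].to_numpy()
    hits = np.flatnonzero(ids == variant_id)
    if hits.size == 0:
        raise KeyError(f"variant {variant_id!r} absent from genotype data")
    l = int(hits[0])
    clusters = np.asarray(clusters)
    labels = list(pd.unique(clusters))
    table = np.zeros((3, len(labels)), dtype=int)
    for ci, lab in enumerate(labels):
        col = G.calls[clusters == lab, l]
        col = col[col != MISSING]
        for gt in (0, 1, 2):
            table[gt, ci] = int((col == gt).sum())
    genotyped = (table.sum(axis=0) > 0).sum()
    if genotyped < 2:
        raise ValueError("variant genotyped in fewer than 2 clusters")
    df = pd.DataFrame(table, index=["hom_ref", "het", "hom_alt"],
                      columns=[str(x) for x in labels])
    active = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if active.shape[0] < 2:
        return df, 0.0, 1.0, 0, False
    chi2, p, dof, expected = stats.chi2_contingency(active, correction=False)
    low_expected = bool((expected < 5).any())
    if low_expected:
        logger.warning("genotype_by_cluster(%s): expected cell count < 5",
                       variant_id)
    return df, float(chi2), float(p), int(dof), low_expected
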