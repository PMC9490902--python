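"""Runs of homozygosity: scanning-window detection and inbreeding summaries.

The detector is the PLINK ``--homozyg`` heuristic with its 1.9 defaults:
a 50-SNP window is "homozygous" when it holds at most 1 heterozygote and 5
missing calls; a SNP is in-run when at least 5% of the windows overlapping
it are homozygous; maximal in-run stretches are split at >1 Mb gaps and
reported when they carry >= 100 SNPs over >= 1 Mb at a density of at least
one SNP per 50 kb.  Only windows fully inside the chromosome contribute to
the per-SNP hit fraction (edge behaviour).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix


@dataclass
class ROHParams:
    window_snps: int = 50
    window_het_max: int = 1
    window_missing_max: int = 5
    hit_fraction: float = 0.05
    min_snps: int = 100
    min_kb: float = 1000.0
    max_gap_kb: float = 1000.0
    min_density_kb_per_snp: float = 50.0

    def __post_init__(self) -> None:
        if min(self.window_snps, self.min_snps) <= 0 or self.min_kb <= 0 \
                or self.max_gap_kb <= 0 or self.min_density_kb_per_snp <= 0:
            raise ValueError("ROH parameters must be positive")
        if not 0 < self.hit_fraction <= 1:
            raise ValueError("hit_fraction must be in (0, 1]")


SEGMENT_COLUMNS = ["sample", "chrom", "start_bp", "end_bp", "n_snps", "length_kb"]


def _window_sums(x: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate(([0], np.cumsum(x)))
    return c[w:] - c[:-w]


def _in_run_snps(het: np.ndarray, miss: np.ndarray, p: ROHParams) -> np.ndarray:
    """Boolean in-run flag per SNP from the sliding-window vote."""
    L = het.size
    w = p.window_snps
    if L < w:
        return np.zeros(L, dtype=bool)
    hom_win = ((_window_sums(het.astype(int), w) <= p.window_het_max)
               & (_window_sums(miss.astype(int), w) <= p.window_missing_max))
    # windows overlapping SNP i: start in [max(0, i-w+1), min(i, L-w)]
    c = np.concatenate(([0], np.cumsum(hom_win)))
    i = np.arange(L)
    lo = np.maximum(0, i - w + 1)
    hi = np.minimum(i, L - w)
    n_win = hi - lo + 1
    n_hom = c[hi + 1] - c[lo]
    return n_hom / n_win >= p.hit_fraction


def detect_roh(G: GenotypeMatrix, params: ROHParams | None = None) -> pd.DataFrame:
    """Detect ROH segments for every sample; returns a sorted segment table
    (sample, chrom, start_bp, end_bp, n_snps, length_kb)."""
    p = params or ROHParams()
    rows = []
    for chrom, sub in G.variants.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"variants unsorted on chromosome {chrom}")
        calls = G.calls[:, idx]
        for si, sample in enumerate(G.samples):
            het = calls[si] == 1
            miss = calls[si] == MISSING
            in_run = _in_run_snps(het, miss, p)
            if not in_run.any():
                continue
            # maximal stretches of in-run SNPs
            bounds = []
            s = None
            for j, flag in enumerate(in_run):
                if flag and s is None:
                    s = j
                elif not flag and s is not None:
                    bounds.append((s, j - 1))
                    s = None
            if s is not None:
                bounds.append((s, len(in_run) - 1))
            for a, b in bounds:
                # split at gaps > max_gap_kb
                seg_start = a
                for j in range(a, b):
                    if (pos[j + 1] - pos[j]) / 1e3 > p.max_gap_kb:
                        rows.append((sample, chrom, seg_start, j, pos))
                        seg_start = j + 1
                rows.append((sample, chrom, seg_start, b, pos))
    out = []
    for sample, chrom, a, b, pos in rows:
        n_snps = b - a + 1
        length_kb = (pos[b] - pos[a] + 1) / 1e3
        if (n_snps >= p.min_snps and length_kb >= p.min_kb
                and length_kb / n_snps <= p.min_density_kb_per_snp):
            out.append((sample, chrom, int(pos[a]), int(pos[b]),
                        int(n_snps), float(length_kb)))
    df = pd.DataFrame(out, columns=SEGMENT_COLUMNS)
    return df.sort_values(["sample", "chrom", "start_bp"]).reset_index(drop=True)


def roh_summary(segments: pd.DataFrame, samples: list[str],
                genome_length_mb: float, clusters=None
                ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-sample total ROH Mb, segment count and F_ROH (= total / genome
    length); optionally mean totals per cluster assignment."""
    per = pd.DataFrame({"sample": samples})
    if len(segments):
        agg = segments.groupby("sample").agg(
            total_mb=("length_kb", lambda x: x.sum() / 1e3),
            n_segments=("length_kb", "size"))
        per = per.merge(agg, on="sample", how="left")
    else:
        per["total_mb"] = 0.0
        per["n_segments"] = 0
    per["total_mb"] = per["total_mb"].fillna(0.0)
    per["n_segments"] = per["n_segments"].fillna(0).astype(int)
    per["f_roh"] = per["total_mb"] / genome_length_mb
    cluster_means = None
    if clusters is not None:
        per["cluster"] = list(clusters)
        cluster_means = per.groupby("cluster")[
            ["total_mb", "n_segments", "f_roh"]].mean().reset_index()
    return per, cluster_means


def genome_span_mb(variants: pd.DataFrame) -> float:
    """Default genome length: summed per-chromosome span of the variant table."""
    span = variants.groupby("chrom")["pos"].agg(lambda x: x.max() - x.min() + 1)
    return float(span.sum() / 1e6)


def het_inbreeding(G: GenotypeMatrix) -> pd.DataFrame:
    """Method-of-moments inbreeding coefficient per sample (the ``--het``
    statistic): F = (O_hom - E_hom) / (L_used - E_hom), with the expected
    homozygosity E_hom = sum_l [1 - 2 p_l (1 - p_l) n_l / (n_l - 1)] taken
    over the sample's non-missing polymorphic sites (n_l = observed allele
    count at l)."""
    if G.n_samples < 2:
        raise ValueError("allele frequencies undefined with a single sample")
    p = G.allele_freqs()
    obs = G.calls != MISSING
    n_alleles = 2 * obs.sum(axis=0)
    poly = np.isfinite(p) & (p > 0) & (p < 1) & (n_alleles > 2)
    e_site = 1 - 2 * p[poly] * (1 - p[poly]) * n_alleles[poly] / (n_alleles[poly] - 1)
    calls = G.calls[:, poly]
    use = calls != MISSING
    o_hom = ((calls == 0) | (calls == 2)) & use
    rows = []
    for i, sample in enumerate(G.samples):
        L_used = int(use[i].sum())
        if L_used == 0:
            rows.append((sample, 0, np.nan, np.nan, np.nan))
            continue
        O = float(o_hom[i].sum())
        E = float(e_site[use[i]].sum())
        F = (O - E) / (L_used - E) if L_used != E else np.nan
        rows.append((sample, L_used, O, E, F))
    return pd.DataFrame(rows, columns=["sample", "n_sites", "o_hom", "e_hom", "F"])
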