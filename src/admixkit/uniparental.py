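"""Haplotype diversity for uniparental marker sets (Y, mtDNA).

Nei's bias-corrected haplotype diversity, H = n/(n-1) · (1 - sum_i p_i²),
is the probability that two haplotypes sampled without replacement differ.
The Y-to-mitochondrial diversity ratio summarises the asymmetry between
male and female effective population sizes (patrilineal societies drive it
below 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


@dataclass
class HaplotypeCounts:
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.counts.values()):
            raise ValueError("haplotype counts must be positive")

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_labels(cls, labels) -> "HaplotypeCounts":
        counts: dict[str, int] = {}
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
        return cls(counts)


def haplotype_diversity(counts: HaplotypeCounts) -> float:
    """Nei's H = n/(n-1) (1 - sum p_i^2); requires n >= 2."""
    n = counts.n
    if n < 2:
        raise ValueError("haplotype diversity needs at least 2 haplotypes")
    sum_p2 = sum((c / n) ** 2 for c in counts.counts.values())
    return n / (n - 1) * (1.0 - sum_p2)


def diversity_ratio(h_y: float, h_mt: float) -> dict[str, float]:
    """Y/mt haplotype-diversity ratio.

    Returns both the full-precision quotient and the value truncated (not
    rounded) to two decimals, the convention that reproduces published
    two-decimal ratios such as 0.574/0.873 -> 0.65.
    """
    if h_mt <= 0:
        raise ValueError("mitochondrial diversity must be positive")
    full = h_y / h_mt
    truncated = math.floor(full * 100) / 100.0
    return {"ratio": full, "ratio_2dp_truncated": truncated}


def read_haplotype_counts(path) -> HaplotypeCounts:
    """Two-column TSV: haplotype label, count."""
    df = pd.read_csv(path, sep="\t", header=None, names=["haplotype", "count"])
    return HaplotypeCounts(dict(zip(df["haplotype"].astype(str), df["count"].astype(int))))
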