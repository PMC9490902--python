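"""Core in-memory containers shared by every pipeline stage.

Genotypes are held as an ``int8`` matrix of alternate-allele dosages
(N samples x L variants, values 0/1/2, missing encoded as -1); phased
haplotypes as a ``2N x L`` binary matrix where allele ``1`` is the derived
allele and rows ``2i``/``2i+1`` are the two haplotypes of sample ``i``.
Variant metadata travels as a pandas DataFrame with 1-based, inclusive bp
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: columns every VariantTable must carry
VARIANT_COLUMNS = ("chrom", "pos", "id", "ref", "alt")


def validate_variant_table(variants: pd.DataFrame, require_cm: bool = False) -> None:
    """Check coordinate conventions: required columns present, positions
    strictly increasing and cM non-decreasing within each chromosome."""
    for col in VARIANT_COLUMNS:
        if col not in variants.columns:
            raise ValueError(f"variant table missing mandatory column {col!r}")
    if require_cm and "cM" not in variants.columns:
        raise ValueError("variant table has no 'cM' column; interpolate from a genetic map first")
    for chrom, sub in variants.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions not strictly increasing on chromosome {chrom}")
        if "cM" in sub.columns:
            cm = sub["cM"].to_numpy(dtype=float)
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"cM not non-decreasing on chromosome {chrom}")


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls for a cohort.

    Attributes
    ----------
    calls : int8 array, N x L; alt-allele dosage 0/1/2, missing = -1.
    samples : ordered sample identifiers.
    variants : VariantTable (chrom, pos, id, ref, alt[, cM]).
    phased : True when the source data were fully phased.
    """

    calls: np.ndarray
    samples: list[str]
    variants: pd.DataFrame
    phased: bool = False

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D samples x variants matrix")
        n, l = self.calls.shape
        if n != len(self.samples):
            raise ValueError(f"{len(self.samples)} samples but {n} genotype rows")
        if l != len(self.variants):
            raise ValueError(f"{len(self.variants)} variants but {l} genotype columns")
        validate_variant_table(self.variants)

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_variants(self) -> int:
        return self.calls.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def allele_freqs(self) -> np.ndarray:
        """Alt-allele frequency per variant over non-missing calls
        (NaN where every call is missing)."""
        obs = self.calls != MISSING
        n_alleles = 2 * obs.sum(axis=0)
        alt = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeMatrix":
        calls = self.calls
        samples = self.samples
        variants = self.variants
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            calls = calls[sample_idx]
            samples = [self.samples[i] for i in np.flatnonzero(sample_idx)] \
                if sample_idx.dtype == bool else [self.samples[i] for i in sample_idx]
        if variant_idx is not None:
            variant_idx = np.asarray(variant_idx)
            calls = calls[:, variant_idx]
            variants = variants.iloc[variant_idx] if variant_idx.dtype != bool \
                else variants.loc[variant_idx]
            variants = variants.reset_index(drop=True)
        return GenotypeMatrix(calls.copy(), list(samples), variants.copy(), self.phased)


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes, derived-allele orientation.

    ``haplotypes`` is 2N x L int8 in {0, 1}; rows 2i and 2i+1 belong to
    ``samples[i]``.  ``variants`` must carry a ``cM`` column for any
    map-aware analysis (selection needs none, dating does).
    """

    haplotypes: np.ndarray
    samples: list[str]
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape[0] != 2 * len(self.samples):
            raise ValueError("haplotype count must equal 2 x sample count")
        if self.haplotypes.shape[1] != len(self.variants):
            raise ValueError("haplotype width must equal variant count")
        validate_variant_table(self.variants)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    def to_genotypes(self) -> GenotypeMatrix:
        """Collapse haplotype pairs to diploid dosages (exact by construction)."""
        g = self.haplotypes[0::2] + self.haplotypes[1::2]
        return GenotypeMatrix(g.astype(np.int8), list(self.samples),
                              self.variants.copy(), phased=True)

    def for_chrom(self, chrom) -> "HaplotypeSet":
        mask = (self.variants["chrom"] == chrom).to_numpy()
        return HaplotypeSet(self.haplotypes[:, mask], list(self.samples),
                            self.variants.loc[mask].reset_index(drop=True))

    def chroms(self) -> list:
        return list(pd.unique(self.variants["chrom"]))


@dataclass
class GeneticMap:
    """Genetic map: per chromosome, bp positions with cumulative cM.

    ``table`` columns: chrom, id, cM, bp (the on-disk column order);
    positions sorted and cM non-decreasing within chromosome.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("chrom", "cM", "bp"):
            if col not in self.table.columns:
                raise ValueError(f"genetic map missing column {col!r}")
        for chrom, sub in self.table.groupby("chrom", sort=False):
            bp = sub["bp"].to_numpy()
            cm = sub["cM"].to_numpy(dtype=float)
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"map positions not strictly increasing on {chrom}")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"map cM decreasing on chromosome {chrom}")

    def chrom_points(self, chrom) -> tuple[np.ndarray, np.ndarray]:
        sub = self.table[self.table["chrom"] == chrom]
        if sub.empty:
            raise KeyError(f"chromosome {chrom} not in genetic map")
        return sub["bp"].to_numpy(dtype=float), sub["cM"].to_numpy(dtype=float)


def uniform_genetic_map(chrom_lengths_bp: dict, cm_per_mb: float = 1.0,
                        points_per_chrom: int = 2) -> GeneticMap:
    """Constant-rate map (default 1 cM/Mb), anchored at both chromosome ends."""
    rows = []
    for chrom, length in chrom_lengths_bp.items():
        bps = np.linspace(1, length, points_per_chrom)
        for i, bp in enumerate(bps):
            rows.append((chrom, f"map_{chrom}_{i}", (bp - 1) / 1e6 * cm_per_mb, int(bp)))
    return GeneticMap(pd.DataFrame(rows, columns=["chrom", "id", "cM", "bp"]))
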