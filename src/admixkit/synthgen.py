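"""Synthetic admixed cohorts with known ground truth.

The generator follows the Balding–Nichols view of population structure:
K ancestral populations whose allele frequencies are Beta-distributed around
a shared ancestral frequency p0 with variance F·p0·(1-p0), individuals with
Dirichlet-style ancestry proportions Q, and haplotypes painted as mosaics of
ancestral segments whose breakpoints follow a Poisson process at rate g per
Morgan (so an admixture pulse g generations ago leaves exponentially
distributed ancestry tracts of mean 1/g Morgan).  Consanguinity is emulated
by copying one haplotype over the other inside a chosen region, and a
deleteriousness-linked frequency model suppresses the frequency of
loss-of-function variants in proportion to their score.

Sites are drawn independently within an ancestry tract: there is no
background LD from recombination inside the ancestral populations, and no
mutation/genealogy process.  Allele 1 is the derived allele throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GeneticMap, GenotypeMatrix, HaplotypeSet, uniform_genetic_map

BENIGN_CONSEQUENCES = ("intergenic_variant", "intron_variant",
                       "synonymous_variant", "missense_variant")


@dataclass
class AncestralFreqs:
    """Ancestral allele-frequency model: P (K x L), per-population F, shared p0."""

    P: np.ndarray
    F: np.ndarray
    p0: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.F = np.atleast_1d(np.asarray(self.F, dtype=float))
        self.p0 = np.asarray(self.p0, dtype=float)
        if self.P.ndim != 2 or self.P.shape != (self.F.size, self.p0.size):
            raise ValueError("P must be K x L with K = len(F), L = len(p0)")
        if np.any(self.P < 0) or np.any(self.P > 1):
            raise ValueError("ancestral frequencies must lie in [0, 1]")

    @property
    def K(self) -> int:
        return self.P.shape[0]

    @property
    def L(self) -> int:
        return self.P.shape[1]


@dataclass
class SimulationTruth:
    """Ground truth recorded by the generator for recovery tests."""

    Q_true: np.ndarray
    pulse_g: list[float]
    roh_regions: list[tuple] = field(default_factory=list)   # (sample, chrom, start_bp, end_bp)
    selection_s: np.ndarray | None = None
    seed: int | None = None
    ancestry: np.ndarray | None = None                        # 2N x L painted ancestries
    tract_cm: np.ndarray | None = None                        # interior inter-breakpoint gaps

    def to_json_dict(self) -> dict:
        return {
            "Q_true": self.Q_true.tolist(),
            "pulse_g": list(self.pulse_g),
            "roh_regions": [list(r) for r in self.roh_regions],
            "selection_s": None if self.selection_s is None else self.selection_s.tolist(),
            "seed": self.seed,
        }


def simulate_ancestral_freqs(K: int, L: int, F, seed: int,
                             p0_range: tuple[float, float] = (0.05, 0.95)) -> AncestralFreqs:
    """Draw Balding–Nichols ancestral frequencies.

    P[k, l] ~ Beta with mean p0[l] and variance F[k]·p0[l]·(1-p0[l]);
    F[k] -> 0 collapses population k onto p0.  p0 is uniform on ``p0_range``,
    bounded away from 0/1 so sites start polymorphic (they may still drift to
    fixation in a sampled cohort).
    """
    if K < 1 or L < 1:
        raise ValueError("K and L must be >= 1")
    F = np.broadcast_to(np.asarray(F, dtype=float), (K,)).copy()
    if not np.all(np.isfinite(F)) or np.any(F < 0) or np.any(F >= 1):
        raise ValueError("each F must be finite and in [0, 1)")
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(*p0_range, size=L)
    P = np.empty((K, L))
    for k in range(K):
        if F[k] == 0.0:
            P[k] = p0
        else:
            # Beta(a, b) with a+b = (1-F)/F gives exactly this mean/variance
            scale = (1.0 - F[k]) / F[k]
            P[k] = rng.beta(p0 * scale, (1.0 - p0) * scale)
    return AncestralFreqs(P, F, p0)


def uniform_variant_table(L: int, chrom_morgans: dict | None = None,
                          cm_per_mb: float = 1.0) -> tuple[pd.DataFrame, GeneticMap]:
    """Evenly spaced variants over one or more chromosomes.

    ``chrom_morgans`` maps chromosome label -> genetic length in Morgans
    (default a single 1-Morgan chromosome "1"); physical length follows the
    constant cm_per_mb rate.  Variants are split across chromosomes in
    proportion to genetic length.
    """
    if chrom_morgans is None:
        chrom_morgans = {"1": 1.0}
    total_m = sum(chrom_morgans.values())
    rows = []
    chrom_lengths_bp = {}
    remaining = L
    items = list(chrom_morgans.items())
    for ci, (chrom, morgans) in enumerate(items):
        lc = remaining if ci == len(items) - 1 else max(1, round(L * morgans / total_m))
        lc = min(lc, remaining)
        remaining -= lc
        length_bp = int(morgans * 100.0 / cm_per_mb * 1e6)
        chrom_lengths_bp[chrom] = length_bp + 2
        pos = np.linspace(1, length_bp, lc).round().astype(int)
        pos = np.maximum.accumulate(pos) + np.arange(lc)  # enforce strict increase
        for j, p in enumerate(pos):
            rows.append((chrom, int(p), f"rs{chrom}_{j}", "A", "G",
                         (p - 1) / 1e6 * cm_per_mb))
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt", "cM"])
    gmap = uniform_genetic_map({c: int(l) for c, l in chrom_lengths_bp.items()},
                               cm_per_mb=cm_per_mb)
    return variants, gmap


def _paint_chromosome(rng: np.random.Generator, cm: np.ndarray, q: np.ndarray,
                      pulse_g: float, gaps: list | None = None) -> np.ndarray:
    """Ancestry labels along one chromosome for one haplotype: breakpoints at
    rate pulse_g per Morgan along the cM axis, each segment's ancestry iid
    from q.  Interior inter-breakpoint gaps (uncensored exponential draws)
    are appended to ``gaps`` when given."""
    K = q.size
    start, end = cm[0], cm[-1]
    mean_cm = 100.0 / pulse_g
    breaks = []
    t = start + rng.exponential(mean_cm)
    while t < end:
        breaks.append(t)
        inc = rng.exponential(mean_cm)
        # each inter-breakpoint increment is a complete (uncensored)
        # exponential draw; recording them all gives an iid sample
        if gaps is not None:
            gaps.append(inc)
        t += inc
    edges = np.concatenate(([start - 1.0], breaks, [end + 1.0]))
    n_seg = len(edges) - 1
    seg_anc = rng.choice(K, size=n_seg, p=q)
    seg_idx = np.searchsorted(edges, cm, side="right") - 1
    return seg_anc[seg_idx]


def simulate_admixed_cohort(freqs: AncestralFreqs, Q: np.ndarray,
                            variants: pd.DataFrame, pulse_g: float,
                            seed: int) -> tuple[HaplotypeSet, GenotypeMatrix, SimulationTruth]:
    """Paint a single-pulse admixed cohort and draw alleles.

    Each haplotype is a mosaic of ancestral segments (breakpoints Poisson at
    rate ``pulse_g`` per Morgan, segment ancestries from the individual's Q
    row); alleles are Bernoulli(P[ancestry, l]); genotypes are the sum of the
    two haplotypes.  Deterministic given seed.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[1] != freqs.K:
        raise ValueError("Q must be N x K matching the ancestral frequency model")
    if not np.allclose(Q.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("rows of Q must sum to 1")
    variants = variants.reset_index(drop=True)
    if "cM" not in variants.columns:
        raise ValueError("variants need a cM column (interpolate from a genetic map)")
    if len(variants) != freqs.L:
        raise ValueError("variant table length does not match frequency model")
    if len(variants) == 0:
        raise ValueError("empty variant table / genetic map")
    if pulse_g < 1:
        raise ValueError("pulse_g must be >= 1 generation")
    rng = np.random.default_rng(seed)
    N = Q.shape[0]
    L = freqs.L
    anc = np.empty((2 * N, L), dtype=np.int8)
    chrom_slices = []
    for chrom, sub in variants.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        chrom_slices.append((idx, sub["cM"].to_numpy(dtype=float)))
    gaps: list = []
    for i in range(N):
        for h in range(2):
            for idx, cm in chrom_slices:
                anc[2 * i + h, idx] = _paint_chromosome(rng, cm, Q[i], pulse_g,
                                                        gaps)
    u = rng.random(size=(2 * N, L))
    haps = (u < freqs.P[anc, np.arange(L)[None, :]]).astype(np.int8)
    samples = [f"S{i:04d}" for i in range(N)]
    hs = HaplotypeSet(haps, samples, variants.reset_index(drop=True).copy())
    gm = hs.to_genotypes()
    truth = SimulationTruth(Q_true=Q.copy(), pulse_g=[float(pulse_g)],
                            seed=seed, ancestry=anc,
                            tract_cm=np.asarray(gaps, dtype=float))
    return hs, gm, truth


def simulate_two_pulse_cohort(freqs: AncestralFreqs, Q_old: np.ndarray,
                              recent_source: int, m_recent: float,
                              variants: pd.DataFrame, g_old: float,
                              g_recent: float, seed: int
                              ) -> tuple[HaplotypeSet, GenotypeMatrix, SimulationTruth]:
    """Two dated admixture pulses, built by mixing two painted layers.

    A background layer is painted at rate ``g_old`` with proportions
    ``Q_old``; a second painting at rate ``g_recent`` overwrites each segment
    with ancestry ``recent_source`` with probability ``m_recent`` and keeps
    the background layer otherwise.  Admixture LD then decays as the sum of
    exp(-g_old·d) and exp(-g_recent·d) components.
    """
    Q_old = np.asarray(Q_old, dtype=float)
    variants = variants.reset_index(drop=True)
    if not 0 < m_recent < 1:
        raise ValueError("m_recent must be in (0, 1)")
    if g_recent >= g_old:
        raise ValueError("the recent pulse must be younger (g_recent < g_old)")
    rng = np.random.default_rng(seed)
    N = Q_old.shape[0]
    L = freqs.L
    anc = np.empty((2 * N, L), dtype=np.int8)
    chrom_slices = [(sub.index.to_numpy(), sub["cM"].to_numpy(dtype=float))
                    for _, sub in variants.groupby("chrom", sort=False)]
    for i in range(N):
        for h in range(2):
            for idx, cm in chrom_slices:
                bg = _paint_chromosome(rng, cm, Q_old[i], g_old)
                # recent layer: segments at rate g_recent choose source vs background
                sel = _paint_chromosome(
                    rng, cm, np.array([m_recent, 1.0 - m_recent]), g_recent)
                anc[2 * i + h, idx] = np.where(sel == 0, recent_source, bg)
    u = rng.random(size=(2 * N, L))
    haps = (u < freqs.P[anc, np.arange(L)[None, :]]).astype(np.int8)
    samples = [f"S{i:04d}" for i in range(N)]
    hs = HaplotypeSet(haps, samples, variants.reset_index(drop=True).copy())
    q_eff = np.empty((N, freqs.K))
    for i in range(N):
        q_eff[i] = (1 - m_recent) * Q_old[i]
        q_eff[i, recent_source] += m_recent
    truth = SimulationTruth(Q_true=q_eff, pulse_g=[float(g_old), float(g_recent)],
                            seed=seed, ancestry=anc)
    return hs, hs.to_genotypes(), truth


def inject_roh(genotypes: GenotypeMatrix, haplotypes: HaplotypeSet, sample: str,
               chrom, start_bp: int, end_bp: int,
               truth: SimulationTruth | None = None) -> None:
    """Force a run of homozygosity: inside [start_bp, end_bp] the sample's
    second haplotype is overwritten by its first (idempotent).  Updates both
    the haplotype set and the genotype matrix in place."""
    if sample not in haplotypes.samples:
        raise KeyError(f"unknown sample {sample!r}")
    v = haplotypes.variants
    if not (v["chrom"] == chrom).any():
        raise KeyError(f"unknown chromosome {chrom!r}")
    cmax = int(v.loc[v["chrom"] == chrom, "pos"].max())
    if start_bp < 1 or end_bp > cmax or end_bp < start_bp:
        raise ValueError("region outside chromosome bounds")
    mask = ((v["chrom"] == chrom) & (v["pos"] >= start_bp)
            & (v["pos"] <= end_bp)).to_numpy()
    i = haplotypes.samples.index(sample)
    haplotypes.haplotypes[2 * i + 1, mask] = haplotypes.haplotypes[2 * i, mask]
    gi = genotypes.samples.index(sample)
    genotypes.calls[gi, mask] = 2 * haplotypes.haplotypes[2 * i, mask]
    if truth is not None:
        truth.roh_regions.append((sample, chrom, int(start_bp), int(end_bp)))


def simulate_annotations(variants: pd.DataFrame, lof_fraction: float,
                         seed: int, trait_fraction: float = 0.2,
                         curated_fraction: float = 0.5,
                         trait_labels: tuple[str, ...] = (
                             "HDL", "LDL", "height", "blood_trait",
                             "serum_metabolite", "BMI"),
                         ) -> pd.DataFrame:
    """Stand-in for a VEP/CADD/GWAS-catalogue annotation table.

    A ``lof_fraction`` of variants become stop_gained with deleteriousness
    scores spanning both the high (>= 25) and low (<= 5) bins; a
    ``curated_fraction`` of the LOFs are additionally flagged as members of a
    curated LOF list; a ``trait_fraction`` of all variants get a trait label.
    """
    if not 0 <= lof_fraction <= 1:
        raise ValueError("lof_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    L = len(variants)
    n_lof = int(round(lof_fraction * L))
    lof_idx = rng.choice(L, size=n_lof, replace=False) if n_lof else np.array([], int)
    consequence = np.array(
        rng.choice(BENIGN_CONSEQUENCES, size=L,
                   p=(0.45, 0.35, 0.12, 0.08)), dtype=object)
    consequence[lof_idx] = "stop_gained"
    cadd = rng.uniform(0, 20, size=L)
    if n_lof:
        # thirds of the LOFs land in high / middle / low score strata
        strata = rng.permutation(n_lof) % 3
        cadd[lof_idx[strata == 0]] = rng.uniform(25, 50, size=(strata == 0).sum())
        cadd[lof_idx[strata == 1]] = rng.uniform(5, 25, size=(strata == 1).sum())
        cadd[lof_idx[strata == 2]] = rng.uniform(0, 5, size=(strata == 2).sum())
    curated = np.zeros(L, dtype=bool)
    if n_lof:
        n_cur = int(round(curated_fraction * n_lof))
        curated[rng.choice(lof_idx, size=n_cur, replace=False)] = True
    traits = np.array([""] * L, dtype=object)
    n_trait = int(round(trait_fraction * L))
    t_idx = rng.choice(L, size=n_trait, replace=False)
    traits[t_idx] = rng.choice(trait_labels, size=n_trait)
    return pd.DataFrame({
        "id": variants["id"].to_numpy(),
        "consequence": consequence,
        "cadd": cadd,
        "curated_lof": curated,
        "traits": traits,
    })


def apply_deleteriousness(freqs: AncestralFreqs, annotations: pd.DataFrame,
                          strength, lof_only: bool = True
                          ) -> tuple[AncestralFreqs, np.ndarray]:
    """Suppress ancestral allele frequencies of deleterious variants.

    The derived-allele frequency of variant l in population k is multiplied
    by exp(-strength[k] · s_l) where s_l = score/50 is the per-variant
    selection surrogate; a larger ``strength`` emulates more efficient
    purifying selection (higher effective population size).  Returns the new
    frequency model and the s vector (stored in SimulationTruth.selection_s).
    """
    strength = np.broadcast_to(np.asarray(strength, dtype=float), (freqs.K,))
    s = annotations["cadd"].to_numpy(dtype=float) / 50.0
    if lof_only:
        is_lof = ((annotations["consequence"] == "stop_gained")
                  | annotations["curated_lof"]).to_numpy()
        s = np.where(is_lof, s, 0.0)
    P = freqs.P * np.exp(-np.outer(strength, s))
    return AncestralFreqs(P, freqs.F.copy(), freqs.p0.copy()), s
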