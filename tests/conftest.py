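"""Shared builders for synthetic cohorts used across the suite.

Study-like defaults: cluster-structured ancestry proportions are drawn
Dirichlet(0.3) so most individuals are strongly anchored to one ancestry
with a minority admixed — the regime in which unsupervised admixture models
are identifiable and which structured human cohorts show.
"""

import numpy as np
import pytest

from admixkit import synthgen as sg
from admixkit.core import GenotypeMatrix, HaplotypeSet


def build_cohort(K=3, L=1000, N=100, F=0.2, alpha=0.3, pulse_g=10, seed=0,
                 chrom_morgans=None, p0_range=(0.05, 0.95)):
    """Balding-Nichols admixed cohort with Dirichlet(alpha) ancestry."""
    variants, gmap = sg.uniform_variant_table(L, chrom_morgans)
    freqs = sg.simulate_ancestral_freqs(K, L, F, seed=seed, p0_range=p0_range)
    rng = np.random.default_rng(seed + 1)
    Q = rng.dirichlet(np.full(K, alpha), size=N)
    H, G, truth = sg.simulate_admixed_cohort(freqs, Q, variants, pulse_g,
                                             seed=seed + 2)
    return H, G, truth, freqs, variants, gmap


def neutral_haplotypes(n_hap=40, L=500, seed=0, p_range=(0.05, 0.95),
                       chrom_morgans=None):
    """Unstructured haplotypes: sites iid Bernoulli(p), no LD."""
    variants, _ = sg.uniform_variant_table(L, chrom_morgans)
    rng = np.random.default_rng(seed)
    p = rng.uniform(*p_range, size=L)
    hap = (rng.random((n_hap, L)) < p).astype(np.int8)
    samples = [f"S{i:04d}" for i in range(n_hap // 2)]
    return HaplotypeSet(hap, samples, variants)


@pytest.fixture
def small_cohort():
    return build_cohort(K=2, L=400, N=40, seed=11)
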