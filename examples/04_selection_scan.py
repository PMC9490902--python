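"""nSL selection scan across two ancestry clusters with an engineered sweep.

One cluster carries a variant whose derived carriers share a long identical
haplotype (the sweep signature); the scan, frequency-bin normalization and
candidate calling should single it out, and the shared/private partition
should mark it private to that cluster."""

import numpy as np
import pandas as pd

from admixkit import selection
from admixkit.core import HaplotypeSet
from admixkit.synthgen import simulate_ancestral_freqs, simulate_admixed_cohort, \
    uniform_variant_table

rng = np.random.default_rng(31)
L = 1200
variants, _ = uniform_variant_table(L)


def neutral_cluster(seed, n_hap=60):
    p = np.random.default_rng(seed).uniform(0.05, 0.95, L)
    hap = (np.random.default_rng(seed + 1).random((n_hap, L)) < p)
    samples = [f"S{i}" for i in range(n_hap // 2)]
    return HaplotypeSet(hap.astype(np.int8), samples, variants.copy())


swept_cluster = neutral_cluster(seed=41)
focal = 600
carriers = rng.choice(60, size=24, replace=False)
hap = swept_cluster.haplotypes
hap[:, focal] = 0
hap[carriers, focal - 40:focal + 40] = hap[carriers[0], focal - 40:focal + 40]
hap[carriers, focal] = 1
swept_id = variants.at[focal, "id"]

other_cluster = neutral_cluster(seed=51)

annotations = pd.DataFrame({
    "id": variants["id"], "consequence": "intron_variant", "cadd": 5.0,
    "curated_lof": False,
    "traits": np.where(variants["id"] == swept_id, "LDL", "")})

sets = []
for name, haplo in [("c1", swept_cluster), ("c2", other_cluster)]:
    scores = selection.normalize_nsl(selection.nsl_scan(haplo), n_bins=25)
    cs = selection.call_candidates(scores, annotations, cluster=name)
    sets.append(cs)
    print(f"cluster {name}: {len(scores)} scored variants, "
          f"candidates: {sorted(cs.variants)}")

cells, shared = selection.shared_private_partition(sets)
print("partition cells:", {tuple(sorted(k)): v for k, v in cells.items()})
# The engineered sweep is called only in c1: a private selection signal.
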