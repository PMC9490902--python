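"""Nei haplotype diversity for uniparental markers and the Y/mt ratio.

A strongly patrilineal population shows reduced Y-chromosome haplotype
diversity relative to mitochondrial diversity, pushing the ratio well
below 1."""

from admixkit.uniparental import (HaplotypeCounts, diversity_ratio,
                                  haplotype_diversity)

# one dominant Y lineage (75% of sampled men) plus minor lineages
y_counts = HaplotypeCounts({"J1": 21, "J2": 3, "R1a": 2, "E1b": 1, "L": 1})
# mitochondrial lineages spread much more evenly
mt_counts = HaplotypeCounts({"H": 8, "L2": 6, "J": 5, "U": 4, "T": 3, "K": 2})

h_y = haplotype_diversity(y_counts)
h_mt = haplotype_diversity(mt_counts)
r = diversity_ratio(h_y, h_mt)
print(f"Y haplotype diversity  = {h_y:.3f}")
print(f"mt haplotype diversity = {h_mt:.3f}")
print(f"Y/mt ratio = {r['ratio']:.4f} "
      f"(printed to two truncated decimals: {r['ratio_2dp_truncated']})")
# A ratio far below 1 means fathers' lineages coalesce much faster than
# mothers' - the signature of patrilineal social structure.
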