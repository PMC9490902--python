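"""Simulate an admixed cohort with known ground truth and push it through QC.

Builds a three-ancestry Balding-Nichols cohort, writes it to VCF, reads it
back, and applies the four standard array-QC filters (relatedness, site
heterozygosity outliers, call rate, exact Hardy-Weinberg).
"""

import tempfile

import numpy as np

from admixkit import iohub, qc
from admixkit import synthgen as sg

variants, gmap = sg.uniform_variant_table(1500, {"1": 1.0, "2": 1.0})
freqs = sg.simulate_ancestral_freqs(K=3, L=1500, F=0.2, seed=1)
Q = np.random.default_rng(2).dirichlet([0.3, 0.3, 0.3], size=120)
haps, geno, truth = sg.simulate_admixed_cohort(freqs, Q, variants,
                                               pulse_g=15, seed=3)

with tempfile.NamedTemporaryFile(suffix=".vcf", mode="w", delete=False) as fh:
    path = fh.name
iohub.write_vcf(path, geno, haps)
back = iohub.read_vcf(path)
print(f"wrote and re-read {back.genotypes.n_samples} samples x "
      f"{back.genotypes.n_variants} variants "
      f"(phased={back.haplotypes is not None})")

clean, report = qc.qc_pipeline(back.genotypes)
print(f"QC: {geno.n_samples - clean.n_samples} samples and "
      f"{geno.n_variants - clean.n_variants} sites removed")
print(report.removed_sites["reason"].value_counts().to_string()
      if len(report.removed_sites) else "no sites removed")
# Clean simulated sites survive QC untouched.  A few samples can exceed the
# PI_HAT threshold even without true relatives: the method-of-moments IBD
# estimator is inflated for pairs sharing the same ancestry background,
# which is why relatedness pruning runs before structure analysis.
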