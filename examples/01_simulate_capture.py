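"""Simulate one capture experiment and inspect its bookkeeping.

Builds a small SNP panel and one ancient-DNA-like library, captures it
with the Twist-like assay preset, and prints the read accounting: total
reads, on-target reads, duplicate collapse, and the ground-truth per-SNP
effects the generator exposes for estimator validation.
"""

import numpy as np

import capturebias as cb

panel = cb.simulate_panel(n_snps=2_000, n_chromosomes=2, chrom_length=20_000_000, seed=1)
truth = cb.simulate_genotypes(panel, {"pop": 1}, seed=1)
library = cb.LibraryProfile(
    name="L1", complexity=200_000, endogenous_fraction=0.4, individual=0
)
assay = cb.make_assay_presets()["twist-like"]

result = cb.simulate_capture(truth, library, assay, n_reads=100_000, seed=1)

pre = result.counts.select(dedup="pre")
post = result.counts.select(dedup="post")
print(f"reads sequenced:        100000")
print(f"background (off-organism): {result.n_background_reads}")
print(f"reads overlapping a SNP:   {result.n_on_target_reads}")
print(f"pre-dedup allele reads:    {int(pre.df[['ref_count','alt_count']].sum().sum())}")
print(f"distinct molecules:        {int(post.df[['ref_count','alt_count']].sum().sum())}")
print(f"true per-SNP bias SD:      {result.effects.per_snp_beta.std():.3f}")
print(f"true efficiency spread:    {np.log(result.effects.efficiency).std():.3f}")

# The gap between pre- and post-dedup totals is the PCR-duplicate load;
# the bias SD and efficiency spread are the ground truth the reference-bias
# EM and the coverage QC are later asked to recover.
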