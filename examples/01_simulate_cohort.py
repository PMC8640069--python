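"""Simulate a case-control multi-omics cohort with planted ground truth.

Generates methylation, expression, genotype and HLA matrices plus a sample
sheet, and prints what was planted where.  The truth registry is what
recovery analyses are scored against.
"""

from siccaomics.simulate import SimulationConfig, simulate_cohort

config = SimulationConfig(
    n_cases=100, n_controls=100, n_cpgs=500, n_genes=200, n_snps=100,
    n_dmp=10, delta_beta_range=(0.2, 0.3),   # mean-shift CpGs
    n_vmp=5, variance_inflation=4.0,          # variance CpGs (cases only)
    n_deg=10, log2fc_range=(1.5, 2.5),        # differentially expressed genes
    n_meqtl=5, n_int_meqtl=3,                 # cis and case-only meQTLs
    ifn_block_size=5,                         # interferon hypomethylation block
    seed=1,
)
cohort = simulate_cohort(config)

print(f"methylation: {cohort.methylation.shape[0]} CpGs x {cohort.methylation.shape[1]} samples")
print(f"expression:  {cohort.expression.shape[0]} genes")
print(f"genotypes:   {cohort.genotypes.shape[0]} SNPs; HLA alleles: {cohort.hla.shape[0]}")
print(f"planted DMPs: {len(cohort.truth.dmp_effects)}  "
      f"(example: {next(iter(cohort.truth.dmp_effects.items()))})")
print(f"planted meQTL pairs: {list(cohort.truth.meqtl)[:2]} ...")
print(f"IFN block CpGs (hypomethylated in SSA+ cases only): {cohort.truth.ifn_block}")
# A negative Δβ means the CpG is hypomethylated in cases, the dominant
# direction in autoimmune interferonopathies.
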