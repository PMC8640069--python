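"""cis-meQTL scanning and disease-dependent (interaction) QTL discovery.

A cis scan over all SNP-CpG pairs within 1 Mb, then a genotype x disease
interaction scan with case/control stratified fits, and the three-condition
filter: replicated interaction with consistent sign, case-only association
without control evidence, and case MAF > 0.10.
"""

from siccaomics import qtl
from siccaomics.pipeline import split_cohort
from siccaomics.simulate import SimulationConfig, simulate_cohort

config = SimulationConfig(
    n_cases=800, n_controls=800, n_cpgs=1000, n_genes=50, n_snps=200,
    n_meqtl=20, qtl_effect_range=(0.05, 0.05), n_int_meqtl=20, seed=21)
cohort = simulate_cohort(config)
disc, repl = split_cohort(cohort.sheet, 0.5, seed=21)

pairs = qtl.cis_pairs(cohort.cpg_annotation, cohort.snp_annotation)
print(f"cis pairs within 1 Mb: {len(pairs)}")

scan = qtl.run_cis_scan(
    cohort.methylation.subset_samples(disc),
    cohort.genotypes.subset_samples(disc),
    cohort.sheet.subset(disc), pairs,
).set_index(["snp_id", "feature_id"])
planted = [k for k in cohort.truth.meqtl if k in scan.index]
sig = scan.loc[planted]
print(f"planted meQTLs at FDR<5%: {(sig.p_fdr < 0.05).mean():.0%}; "
      f"mean |beta| {sig.beta_qtl.abs().mean():.3f} per allele (planted 0.05)")

int_disc = qtl.run_interaction_scan(
    cohort.methylation.subset_samples(disc),
    cohort.genotypes.subset_samples(disc), cohort.sheet.subset(disc), pairs)
int_repl = qtl.run_interaction_scan(
    cohort.methylation.subset_samples(repl),
    cohort.genotypes.subset_samples(repl), cohort.sheet.subset(repl), pairs,
    maf_case_min=0.0)
selected = qtl.select_disease_dependent(int_disc, int_repl)
passing = selected[selected.passes_filter].set_index(["snp_id", "feature_id"])
truth_pairs = set(cohort.truth.interaction_meqtl)
print(f"pairs passing the disease-dependent filter: {len(passing)} "
      f"({sum(1 for k in passing.index if k in truth_pairs)} planted, "
      f"{sum(1 for k in passing.index if k not in truth_pairs)} false)")
row = passing.iloc[0]
print(f"example: beta_int={row.beta_int:+.3f} (case-only effect), "
      f"p_case={row.p_case:.1e}, p_ctrl={row.p_ctrl:.2f}, "
      f"replication p={row.replication_p_int:.3f}")
# beta_int is the extra per-allele effect present in patients only -- the
# genetic effect unmasked by the disease environment
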