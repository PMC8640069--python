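"""Mediation-direction verdicts and the HLA / autoantibody / IFN chain.

First classifies the bundled catalog of reported meQTL/eQTL SNPs by whether
allelic risk, molecular effect and disease effect compose coherently; then
runs the six-model HLA suite on a simulated chain where a class-II allele
raises anti-Ro/SSA risk, which in turn hypomethylates an interferon block.
"""

from siccaomics.assoc import hla_suite, mediation_consistency
from siccaomics.datasets import mediation_catalog
from siccaomics.ewas import bonferroni_threshold
from siccaomics.simulate import SimulationConfig, simulate_cohort

catalog = mediation_catalog()
verdicts = mediation_consistency(
    catalog[["snp_id", "feature_id", "layer", "beta_qtl"]],
    catalog[["feature_id", "beta_disease"]],
    catalog[["snp_id", "or_", "p"]], alpha_snp=0.05)
print(f"catalog rows mediation-consistent: "
      f"{verdicts.consistent.sum()}/{len(verdicts)}")
ex = verdicts[verdicts.snp_id == "rs9838739"].iloc[0]
print(f"example {ex.snp_id} -> {ex.feature_id}: {ex.narrative}")

config = SimulationConfig(n_cases=400, n_controls=400, n_cpgs=100, n_genes=10,
                          n_snps=10, ifn_block_size=10, seed=7)
cohort = simulate_cohort(config)
proxy = cohort.methylation.values.loc[cohort.truth.ifn_proxy_cpg]
alpha = bonferroni_threshold(0.05, config.n_hla_alleles)
suite = hla_suite(cohort.hla, cohort.sheet, proxy, alpha=alpha)
row = suite[suite.allele == cohort.truth.hla_risk_allele].iloc[0]
print(f"\nrisk allele {row.allele} (alpha={alpha:.1e}):")
print(f"  signature ~ allele:              p={row.p_epigifn:.1e}  (significant)")
print(f"  signature ~ allele + SSA:        p={row.p_epigifn_ssa:.2f} (attenuated)")
print(f"  disease ~ allele, signature+:    p={row.p_ss_pos:.1e}  (significant)")
print(f"  disease ~ allele, signature-:    p={row.p_ss_neg:.2f} (null)")
# the attenuation under the SSA covariate and the positive-stratum-only
# disease association are the signature of full mediation through the
# autoantibody-linked interferon state
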