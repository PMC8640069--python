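# Methods

This note documents the statistical models, the generative model behind the
synthetic cohorts, the numerical choices, and the limits of what the test
suite demonstrates.

## Analysis models

### Differential methylation (DMP)

Methylation is analysed on the beta scale (the fraction of methylated
molecules, in [0,1]); an M-value (logit₂) mode exists behind
`ModelSpec(m_values=True)` but is not the default, because effect sizes are
reported as Δβ and the beta scale keeps them interpretable. Per CpG an OLS
model regresses beta values on the case/control indicator plus covariates:
sex, age, the first genetic principal component, measured blood-cell
proportions, and batch. Cell proportions enter as k−1 columns (one dropped —
they sum to ~1 and would be collinear with the intercept); categorical batch
factors enter as treatment-coded dummies (reference level dropped). Because
the design is shared across CpGs, the scan solves one least-squares system
with a matrix of responses; tests verify the batched path against
`statsmodels.OLS` coefficient-for-coefficient. Inference is a two-sided *t*
test on the disease coefficient with both Bonferroni (over the CpGs actually
tested) and Benjamini–Hochberg columns.

### Differential variability (VMP)

Betas are first residualised on all covariates *except* disease, so that the
spread comparison is not contaminated by covariate effects; group mean
differences are then handled by the centring step of the test rather than by
regression. The test is Brown–Forsythe — Levene's statistic with
*median*-centred absolute deviations — which is the standard robust reading
of "a Levene test that accounts for mean differences"; classic mean-centred
Levene is available via `ModelSpec(levene_center="mean")`. Degenerate CpGs
(zero residual variance in a group, or all absolute deviations identical,
where the F statistic is 0/0) are reported with p = 1 and a flag.

### Region detection (DMR) and eQTM

CpGs are ranked by the signed disease *t* statistic (descending; ties broken
lexicographically on the CpG id so the ranking is a pure function of the
input). For each region with ≥ 5 ranked members, a weighted
Kolmogorov–Smirnov running sum is computed: member hits add
|score|ᵖ / Σ_members|score|ᵖ (p = 1, the GSEA-classic weight, configurable),
misses subtract 1/(N − n_members). The enrichment score is the running-sum
value of largest absolute deviation, signed; when peak and trough tie in
magnitude the positive extremum is taken (a 1e-12 tolerance keeps this
stable under float accumulation order). The leading edge is the members at
or before the extremum (at or after, for negative scores).

Significance uses a permutation null that redraws member sets of equal size
from the ranked list (the gene-permutation scheme of the GSEA family;
sample-label permutation would be much slower and tests a different null).
p_perm = (1 + #{|ES_null| ≥ |ES_obs|}) / (n_perm + 1), so the minimum
attainable p is 1/(n_perm+1); NES = ES / mean|ES_null|; BH-FDR is applied
within each region kind. Default n_perm = 999.

For eQTM, the leading-edge betas are averaged per sample and Pearson-
correlated with log-scale expression of genes whose TSS falls within 1500 bp
of the region span ([min member position, max member position], boundary
inclusive; distance 0 inside the span). Zero-variance vectors flag the
record rather than erroring.

### Differential expression

A deliberately compact count model: median-of-ratios size factors (computed
on genes with positive counts in all samples, normalised to geometric mean
1), a shifted log2 transform `log2(count/sf + 1)` for downstream
correlation/QTL use, and per-gene negative-binomial log-link regression
(statsmodels IRLS) with the log size factor as offset and a Wald test on the
disease coefficient. The gene-wise dispersion is estimated from Poisson-fit
residuals, `α = Σ[(y−μ)² − μ] / Σμ²`, floored at 1e-8: estimating α from
marginal moments would absorb covariate signal into overdispersion and make
the Wald test conservative. The marginal method-of-moments estimator remains
available as `estimate_dispersion`. There is no dispersion shrinkage,
outlier refitting or independent filtering; correctness is defined by
parameter recovery and null calibration on synthetic NB data, not by
equivalence with any larger DE framework. All-zero genes are dropped before
testing and excluded from the Bonferroni denominator.

### QTL scans

cis pairs are same-chromosome SNP–feature pairs with |SNP − anchor| ≤ 1 Mb,
boundary inclusive; anchors are the CpG coordinate and the strand-aware gene
TSS. All coordinates are 1-based. MAF = min(f, 1−f) with f = mean dosage / 2
over non-missing entries; dosages are analysed as given (fractional imputed
values allowed, no hard-calling), and missing dosages are dropped per pair
(complete-case). The cis model includes disease status as a covariate; the
interaction model adds dosage × disease and additionally reports case-only
and control-only stratified fits (a monomorphic stratum yields NA fields,
with the pair retained). The MAF floor for the cis scan (0.05) is computed
on the full cohort; the interaction floor (0.10) in cases only.

The disease-dependent filter requires (i) interaction P < 0.005 in discovery
and < 0.05 in replication with the same interaction sign, (ii) case-only
evidence (P_case < 0.05) with no control evidence (P_ctrl > 0.05 or NA), and
(iii) case MAF > 0.10. Case-group evidence can alternatively be taken at
BH-FDR < 0.05 (`FilterThresholds(ss_evidence="fdr")`); nominal P is the
default. Sign consistency compares interaction-term signs only. The filter
is idempotent and per-pair, with audit columns for each condition.

### Genetic association, mediation, HLA

Case–control association uses additive logistic regression (IRLS, Wald test)
with PC1 + sex + age as default covariates; complete separation and
non-convergence are flagged, not raised. A QTL SNP's verdict is
*mediation-consistent* when sign(β_QTL) × sign(log OR) equals
sign(β_disease-feature); an OR of exactly 1 has no sign and is flagged
`null_assoc`. The verdict is invariant to flipping the coded allele (both
signs flip). The epigenetic IFN label is a pure threshold on the proxy-CpG
beta (positive < 0.8; the boundary itself is negative). The six-model HLA
suite fits, per allele: logistic disease ~ allele + sex + age; logistic
autoantibody ~ allele + sex + age among cases only (controls are negative by
construction — including them would duplicate the disease model); linear
proxy-beta ~ allele + sex + age + cells + batch among cases, with and
without the autoantibody covariate; and the disease model restricted to
signature-positive (resp. negative) cases versus **all** controls. Bonferroni
is over the alleles tested.

## The synthetic cohort

Methylation is generated on the logit scale — baseline logit(b₀) per CpG
plus covariate loadings, disease effects and N(0, 0.35) noise — and passed
through the inverse logit, which keeps betas bounded. The beta-scale noise
sd is therefore ≈ 0.09 at mid-range CpGs and smaller near the boundaries,
the magnitude seen for variable whole-blood CpGs. Two calibrations translate
effect targets onto the logit scale:

- planted Δβ: the disease shift is logit(b₀+Δβ) − logit(b₀), i.e. the exact
  inversion at the baseline mean (noise smoothing leaves a residual bias
  below 0.01 at the default noise level);
- planted variance inflation: multiplying the logit noise sd by √inflation
  under-delivers on the beta scale (logistic compression turns a nominal 4×
  into ≈ 3.45×), so the case-noise multiplier is solved per site by
  Gauss–Hermite quadrature and bisection to hit the target beta-scale ratio.

cis effects (per-allele, beta scale) use the same logit inversion; case-only
interaction effects multiply the dosage term by the case indicator, so the
planted control-group effect is exactly zero. Planted QTL SNPs are placed
within 100 kb of their target and given MAF in (0.2, 0.45). Genotypes are
LD-free Binomial(2, MAF) draws; positions are uniform over a 4-chromosome,
200 Mb-per-chromosome genome.

Expression is negative-binomial with log2-scale means: baseline ~ N(6.5,
1.5), covariate loadings, planted log2FC · case (70% up-regulated by
default), planted QTL effects in log2 units per allele (so the log-scale
scan estimates them directly), a per-sample library factor, and dispersion
0.1. Region-companion genes additionally track their region's mean
methylation with a negative coupling, producing genuine eQTM correlations.

Confounding is real but controlled: cell proportions are Dirichlet with
case/control-specific concentrations (neutrophilia/lymphopenia in cases;
unadjusted DMP scans show ~2× type-I inflation, adjusted scans are
calibrated). The concentration separation and loading scale were chosen so
that the nonlinear logit→beta map does not convert composition differences
into spurious *variance* differences — with much stronger confounding the
null VMP scan genuinely loses calibration, a real phenomenon worth knowing
about when interpreting variability scans on the beta scale.

The HLA → SSA → IFN chain is retrospective: SSA status is drawn first among
cases (55% positive), and the risk-allele dosage of SSA-positive cases is
redrawn from the exponentially tilted genotype distribution
P(d) ∝ Binom(2, f)(d)·e^(log-OR·d) (f = 0.2, log-OR = 1.2/allele). This
makes the allele a risk factor for the autoantibody-positive disease subtype
specifically: signature-negative cases carry the population frequency, so
the stratified disease association is null there — the qualitative pattern
the HLA suite is designed to detect. (A prospective logistic draw instead
*depletes* the allele among signature-negatives, a selection artefact.) The
IFN block (default 10 CpGs, baselines 0.82–0.92) is hypomethylated by
ifn_delta_beta = 0.25 in SSA-positive cases only; the first block CpG serves
as the signature proxy, so the beta < 0.8 rule separates the strata cleanly.

Determinism: one `numpy` Generator seeded from the config drives every draw
in fixed order; identical configs give bit-identical matrices and truth.

## What passing tests show — and what they do not

Recovery and calibration results hold under the generator's assumptions:
independent SNPs (no LD), independent CpGs apart from planted regions,
Gaussian logit noise, NB counts with constant dispersion, covariates
measured without error, and effects that are exactly linear on the
generative scale. Real data violate all of these to some degree —
correlated probes, cell-type interactions, batch×disease entanglement,
count outliers — so the suite demonstrates *software correctness and
statistical calibration*, not robustness to misspecification. Array
preprocessing, alignment/quantification, genotype QC/imputation, HLA
imputation and ancestry estimation are all upstream of this package and out
of scope; the simulator hands over clean post-QC matrices by construction.

## Study sizes used in tests

Scan-level checks use 200+200 samples with 1000–2000 features; null
calibration uses a 200+200 no-effect cohort (2000 CpGs, 1000 genes, 500
SNPs); recovery uses an 800+800 cohort split 50/50 into discovery and
replication halves, so each interaction fit sees 400+400 — chosen from
power arithmetic so that β = 0.05/allele case-only effects clear the
replicated filter with ≥ 90% probability. The subtle-region demonstration
deliberately uses a small cohort (30+30) because that is the regime where a
coordinated Δβ = 0.05 × 8-CpG shift is invisible to single-CpG testing yet
detectable as a region.

## Known limitations

- HLA allele dosages are simulated independently per allele; real classical
  alleles at one locus are mutually exclusive haplotypes.
- The interaction model includes no covariate×disease terms; if covariate
  effects differ by group in real data, interaction estimates absorb them.
- Median-of-ratios normalization assumes most genes are not differentially
  expressed; with strongly asymmetric planted fold changes part of the
  shift is absorbed into size factors (a few percent at the 5% DE fraction
  used in tests).
- The permutation null for regions redraws CpG sets, which ignores
  inter-CpG correlation; on real arrays a sample-permutation null would be
  more conservative.
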