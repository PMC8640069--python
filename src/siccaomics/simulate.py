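"""Synthetic multi-omics case-control cohort generator with planted truth.

Emulates the data structure of a whole-blood Sjögren's-syndrome cohort:
DNA-methylation beta values with case/control mean shifts (DMPs) and
case-specific variance inflation (VMPs), negative-binomial RNA-seq counts
with planted log2 fold changes, additive cis genetic effects on both layers,
case-only (disease-interacting) genetic effects, cell-proportion and batch
confounding, and an HLA-allele → anti-Ro/SSA autoantibody → interferon
hypomethylation-block causal chain.  Every planted effect is recorded in a
:class:`CohortTruth` registry so recovery tests can score the pipeline.

Methylation is simulated on the logit scale and analysed on the beta scale;
planted Δβ and per-allele β targets are calibrated by inverting the logit
shift at each site's baseline mean, which keeps betas bounded while matching
the beta-scale effect-size metric used downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    MolecularMatrix,
    RegionSet,
    SampleSheet,
    feature_annotation_frame,
)

__all__ = [
    "SimulationConfig",
    "CohortTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "write_truth",
    "read_truth",
]


def _logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(64)


def _beta_scale_var(x0: float, sd: float) -> float:
    """Var of expit(x0 + sd·Z), Z ~ N(0,1), by Gauss–Hermite quadrature."""
    vals = _expit(x0 + sd * np.sqrt(2.0) * _GH_NODES)
    w = _GH_WEIGHTS / np.sqrt(np.pi)
    mean = np.sum(w * vals)
    return float(np.sum(w * (vals - mean) ** 2))


def _variance_multiplier(x0: float, sd: float, inflation: float) -> float:
    """Logit-noise multiplier whose beta-scale variance ratio is ``inflation``.

    The logistic transform compresses spread, so multiplying the logit noise
    sd by sqrt(inflation) under-delivers on the beta scale; solve for the
    multiplier by bisection instead.
    """
    base = _beta_scale_var(x0, sd)
    target = inflation * base
    lo, hi = 1.0, 10.0 * np.sqrt(inflation)
    if _beta_scale_var(x0, hi * sd) < target:
        return hi  # saturated; best achievable
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _beta_scale_var(x0, mid * sd) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class SimulationConfig:
    """Generative parameters of the synthetic cohort.

    Counts of planted effects must not exceed the corresponding feature
    counts; all ranges must be well-ordered.  ``qtl_effect_range`` is on the
    methylation beta scale (per minor allele); ``eqtl_effect_range`` is in
    log2 expression units per allele.
    """

    n_cases: int = 200
    n_controls: int = 200
    n_cpgs: int = 2000
    n_genes: int = 1000
    n_snps: int = 500
    maf_range: tuple[float, float] = (0.1, 0.5)
    # planted mean-shift CpGs
    n_dmp: int = 0
    delta_beta_range: tuple[float, float] = (0.1, 0.3)
    dmp_hypo_fraction: float = 0.9
    # planted variance CpGs
    n_vmp: int = 0
    variance_inflation: float = 4.0
    # planted differentially expressed genes
    n_deg: int = 0
    log2fc_range: tuple[float, float] = (1.0, 2.0)
    deg_up_fraction: float = 0.7
    nb_dispersion: float = 0.1
    # planted cis and interaction QTLs
    n_meqtl: int = 0
    n_eqtl: int = 0
    n_int_meqtl: int = 0
    n_int_eqtl: int = 0
    qtl_effect_range: tuple[float, float] = (0.03, 0.08)
    eqtl_effect_range: tuple[float, float] = (0.2, 0.5)
    qtl_maf_range: tuple[float, float] = (0.2, 0.45)
    cis_offset_bp: int = 100_000
    # coordinated region (DMR) planting
    n_dmr_regions: int = 0
    dmr_region_size: int = 8
    dmr_delta_beta: float = 0.05
    n_regions: int = 40
    eqtm_coupling: float = -12.0
    # HLA → SSA → IFN chain
    n_hla_alleles: int = 30
    hla_risk_freq: float = 0.2
    hla_ssa_log_or: float = 1.2
    ssa_pos_fraction: float = 0.55
    ifn_block_size: int = 0
    ifn_delta_beta: float = 0.25
    # nuisance structure
    noise_sd: float = 0.35
    cell_load_sd: float = 0.4
    confounded_batch: bool = False
    n_chrom: int = 4
    chrom_length: int = 200_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 cases and 2 controls")
        for name in ("maf_range", "delta_beta_range", "log2fc_range",
                     "qtl_effect_range", "eqtl_effect_range", "qtl_maf_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is not well-ordered: {lo} > {hi}")
        if not (0 < self.maf_range[0] and self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if self.variance_inflation <= 1:
            raise ValueError("variance_inflation must exceed 1")
        cpg_used = (self.n_dmp + self.n_vmp + self.n_meqtl + self.n_int_meqtl
                    + self.ifn_block_size + self.n_dmr_regions * self.dmr_region_size)
        if cpg_used > self.n_cpgs:
            raise ValueError("planted CpG effects exceed n_cpgs")
        if self.n_deg + self.n_eqtl + self.n_int_eqtl > self.n_genes:
            raise ValueError("planted gene effects exceed n_genes")
        if self.n_meqtl + self.n_eqtl + self.n_int_meqtl + self.n_int_eqtl > self.n_snps:
            raise ValueError("planted QTL SNPs exceed n_snps")
        if not (0 < self.ifn_delta_beta < 1):
            raise ValueError("ifn_delta_beta must lie in (0, 1)")


@dataclass
class CohortTruth:
    """Registry of every planted effect, keyed by feature / pair ids.

    QTL maps are keyed ``(snp_id, feature_id)``; interaction entries have a
    zero planted control-group effect by construction.
    """

    dmp_effects: dict = field(default_factory=dict)       # cpg -> Δβ (case − control)
    vmp_features: dict = field(default_factory=dict)      # cpg -> variance factor
    deg_effects: dict = field(default_factory=dict)       # gene -> log2FC
    meqtl: dict = field(default_factory=dict)             # (snp, cpg) -> β per allele
    eqtl: dict = field(default_factory=dict)              # (snp, gene) -> log2 per allele
    interaction_meqtl: dict = field(default_factory=dict)  # (snp, cpg) -> case-only β
    interaction_eqtl: dict = field(default_factory=dict)   # (snp, gene) -> case-only log2
    dmr_regions: dict = field(default_factory=dict)       # region_id -> {"members": [...], "delta_beta": x, "gene": id}
    ifn_block: list = field(default_factory=list)         # CpG ids
    ifn_proxy_cpg: str | None = None
    hla_risk_allele: str | None = None
    hla_ssa_log_or: float = 0.0

    def is_empty(self) -> bool:
        return not (self.dmp_effects or self.vmp_features or self.deg_effects
                    or self.meqtl or self.eqtl or self.interaction_meqtl
                    or self.interaction_eqtl or self.dmr_regions or self.ifn_block)


@dataclass
class SimulatedCohort:
    genotypes: MolecularMatrix
    methylation: MolecularMatrix
    expression: MolecularMatrix
    hla: MolecularMatrix
    sheet: SampleSheet
    truth: CohortTruth
    snp_annotation: pd.DataFrame
    cpg_annotation: pd.DataFrame
    gene_annotation: pd.DataFrame
    regions: list[RegionSet]


# cell types tracked in the sheet; concentrations give neutrophilia /
# lymphopenia in cases, a genuine confounder of the disease contrast
_CELLS = ("neu", "lym", "mono", "eos", "bas")
_ALPHA_CASE = np.array([52.0, 28.0, 9.0, 3.5, 2.0])
_ALPHA_CTRL = np.array([48.0, 32.0, 9.5, 3.8, 2.0])


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate all data layers plus the planted-truth registry.

    Identical config (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    samples = [f"S{i:04d}" for i in range(n)]
    case = np.zeros(n, dtype=bool)
    case[: config.n_cases] = True

    # ------------------------------------------------------------------ sheet
    sex_m = rng.random(n) < np.where(case, 0.08, 0.12)       # female-predominant
    age = np.clip(rng.normal(np.where(case, 55.0, 50.0), 12.0), 18, 85)
    cells = np.empty((n, len(_CELLS)))
    cells[case] = rng.dirichlet(_ALPHA_CASE, case.sum())
    cells[~case] = rng.dirichlet(_ALPHA_CTRL, (~case).sum())
    if config.confounded_batch:
        batch_b = rng.random(n) < np.where(case, 0.7, 0.3)
    else:
        batch_b = rng.random(n) < 0.5
    batch = np.where(batch_b, "B2", "B1")
    pool = rng.choice(["P1", "P2", "P3"], size=n)
    rin = np.clip(rng.normal(8.0, 0.7, n), 5.0, 10.0)
    pc1 = rng.normal(0.0, 1.0, n)
    antimalarial = case & (rng.random(n) < 0.30)
    steroids = case & (rng.random(n) < 0.25)
    immunosup = case & (rng.random(n) < 0.20)

    # -------------------------------------------------------------- HLA layer
    hla_ids = [f"HLA_{i:03d}" for i in range(config.n_hla_alleles)]
    hla_freq = rng.uniform(0.02, 0.35, config.n_hla_alleles)
    risk_allele = None
    if config.n_hla_alleles and config.hla_ssa_log_or != 0.0:
        hla_freq[0] = config.hla_risk_freq
        risk_allele = hla_ids[0]
    hla_dose = rng.binomial(2, hla_freq[:, None], (config.n_hla_alleles, n)).astype(float)

    # SSA status first (fixed case fraction), then the risk-allele dosage of
    # SSA-positive cases is redrawn from the exponentially tilted genotype
    # distribution P(d) ∝ Binom(2, f)(d) · exp(log_or · d).  SSA-negative
    # cases and controls keep the population distribution, so the allele is
    # associated with the autoantibody-positive disease subtype only.
    ssa = np.full(n, "negative", dtype=object)
    ssa_pos = case & (rng.random(n) < config.ssa_pos_fraction)
    if risk_allele is not None and ssa_pos.any():
        f = config.hla_risk_freq
        base = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
        tilt = base * np.exp(config.hla_ssa_log_or * np.arange(3))
        tilt /= tilt.sum()
        hla_dose[0, ssa_pos] = rng.choice(3, size=ssa_pos.sum(), p=tilt).astype(float)
    ssa[ssa_pos] = "positive"
    ssb = np.full(n, "negative", dtype=object)
    ssb[ssa_pos & (rng.random(n) < 0.45)] = "positive"

    sheet_df = pd.DataFrame(
        {
            "sample_id": samples,
            "disease": np.where(case, "case", "control"),
            "sex": np.where(sex_m, "M", "F"),
            "age": np.round(age, 1),
            "ssa": ssa,
            "ssb": ssb,
            **{f"cell_{c}": cells[:, i] for i, c in enumerate(_CELLS)},
            "batch": batch,
            "pool": pool,
            "rin": np.round(rin, 2),
            "pc1": pc1,
            "antimalarial": antimalarial,
            "steroids": steroids,
            "immunosuppressant": immunosup,
        }
    )
    sheet = SampleSheet(sheet_df)

    # -------------------------------------------------------- genome geometry
    cpg_ids = [f"cg{i:06d}" for i in range(config.n_cpgs)]
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    snp_ids = [f"rs{i:06d}" for i in range(config.n_snps)]
    cpg_chrom = rng.integers(1, config.n_chrom + 1, config.n_cpgs)
    cpg_pos = rng.integers(1, config.chrom_length, config.n_cpgs)
    gene_chrom = rng.integers(1, config.n_chrom + 1, config.n_genes)
    gene_pos = rng.integers(1, config.chrom_length, config.n_genes)
    gene_strand = rng.choice(["+", "-"], config.n_genes)
    snp_chrom = rng.integers(1, config.n_chrom + 1, config.n_snps)
    snp_pos = rng.integers(1, config.chrom_length, config.n_snps)

    # ------------------------------------------------------------- genotypes
    maf = rng.uniform(*config.maf_range, config.n_snps)
    truth = CohortTruth(hla_risk_allele=risk_allele,
                        hla_ssa_log_or=config.hla_ssa_log_or if risk_allele else 0.0)

    # assign planted features without overlap
    cpg_pool = list(rng.permutation(config.n_cpgs))
    gene_pool = list(rng.permutation(config.n_genes))
    snp_pool = list(rng.permutation(config.n_snps))

    def take(pool: list, k: int) -> list[int]:
        out, del_ = pool[:k], pool[k:]
        pool[:] = del_
        return out

    dmp_idx = take(cpg_pool, config.n_dmp)
    vmp_idx = take(cpg_pool, config.n_vmp)
    meqtl_cpg = take(cpg_pool, config.n_meqtl)
    int_meqtl_cpg = take(cpg_pool, config.n_int_meqtl)
    ifn_idx = take(cpg_pool, config.ifn_block_size)
    dmr_idx = [take(cpg_pool, config.dmr_region_size) for _ in range(config.n_dmr_regions)]
    deg_idx = take(gene_pool, config.n_deg)
    eqtl_gene = take(gene_pool, config.n_eqtl)
    int_eqtl_gene = take(gene_pool, config.n_int_eqtl)
    meqtl_snp = take(snp_pool, config.n_meqtl)
    eqtl_snp = take(snp_pool, config.n_eqtl)
    int_meqtl_snp = take(snp_pool, config.n_int_meqtl)
    int_eqtl_snp = take(snp_pool, config.n_int_eqtl)

    # planted QTL SNPs are placed in cis of their target and given a
    # comfortably common MAF so stratified fits are well-conditioned
    for snps, feats, fchrom, fpos in (
        (meqtl_snp, meqtl_cpg, cpg_chrom, cpg_pos),
        (int_meqtl_snp, int_meqtl_cpg, cpg_chrom, cpg_pos),
        (eqtl_snp, eqtl_gene, gene_chrom, gene_pos),
        (int_eqtl_snp, int_eqtl_gene, gene_chrom, gene_pos),
    ):
        for s_i, f_i in zip(snps, feats):
            snp_chrom[s_i] = fchrom[f_i]
            snp_pos[s_i] = max(1, fpos[f_i] + int(rng.integers(-config.cis_offset_bp,
                                                               config.cis_offset_bp + 1)))
            maf[s_i] = rng.uniform(*config.qtl_maf_range)

    dosages = rng.binomial(2, maf[:, None], (config.n_snps, n)).astype(float)

    # --------------------------------------------------------- methylation
    baseline = rng.uniform(0.1, 0.9, config.n_cpgs)
    delta = np.zeros(config.n_cpgs)
    for i in dmp_idx:
        mag = rng.uniform(*config.delta_beta_range)
        sign = -1.0 if rng.random() < config.dmp_hypo_fraction else 1.0
        d = sign * mag
        lo = 0.08 + max(0.0, -d)
        hi = 0.92 - max(0.0, d)
        baseline[i] = rng.uniform(lo, hi)
        delta[i] = d
        truth.dmp_effects[cpg_ids[i]] = d
    for i in vmp_idx:
        baseline[i] = rng.uniform(0.35, 0.65)
        truth.vmp_features[cpg_ids[i]] = config.variance_inflation

    region_records: list[RegionSet] = []
    kinds = RegionSet.REGION_KINDS
    for r, members in enumerate(dmr_idx):
        rid = f"DMR{r:03d}"
        d = config.dmr_delta_beta
        # members sit consecutively on one chromosome so the region has a
        # compact span; a companion gene TSS lands within the eQTM window
        chrom = int(rng.integers(1, config.n_chrom + 1))
        start = int(rng.integers(1, config.chrom_length - 100_000))
        for j, i in enumerate(members):
            cpg_chrom[i] = chrom
            cpg_pos[i] = start + 500 * j
            baseline[i] = rng.uniform(0.25 + max(0.0, -d), 0.75 - max(0.0, d))
            delta[i] = d
        gene_i = gene_pool.pop() if gene_pool else None
        if gene_i is not None:
            gene_chrom[gene_i] = chrom
            gene_pos[gene_i] = start + 500 * (len(members) - 1) + 800
        truth.dmr_regions[rid] = {
            "members": [cpg_ids[i] for i in members],
            "delta_beta": d,
            "gene": gene_ids[gene_i] if gene_i is not None else None,
        }
        region_records.append(RegionSet(rid, "promoter", [cpg_ids[i] for i in members]))

    for i in ifn_idx:
        baseline[i] = rng.uniform(0.82, 0.92)
    truth.ifn_block = [cpg_ids[i] for i in ifn_idx]
    truth.ifn_proxy_cpg = cpg_ids[ifn_idx[0]] if ifn_idx else None

    # background regions from position-sorted CpGs
    order = np.lexsort((cpg_pos, cpg_chrom))
    cursor = 0
    for r in range(config.n_regions):
        size = int(rng.integers(5, 13))
        if cursor + size > config.n_cpgs:
            break
        members = [cpg_ids[i] for i in order[cursor: cursor + size]]
        region_records.append(RegionSet(f"R{r:03d}", kinds[r % len(kinds)], members))
        cursor += size

    logit_base = _logit(baseline)
    L = np.tile(logit_base[:, None], (1, n))

    # disease shifts calibrated by logit inversion at the baseline mean
    shift = _logit(np.clip(baseline + delta, 1e-4, 1 - 1e-4)) - logit_base
    L += np.outer(shift, case.astype(float))

    # IFN-block hypomethylation only in SSA-positive cases
    if ifn_idx:
        ifn_shift = _logit(np.clip(baseline[ifn_idx] - config.ifn_delta_beta,
                                   1e-4, 1 - 1e-4)) - logit_base[ifn_idx]
        L[ifn_idx] += np.outer(ifn_shift, ssa_pos.astype(float))

    # covariate loadings on centred covariates (keeps baselines interpretable)
    mean_cells = (_ALPHA_CASE / _ALPHA_CASE.sum() + _ALPHA_CTRL / _ALPHA_CTRL.sum()) / 2
    cells_c = cells - mean_cells
    cell_load = rng.normal(0.0, config.cell_load_sd, (config.n_cpgs, len(_CELLS)))
    L += cell_load @ cells_c.T
    sex_load = rng.normal(0.0, 0.5, config.n_cpgs) * (rng.random(config.n_cpgs) < 0.1)
    L += np.outer(sex_load, sex_m.astype(float) - 0.1)
    age_load = rng.normal(0.0, 0.005, config.n_cpgs)
    L += np.outer(age_load, (age - 52.0))
    batch_load = rng.normal(0.0, 0.3, config.n_cpgs) * (rng.random(config.n_cpgs) < 0.2)
    L += np.outer(batch_load, batch_b.astype(float) - 0.5)
    pc1_load = rng.normal(0.0, 0.1, config.n_cpgs)
    L += np.outer(pc1_load, pc1)

    # cis meQTL effects (additive per allele, both groups)
    for s_i, c_i in zip(meqtl_snp, meqtl_cpg):
        beta = rng.uniform(*config.qtl_effect_range) * (1 if rng.random() < 0.5 else -1)
        b0 = np.clip(baseline[c_i], 0.15, 0.85)
        baseline[c_i] = b0
        L[c_i] = _logit(b0) + (L[c_i] - logit_base[c_i])
        slope = _logit(np.clip(b0 + beta, 1e-4, 1 - 1e-4)) - _logit(b0)
        L[c_i] += slope * dosages[s_i]
        truth.meqtl[(snp_ids[s_i], cpg_ids[c_i])] = beta

    # interaction meQTLs: dosage effect only in cases (zero control effect)
    for s_i, c_i in zip(int_meqtl_snp, int_meqtl_cpg):
        beta = rng.uniform(*config.qtl_effect_range) * (1 if rng.random() < 0.5 else -1)
        b0 = np.clip(baseline[c_i], 0.15, 0.85)
        baseline[c_i] = b0
        L[c_i] = _logit(b0) + (L[c_i] - logit_base[c_i])
        slope = _logit(np.clip(b0 + beta, 1e-4, 1 - 1e-4)) - _logit(b0)
        L[c_i] += slope * dosages[s_i] * case.astype(float)
        truth.interaction_meqtl[(snp_ids[s_i], cpg_ids[c_i])] = beta

    noise_sd = np.full((config.n_cpgs, n), config.noise_sd)
    if vmp_idx:
        mult = np.array([
            _variance_multiplier(_logit(baseline[i]), config.noise_sd,
                                 config.variance_inflation)
            for i in vmp_idx
        ])
        noise_sd[np.ix_(vmp_idx, np.where(case)[0])] *= mult[:, None]
    L += rng.normal(0.0, 1.0, (config.n_cpgs, n)) * noise_sd
    betas = _expit(L)

    # ---------------------------------------------------------- expression
    base_log2 = rng.normal(6.5, 1.5, config.n_genes)
    M = np.tile(base_log2[:, None], (1, n))
    for i in deg_idx:
        mag = rng.uniform(*config.log2fc_range)
        sign = 1.0 if rng.random() < config.deg_up_fraction else -1.0
        lfc = sign * mag
        M[i] += lfc * case.astype(float)
        truth.deg_effects[gene_ids[i]] = lfc
    for s_i, g_i in zip(eqtl_snp, eqtl_gene):
        b = rng.uniform(*config.eqtl_effect_range) * (1 if rng.random() < 0.5 else -1)
        M[g_i] += b * dosages[s_i]
        truth.eqtl[(snp_ids[s_i], gene_ids[g_i])] = b
    for s_i, g_i in zip(int_eqtl_snp, int_eqtl_gene):
        b = rng.uniform(*config.eqtl_effect_range) * (1 if rng.random() < 0.5 else -1)
        M[g_i] += b * dosages[s_i] * case.astype(float)
        truth.interaction_eqtl[(snp_ids[s_i], gene_ids[g_i])] = b

    # expression of DMR companion genes tracks region methylation (eQTM)
    for rid, info in truth.dmr_regions.items():
        if info["gene"] is None:
            continue
        rows = [cpg_ids.index(c) for c in info["members"]]
        prof = betas[rows].mean(axis=0)
        g_i = gene_ids.index(info["gene"])
        M[g_i] += config.eqtm_coupling * (prof - prof.mean())

    cell_load_e = rng.normal(0.0, 1.0, (config.n_genes, len(_CELLS)))
    M += cell_load_e @ cells_c.T
    M += np.outer(rng.normal(0.0, 0.3, config.n_genes) *
                  (rng.random(config.n_genes) < 0.3), batch_b.astype(float) - 0.5)
    pool_levels = {"P1": -1.0, "P2": 0.0, "P3": 1.0}
    pool_num = np.array([pool_levels[p] for p in pool])
    M += np.outer(rng.normal(0.0, 0.15, config.n_genes), pool_num)
    M += np.outer(rng.normal(0.0, 0.05, config.n_genes), rin - 8.0)
    M += np.outer(rng.normal(0.0, 0.005, config.n_genes), age - 52.0)
    M += np.outer(rng.normal(0.0, 0.05, config.n_genes), pc1)

    lib = np.exp(rng.normal(0.0, 0.25, n))
    mu = lib[None, :] * np.power(2.0, M)
    r_nb = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r_nb, r_nb / (r_nb + mu)).astype(float)

    # ------------------------------------------------------------- assemble
    genotypes = MolecularMatrix(pd.DataFrame(dosages, index=snp_ids, columns=samples),
                                "dosage")
    methylation = MolecularMatrix(pd.DataFrame(betas, index=cpg_ids, columns=samples),
                                  "methylation")
    expression = MolecularMatrix(pd.DataFrame(counts, index=gene_ids, columns=samples),
                                 "expression")
    hla = MolecularMatrix(pd.DataFrame(hla_dose, index=hla_ids, columns=samples), "hla")

    snp_annot = feature_annotation_frame(
        [{"feature_id": s, "chrom": f"chr{c}", "pos": int(p)}
         for s, c, p in zip(snp_ids, snp_chrom, snp_pos)]
    )
    cpg_annot = feature_annotation_frame(
        [{"feature_id": s, "chrom": f"chr{c}", "pos": int(p)}
         for s, c, p in zip(cpg_ids, cpg_chrom, cpg_pos)]
    )
    gene_annot = feature_annotation_frame(
        [{"feature_id": s, "chrom": f"chr{c}", "pos": int(p), "strand": st}
         for s, c, p, st in zip(gene_ids, gene_chrom, gene_pos, gene_strand)]
    )
    return SimulatedCohort(genotypes, methylation, expression, hla, sheet, truth,
                           snp_annot, cpg_annot, gene_annot, region_records)


# ----------------------------------------------------------------------
# truth registry serialization (JSON; pair keys joined with "|")
# ----------------------------------------------------------------------

def _pairs_out(d: dict) -> dict:
    return {f"{k[0]}|{k[1]}": v for k, v in d.items()}


def _pairs_in(d: dict) -> dict:
    return {tuple(k.split("|", 1)): v for k, v in d.items()}


def write_truth(truth: CohortTruth, path: str | Path) -> None:
    obj = {
        "dmp_effects": truth.dmp_effects,
        "vmp_features": truth.vmp_features,
        "deg_effects": truth.deg_effects,
        "meqtl": _pairs_out(truth.meqtl),
        "eqtl": _pairs_out(truth.eqtl),
        "interaction_meqtl": _pairs_out(truth.interaction_meqtl),
        "interaction_eqtl": _pairs_out(truth.interaction_eqtl),
        "dmr_regions": truth.dmr_regions,
        "ifn_block": truth.ifn_block,
        "ifn_proxy_cpg": truth.ifn_proxy_cpg,
        "hla_risk_allele": truth.hla_risk_allele,
        "hla_ssa_log_or": truth.hla_ssa_log_or,
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(path: str | Path) -> CohortTruth:
    with open(path) as fh:
        obj = json.load(fh)
    try:
        return CohortTruth(
            dmp_effects=obj["dmp_effects"],
            vmp_features=obj["vmp_features"],
            deg_effects=obj["deg_effects"],
            meqtl=_pairs_in(obj["meqtl"]),
            eqtl=_pairs_in(obj["eqtl"]),
            interaction_meqtl=_pairs_in(obj["interaction_meqtl"]),
            interaction_eqtl=_pairs_in(obj["interaction_eqtl"]),
            dmr_regions=obj["dmr_regions"],
            ifn_block=obj["ifn_block"],
            ifn_proxy_cpg=obj["ifn_proxy_cpg"],
            hla_risk_allele=obj["hla_risk_allele"],
            hla_ssa_log_or=obj["hla_ssa_log_or"],
        )
    except KeyError as e:  # malformed file
        raise ValueError(f"truth registry missing field {e}") from e
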