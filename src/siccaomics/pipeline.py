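"""End-to-end orchestration: simulate → EWAS → DMR → eQTM → DE → QTL →
interaction → mediation → HLA, from one config, with seeding, per-stage TSV
outputs plus JSON parameter sidecars, and a machine-readable run manifest.

The discovery/replication design is a stratified split of the cohort:
discovery-selected features (DMPs, DEGs, interaction pairs) are re-tested on
the held-out replication samples.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, diffexpr, dmr, ewas, qtl
from .io import (
    SampleSheet,
    write_annotation,
    write_gmt,
    write_json,
    write_matrix,
    write_results,
    write_sample_sheet,
    write_vcf_dosages,
)
from .simulate import SimulationConfig, SimulatedCohort, simulate_cohort, write_truth

__all__ = ["RunConfig", "run_pipeline", "split_cohort"]

log = logging.getLogger("siccaomics.pipeline")


@dataclass
class RunConfig:
    """Pipeline configuration (simulation block + per-stage parameters)."""

    simulation: SimulationConfig
    out_dir: str | Path = "pipeline_out"
    seed: int = 0
    split_fraction: float = 0.5
    alpha: float = 0.05
    covariates_meth: tuple = ewas.DEFAULT_COVARIATES
    covariates_expr: tuple = diffexpr.DEFAULT_DE_COVARIATES
    cis_window: int = qtl.CIS_WINDOW
    maf_min: float = 0.05
    n_perm: int = 999
    dmr_fdr: float = 0.05
    eqtm_window: int = 1500
    interaction: qtl.FilterThresholds = field(default_factory=qtl.FilterThresholds)
    alpha_snp: float = 0.05
    simulate_only: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")
        if self.cis_window <= 0:
            raise ValueError("cis window must be positive")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split fraction must lie in (0,1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        inter = qtl.FilterThresholds(**raw.pop("interaction", {}))
        return cls(simulation=sim, interaction=inter, **raw)


def split_cohort(
    sheet: SampleSheet, fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Disjoint discovery/replication sample ids, stratified by disease."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0,1)")
    rng = np.random.default_rng(seed)
    discovery: list[str] = []
    replication: list[str] = []
    for _, sub in sheet.data.groupby("disease"):
        ids = list(sub["sample_id"])
        if len(ids) < 2:
            raise ValueError("stratum too small to split")
        perm = rng.permutation(len(ids))
        k = int(round(fraction * len(ids)))
        k = min(max(k, 1), len(ids) - 1)
        discovery += [ids[i] for i in perm[:k]]
        replication += [ids[i] for i in perm[k:]]
    order = {s: i for i, s in enumerate(sheet.sample_ids)}
    return sorted(discovery, key=order.get), sorted(replication, key=order.get)


def _stage(manifest: dict, name: str, params: dict, out_dir: Path):
    start = time.perf_counter()

    def finish(table: pd.DataFrame | None):
        elapsed = time.perf_counter() - start
        rows = 0 if table is None else len(table)
        if table is not None:
            write_results(table, out_dir / f"{name}.tsv")
        write_json({"stage": name, "params": params, "rows": rows},
                   out_dir / f"{name}.params.json")
        manifest["stages"][name] = {"rows": rows, "elapsed_s": round(elapsed, 3),
                                    "params": params}
        log.info("stage=%s rows=%d elapsed=%.2fs", name, rows, elapsed)

    return finish


def run_pipeline(config: RunConfig, cohort: SimulatedCohort | None = None) -> dict:
    """Execute all stages in DAG order; returns the run manifest dict.

    ``cohort`` may be supplied to skip simulation (e.g. loaded data).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(name)s %(levelname)s %(message)s")
    manifest: dict = {"seed": config.seed, "stages": {}, "thresholds": {
        "alpha": config.alpha, "maf_min": config.maf_min,
        "cis_window": config.cis_window, "dmr_fdr": config.dmr_fdr,
        "eqtm_window": config.eqtm_window, "alpha_snp": config.alpha_snp,
        "p_int_discovery": config.interaction.p_int_discovery,
        "p_int_replication": config.interaction.p_int_replication,
        "maf_case_min": config.interaction.maf_case_min,
    }}

    # ----------------------------------------------------------- simulate
    finish = _stage(manifest, "simulate", {"seed": config.simulation.seed}, out)
    if cohort is None:
        cohort = simulate_cohort(config.simulation)
    write_matrix(cohort.methylation, out / "methylation.tsv")
    write_matrix(cohort.expression, out / "expression.tsv")
    write_matrix(cohort.hla, out / "hla.tsv")
    write_vcf_dosages(cohort.genotypes, cohort.snp_annotation, out / "genotypes.vcf")
    write_sample_sheet(cohort.sheet, out / "samples.tsv")
    write_gmt(cohort.regions, out / "regions.gmt")
    write_annotation(cohort.cpg_annotation, out / "cpgs.tsv")
    write_annotation(cohort.gene_annotation, out / "genes.tsv")
    write_annotation(cohort.snp_annotation, out / "snps.tsv")
    write_truth(cohort.truth, out / "truth.json")
    finish(cohort.sheet.data)
    if config.simulate_only:
        write_json(manifest, out / "manifest.json")
        return manifest

    # ------------------------------------------------------------- split
    disc_ids, repl_ids = split_cohort(cohort.sheet, config.split_fraction,
                                      config.seed)
    sheet_d = cohort.sheet.subset(disc_ids)
    sheet_r = cohort.sheet.subset(repl_ids)
    meth_d = cohort.methylation.subset_samples(disc_ids)
    meth_r = cohort.methylation.subset_samples(repl_ids)
    expr_d = cohort.expression.subset_samples(disc_ids)
    expr_r = cohort.expression.subset_samples(repl_ids)
    geno_d = cohort.genotypes.subset_samples(disc_ids)
    geno_r = cohort.genotypes.subset_samples(repl_ids)

    spec_m = ewas.ModelSpec(covariates=config.covariates_meth)
    spec_e = ewas.ModelSpec(covariates=config.covariates_expr)
    m_cpgs = cohort.methylation.shape[0]

    # --------------------------------------------------------------- EWAS
    finish = _stage(manifest, "dmp_discovery", {"covariates": list(spec_m.covariates)}, out)
    dmp_d = ewas.run_dmp_scan(meth_d, sheet_d, spec_m)
    finish(dmp_d)
    dmp_threshold = ewas.bonferroni_threshold(config.alpha, m_cpgs)
    dmp_hits = dmp_d[dmp_d["p"] < dmp_threshold]

    finish = _stage(manifest, "dmp_replication", {"threshold": 0.05}, out)
    dmp_r = ewas.run_dmp_scan(meth_r.subset_features(list(dmp_hits["feature_id"])),
                              sheet_r, spec_m) if len(dmp_hits) else dmp_d.iloc[0:0]
    finish(dmp_r)

    finish = _stage(manifest, "vmp", {"center": spec_m.levene_center}, out)
    vmp_d = ewas.run_vmp_scan(meth_d, sheet_d, spec_m)
    finish(vmp_d)

    # ---------------------------------------------------------------- DMR
    finish = _stage(manifest, "dmr", {"n_perm": config.n_perm}, out)
    dmr_d = dmr.dmr_scan(dmp_d, cohort.regions, n_perm=config.n_perm,
                         seed=config.seed)
    finish(dmr_d)

    # --------------------------------------------------------------- eQTM
    finish = _stage(manifest, "eqtm", {"window": config.eqtm_window}, out)
    vst_d = diffexpr.vst_matrix(expr_d)
    sig_dmr = dmr_d[dmr_d["p_fdr"] < config.dmr_fdr] if len(dmr_d) else dmr_d
    profiles = pd.DataFrame(
        {rid: dmr.leading_edge_profile(meth_d, edge.split(","))
         for rid, edge in zip(sig_dmr.get("region_id", []),
                              sig_dmr.get("leading_edge", []))}
    ).T
    spans = dmr.region_spans(cohort.regions, cohort.cpg_annotation)
    eqtm_t = (dmr.eqtm_scan(profiles, vst_d.values, cohort.gene_annotation, spans,
                            config.eqtm_window)
              if len(profiles) else pd.DataFrame(
                  columns=["region_id", "gene_id", "pearson_r", "p", "n",
                           "degenerate"]))
    finish(eqtm_t)

    # ----------------------------------------------------------------- DE
    finish = _stage(manifest, "de_discovery", {"covariates": list(spec_e.covariates)}, out)
    de_d = diffexpr.run_de_scan(expr_d, sheet_d, spec_e)
    finish(de_d)
    de_threshold = ewas.bonferroni_threshold(config.alpha, len(de_d))
    deg_hits = de_d[de_d["p"] < de_threshold]

    # ---------------------------------------------------------------- QTL
    qtl_spec = ewas.ModelSpec(covariates=qtl.DEFAULT_QTL_COVARIATES)
    cpg_annot_hits = cohort.cpg_annotation[
        cohort.cpg_annotation["feature_id"].isin(dmp_hits["feature_id"])]
    gene_annot_hits = cohort.gene_annotation[
        cohort.gene_annotation["feature_id"].isin(deg_hits["gene_id"])]
    pairs_m = qtl.cis_pairs(cpg_annot_hits, cohort.snp_annotation, config.cis_window)
    pairs_e = qtl.cis_pairs(gene_annot_hits, cohort.snp_annotation, config.cis_window)

    finish = _stage(manifest, "meqtl", {"window": config.cis_window,
                                        "maf_min": config.maf_min}, out)
    meqtl_t = qtl.run_cis_scan(meth_d, geno_d, sheet_d, pairs_m, qtl_spec,
                               maf_min=config.maf_min)
    finish(meqtl_t)

    finish = _stage(manifest, "eqtl", {"window": config.cis_window,
                                       "maf_min": config.maf_min}, out)
    eqtl_t = qtl.run_cis_scan(vst_d, geno_d, sheet_d, pairs_e, qtl_spec,
                              maf_min=config.maf_min, layer="expression")
    finish(eqtl_t)

    # --------------------------------------------------- interaction QTLs
    finish = _stage(manifest, "interaction_discovery",
                    {"maf_case_min": config.interaction.maf_case_min}, out)
    int_m_d = qtl.run_interaction_scan(meth_d, geno_d, sheet_d, pairs_m, qtl_spec,
                                       maf_case_min=config.interaction.maf_case_min)
    int_e_d = qtl.run_interaction_scan(vst_d, geno_d, sheet_d, pairs_e, qtl_spec,
                                       maf_case_min=config.interaction.maf_case_min)
    parts = [t for t in (int_m_d, int_e_d) if len(t)]
    int_d = pd.concat(parts, ignore_index=True) if parts else int_m_d
    finish(int_d)

    finish = _stage(manifest, "interaction_replication", {}, out)
    vst_r = diffexpr.vst_matrix(expr_r)
    int_m_r = qtl.run_interaction_scan(meth_r, geno_r, sheet_r, pairs_m, qtl_spec,
                                       maf_case_min=0.0)
    int_e_r = qtl.run_interaction_scan(vst_r, geno_r, sheet_r, pairs_e, qtl_spec,
                                       maf_case_min=0.0)
    parts = [t for t in (int_m_r, int_e_r) if len(t)]
    int_r = pd.concat(parts, ignore_index=True) if parts else int_m_r
    finish(int_r)

    finish = _stage(manifest, "disease_dependent", {
        "p_int_discovery": config.interaction.p_int_discovery}, out)
    selected = qtl.select_disease_dependent(int_d, int_r, config.interaction)
    finish(selected)

    # ---------------------------------------------------------- mediation
    finish = _stage(manifest, "snp_assoc", {"alpha_snp": config.alpha_snp}, out)
    nonempty = [t for t in (meqtl_t, eqtl_t) if len(t)]
    qtl_fdr = (pd.concat(nonempty, ignore_index=True) if nonempty
               else meqtl_t)
    sig_qtl = qtl_fdr[qtl_fdr["p_fdr"] < 0.05] if len(qtl_fdr) else qtl_fdr
    assoc_rows = []
    pc1 = build_pc1_design(cohort.sheet)
    status = cohort.sheet.is_case.astype(float)
    for snp in sig_qtl["snp_id"].unique() if len(sig_qtl) else []:
        dose = cohort.genotypes.values.loc[snp].to_numpy(dtype=float)
        try:
            fit = assoc.fit_logistic_additive(dose, status, pc1, model_tag=snp)
        except ValueError:
            continue
        assoc_rows.append({"snp_id": snp, "beta_logit": fit.beta_logit,
                           "or_": fit.or_, "se": fit.se, "p": fit.p})
    assoc_t = pd.DataFrame(assoc_rows,
                           columns=["snp_id", "beta_logit", "or_", "se", "p"])
    finish(assoc_t)

    finish = _stage(manifest, "mediation", {"alpha_snp": config.alpha_snp}, out)
    disease_eff = pd.concat([
        dmp_d[["feature_id", "estimate"]].rename(columns={"estimate": "beta_disease"}),
        de_d[["gene_id", "log2fc"]].rename(
            columns={"gene_id": "feature_id", "log2fc": "beta_disease"}),
    ], ignore_index=True)
    mediation_t = (assoc.mediation_consistency(sig_qtl, disease_eff, assoc_t,
                                               config.alpha_snp)
                   if len(sig_qtl) and len(assoc_t) else pd.DataFrame())
    finish(mediation_t)

    # ---------------------------------------------------------------- HLA
    finish = _stage(manifest, "hla", {}, out)
    proxy = (cohort.methylation.values.loc[cohort.truth.ifn_proxy_cpg]
             if cohort.truth.ifn_proxy_cpg else pd.Series(dtype=float))
    n_alleles = cohort.hla.shape[0]
    hla_t = (assoc.hla_suite(cohort.hla, cohort.sheet, proxy,
                             alpha=ewas.bonferroni_threshold(config.alpha,
                                                             max(n_alleles, 1)))
             if len(proxy) else pd.DataFrame())
    finish(hla_t)

    write_json(manifest, out / "manifest.json")
    return manifest


def build_pc1_design(sheet: SampleSheet) -> np.ndarray:
    from .ewas import build_design

    return build_design(sheet, ("pc1", "sex", "age")).to_numpy()
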