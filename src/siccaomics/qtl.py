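"""cis-QTL scanning and genotype-by-disease interaction analysis.

cis pairs are same-chromosome SNP–feature pairs with |SNP pos − anchor| ≤
window (1 Mb default, boundary inclusive; anchor = CpG coordinate or gene
TSS).  The cis scan fits, per pair, an OLS model of the molecular phenotype
on allele dosage plus covariates (including disease status), with BH-FDR
over all tested pairs within a layer.  The interaction scan adds a
dosage × disease term and also reports case-only and control-only
stratified fits; the disease-dependent filter then requires a replicated
interaction with consistent sign, case-only association without control
evidence, and a case-group MAF floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .ewas import ModelSpec, batched_ols, build_design
from .io import MolecularMatrix, SampleSheet

__all__ = [
    "minor_allele_frequency",
    "cis_pairs",
    "run_cis_scan",
    "run_interaction_scan",
    "select_disease_dependent",
    "FilterThresholds",
    "gene_tss",
]

DEFAULT_QTL_COVARIATES = ("sex", "age", "pc1", "cells", "batch", "disease")
CIS_WINDOW = 1_000_000


def minor_allele_frequency(dosages: np.ndarray) -> float:
    """maf = min(f, 1 − f) with f = mean(dosage)/2 over non-missing entries."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("all dosages missing")
    f = d.mean() / 2.0
    return float(min(f, 1.0 - f))


def gene_tss(start: int, end: int, strand: str) -> int:
    """Strand-aware TSS: minus-strand genes anchor at the higher coordinate."""
    return int(end) if strand == "-" else int(start)


def cis_pairs(
    feature_annot: pd.DataFrame,
    snp_annot: pd.DataFrame,
    window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """All same-chromosome SNP–feature pairs within ``window`` bp (inclusive)."""
    feats = feature_annot[["feature_id", "chrom", "pos"]].rename(
        columns={"pos": "anchor"}
    )
    snps = snp_annot[["feature_id", "chrom", "pos"]].rename(
        columns={"feature_id": "snp_id", "pos": "snp_pos"}
    )
    merged = feats.merge(snps, on="chrom")
    merged["distance_bp"] = (merged["snp_pos"] - merged["anchor"]).abs()
    out = merged[merged["distance_bp"] <= window]
    return out[["snp_id", "feature_id", "chrom", "distance_bp"]].reset_index(drop=True)


def _prepare(genotypes, sheet, covariates):
    group = sheet.is_case.astype(float)
    design = build_design(sheet, [c for c in covariates if c != "disease"])
    cov = design.to_numpy()
    if "disease" in covariates:
        cov = np.column_stack([group, cov])
    return group, cov


def run_cis_scan(
    feature_matrix: MolecularMatrix,
    genotypes: MolecularMatrix,
    sheet: SampleSheet,
    pairs: pd.DataFrame,
    model_spec: ModelSpec | None = None,
    maf_min: float = 0.05,
    layer: str | None = None,
) -> pd.DataFrame:
    """Per-pair OLS of phenotype on dosage + covariates (incl. disease).

    Pairs whose SNP is monomorphic after dropping missing dosages, or below
    the MAF floor, are skipped.  Missing dosages are handled per pair by
    complete-case analysis.  BH FDR over all tested pairs.
    """
    spec = model_spec or ModelSpec(covariates=DEFAULT_QTL_COVARIATES)
    if feature_matrix.sample_ids != sheet.sample_ids or (
        genotypes.sample_ids != sheet.sample_ids
    ):
        raise ValueError("matrices and sheet samples are not aligned")
    layer = layer or (
        "methylation" if feature_matrix.kind == "methylation" else "expression"
    )
    _, cov = _prepare(genotypes, sheet, spec.covariates)
    Y = feature_matrix.values
    G = genotypes.values
    n = len(sheet.sample_ids)
    ones = np.ones(n)

    rows = []
    for snp_id, sub in pairs.groupby("snp_id", sort=False):
        if snp_id not in G.index:
            continue
        d = G.loc[snp_id].to_numpy(dtype=float)
        ok = ~np.isnan(d)
        if np.ptp(d[ok]) == 0:
            continue  # monomorphic after missing-drop
        maf = minor_allele_frequency(d)
        if maf < maf_min:
            continue
        feats = [f for f in sub["feature_id"] if f in Y.index]
        if not feats:
            continue
        X = np.column_stack([ones[ok], d[ok], cov[ok]])
        Yk = Y.loc[feats].to_numpy(dtype=float)[:, ok]
        est, se, t, p, dof = batched_ols(X, Yk.T, coef_index=1)
        dist = sub.set_index("feature_id")["distance_bp"]
        for j, f in enumerate(feats):
            rows.append((snp_id, f, layer, int(dist[f]), maf, est[j], se[j], t[j], p[j],
                         int(ok.sum())))
    table = pd.DataFrame(
        rows,
        columns=["snp_id", "feature_id", "layer", "distance_bp", "maf_all",
                 "beta_qtl", "se", "statistic", "p", "n_used"],
    )
    if len(table):
        table["p_fdr"] = multipletests(table["p"], method="fdr_bh")[1]
        table = table.sort_values("p", kind="mergesort").reset_index(drop=True)
    return table


def run_interaction_scan(
    feature_matrix: MolecularMatrix,
    genotypes: MolecularMatrix,
    sheet: SampleSheet,
    pairs: pd.DataFrame,
    model_spec: ModelSpec | None = None,
    maf_case_min: float = 0.10,
) -> pd.DataFrame:
    """Genotype × disease interaction scan over the supplied pairs.

    Full-cohort model: phenotype ~ dosage + disease + dosage×disease +
    covariates (Wald t on the interaction term), plus case-only and
    control-only stratified fits (dosage + covariates).  Pairs whose SNP is
    monomorphic in one stratum keep the full-model fields with the stratum
    fields set to NA.  Pairs below the case-MAF floor are dropped.
    """
    spec = model_spec or ModelSpec(covariates=DEFAULT_QTL_COVARIATES)
    if feature_matrix.sample_ids != sheet.sample_ids or (
        genotypes.sample_ids != sheet.sample_ids
    ):
        raise ValueError("matrices and sheet samples are not aligned")
    layer = "methylation" if feature_matrix.kind == "methylation" else "expression"
    case = sheet.is_case
    group = case.astype(float)
    design = build_design(sheet, [c for c in spec.covariates if c != "disease"])
    cov = design.to_numpy()
    Y = feature_matrix.values
    G = genotypes.values
    n = len(group)
    ones = np.ones(n)

    rows = []
    for snp_id, sub in pairs.groupby("snp_id", sort=False):
        if snp_id not in G.index:
            continue
        d = G.loc[snp_id].to_numpy(dtype=float)
        ok = ~np.isnan(d)
        ok_case = ok & case
        ok_ctrl = ok & ~case
        if ok_case.sum() == 0:
            continue
        maf_case = minor_allele_frequency(d[ok_case])
        if maf_case < maf_case_min:
            continue
        feats = [f for f in sub["feature_id"] if f in Y.index]
        if not feats:
            continue
        Yk = Y.loc[feats].to_numpy(dtype=float)

        X_full = np.column_stack(
            [ones[ok], d[ok], group[ok], (d * group)[ok], cov[ok]]
        )
        b_int, se_int, t_int, p_int, _ = batched_ols(X_full, Yk[:, ok].T, coef_index=3)

        def stratum_fit(mask):
            if mask.sum() < cov.shape[1] + 3 or np.ptp(d[mask]) == 0:
                k = len(feats)
                return np.full(k, np.nan), np.full(k, np.nan)
            Xs = np.column_stack([np.ones(mask.sum()), d[mask], cov[mask]])
            est, se, t, p, _ = batched_ols(Xs, Yk[:, mask].T, coef_index=1)
            return est, p

        b_case, p_case = stratum_fit(ok_case)
        b_ctrl, p_ctrl = stratum_fit(ok_ctrl)
        for j, f in enumerate(feats):
            rows.append(
                (snp_id, f, layer, maf_case, b_int[j], p_int[j],
                 b_case[j], p_case[j], b_ctrl[j], p_ctrl[j])
            )
    return pd.DataFrame(
        rows,
        columns=["snp_id", "feature_id", "layer", "maf_case", "beta_int", "p_int",
                 "beta_case", "p_case", "beta_ctrl", "p_ctrl"],
    )


@dataclass
class FilterThresholds:
    """Three-condition disease-dependent QTL filter.

    (i) interaction P below ``p_int_discovery`` in discovery and below
    ``p_int_replication`` in replication with consistent interaction sign;
    (ii) case-only association (``p_case`` < alpha_case) without control
    evidence (``p_ctrl`` > alpha_ctrl, or control fit NA);
    (iii) case-group MAF above ``maf_case_min``.
    """

    p_int_discovery: float = 0.005
    p_int_replication: float = 0.05
    alpha_case: float = 0.05
    alpha_ctrl: float = 0.05
    maf_case_min: float = 0.10
    ss_evidence: str = "nominal"  # or "fdr": BH-adjust p_case across pairs


def select_disease_dependent(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
) -> pd.DataFrame:
    """Apply the three-condition filter to joined discovery/replication scans.

    Returns all discovery records with per-condition audit columns,
    replication fields, ``passes_filter`` and ``filter_reasons``.
    Idempotent and order-independent: the verdict for a pair depends only on
    that pair's fields.
    """
    th = thresholds or FilterThresholds()
    rep = replication.set_index(["snp_id", "feature_id"])
    out = discovery.copy().reset_index(drop=True)
    p_case = out["p_case"].to_numpy(dtype=float)
    if th.ss_evidence == "fdr":
        adj = np.full(p_case.shape, np.nan)
        ok = ~np.isnan(p_case)
        if ok.any():
            adj[ok] = multipletests(p_case[ok], method="fdr_bh")[1]
        case_evidence = adj < th.alpha_case
    else:
        case_evidence = p_case < th.alpha_case

    rep_beta = np.full(len(out), np.nan)
    rep_p = np.full(len(out), np.nan)
    reasons: list[str] = []
    passes = np.zeros(len(out), dtype=bool)
    cond_cols = {k: np.zeros(len(out), dtype=bool) for k in
                 ("cond_interaction", "cond_case_only", "cond_maf")}
    for i, row in out.iterrows():
        key = (row["snp_id"], row["feature_id"])
        why = []
        if key in rep.index:
            rrow = rep.loc[key]
            rep_beta[i] = rrow["beta_int"]
            rep_p[i] = rrow["p_int"]
            same_sign = np.sign(rrow["beta_int"]) == np.sign(row["beta_int"])
            cond_i = (
                row["p_int"] < th.p_int_discovery
                and rrow["p_int"] < th.p_int_replication
                and same_sign
            )
            if row["p_int"] >= th.p_int_discovery:
                why.append("discovery_interaction_ns")
            if rrow["p_int"] >= th.p_int_replication:
                why.append("replication_interaction_ns")
            if not same_sign:
                why.append("sign_inconsistent")
        else:
            cond_i = False
            why.append("no_replication")
        cond_ii = bool(case_evidence[i]) and (
            np.isnan(row["p_ctrl"]) or row["p_ctrl"] > th.alpha_ctrl
        )
        if not case_evidence[i]:
            why.append("case_ns")
        if not np.isnan(row["p_ctrl"]) and row["p_ctrl"] <= th.alpha_ctrl:
            why.append("ctrl_significant")
        cond_iii = row["maf_case"] > th.maf_case_min
        if not cond_iii:
            why.append("maf_case_low")
        cond_cols["cond_interaction"][i] = cond_i
        cond_cols["cond_case_only"][i] = cond_ii
        cond_cols["cond_maf"][i] = cond_iii
        passes[i] = cond_i and cond_ii and cond_iii
        reasons.append(";".join(why))
    out["replication_beta_int"] = rep_beta
    out["replication_p_int"] = rep_p
    for k, v in cond_cols.items():
        out[k] = v
    out["passes_filter"] = passes
    out["filter_reasons"] = reasons
    return out
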