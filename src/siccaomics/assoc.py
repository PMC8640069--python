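"""Case-control genetic association, mediation-direction classification,
epigenetic IFN-signature labelling and the HLA stratified/conditional suite.

Genetic associations use additive logistic regression (allele dosage as a
continuous predictor) fitted by IRLS, reporting the per-allele log-odds and
odds ratio.  A QTL SNP is called *mediation-consistent* when the direction
of its molecular effect, the disease effect of the molecular feature and
the allelic disease risk compose coherently:
``sign(β_QTL) × sign(log OR) == sign(β_disease_feature)`` — e.g. a risk
allele that lowers methylation at a site that is hypomethylated in cases.

Patients are labelled for the epigenetic IFN signature by methylation at a
proxy interferon-regulated CpG (positive if beta < 0.8).  The HLA suite
fits, per classical allele dosage: disease ~ allele, autoantibody ~ allele
(cases only), proxy methylation ~ allele with and without the autoantibody
covariate, and disease ~ allele within the signature-positive and
signature-negative patient strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ewas import ModelSpec, build_design, batched_ols
from .io import MolecularMatrix, SampleSheet

__all__ = [
    "fit_logistic_additive",
    "mediation_consistency",
    "classify_epig_ifn",
    "hla_suite",
]


@dataclass
class LogisticFit:
    beta_logit: float
    or_: float
    se: float
    p: float
    model_tag: str
    converged: bool = True
    separation: bool = False


def fit_logistic_additive(
    dosage: np.ndarray,
    status: np.ndarray,
    covariates: np.ndarray | None = None,
    model_tag: str = "additive",
    max_iter: int = 50,
    tol: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood logistic fit of a binary outcome on allele dosage.

    IRLS with Wald p on the dosage term.  Complete separation or
    non-convergence is flagged (p = NaN) rather than raised.
    """
    dosage = np.asarray(dosage, dtype=float)
    status = np.asarray(status, dtype=float)
    if len(np.unique(status)) < 2:
        raise ValueError("both outcome classes must be present")
    if np.ptp(dosage[~np.isnan(dosage)]) == 0:
        raise ValueError("dosage is constant")
    ok = ~np.isnan(dosage)
    cov = np.empty((ok.sum(), 0)) if covariates is None else np.atleast_2d(
        np.asarray(covariates, dtype=float)
    )
    if covariates is not None and cov.shape[0] != ok.sum():
        cov = cov.T[ok] if cov.shape[1] == len(dosage) else cov[ok]
    X = np.column_stack([np.ones(ok.sum()), dosage[ok], cov])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(status[ok], X, family=sm.families.Binomial()).fit(
                maxiter=max_iter, tol=tol
            )
    except Exception:
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, model_tag,
                           converged=False)
    mu = res.fittedvalues
    separated = bool(np.min(np.abs(mu - status[ok])) < 1e-10 and
                     (np.abs(res.params) > 15).any())
    beta = float(res.params[1])
    se = float(res.bse[1])
    if separated or not res.converged or not np.isfinite(se) or se > 1e3:
        return LogisticFit(beta, np.exp(beta), se, np.nan, model_tag,
                           converged=bool(res.converged), separation=True)
    return LogisticFit(beta, float(np.exp(beta)), se, float(res.pvalues[1]),
                       model_tag)


# ----------------------------------------------------------------------
# mediation-direction consistency
# ----------------------------------------------------------------------

def mediation_consistency(
    qtl_table: pd.DataFrame,
    disease_effect_table: pd.DataFrame,
    assoc_table: pd.DataFrame,
    alpha_snp: float,
) -> pd.DataFrame:
    """Classify QTL SNPs by mediation-direction consistency.

    ``qtl_table``: snp_id, feature_id, layer, beta_qtl.
    ``disease_effect_table``: feature_id, beta_disease (β_EWAS or log2FC).
    ``assoc_table``: snp_id, or_, p.  Only SNPs with assoc p < ``alpha_snp``
    receive a verdict; an OR of exactly 1 (zero log-odds) is inconsistent
    and flagged ``null_assoc``.
    """
    eff = disease_effect_table.set_index("feature_id")["beta_disease"]
    assoc = assoc_table.set_index("snp_id")
    rows = []
    for _, row in qtl_table.iterrows():
        snp, feat = row["snp_id"], row["feature_id"]
        if snp not in assoc.index or feat not in eff.index:
            rows.append((snp, feat, row.get("layer", ""), row["beta_qtl"],
                         np.nan, np.nan, False, "missing_join"))
            continue
        a = assoc.loc[snp]
        if a["p"] >= alpha_snp:
            continue
        log_or = np.log(a["or_"])
        beta_d = eff[feat]
        if log_or == 0 or row["beta_qtl"] == 0 or beta_d == 0:
            rows.append((snp, feat, row.get("layer", ""), row["beta_qtl"],
                         beta_d, a["or_"], False, "null_assoc"))
            continue
        consistent = np.sign(row["beta_qtl"]) * np.sign(log_or) == np.sign(beta_d)
        qdir = "lowers" if row["beta_qtl"] < 0 else "raises"
        ddir = "decreased" if beta_d < 0 else "increased"
        risk = "risk" if log_or > 0 else "protective"
        narrative = (
            f"{risk} allele {qdir} {row.get('layer', 'phenotype')}; "
            f"feature shows {ddir} level in cases"
        )
        rows.append((snp, feat, row.get("layer", ""), row["beta_qtl"], beta_d,
                     a["or_"], bool(consistent), narrative))
    return pd.DataFrame(
        rows,
        columns=["snp_id", "feature_id", "layer", "beta_qtl",
                 "beta_disease_feature", "or_", "consistent", "narrative"],
    )


# ----------------------------------------------------------------------
# epigenetic IFN signature
# ----------------------------------------------------------------------

def classify_epig_ifn(proxy_betas: pd.Series, cutoff: float = 0.8) -> pd.DataFrame:
    """Label samples by methylation at the proxy CpG.

    beta < cutoff → positive; beta ≥ cutoff → negative (the boundary itself
    is negative); missing beta → NA label.
    """
    labels = []
    for sid, b in proxy_betas.items():
        if pd.isna(b):
            labels.append((sid, np.nan, pd.NA))
        else:
            labels.append((sid, float(b), "positive" if b < cutoff else "negative"))
    return pd.DataFrame(labels, columns=["sample_id", "proxy_beta", "label"])


# ----------------------------------------------------------------------
# HLA suite
# ----------------------------------------------------------------------

_HLA_MODELS = (
    "ss_hla",            # (1) logistic disease ~ allele + sex + age
    "ssa_hla",           # (2) logistic SSA ~ allele + sex + age, cases only
    "epigifn_hla",       # (3) linear proxy beta ~ allele + sex + age + cells + batch
    "epigifn_hla_ssa",   # (4) model 3 plus the SSA covariate
    "ss_hla_pos",        # (5) model 1 in epigIFN-positive cases vs all controls
    "ss_hla_neg",        # (6) model 1 in epigIFN-negative cases vs all controls
)


def hla_suite(
    hla: MolecularMatrix,
    sheet: SampleSheet,
    proxy_betas: pd.Series,
    alpha: float = 1.7e-4,
    cutoff: float = 0.8,
) -> pd.DataFrame:
    """Six-model stratified/conditional association suite per HLA allele.

    Returns one row per allele with beta/p per model, Bonferroni over the
    alleles tested, and ``significant`` flags at ``alpha``.  Monomorphic
    alleles within a stratum yield NA for that model.
    """
    if hla.sample_ids != sheet.sample_ids:
        raise ValueError("hla matrix and sheet samples are not aligned")
    df = sheet.data
    case = sheet.is_case
    status = case.astype(float)
    ssa_pos = (df["ssa"] == "positive").to_numpy()
    proxy = proxy_betas.reindex(sheet.sample_ids).to_numpy(dtype=float)
    label = np.where(np.isnan(proxy), "na",
                     np.where(proxy < cutoff, "positive", "negative"))

    base_design = build_design(sheet, ("sex", "age")).to_numpy()
    lin_design = build_design(sheet, ("sex", "age", "cells", "batch")).to_numpy()
    ssa_col = ssa_pos.astype(float)[:, None]

    def logistic(mask, dose, outcome, tag):
        d = dose[mask]
        if np.ptp(d) == 0:
            return np.nan, np.nan
        try:
            fit = fit_logistic_additive(d, outcome[mask], base_design[mask], tag)
        except ValueError:
            return np.nan, np.nan
        return fit.beta_logit, fit.p

    def linear(mask, dose, y, design):
        d = dose[mask]
        if np.ptp(d) == 0 or mask.sum() <= design.shape[1] + 2:
            return np.nan, np.nan
        X = np.column_stack([np.ones(mask.sum()), d, design[mask]])
        est, se, t, p, _ = batched_ols(X, y[mask, None], coef_index=1)
        return float(est[0]), float(p[0])

    rows = []
    for allele in hla.feature_ids:
        dose = hla.values.loc[allele].to_numpy(dtype=float)
        rec: dict = {"allele": allele}
        rec["beta_ss"], rec["p_ss"] = logistic(np.ones_like(case, bool), dose,
                                               status, "ss_hla")
        rec["beta_ssa"], rec["p_ssa"] = logistic(case, dose,
                                                 ssa_pos.astype(float), "ssa_hla")
        case_proxy = case & ~np.isnan(proxy)
        rec["beta_epigifn"], rec["p_epigifn"] = linear(case_proxy, dose, proxy,
                                                       lin_design)
        rec["beta_epigifn_ssa"], rec["p_epigifn_ssa"] = linear(
            case_proxy, dose, proxy, np.column_stack([lin_design, ssa_col])
        )
        pos_mask = ~case | (case & (label == "positive"))
        neg_mask = ~case | (case & (label == "negative"))
        rec["beta_ss_pos"], rec["p_ss_pos"] = logistic(pos_mask, dose, status,
                                                       "ss_hla_pos")
        rec["beta_ss_neg"], rec["p_ss_neg"] = logistic(neg_mask, dose, status,
                                                       "ss_hla_neg")
        rows.append(rec)
    table = pd.DataFrame(rows)
    m = len(table)
    for model in ("ss", "ssa", "epigifn", "epigifn_ssa", "ss_pos", "ss_neg"):
        table[f"significant_{model}"] = table[f"p_{model}"] < alpha
    table["bonferroni_alpha"] = alpha
    table["n_alleles_tested"] = m
    return table
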