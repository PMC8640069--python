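"""Differential methylation position (DMP) and variability (VMP) scans.

The DMP scan fits, per CpG, an ordinary-least-squares model of beta values
on a case/control indicator plus covariates (sex, age, first genetic PC,
measured blood-cell proportions, batch dummies), with a two-sided t test on
the disease coefficient and Bonferroni/BH control over the CpGs tested.
Methylation is modelled on the beta scale by default (an M-value transform
is available behind a flag).

The VMP scan first residualizes betas on all covariates except disease and
then compares residual spread between groups with a Brown–Forsythe test
(Levene with median centring); median centring is what makes the test
robust to residual mean differences between the groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import SampleSheet, MolecularMatrix

__all__ = [
    "ModelSpec",
    "LinearFit",
    "build_design",
    "fit_linear_model",
    "batched_ols",
    "bonferroni_threshold",
    "brown_forsythe",
    "run_dmp_scan",
    "run_vmp_scan",
    "sensitivity_refit",
    "stratified_scan",
]

#: default covariate set of the methylation model
DEFAULT_COVARIATES = ("sex", "age", "pc1", "cells", "batch")


@dataclass
class ModelSpec:
    """Names the covariate columns entering the per-feature linear model.

    ``cells`` expands to the sheet's ``cell_*`` columns with one dropped
    (the proportions sum to ~1, so the full set is collinear with the
    intercept); ``batch``/``pool`` expand to treatment-coded dummies.
    """

    covariates: Sequence[str] = DEFAULT_COVARIATES
    m_values: bool = False
    levene_center: str = "median"  # "median" = Brown–Forsythe, "mean" = classic


class DegenerateFitError(ValueError):
    pass


def build_design(sheet: SampleSheet, covariates: Sequence[str]) -> pd.DataFrame:
    """Translate sheet columns into numeric design columns (no intercept)."""
    df = sheet.data
    cols: dict[str, np.ndarray] = {}
    for name in covariates:
        if name == "cells":
            cells = sheet.cell_columns
            for c in cells[:-1]:  # drop one to break the sum-to-one collinearity
                cols[c] = df[c].to_numpy(dtype=float)
        elif name in ("batch", "pool"):
            if df[name].isna().any():
                raise ValueError(f"covariate {name!r} has missing values")
            levels = sorted(df[name].unique())
            for lev in levels[1:]:
                cols[f"{name}_{lev}"] = (df[name] == lev).to_numpy(dtype=float)
        elif name == "sex":
            cols["sex"] = (df["sex"] == "M").to_numpy(dtype=float)
        elif name in ("ssa", "ssb"):
            cols[name] = (df[name] == "positive").to_numpy(dtype=float)
        else:
            v = df[name]
            if v.dtype == bool:
                cols[name] = v.to_numpy(dtype=float)
            else:
                arr = pd.to_numeric(v).to_numpy(dtype=float)
                if np.isnan(arr).all():
                    raise ValueError(f"covariate {name!r} is entirely missing")
                cols[name] = arr
    return pd.DataFrame(cols, index=df["sample_id"])


@dataclass
class LinearFit:
    estimate: float
    se: float
    statistic: float
    p: float
    df: int
    degenerate: bool = False


def _name_collinear(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Identify columns whose removal restores full rank."""
    full = np.linalg.matrix_rank(X)
    bad = []
    for j in range(X.shape[1]):
        keep = [k for k in range(X.shape[1]) if k != j]
        if np.linalg.matrix_rank(X[:, keep]) == full:
            bad.append(names[j])
    return bad


def fit_linear_model(
    y: np.ndarray,
    group: np.ndarray,
    covariates: np.ndarray | None = None,
) -> LinearFit:
    """OLS of ``y`` on a binary group indicator plus optional covariates.

    Returns the group coefficient with a two-sided t test.  A constant
    response gives a degenerate fit (estimate 0, p = 1); a rank-deficient
    design raises, naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group, dtype=float)
    n = y.size
    if np.ptp(group) == 0:
        raise DegenerateFitError("group indicator is constant")
    cov = np.empty((n, 0)) if covariates is None else np.atleast_2d(
        np.asarray(covariates, dtype=float)
    )
    if cov.shape[0] != n:
        cov = cov.T
    X = np.column_stack([np.ones(n), group, cov])
    names = ["intercept", "group"] + [f"covariate_{j}" for j in range(cov.shape[1])]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _name_collinear(X, names)
        raise DegenerateFitError(f"rank-deficient design; collinear columns: {bad}")
    if n <= X.shape[1]:
        raise DegenerateFitError("fewer observations than design rank")
    if np.ptp(y) == 0:
        return LinearFit(0.0, 0.0, 0.0, 1.0, n - X.shape[1], degenerate=True)
    est, se, t, p, dof = batched_ols(X, y[:, None], coef_index=1)
    return LinearFit(float(est[0]), float(se[0]), float(t[0]), float(p[0]), dof)


def batched_ols(
    X: np.ndarray, Y: np.ndarray, coef_index: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Fit ``Y`` (n × m responses) on a shared design ``X`` (n × p).

    Returns (estimate, se, t, p, df) for the ``coef_index``-th coefficient,
    vectorized across responses.
    """
    n, p = X.shape
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)                       # p × m
    resid = Y - X @ beta
    dof = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[coef_index, coef_index], 0.0))
    est = beta[coef_index]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, est / np.where(se > 0, se, 1.0), 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    pvals = np.where(se > 0, pvals, 1.0)
    return est, se, t, pvals, dof


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha / m for m tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be ≥ 1")
    return alpha / m


def brown_forsythe(a: np.ndarray, b: np.ndarray, center: str = "median") -> tuple[float, float]:
    """Two-group Levene test on spread; median centring = Brown–Forsythe.

    Returns (F, p).  When every absolute deviation from the group centres is
    identical (no spread information at all) the statistic is 0 with p = 1;
    scipy would return NaN there.  Exactly invariant to adding a constant to
    either group.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    centre = np.median if center == "median" else np.mean
    za = np.abs(a - centre(a))
    zb = np.abs(b - centre(b))
    if np.ptp(np.concatenate([za, zb])) == 0:
        return 0.0, 1.0
    stat, p = stats.levene(a, b, center=center)
    return float(stat), float(p)


def _beta_to_m(b: np.ndarray) -> np.ndarray:
    b = np.clip(b, 1e-6, 1 - 1e-6)
    return np.log2(b / (1 - b))


def _scan_frame(
    Y: np.ndarray,
    feature_ids: Sequence[str],
    X: np.ndarray,
    group: np.ndarray,
    n: int,
) -> pd.DataFrame:
    est, se, t, p, dof = batched_ols(X, Y.T, coef_index=1)
    m = len(feature_ids)
    mean_case = Y[:, group.astype(bool)].mean(axis=1)
    mean_ctrl = Y[:, ~group.astype(bool)].mean(axis=1)
    table = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "estimate": est,
            "se": se,
            "statistic": t,
            "p": p,
            "p_bonferroni": np.minimum(1.0, p * m),
            "p_fdr": multipletests(p, method="fdr_bh")[1],
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
            "delta_beta": mean_case - mean_ctrl,
            "n_used": n,
        }
    )
    return table.sort_values("p", kind="mergesort").reset_index(drop=True)


def run_dmp_scan(
    methylation: MolecularMatrix,
    sheet: SampleSheet,
    model_spec: ModelSpec | None = None,
) -> pd.DataFrame:
    """Per-CpG disease association, Bonferroni over the CpGs tested."""
    spec = model_spec or ModelSpec()
    if methylation.sample_ids != sheet.sample_ids:
        raise ValueError("methylation and sheet samples are not aligned")
    group = sheet.is_case.astype(float)
    if np.ptp(group) == 0:
        raise DegenerateFitError("cohort contains only one disease group")
    design = build_design(sheet, spec.covariates)
    X = np.column_stack([np.ones(len(group)), group, design.to_numpy()])
    Y = methylation.values.to_numpy(dtype=float)
    if spec.m_values:
        Y = _beta_to_m(Y)
    return _scan_frame(Y, methylation.feature_ids, X, group, len(group))


def run_vmp_scan(
    methylation: MolecularMatrix,
    sheet: SampleSheet,
    model_spec: ModelSpec | None = None,
) -> pd.DataFrame:
    """Per-CpG differential-variability scan on covariate residuals.

    Residualizes on all covariates except disease, then applies a
    Brown–Forsythe (median-centred Levene) test between cases and controls.
    A zero-variance group yields p = 1 with ``degenerate`` set.
    """
    spec = model_spec or ModelSpec()
    if methylation.sample_ids != sheet.sample_ids:
        raise ValueError("methylation and sheet samples are not aligned")
    case = sheet.is_case
    if case.sum() < 3 or (~case).sum() < 3:
        raise ValueError("need at least 3 samples per group")
    design = build_design(sheet, spec.covariates)
    n = len(case)
    X = np.column_stack([np.ones(n), design.to_numpy()])
    Y = methylation.values.to_numpy(dtype=float)
    if spec.m_values:
        Y = _beta_to_m(Y)
    beta = np.linalg.pinv(X) @ Y.T
    R = (Y.T - X @ beta).T                     # features × samples residuals

    rows = []
    for i, fid in enumerate(methylation.feature_ids):
        rc, rn = R[i, case], R[i, ~case]
        var_case, var_ctrl = rc.var(ddof=1), rn.var(ddof=1)
        if var_case == 0 or var_ctrl == 0:
            rows.append((fid, 0.0, 1.0, var_case, var_ctrl, np.nan, True))
            continue
        stat, p = brown_forsythe(rc, rn, center=spec.levene_center)
        rows.append((fid, stat, p, var_case, var_ctrl, var_case / var_ctrl, False))
    table = pd.DataFrame(
        rows,
        columns=["feature_id", "levene_statistic", "p", "var_case", "var_control",
                 "variance_ratio", "degenerate"],
    )
    return table.sort_values("p", kind="mergesort").reset_index(drop=True)


def sensitivity_refit(
    methylation: MolecularMatrix,
    sheet: SampleSheet,
    base_spec: ModelSpec,
    extra_covariates: Sequence[str],
    feature_subset: Sequence[str],
    threshold: float,
) -> tuple[pd.DataFrame, float, float]:
    """Re-fit the DMP model with added covariates on a feature subset.

    Returns the refit table, the Pearson correlation of the effect estimates
    across the two fits, and the fraction of subset features still passing
    ``threshold`` (on raw p) after adjustment.
    """
    if len(feature_subset) == 0:
        raise ValueError("empty feature subset")
    sub = methylation.subset_features(feature_subset)
    base = run_dmp_scan(sub, sheet, base_spec).set_index("feature_id")
    refit_spec = ModelSpec(
        covariates=tuple(base_spec.covariates) + tuple(extra_covariates),
        m_values=base_spec.m_values,
    )
    refit = run_dmp_scan(sub, sheet, refit_spec).set_index("feature_id")
    joined = base[["estimate", "p"]].join(refit[["estimate", "p"]],
                                          lsuffix="_base", rsuffix="_refit")
    r = float(np.corrcoef(joined["estimate_base"], joined["estimate_refit"])[0, 1])
    retained = float((joined["p_refit"] < threshold).mean())
    return refit.reset_index(), r, retained


def stratified_scan(
    methylation: MolecularMatrix,
    sheet: SampleSheet,
    stratum_filter,
    model_spec: ModelSpec | None = None,
    conditional_on: str | None = None,
) -> pd.DataFrame:
    """DMP scan restricted to a sample stratum, or conditional on a column.

    ``stratum_filter`` maps the sheet DataFrame to a boolean mask (e.g. keep
    SSA-positive cases plus all controls).  ``conditional_on`` instead keeps
    the full cohort and adds the named column (e.g. ``"ssa"``) as a
    covariate.
    """
    spec = model_spec or ModelSpec()
    if conditional_on is not None:
        spec = ModelSpec(covariates=tuple(spec.covariates) + (conditional_on,),
                         m_values=spec.m_values)
        return run_dmp_scan(methylation, sheet, spec)
    mask = np.asarray(stratum_filter(sheet.data), dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty stratum")
    ids = [s for s, keep in zip(sheet.sample_ids, mask) if keep]
    sub_sheet = sheet.subset(ids)
    if len(set(sub_sheet.data["disease"])) < 2:
        raise ValueError("stratum lacks one side of the case/control contrast")
    return run_dmp_scan(methylation.subset_samples(ids), sub_sheet, spec)
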