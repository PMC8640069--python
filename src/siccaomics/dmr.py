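"""GSEA-style differentially methylated region (DMR) detection and eQTM.

CpGs are ranked by the signed t statistic of the disease term; a weighted
Kolmogorov–Smirnov running sum scores each predefined CpG set (promoter,
gene body, CpG island), so a region of subtly but consistently shifted CpGs
can reach significance even when no single member survives genome-wide
correction.  Significance comes from a permutation null that redraws member
sets of equal size from the ranked list; the leading-edge members (those at
or before the running-sum extremum) are averaged per sample and correlated
with the expression of genes whose TSS lies within a small window of the
region span (eQTM).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import MolecularMatrix, RegionSet

__all__ = [
    "rank_cpgs",
    "enrichment_score",
    "dmr_scan",
    "leading_edge_profile",
    "eqtm_scan",
]

MIN_REGION_CPGS = 5


def rank_cpgs(dmp_table: pd.DataFrame) -> pd.DataFrame:
    """Rank CpGs by signed disease t statistic, descending.

    Ties are broken lexicographically on the CpG id (documented rule so the
    ranking is a pure function of the table content).
    """
    if len(dmp_table) == 0:
        raise ValueError("empty DMP table")
    stat = dmp_table["statistic"]
    if not np.isfinite(stat).all():
        raise ValueError("non-finite statistics in DMP table")
    out = dmp_table[["feature_id", "statistic"]].rename(
        columns={"feature_id": "cpg", "statistic": "score"}
    )
    return out.sort_values(["score", "cpg"], ascending=[False, True],
                           kind="mergesort").reset_index(drop=True)


def enrichment_score(
    ranked_scores: np.ndarray,
    member_positions: Sequence[int],
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted KS running-sum enrichment score of a member set.

    ``member_positions`` are 0-based indices into the ranked score list.
    Hits increment the running sum by |score|^p / Σ_members |score|^p and
    misses decrement by 1/(N − n_members); the score is the running-sum
    value of maximal absolute deviation (signed).  The leading edge is the
    members at or before the extremum for positive scores, and at or after
    it for negative scores.
    """
    scores = np.asarray(ranked_scores, dtype=float)
    pos = np.asarray(sorted(member_positions), dtype=int)
    N = scores.size
    k = pos.size
    if k == 0:
        raise ValueError("member set is empty")
    if k >= N:
        raise ValueError("member set covers the whole ranked list; score degenerate")
    if pos.min() < 0 or pos.max() >= N:
        raise ValueError("member positions outside the ranked list")
    w = np.abs(scores[pos]) ** weight_exponent
    total = w.sum()
    if total == 0:
        raise ValueError("all member scores are zero; hit weights undefined")
    miss = 1.0 / (N - k)
    hit_cum = np.cumsum(w) / total
    j = np.arange(k)
    # running sum immediately after each member, and immediately before it
    after = hit_cum - (pos - j) * miss
    before = np.concatenate([[0.0], hit_cum[:-1]]) - (pos - j) * miss
    i_max = int(np.argmax(after))
    i_min = int(np.argmin(before))
    es_pos = after[i_max]
    es_neg = before[i_min]
    # |peak| == |trough| ties resolve to the positive extremum; the small
    # tolerance keeps the choice stable under float accumulation order
    if abs(es_pos) >= abs(es_neg) - 1e-12:
        es = float(es_pos)
        leading = pos[: i_max + 1]
    else:
        es = float(es_neg)
        leading = pos[i_min:]
    return es, leading


def _es_batch(scores: np.ndarray, pos_sets: np.ndarray, weight_exponent: float) -> np.ndarray:
    """Vectorized |ES| for many equal-size member sets (rows of positions)."""
    pos = np.sort(pos_sets, axis=1)
    w = np.abs(scores[pos]) ** weight_exponent
    total = w.sum(axis=1, keepdims=True)
    total[total == 0] = np.nan
    N = scores.size
    k = pos.shape[1]
    miss = 1.0 / (N - k)
    hit_cum = np.cumsum(w, axis=1) / total
    j = np.arange(k)[None, :]
    after = hit_cum - (pos - j) * miss
    before = np.concatenate([np.zeros((pos.shape[0], 1)), hit_cum[:, :-1]], axis=1) - (
        pos - j
    ) * miss
    es_pos = after.max(axis=1)
    es_neg = before.min(axis=1)
    return np.where(np.abs(es_pos) >= np.abs(es_neg), es_pos, es_neg)


def dmr_scan(
    dmp_table: pd.DataFrame,
    region_sets: Sequence[RegionSet],
    n_perm: int = 999,
    seed: int = 0,
    weight_exponent: float = 1.0,
    min_cpgs: int = MIN_REGION_CPGS,
) -> pd.DataFrame:
    """Score every region set against the ranked CpG list.

    Per region (≥ ``min_cpgs`` ranked members): observed enrichment score,
    permutation p from ``n_perm`` random member sets of equal size,
    NES = es / mean(|es_null|), and BH FDR within each region kind.
    """
    if n_perm < 100:
        raise ValueError("need n_perm ≥ 100")
    ranked = rank_cpgs(dmp_table)
    scores = ranked["score"].to_numpy()
    index = {c: i for i, c in enumerate(ranked["cpg"])}
    rng = np.random.default_rng(seed)
    rows = []
    for region in region_sets:
        pos = [index[c] for c in region.member_cpgs if c in index]
        if len(pos) < min_cpgs:
            continue
        es, leading = enrichment_score(scores, pos, weight_exponent)
        null_sets = np.empty((n_perm, len(pos)), dtype=int)
        for b in range(n_perm):
            null_sets[b] = rng.choice(scores.size, size=len(pos), replace=False)
        es_null = _es_batch(scores, null_sets, weight_exponent)
        p_perm = (1.0 + np.sum(np.abs(es_null) >= abs(es))) / (n_perm + 1.0)
        nes = es / np.nanmean(np.abs(es_null))
        rows.append(
            {
                "region_id": region.region_id,
                "region_kind": region.region_kind,
                "n_cpgs": len(pos),
                "es": es,
                "nes": nes,
                "p_perm": p_perm,
                "leading_edge": ",".join(ranked["cpg"].iloc[leading]),
                "direction": "hyper" if es > 0 else "hypo",
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_fdr"] = np.nan
        for kind, idx in table.groupby("region_kind").groups.items():
            table.loc[idx, "p_fdr"] = multipletests(
                table.loc[idx, "p_perm"], method="fdr_bh"
            )[1]
        table = table[
            ["region_id", "region_kind", "n_cpgs", "es", "nes", "p_perm", "p_fdr",
             "leading_edge", "direction"]
        ].sort_values("p_perm", kind="mergesort").reset_index(drop=True)
    return table


def leading_edge_profile(
    methylation: MolecularMatrix, leading_edge: Sequence[str]
) -> pd.Series:
    """Per-sample arithmetic mean beta across the leading-edge CpGs."""
    missing = [c for c in leading_edge if c not in methylation.values.index]
    if missing:
        raise KeyError(f"CpGs absent from matrix: {missing}")
    if len(leading_edge) == 0:
        raise ValueError("empty leading edge")
    return methylation.values.loc[list(leading_edge)].mean(axis=0)


def eqtm_scan(
    profiles: pd.DataFrame,
    expression_log: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    region_annotation: pd.DataFrame,
    window: int = 1500,
) -> pd.DataFrame:
    """Correlate region methylation profiles with nearby gene expression.

    ``profiles``: region × sample mean leading-edge betas.
    ``region_annotation``: columns region_id, chrom, start, end (the span of
    the region's member CpGs, 1-based inclusive).  A gene pairs with a
    region when its TSS lies within ``window`` bp of the span (inclusive;
    distance 0 inside the span).  Pearson r with a two-sided t-based p per
    pair; a zero-variance vector flags the record instead of failing.
    """
    genes = gene_annotation.set_index("feature_id")
    rows = []
    for _, reg in region_annotation.iterrows():
        rid = reg["region_id"]
        if rid not in profiles.index:
            continue
        prof = profiles.loc[rid]
        near = genes[
            (genes["chrom"] == reg["chrom"])
            & (genes["pos"] >= reg["start"] - window)
            & (genes["pos"] <= reg["end"] + window)
        ]
        for gid in near.index:
            if gid not in expression_log.index:
                continue
            expr = expression_log.loc[gid, prof.index]
            x = prof.to_numpy(dtype=float)
            y = expr.to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append((rid, gid, np.nan, np.nan, x.size, True))
                continue
            r, p = stats.pearsonr(x, y)
            rows.append((rid, gid, r, p, x.size, False))
    return pd.DataFrame(
        rows, columns=["region_id", "gene_id", "pearson_r", "p", "n", "degenerate"]
    )


def region_spans(
    region_sets: Sequence[RegionSet], cpg_annotation: pd.DataFrame
) -> pd.DataFrame:
    """Span [min CpG pos, max CpG pos] of each region's annotated members."""
    annot = cpg_annotation.set_index("feature_id")
    rows = []
    for r in region_sets:
        members = [c for c in r.member_cpgs if c in annot.index]
        if not members:
            continue
        sub = annot.loc[members]
        chrom = sub["chrom"].iloc[0]
        rows.append(
            {
                "region_id": r.region_id,
                "chrom": chrom,
                "start": int(sub["pos"].min()),
                "end": int(sub["pos"].max()),
            }
        )
    return pd.DataFrame(rows)
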