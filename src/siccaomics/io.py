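"""Readers and writers for every external format the pipeline touches.

All tabular data travel as TSV with a header row of sample ids and a first
column of feature ids.  Genotypes may also arrive as VCF (GT or DS per
genotype).  Region sets use a GMT-like line format ``region_id<TAB>kind<TAB>
member1<TAB>member2...``.  Genomic coordinates are 1-based inclusive
throughout (VCF / array-manifest convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MolecularMatrix",
    "FeatureAnnotation",
    "RegionSet",
    "SampleSheet",
    "read_matrix",
    "write_matrix",
    "read_vcf_dosages",
    "write_vcf_dosages",
    "read_gmt",
    "write_gmt",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_annotation",
    "write_annotation",
    "write_results",
    "align_samples",
]

MATRIX_KINDS = ("methylation", "expression", "expression_log", "dosage", "hla")

#: sample-sheet columns that must always be present
MANDATORY_SHEET_COLUMNS = ("sample_id", "disease", "sex", "age")

FLOAT_FMT = "%.12g"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class MolecularMatrix:
    """Dense feature-by-sample numeric matrix with kind-specific validation.

    ``values`` is a pandas DataFrame indexed by feature id with sample ids as
    columns.  Kinds: ``methylation`` (betas in [0,1]), ``expression``
    (non-negative integer counts), ``dosage`` / ``hla`` (allele dosages in
    [0,2]; NaN allowed for ``dosage`` only and means a missing genotype).
    """

    values: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in MATRIX_KINDS:
            raise FormatError(f"unknown matrix kind {self.kind!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        vals = self.values.to_numpy(dtype=float)
        nan = np.isnan(vals)
        if nan.any() and self.kind != "dosage":
            raise FormatError(f"missing values not permitted for kind {self.kind!r}")
        finite = vals[~nan]
        if self.kind == "methylation":
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise FormatError("methylation beta values must lie in [0, 1]")
        elif self.kind == "expression":
            if finite.size and (finite.min() < 0 or np.any(finite != np.round(finite))):
                raise FormatError("expression counts must be non-negative integers")
        elif self.kind == "expression_log":
            pass  # continuous log-scale values, no range constraint
        else:  # dosage / hla
            if finite.size and (finite.min() < 0 or finite.max() > 2):
                raise FormatError("allele dosages must lie in [0, 2]")

    # ------------------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "MolecularMatrix":
        return MolecularMatrix(self.values.loc[:, list(sample_ids)], self.kind)

    def subset_features(self, feature_ids: Sequence[str]) -> "MolecularMatrix":
        return MolecularMatrix(self.values.loc[list(feature_ids)], self.kind)


@dataclass
class RegionSet:
    """Named CpG set (promoter, gene body or CpG island)."""

    region_id: str
    region_kind: str
    member_cpgs: list[str]

    REGION_KINDS = ("promoter", "gene_body", "CGI")

    def __post_init__(self) -> None:
        if self.region_kind not in self.REGION_KINDS:
            raise FormatError(
                f"unknown region kind {self.region_kind!r} for {self.region_id!r}"
            )
        if not self.member_cpgs:
            raise FormatError(f"region {self.region_id!r} has no members")


@dataclass
class SampleSheet:
    """Per-sample covariate sheet.

    Wraps a DataFrame with one row per sample.  ``disease`` is
    ``case``/``control``; ``ssa``/``ssb`` are ``positive``/``negative``
    (controls are negative by construction); cell proportions live in
    ``cell_*`` columns and each lie in [0,1] with sum ≤ 1.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in MANDATORY_SHEET_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"sample sheet missing mandatory column {col!r}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample id {dup!r}")
        bad = set(df["disease"]) - {"case", "control"}
        if bad:
            raise FormatError(f"unknown disease labels {sorted(bad)}")
        cells = self.cell_columns
        if cells:
            frac = df[cells].to_numpy(dtype=float)
            if frac.min() < 0 or frac.max() > 1 or (frac.sum(axis=1) > 1 + 1e-6).any():
                raise FormatError("cell proportions must lie in [0,1] and sum to ≤ 1")
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def cell_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("cell_")]

    @property
    def is_case(self) -> np.ndarray:
        return (self.data["disease"] == "case").to_numpy()

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        df = self.data.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleSheet(df)


def feature_annotation_frame(records: Iterable[dict]) -> pd.DataFrame:
    """Normalise annotation records to the canonical column order."""
    df = pd.DataFrame(records)
    cols = ["feature_id", "chrom", "pos"]
    for extra in ("strand", "gene_label", "region_class"):
        if extra in df.columns:
            cols.append(extra)
    df = df[cols]
    if (df["pos"] < 1).any():
        raise FormatError("annotation positions must be ≥ 1 (1-based)")
    if df["feature_id"].duplicated().any():
        raise FormatError("duplicate feature id in annotation")
    return df


# kept as an alias for readers of the type names used in the docs
FeatureAnnotation = pd.DataFrame


# ----------------------------------------------------------------------
# matrices
# ----------------------------------------------------------------------

def read_matrix(path: str | Path, kind: str) -> MolecularMatrix:
    """Read a feature × sample TSV matrix and validate it for ``kind``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return MolecularMatrix(df.astype(float), kind)


def write_matrix(matrix: MolecularMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="feature_id")


# ----------------------------------------------------------------------
# VCF dosages
# ----------------------------------------------------------------------

def read_vcf_dosages(path: str | Path) -> tuple[MolecularMatrix, pd.DataFrame]:
    """Read SNP allele dosages from a VCF.

    Uses the DS FORMAT field when present, otherwise the ALT allele count of
    the GT call.  Missing genotypes become NaN dosages.  Multi-allelic
    records are rejected.
    """
    import pysam

    rows: list[np.ndarray] = []
    ids: list[str] = []
    annot: list[dict] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise FormatError("VCF has no sample columns")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise FormatError(
                    f"multi-allelic record at {rec.chrom}:{rec.pos} not supported"
                )
            snp_id = rec.id or f"{rec.chrom}:{rec.pos}"
            dose = np.full(len(samples), np.nan)
            for j, s in enumerate(samples):
                call = rec.samples[s]
                ds = call.get("DS")
                if ds is not None:
                    dose[j] = float(ds)
                    continue
                gt = call.get("GT")
                if gt is not None and not any(a is None for a in gt):
                    dose[j] = float(sum(1 for a in gt if a == 1))
            ids.append(snp_id)
            rows.append(dose)
            annot.append({"feature_id": snp_id, "chrom": rec.chrom, "pos": rec.pos})
    values = pd.DataFrame(rows, index=ids, columns=samples)
    return MolecularMatrix(values, "dosage"), feature_annotation_frame(annot)


def write_vcf_dosages(
    matrix: MolecularMatrix, annotation: pd.DataFrame, path: str | Path
) -> None:
    """Write integer/fractional dosages as a minimal VCFv4.2 with GT:DS."""
    annot = annotation.set_index("feature_id")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">\n'
        )
        chroms = annot.loc[matrix.feature_ids, "chrom"].unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        order = annot.loc[matrix.feature_ids].sort_values(["chrom", "pos"]).index
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for snp in order:
            row = matrix.values.loc[snp]
            fields = []
            for d in row.to_numpy(dtype=float):
                if np.isnan(d):
                    fields.append("./.:.")
                else:
                    gt = gt_map.get(int(round(d)), "./.") if abs(d - round(d)) < 1e-9 else "./."
                    fields.append(f"{gt}:{d:g}")
            fh.write(
                f"{annot.at[snp, 'chrom']}\t{int(annot.at[snp, 'pos'])}\t{snp}"
                f"\tA\tG\t.\tPASS\t.\tGT:DS\t" + "\t".join(fields) + "\n"
            )


# ----------------------------------------------------------------------
# region sets, sample sheets, annotations, result tables
# ----------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[RegionSet]:
    regions: list[RegionSet] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected id, kind and ≥1 member")
            region_id, kind, *members = parts
            key = (kind, region_id)
            if key in seen:
                raise FormatError(f"duplicate region id {region_id!r} for kind {kind!r}")
            seen.add(key)
            regions.append(RegionSet(region_id, kind, members))
    return regions


def write_gmt(regions: Iterable[RegionSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write("\t".join([r.region_id, r.region_kind, *r.member_cpgs]) + "\n")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.data.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "chrom": str})
    return feature_annotation_frame(df.to_dict("records"))


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table with its documented column order preserved."""
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ----------------------------------------------------------------------
# sample alignment
# ----------------------------------------------------------------------

def align_samples(
    sheet: SampleSheet,
    *matrices: MolecularMatrix,
    allow_subset: bool = False,
) -> tuple[SampleSheet, list[MolecularMatrix]]:
    """Intersect sample ids across matrices, preserving sheet order.

    Raises unless the sample sets are identical or ``allow_subset`` is set.
    """
    common = [s for s in sheet.sample_ids if all(s in m.values.columns for m in matrices)]
    full = all(len(common) == len(m.sample_ids) for m in matrices) and len(
        common
    ) == len(sheet.sample_ids)
    if not full and not allow_subset:
        raise FormatError(
            "sample ids differ between sheet and matrices (pass allow_subset to intersect)"
        )
    if not common:
        raise FormatError("no samples in common")
    return sheet.subset(common), [m.subset_samples(common) for m in matrices]


# ----------------------------------------------------------------------
# JSON sidecars
# ----------------------------------------------------------------------

def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
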