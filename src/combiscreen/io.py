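"""Readers and writers for the package's plain-text table formats.

Plate tables are long-format CSV with one well per row; concentrations are
always serialized in µM with the unit in the column name (``dose_a_um``,
``dose_b_um``), avoiding nM/µM ambiguity. Expression matrices are TSV with
gene ids in the first column and sample ids as the header; Ct tables are
long-format CSV (gene, group, replicate, ct).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import PLATE_COLUMNS, ExpressionTable

__all__ = [
    "read_plate_csv",
    "write_plate_csv",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_ct_csv",
    "write_ct_csv",
]


class SchemaError(ValueError):
    """A file does not match its documented schema."""


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format plate table.

    Errors name the missing column or the offending row number (1-based,
    excluding the header) for negative signals and unparseable doses.
    """
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col in ("dose_a_um", "dose_b_um", "raw_signal"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{path}: unparseable value in column {col!r} at row {bad[0] + 1}"
            )
        df[col] = coerced
    neg = df.index[df["raw_signal"] < 0]
    if len(neg):
        raise SchemaError(f"{path}: negative raw_signal at row {neg[0] + 1}")
    neg_dose = df.index[(df["dose_a_um"] < 0) | (df["dose_b_um"] < 0)]
    if len(neg_dose):
        raise SchemaError(f"{path}: negative dose at row {neg_dose[0] + 1}")
    df["is_vehicle"] = df["is_vehicle"].astype(bool)
    no_vehicle = [
        str(s) for s, grp in df.groupby("sample_id") if not grp["is_vehicle"].any()
    ]
    if no_vehicle:
        raise SchemaError(f"{path}: samples without vehicle wells: {no_vehicle}")
    return df


def write_plate_csv(plate: pd.DataFrame, path: str | Path) -> None:
    plate.to_csv(path, index=False)


def read_expression_tsv(
    path: str | Path, groups_path: str | Path
) -> ExpressionTable:
    """Read a gene × sample TSV plus a (sample_id, group) CSV map."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    groups_df = pd.read_csv(groups_path)
    for col in ("sample_id", "group"):
        if col not in groups_df.columns:
            raise SchemaError(f"{groups_path}: missing column {col!r}")
    groups = groups_df.set_index("sample_id")["group"]
    return ExpressionTable(values=values, groups=groups)


def write_expression_tsv(
    expr: ExpressionTable, path: str | Path, groups_path: str | Path | None = None
) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")
    if groups_path is not None:
        expr.groups.rename("group").rename_axis("sample_id").reset_index().to_csv(
            groups_path, index=False
        )


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("gene", "group", "replicate", "ct") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def write_ct_csv(ct: pd.DataFrame, path: str | Path) -> None:
    ct.to_csv(path, index=False)
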