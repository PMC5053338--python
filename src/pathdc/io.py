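"""Plain-TSV readers and writers for hierarchies, impact matrices,
differential-expression tables and decision reports.

All files are UTF-8 TSV with a header row.  Missing impact cells may be
written as the empty string or ``NA``; they are read back as missing,
never as zero.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .hierarchy import PathwayHierarchy, PathwayNode

__all__ = [
    "DEGRecord",
    "read_hierarchy",
    "write_hierarchy",
    "read_impact_matrix",
    "write_impact_matrix",
    "read_deg_table",
    "write_decision_report",
    "read_decision_report",
    "write_subdivision_matrix",
]

_MISSING_TOKENS = ("", "NA")

REPORT_COLUMNS = [
    "parent_id",
    "child_id",
    "b_star",
    "direct_factor",
    "indirect_factor",
    "dc",
    "cutoff_0.01",
    "cutoff_0.05",
    "cutoff_0.10",
    "significant_at",
    "direction",
    "decision_percentage",
]


@dataclass(frozen=True)
class DEGRecord:
    """One gene-level differential-expression result for one contrast."""

    gene_id: str
    pathway_ids: frozenset[str]
    contrast: str
    log2fc: float
    pvalue: float
    is_deg: bool

    def __post_init__(self):
        if not 0.0 < self.pvalue <= 1.0:
            raise ValueError(
                f"gene {self.gene_id!r}: p-value must lie in (0, 1], got {self.pvalue}"
            )
        if not self.pathway_ids:
            raise ValueError(f"gene {self.gene_id!r}: at least one pathway required")


# ----------------------------------------------------------------------
# hierarchy
# ----------------------------------------------------------------------
def read_hierarchy(path) -> PathwayHierarchy:
    """Read a 3-level pathway hierarchy from TSV.

    Expected header columns: ``level``, ``id``, ``name``, ``parent_id``.
    """
    path = Path(path)
    nodes: list[PathwayNode] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"level", "id", "name", "parent_id"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"{path}: header must contain columns {sorted(required)}"
            )
        for row in reader:
            lineno = reader.line_num
            if any(row.get(col) is None for col in ("level", "id", "name")):
                raise ValueError(f"{path}: malformed row at line {lineno}")
            nodes.append(
                PathwayNode(
                    id=row["id"].strip(),
                    name=row["name"].strip(),
                    level=row["level"].strip(),
                    parent_id=(row["parent_id"] or "").strip(),
                )
            )
    return PathwayHierarchy(nodes)


def write_hierarchy(hierarchy: PathwayHierarchy, path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["level", "id", "name", "parent_id"])
        for node in hierarchy:
            writer.writerow([node.level, node.id, node.name, node.parent_id])


# ----------------------------------------------------------------------
# impact matrices
# ----------------------------------------------------------------------
def read_impact_matrix(path) -> pd.DataFrame:
    """Read a pathway x contrast impact matrix.

    First column holds pathway ids; remaining columns are numeric or a
    missing token ("" or "NA").  Column order is preserved.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            na_values=list(_MISSING_TOKENS),
            keep_default_na=False,
            float_precision="round_trip",
        )
        df = df.astype(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric impact cell: {exc}") from exc
    if df.shape[1] < 1:
        raise ValueError(f"{path}: impact matrix needs at least one contrast column")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate pathway ids {dupes}")
    df.index = df.index.astype(str)
    df.index.name = "pathway_id"
    return df


def write_impact_matrix(matrix: pd.DataFrame, path) -> None:
    """Write an impact matrix; full-precision floats, NA for missing."""
    matrix.to_csv(Path(path), sep="\t", na_rep="NA", float_format="%.17g",
                  index_label="pathway_id", lineterminator="\n")


# ----------------------------------------------------------------------
# DEG tables
# ----------------------------------------------------------------------
def read_deg_table(path) -> list[DEGRecord]:
    """Read gene-level results: columns gene_id, contrast, log2fc,
    pvalue, is_deg, pathway_ids (semicolon-separated)."""
    path = Path(path)
    records: list[DEGRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene_id", "contrast", "log2fc", "pvalue", "is_deg", "pathway_ids"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: header must contain columns {sorted(required)}")
        for row in reader:
            lineno = reader.line_num
            try:
                records.append(
                    DEGRecord(
                        gene_id=row["gene_id"].strip(),
                        contrast=row["contrast"].strip(),
                        log2fc=float(row["log2fc"]),
                        pvalue=float(row["pvalue"]),
                        is_deg=row["is_deg"].strip().lower() in ("1", "true", "yes"),
                        pathway_ids=frozenset(
                            p.strip() for p in row["pathway_ids"].split(";") if p.strip()
                        ),
                    )
                )
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
    return records


# ----------------------------------------------------------------------
# decision reports
# ----------------------------------------------------------------------
def write_decision_report(report: pd.DataFrame, path) -> None:
    """Write the per-child decision report (one row per child pathway).

    Numeric columns are emitted with 6 decimal places; an empty report
    yields a header-only file.
    """
    out = report.reindex(columns=REPORT_COLUMNS)
    out.to_csv(Path(path), sep="\t", index=False, float_format="%.6f",
               na_rep="NA", lineterminator="\n")


def read_decision_report(path) -> pd.DataFrame:
    df = pd.read_csv(
        Path(path), sep="\t", na_values=["NA"], keep_default_na=False,
        dtype={"parent_id": str, "child_id": str, "significant_at": str,
               "direction": str},
    )
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: report missing columns {missing}")
    if "significant_at" in df.columns:
        df["significant_at"] = df["significant_at"].fillna("")
    return df


def write_subdivision_matrix(subdivision: pd.DataFrame, path) -> None:
    """Write a labelled q x q determination-factor table.

    The diagonal holds the direct factors (b*_j)^2; cell (t, j) holds
    the indirect factor 2 b*_t r_tj b*_j.
    """
    subdivision.to_csv(Path(path), sep="\t", float_format="%.6f",
                       index_label="child_id", lineterminator="\n")


def write_removal_log(log: pd.DataFrame, path) -> None:
    """Write the preprocessing removal log (pathway_id, reason)."""
    log.to_csv(Path(path), sep="\t", index=False, lineterminator="\n")
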