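"""Readers, validation and harmonization for cell-line panel inputs.

Three tables describe a panel (CCLE- or GDSC-style):

* an expression matrix, genes x cell lines (plain TSV or GCT 1.2);
* a long-format drug-response table, one row per (cell line, drug)
  carrying an IC50 or EC50 value;
* an annotation table mapping each cell line to its lineage
  (tissue of origin / cancer-type label).

Cell-line names differ between sources ("SK-MEL-28" vs "SKMEL28"), so
every identifier is normalized to uppercase alphanumerics before any
join.  Gene identifiers are treated as opaque symbols and kept verbatim.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ResponseTable",
    "LineageAnnotation",
    "HarmonizedPanel",
    "PanelFormatError",
    "PanelValidationError",
    "normalize_cell_line_id",
    "read_expression_tsv",
    "read_expression_gct",
    "read_response_tsv",
    "read_annotation_tsv",
    "harmonize",
    "write_expression_tsv",
    "write_response_tsv",
    "write_annotation_tsv",
]

logger = logging.getLogger(__name__)

VALID_METRICS = ("IC50", "EC50")

_NON_ALNUM = re.compile(r"[^A-Z0-9]")


class PanelFormatError(ValueError):
    """Malformed input file (bad header, dimension mismatch, missing column)."""


class PanelValidationError(ValueError):
    """Structurally valid file whose content violates a panel invariant."""


def normalize_cell_line_id(raw: str) -> str:
    """Canonical cell-line key: uppercase, all non-alphanumerics removed."""
    if not isinstance(raw, str) or not raw.strip():
        raise PanelValidationError("cell-line identifier must be non-empty text")
    out = _NON_ALNUM.sub("", raw.upper())
    if not out:
        raise PanelValidationError(f"cell-line identifier {raw!r} has no alphanumerics")
    return out


@dataclass
class ExpressionMatrix:
    """Genes x cell lines matrix of continuous expression values.

    ``data`` is a DataFrame indexed by gene symbol with normalized
    cell-line columns; NaN marks missing measurements.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise PanelValidationError("duplicate gene identifiers after de-duplication")
        if self.data.columns.has_duplicates:
            raise PanelValidationError("duplicate cell-line columns")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise PanelValidationError(
                f"expression matrix needs >=1 gene and >=1 cell line, got {self.data.shape}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class ResponseTable:
    """Long-format drug response records: cell_line, drug, metric, value[, units]."""

    data: pd.DataFrame  # columns: cell_line, drug, metric, value, units

    def __post_init__(self) -> None:
        required = {"cell_line", "drug", "metric", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise PanelValidationError(f"response table missing columns: {sorted(missing)}")
        if "units" not in self.data.columns:
            self.data = self.data.assign(units="")
        bad = set(self.data["metric"]) - set(VALID_METRICS)
        if bad:
            raise PanelValidationError(f"unknown response metrics: {sorted(bad)}")
        if self.data.duplicated(["cell_line", "drug", "metric"]).any():
            raise PanelValidationError("duplicate (cell_line, drug, metric) records")
        if not np.all(np.isfinite(self.data["value"].to_numpy(dtype=float))):
            raise PanelValidationError("response values must be finite")

    @property
    def cell_line_ids(self) -> set[str]:
        return set(self.data["cell_line"])

    @property
    def drug_ids(self) -> list[str]:
        return sorted(set(self.data["drug"]))


@dataclass
class LineageAnnotation:
    """Mapping from normalized cell-line identifier to lineage label."""

    lineage_of: dict[str, str]

    def __post_init__(self) -> None:
        for line, lineage in self.lineage_of.items():
            if not lineage or not str(lineage).strip():
                raise PanelValidationError(f"empty lineage label for cell line {line!r}")

    @property
    def cell_line_ids(self) -> set[str]:
        return set(self.lineage_of)

    @property
    def lineages(self) -> list[str]:
        return sorted(set(self.lineage_of.values()))


@dataclass
class HarmonizedPanel:
    """Expression, response and annotation restricted to their shared cell lines."""

    expression: ExpressionMatrix
    response: ResponseTable
    annotation: LineageAnnotation
    tag: str = field(default="panel")

    def __post_init__(self) -> None:
        e = set(self.expression.cell_line_ids)
        r = self.response.cell_line_ids
        a = self.annotation.cell_line_ids
        if not (e == r == a):
            raise PanelValidationError("panel components cover different cell-line sets")
        if not e:
            raise PanelValidationError("panel has no cell lines")

    @property
    def cell_lines(self) -> list[str]:
        return list(self.expression.cell_line_ids)

    @property
    def lineages(self) -> list[str]:
        return self.annotation.lineages

    def lines_in_lineage(self, lineage: str) -> list[str]:
        return [c for c in self.cell_lines if self.annotation.lineage_of[c] == lineage]


# ---------------------------------------------------------------------------
# readers


def _open_text(path: str | Path) -> io.TextIOWrapper:
    path = Path(path)
    fh = open(path, "rb")
    if fh.read(2) == b"\x1f\x8b":
        fh.seek(0)
        return io.TextIOWrapper(gzip.GzipFile(fileobj=fh), encoding="utf-8")
    fh.seek(0)
    return io.TextIOWrapper(fh, encoding="utf-8")


def _dedupe_gene_rows(df: pd.DataFrame) -> pd.DataFrame:
    dup = df.index.duplicated(keep="first")
    if dup.any():
        logger.warning(
            "dropping %d duplicate gene row(s): %s",
            int(dup.sum()),
            sorted(set(df.index[dup]))[:10],
        )
        df = df[~dup]
    return df


def _finalize_expression(df: pd.DataFrame) -> ExpressionMatrix:
    norm_cols = [normalize_cell_line_id(c) for c in df.columns]
    if len(set(norm_cols)) != len(norm_cols):
        seen: set[str] = set()
        dups = sorted({c for c in norm_cols if c in seen or seen.add(c)})
        raise PanelValidationError(f"duplicate cell-line columns after normalization: {dups}")
    if len(norm_cols) < 3:
        raise PanelValidationError(
            f"expression matrix needs at least 3 cell lines, got {len(norm_cols)}"
        )
    df = df.copy()
    df.columns = norm_cols
    df.index = df.index.astype(str)
    return ExpressionMatrix(_dedupe_gene_rows(df).astype(float))


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a genes-x-lines TSV matrix (header row = cell lines, col 1 = gene)."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0, na_values=["NA", ""])
    return _finalize_expression(df)


def read_expression_gct(path: str | Path) -> ExpressionMatrix:
    """Read a GCT 1.2 expression file (the dialect CCLE distributes)."""
    with _open_text(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise PanelFormatError(f"not a GCT 1.2 file (first line {version!r})")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise PanelFormatError("GCT dimensions line must hold two integers")
        n_rows, n_cols = (int(d) for d in dims)
        df = pd.read_csv(fh, sep="\t", na_values=["NA", ""])
    if df.columns[:2].tolist() != ["Name", "Description"]:
        raise PanelFormatError("GCT header must start with 'Name\\tDescription'")
    if df.shape[0] != n_rows or df.shape[1] - 2 != n_cols:
        raise PanelFormatError(
            f"GCT header declares {n_rows}x{n_cols} but body is "
            f"{df.shape[0]}x{df.shape[1] - 2}"
        )
    body = df.drop(columns="Description").set_index("Name")
    return _finalize_expression(body)


def read_response_tsv(
    path: str | Path,
    cell_line_col: str = "cell_line",
    drug_col: str = "drug",
    metric_col: str = "metric",
    value_col: str = "value",
    units_col: str | None = "units",
) -> ResponseTable:
    """Read long-format drug response records.

    Rows with missing or non-numeric values are dropped (count logged);
    replicate (cell line, drug, metric) rows are collapsed to their
    arithmetic mean.
    """
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", na_values=["NA", ""], dtype=str)
    need = [cell_line_col, drug_col, metric_col, value_col]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise PanelFormatError(f"response table missing required column(s): {missing}")
    out = pd.DataFrame(
        {
            "cell_line": df[cell_line_col],
            "drug": df[drug_col],
            "metric": df[metric_col].str.upper(),
            "value": pd.to_numeric(df[value_col], errors="coerce"),
            "units": df[units_col] if units_col and units_col in df.columns else "",
        }
    )
    n_before = len(out)
    out = out.dropna(subset=["cell_line", "drug", "metric", "value"])
    if len(out) < n_before:
        logger.info("dropped %d response row(s) with missing values", n_before - len(out))
    out["cell_line"] = out["cell_line"].map(normalize_cell_line_id)
    out["units"] = out["units"].fillna("")
    # replicate screens: arithmetic mean of the response value
    out = (
        out.groupby(["cell_line", "drug", "metric"], as_index=False, sort=True)
        .agg(value=("value", "mean"), units=("units", "first"))
    )
    return ResponseTable(out.reset_index(drop=True))


def read_annotation_tsv(
    path: str | Path,
    cell_line_col: str = "cell_line",
    lineage_col: str = "lineage",
) -> LineageAnnotation:
    """Read the cell line -> lineage mapping."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", na_values=["NA", ""], dtype=str)
    missing = [c for c in (cell_line_col, lineage_col) if c not in df.columns]
    if missing:
        raise PanelFormatError(f"annotation table missing required column(s): {missing}")
    df = df.dropna(subset=[cell_line_col, lineage_col])
    mapping: dict[str, str] = {}
    for raw, lineage in zip(df[cell_line_col], df[lineage_col]):
        key = normalize_cell_line_id(raw)
        if key in mapping and mapping[key] != lineage:
            raise PanelValidationError(
                f"cell line {key} annotated with conflicting lineages "
                f"{mapping[key]!r} and {lineage!r}"
            )
        mapping[key] = lineage
    return LineageAnnotation(mapping)


# ---------------------------------------------------------------------------
# harmonization


def harmonize(
    expression: ExpressionMatrix,
    response: ResponseTable,
    annotation: LineageAnnotation,
    tag: str = "panel",
) -> HarmonizedPanel:
    """Restrict all three components to their shared (normalized) cell lines."""
    shared = (
        set(expression.cell_line_ids) & response.cell_line_ids & annotation.cell_line_ids
    )
    if not shared:
        raise PanelValidationError("no cell line is shared by all three inputs")
    keep = [c for c in expression.cell_line_ids if c in shared]
    logger.info("panel %s: %d shared cell line(s)", tag, len(keep))
    expr = ExpressionMatrix(expression.data.loc[:, keep])
    resp = ResponseTable(
        response.data[response.data["cell_line"].isin(shared)].reset_index(drop=True)
    )
    ann = LineageAnnotation({c: annotation.lineage_of[c] for c in keep})
    return HarmonizedPanel(expr, resp, ann, tag=tag)


# ---------------------------------------------------------------------------
# writers (round-trip support and simulate output)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene", na_rep="NA")


def write_response_tsv(table: ResponseTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_annotation_tsv(annotation: LineageAnnotation, path: str | Path) -> None:
    pd.DataFrame(
        {"cell_line": list(annotation.lineage_of), "lineage": list(annotation.lineage_of.values())}
    ).to_csv(path, sep="\t", index=False)
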