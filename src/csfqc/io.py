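"""Readers and writers for the pipeline's tabular interchange formats.

All formats are plain UTF-8 delimited text with a header row:

* sample sheet — ``sample_id``, ``strip_grade`` (negative|+|++|+++|++++),
  ``hb_ng_ml``, ``rbc_per_ul``, ``asyn_ng_ml``, ``blood_fraction``
  (proportion); every column except ``sample_id`` is optional per row;
* peptide report — ``sample_id``, ``protein_accession``,
  ``peptide_sequence``, ``is_unique`` (true/false/1/0), with an optional
  column-mapping config to adapt search-engine exports;
* protein quantification matrix — rows are accessions (first column header
  ``protein``), columns are run ids, empty cells mean not quantified; run
  metadata sidecar with ``run_id``, ``sample_id``, ``blood_fraction``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .grading import ElisaReading, SampleGrade, SampleRecord, StripGrade, ValidationError
from .quant import ProteinQuantTable

__all__ = [
    "read_sample_sheet",
    "read_peptide_report",
    "read_quant_table",
    "write_grading_report",
    "read_grade_matrix",
]

_TRUE_TOKENS = {"true", "1", "yes", "y", "t"}
_FALSE_TOKENS = {"false", "0", "no", "n", "f"}


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a CSV or TSV file, sniffing the delimiter."""
    return pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)


def _opt_float(value: str, column: str, row: int) -> Optional[float]:
    if value == "" or value.lower() in {"na", "nan", "none"}:
        return None
    try:
        return float(value)
    except ValueError:
        raise ValidationError(f"row {row}: cannot parse {column}={value!r} as a number") from None


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    """Parse a sample sheet into :class:`SampleRecord` objects.

    Malformed rows raise a validation error naming the offending row
    (1-based, excluding the header).
    """
    df = _read_delimited(path)
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: sample sheet needs a sample_id column")
    if df.empty:
        raise ValidationError(f"{path}: sample sheet has no data rows")
    records = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        sid = str(row["sample_id"]).strip()
        if not sid:
            raise ValidationError(f"row {i}: empty sample_id")
        strip = None
        token = str(row.get("strip_grade", "")).strip()
        if token:
            try:
                strip = StripGrade.parse(token)
            except ValidationError as exc:
                raise ValidationError(f"row {i}: {exc}") from None
        hb = _opt_float(str(row.get("hb_ng_ml", "")), "hb_ng_ml", i)
        records.append(
            SampleRecord(
                sample_id=sid,
                elisa=ElisaReading(hb) if hb is not None else None,
                strip=strip,
                rbc_per_ul=_opt_float(str(row.get("rbc_per_ul", "")), "rbc_per_ul", i),
                asyn_ng_ml=_opt_float(str(row.get("asyn_ng_ml", "")), "asyn_ng_ml", i),
                blood_fraction=_opt_float(
                    str(row.get("blood_fraction", "")), "blood_fraction", i
                ),
            )
        )
    return records


def read_peptide_report(
    path: str | Path, column_map: Optional[Mapping[str, str]] = None
) -> pd.DataFrame:
    """Parse a peptide identification report.

    ``column_map`` renames report columns onto the expected four, e.g.
    ``{"Accession": "protein_accession"}`` for a search-engine export.
    """
    df = _read_delimited(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    required = ["sample_id", "protein_accession", "peptide_sequence", "is_unique"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: peptide report is missing columns {missing}")

    def parse_bool(value: str, row: int) -> bool:
        token = str(value).strip().lower()
        if token in _TRUE_TOKENS:
            return True
        if token in _FALSE_TOKENS:
            return False
        raise ValidationError(f"row {row}: cannot parse is_unique={value!r}")

    df = df[required].copy()
    df["is_unique"] = [
        parse_bool(v, i) for i, v in enumerate(df["is_unique"], start=1)
    ]
    return df


def read_quant_table(matrix_path: str | Path, runs_path: str | Path) -> ProteinQuantTable:
    """Parse a protein × run intensity matrix and its run-metadata sidecar."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col="protein")
    matrix = matrix.astype(float)
    runs = pd.read_csv(runs_path, sep="\t", index_col="run_id")
    runs["blood_fraction"] = runs["blood_fraction"].astype(float)
    runs["sample_id"] = runs["sample_id"].astype(str)
    return ProteinQuantTable(matrix, runs)


def write_grading_report(
    grades: Sequence[SampleGrade],
    tsv_path: str | Path,
    json_path: Optional[str | Path] = None,
    extra: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Write per-sample grading results as TSV (and optionally JSON).

    ``extra`` may carry additional per-sample columns (indexed by
    sample id), e.g. aSyn reliability annotations.
    """
    rows = []
    for g in grades:
        row = {
            "sample_id": g.sample_id,
            "elisa_value": int(g.per_method["elisa"]) if "elisa" in g.per_method else None,
            "strip_value": int(g.per_method["strip"]) if "strip" in g.per_method else None,
            "lc_ms_value": int(g.per_method["lc_ms"]) if "lc_ms" in g.per_method else None,
            "combined_value": int(g.combined),
            "combined_label": g.label,
            "excluded": g.excluded,
        }
        rows.append(row)
    report = pd.DataFrame(rows).set_index("sample_id")
    if extra is not None:
        report = report.join(extra, how="left")
    report.to_csv(tsv_path, sep="\t", index_label="sample_id")
    if json_path is not None:
        payload = report.reset_index().to_dict("records")
        cleaned = [
            {k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in row.items()}
            for row in payload
        ]
        with open(json_path, "w") as fh:
            json.dump(cleaned, fh, indent=2, default=str)
            fh.write("\n")
    return report


def read_grade_matrix(path: str | Path, methods: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Read a wide grading report back as a sample × method grade matrix."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    if methods is None:
        methods = [c for c in ("elisa_value", "strip_value", "lc_ms_value") if c in df.columns]
        if not methods:
            methods = [c for c in df.columns if c not in ("combined_value", "combined_label", "excluded")]
    matrix = df[list(methods)].astype(float)
    matrix.columns = [c.removesuffix("_value") for c in matrix.columns]
    return matrix
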