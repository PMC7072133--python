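"""End-to-end grading runs and human-readable summaries.

Ties the modules together: read a sample sheet (plus an optional peptide
report), grade every sample across its available modalities, annotate aSyn
reliability, and render a plain-text summary of grade distribution,
exclusions, lysed-cell flags and method concordance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Optional

import pandas as pd

from . import concordance as conc
from . import io as qcio
from .asyn import DEFAULT_BIAS_CONFIG, AsynBiasConfig, flag_biased_quantification
from .grading import (
    DEFAULT_CONFIG,
    GradingConfig,
    SampleGrade,
    SampleRecord,
    ValidationError,
    grade_sample,
)
from .markers import DEFAULT_ACCESSIONS, MarkerAccessionMap, build_marker_panels

__all__ = ["GradingRun", "run_grade", "run_report"]


@dataclass
class GradingRun:
    """Everything one grading run produced."""

    records: list[SampleRecord]
    grades: list[SampleGrade]
    report: pd.DataFrame
    matrix: pd.DataFrame  # sample × method grade matrix (NaN = absent)


def run_grade(
    sample_sheet: str | Path,
    peptide_report: Optional[str | Path] = None,
    out_tsv: Optional[str | Path] = None,
    out_json: Optional[str | Path] = None,
    config: GradingConfig = DEFAULT_CONFIG,
    bias_config: AsynBiasConfig = DEFAULT_BIAS_CONFIG,
    accession_map: MarkerAccessionMap = DEFAULT_ACCESSIONS,
) -> GradingRun:
    """Grade every sample of a sample sheet, with optional MS evidence.

    If a peptide report is given, marker panels are built per sample and
    the LC-MS modality joins the grade. The written report carries the
    per-method and combined values, the exclusion flag, and per-sample
    aSyn reliability flags.
    """
    records = qcio.read_sample_sheet(sample_sheet)
    if peptide_report is not None:
        panels = build_marker_panels(qcio.read_peptide_report(peptide_report), accession_map)
        records = [
            replace(r, panel=panels[r.sample_id]) if r.sample_id in panels else r
            for r in records
        ]
    grades = [grade_sample(r, config) for r in records]

    extra_rows = {}
    for record, grade in zip(records, grades):
        flags = flag_biased_quantification(
            grades=grade.per_method,
            blood_fraction=record.blood_fraction,
            config=bias_config,
        )
        extra_rows[record.sample_id] = {
            "rbc_per_ul": record.rbc_per_ul,
            "asyn_ng_ml": record.asyn_ng_ml,
            "asyn_elisa_unreliable": flags.elisa_unreliable,
            "asyn_ms_unreliable": flags.ms_unreliable,
        }
    extra = pd.DataFrame.from_dict(extra_rows, orient="index")

    tmp_tsv = Path(out_tsv) if out_tsv else None
    if tmp_tsv is None:
        import io as _io

        buf = _io.StringIO()
        report = qcio.write_grading_report(grades, buf, None, extra=extra)
    else:
        report = qcio.write_grading_report(grades, tmp_tsv, out_json, extra=extra)
    matrix = report[[c for c in ("elisa_value", "strip_value", "lc_ms_value")]].astype(float)
    matrix.columns = ["elisa", "strip", "lc_ms"]
    return GradingRun(records=records, grades=grades, report=report, matrix=matrix)


def run_report(run_or_report: GradingRun | pd.DataFrame) -> str:
    """Render a Markdown summary of a grading report.

    Covers the grade distribution, excluded samples, lysed-cell flags and
    pairwise method concordance (for methods graded on >= 1 shared sample).
    """
    report = run_or_report.report if isinstance(run_or_report, GradingRun) else run_or_report
    lines = ["# CSF blood-contamination grading summary", ""]

    counts = report["combined_value"].value_counts().sort_index()
    lines.append("## Grade distribution (combined)")
    for value, n in counts.items():
        lines.append(f"- value {int(value)}: {int(n)} sample(s)")
    lines.append("")

    excluded = report.index[report["excluded"].astype(bool)].tolist()
    lines.append(f"## Excluded samples ({len(excluded)})")
    lines.extend(f"- {s}" for s in excluded)
    lines.append("")

    method_cols = [c for c in ("elisa_value", "strip_value", "lc_ms_value") if c in report.columns]
    matrix = report[method_cols].astype(float)
    matrix.columns = [c.removesuffix("_value") for c in method_cols]
    usable = [m for m in matrix.columns if matrix[m].notna().any()]

    if "rbc_per_ul" in report.columns:
        disc = conc.discordance_report(matrix[usable], report["rbc_per_ul"]) if len(usable) >= 2 else None
        if disc is not None:
            flagged = disc.index[disc["lysed_cell_flag"]].tolist()
            lines.append(f"## Possible lysed-cell contamination ({len(flagged)})")
            lines.extend(f"- {s}" for s in flagged)
            lines.append("")

    if len(usable) >= 2:
        lines.append("## Method concordance")
        complete = matrix[usable].dropna()
        if len(complete) and len(usable) >= 2:
            n_agree, _ = conc.all_agree_count(matrix[usable])
            lines.append(f"- all methods agree: {n_agree}/{len(complete)} samples")
        for a, b in combinations(usable, 2):
            try:
                res = conc.pairwise_agreement(matrix, a, b)
            except ValidationError:
                continue
            lines.append(f"- {a} vs {b}: {res}")
        lines.append("")
    return "\n".join(lines)
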