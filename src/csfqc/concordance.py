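"""Cross-method agreement statistics over graded sample sets.

A grade matrix holds one contamination value per sample and method (ELISA,
strip, LC-MS); missing cells are allowed. The module counts samples on
which all methods agree, computes pairwise percent agreement (truncated to
an integer for the headline figure, with the exact fraction alongside),
and annotates discordant samples — in particular the lysed-cell phenotype,
where hemoglobin-sensitive methods call contamination while the RBC count
is low because the cells have ruptured.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Optional

import pandas as pd

from .grading import ContaminationValue, ValidationError

__all__ = [
    "AgreementResult",
    "DEFAULT_RBC_CUTOFF",
    "all_agree_count",
    "pairwise_agreement",
    "discordance_report",
]

#: Recommended clinical cut-off for blood contamination, in RBC/µL.
DEFAULT_RBC_CUTOFF = 50.0


def _check_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    if matrix.shape[1] < 2:
        raise ValidationError("grade matrix needs at least two method columns")
    return matrix


def all_agree_count(matrix: pd.DataFrame) -> tuple[int, list[str]]:
    """Count samples graded identically by every method.

    Samples with a missing method value are excluded from the comparison
    (and simply absent from the returned list), not treated as errors.
    """
    _check_matrix(matrix)
    complete = matrix.dropna()
    agree = complete[complete.nunique(axis=1) == 1]
    return len(agree), [str(s) for s in agree.index]


@dataclass(frozen=True)
class AgreementResult:
    """Pairwise agreement: headline integer percent plus the exact count."""

    method_a: str
    method_b: str
    matched: int
    compared: int

    @property
    def fraction(self) -> Fraction:
        return Fraction(self.matched, self.compared)

    @property
    def percent(self) -> int:
        """100 × matched/compared, truncated toward zero."""
        return (100 * self.matched) // self.compared

    def __str__(self) -> str:
        return f"{self.percent}% ({self.matched}/{self.compared})"


def pairwise_agreement(matrix: pd.DataFrame, method_a: str, method_b: str) -> AgreementResult:
    """Percent of samples on which two methods assign the same grade."""
    _check_matrix(matrix)
    pair = matrix[[method_a, method_b]].dropna()
    if pair.empty:
        raise ValidationError(
            f"no sample has grades for both {method_a!r} and {method_b!r}"
        )
    matched = int((pair[method_a] == pair[method_b]).sum())
    return AgreementResult(method_a, method_b, matched, len(pair))


def discordance_report(
    matrix: pd.DataFrame,
    rbc_per_ul: Optional[Mapping[str, float] | pd.Series] = None,
    rbc_cutoff: float = DEFAULT_RBC_CUTOFF,
    step_threshold: int = 2,
) -> pd.DataFrame:
    """Annotate samples with lysed-cell and step-disagreement flags.

    ``lysed_cell_flag``: any method grade >= 30 while the RBC count is below
    ``rbc_cutoff`` — hemoglobin without intact cells suggests the blood
    cells lysed before counting (invisible to routine RBC determination).
    Samples without an RBC count are never flagged.

    ``step_disagreement_flag``: method grades spread over at least
    ``step_threshold`` steps of the five-level ladder.
    """
    _check_matrix(matrix)
    rbc = pd.Series(rbc_per_ul) if rbc_per_ul is not None else pd.Series(dtype=float)
    rows = []
    for sample, grades in matrix.iterrows():
        present = grades.dropna()
        values = [ContaminationValue(int(v)) for v in present]
        max_grade = max(values) if values else None
        ranks = [v.rank for v in values]
        step_spread = (max(ranks) - min(ranks)) if ranks else 0
        rbc_value = float(rbc[sample]) if sample in rbc.index and pd.notna(rbc[sample]) else None
        lysed = (
            max_grade is not None
            and max_grade >= ContaminationValue.HIGH
            and rbc_value is not None
            and rbc_value < rbc_cutoff
        )
        notes = []
        if lysed:
            notes.append("possible lysed-cell contamination (hemoglobin without cells)")
        if step_spread >= step_threshold:
            notes.append(f"methods disagree by {step_spread} grade steps")
        rows.append(
            {
                "sample_id": sample,
                "max_grade": int(max_grade) if max_grade is not None else None,
                "rbc_per_ul": rbc_value,
                "lysed_cell_flag": bool(lysed),
                "step_disagreement_flag": step_spread >= step_threshold,
                "notes": "; ".join(notes),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
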