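"""Blood marker-protein panels from peptide-level identification reports.

Bottom-up proteomics identifies blood in CSF through three marker proteins:
hemoglobin (subunits alpha/beta/delta, UniProt P69905/P68871/P02042),
carbonic anhydrase 1 (P00915) and catalase (P04040). This module counts
distinct unique-flagged peptide sequences per marker group in a generic
four-column peptide report and decides whether the joint blood signature
(all three markers present) is met.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

from .grading import DEFAULT_CONFIG, GradingConfig, MarkerPanel, ValidationError

__all__ = [
    "PeptideRecord",
    "MarkerAccessionMap",
    "DEFAULT_ACCESSIONS",
    "build_marker_panel",
    "build_marker_panels",
    "detect_blood_signature",
]

logger = logging.getLogger(__name__)

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PeptideRecord:
    """One identified peptide in one run."""

    sample_id: str
    protein_accession: str
    peptide_sequence: str
    is_unique: bool

    def __post_init__(self) -> None:
        seq = self.peptide_sequence
        if not seq or not set(seq) <= _AA:
            raise ValidationError(
                f"peptide_sequence must be a non-empty uppercase amino-acid string, got {seq!r}"
            )


@dataclass(frozen=True)
class MarkerAccessionMap:
    """Which accessions count toward each marker group.

    ``hb_mode`` controls how hemoglobin subunits enter the panel count:
    ``pooled`` (default) deduplicates peptide sequences across all subunit
    accessions; ``per_subunit_max`` takes the largest per-subunit count.
    """

    hemoglobin: frozenset[str] = frozenset({"P69905", "P68871", "P02042"})
    cah1: str = "P00915"
    cata: str = "P04040"
    hb_mode: Literal["pooled", "per_subunit_max"] = "pooled"

    def __post_init__(self) -> None:
        object.__setattr__(self, "hemoglobin", frozenset(self.hemoglobin))
        groups = set(self.hemoglobin) | {self.cah1, self.cata}
        if len(groups) != len(self.hemoglobin) + 2:
            raise ValidationError("marker accession sets must be disjoint")

    @property
    def all_accessions(self) -> frozenset[str]:
        return self.hemoglobin | {self.cah1, self.cata}


DEFAULT_ACCESSIONS = MarkerAccessionMap()


def _as_records(records: Iterable[PeptideRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        required = {"sample_id", "protein_accession", "peptide_sequence", "is_unique"}
        missing = required - set(records.columns)
        if missing:
            raise ValidationError(f"peptide report is missing columns: {sorted(missing)}")
        return records
    rows = [
        (r.sample_id, r.protein_accession, r.peptide_sequence, r.is_unique) for r in records
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "protein_accession", "peptide_sequence", "is_unique"]
    )


def build_marker_panel(
    records: Iterable[PeptideRecord] | pd.DataFrame,
    sample_id: str,
    accession_map: MarkerAccessionMap = DEFAULT_ACCESSIONS,
) -> MarkerPanel:
    """Count distinct unique peptides per marker group for one sample.

    Only rows flagged unique are counted, deduplicated by sequence within
    each marker group; a hemoglobin peptide listed under two subunits
    counts once in pooled mode. An empty record set yields a panel of
    zeros; accessions outside the marker map are ignored (a debug count is
    logged).
    """
    df = _as_records(records)
    df = df[(df["sample_id"] == sample_id) & df["is_unique"].astype(bool)]
    marker_rows = df[df["protein_accession"].isin(accession_map.all_accessions)]
    ignored = len(df) - len(marker_rows)
    if ignored:
        logger.debug("sample %s: %d non-marker peptide rows ignored", sample_id, ignored)

    def distinct(accessions: set[str] | frozenset[str]) -> int:
        sel = marker_rows[marker_rows["protein_accession"].isin(accessions)]
        return int(sel["peptide_sequence"].nunique())

    if accession_map.hb_mode == "pooled":
        hb = distinct(accession_map.hemoglobin)
    else:
        hb = max((distinct({a}) for a in accession_map.hemoglobin), default=0)
    return MarkerPanel(
        hb_peptides=hb,
        cah1_peptides=distinct({accession_map.cah1}),
        cata_peptides=distinct({accession_map.cata}),
    )


def build_marker_panels(
    records: Iterable[PeptideRecord] | pd.DataFrame,
    accession_map: MarkerAccessionMap = DEFAULT_ACCESSIONS,
) -> dict[str, MarkerPanel]:
    """Build one panel per sample id present in the report."""
    df = _as_records(records)
    return {
        sid: build_marker_panel(df, sid, accession_map)
        for sid in df["sample_id"].unique()
    }


def detect_blood_signature(
    panel: MarkerPanel, config: GradingConfig = DEFAULT_CONFIG
) -> tuple[bool, str]:
    """Decide whether the joint blood signature is present.

    True iff all three markers are detected: pooled hemoglobin at or above
    the grading threshold, carbonic anhydrase 1 and catalase each with at
    least one unique peptide. Returns the decision plus a short narrative.
    """
    present = {
        "HB": panel.hb_peptides >= config.hb_peptide_min,
        "CAH1": panel.cah1_peptides >= config.cah1_peptide_min,
        "CATA": panel.cata_peptides >= 1,
    }
    positive = all(present.values())
    if positive:
        narrative = (
            f"blood signature present: HB ({panel.hb_peptides} peptides), "
            f"CAH1 ({panel.cah1_peptides}), CATA ({panel.cata_peptides}) all detected"
        )
    else:
        missing = [name for name, ok in present.items() if not ok]
        narrative = "blood signature absent: missing " + ", ".join(missing)
    return positive, narrative
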