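"""Five-level blood-contamination grading for CSF samples.

Blood contamination of cerebrospinal fluid (CSF) — typically introduced by
vascular bleeding during lumbar puncture — is graded on a five-level scale
of *contamination values* ``{1, 10, 20, 30, 40}`` (negative .. very high).
The same scale is assigned independently from three modalities:

* **ELISA** — the measured hemoglobin concentration (ng/mL) falls into one
  of five left-open, right-closed concentration intervals.
* **Urine test strip** — the semi-quantitative colorimetric blood pad read
  as negative / 1+ / 2+ / 3+ / 4+ maps one-to-one onto the scale.
* **LC-MS** — the unique-peptide counts of three blood marker proteins
  (hemoglobin subunits pooled, carbonic anhydrase 1, catalase) are pushed
  through a decision cascade: more markers, and more catalase peptides,
  mean more blood.

Per-sample grades from the available modalities are combined conservatively
(maximum), and samples strictly above a configurable exclusion threshold
(default 30) are recommended for exclusion from quantitative proteomics.
"""

from __future__ import annotations

import enum
import math
from bisect import bisect_left
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

__all__ = [
    "ContaminationValue",
    "StripGrade",
    "ElisaReading",
    "MarkerPanel",
    "GradingConfig",
    "SampleRecord",
    "SampleGrade",
    "ValidationError",
    "DEFAULT_CONFIG",
    "categorize_elisa",
    "categorize_strip",
    "categorize_ms",
    "grade_sample",
]


class ValidationError(ValueError):
    """Raised when an input measurement or record is invalid."""


class ContaminationValue(enum.IntEnum):
    """Blood-contamination grade; integer magnitude carries the ordering."""

    NEGATIVE = 1
    VERY_LOW = 10
    LOW = 20
    HIGH = 30
    VERY_HIGH = 40

    @property
    def label(self) -> str:
        return _CV_LABELS[self]

    @property
    def rank(self) -> int:
        """Position on the five-step ladder (0..4), for step-distance logic."""
        return _CV_ORDER.index(self)


_CV_LABELS: dict[ContaminationValue, str] = {
    ContaminationValue.NEGATIVE: "negative",
    ContaminationValue.VERY_LOW: "very low",
    ContaminationValue.LOW: "low",
    ContaminationValue.HIGH: "high",
    ContaminationValue.VERY_HIGH: "very high",
}
_CV_ORDER: tuple[ContaminationValue, ...] = tuple(ContaminationValue)


class StripGrade(enum.IntEnum):
    """Semi-quantitative blood-pad grade of the urine test strip.

    The manufacturer's comparison scale associates each grade with a nominal
    erythrocyte density: + ~10/µL, ++ ~25/µL, +++ ~50/µL, ++++ ~250/µL.
    """

    NEGATIVE = 0
    PLUS1 = 1
    PLUS2 = 2
    PLUS3 = 3
    PLUS4 = 4

    @property
    def nominal_ery_per_ul(self) -> int:
        return _STRIP_NOMINAL[self]

    @property
    def token(self) -> str:
        return _STRIP_TOKENS[self]

    @classmethod
    def parse(cls, token: str) -> "StripGrade":
        """Parse a textual strip grade (``negative``/``neg``, ``+``/``1+`` ..)."""
        key = str(token).strip().lower()
        try:
            return _STRIP_PARSE[key]
        except KeyError:
            raise ValidationError(f"unknown strip grade token: {token!r}") from None


_STRIP_NOMINAL: dict[StripGrade, int] = {
    StripGrade.NEGATIVE: 0,
    StripGrade.PLUS1: 10,
    StripGrade.PLUS2: 25,
    StripGrade.PLUS3: 50,
    StripGrade.PLUS4: 250,
}
_STRIP_TOKENS: dict[StripGrade, str] = {
    StripGrade.NEGATIVE: "negative",
    StripGrade.PLUS1: "+",
    StripGrade.PLUS2: "++",
    StripGrade.PLUS3: "+++",
    StripGrade.PLUS4: "++++",
}
_STRIP_PARSE: dict[str, StripGrade] = {
    "negative": StripGrade.NEGATIVE,
    "neg": StripGrade.NEGATIVE,
    "-": StripGrade.NEGATIVE,
    "0": StripGrade.NEGATIVE,
    "+": StripGrade.PLUS1,
    "1+": StripGrade.PLUS1,
    "plus1": StripGrade.PLUS1,
    "++": StripGrade.PLUS2,
    "2+": StripGrade.PLUS2,
    "plus2": StripGrade.PLUS2,
    "+++": StripGrade.PLUS3,
    "3+": StripGrade.PLUS3,
    "plus3": StripGrade.PLUS3,
    "++++": StripGrade.PLUS4,
    "4+": StripGrade.PLUS4,
    "plus4": StripGrade.PLUS4,
}


@dataclass(frozen=True)
class ElisaReading:
    """One hemoglobin ELISA readout (ng/mL), optionally with replicates.

    If replicates are given, ``hemoglobin_ng_per_ml`` must equal their
    arithmetic mean (readouts are routinely measured in duplicate).
    """

    hemoglobin_ng_per_ml: float
    replicates: Optional[tuple[float, ...]] = None
    cv_percent: Optional[float] = None

    def __post_init__(self) -> None:
        if self.replicates is not None:
            reps = tuple(float(r) for r in self.replicates)
            object.__setattr__(self, "replicates", reps)
            if any(r < 0 or not math.isfinite(r) for r in reps):
                raise ValidationError("ELISA replicates must be finite and >= 0")
            mean = sum(reps) / len(reps)
            if not math.isclose(mean, self.hemoglobin_ng_per_ml, rel_tol=1e-9, abs_tol=1e-9):
                raise ValidationError(
                    "hemoglobin_ng_per_ml must be the arithmetic mean of the replicates"
                )
        if self.cv_percent is not None and self.cv_percent < 0:
            raise ValidationError("cv_percent must be >= 0")

    @classmethod
    def from_replicates(cls, replicates: Sequence[float], cv_percent: float | None = None) -> "ElisaReading":
        reps = tuple(float(r) for r in replicates)
        return cls(sum(reps) / len(reps), replicates=reps, cv_percent=cv_percent)


@dataclass(frozen=True)
class MarkerPanel:
    """Unique-peptide counts of the three blood marker proteins in one run.

    Hemoglobin peptides are pooled over the alpha/beta/delta subunits with
    sequence-level deduplication.
    """

    hb_peptides: int
    cah1_peptides: int
    cata_peptides: int

    def __post_init__(self) -> None:
        for name in ("hb_peptides", "cah1_peptides", "cata_peptides"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")


@dataclass(frozen=True)
class GradingConfig:
    """Tunable thresholds of the categorization system.

    ``elisa_breakpoints`` are the interval edges in ng/mL; concentration c
    maps to grade i such that ``b_i < c <= b_{i+1}`` (c = 0 is negative).
    ``exclusion_threshold`` is exclusive: grades strictly above it are
    recommended for exclusion.
    """

    elisa_breakpoints: tuple[float, ...] = (0.0, 1000.0, 15000.0, 100000.0)
    hb_peptide_min: int = 5
    cata_peptide_split: int = 5
    cah1_peptide_min: int = 1
    exclusion_threshold: ContaminationValue = ContaminationValue.HIGH

    def __post_init__(self) -> None:
        bp = tuple(float(b) for b in self.elisa_breakpoints)
        object.__setattr__(self, "elisa_breakpoints", bp)
        if len(bp) != len(_CV_ORDER) - 1:
            raise ValidationError(
                f"need {len(_CV_ORDER) - 1} ELISA breakpoints for "
                f"{len(_CV_ORDER)} grades, got {len(bp)}"
            )
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValidationError("elisa_breakpoints must be strictly increasing")
        object.__setattr__(
            self, "exclusion_threshold", ContaminationValue(self.exclusion_threshold)
        )


DEFAULT_CONFIG = GradingConfig()


@dataclass(frozen=True)
class SampleRecord:
    """One CSF sample's multi-modality measurements.

    Any modality may be absent; at least one is required for grading. The
    RBC count and a known spike fraction are carried along but do not enter
    the grade.
    """

    sample_id: str
    elisa: Optional[ElisaReading] = None
    strip: Optional[StripGrade] = None
    panel: Optional[MarkerPanel] = None
    rbc_per_ul: Optional[float] = None
    asyn_ng_ml: Optional[float] = None
    blood_fraction: Optional[float] = None


@dataclass(frozen=True)
class SampleGrade:
    """Grading result: per-modality values, combined value, exclusion flag."""

    sample_id: str
    per_method: Mapping[str, ContaminationValue]
    combined: ContaminationValue
    excluded: bool

    @property
    def label(self) -> str:
        return self.combined.label


def categorize_elisa(
    reading: ElisaReading | float,
    config: GradingConfig = DEFAULT_CONFIG,
    sample_id: str | None = None,
) -> ContaminationValue:
    """Grade a hemoglobin ELISA concentration by interval lookup.

    Intervals are left-open, right-closed: with the default breakpoints,
    (0, 1000] -> 10, (1000, 15000] -> 20, (15000, 100000] -> 30,
    > 100000 -> 40; exactly 0 -> 1.
    """
    conc = reading.hemoglobin_ng_per_ml if isinstance(reading, ElisaReading) else float(reading)
    if not math.isfinite(conc) or conc < 0:
        who = f" in sample {sample_id!r}" if sample_id else ""
        raise ValidationError(f"invalid hemoglobin concentration{who}: {conc!r}")
    if conc == 0:
        return _CV_ORDER[0]
    # b_i < conc <= b_{i+1}  <=>  index = #breakpoints strictly below conc
    return _CV_ORDER[bisect_left(config.elisa_breakpoints, conc)]


def categorize_strip(grade: StripGrade | str) -> ContaminationValue:
    """Grade a strip readout: negative->1, 1+->10, 2+->20, 3+->30, 4+->40."""
    if not isinstance(grade, StripGrade):
        grade = StripGrade.parse(grade)
    return _CV_ORDER[int(grade)]


def categorize_ms(panel: MarkerPanel, config: GradingConfig = DEFAULT_CONFIG) -> ContaminationValue:
    """Grade an LC-MS marker panel through the decision cascade.

    No/weak hemoglobin -> negative; hemoglobin alone -> very low; plus
    carbonic anhydrase 1 -> low; plus catalase -> high, or very high once
    catalase reaches ``cata_peptide_split`` peptides.
    """
    if panel.hb_peptides < config.hb_peptide_min:
        return ContaminationValue.NEGATIVE
    if panel.cah1_peptides < config.cah1_peptide_min:
        return ContaminationValue.VERY_LOW
    if panel.cata_peptides == 0:
        return ContaminationValue.LOW
    if panel.cata_peptides < config.cata_peptide_split:
        return ContaminationValue.HIGH
    return ContaminationValue.VERY_HIGH


def grade_sample(record: SampleRecord, config: GradingConfig = DEFAULT_CONFIG) -> SampleGrade:
    """Grade every available modality and combine conservatively.

    The combined value is the maximum over the per-method values (a
    contaminated call by any modality is never masked); the exclusion flag
    is true iff the combined value is strictly above the configured
    threshold. Missing modalities are reported as absent, never imputed.
    """
    per: dict[str, ContaminationValue] = {}
    if record.elisa is not None:
        per["elisa"] = categorize_elisa(record.elisa, config, sample_id=record.sample_id)
    if record.strip is not None:
        per["strip"] = categorize_strip(record.strip)
    if record.panel is not None:
        per["lc_ms"] = categorize_ms(record.panel, config)
    if not per:
        raise ValidationError(f"sample {record.sample_id!r} has no modality to grade")
    combined = max(per.values())
    return SampleGrade(
        sample_id=record.sample_id,
        per_method=per,
        combined=combined,
        excluded=combined > config.exclusion_threshold,
    )
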