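"""Impact of blood contamination on the global CSF proteome.

Label-free protein intensities from blood-spiked CSF runs are compared
against each subject's clean (0% blood) reference run. Because a fixed
peptide mass is injected per run, abundant blood proteins displace CSF
signal — a compositional constraint: as the blood fraction grows, the
normalized intensity of CSF-specific proteins is suppressed while
blood-derived proteins intrude into the identified proteome.

The module provides cross-run normalization (ratio-median to a reference
run, or total-intensity), the definition of the CSF-specific reference
protein set, and per-fraction suppression/intrusion summaries with a
scatter-ready paired-intensity export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .grading import ValidationError

__all__ = [
    "ProteinQuantTable",
    "ImpactSummary",
    "NormalizationResult",
    "normalize_runs",
    "define_csf_reference_set",
    "impact_summary",
]

logger = logging.getLogger(__name__)

#: Minimum shared proteins for a trustworthy ratio-median scale factor.
MIN_SHARED_PROTEINS = 10


@dataclass
class ProteinQuantTable:
    """Protein × run intensity matrix with per-run metadata.

    ``intensities``: rows = protein accessions, columns = run ids, NaN =
    not quantified in that run. ``run_meta``: indexed by run id with
    columns ``sample_id`` and ``blood_fraction``.
    """

    intensities: pd.DataFrame
    run_meta: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.intensities.columns) - set(self.run_meta.index)
        if missing:
            raise ValidationError(f"runs without metadata: {sorted(missing)}")
        for col in ("sample_id", "blood_fraction"):
            if col not in self.run_meta.columns:
                raise ValidationError(f"run metadata is missing column {col!r}")
        values = self.intensities.to_numpy(dtype=float)
        if np.nanmin(values, initial=0.0) < 0:
            raise ValidationError("intensities must be non-negative")

    def runs_for_subject(self, subject: str) -> pd.DataFrame:
        return self.run_meta[self.run_meta["sample_id"] == subject]

    def reference_run(self, subject: str) -> str:
        """The subject's blood_fraction = 0 run id."""
        runs = self.runs_for_subject(subject)
        ref = runs[runs["blood_fraction"] == 0]
        if ref.empty:
            raise ValidationError(f"subject {subject!r} has no blood_fraction=0 reference run")
        return str(ref.index[0])


@dataclass(frozen=True)
class NormalizationResult:
    """Normalized table plus the per-run scale factors applied."""

    table: ProteinQuantTable
    factors: pd.Series
    reference_run: Optional[str]


def normalize_runs(
    table: ProteinQuantTable,
    reference_run: Optional[str] = None,
    method: Literal["ratio_median", "total"] = "ratio_median",
) -> NormalizationResult:
    """Scale each run onto a common intensity level.

    ``ratio_median`` (default): each run is multiplied by the factor that
    makes the median log-ratio of its shared quantified proteins against
    the reference run zero. Runs sharing fewer than ten proteins with the
    reference keep factor 1 (with a warning). ``total``: each run is scaled
    to the reference run's summed intensity, which preserves compositional
    shifts between runs of different makeup.
    """
    X = table.intensities
    if X.shape[1] < 1:
        raise ValidationError("need at least one run")
    if reference_run is None:
        zero = table.run_meta[table.run_meta["blood_fraction"] == 0]
        reference_run = str(zero.index[0]) if not zero.empty else str(X.columns[0])
    if reference_run not in X.columns:
        raise ValidationError(f"reference run {reference_run!r} not in table")

    ref = X[reference_run]
    factors = {}
    for run in X.columns:
        col = X[run]
        if method == "total":
            s_run, s_ref = float(col.sum(skipna=True)), float(ref.sum(skipna=True))
            factors[run] = s_ref / s_run if s_run > 0 else 1.0
            continue
        shared = (col > 0) & (ref > 0)
        if int(shared.sum()) < MIN_SHARED_PROTEINS:
            if run != reference_run:
                logger.warning(
                    "run %s shares only %d proteins with reference %s; scale factor 1",
                    run, int(shared.sum()), reference_run,
                )
            factors[run] = 1.0
            continue
        log_ratio = np.log(col[shared] / ref[shared])
        factors[run] = float(np.exp(-np.median(log_ratio)))
    factor_series = pd.Series(factors, name="scale_factor")
    normalized = X.mul(factor_series, axis=1)
    return NormalizationResult(
        table=ProteinQuantTable(normalized, table.run_meta),
        factors=factor_series,
        reference_run=reference_run,
    )


def define_csf_reference_set(table: ProteinQuantTable, subject: str) -> frozenset[str]:
    """Proteins quantified in the subject's clean reference run.

    All proteins detected at 0% blood define the CSF-specific set; anything
    appearing only in spiked runs is treated as blood-derived intrusion.
    """
    ref_run = table.reference_run(subject)
    col = table.intensities[ref_run]
    return frozenset(col.index[col.notna() & (col > 0)])


@dataclass(frozen=True)
class ImpactSummary:
    """Per-fraction effect of blood on the CSF-specific proteome."""

    subject: str
    blood_fraction: float
    run_id: str
    n_reference_proteins: int
    suppressed: int  #: CSF-specific proteins down by >= fold_threshold vs reference
    intrusions: int  #: proteins quantified in the spike run but not CSF-specific
    median_log2_ratio: float  #: over CSF-specific proteins quantified in both runs
    pairs: pd.DataFrame = field(repr=False, compare=False)


def impact_summary(
    table: ProteinQuantTable,
    subject: str,
    fold_threshold: float = 2.0,
) -> list[ImpactSummary]:
    """Summarize suppression and intrusion per spike fraction of a subject.

    For each of the subject's spiked runs: ``suppressed`` counts
    CSF-specific proteins whose intensity dropped by at least
    ``fold_threshold`` relative to the reference run (a protein that
    disappears entirely counts as suppressed); ``intrusions`` counts
    proteins quantified in the spiked run that are not in the CSF-specific
    set; the median log2 ratio is computed over CSF-specific proteins
    quantified in both runs. ``pairs`` carries the scatter-ready
    reference-vs-spike intensities.
    """
    if fold_threshold <= 1:
        raise ValidationError("fold_threshold must be > 1")
    ref_set = define_csf_reference_set(table, subject)
    ref_run = table.reference_run(subject)
    X = table.intensities
    ref = X[ref_run]
    results: list[ImpactSummary] = []
    runs = table.runs_for_subject(subject).sort_values("blood_fraction")
    for run_id, meta in runs.iterrows():
        if run_id == ref_run:
            continue
        spike = X[str(run_id)]
        in_ref = ref.index.isin(ref_set)
        ref_q = ref.notna() & (ref > 0)
        spike_q = spike.notna() & (spike > 0)

        both = in_ref & ref_q & spike_q
        ratio = spike[both] / ref[both]
        suppressed = int((ratio <= 1.0 / fold_threshold).sum())
        suppressed += int((in_ref & ref_q & ~spike_q).sum())  # dropped out entirely
        intrusions = int((spike_q & ~ref.index.isin(ref_set)).sum())
        median_log2 = float(np.median(np.log2(ratio))) if len(ratio) else float("nan")

        pairs = pd.DataFrame(
            {
                "reference_intensity": ref,
                "spike_intensity": spike,
                "csf_specific": in_ref,
            }
        )
        results.append(
            ImpactSummary(
                subject=subject,
                blood_fraction=float(meta["blood_fraction"]),
                run_id=str(run_id),
                n_reference_proteins=len(ref_set),
                suppressed=suppressed,
                intrusions=intrusions,
                median_log2_ratio=median_log2,
                pairs=pairs,
            )
        )
    return results
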