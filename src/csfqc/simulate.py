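"""Synthetic blood-contaminated CSF datasets.

Generates artificial spike-in experiments with the statistical structure the
grading pipeline assumes, so every stage can run and be tested without any
instrument data:

* a two-component proteome mixture — per-protein concentration
  ``(1-f)*a_csf + f*a_blood`` at blood volume fraction ``f`` — under fixed
  total sample loading, so abundant blood proteins (hemoglobin above all)
  compositionally displace CSF signal;
* abundance-dependent peptide detection: each protein's theoretical
  peptides are detected independently with a probability that saturates
  logistically in the log10 of its normalized abundance;
* a hemoglobin ELISA readout with multiplicative log-normal noise,
  a semi-quantitative strip grade from the erythrocyte-equivalent signal
  (intact plus lysed cells — the colorimetric chemistry sees hemoglobin,
  not membranes), and an RBC count that is blind to lysed cells;
* an aSyn concentration following the same linear mixing law.

Outputs are the three pipeline input files (sample sheet, peptide report,
protein quantification matrix with run metadata) plus a ground-truth record
of true fractions, marker panels and detection sets.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .grading import StripGrade, ValidationError

__all__ = [
    "SpikeInModel",
    "SyntheticDataset",
    "MARKER_THEORETICAL_PEPTIDES",
    "simulate_mixture",
    "simulate_marker_panels",
    "estimate_fraction",
    "strip_grade_from_ery",
]

# Marker accessions with fixed theoretical (fully tryptic, unique) peptide
# counts; all other proteins get a stable per-accession draw in 5..40.
MARKER_THEORETICAL_PEPTIDES: dict[str, int] = {
    "P69905": 10,  # hemoglobin subunit alpha
    "P68871": 10,  # hemoglobin subunit beta
    "P02042": 3,   # hemoglobin subunit delta
    "P00915": 20,  # carbonic anhydrase 1
    "P04040": 30,  # catalase
    "P37840": 10,  # alpha-synuclein
}

_STRIP_EDGES = (10.0, 25.0, 50.0, 250.0)  # Ery-equivalents/µL grade edges


def strip_grade_from_ery(ery_equiv_per_ul: float) -> StripGrade:
    """Map an erythrocyte-equivalent signal to the five strip grades.

    Uses the manufacturer's nominal scale: < 10 negative, then 1+ (~10),
    2+ (~25), 3+ (~50), 4+ (>= 250 Ery/µL).
    """
    return StripGrade(int(np.searchsorted(_STRIP_EDGES, ery_equiv_per_ul, side="right")))


@dataclass(frozen=True)
class SpikeInModel:
    """Parameters of the CSF/blood two-component spike-in simulator.

    Concentrations are ng/mL unless noted. The defaults describe a clean
    CSF proteome of 700 proteins totalling 0.4 g/L mixed with whole blood
    dominated by hemoglobin (140 g/L); blood contributes 300 proteins, of
    which half are plasma proteins already present in CSF at ~100-fold
    lower concentration and half are blood-specific (the marker proteins
    pinned among them).
    """

    # proteome composition
    n_csf_proteins: int = 700
    n_blood_proteins: int = 300
    n_shared_plasma: int = 150
    csf_total: float = 4.0e5
    csf_log10_sigma: float = 0.8
    blood_specific_total: float = 1.0e7
    plasma_ratio_log10_mean: float = 2.3
    plasma_ratio_log10_sigma: float = 0.3
    # pinned marker concentrations
    hb_blood: float = 1.4e8          # whole-blood hemoglobin (~140 g/L)
    hb_csf: float = 0.0              # endogenous sample hemoglobin (ELISA)
    hb_csf_marker: float = 20.0      # baseline HBA/HBB in clean CSF (MS)
    cah1_blood: float = 1.4e6
    cata_blood: float = 1.4e5
    asyn_csf: float = 0.15
    asyn_blood: float = 8000.0
    # cellular readouts
    rbc_blood: float = 5.0e6         # RBC density of whole blood, cells/µL
    lysis_fraction: float = 0.0
    strip_mapping: Literal["published", "physiological"] = "published"
    # noise
    elisa_cv: float = 0.15           # multiplicative CV of the ELISA readout
    elisa_replicates: int = 2
    between_subject_cv: float = 0.3
    # peptide detection law: p = logistic(slope * (log10 x - midpoint))
    detection_midpoint: float = -3.28
    detection_slope: float = 2.0
    load_intensity: float = 1.0e9    # arbitrary total MS signal per run
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.lysis_fraction <= 1:
            raise ValidationError("lysis_fraction must be in [0, 1]")
        for name in ("csf_total", "hb_blood", "rbc_blood", "load_intensity"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.elisa_cv < 0 or self.elisa_cv > 0.25:
            raise ValidationError("elisa_cv must be in [0, 0.25]")
        if self.n_shared_plasma + len(MARKER_THEORETICAL_PEPTIDES) > self.n_blood_proteins:
            raise ValidationError("n_blood_proteins too small for shared + marker proteins")

    @property
    def strip_equiv_per_fraction(self) -> float:
        """Ery-equivalents/µL contributed per unit blood fraction.

        ``published`` mode follows the reported equivalence of a 0.01% blood
        level with ~50 RBC/µL (5e5 equiv/µL per unit fraction);
        ``physiological`` mode uses the whole-blood RBC density.
        """
        return 5.0e5 if self.strip_mapping == "published" else self.rbc_blood


def _stable_rng(accession: str) -> np.random.Generator:
    return np.random.default_rng(zlib.crc32(accession.encode()))


def _theoretical_peptides(accession: str) -> int:
    if accession in MARKER_THEORETICAL_PEPTIDES:
        return MARKER_THEORETICAL_PEPTIDES[accession]
    return 5 + int(zlib.crc32((accession + "/n").encode()) % 36)


_PEPTIDE_ALPHABET = np.array(list("ACDEFGHILMNPQSTVWY"))  # internal residues


def _peptide_catalogue(accession: str) -> list[str]:
    """Deterministic synthetic tryptic-like peptide sequences per protein."""
    rng = _stable_rng(accession)
    n = _theoretical_peptides(accession)
    peptides = []
    for _ in range(n):
        length = int(rng.integers(7, 19))
        body = "".join(rng.choice(_PEPTIDE_ALPHABET, size=length - 1))
        peptides.append(body + ("K" if rng.random() < 0.5 else "R"))
    return peptides


@dataclass
class _Catalogue:
    """Protein catalogue shared by all subjects of one simulation."""

    accessions: np.ndarray
    csf: np.ndarray       # concentration in clean CSF
    blood: np.ndarray     # concentration in whole blood
    n_theo: np.ndarray
    marker_idx: dict[str, int]


def _build_catalogue(model: SpikeInModel, rng: np.random.Generator) -> _Catalogue:
    markers = list(MARKER_THEORETICAL_PEPTIDES)
    n_csf_random = model.n_csf_proteins - 2  # HBA/HBB sit inside the CSF catalogue
    csf_random = [f"CSF{i:04d}" for i in range(n_csf_random)]
    n_blood_random = model.n_blood_proteins - model.n_shared_plasma - len(markers)
    blood_random = [f"BLD{i:04d}" for i in range(n_blood_random)]

    accessions = np.array(markers + csf_random + blood_random)
    csf = np.zeros(len(accessions))
    blood = np.zeros(len(accessions))
    idx = {a: i for i, a in enumerate(accessions)}

    # CSF side: pinned hemoglobin baseline plus a log-normal proteome
    csf[idx["P69905"]] = model.hb_csf_marker
    csf[idx["P68871"]] = model.hb_csf_marker
    csf[idx["P37840"]] = model.asyn_csf
    draws = 10 ** rng.normal(0.0, model.csf_log10_sigma, size=n_csf_random)
    budget = model.csf_total - 2 * model.hb_csf_marker - model.asyn_csf
    csf_vals = draws * (budget / draws.sum())
    for acc, v in zip(csf_random, csf_vals):
        csf[idx[acc]] = v

    # blood side: pinned markers
    blood[idx["P69905"]] = 0.500 * model.hb_blood
    blood[idx["P68871"]] = 0.475 * model.hb_blood
    blood[idx["P02042"]] = 0.025 * model.hb_blood
    blood[idx["P00915"]] = model.cah1_blood
    blood[idx["P04040"]] = model.cata_blood
    blood[idx["P37840"]] = model.asyn_blood
    # shared plasma proteins: the most abundant CSF proteins, present in
    # blood at a ~100-1000x higher concentration
    order = np.argsort(csf_vals)[::-1][: model.n_shared_plasma]
    ratios = 10 ** rng.normal(
        model.plasma_ratio_log10_mean, model.plasma_ratio_log10_sigma, size=len(order)
    )
    for j, r in zip(order, ratios):
        blood[idx[csf_random[j]]] = csf_vals[j] * r
    # blood-specific background proteome
    if n_blood_random:
        bdraws = 10 ** rng.normal(0.0, model.csf_log10_sigma, size=n_blood_random)
        bvals = bdraws * (model.blood_specific_total / bdraws.sum())
        for acc, v in zip(blood_random, bvals):
            blood[idx[acc]] = v

    n_theo = np.array([_theoretical_peptides(a) for a in accessions])
    return _Catalogue(accessions, csf, blood, n_theo, idx)


def _detection_probability(model: SpikeInModel, x: np.ndarray) -> np.ndarray:
    """Per-peptide detection probability for normalized abundances x."""
    p = np.zeros_like(x)
    pos = x > 0
    z = model.detection_slope * (np.log10(x[pos]) - model.detection_midpoint)
    p[pos] = 1.0 / (1.0 + np.exp(-z))
    return p


def _detected_counts(
    model: SpikeInModel,
    cat: _Catalogue,
    csf_conc: np.ndarray,
    f: float,
    rng: Optional[np.random.Generator],
) -> tuple[np.ndarray, np.ndarray]:
    """Peptide counts and normalized abundances for one run.

    With ``rng`` None (noise-free), counts are the rounded expectations.
    """
    conc = (1.0 - f) * csf_conc + f * cat.blood
    total = conc.sum()
    x = conc / total if total > 0 else conc
    p = _detection_probability(model, x)
    if rng is None:
        k = np.rint(p * cat.n_theo).astype(int)
    else:
        k = rng.binomial(cat.n_theo, p)
    return k, x


@dataclass
class SyntheticDataset:
    """A full simulated spike-in experiment, ready for the pipeline."""

    samples: pd.DataFrame
    peptides: pd.DataFrame
    matrix: pd.DataFrame
    run_meta: pd.DataFrame
    ground_truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the pipeline input files plus the ground-truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "samples": outdir / "samples.tsv",
            "peptides": outdir / "peptides.tsv",
            "matrix": outdir / "protein_matrix.tsv",
            "runs": outdir / "runs.tsv",
            "ground_truth": outdir / "ground_truth.json",
        }
        self.samples.to_csv(paths["samples"], sep="\t", index=False)
        self.peptides.to_csv(paths["peptides"], sep="\t", index=False)
        self.matrix.to_csv(paths["matrix"], sep="\t", index_label="protein")
        self.run_meta.to_csv(paths["runs"], sep="\t", index_label="run_id")
        with open(paths["ground_truth"], "w") as fh:
            json.dump(self.ground_truth, fh, indent=2, sort_keys=True, default=_jsonable)
            fh.write("\n")
        return paths


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def simulate_mixture(
    model: SpikeInModel,
    fractions: Sequence[float],
    n_subjects: int = 4,
    noise: bool = True,
    seed: Optional[int] = None,
    with_peptides: bool = True,
) -> SyntheticDataset:
    """Simulate a spike-in experiment over the given blood fractions.

    One run per (subject, fraction). With ``noise=False`` the ELISA/aSyn
    noise, the between-subject proteome jitter and the binomial peptide
    sampling are all switched off (counts become rounded expectations), so
    identical calls are exactly reproducible closed-form.

    ``with_peptides=False`` skips materializing the peptide report (the
    ground-truth marker panels are still recorded) — useful for replicate
    studies where only grades or the quant matrix matter.
    """
    fractions = [float(f) for f in fractions]
    for f in fractions:
        if not 0 <= f <= 1:
            raise ValidationError(f"blood fraction must be in [0, 1], got {f}")
    root = np.random.SeedSequence(model.seed if seed is None else seed)
    # independent streams per readout, so toggling one noise source leaves
    # the draws of the others unchanged
    s_proteome, s_elisa, s_detection, s_counting = root.spawn(4)
    rng_proteome = np.random.default_rng(s_proteome)
    rng_elisa = np.random.default_rng(s_elisa)
    rng_detection = np.random.default_rng(s_detection)
    rng_counting = np.random.default_rng(s_counting)

    cat = _build_catalogue(model, rng_proteome)
    sigma_ln = float(np.sqrt(np.log1p(model.elisa_cv**2)))

    sample_rows = []
    peptide_rows = []
    matrix_cols: dict[str, np.ndarray] = {}
    run_rows = []
    gt_samples = {}
    gt_reference_detected = {}
    catalogues = (
        {a: _peptide_catalogue(a) for a in cat.accessions} if with_peptides else {}
    )

    for s in range(1, n_subjects + 1):
        subject = f"CSF{s}"
        if noise and model.between_subject_cv > 0:
            jitter_sigma = float(np.sqrt(np.log1p(model.between_subject_cv**2)))
            jitter = np.exp(rng_proteome.normal(0.0, jitter_sigma, size=len(cat.csf)))
        else:
            jitter = np.ones(len(cat.csf))
        csf_conc = cat.csf * jitter
        # ground truth: noise-free detection set of the clean run
        k_ref, _ = _detected_counts(model, cat, csf_conc, 0.0, None)
        gt_reference_detected[subject] = sorted(cat.accessions[k_ref >= 1])

        for f in fractions:
            sample_id = f"{subject}_f{f:g}"
            k, x = _detected_counts(
                model, cat, csf_conc, f, rng_detection if noise else None
            )
            # ELISA hemoglobin: linear mixing with multiplicative noise
            hb_true = (1.0 - f) * model.hb_csf + f * model.hb_blood
            if noise and model.elisa_cv > 0:
                reps = hb_true * np.exp(
                    rng_elisa.normal(0.0, sigma_ln, size=model.elisa_replicates)
                )
                hb_obs = float(np.mean(reps))
            else:
                hb_obs = hb_true
            # aSyn: same mixing law, ELISA-style noise
            asyn_true = (1.0 - f) * model.asyn_csf + f * model.asyn_blood
            if noise and model.elisa_cv > 0:
                asyn_obs = float(
                    np.mean(
                        asyn_true
                        * np.exp(rng_elisa.normal(0.0, sigma_ln, size=model.elisa_replicates))
                    )
                )
            else:
                asyn_obs = asyn_true
            # cells: the count sees only intact cells, the strip also lysed
            rbc_mean = f * model.rbc_blood * (1.0 - model.lysis_fraction)
            rbc = int(rng_counting.poisson(rbc_mean)) if noise else int(round(rbc_mean))
            ery_equiv = f * model.strip_equiv_per_fraction
            strip = strip_grade_from_ery(ery_equiv)

            sample_rows.append(
                {
                    "sample_id": sample_id,
                    "strip_grade": strip.token,
                    "hb_ng_ml": hb_obs,
                    "rbc_per_ul": rbc,
                    "asyn_ng_ml": asyn_obs,
                    "blood_fraction": f,
                }
            )
            run_rows.append(
                {"run_id": sample_id, "sample_id": subject, "blood_fraction": f}
            )
            intensities = np.where(k >= 1, x * model.load_intensity, np.nan)
            matrix_cols[sample_id] = intensities
            for i, acc in enumerate(cat.accessions) if with_peptides else ():
                ki = int(k[i])
                if ki < 1:
                    continue
                seqs = catalogues[acc]
                ki = min(ki, len(seqs))
                if noise:
                    chosen = rng_detection.choice(len(seqs), size=ki, replace=False)
                    chosen.sort()
                else:
                    chosen = range(ki)
                for j in chosen:
                    peptide_rows.append((sample_id, acc, seqs[int(j)], True))
            hb_total = int(
                k[cat.marker_idx["P69905"]]
                + k[cat.marker_idx["P68871"]]
                + k[cat.marker_idx["P02042"]]
            )
            gt_samples[sample_id] = {
                "subject": subject,
                "blood_fraction": f,
                "hb_true_ng_ml": hb_true,
                "asyn_true_ng_ml": asyn_true,
                "marker_panel": {
                    "hb_peptides": hb_total,
                    "cah1_peptides": int(k[cat.marker_idx["P00915"]]),
                    "cata_peptides": int(k[cat.marker_idx["P04040"]]),
                },
            }

    samples = pd.DataFrame(sample_rows)
    peptides = pd.DataFrame(
        peptide_rows,
        columns=["sample_id", "protein_accession", "peptide_sequence", "is_unique"],
    )
    matrix = pd.DataFrame(matrix_cols, index=pd.Index(cat.accessions, name="protein"))
    run_meta = pd.DataFrame(run_rows).set_index("run_id")
    ground_truth = {
        "model": dataclasses.asdict(model),
        "fractions": fractions,
        "n_subjects": n_subjects,
        "noise": noise,
        "csf_proteins": sorted(cat.accessions[cat.csf > 0]),
        "blood_proteins": sorted(cat.accessions[cat.blood > 0]),
        "reference_detected": gt_reference_detected,
        "samples": gt_samples,
    }
    return SyntheticDataset(samples, peptides, matrix, run_meta, ground_truth)


def simulate_marker_panels(
    model: SpikeInModel,
    fractions: Sequence[float],
    n_subjects: int = 4,
    n_replicates: int = 1,
    noise: bool = True,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Fast path: marker-panel peptide counts only, over many replicates.

    Skips file materialization; returns one row per (replicate, subject,
    fraction) with the three marker counts. Used for detection-frequency
    studies that would be wasteful through :func:`simulate_mixture`.
    """
    root = np.random.SeedSequence(model.seed if seed is None else seed)
    s_proteome, _, s_detection, _ = root.spawn(4)
    rng_proteome = np.random.default_rng(s_proteome)
    rng_detection = np.random.default_rng(s_detection)
    cat = _build_catalogue(model, rng_proteome)
    rows = []
    for rep in range(n_replicates):
            for s in range(1, n_subjects + 1):
                if noise and model.between_subject_cv > 0:
                    js = float(np.sqrt(np.log1p(model.between_subject_cv**2)))
                    jitter = np.exp(rng_proteome.normal(0.0, js, size=len(cat.csf)))
                else:
                    jitter = np.ones(len(cat.csf))
                csf_conc = cat.csf * jitter
                for f in fractions:
                    k, _ = _detected_counts(
                        model, cat, csf_conc, float(f),
                        rng_detection if noise else None,
                    )
                    rows.append(
                        {
                            "replicate": rep,
                            "subject": f"CSF{s}",
                            "blood_fraction": float(f),
                            "hb_peptides": int(
                                k[cat.marker_idx["P69905"]]
                                + k[cat.marker_idx["P68871"]]
                                + k[cat.marker_idx["P02042"]]
                            ),
                            "cah1_peptides": int(k[cat.marker_idx["P00915"]]),
                            "cata_peptides": int(k[cat.marker_idx["P04040"]]),
                        }
                    )
    return pd.DataFrame(rows)


def estimate_fraction(observed_hb_ng_ml: float, model: SpikeInModel) -> float:
    """Invert the hemoglobin mixing model to a blood volume fraction.

    Returns ``(observed - hb_csf) / (hb_blood - hb_csf)``; observations
    below the endogenous level return 0 with a warning.
    """
    if observed_hb_ng_ml < model.hb_csf:
        warnings.warn(
            "observed hemoglobin below the endogenous CSF level; returning fraction 0",
            stacklevel=2,
        )
        return 0.0
    return (observed_hb_ng_ml - model.hb_csf) / (model.hb_blood - model.hb_csf)
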