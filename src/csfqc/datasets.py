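"""Packaged reference fixtures from the published spike-in study.

Two small tables ship with the package:

* the strip grades of the four-subject spike-in series (five blood
  fractions per subject, 0 to 1%), used to check the grading staircase;
* the fifteen-sample clinical grade matrix (ELISA / strip / LC-MS
  contamination values), used for the concordance analysis.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_spikein_strip_grades", "load_clinical_grades", "CLINICAL_RBC_PER_UL"]

#: RBC counts (cells/µL) reported for clinical samples where published:
#: two high-aSyn samples exceeded the 50/µL cut-off while one (CSF19) had
#: no countable cells despite a grade-40 strip — the lysed-cell case.
CLINICAL_RBC_PER_UL: dict[str, float] = {"CSF19": 0.0}


def _load(name: str) -> pd.DataFrame:
    with resources.files("csfqc.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_spikein_strip_grades() -> pd.DataFrame:
    """Strip grades of the artificial spike-in series (long form)."""
    return _load("spikein_strip_grades.tsv")


def load_clinical_grades() -> pd.DataFrame:
    """Clinical sample × method contamination-value matrix."""
    return _load("clinical_grades.tsv").set_index("sample_id")
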