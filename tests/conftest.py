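import pandas as pd
import pytest

from csfqc.datasets import load_clinical_grades, load_spikein_strip_grades
from csfqc.simulate import SpikeInModel, simulate_mixture

STUDY_FRACTIONS = [0.0, 1e-5, 1e-4, 1e-3, 1e-2]


@pytest.fixture(scope="session")
def spikein_strips() -> pd.DataFrame:
    """Strip grades of the four-subject spike-in series (long form)."""
    return load_spikein_strip_grades()


@pytest.fixture(scope="session")
def clinical_matrix() -> pd.DataFrame:
    """Fifteen clinical samples × three grading methods."""
    return load_clinical_grades()


@pytest.fixture(scope="session")
def model() -> SpikeInModel:
    return SpikeInModel(seed=1)


@pytest.fixture(scope="session")
def noisefree_dataset(model):
    """Deterministic four-subject spike-in dataset across the study fractions."""
    return simulate_mixture(model, STUDY_FRACTIONS, n_subjects=4, noise=False)


@pytest.fixture(scope="session")
def noisy_dataset(model):
    return simulate_mixture(model, STUDY_FRACTIONS, n_subjects=4, noise=True, seed=11)
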