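"""Synthetic spike-in generator: determinism, round-trips, staircases."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from csfqc import io as qcio
from csfqc.grading import (
    ElisaReading,
    MarkerPanel,
    SampleRecord,
    StripGrade,
    ValidationError,
    grade_sample,
)
from csfqc.markers import build_marker_panels
from csfqc.simulate import (
    SpikeInModel,
    estimate_fraction,
    simulate_marker_panels,
    simulate_mixture,
    strip_grade_from_ery,
)

FRACTIONS = [0.0, 1e-5, 1e-4, 1e-3, 1e-2]


def combined_grades(dataset):
    """Grade every simulated sample from its sheet row + true marker panel."""
    grades = {}
    for row in dataset.samples.itertuples():
        panel = dataset.ground_truth["samples"][row.sample_id]["marker_panel"]
        record = SampleRecord(
            row.sample_id,
            elisa=ElisaReading(row.hb_ng_ml),
            strip=StripGrade.parse(row.strip_grade),
            panel=MarkerPanel(**panel),
        )
        grades[row.sample_id] = int(grade_sample(record).combined)
    return grades


class TestDeterminismAndRoundTrip:
    def test_identical_seeds_give_byte_identical_files(self, model, tmp_path):
        d1 = simulate_mixture(model, [0.0, 1e-4], n_subjects=2, seed=5)
        d2 = simulate_mixture(model, [0.0, 1e-4], n_subjects=2, seed=5)
        p1 = d1.write(tmp_path / "a")
        p2 = d2.write(tmp_path / "b")
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_different_seeds_differ(self, model):
        d1 = simulate_mixture(model, [1e-4], n_subjects=1, seed=5)
        d2 = simulate_mixture(model, [1e-4], n_subjects=1, seed=6)
        assert not d1.samples.equals(d2.samples)

    def test_emitted_files_reparse_losslessly(self, noisy_dataset, tmp_path):
        paths = noisy_dataset.write(tmp_path)
        records = qcio.read_sample_sheet(paths["samples"])
        assert [r.sample_id for r in records] == list(noisy_dataset.samples["sample_id"])
        for record, row in zip(records, noisy_dataset.samples.itertuples()):
            assert record.elisa.hemoglobin_ng_per_ml == pytest.approx(row.hb_ng_ml)
            assert record.strip.token == row.strip_grade
            assert record.blood_fraction == row.blood_fraction

        peptides = qcio.read_peptide_report(paths["peptides"])
        pd.testing.assert_frame_equal(peptides, noisy_dataset.peptides)

        table = qcio.read_quant_table(paths["matrix"], paths["runs"])
        assert np.allclose(
            table.intensities.fillna(-1).to_numpy(),
            noisy_dataset.matrix.fillna(-1).to_numpy(),
        )

    def test_peptide_report_reproduces_ground_truth_panels(self, noisy_dataset):
        panels = build_marker_panels(noisy_dataset.peptides)
        for sample_id, truth in noisy_dataset.ground_truth["samples"].items():
            expected = MarkerPanel(**truth["marker_panel"])
            assert panels.get(sample_id, MarkerPanel(0, 0, 0)) == expected


class TestNoiseFreeBehaviour:
    def test_clean_sample_is_clean(self, noisefree_dataset):
        row = noisefree_dataset.samples.set_index("sample_id").loc["CSF1_f0"]
        assert row.hb_ng_ml == 0.0
        assert row.strip_grade == "negative"
        panel = noisefree_dataset.ground_truth["samples"]["CSF1_f0"]["marker_panel"]
        assert panel["hb_peptides"] < 5 and panel["cah1_peptides"] == 0

    def test_grade_staircase_non_decreasing(self, noisefree_dataset):
        grades = combined_grades(noisefree_dataset)
        for s in range(1, 5):
            chain = [grades[f"CSF{s}_f{f:g}"] for f in FRACTIONS]
            assert chain == sorted(chain), chain
            assert chain[0] == 1 and chain[-1] == 40

    def test_clean_run_identifies_most_of_the_catalogue(self, noisefree_dataset):
        detected = noisefree_dataset.matrix["CSF1_f0"].notna().sum()
        assert 600 <= detected <= 700

    def test_fraction_recovery_round_trip(self, model, noisefree_dataset):
        sheet = noisefree_dataset.samples
        for row in sheet.itertuples():
            est = estimate_fraction(row.hb_ng_ml, model)
            assert est == pytest.approx(row.blood_fraction, rel=1e-9, abs=1e-15)

    def test_full_lysis_gives_csf19_phenotype(self):
        """All spiked cells lysed: nothing to count, but hemoglobin-driven
        readouts (strip, ELISA) still call blood."""
        model = SpikeInModel(seed=2, lysis_fraction=1.0)
        ds = simulate_mixture(model, [1e-4], n_subjects=1, noise=False,
                              with_peptides=False)
        row = ds.samples.iloc[0]
        assert row.rbc_per_ul == 0
        assert row.strip_grade == "+++"  # grade 30 despite zero countable cells
        assert row.hb_ng_ml >= 10_000


class TestModelValidation:
    def test_invalid_fraction_rejected(self, model):
        with pytest.raises(ValidationError):
            simulate_mixture(model, [1.5], n_subjects=1)

    def test_lysis_fraction_bounds(self):
        with pytest.raises(ValidationError):
            SpikeInModel(lysis_fraction=1.2)

    def test_elisa_cv_capped(self):
        with pytest.raises(ValidationError):
            SpikeInModel(elisa_cv=0.5)

    def test_below_endogenous_level_warns_and_clamps(self):
        model = SpikeInModel(hb_csf=100.0)
        with pytest.warns(UserWarning):
            assert estimate_fraction(50.0, model) == 0.0

    def test_endmember_inversion(self, model):
        assert estimate_fraction(model.hb_blood, model) == pytest.approx(1.0)
        assert estimate_fraction(model.hb_csf, model) == 0.0


class TestStripSimulation:
    @pytest.mark.parametrize(
        "ery,token",
        [(0, "negative"), (9.9, "negative"), (10, "+"), (25, "++"), (49, "++"),
         (50, "+++"), (249, "+++"), (250, "++++"), (5000, "++++")],
    )
    def test_nominal_thresholds(self, ery, token):
        assert strip_grade_from_ery(ery).token == token

    def test_published_mapping_ties_50_cells_to_1e4_fraction(self, model):
        assert model.strip_equiv_per_fraction * 1e-4 == pytest.approx(50.0)

    def test_physiological_mapping_uses_blood_density(self):
        model = SpikeInModel(strip_mapping="physiological")
        assert model.strip_equiv_per_fraction == model.rbc_blood


class TestMarkerStaircase:
    def test_detection_frequency_ordering(self, model):
        """Hemoglobin everywhere, carbonic anhydrase 1 before catalase,
        catalase mostly absent at 0.001% and mostly present from 0.01%."""
        panels = simulate_marker_panels(
            model, FRACTIONS, n_subjects=4, n_replicates=30, noise=True, seed=3
        )
        freq = panels.groupby("blood_fraction").agg(
            hb=("hb_peptides", lambda k: (k >= 1).mean()),
            cah1=("cah1_peptides", lambda k: (k >= 1).mean()),
            cata=("cata_peptides", lambda k: (k >= 1).mean()),
        )
        assert (freq.loc[1e-5:, "hb"] >= 0.99).all()
        assert (freq["cah1"] >= freq["cata"]).all()
        assert freq["cata"].is_monotonic_increasing
        assert freq.loc[1e-5, "cata"] < 0.5 <= freq.loc[1e-4, "cata"]
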