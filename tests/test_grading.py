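"""Grading rules: interval lookup, strip mapping, MS cascade, combination."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csfqc.grading import (
    DEFAULT_CONFIG,
    ContaminationValue,
    ElisaReading,
    GradingConfig,
    MarkerPanel,
    SampleRecord,
    StripGrade,
    ValidationError,
    categorize_elisa,
    categorize_ms,
    categorize_strip,
    grade_sample,
)


def elisa_by_linear_scan(conc: float, config: GradingConfig = DEFAULT_CONFIG) -> int:
    """Independent oracle: walk the interval rows one by one."""
    values = [1, 10, 20, 30, 40]
    if conc == 0:
        return 1
    bp = list(config.elisa_breakpoints) + [math.inf]
    for i in range(1, len(values)):
        if bp[i - 1] < conc <= bp[i]:
            return values[i]
    raise AssertionError("unreachable")


class TestCategorizeElisa:
    @pytest.mark.parametrize(
        "conc,expected",
        [
            (14_820, 20),  # reference sample with elevated endogenous hemoglobin
            (0, 1),
            (201_940, 40),
            (236_650, 40),
            (2_332_350, 40),
            (2_906_110, 40),
            (18_130, 30),
            (20_820, 30),
            (1_000, 10),  # intervals are right-closed
            (1_000.01, 20),
            (15_000, 20),
            (100_000, 30),
            (0.001, 10),
        ],
    )
    def test_interval_examples(self, conc, expected):
        assert categorize_elisa(conc) == expected

    @pytest.mark.parametrize("bad", [-1.0, float("nan"), float("inf")])
    def test_invalid_concentration_rejected(self, bad):
        with pytest.raises(ValidationError, match="CSF x"):
            categorize_elisa(bad, sample_id="CSF x")

    @given(st.floats(min_value=0, max_value=1e7, allow_nan=False))
    @settings(max_examples=200)
    def test_matches_linear_scan_oracle(self, conc):
        assert categorize_elisa(conc) == elisa_by_linear_scan(conc)

    @given(
        st.floats(min_value=0, max_value=1e7),
        st.floats(min_value=0, max_value=1e7),
    )
    @settings(max_examples=200)
    def test_monotone_in_concentration(self, a, b):
        lo, hi = sorted((a, b))
        assert categorize_elisa(lo) <= categorize_elisa(hi)

    def test_accepts_reading_with_replicates(self):
        reading = ElisaReading.from_replicates([14_000, 15_640])
        assert categorize_elisa(reading) == 20

    def test_replicate_mean_invariant_enforced(self):
        with pytest.raises(ValidationError):
            ElisaReading(10.0, replicates=(1.0, 2.0))

    def test_custom_breakpoints_must_increase(self):
        with pytest.raises(ValidationError):
            GradingConfig(elisa_breakpoints=(0, 1000, 1000, 5000))


class TestCategorizeStrip:
    @pytest.mark.parametrize(
        "token,expected",
        [("negative", 1), ("+", 10), ("++", 20), ("+++", 30), ("++++", 40), ("3+", 30)],
    )
    def test_token_mapping(self, token, expected):
        assert categorize_strip(token) == expected

    def test_unknown_token_rejected(self):
        with pytest.raises(ValidationError, match="\\+{5}"):
            categorize_strip("+++++")

    def test_nominal_ery_counts(self):
        assert [g.nominal_ery_per_ul for g in StripGrade] == [0, 10, 25, 50, 250]


class TestCategorizeMs:
    @pytest.mark.parametrize(
        "panel,expected",
        [
            ((4, 0, 0), 1),
            ((4, 3, 3), 1),  # weak hemoglobin dominates the cascade
            ((9, 2, 0), 20),
            ((9, 0, 0), 10),
            ((5, 0, 7), 10),  # no CAH1 means at most very low
            ((12, 4, 3), 30),
            ((12, 4, 5), 40),
            ((12, 4, 4), 30),
        ],
    )
    def test_cascade_examples(self, panel, expected):
        assert categorize_ms(MarkerPanel(*panel)) == expected

    @given(
        st.integers(0, 30), st.integers(0, 30), st.integers(0, 30),
        st.integers(0, 5), st.integers(0, 5), st.integers(0, 5),
    )
    @settings(max_examples=200)
    def test_monotone_under_componentwise_increase(self, hb, cah1, cata, dh, dc, dt):
        low = categorize_ms(MarkerPanel(hb, cah1, cata))
        high = categorize_ms(MarkerPanel(hb + dh, cah1 + dc, cata + dt))
        assert low <= high

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            MarkerPanel(-1, 0, 0)


class TestGradeSample:
    def test_concordant_high_sample(self):
        record = SampleRecord(
            "s1",
            elisa=ElisaReading(18_130),
            strip=StripGrade.PLUS3,
            panel=MarkerPanel(15, 3, 2),
        )
        grade = grade_sample(record)
        assert grade.per_method == {
            "elisa": ContaminationValue.HIGH,
            "strip": ContaminationValue.HIGH,
            "lc_ms": ContaminationValue.HIGH,
        }
        assert grade.combined == 30 and not grade.excluded

    def test_single_modality(self):
        grade = grade_sample(SampleRecord("s2", strip=StripGrade.NEGATIVE))
        assert grade.combined == 1 and not grade.excluded
        assert set(grade.per_method) == {"strip"}

    def test_combined_is_maximum(self):
        record = SampleRecord(
            "s3", elisa=ElisaReading(2_143), strip=StripGrade.PLUS2, rbc_per_ul=0.0
        )
        grade = grade_sample(record)
        assert grade.combined == 20

    def test_exclusion_above_threshold(self):
        grade = grade_sample(SampleRecord("s4", elisa=ElisaReading(150_000)))
        assert grade.combined == 40 and grade.excluded
        assert grade.label == "very high"

    def test_no_modality_is_error(self):
        with pytest.raises(ValidationError, match="s5"):
            grade_sample(SampleRecord("s5", rbc_per_ul=3.0))


class TestSpikeinStripPattern:
    def test_reproduces_published_grade_pattern(self, spikein_strips):
        """The four-subject spike-in series: one grade per fraction, with the
        one subject that carried endogenous blood elevated one step at every
        fraction."""
        expected_base = {0.01: 40, 0.001: 40, 0.0001: 30, 0.00001: 20, 0.0: 1}
        elevated = {0.01: 40, 0.001: 40, 0.0001: 40, 0.00001: 30, 0.0: 20}
        for row in spikein_strips.itertuples():
            value = categorize_strip(row.strip_grade)
            want = (elevated if row.sample_id == "CSF2" else expected_base)[row.blood_fraction]
            assert value == want, (row.sample_id, row.blood_fraction)

    def test_label_bijection(self):
        labels = {int(v): v.label for v in ContaminationValue}
        assert labels == {1: "negative", 10: "very low", 20: "low", 30: "high", 40: "very high"}
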