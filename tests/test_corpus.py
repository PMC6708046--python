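"""Corpus model: unit normalisation, covariate classification, filtering,
validation and the tabular exchange format."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from headconduct import (
    AgeClass,
    Compartment,
    Corpus,
    CorpusError,
    Subtissue,
    TemperatureClass,
    TissueLabel,
    apply_frequency_filter,
    classify_age,
    classify_temperature,
    read_corpus,
    to_conductivity,
    validate_corpus,
    write_corpus,
)
from conftest import make_record


class TestUnitConversion:
    @pytest.mark.parametrize(
        "value,unit,expected",
        [
            (2.0, "ohm.m", 0.5),          # σ = 1/ρ
            (10.0, "mS/cm", 1.0),         # 10 mS/cm = 1 S/m
            (0.41, "S/m", 0.41),          # identity
            (100.0, "ohm.cm", 1.0),       # 100 Ω·cm = 1 Ω·m
            (0.1, "kohm.cm", 1.0),        # 0.1 kΩ·cm = 1 Ω·m
            (0.01, "S/cm", 1.0),
            (50.4, "ratio", 50.4),        # BSCR passes through
        ],
    )
    def test_examples(self, value, unit, expected):
        assert to_conductivity(value, unit) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan"), float("inf")])
    def test_rejects_non_positive(self, bad):
        with pytest.raises(CorpusError):
            to_conductivity(bad, "S/m")

    def test_rejects_unknown_unit(self):
        with pytest.raises(CorpusError, match="unknown unit"):
            to_conductivity(1.0, "furlongs")

    @given(st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=50, deadline=None)
    def test_resistivity_round_trip(self, rho):
        """ρ → σ → ρ recovers the input to 1e-12 relative error."""
        sigma = to_conductivity(rho, "ohm.m")
        back = to_conductivity(sigma, "ohm.m")
        assert back == pytest.approx(rho, rel=1e-12)


class TestTemperatureClassification:
    @pytest.mark.parametrize(
        "temp,expected",
        [
            (37.0, TemperatureClass.BODY),
            (20.0, TemperatureClass.ROOM),
            (30.0, TemperatureClass.UNKNOWN),   # between the bands
            (35.0, TemperatureClass.BODY),
            (38.0, TemperatureClass.BODY),
            (18.0, TemperatureClass.ROOM),
            (25.0, TemperatureClass.ROOM),
            (40.0, TemperatureClass.UNKNOWN),   # above body band
            (10.0, TemperatureClass.UNKNOWN),
            (None, TemperatureClass.UNKNOWN),
        ],
    )
    def test_bands(self, temp, expected):
        assert classify_temperature(temp) is expected


class TestAgeClassification:
    @pytest.mark.parametrize(
        "ages,expected",
        [
            ([25, 68], AgeClass.ADULT),
            ([0.33, 16], AgeClass.PAEDIATRIC),
            ([10, 40], AgeClass.BOTH),
            (None, AgeClass.UNKNOWN),
            ([], AgeClass.UNKNOWN),
            ([18], AgeClass.ADULT),   # 18 is the adult boundary, inclusive
        ],
    )
    def test_classes(self, ages, expected):
        assert classify_age(ages) is expected

    def test_label_fallback(self):
        assert classify_age(label="paediatric") is AgeClass.PAEDIATRIC

    def test_negative_age_rejected(self):
        with pytest.raises(CorpusError):
            classify_age([-1.0, 20.0])

    @given(st.lists(st.floats(min_value=0, max_value=100), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariant(self, ages):
        assert classify_age(ages) is classify_age(list(reversed(ages)))


class TestTissueTaxonomy:
    def test_compartments(self):
        assert TissueLabel.from_name("spongiform").compartment is Compartment.SKULL
        assert TissueLabel.from_name("wm_par").compartment is Compartment.BRAIN
        assert TissueLabel.from_name("csf").compartment is Compartment.CSF
        assert TissueLabel.from_name("bscr").is_ratio

    def test_every_subtissue_has_a_compartment(self):
        for sub in Subtissue:
            assert TissueLabel(sub).compartment in Compartment

    def test_bscr_rejects_conductivity_unit(self):
        with pytest.raises(CorpusError, match="dimensionless"):
            make_record("s1", "bscr", 50.0)  # default unit S/m

    def test_unknown_tissue(self):
        with pytest.raises(CorpusError, match="unknown tissue"):
            TissueLabel.from_name("bone_marrow")


class TestFrequencyFilter:
    def test_below_cutoff_retained(self):
        corpus = Corpus(records=[
            make_record(frequency_hz=40.0),
            make_record(frequency_hz=500.0),
        ])
        assert len(apply_frequency_filter(corpus)) == 2

    def test_above_cutoff_removed_missing_retained(self):
        corpus = Corpus(records=[
            make_record(frequency_hz=10_000.0),
            make_record(frequency_hz=None),
            make_record(frequency_hz=1000.0),  # exactly at cutoff: retained
        ])
        assert len(apply_frequency_filter(corpus)) == 2

    def test_empty_corpus(self):
        assert len(apply_frequency_filter(Corpus())) == 0

    def test_idempotent_and_monotone(self):
        corpus = Corpus(records=[
            make_record(frequency_hz=f) for f in (5, 900, 1005, 5000, None)
        ])
        once = apply_frequency_filter(corpus)
        twice = apply_frequency_filter(once)
        assert len(once) <= len(corpus)
        assert [r.sigma for r in twice] == [r.sigma for r in once]

    def test_configurable_cutoff(self):
        corpus = Corpus(records=[make_record(frequency_hz=1005.0)])
        assert len(apply_frequency_filter(corpus, cutoff_hz=1000.0)) == 0
        assert len(apply_frequency_filter(corpus, cutoff_hz=1005.0)) == 1


class TestValidation:
    def test_valid_record_passes(self):
        report = validate_corpus(Corpus(records=[make_record()]))
        assert report.ok and not report.errors

    def test_non_positive_conductivity(self):
        rec = make_record()
        rec.sigma = -0.1
        report = validate_corpus(Corpus(records=[rec]))
        assert not report.ok
        assert any("non-positive conductivity" in e.message for e in report.errors)
        assert report.errors[0].index == 0

    def test_double_dispersion_warns_precedence(self):
        rec = make_record(sd_percent=8.0, method_error=0.05)
        report = validate_corpus(Corpus(records=[rec]))
        assert report.ok
        assert any("sd_percent takes precedence" in w.message for w in report.warnings)

    def test_sanity_band(self):
        rec = make_record(sigma=1.0)
        rec.sigma = 50.0  # tissues must lie in (0, 10] S/m
        report = validate_corpus(Corpus(records=[rec]))
        assert any("outside" in e.message for e in report.errors)

    def test_report_json_shape(self):
        import json

        rec = make_record()
        payload = json.loads(validate_corpus(Corpus(records=[rec])).to_json())
        assert payload["analysable"] is True
        assert payload["errors"] == []


class TestTabularIO:
    def test_round_trip(self, small_corpus, tmp_path):
        path = tmp_path / "corpus.tsv"
        write_corpus(small_corpus, path)
        back = read_corpus(path)
        assert len(back) == len(small_corpus)
        for a, b in zip(small_corpus.records, back.records):
            assert a.study_id == b.study_id
            assert a.tissue == b.tissue
            assert a.sigma == pytest.approx(b.sigma, rel=1e-12)
            assert a.sd_percent == b.sd_percent
            assert a.method == b.method
            assert a.temperature_class == b.temperature_class
            assert a.pathology == b.pathology

    def test_versioned_header(self, small_corpus, tmp_path):
        path = tmp_path / "corpus.tsv"
        write_corpus(small_corpus, path)
        first = path.read_text().splitlines()[0]
        assert first.startswith("#headconduct-corpus")

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("study\tvalue\nx\t1\n")
        with pytest.raises(CorpusError, match="header"):
            read_corpus(path)

    def test_bad_value_identifies_row(self, tmp_path, small_corpus):
        path = tmp_path / "corpus.tsv"
        write_corpus(small_corpus, path)
        lines = path.read_text().splitlines()
        lines[2] = lines[2].replace("\t0.4\t", "\t-0.4\t", 1)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(CorpusError, match=":3"):
            read_corpus(path)
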