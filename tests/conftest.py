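import numpy as np
import pytest

from headconduct import (
    ChecklistItem,
    ConductivityRecord,
    Corpus,
    StudyInfo,
    weight_records,
)


def make_record(study="s1", tissue="gm", sigma=0.5, **kwargs):
    """A fully-specified valid record unless overridden."""
    defaults = dict(
        sd_percent=10.0,
        method="EIT",
        condition="in_vivo",
        frequency_hz=50.0,
        temperature_c=37.0,
        age_mean_years=35.0,
        pathology="healthy",
    )
    defaults.update(kwargs)
    return ConductivityRecord.from_reported(
        study_id=study, tissue=tissue, value=sigma, unit="S/m", **defaults
    )


@pytest.fixture
def small_corpus():
    """Three studies, two tissues, known weights."""
    records = [
        make_record("s1", "gm", 0.40, sd_percent=10.0),
        make_record("s1", "wm", 0.20, sd_percent=20.0),
        make_record("s2", "gm", 0.50, sd_percent=None, method_error=0.05),
        make_record("s3", "gm", 0.60, sd_percent=5.0),
    ]
    studies = {
        "s1": StudyInfo(n_participants=4),
        "s2": StudyInfo(n_participants=6),
        "s3": StudyInfo(n_participants=2),
    }
    return Corpus(records=records, studies=studies)


@pytest.fixture
def small_scores(small_corpus):
    qas = {"s1": 0.9, "s2": 0.8, "s3": 1.0}
    return weight_records(small_corpus, qas)


def scored_checklist(qas, n_items=5):
    return [
        ChecklistItem(item_id=f"item{i}", relevant=True, score=qas)
        for i in range(n_items)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(42)
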