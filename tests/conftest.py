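from datetime import date

import numpy as np
import pytest

from notecast.embed import NoteVector
from notecast.preprocess import TermLexicon
from notecast.timeline import PatientTimeline


@pytest.fixture
def tiny_lexicon():
    return TermLexicon(
        {
            "brother": "FAM",
            "mother": "FAM",
            "son": "FAM",
            "cancer": "CA",
            "lesion": "CA",
            "oncology": "CA",
        }
    )


def make_timeline(
    patient_id="P1",
    note_dates=(),
    recurrence_date=None,
    dim=4,
    seed=0,
    label_source="manual",
):
    """A timeline with deterministic random vectors on the given dates."""
    rng = np.random.default_rng(seed)
    notes = [
        NoteVector(f"{patient_id}-n{i}", patient_id, d, rng.normal(size=dim))
        for i, d in enumerate(note_dates)
    ]
    return PatientTimeline(patient_id, notes, recurrence_date, label_source)


@pytest.fixture
def timeline_factory():
    return make_timeline


@pytest.fixture
def d():
    return date
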