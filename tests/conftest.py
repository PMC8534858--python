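import numpy as np
import pandas as pd
import pytest

from phenotree import (
    EventTable,
    LabelTable,
    build_matrix,
    build_vocabulary,
    golden_fixture,
    split_patients,
)


@pytest.fixture
def toy_events():
    rows = [
        ("p1", "N100.", "2004-07-01", "primary"),
        ("p1", "N100.", None, None),
        ("p2", "N100.", None, "secondary"),
        ("p2", "F440.", None, None),
        ("p3", "F440.", None, None),
    ]
    return EventTable(
        pd.DataFrame(rows, columns=["patient_id", "code", "date", "source"])
    )


@pytest.fixture
def toy_labels():
    return LabelTable({"p1": 1, "p2": 1, "p3": 0, "p4": 0})


@pytest.fixture
def toy_matrix(toy_events, toy_labels):
    vocab = build_vocabulary(toy_events)
    return build_matrix(toy_events, toy_labels, vocab)


@pytest.fixture(scope="session")
def tiny_separable():
    return golden_fixture("tiny_separable")


@pytest.fixture(scope="session")
def tiny_imbalanced():
    return golden_fixture("tiny_imbalanced")


@pytest.fixture(scope="session")
def tiny_imbalanced_matrix(tiny_imbalanced):
    events, labels = tiny_imbalanced
    return build_matrix(events, labels, build_vocabulary(events))


@pytest.fixture(scope="session")
def as_like_matrix():
    events, labels = golden_fixture("as_like")
    return build_matrix(events, labels, build_vocabulary(events))


@pytest.fixture(scope="session")
def as_like_split(as_like_matrix):
    plan = split_patients(as_like_matrix, (0.6, 0.2, 0.2), seed=7)
    return {
        part: as_like_matrix.subset(plan.part(part))
        for part in ("train", "validation", "test")
    }
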