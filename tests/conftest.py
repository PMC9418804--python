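import numpy as np
import pytest

from claimseq.events import (
    ConceptDictionary,
    Event,
    PatientTimeline,
    WindowSpec,
    build_dictionary,
    prepare_sample,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_timelines():
    """Three patients, concept frequencies A:5 B:3 C:2 D:1."""
    day0 = 2_450_000
    return [
        PatientTimeline.from_events(
            "p1",
            [
                Event("A", day0 + 1),
                Event("A", day0 + 10),
                Event("B", day0 + 20),
                Event("C", day0 + 30),
            ],
        ),
        PatientTimeline.from_events(
            "p2",
            [
                Event("A", day0 + 5),
                Event("B", day0 + 5),
                Event("D", day0 + 40),
            ],
        ),
        PatientTimeline.from_events(
            "p3",
            [
                Event("A", day0 + 2),
                Event("A", day0 + 3),
                Event("B", day0 + 4),
                Event("C", day0 + 6),
            ],
        ),
    ]


@pytest.fixture
def toy_dictionary(toy_timelines):
    return build_dictionary(toy_timelines, 4)


@pytest.fixture
def toy_sample(toy_timelines, toy_dictionary):
    return prepare_sample(
        toy_timelines[0],
        toy_dictionary,
        index_day=2_450_100,
        window=WindowSpec(max_len=8),
        label=1,
    )
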