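import numpy as np
import pytest

from emoseg import Dataset, SegmentationRecord, StimulusInfo
from emoseg.synthetic import build_embedding, build_norms, default_lexicon


def make_dataset(pauses_by_participant, duration=30.0, stimulus_id="s1", block="affective", labels=None):
    """Small dataset from {participant: [times]}; optional {participant: [labels]}."""
    records = []
    for p, times in pauses_by_participant.items():
        labs = (labels or {}).get(p, [""] * len(times))
        for t, lab in zip(times, labs):
            records.append(SegmentationRecord(p, stimulus_id, float(t), lab))
    return Dataset(records, [StimulusInfo(stimulus_id, duration, block)])


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def norms(lexicon):
    return build_norms(lexicon)


@pytest.fixture(scope="session")
def embedding(lexicon):
    return build_embedding(lexicon)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
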