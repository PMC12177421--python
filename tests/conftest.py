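import numpy as np
import pytest

from toobert.ehr_data import (
    CodeKind,
    CodeToken,
    Trajectory,
    Visit,
    Vocabulary,
    filter_rare_codes,
)


def make_trajectory(patient_id: str, visits: list[list[str]], los=None) -> Trajectory:
    """Build a trajectory from per-visit code-name lists.

    Codes starting with 'R' become medications, everything else diagnoses.
    """
    out = []
    for i, codes in enumerate(visits, start=1):
        toks = [
            CodeToken(c, CodeKind.MEDICATION if c.startswith("R") else CodeKind.DIAGNOSIS)
            for c in codes
        ]
        out.append(Visit(i, toks, los_days=los[i - 1] if los else None))
    return Trajectory(patient_id, out)


def make_corpus(visit_lists: list[list[list[str]]]) -> list[Trajectory]:
    return [make_trajectory(f"P{i}", v) for i, v in enumerate(visit_lists)]


@pytest.fixture
def toy_corpus() -> list[Trajectory]:
    return make_corpus(
        [
            [["A"], ["B"]],
            [["A"], ["B"]],
            [["B"], ["A"]],
            [["A", "C"], ["B"], ["C"]],
        ]
    )


@pytest.fixture
def toy_vocab(toy_corpus) -> Vocabulary:
    _, vocab = filter_rare_codes(toy_corpus, 1)
    return vocab


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
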