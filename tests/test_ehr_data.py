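"""Data model: normalization, windowing, tokenization, splitting."""

from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toobert.ehr_data import (
    CLS_ID,
    SEP_ID,
    CodeKind,
    Event,
    TokenizedSequence,
    detokenize,
    filter_rare_codes,
    read_csv,
    read_jsonl,
    sliding_window,
    split_corpus,
    tokenize,
    truncate_code,
    window_visits,
    write_jsonl,
)

from conftest import make_corpus, make_trajectory


@pytest.mark.parametrize(
    "code,expected",
    [
        ("I50.12", "I501"),  # dot removed before the 4-character cut
        ("C03", "C03"),
        ("4280", "4280"),
        ("428.0", "4280"),
        ("E11.9x", "E119"),
    ],
)
def test_truncate_code(code, expected):
    assert truncate_code(code) == expected


def test_truncate_code_rejects_empty():
    with pytest.raises(ValueError):
        truncate_code("")


class TestFilterRareCodes:
    def test_threshold_removes_rare_codes(self):
        # counts: A=5, B=2, C=1 over three trajectories
        corpus = make_corpus(
            [
                [["A", "A"], ["A", "B"]],
                [["A", "B"], ["A"]],
                [["C"]],
            ]
        )
        kept, vocab = filter_rare_codes(corpus, min_count=2)
        assert "A" in vocab and "B" in vocab and "C" not in vocab
        assert len(vocab) == 2 + 5  # two codes + special tokens
        assert len(kept) == 2  # third trajectory emptied and dropped

    def test_min_count_one_is_identity(self, toy_corpus):
        kept, vocab = filter_rare_codes(toy_corpus, 1)
        assert sum(t.n_codes() for t in kept) == sum(t.n_codes() for t in toy_corpus)

    def test_empty_result_errors_with_threshold(self):
        corpus = make_corpus([[["X"]]])
        with pytest.raises(ValueError, match="99"):
            filter_rare_codes(corpus, 99)

    def test_visit_reindexing_after_drop(self):
        corpus = make_corpus([[["A"], ["C"], ["A"]], [["A"], ["A"]]])
        kept, _ = filter_rare_codes(corpus, 2)
        assert [v.index for v in kept[0].visits] == [1, 2]


class TestWindowVisits:
    @staticmethod
    def events(days):
        d0 = date(2015, 1, 1)
        return [
            Event(date.fromordinal(d0.toordinal() + d), f"C{i}", CodeKind.DIAGNOSIS)
            for i, d in enumerate(days)
        ]

    def test_greedy_grouping(self):
        traj = window_visits("p", self.events([0, 10, 200]), 183)
        assert [len(v.codes) for v in traj.visits] == [2, 1]

    def test_single_event(self):
        traj = window_visits("p", self.events([0]))
        assert traj.n_visits == 1

    def test_boundary_day_inclusive(self):
        assert window_visits("p", self.events([0, 183]), 183).n_visits == 1
        assert window_visits("p", self.events([0, 184]), 183).n_visits == 2

    def test_unsorted_dates_error(self):
        evs = self.events([5, 0])
        with pytest.raises(ValueError, match="sorted"):
            window_visits("p", evs)

    def test_consecutive_visit_openers_farther_than_window(self):
        rng = np.random.default_rng(3)
        days = np.cumsum(rng.integers(0, 300, size=40)).tolist()
        traj = window_visits("p", self.events(days), 183)
        openers = [v.date for v in traj.visits]
        assert all((b - a).days > 0 for a, b in zip(openers, openers[1:]))
        # one giant window collapses everything into a single visit
        assert window_visits("p", self.events(days), 10**6).n_visits == 1


class TestTokenize:
    def test_structure_and_visit_numbers(self, toy_vocab):
        traj = make_trajectory("p", [["A"], ["B", "C"]])
        seq = tokenize(traj, toy_vocab)
        a, b, c = (toy_vocab.id_of(x) for x in "ABC")
        assert seq.token_ids == [CLS_ID, a, SEP_ID, b, c, SEP_ID]
        assert seq.visit_numbers == [0, 1, 1, 2, 2, 2]

    def test_minimal_trajectory(self, toy_vocab):
        seq = tokenize(make_trajectory("p", [["A"]]), toy_vocab)
        assert len(seq) == 3

    def test_unknown_code_maps_to_unk(self, toy_vocab, caplog):
        seq = tokenize(make_trajectory("p", [["ZZZ"]]), toy_vocab)
        assert seq.token_ids[1] == toy_vocab.id_of("ZZZ") == 4  # UNK id

    @given(
        visits=st.lists(
            st.lists(st.sampled_from("ABC"), min_size=1, max_size=4),
            min_size=1,
            max_size=6,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip_recovers_visit_structure(self, visits):
        corpus = make_corpus([visits])
        _, vocab = filter_rare_codes(corpus, 1)
        seq = tokenize(corpus[0], vocab)
        assert detokenize(seq, vocab) == visits


class TestSlidingWindow:
    def test_short_sequence_identity(self, toy_vocab):
        seq = tokenize(make_trajectory("p", [["A"], ["B"]]), toy_vocab)
        assert sliding_window(seq, 10) == [seq]

    def test_windows_are_visit_aligned_and_cover_all_visits(self, toy_vocab):
        visits = [["A", "B"]] * 6
        seq = tokenize(make_trajectory("p", visits), toy_vocab)
        windows = sliding_window(seq, max_len=10)  # 3 visits per window
        assert len(windows) >= 2
        covered = set()
        for w in windows:
            assert w.token_ids[0] == CLS_ID
            assert w.token_ids[-1] == SEP_ID
            assert len(w) <= 10
            covered.update(n for n in w.visit_numbers if n > 0)
        assert covered == set(range(1, 7))

    def test_original_visit_numbers_preserved(self, toy_vocab):
        seq = tokenize(make_trajectory("p", [["A", "B"]] * 6), toy_vocab)
        tail = sliding_window(seq, max_len=10)[-1]
        assert max(tail.visit_numbers) == 6

    def test_no_window_is_empty(self, toy_vocab):
        # mixed visit sizes once triggered an empty [CLS]-only window
        visits = [["A", "B"], ["A", "B", "C", "A"], ["B", "C", "A"], ["A", "B"],
                  ["A"] * 8, ["B"] * 12]
        seq = tokenize(make_trajectory("p", visits), toy_vocab)
        for w in sliding_window(seq, max_len=17):
            assert sum(1 for t in w.token_ids if t >= 5) > 0

    def test_oversized_visit_tail_truncated(self, toy_vocab, caplog):
        seq = tokenize(make_trajectory("p", [["A"] * 30, ["B"]]), toy_vocab)
        windows = sliding_window(seq, max_len=12)
        assert all(len(w) <= 12 for w in windows)


class TestSplitCorpus:
    def test_sizes_and_partition(self):
        corpus = make_corpus([[["A"]]] * 100)
        a, b, c = split_corpus(corpus, (0.7, 0.2, 0.1), seed=5)
        assert (len(a), len(b), len(c)) == (70, 20, 10)
        ids = [t.patient_id for part in (a, b, c) for t in part]
        assert sorted(ids) == sorted(t.patient_id for t in corpus)

    def test_seed_determinism(self):
        corpus = make_corpus([[["A"]]] * 37)
        r1 = split_corpus(corpus, seed=9)
        r2 = split_corpus(corpus, seed=9)
        for p1, p2 in zip(r1, r2):
            assert [t.patient_id for t in p1] == [t.patient_id for t in p2]

    def test_bad_fractions_error(self):
        with pytest.raises(ValueError):
            split_corpus(make_corpus([[["A"]]]), (0.5, 0.2, 0.1))


def test_jsonl_round_trip(tmp_path, toy_corpus):
    path = tmp_path / "c.jsonl"
    write_jsonl(toy_corpus, path)
    back = read_jsonl(path)
    assert len(back) == len(toy_corpus)
    assert back[0].patient_id == toy_corpus[0].patient_id
    assert [len(v.codes) for v in back[3].visits] == [2, 1, 1]


def test_csv_reader_applies_windowing(tmp_path):
    path = tmp_path / "c.csv"
    path.write_text(
        "patient_id,date,code,kind,los_days\n"
        "p1,2015-01-01,I50,dx,2.0\n"
        "p1,2015-01-05,C03,rx,\n"
        "p1,2016-06-01,E11,dx,1.0\n"
    )
    corpus = read_csv(path)
    assert corpus[0].n_visits == 2
    assert corpus[0].visits[0].los_days == 2.0


def test_vocabulary_save_load_round_trip(tmp_path, toy_vocab):
    path = tmp_path / "vocab.tsv"
    toy_vocab.save(path)
    from toobert.ehr_data import Vocabulary

    back = Vocabulary.load(path)
    assert back.code_to_id == toy_vocab.code_to_id
    assert back.counts == toy_vocab.counts
    assert all(back.kinds[c] == toy_vocab.kinds[c] for c in toy_vocab.code_to_id)
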