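"""MLM masking and order-permutation contracts."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toobert.corruption import (
    IGNORE_ID,
    SwapMethod,
    TrajectoryTooShort,
    make_too_batch,
    mlm_corrupt,
    ordered_sample,
    permute,
    swap_codes,
    swap_visits,
)
from toobert.ehr_data import CLS_ID, MASK_ID, SEP_ID, filter_rare_codes, tokenize
from toobert.swap_stats import SwapWeights

from conftest import make_corpus, make_trajectory


@pytest.fixture
def seq(toy_vocab):
    return tokenize(make_trajectory("p", [["A", "C"], ["B", "A"], ["C"]]), toy_vocab)


class TestMlmCorrupt:
    def test_targets_mark_exactly_the_corrupted_positions(self, seq, toy_vocab, rng):
        s = mlm_corrupt(seq, toy_vocab, 0.5, rng)
        orig = np.asarray(seq.token_ids)
        sup = s.target_ids != IGNORE_ID
        assert np.array_equal(s.target_ids[sup], orig[sup])
        # non-selected positions are untouched
        assert np.array_equal(s.input_ids[~sup], orig[~sup])

    def test_specials_never_corrupted(self, seq, toy_vocab, rng):
        for _ in range(50):
            s = mlm_corrupt(seq, toy_vocab, 0.9, rng)
            orig = np.asarray(seq.token_ids)
            special = orig < 5
            assert np.all(s.target_ids[special] == IGNORE_ID)
            assert np.array_equal(s.input_ids[special], orig[special])

    def test_deterministic_under_seed(self, seq, toy_vocab):
        a = mlm_corrupt(seq, toy_vocab, 0.3, np.random.default_rng(4))
        b = mlm_corrupt(seq, toy_vocab, 0.3, np.random.default_rng(4))
        assert np.array_equal(a.input_ids, b.input_ids)
        assert np.array_equal(a.target_ids, b.target_ids)

    def test_no_maskable_tokens_errors(self, toy_vocab, rng):
        from toobert.ehr_data import TokenizedSequence

        bare = TokenizedSequence([CLS_ID, SEP_ID], [0, 1])
        with pytest.raises(ValueError):
            mlm_corrupt(bare, toy_vocab, 0.15, rng)


class TestSwapCodes:
    def test_single_eligible_pair(self, toy_vocab, rng):
        seq = tokenize(make_trajectory("p", [["A"], ["B"]]), toy_vocab)
        out = swap_codes(seq, 0.0, rng)  # minimum k = 1
        a, b = toy_vocab.id_of("A"), toy_vocab.id_of("B")
        assert list(out.input_ids) == [CLS_ID, b, SEP_ID, a, SEP_ID]
        assert out.y_state == 0 and out.state == "permutated"

    def test_structure_tracks_unchanged(self, seq, rng):
        out = swap_codes(seq, 1.0, rng)
        assert np.array_equal(out.visit_numbers, seq.visit_numbers)
        sep_positions = [i for i, t in enumerate(seq.token_ids) if t == SEP_ID]
        assert all(out.input_ids[i] == SEP_ID for i in sep_positions)

    def test_multiset_preserved(self, seq, rng):
        out = swap_codes(seq, 1.0, rng)
        assert Counter(out.input_ids.tolist()) == Counter(seq.token_ids)

    def test_requires_two_visits(self, toy_vocab, rng):
        seq = tokenize(make_trajectory("p", [["A", "B", "C"]]), toy_vocab)
        with pytest.raises(TrajectoryTooShort):
            swap_codes(seq, 0.5, rng)

    def test_weighted_sampling_prefers_high_ccs_pair(self, toy_vocab, rng):
        seq = tokenize(make_trajectory("p", [["A", "C"], ["B"]]), toy_vocab)
        a, b, c = (toy_vocab.id_of(x) for x in "ABC")
        weights = SwapWeights({(b, a): 5.0}, 0.01, {}, toy_vocab)
        hits = 0
        for _ in range(300):
            out = swap_codes(seq, 0.0, rng, weights)
            if out.input_ids[1] == b:  # A <-> B exchanged
                hits += 1
        assert hits > 250  # 5.0 vs 0.01: near-certain selection


class TestSwapVisits:
    def test_block_exchange_renumbers_slots(self, toy_vocab, rng):
        seq = tokenize(make_trajectory("p", [["A"], ["B", "C"]]), toy_vocab)
        out = swap_visits(seq, 1.0, rng)
        a, b, c = (toy_vocab.id_of(x) for x in "ABC")
        assert list(out.input_ids) == [CLS_ID, b, c, SEP_ID, a, SEP_ID]
        assert list(out.visit_numbers) == [0, 1, 1, 1, 2, 2]

    def test_per_visit_grouping_preserved(self, toy_vocab, rng):
        traj = make_trajectory("p", [["A", "C"], ["B"], ["C", "A", "B"], ["A"]])
        seq = tokenize(traj, toy_vocab)
        out = swap_visits(seq, 1.0, rng)
        from toobert.corruption import _visit_blocks
        from toobert.ehr_data import TokenizedSequence

        before, _ = _visit_blocks(seq)
        after, _ = _visit_blocks(
            TokenizedSequence(list(out.input_ids), list(out.visit_numbers))
        )
        assert sorted(map(tuple, before)) == sorted(map(tuple, after))

    def test_fraction_one_moves_all_four_visits(self, toy_vocab, rng):
        seq = tokenize(make_trajectory("p", [["A"], ["B"], ["C"], ["A", "B"]]), toy_vocab)
        out = swap_visits(seq, 1.0, rng)
        from toobert.corruption import _visit_blocks
        from toobert.ehr_data import TokenizedSequence

        before, _ = _visit_blocks(seq)
        after, _ = _visit_blocks(
            TokenizedSequence(list(out.input_ids), list(out.visit_numbers))
        )
        # k = round(1 * 4 / 2) = 2 disjoint pairs: no block stays in place
        assert all(b != a for b, a in zip(before, after))

    def test_single_visit_errors(self, toy_vocab, rng):
        seq = tokenize(make_trajectory("p", [["A", "B"]]), toy_vocab)
        with pytest.raises(TrajectoryTooShort):
            swap_visits(seq, 0.5, rng)


class TestMakeTooBatch:
    def test_ratio_and_labels(self, toy_vocab, rng):
        seqs = [
            tokenize(t, toy_vocab)
            for t in make_corpus([[["A"], ["B"]]] * 8)
        ]
        batch = make_too_batch(seqs, SwapMethod.RCS, 0.5, rng)
        assert len(batch) == 16
        assert sum(s.y_state for s in batch) == 8

    def test_ordered_samples_identical_to_source(self, seq, rng):
        batch = make_too_batch([seq], SwapMethod.RVS, 1.0, rng)
        ordered = [s for s in batch if s.y_state == 1][0]
        assert list(ordered.input_ids) == seq.token_ids
        assert list(ordered.visit_numbers) == seq.visit_numbers

    def test_short_sequences_contribute_ordered_only(self, toy_vocab, rng):
        seqs = [tokenize(make_trajectory("p", [["A", "B"]]), toy_vocab)]
        batch = make_too_batch(seqs, SwapMethod.RVS, 1.0, rng)
        assert len(batch) == 1 and batch[0].y_state == 1

    def test_conditional_method_requires_weights(self, seq, rng):
        with pytest.raises(ValueError):
            permute(seq, SwapMethod.CCS, 0.5, rng, None)

    @given(frac=st.floats(0.0, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_multiset_invariant_all_methods(self, frac):
        rng = np.random.default_rng(11)
        corpus = make_corpus([[["A", "C"], ["B"], ["C", "B"]]])
        _, vocab = filter_rare_codes(corpus, 1)
        seq = tokenize(corpus[0], vocab)
        for method in (SwapMethod.RCS, SwapMethod.RVS):
            out = permute(seq, method, frac, rng)
            assert Counter(out.input_ids.tolist()) == Counter(seq.token_ids)


def test_hamming_distance_monotone_in_fraction(toy_vocab):
    """More swapping moves more positions, in expectation."""
    traj = make_trajectory("p", [["A", "B", "C"], ["B", "C"], ["A", "C"], ["B", "A"]])
    seq = tokenize(traj, toy_vocab)
    orig = np.asarray(seq.token_ids)
    means = []
    for frac in (0.1, 0.5, 1.0):
        rng = np.random.default_rng(5)
        d = [
            np.sum(swap_codes(seq, frac, rng).input_ids != orig) for _ in range(400)
        ]
        means.append(np.mean(d))
    assert means[0] <= means[1] + 0.2
    assert means[1] <= means[2] + 0.2
    assert means[2] > means[0]
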