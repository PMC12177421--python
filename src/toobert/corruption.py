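"""Input corruption for self-supervised pretraining.

Two families of corruption are produced here:

* **MLM masking** -- each non-special token is independently selected with
  probability ``mask_rate`` (default 15%); a selected token is replaced by
  [MASK] 80% of the time, by a random code 10%, and left unchanged (but
  still supervised) 10%.

* **Order permutation** for the trajectory-order objective -- a controlled
  number of disjoint cross-visit code pairs (RCS/CCS) or visit-block pairs
  (RVS/CVS) are exchanged.  The "R" variants sample pairs uniformly; the
  "C" variants sample proportionally to the conditional swap weights so the
  permutation preferentially destroys observed temporal dependencies.

The swap fraction f maps to k = max(1, round(f * n / 2)) disjoint pairs,
i.e. f is the fraction of code (or visit) positions touched by a swap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .ehr_data import (
    CLS_ID,
    MASK_ID,
    PAD_ID,
    SEP_ID,
    SPECIAL_TOKENS,
    TokenizedSequence,
    Vocabulary,
)
from .swap_stats import SwapWeights, cvs_from_id_blocks

logger = logging.getLogger(__name__)

IGNORE_ID = -100  # sentinel for unsupervised positions in MLM targets

N_SPECIAL = len(SPECIAL_TOKENS)


class SwapMethod(str, Enum):
    RCS = "rcs"  # random code swapping
    CCS = "ccs"  # conditional code swapping
    RVS = "rvs"  # random visit swapping
    CVS = "cvs"  # conditional visit swapping

    @property
    def is_visit_level(self) -> bool:
        return self in (SwapMethod.RVS, SwapMethod.CVS)

    @property
    def is_conditional(self) -> bool:
        return self in (SwapMethod.CCS, SwapMethod.CVS)


@dataclass
class MlmSample:
    input_ids: np.ndarray
    target_ids: np.ndarray  # original ids at corrupted positions, else IGNORE_ID
    visit_numbers: np.ndarray


@dataclass
class TooSample:
    input_ids: np.ndarray
    visit_numbers: np.ndarray
    state: str  # "ordered" | "permutated"
    y_state: int  # ordered = 1, permutated = 0
    swap_fraction: float
    method: SwapMethod


class TrajectoryTooShort(ValueError):
    """Raised when a sequence has no eligible cross-visit pair to swap."""


def _code_positions(seq: TokenizedSequence) -> np.ndarray:
    ids = np.asarray(seq.token_ids)
    return np.nonzero(ids >= N_SPECIAL)[0]


def mlm_corrupt(
    seq: TokenizedSequence,
    vocab: Vocabulary,
    mask_rate: float = 0.15,
    rng: np.random.Generator | None = None,
    replace_probs: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> MlmSample:
    """Mask-corrupt a sequence for the masked-language-model objective."""
    rng = rng or np.random.default_rng()
    ids = np.asarray(seq.token_ids).copy()
    maskable = _code_positions(seq)
    if maskable.size == 0:
        raise ValueError("sequence has no maskable (non-special) tokens")
    targets = np.full(ids.shape, IGNORE_ID, dtype=np.int64)
    selected = maskable[rng.random(maskable.size) < mask_rate]
    real_ids = np.asarray(vocab.real_code_ids())
    for pos in selected:
        targets[pos] = ids[pos]
        u = rng.random()
        if u < replace_probs[0]:
            ids[pos] = MASK_ID
        elif u < replace_probs[0] + replace_probs[1]:
            ids[pos] = int(rng.choice(real_ids))
        # else: unchanged, still supervised
    return MlmSample(ids, targets, np.asarray(seq.visit_numbers).copy())


def _select_disjoint_pairs(
    pairs: np.ndarray,
    weights: np.ndarray | None,
    k: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Pick up to k pairs with no shared endpoint.

    Uniform when ``weights`` is None, else proportional to ``weights`` with
    sequential renormalization over pairs whose endpoints are still free.
    """
    chosen: list[tuple[int, int]] = []
    used: set[int] = set()
    alive = np.ones(len(pairs), dtype=bool)
    w = None if weights is None else weights.astype(float).copy()
    while len(chosen) < k and alive.any():
        idx_alive = np.nonzero(alive)[0]
        if w is None:
            pick = int(rng.choice(idx_alive))
        else:
            p = w[idx_alive]
            pick = int(rng.choice(idx_alive, p=p / p.sum()))
        a, b = int(pairs[pick, 0]), int(pairs[pick, 1])
        chosen.append((a, b))
        used.update((a, b))
        alive &= ~np.isin(pairs[:, 0], list(used))
        alive &= ~np.isin(pairs[:, 1], list(used))
    return chosen


def swap_codes(
    seq: TokenizedSequence,
    fraction: float,
    rng: np.random.Generator,
    weights: SwapWeights | None = None,
) -> TooSample:
    """Exchange disjoint cross-visit code pairs (RCS uniform / CCS weighted).

    Only token values move; [CLS]/[SEP] positions and the visit-number track
    are untouched, so the visit structure of the sequence is preserved.
    """
    ids = np.asarray(seq.token_ids).copy()
    nums = np.asarray(seq.visit_numbers)
    codes = _code_positions(seq)
    if codes.size < 2 or np.unique(nums[codes]).size < 2:
        raise TrajectoryTooShort("need >= 2 code tokens in >= 2 distinct visits")

    # eligible ordered pairs: (later occurrence, strictly earlier occurrence)
    later = nums[codes][:, None] > nums[codes][None, :]
    li, ei = np.nonzero(later)
    pairs = np.stack([codes[li], codes[ei]], axis=1)
    k = max(1, round(fraction * codes.size / 2))

    pair_w = None
    if weights is not None:
        pair_w = np.array(
            [weights.weight(int(ids[a]), int(ids[b])) for a, b in pairs]
        )
    for a, b in _select_disjoint_pairs(pairs, pair_w, k, rng):
        ids[a], ids[b] = ids[b], ids[a]
    method = SwapMethod.CCS if weights is not None else SwapMethod.RCS
    return TooSample(ids, nums.copy(), "permutated", 0, fraction, method)


def _visit_blocks(seq: TokenizedSequence) -> tuple[list[list[int]], list[int]]:
    """Per-visit code-id lists (SEP excluded) and slot visit numbers."""
    blocks: list[list[int]] = []
    slot_nums: list[int] = []
    cur: list[int] = []
    for tid, num in zip(seq.token_ids[1:], seq.visit_numbers[1:]):
        if tid == SEP_ID:
            blocks.append(cur)
            slot_nums.append(int(num))
            cur = []
        elif tid != PAD_ID:
            cur.append(int(tid))
    return blocks, slot_nums


def _assemble(
    blocks: list[list[int]], slot_nums: list[int], patient_id: str
) -> TokenizedSequence:
    ids = [CLS_ID]
    nums = [0]
    for block, num in zip(blocks, slot_nums):
        ids.extend(block)
        ids.append(SEP_ID)
        nums.extend([num] * (len(block) + 1))
    return TokenizedSequence(ids, nums, patient_id)


def swap_visits(
    seq: TokenizedSequence,
    fraction: float,
    rng: np.random.Generator,
    weights: SwapWeights | None = None,
) -> TooSample:
    """Exchange whole visit blocks between slots (RVS uniform / CVS weighted).

    Contents move, slots do not: the visit-number track is re-derived so each
    position keeps its slot's number even when block lengths differ.
    """
    blocks, slot_nums = _visit_blocks(seq)
    n_visits = len(blocks)
    if n_visits < 2:
        raise TrajectoryTooShort("need >= 2 visits to swap")
    k = max(1, round(fraction * n_visits / 2))

    xi, yi = np.triu_indices(n_visits, k=1)
    pairs = np.stack([xi, yi], axis=1)
    pair_w = None
    if weights is not None:
        pair_w = np.array(
            [cvs_from_id_blocks(weights, blocks[x], blocks[y]) for x, y in pairs]
        )
        if pair_w.sum() == 0:
            pair_w = None  # no in-vocabulary evidence anywhere; fall back uniform
    for x, y in _select_disjoint_pairs(pairs, pair_w, k, rng):
        blocks[x], blocks[y] = blocks[y], blocks[x]
    out = _assemble(blocks, slot_nums, seq.patient_id)
    method = SwapMethod.CVS if weights is not None else SwapMethod.RVS
    return TooSample(
        np.asarray(out.token_ids),
        np.asarray(out.visit_numbers),
        "permutated",
        0,
        fraction,
        method,
    )


def permute(
    seq: TokenizedSequence,
    method: SwapMethod,
    fraction: float,
    rng: np.random.Generator,
    weights: SwapWeights | None = None,
) -> TooSample:
    """Dispatch to the configured swap strategy."""
    if method.is_conditional and weights is None:
        raise ValueError(f"{method.value} requires swap weights")
    w = weights if method.is_conditional else None
    if method.is_visit_level:
        return swap_visits(seq, fraction, rng, w)
    return swap_codes(seq, fraction, rng, w)


def ordered_sample(seq: TokenizedSequence, method: SwapMethod, fraction: float) -> TooSample:
    return TooSample(
        np.asarray(seq.token_ids),
        np.asarray(seq.visit_numbers),
        "ordered",
        1,
        fraction,
        method,
    )


def make_too_batch(
    seqs: Sequence[TokenizedSequence],
    method: SwapMethod,
    fraction: float,
    rng: np.random.Generator,
    weights: SwapWeights | None = None,
    pos_neg_ratio: tuple[int, int] = (1, 1),
) -> list[TooSample]:
    """Balanced ordered/permuted samples from a batch of source sequences.

    Each source contributes an ordered copy (label 1) and a permuted copy
    (label 0) per the ratio; sources too short to permute contribute
    ordered-only and are logged.  The result is shuffled.
    """
    if not seqs:
        raise ValueError("empty batch")
    n_pos, n_neg = pos_neg_ratio
    out: list[TooSample] = []
    for seq in seqs:
        for _ in range(n_pos):
            out.append(ordered_sample(seq, method, fraction))
        for _ in range(n_neg):
            try:
                out.append(permute(seq, method, fraction, rng, weights))
            except TrajectoryTooShort:
                logger.info(
                    "patient %s too short for %s; ordered-only",
                    seq.patient_id,
                    method.value,
                )
    rng.shuffle(out)
    return out
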