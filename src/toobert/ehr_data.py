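"""Canonical data model for coded patient trajectories.

A trajectory is one patient's ordered sequence of visits; each visit is a
multiset of diagnosis (ICD-style) and medication (ATC-style) codes, with
optional length-of-stay and calendar date.  This module covers reading and
writing trajectory corpora (JSON-Lines and flat CSV), code normalization,
time-window visit grouping, rare-code filtering, special-token vocabulary
construction, flattening to model-ready token sequences, visit-aligned
sliding windows, and patient-level corpus splitting.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from datetime import date as _date
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# reserved vocabulary slots, fixed across save/load
PAD, CLS, SEP, MASK, UNK = "[PAD]", "[CLS]", "[SEP]", "[MASK]", "[UNK]"
SPECIAL_TOKENS = (PAD, CLS, SEP, MASK, UNK)
PAD_ID, CLS_ID, SEP_ID, MASK_ID, UNK_ID = range(5)


class CodeKind(str, Enum):
    DIAGNOSIS = "dx"
    MEDICATION = "rx"
    SPECIAL = "special"


@dataclass(frozen=True)
class CodeToken:
    """A single medical code with its coding-system kind."""

    code: str
    kind: CodeKind

    def __post_init__(self):
        if self.kind != CodeKind.SPECIAL:
            if not self.code or any(c.isspace() for c in self.code):
                raise ValueError(f"invalid code {self.code!r}")
        elif self.code not in SPECIAL_TOKENS:
            raise ValueError(f"unknown special token {self.code!r}")


@dataclass
class Visit:
    """One visit: 1-based order index plus the codes recorded at it."""

    index: int
    codes: list[CodeToken]
    los_days: float | None = None
    date: _date | None = None

    def __post_init__(self):
        if self.index < 1:
            raise ValueError("visit index must be >= 1")
        if self.los_days is not None and self.los_days < 0:
            raise ValueError("los_days must be non-negative")


@dataclass
class Trajectory:
    """One patient's ordered visit sequence."""

    patient_id: str
    visits: list[Visit]

    def __post_init__(self):
        if not self.visits:
            raise ValueError("trajectory must contain at least one visit")
        for i, v in enumerate(self.visits, start=1):
            if v.index != i:
                raise ValueError("visit indices must run 1..O")

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    def n_codes(self) -> int:
        return sum(len(v.codes) for v in self.visits)


@dataclass
class Vocabulary:
    """Bijection between retained code strings and integer ids.

    Ids 0..4 are reserved for [PAD], [CLS], [SEP], [MASK], [UNK] in that
    order; real codes follow in descending corpus frequency.
    """

    code_to_id: dict[str, int] = field(default_factory=dict)
    id_to_code: dict[int, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    kinds: dict[str, CodeKind] = field(default_factory=dict)

    def __post_init__(self):
        for sid, tok in enumerate(SPECIAL_TOKENS):
            if tok not in self.code_to_id:
                self.code_to_id[tok] = sid
                self.id_to_code[sid] = tok
                self.kinds[tok] = CodeKind.SPECIAL

    @classmethod
    def build(cls, counts: dict[str, int], kinds: dict[str, CodeKind]) -> "Vocabulary":
        vocab = cls()
        # descending frequency, code string as tie-break, for stable ids
        for code in sorted(counts, key=lambda c: (-counts[c], c)):
            i = len(vocab.code_to_id)
            vocab.code_to_id[code] = i
            vocab.id_to_code[i] = code
        vocab.counts = dict(counts)
        vocab.kinds.update(kinds)
        return vocab

    def __len__(self) -> int:
        return len(self.code_to_id)

    def __contains__(self, code: str) -> bool:
        return code in self.code_to_id

    def id_of(self, code: str) -> int:
        return self.code_to_id.get(code, UNK_ID)

    def kind_of_id(self, i: int) -> CodeKind:
        return self.kinds[self.id_to_code[i]]

    def real_code_ids(self) -> list[int]:
        return [i for i in self.id_to_code if i >= len(SPECIAL_TOKENS)]

    def top_codes(self, k: int) -> list[str]:
        return sorted(self.counts, key=lambda c: (-self.counts[c], c))[:k]

    # -- persistence: two-column text table with a special-token header ----
    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# special\t" + ",".join(f"{t}:{self.code_to_id[t]}" for t in SPECIAL_TOKENS) + "\n")
            for i in sorted(self.id_to_code):
                code = self.id_to_code[i]
                if code in SPECIAL_TOKENS:
                    continue
                kind = self.kinds.get(code, CodeKind.DIAGNOSIS).value
                fh.write(f"{i}\t{code}\t{kind}\t{self.counts.get(code, 0)}\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        vocab = cls()
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# special"):
                raise ValueError("vocabulary file missing special-token header")
            for line in fh:
                i, code, kind, count = line.rstrip("\n").split("\t")
                vocab.code_to_id[code] = int(i)
                vocab.id_to_code[int(i)] = code
                vocab.kinds[code] = CodeKind(kind)
                vocab.counts[code] = int(count)
        return vocab


@dataclass
class TokenizedSequence:
    """Flattened trajectory: token ids plus a parallel visit-number track.

    Starts with [CLS] (visit number 0); each visit's codes and its trailing
    [SEP] carry that visit's 1-based number.
    """

    token_ids: list[int]
    visit_numbers: list[int]
    patient_id: str = ""

    def __post_init__(self):
        if len(self.token_ids) != len(self.visit_numbers):
            raise ValueError("token and visit-number tracks differ in length")
        if self.token_ids and self.token_ids[0] != CLS_ID:
            raise ValueError("sequence must start with CLS")

    def __len__(self) -> int:
        return len(self.token_ids)

    @property
    def n_visits(self) -> int:
        return max(self.visit_numbers) if self.visit_numbers else 0


# ---------------------------------------------------------------------------
# operations


def truncate_code(code: str, kind: CodeKind = CodeKind.DIAGNOSIS) -> str:
    """Normalize an ICD/ATC code: strip dot separators, keep 4 characters.

    Hierarchical code systems put the clinically meaningful prefix first;
    the leading 4 characters (after removing the dot) identify the category.
    """
    if not code:
        raise ValueError("empty code")
    return code.replace(".", "")[:4]


def filter_rare_codes(
    corpus: Sequence[Trajectory], min_count: int
) -> tuple[list[Trajectory], Vocabulary]:
    """Drop codes seen fewer than `min_count` times; build the vocabulary.

    Visits emptied by the filter are dropped (remaining visits re-indexed);
    trajectories emptied entirely are dropped.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: dict[str, int] = {}
    kinds: dict[str, CodeKind] = {}
    for traj in corpus:
        for visit in traj.visits:
            for tok in visit.codes:
                counts[tok.code] = counts.get(tok.code, 0) + 1
                kinds[tok.code] = tok.kind
    keep = {c for c, n in counts.items() if n >= min_count}
    out: list[Trajectory] = []
    for traj in corpus:
        visits = []
        for visit in traj.visits:
            codes = [t for t in visit.codes if t.code in keep]
            if codes:
                visits.append(
                    Visit(len(visits) + 1, codes, visit.los_days, visit.date)
                )
        if visits:
            out.append(Trajectory(traj.patient_id, visits))
    if not out:
        raise ValueError(
            f"corpus empty after rare-code filtering at min_count={min_count}"
        )
    vocab = Vocabulary.build(
        {c: counts[c] for c in keep}, {c: kinds[c] for c in keep}
    )
    return out, vocab


@dataclass(frozen=True)
class Event:
    """A single date-stamped coded event, before visit grouping."""

    date: _date
    code: str
    kind: CodeKind
    los_days: float | None = None


def window_visits(
    patient_id: str, events: Sequence[Event], window_days: int = 183
) -> Trajectory:
    """Group a date-sorted event stream into visits by a rolling time window.

    Greedy left-to-right: a visit opens at its first event; any event at most
    `window_days` after that opening date (boundary inclusive) joins it, a
    later event opens the next visit.
    """
    if not events:
        raise ValueError("no events")
    for a, b in zip(events, events[1:]):
        if b.date < a.date:
            raise ValueError("events must be sorted by date")
    visits: list[Visit] = []
    current: list[Event] = []
    anchor: _date | None = None
    for ev in events:
        if anchor is None or (ev.date - anchor).days > window_days:
            if current:
                visits.append(_events_to_visit(len(visits) + 1, current))
            current, anchor = [], ev.date
        current.append(ev)
    visits.append(_events_to_visit(len(visits) + 1, current))
    return Trajectory(patient_id, visits)


def _events_to_visit(index: int, events: list[Event]) -> Visit:
    codes = [CodeToken(e.code, e.kind) for e in events]
    los = max((e.los_days for e in events if e.los_days is not None), default=None)
    return Visit(index, codes, los_days=los, date=events[0].date)


def tokenize(
    trajectory: Trajectory, vocab: Vocabulary, max_len: int | None = None
) -> TokenizedSequence:
    """Flatten to [CLS] v1 [SEP] v2 [SEP] ... with the visit-number track.

    Unknown codes map to [UNK] with a warning.  Truncation of long sequences
    is the job of `sliding_window`; `max_len` here only bounds a hard error.
    """
    ids = [CLS_ID]
    nums = [0]
    for visit in trajectory.visits:
        for tok in visit.codes:
            i = vocab.id_of(tok.code)
            if i == UNK_ID and tok.code != UNK:
                logger.warning(
                    "unknown code %r (patient %s) mapped to [UNK]",
                    tok.code,
                    trajectory.patient_id,
                )
            ids.append(i)
            nums.append(visit.index)
        ids.append(SEP_ID)
        nums.append(visit.index)
    return TokenizedSequence(ids, nums, trajectory.patient_id)


def detokenize(seq: TokenizedSequence, vocab: Vocabulary) -> list[list[str]]:
    """Recover the per-visit code lists from a tokenized sequence."""
    visits: list[list[str]] = []
    current: list[str] = []
    for tid in seq.token_ids[1:]:  # skip CLS
        if tid == SEP_ID:
            visits.append(current)
            current = []
        elif tid != PAD_ID:
            current.append(vocab.id_to_code[tid])
    return visits


def sliding_window(
    seq: TokenizedSequence, max_len: int, stride_visits: int | None = None
) -> list[TokenizedSequence]:
    """Cut a long sequence into visit-aligned windows of at most `max_len`.

    Windows never split a visit; each is re-prefixed with [CLS] and keeps
    the original visit numbers of its visits (a mid-history window stays
    recognizable as mid-history).  The stride defaults to half the window
    (in visits) and the last window always covers the trajectory tail.  A
    single visit longer than max_len - 2 is tail-truncated with a warning.
    """
    if max_len < 3:
        raise ValueError("max_len must be >= 3")
    if len(seq) <= max_len:
        return [seq]

    # split into per-visit blocks of (ids, number) excluding CLS
    blocks: list[list[int]] = []
    block_nums: list[int] = []
    cur: list[int] = []
    for tid, num in zip(seq.token_ids[1:], seq.visit_numbers[1:]):
        cur.append(tid)
        if tid == SEP_ID:
            blocks.append(cur)
            block_nums.append(num)
            cur = []
    n_visits = len(blocks)

    # oversized single visits are tail-truncated (keep the trailing SEP)
    budget = max_len - 1
    for b, block in enumerate(blocks):
        if len(block) > budget:
            logger.warning("visit %d longer than window; tail-truncated", b + 1)
            blocks[b] = block[: budget - 1] + [SEP_ID]

    def visits_fitting(start: int) -> int:
        used, count = 0, 0
        for block in blocks[start:]:
            if used + len(block) > budget:
                break
            used += len(block)
            count += 1
        return max(count, 1)

    if stride_visits is None:
        stride_visits = max(1, visits_fitting(0) // 2)

    windows: list[TokenizedSequence] = []
    starts: list[int] = []
    s = 0
    while s < n_visits:
        starts.append(s)
        fits = visits_fitting(s)
        if s + fits >= n_visits:
            break
        # never advance past the current window's coverage (no visit skipped)
        s += min(stride_visits, fits)

    for s in starts:
        k = visits_fitting(s)
        ids = [CLS_ID]
        nums = [0]
        for block, num in zip(blocks[s : s + k], block_nums[s : s + k]):
            ids.extend(block)
            nums.extend([num] * len(block))
        windows.append(TokenizedSequence(ids, nums, seq.patient_id))
    return windows


def split_corpus(
    corpus: Sequence[Trajectory],
    fractions: tuple[float, float, float] = (0.70, 0.20, 0.10),
    seed: int = 0,
) -> tuple[list[Trajectory], list[Trajectory], list[Trajectory]]:
    """Patient-level random partition into (pretrain, finetune, test)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))
    n = len(corpus)
    # largest-remainder apportionment so sizes sum exactly to n
    raw = [f * n for f in fractions]
    sizes = [math.floor(x) for x in raw]
    rema = sorted(range(len(raw)), key=lambda i: raw[i] - sizes[i], reverse=True)
    for i in rema[: n - sum(sizes)]:
        sizes[i] += 1
    out: list[list[Trajectory]] = []
    pos = 0
    for sz in sizes:
        out.append([corpus[i] for i in order[pos : pos + sz]])
        pos += sz
    return out[0], out[1], out[2]


# ---------------------------------------------------------------------------
# corpus I/O


def trajectory_to_dict(traj: Trajectory) -> dict:
    return {
        "patient_id": traj.patient_id,
        "visits": [
            {
                "index": v.index,
                "date": v.date.isoformat() if v.date else None,
                "los_days": v.los_days,
                "codes": [{"code": t.code, "kind": t.kind.value} for t in v.codes],
            }
            for v in traj.visits
        ],
    }


def trajectory_from_dict(d: dict) -> Trajectory:
    visits = [
        Visit(
            v["index"],
            [CodeToken(c["code"], CodeKind(c["kind"])) for c in v["codes"]],
            v.get("los_days"),
            _date.fromisoformat(v["date"]) if v.get("date") else None,
        )
        for v in d["visits"]
    ]
    return Trajectory(d["patient_id"], visits)


def write_jsonl(corpus: Iterable[Trajectory], path: str | Path) -> None:
    with open(path, "w") as fh:
        for traj in corpus:
            fh.write(json.dumps(trajectory_to_dict(traj)) + "\n")


def read_jsonl(path: str | Path) -> list[Trajectory]:
    with open(path) as fh:
        return [trajectory_from_dict(json.loads(line)) for line in fh if line.strip()]


def read_csv(path: str | Path, window_days: int = 183) -> list[Trajectory]:
    """Read a flat event CSV (patient_id, date, code, kind, los_days).

    Events are grouped into visits with `window_visits`.
    """
    import pandas as pd

    frame = pd.read_csv(path, dtype={"patient_id": str, "code": str, "kind": str})
    if "los_days" not in frame.columns:
        frame["los_days"] = float("nan")
    corpus = []
    for pid, group in frame.groupby("patient_id", sort=True):
        events = [
            Event(
                _date.fromisoformat(str(row.date)[:10]),
                row.code,
                CodeKind(row.kind),
                None if pd.isna(row.los_days) else float(row.los_days),
            )
            for row in group.itertuples()
        ]
        events.sort(key=lambda e: e.date)
        corpus.append(window_visits(pid, events, window_days))
    return corpus
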