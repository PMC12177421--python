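"""Labeled downstream cohorts: disease-onset and prolonged-stay labels.

Two labeling schemes over trajectory corpora:

* **Code-onset** (heart failure, Alzheimer disease): a patient with any
  target code is a positive whose history is truncated strictly before the
  first visit containing a target code; patients without the code are
  negatives with their full history.  Medication codes tied to treatment of
  the target condition can be stripped from histories to prevent label
  leakage through prescriptions.

* **Prolonged length of stay**: the index visit is the last visit; the
  label marks a stay strictly longer than the day threshold; the history is
  everything before the index visit.

The default target-code lists below are standard prefix reconstructions
(HF: ICD-9 428* / ICD-10 I50*; AD: G30* / 331*), configurable per run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ehr_data import CodeKind, Trajectory, Visit

logger = logging.getLogger(__name__)

# prefix lists applied after 4-character code normalization
HF_TARGET_PREFIXES = ("I50", "428")
AD_TARGET_PREFIXES = ("G30", "3310")
# loop diuretics, beta blockers, RAS agents: common HF-treatment classes
HF_TREATMENT_RX_PREFIXES = ("C03", "C07", "C09")


@dataclass
class CohortExample:
    patient_id: str
    history: Trajectory
    label: int
    task: str


@dataclass
class CohortSummary:
    task: str
    n: int
    n_positive: int
    mean_visits_positive: float
    mean_visits_negative: float

    @property
    def prevalence(self) -> float:
        return self.n_positive / self.n if self.n else float("nan")


def _matches(code: str, prefixes: Sequence[str]) -> bool:
    return any(code.startswith(p) for p in prefixes)


def _strip_codes(traj: Trajectory, rx_prefixes: Sequence[str]) -> Trajectory | None:
    if not rx_prefixes:
        return traj
    visits = []
    for v in traj.visits:
        codes = [
            t
            for t in v.codes
            if not (t.kind == CodeKind.MEDICATION and _matches(t.code, rx_prefixes))
        ]
        if codes:
            visits.append(Visit(len(visits) + 1, codes, v.los_days, v.date))
    return Trajectory(traj.patient_id, visits) if visits else None


def summarize(examples: Sequence[CohortExample], task: str) -> CohortSummary:
    pos = [e.history.n_visits for e in examples if e.label == 1]
    neg = [e.history.n_visits for e in examples if e.label == 0]
    return CohortSummary(
        task,
        len(examples),
        len(pos),
        float(np.mean(pos)) if pos else float("nan"),
        float(np.mean(neg)) if neg else float("nan"),
    )


def build_code_onset_cohort(
    corpus: Sequence[Trajectory],
    target_codes: Sequence[str],
    excluded_rx: Sequence[str] = (),
    min_visits: int = 3,
    task: str = "HF",
) -> tuple[list[CohortExample], CohortSummary]:
    """Onset-prediction cohort with history truncation at first target visit.

    Emits per-class mean visit counts so trajectory-length bias between
    classes can be checked (and, if needed, equalized with
    `equalize_mean_visits`).
    """
    if not target_codes:
        raise ValueError("target code set must be non-empty")
    examples: list[CohortExample] = []
    for traj in corpus:
        onset = None
        for v in traj.visits:
            if any(_matches(t.code, target_codes) for t in v.codes):
                onset = v.index
                break
        if onset is not None:
            history_visits = traj.visits[: onset - 1]
            label = 1
        else:
            history_visits = traj.visits
            label = 0
        if len(history_visits) < max(min_visits, 1):
            continue
        hist = Trajectory(
            traj.patient_id,
            [
                Visit(i, v.codes, v.los_days, v.date)
                for i, v in enumerate(history_visits, start=1)
            ],
        )
        hist = _strip_codes(hist, excluded_rx)
        if hist is None or hist.n_visits < max(min_visits, 1):
            continue
        examples.append(CohortExample(traj.patient_id, hist, label, task))
    summary = summarize(examples, task)
    if summary.n_positive == 0:
        logger.warning("cohort %s has zero positive cases", task)
    # leak check: no target code may survive in any positive history
    for e in examples:
        if e.label == 1:
            for v in e.history.visits:
                assert not any(_matches(t.code, target_codes) for t in v.codes)
    return examples, summary


def build_pls_cohort(
    corpus: Sequence[Trajectory],
    threshold_days: float = 5.0,
    min_visits: int = 3,
) -> tuple[list[CohortExample], CohortSummary]:
    """Prolonged-stay cohort: label = last visit's stay strictly > threshold."""
    examples: list[CohortExample] = []
    for traj in corpus:
        if traj.n_visits < min_visits:
            continue
        index_visit = traj.visits[-1]
        if index_visit.los_days is None:
            logger.info("patient %s missing stay length at index visit; skipped", traj.patient_id)
            continue
        label = int(index_visit.los_days > threshold_days)
        hist = Trajectory(
            traj.patient_id,
            [
                Visit(i, v.codes, v.los_days, v.date)
                for i, v in enumerate(traj.visits[:-1], start=1)
            ],
        )
        examples.append(CohortExample(traj.patient_id, hist, label, "PLS"))
    return examples, summarize(examples, "PLS")


def subsample_finetune(
    cohort: Sequence[CohortExample], fraction: float, seed: int
) -> list[CohortExample]:
    """Label-stratified random subset, deterministic under the seed."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return list(cohort)
    rng = np.random.default_rng(seed)
    out: list[CohortExample] = []
    for label in (0, 1):
        group = [e for e in cohort if e.label == label]
        k = round(fraction * len(group))
        if group and k == 0:
            raise ValueError(f"subsampling at {fraction} loses label {label}")
        idx = rng.choice(len(group), size=k, replace=False)
        out.extend(group[i] for i in sorted(idx))
    if len({e.label for e in out}) < 2:
        raise ValueError("subsample lost a class")
    return out


def equalize_mean_visits(
    examples: Sequence[CohortExample], tolerance: float = 0.05, max_drop: float = 0.25
) -> list[CohortExample]:
    """Optional trimming to equalize mean history length between classes.

    Greedily drops the most extreme-length examples from the longer-mean
    class until the class means agree within `tolerance` (relative) or the
    drop budget is exhausted.
    """
    pool = list(examples)
    n_min = int(len(pool) * (1 - max_drop))
    while len(pool) > n_min:
        pos = [e for e in pool if e.label == 1]
        neg = [e for e in pool if e.label == 0]
        if not pos or not neg:
            break
        mp = np.mean([e.history.n_visits for e in pos])
        mn = np.mean([e.history.n_visits for e in neg])
        if abs(mp - mn) <= tolerance * max(mp, mn):
            break
        longer = pos if mp > mn else neg
        drop = max(longer, key=lambda e: e.history.n_visits)
        pool.remove(drop)
    return pool
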