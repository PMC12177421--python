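"""Synthetic trajectory corpora with known, controllable structure.

The generator emulates the statistical features of coded inpatient/cohort
EHR data that matter to order-aware pretraining, without any clinical
semantics:

* **long-tail code frequencies** -- a Zipf law over a diagnosis+medication
  vocabulary;
* **planted directed transitions** -- ordered code pairs (a -> b) whose
  occurrence of ``a`` multiplies the *odds* of ``b`` in every later visit
  by a lift > 1 (the "kidney disease follows diabetes" pattern);
* **progression** -- the expected number of codes per visit grows with the
  visit index, mirroring accumulation of problems over a patient history;
* **chronic-code persistence** -- a code already present in the history has
  its re-inclusion odds multiplied by a persistence factor, so chronic
  conditions recur visit after visit the way they do in real records;
* **indication structure** -- every medication code is tied to an
  indication diagnosis of similar frequency; the medication is rare until
  its indication has appeared and common afterwards, reproducing the
  prescriptions-follow-diagnoses asymmetry of real records;
* **care-phase typing** -- each code prefers a phase of the patient
  history (intake/acute codes early, chronic follow-up codes late), so
  visit content is strongly index-typed, which is what makes true visit
  order recognizable in real coded records;
* **two visit-count regimes** -- "short" (mean ~2.5 visits) and "long"
  (mean ~18 visits), the contrast between acute inpatient records and a
  decades-long cohort;
* **order-dependent outcomes** -- a target code whose onset risk is
  logistic in the presence *and the order* of trigger pairs, so an
  order-aware model has known headroom over any bag-of-codes model.

Codes are sampled per visit by independent Bernoulli inclusion with
probability ``sigma(logit(target_count * p_i) + log lift_i)``; working in
odds space makes the planted lift exactly recoverable as an odds ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np

from .ehr_data import CodeKind, CodeToken, Trajectory, Visit

logger = logging.getLogger(__name__)

TARGET_CODE = "TGT"  # synthetic target-disease code injected at onset


@dataclass
class SyntheticSpec:
    """Full description of a synthetic corpus; the seed fixes it bit-exactly."""

    n_patients: int = 1000
    # visit count ~ 1 + Poisson(mean_visits - 1)
    mean_visits: float = 2.5
    # expected codes in visit j ~ codes_base + codes_growth * (j - 1)
    codes_base: float = 5.0
    codes_growth: float = 0.5
    n_dx: int = 60
    n_rx: int = 20
    zipf_exponent: float = 1.1
    n_planted: int = 20
    lift: float = 8.0
    # chronicity: odds multiplier for re-including a code already in history
    persistence: float = 6.0
    # prescriptions follow diagnoses: each medication has an indication
    # diagnosis; its inclusion odds are damped until the indication has
    # appeared (earlier in the history or in the current visit) and lifted
    # afterwards
    rx_indication_lift: float = 12.0
    rx_unindicated_damp: float = 0.04
    # care-phase typing: code i prefers phase phi_i in [0,1]; its inclusion
    # log-odds at visit j gain -kappa * (pos_j - phi_i)^2 where pos_j is the
    # relative position (j-1)/(O-1) within the trajectory.  Intake/acute
    # codes cluster early, chronic follow-up codes late; adjacent visits in
    # long trajectories differ only slightly in phase, so local order cues
    # weaken as trajectories grow, as observed in real cohort data.
    phase_concentration: float = 12.0
    # lognormal length-of-stay (days)
    los_mu: float = 1.1
    los_sigma: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.lift < 1.0:
            raise ValueError("planted lifts must be >= 1")
        if self.codes_base < 1 or self.n_patients < 1:
            raise ValueError("infeasible spec")
        max_codes = self.codes_base + self.codes_growth * 40
        if max_codes > self.n_dx + self.n_rx:
            raise ValueError("codes per visit exceed vocabulary size")


@dataclass
class TaskRule:
    """Logistic onset rule over trigger pairs.

    logit(p) = beta0 + beta_presence * (#pairs with both codes present)
                     + beta_order * (#pairs whose onset is in a -> b order)

    With ``beta_order`` > 0 the Bayes-optimal classifier must read event
    order: only the canonical a -> b onset order carries risk, so a
    bag-of-codes model can exploit presence solely through its correlation
    with order and the Bayes-optimal classifier must read onset order.
    """

    trigger_pairs: list[tuple[str, str]]
    beta0: float = -2.0
    beta_presence: float = 0.0
    beta_order: float = 3.0


def short_regime(n_patients: int, seed: int) -> SyntheticSpec:
    """Acute-inpatient-like regime: mean ~2.5 visits per patient."""
    return SyntheticSpec(n_patients=n_patients, mean_visits=2.5, seed=seed)


def long_regime(n_patients: int, seed: int) -> SyntheticSpec:
    """Cohort-like regime: mean ~18 visits per patient."""
    return SyntheticSpec(
        n_patients=n_patients, mean_visits=18.0, codes_growth=0.15, seed=seed
    )


def _vocab_codes(spec: SyntheticSpec) -> tuple[list[str], np.ndarray]:
    """Code names interleaving dx/rx, with Zipf base probabilities by rank."""
    codes: list[str] = []
    di = ri = 0
    for rank in range(spec.n_dx + spec.n_rx):
        # every 4th rank is a medication, approximating the dx/rx mix
        if rank % 4 == 3 and ri < spec.n_rx:
            ri += 1
            codes.append(f"R{ri:03d}")
        elif di < spec.n_dx:
            di += 1
            codes.append(f"D{di:03d}")
        else:
            ri += 1
            codes.append(f"R{ri:03d}")
    ranks = np.arange(1, len(codes) + 1, dtype=float)
    p = ranks ** -spec.zipf_exponent
    return codes, p / p.sum()


def planted_pairs(spec: SyntheticSpec) -> list[tuple[str, str]]:
    """The planted directed transition set (deterministic given the seed).

    Pairs are drawn among moderately frequent codes (ranks 3..40) so both
    ends occur often enough for their asymmetry to be estimable, and the
    very head of the distribution (whose inclusion probabilities saturate)
    is avoided.
    """
    codes, _ = _vocab_codes(spec)
    rng = np.random.default_rng([spec.seed, 101])
    # diagnosis codes only (the "kidney disease follows diabetes" pattern);
    # medications have their own directed structure via indications
    dx = [c for c in codes if c.startswith("D")]
    lo = 2
    hi = min(lo + 2 * spec.n_planted + 6, len(dx))
    if hi - lo < 2 * spec.n_planted:
        raise ValueError("vocabulary too small for the planted pair count")
    candidates = [dx[int(r)] for r in rng.permutation(np.arange(lo, hi))[: 2 * spec.n_planted]]
    # pair codes a MODERATE care-phase apart, oriented along the gradient:
    # close enough that onset order stays genuinely variable given both
    # occur, far enough that the planted direction agrees with the natural
    # phase direction (progression runs early-phase -> late-phase)
    phase = {c: ((i + 1) * 0.618033988749895) % 1.0 for i, c in enumerate(codes)}
    candidates.sort(key=lambda c: phase[c])
    half = spec.n_planted  # quarter-offset pairing within each half
    q = max(1, half // 2)
    pairs = []
    for block in range(2):
        base = block * half
        for i in range(q):
            a = candidates[base + i]
            b = candidates[base + i + q]
            pairs.append((a, b))
    # vertex-disjoint by construction: each code joins exactly one pair
    return sorted(pairs)


def default_task_rule(spec: SyntheticSpec, n_triggers: int = 8) -> TaskRule:
    """Trigger pairs taken from the planted transition set.

    Progression pairs that shape trajectories are also the ones that drive
    onset, which couples the conditional-swap pretraining signal to the
    downstream task the way directed comorbidity chains do in real data.
    The most frequent planted pairs are used so the rule fires at a usable
    rate even in short trajectories.
    """
    codes, _ = _vocab_codes(spec)
    rank = {c: i for i, c in enumerate(codes)}
    pairs = sorted(planted_pairs(spec), key=lambda ab: rank[ab[0]] + rank[ab[1]])
    return TaskRule(trigger_pairs=pairs[: min(n_triggers, len(pairs))])


def indication_map(spec: SyntheticSpec) -> dict[str, str]:
    """Each medication's indication: the diagnosis just above it in rank."""
    codes, _ = _vocab_codes(spec)
    mapping: dict[str, str] = {}
    last_dx: str | None = None
    for c in codes:
        if c.startswith("D"):
            last_dx = c
        elif last_dx is not None:
            mapping[c] = last_dx
    return mapping


def generate_corpus(spec: SyntheticSpec) -> list[Trajectory]:
    """Draw a corpus of trajectories under the spec.  Seed-deterministic.

    Codes are included per visit by independent Bernoulli draws whose odds
    combine the Zipf base rate (scaled by the visit's target count), the
    planted transition lifts, persistence of codes already in the history,
    and the medication-indication state.  Diagnoses are drawn before
    medications so a medication can respond to a same-visit diagnosis.
    """
    codes, base_p = _vocab_codes(spec)
    kind = [CodeKind.MEDICATION if c.startswith("R") else CodeKind.DIAGNOSIS for c in codes]
    is_rx = np.array([k == CodeKind.MEDICATION for k in kind])
    pairs = planted_pairs(spec)
    code_index = {c: i for i, c in enumerate(codes)}
    lift_targets: dict[int, list[int]] = {}
    for a, b in pairs:
        lift_targets.setdefault(code_index[a], []).append(code_index[b])
    # indication[i] = dx index for rx i
    indication = {
        code_index[rx]: code_index[dx] for rx, dx in indication_map(spec).items()
    }
    log_lift = math.log(spec.lift)
    log_persist = math.log(spec.persistence)
    log_ind_lift = math.log(spec.rx_indication_lift)
    log_ind_damp = math.log(spec.rx_unindicated_damp)
    # golden-ratio spread of preferred phases over the rank order
    phases = (np.arange(1, len(codes) + 1) * 0.618033988749895) % 1.0

    rng = np.random.default_rng([spec.seed, 1])
    out: list[Trajectory] = []
    n_codes_total = len(codes)
    dx_idx = np.nonzero(~is_rx)[0]
    rx_idx = np.nonzero(is_rx)[0]
    for pid in range(spec.n_patients):
        n_visits = 1 + rng.poisson(spec.mean_visits - 1.0)
        seen: set[int] = set()
        seen_mask = np.zeros(n_codes_total, dtype=bool)
        lifted = np.zeros(n_codes_total, dtype=bool)
        visits: list[Visit] = []
        day = 0
        for j in range(1, n_visits + 1):
            target = spec.codes_base + spec.codes_growth * (j - 1)
            pi = np.clip(target * base_p, 1e-9, 0.95)
            pos = (j - 1) / max(n_visits - 1, 1)
            phase_factor = np.exp(-spec.phase_concentration * (pos - phases) ** 2)
            # count-preserving normalization: phase typing redistributes
            # which codes occur at this position without thinning the visit
            norm = base_p.sum() / float((base_p * phase_factor).sum())
            logit = (
                np.log(pi / (1 - pi))
                + np.log(phase_factor * norm)
                + log_lift * lifted
                + log_persist * seen_mask
            )
            prob = 1.0 / (1.0 + np.exp(-logit))
            # stage 1: diagnoses
            dx_draw = dx_idx[rng.random(dx_idx.size) < prob[dx_idx]]
            visit_dx = set(int(i) for i in dx_draw)
            # stage 2: medications, conditioned on indication state
            indicated = np.array(
                [
                    indication.get(int(i)) in seen
                    or indication.get(int(i)) in visit_dx
                    for i in rx_idx
                ]
            )
            rx_logit = logit[rx_idx] + np.where(indicated, log_ind_lift, log_ind_damp)
            rx_prob = 1.0 / (1.0 + np.exp(-rx_logit))
            rx_draw = rx_idx[rng.random(rx_idx.size) < rx_prob]
            draw = np.concatenate([dx_draw, rx_draw])
            if draw.size == 0:
                draw = np.array([rng.choice(dx_idx, p=base_p[dx_idx] / base_p[dx_idx].sum())])
            toks = [CodeToken(codes[int(i)], kind[int(i)]) for i in sorted(draw)]
            los = float(np.round(rng.lognormal(spec.los_mu, spec.los_sigma), 1))
            visits.append(
                Visit(
                    j,
                    toks,
                    los_days=los,
                    date=date(2000, 1, 1) + timedelta(days=day),
                )
            )
            day += int(rng.integers(20, 380))
            for i in draw:
                if int(i) not in seen:
                    seen.add(int(i))
                    seen_mask[int(i)] = True
                    for t in lift_targets.get(int(i), ()):
                        lifted[t] = True
        out.append(Trajectory(f"P{pid:05d}", visits))
    return out


def _pair_features(traj: Trajectory, pairs: list[tuple[str, str]]) -> tuple[int, int]:
    """(#pairs with both codes present, #pairs with onset in a->b order).

    Onset order -- the visit of each code's *first* occurrence -- is the
    clinically meaningful progression direction and, unlike co-occurrence,
    is not implied by presence alone.
    """
    first: dict[str, int] = {}
    for visit in traj.visits:
        for tok in visit.codes:
            first.setdefault(tok.code, visit.index)
    n_present = n_ordered = 0
    for a, b in pairs:
        if a in first and b in first:
            n_present += 1
            if first[a] < first[b]:
                n_ordered += 1
    return n_present, n_ordered


@dataclass
class LabeledCorpus:
    trajectories: list[Trajectory]  # target visit appended for positives
    labels: dict[str, int]
    true_logits: dict[str, float]  # the generating logit (oracle score)
    rule: TaskRule

    @property
    def prevalence(self) -> float:
        return float(np.mean(list(self.labels.values())))

    def oracle_auc(self) -> float:
        """AUC of the generating rule used as a classifier: the Bayes ceiling."""
        from sklearn.metrics import roc_auc_score

        pids = sorted(self.labels)
        return float(
            roc_auc_score(
                [self.labels[p] for p in pids], [self.true_logits[p] for p in pids]
            )
        )


def generate_labeled_cohort(
    spec: SyntheticSpec, rule: TaskRule | None = None
) -> LabeledCorpus:
    """Attach order-dependent target-code onsets to a generated corpus.

    Onset probability follows the rule's logistic model over the patient's
    trajectory; positive patients get a new final visit containing the
    target code (so truncating at first target occurrence recovers exactly
    the risk-bearing history).
    """
    if rule is None:
        rule = default_task_rule(spec)
    corpus = generate_corpus(spec)
    rng = np.random.default_rng([spec.seed, 2])
    labels: dict[str, int] = {}
    logits: dict[str, float] = {}
    out: list[Trajectory] = []
    for traj in corpus:
        n_present, n_ordered = _pair_features(traj, rule.trigger_pairs)
        z = rule.beta0 + rule.beta_presence * n_present + rule.beta_order * n_ordered
        y = int(rng.random() < 1.0 / (1.0 + math.exp(-z)))
        labels[traj.patient_id] = y
        logits[traj.patient_id] = z
        if y:
            onset = Visit(
                traj.n_visits + 1,
                [CodeToken(TARGET_CODE, CodeKind.DIAGNOSIS)],
                los_days=None,
                date=None,
            )
            traj = Trajectory(traj.patient_id, traj.visits + [onset])
        out.append(traj)
    lc = LabeledCorpus(out, labels, logits, rule)
    if not 0.05 <= lc.prevalence <= 0.95:
        logger.warning("degenerate task rule: prevalence %.3f", lc.prevalence)
    return lc


def estimate_lift(corpus: list[Trajectory], a: str, b: str) -> float:
    """Empirical odds ratio for ``b`` in visits after ``a`` has occurred.

    Mantel-Haenszel combination across (visit index, trajectory length,
    ``b`` seen earlier) strata: exposure correlates with visit index (later
    visits carry more codes under progression), with relative position
    (care-phase typing, which depends on trajectory length), and with prior
    ``b`` occurrences (persistence), so the crude odds ratio is confounded
    by all three.  Consistent for the planted lift because the generator
    applies all effects in odds space within each visit.
    """
    # per stratum: [exposed & b, exposed & !b, unexp & b, unexp & !b]
    strata: dict[tuple[int, int, bool], list[int]] = {}
    for traj in corpus:
        a_seen = False
        b_seen = False
        for visit in traj.visits:
            codes = {t.code for t in visit.codes}
            cell = strata.setdefault((visit.index, traj.n_visits, b_seen), [0, 0, 0, 0])
            has_b = b in codes
            if a_seen:
                cell[0 if has_b else 1] += 1
            else:
                cell[2 if has_b else 3] += 1
            if a in codes:
                a_seen = True
            if has_b:
                b_seen = True
    num = den = 0.0
    for e_b, e_nb, u_b, u_nb in strata.values():
        n = e_b + e_nb + u_b + u_nb
        if n == 0 or (e_b + e_nb) == 0 or (u_b + u_nb) == 0:
            continue
        num += e_b * u_nb / n
        den += e_nb * u_b / n
    if den == 0:
        return float("nan")
    return num / den
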