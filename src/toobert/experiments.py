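"""Canonical synthetic-data experiments.

These are the package's reference study recipes, sized for a single CPU:

* :func:`planted_sign_recovery` -- can the conditional code-swap statistic
  recover the direction of planted transitions from a long-trajectory
  corpus?
* :func:`too_learnability` -- after alternating MLM + order-objective
  pretraining, how well does the model detect permuted trajectories as a
  function of the swap fraction?
* :func:`headroom_benchmark` -- does adding the conditional-code-swap
  order objective to MLM pretraining improve fine-tuned risk prediction on
  an order-dependent outcome, and does the gap persist as the fine-tuning
  set shrinks?

Every recipe is deterministic given its seed.  Problem sizes are chosen so
the full battery runs on one desktop CPU core in tens of minutes; they are
deliberately far below the scale of real hospital corpora, so absolute
numbers are illustrative while the qualitative contrasts are the object of
interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .cohorts import build_code_onset_cohort, subsample_finetune
from .corruption import SwapMethod
from .ehr_data import (
    Trajectory,
    Visit,
    filter_rare_codes,
    split_corpus,
    tokenize,
)
from .model import ModelConfig, TooBert
from .swap_stats import compute_ccs, count_pairs
from .synthetic_data import (
    TARGET_CODE,
    generate_corpus,
    generate_labeled_cohort,
    long_regime,
    planted_pairs,
    short_regime,
)
from .training import (
    FinetuneConfig,
    PretrainConfig,
    evaluate_auc,
    evaluate_too,
    finetune,
    prepare_pretraining_sequences,
    pretrain,
)

__all__ = [
    "planted_sign_recovery",
    "too_learnability",
    "headroom_benchmark",
    "HeadroomResult",
]


def planted_sign_recovery(
    n_patients: int = 2000, seed: int = 1, min_count: int = 5
) -> dict:
    """Fraction of planted transition directions recovered by CCS.

    Generates a long-regime corpus with the generator's default 20 planted pairs
    at lift 8, computes pair counts and conditional swap weights, and
    checks for each planted pair (a -> b) that CCS(b, a) > CCS(a, b).
    """
    spec = long_regime(n_patients, seed)
    corpus = generate_corpus(spec)
    kept, vocab = filter_rare_codes(corpus, min_count)
    weights = compute_ccs(count_pairs(kept, vocab))
    pairs = planted_pairs(spec)
    recovered = sum(
        weights.weight(vocab.id_of(b), vocab.id_of(a))
        > weights.weight(vocab.id_of(a), vocab.id_of(b))
        for a, b in pairs
    )
    return {
        "n_pairs": len(pairs),
        "n_recovered": int(recovered),
        "recovery_rate": recovered / len(pairs),
    }


def too_learnability(
    seed: int = 1,
    n_patients: int = 2000,
    method: SwapMethod = SwapMethod.RVS,
    fractions: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0),
    max_epochs: int = 40,
    n_eval: int = 500,
) -> dict:
    """Pretrain on the short-regime preset and trace the detection curve.

    Returns the untrained-model accuracy at full swap, the accuracy per
    fraction on held-out full trajectories, and the Spearman correlation
    of accuracy with fraction.
    """
    corpus = generate_corpus(short_regime(n_patients, seed))
    corpus, vocab = filter_rare_codes(corpus, 10)
    seqs, _ = prepare_pretraining_sequences(corpus, vocab)
    max_visits = max(max(s.visit_numbers) for s in seqs)
    model = TooBert(
        ModelConfig(vocab_size=len(vocab), max_len=96, max_visits=max(max_visits, 16)),
        seed=seed,
    )
    weights = None
    if method.is_conditional:
        weights = compute_ccs(count_pairs(corpus, vocab))
    full = [tokenize(t, vocab) for t in corpus[:n_eval]]
    untrained = evaluate_too(model, full, method, [1.0], weights, seed=seed)[1.0][0]
    cfg = PretrainConfig(
        lr=5e-3,
        weight_decay=1e-4,
        batch_size=32,
        max_epochs=max_epochs,
        too_method=method,
        too_fraction=1.0,
        seed=seed,
        plateau_patience=6,
    )
    log = pretrain(model, seqs, vocab, cfg, weights)
    curve = evaluate_too(model, full, method, list(fractions), weights, seed=seed)
    accs = [curve[f][0] for f in fractions]
    rho = float(spearmanr(list(fractions), accs).statistic)
    return {
        "untrained_accuracy": untrained,
        "fractions": list(fractions),
        "accuracies": accs,
        "accuracy_at_full_swap": accs[-1],
        "spearman_rho": rho,
        "n_per_fraction": curve[fractions[0]][1],
        "epochs_run": sum(1 for e in log if e.get("objective") == "monitor"),
    }


def strip_target_visits(trajectories: list[Trajectory]) -> list[Trajectory]:
    """Remove the injected target-onset visits (pretraining must not see them)."""
    out = []
    for t in trajectories:
        visits = [
            v for v in t.visits if not any(c.code == TARGET_CODE for c in v.codes)
        ]
        if visits:
            out.append(
                Trajectory(
                    t.patient_id,
                    [
                        Visit(i, v.codes, v.los_days, v.date)
                        for i, v in enumerate(visits, 1)
                    ],
                )
            )
    return out


@dataclass
class HeadroomResult:
    """Per-seed outcome of the order-objective headroom benchmark."""

    seed: int
    oracle_auc: float
    auc: dict[float, dict[str, float]]  # fraction -> {"mlm": ..., "mlm_too_ccs": ...}

    def gap(self, fraction: float) -> float:
        row = self.auc[fraction]
        return row["mlm_too_ccs"] - row["mlm"]


def headroom_benchmark(
    seed: int,
    n_patients: int = 1200,
    fractions: tuple[float, ...] = (1.0, 0.5, 0.2),
    pretrain_epochs: int = 12,
    finetune_epochs: int = 18,
) -> HeadroomResult:
    """One seed of the MLM vs MLM+TOO(CCS) fine-tuning comparison.

    Pipeline: generate an order-dependent labeled short-regime cohort;
    split patients 50/20/30 into pretraining, fine-tuning and test;
    pretrain one encoder on MLM alone and one on alternating MLM + the
    conditional-code-swap order objective (loss weights 1 : 0.5); build
    the onset cohort; fine-tune each encoder with the bidirectional-GRU
    head on the full fine-tuning cohort and on label-stratified subsets;
    report mean test AUC per variant.
    """
    lc = generate_labeled_cohort(short_regime(n_patients, seed))
    corpus, vocab = filter_rare_codes(lc.trajectories, 10)
    pre, fin, test = split_corpus(corpus, (0.5, 0.2, 0.3), seed=seed)
    pre_hist = strip_target_visits(pre)
    seqs, _ = prepare_pretraining_sequences(pre_hist, vocab)
    max_visits = max(max(s.visit_numbers) for s in seqs)
    weights = compute_ccs(count_pairs(pre_hist, vocab))
    model_cfg = ModelConfig(
        vocab_size=len(vocab), max_len=96, max_visits=max(max_visits, 20)
    )

    variants = {}
    for name, w_too in (("mlm", 0.0), ("mlm_too_ccs", 0.5)):
        model = TooBert(model_cfg, seed=seed)
        cfg = PretrainConfig(
            lr=5e-3,
            weight_decay=1e-4,
            batch_size=32,
            max_epochs=pretrain_epochs,
            w_too=w_too,
            too_method=SwapMethod.CCS,
            too_fraction=0.4,
            seed=seed,
            plateau_patience=6,
        )
        pretrain(model, seqs, vocab, cfg, weights if w_too else None)
        variants[name] = model

    cohort_fin, _ = build_code_onset_cohort(fin, (TARGET_CODE,), min_visits=2, task="HF")
    cohort_test, _ = build_code_onset_cohort(test, (TARGET_CODE,), min_visits=2, task="HF")
    for e in cohort_fin + cohort_test:
        e.label = lc.labels[e.patient_id]

    auc: dict[float, dict[str, float]] = {}
    for frac in fractions:
        sub = subsample_finetune(cohort_fin, frac, seed)
        row = {}
        for name, model in variants.items():
            fcfg = FinetuneConfig(
                n_splits=5,
                lr=1.5e-3,
                layer_decay_factor=0.5,
                patience=6,
                max_epochs=finetune_epochs,
                batch_size=16,
                seed=seed,
            )
            models, _ = finetune(model, sub, vocab, fcfg)
            mean, _, _ = evaluate_auc(models, cohort_test, vocab)
            row[name] = mean
        auc[frac] = row
    return HeadroomResult(seed=seed, oracle_auc=lc.oracle_auc(), auc=auc)
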