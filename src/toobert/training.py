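"""Pretraining, fine-tuning, and evaluation loops.

Pretraining alternates strictly between the masked-language-model objective
and the trajectory-order objective batch by batch, optimizing the weighted
loss ``W_MLM * L_MLM`` or ``W_TOO * L_TOO`` for that batch; a held-out
monitor split (default 10% of the pretraining sequences) tracks both losses
and order-detection accuracy, and training stops when the monitor loss
plateaus.  The maximum sequence length is set to the 0.7 quantile of the
tokenized trajectory lengths, with visit-aligned sliding windows providing
extra samples for longer trajectories.

Fine-tuning adds the bidirectional-GRU head, splits the labeled cohort into
``n_splits`` folds (train on all but one, early-stop on the held-out fold's
AUC), and applies layer-wise learning-rate decay: with decay factor f and
top level T, level l (0 = embeddings) trains at lr * f**(T - l), so
pretrained early layers move least.  Reported performance is the mean and
SD of per-fold AUC on an untouched test set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from . import nn
from .cohorts import CohortExample
from .corruption import (
    SwapMethod,
    TrajectoryTooShort,
    make_too_batch,
    mlm_corrupt,
    ordered_sample,
    permute,
)
from .ehr_data import TokenizedSequence, Trajectory, Vocabulary, sliding_window, tokenize
from .model import (
    ModelConfig,
    TooBert,
    binary_cross_entropy_with_logits,
    pad_batch,
)
from .swap_stats import SwapWeights

logger = logging.getLogger(__name__)

MetricsLog = list[dict]


@dataclass
class PretrainConfig:
    lr: float = 7e-5
    weight_decay: float = 0.015
    w_mlm: float = 1.0
    w_too: float = 1.0
    mask_rate: float = 0.15
    batch_size: int = 32
    max_epochs: int = 10
    monitor_fraction: float = 0.10
    too_method: SwapMethod = SwapMethod.RCS
    too_fraction: float = 0.4
    plateau_patience: int = 3
    plateau_rel_tol: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.w_mlm + self.w_too <= 0:
            raise ValueError("at least one loss weight must be positive")
        self.too_method = SwapMethod(self.too_method)


@dataclass
class FinetuneConfig:
    n_splits: int = 5
    lr: float = 1e-3
    weight_decay: float = 0.015
    layer_decay_factor: float = 0.9
    patience: int = 3
    max_epochs: int = 20
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.n_splits < 2:
            raise ValueError("n_splits must be >= 2")
        if not 0.0 < self.layer_decay_factor <= 1.0:
            raise ValueError("layer_decay_factor must be in (0, 1]")


def quantile_max_length(seqs: Sequence[TokenizedSequence], q: float = 0.7) -> int:
    """The q-quantile of tokenized lengths, used as the model max length."""
    lengths = [len(s) for s in seqs]
    return max(8, int(np.quantile(lengths, q)))


def prepare_pretraining_sequences(
    corpus: Sequence[Trajectory],
    vocab: Vocabulary,
    length_quantile: float = 0.7,
) -> tuple[list[TokenizedSequence], int]:
    """Tokenize a corpus and window long trajectories to the quantile length."""
    seqs = [tokenize(t, vocab) for t in corpus]
    max_len = quantile_max_length(seqs, length_quantile)
    out: list[TokenizedSequence] = []
    for s in seqs:
        out.extend(sliding_window(s, max_len))
    return out, max_len


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def _forward_mlm(model: TooBert, samples, max_len: int):
    tok, vis = pad_batch([(s.input_ids, s.visit_numbers) for s in samples], max_len)
    tgt, _ = pad_batch([(s.target_ids, s.visit_numbers) for s in samples], max_len)
    tgt[tok == 0] = -100  # padded tail is never supervised
    tgt[:, 0] = -100  # nor the (possibly re-attached) CLS slot
    out = model.encode(tok, vis)
    return model.mlm_loss(out, tgt)


def _forward_too(model: TooBert, samples, max_len: int):
    tok, vis = pad_batch([(s.input_ids, s.visit_numbers) for s in samples], max_len)
    y = np.array([s.y_state for s in samples])
    out = model.encode(tok, vis)
    logit = model.too_logit(out)
    loss = binary_cross_entropy_with_logits(logit, y)
    acc = float(np.mean((logit.data[:, 0] > 0).astype(int) == y))
    return loss, acc


def pretrain(
    model: TooBert,
    seqs: Sequence[TokenizedSequence],
    vocab: Vocabulary,
    cfg: PretrainConfig,
    weights: SwapWeights | None = None,
) -> MetricsLog:
    """Alternating multitask pretraining; returns the metrics log.

    The model is trained in place.  Conditional swap methods require
    ``weights``.
    """
    if cfg.too_method.is_conditional and cfg.w_too > 0 and weights is None:
        raise ValueError(f"{cfg.too_method.value} pretraining requires swap weights")
    rng_split = np.random.default_rng([cfg.seed, 0])
    rng_mlm = np.random.default_rng([cfg.seed, 1])
    rng_too = np.random.default_rng([cfg.seed, 2])
    rng_batch = np.random.default_rng([cfg.seed, 3])

    order = rng_split.permutation(len(seqs))
    n_mon = max(1, round(cfg.monitor_fraction * len(seqs)))
    monitor = [seqs[i] for i in order[:n_mon]]
    train = [seqs[i] for i in order[n_mon:]]

    opt = nn.Adam(
        list(model.named_parameters()), lr=cfg.lr, weight_decay=cfg.weight_decay
    )
    log: MetricsLog = []
    max_len = model.cfg.max_len
    step = 0
    best = np.inf
    stall = 0
    model.train()
    for epoch in range(cfg.max_epochs):
        for idx in _batches(len(train), cfg.batch_size, rng_batch):
            batch = [train[i] for i in idx]
            if step % 2 == 0:  # MLM batch
                samples = [
                    mlm_corrupt(s, vocab, cfg.mask_rate, rng_mlm) for s in batch
                ]
                loss = _forward_mlm(model, samples, max_len) * cfg.w_mlm
                entry = {"step": step, "objective": "mlm", "loss": float(loss.data)}
                opt.zero_grad()
                loss.backward()
                opt.step()
            else:  # TOO batch
                if cfg.w_too == 0:
                    step += 1
                    continue
                samples = make_too_batch(
                    batch, cfg.too_method, cfg.too_fraction, rng_too, weights
                )
                loss, acc = _forward_too(model, samples, max_len)
                loss = loss * cfg.w_too
                entry = {
                    "step": step,
                    "objective": "too",
                    "loss": float(loss.data),
                    "accuracy": acc,
                }
                opt.zero_grad()
                loss.backward()
                opt.step()
            entry["lr"] = cfg.lr
            log.append(entry)
            step += 1
        mon = monitor_metrics(model, monitor, vocab, cfg, weights, epoch)
        log.append(mon)
        total = mon["loss"]
        if total < best * (1 - cfg.plateau_rel_tol):
            best, stall = total, 0
        else:
            stall += 1
            if stall >= cfg.plateau_patience:
                logger.info("monitor loss plateaued at epoch %d", epoch)
                break
    model.eval()
    return log


def monitor_metrics(
    model: TooBert,
    monitor: Sequence[TokenizedSequence],
    vocab: Vocabulary,
    cfg: PretrainConfig,
    weights: SwapWeights | None,
    epoch: int,
) -> dict:
    """Held-out MLM loss and order-detection accuracy (deterministic per epoch)."""
    was_training = model.training
    model.eval()
    rng = np.random.default_rng([cfg.seed, 4, epoch])
    mlm_losses = []
    too_losses = []
    accs = []
    for i in range(0, len(monitor), cfg.batch_size):
        batch = monitor[i : i + cfg.batch_size]
        samples = [mlm_corrupt(s, vocab, cfg.mask_rate, rng) for s in batch]
        mlm_losses.append(float(_forward_mlm(model, samples, model.cfg.max_len).data))
        if cfg.w_too > 0:
            too = make_too_batch(batch, cfg.too_method, cfg.too_fraction, rng, weights)
            loss, acc = _forward_too(model, too, model.cfg.max_len)
            too_losses.append(float(loss.data))
            accs.append(acc)
    model.train(was_training)
    mlm = float(np.mean(mlm_losses))
    too = float(np.mean(too_losses)) if too_losses else 0.0
    return {
        "epoch": epoch,
        "objective": "monitor",
        "mlm_loss": mlm,
        "too_loss": too,
        "loss": cfg.w_mlm * mlm + cfg.w_too * too,
        "too_accuracy": float(np.mean(accs)) if accs else float("nan"),
    }


def evaluate_too(
    model: TooBert,
    seqs: Sequence[TokenizedSequence],
    method: SwapMethod,
    fractions: Sequence[float],
    weights: SwapWeights | None = None,
    seed: int = 0,
    batch_size: int = 64,
) -> dict[float, tuple[float, int]]:
    """Permutation-detection accuracy per swap fraction on balanced samples.

    For each fraction, every sequence that can be permuted contributes one
    ordered and one permuted sample; returns {fraction: (accuracy, n)}.
    """
    was_training = model.training
    model.eval()
    results: dict[float, tuple[float, int]] = {}
    for f_i, frac in enumerate(fractions):
        rng = np.random.default_rng([seed, 7, f_i])
        samples = []
        for s in seqs:
            try:
                neg = permute(s, method, frac, rng, weights if method.is_conditional else None)
            except TrajectoryTooShort:
                continue
            samples.append(ordered_sample(s, method, frac))
            samples.append(neg)
        correct = 0
        for i in range(0, len(samples), batch_size):
            chunk = samples[i : i + batch_size]
            tok, vis = pad_batch(
                [(x.input_ids, x.visit_numbers) for x in chunk], model.cfg.max_len
            )
            out = model.encode(tok, vis)
            pred = (model.too_logit(out).data[:, 0] > 0).astype(int)
            correct += int(np.sum(pred == np.array([x.y_state for x in chunk])))
        results[frac] = (correct / len(samples) if samples else float("nan"), len(samples))
    model.train(was_training)
    return results


# ---------------------------------------------------------------------------
# fine-tuning


def _layer_level(name: str, n_layers: int) -> int:
    """0 = embeddings, 1..n_layers = encoder blocks, n_layers+1 = heads."""
    if name.startswith(("code_emb", "visit_emb", "emb_ln")):
        return 0
    if name.startswith("layers."):
        return 1 + int(name.split(".")[1])
    return n_layers + 1


def layerwise_groups(model: TooBert, lr: float, factor: float) -> list[dict]:
    top = model.cfg.n_layers + 1
    groups: dict[int, list] = {}
    for name, p in model.named_parameters():
        groups.setdefault(_layer_level(name, model.cfg.n_layers), []).append((name, p))
    return [
        {"params": params, "lr": lr * factor ** (top - level)}
        for level, params in sorted(groups.items())
    ]


def _examples_to_batch(
    examples: Sequence[CohortExample], vocab: Vocabulary, max_len: int
):
    seqs = [tokenize(e.history, vocab) for e in examples]
    tok, vis = pad_batch(seqs, max_len)
    y = np.array([e.label for e in examples])
    return tok, vis, y


def predict_proba(
    model: TooBert,
    examples: Sequence[CohortExample],
    vocab: Vocabulary,
    batch_size: int = 64,
) -> np.ndarray:
    was_training = model.training
    model.eval()
    probs = []
    for i in range(0, len(examples), batch_size):
        tok, vis, _ = _examples_to_batch(
            examples[i : i + batch_size], vocab, model.cfg.max_len
        )
        out = model.encode(tok, vis)
        probs.append(model.downstream_probability(out))
    model.train(was_training)
    return np.concatenate(probs)


def _clone(model: TooBert) -> TooBert:
    clone = TooBert(replace(model.cfg))
    clone.load_state_dict(model.state_dict())
    return clone


def finetune(
    model: TooBert,
    cohort: Sequence[CohortExample],
    vocab: Vocabulary,
    cfg: FinetuneConfig,
) -> tuple[list[TooBert], MetricsLog]:
    """k-fold fine-tuning with layer-wise LR decay and AUC early stopping.

    Returns one fine-tuned model per fold plus the per-fold metrics log.
    The input model is left untouched.
    """
    rng = np.random.default_rng([cfg.seed, 10])
    # label-stratified folds: every validation fold sees both classes at
    # the cohort prevalence, stabilizing the early-stopping AUC
    labels = np.array([e.label for e in cohort])
    folds_parts: list[list[np.ndarray]] = [[] for _ in range(cfg.n_splits)]
    for label in np.unique(labels):
        idx = rng.permutation(np.nonzero(labels == label)[0])
        for k, part in enumerate(np.array_split(idx, cfg.n_splits)):
            folds_parts[k].append(part)
    folds = [np.concatenate(parts) for parts in folds_parts]
    models: list[TooBert] = []
    log: MetricsLog = []
    for k, val_idx in enumerate(folds):
        train_idx = np.concatenate([f for j, f in enumerate(folds) if j != k])
        train = [cohort[i] for i in train_idx]
        val = [cohort[i] for i in val_idx]
        if len({e.label for e in train}) < 2:
            raise ValueError(f"fold {k}: training split has a single class")
        m = _clone(model)
        opt = nn.Adam(
            layerwise_groups(m, cfg.lr, cfg.layer_decay_factor),
            weight_decay=cfg.weight_decay,
        )
        best_auc, best_state, stall = -np.inf, m.state_dict(), 0
        rng_fold = np.random.default_rng([cfg.seed, 11, k])
        m.train()
        for epoch in range(cfg.max_epochs):
            for idx in _batches(len(train), cfg.batch_size, rng_fold):
                batch = [train[i] for i in idx]
                tok, vis, y = _examples_to_batch(batch, vocab, m.cfg.max_len)
                out = m.encode(tok, vis)
                loss = binary_cross_entropy_with_logits(m.bigru_logit(out), y)
                opt.zero_grad()
                loss.backward()
                opt.step()
            val_auc = _safe_auc(
                [e.label for e in val], predict_proba(m, val, vocab)
            )
            log.append({"fold": k, "epoch": epoch, "val_auc": val_auc})
            if val_auc > best_auc:
                best_auc, best_state, stall = val_auc, m.state_dict(), 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    break
        m.load_state_dict(best_state)
        m.eval()
        models.append(m)
        log.append({"fold": k, "best_val_auc": best_auc})
    return models, log


def _safe_auc(y, p) -> float:
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        return 0.5
    return float(roc_auc_score(y, p))


def evaluate_auc(
    models: Sequence[TooBert],
    test_cohort: Sequence[CohortExample],
    vocab: Vocabulary,
) -> tuple[float, float, list[float]]:
    """Mean and SD of per-model ROC-AUC on the untouched test cohort."""
    if not models:
        raise ValueError("no models to evaluate")
    y = [e.label for e in test_cohort]
    if len(set(y)) < 2:
        raise ValueError("test cohort has a single class")
    aucs = [
        float(roc_auc_score(y, predict_proba(m, test_cohort, vocab)))
        for m in models
    ]
    return float(np.mean(aucs)), float(np.std(aucs)), aucs


def rank_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-based AUC with 0.5 tie credit (independent of sklearn).

    Equals the Mann-Whitney U statistic normalized by n_pos * n_neg.
    """
    from scipy.stats import rankdata

    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both classes")
    r = rankdata(s)
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def warm_start(source_state: dict[str, np.ndarray], target: TooBert) -> list[str]:
    """Load encoder/embedding tensors from a checkpoint state into a model.

    Tensors whose shapes match are copied; mismatching head tensors keep
    their fresh initialization.  A code-embedding shape mismatch means the
    vocabularies differ and is an error.
    """
    own = dict(target.named_parameters())
    key = "code_emb.weight"
    if key in source_state and source_state[key].shape != own[key].data.shape:
        raise ValueError("vocabulary mismatch between checkpoint and model")
    transferred = []
    for name, arr in source_state.items():
        if name in own and own[name].data.shape == arr.shape:
            own[name].data = arr.copy()
            transferred.append(name)
        else:
            logger.info("warm start skipped %s", name)
    return transferred
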