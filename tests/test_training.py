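"""Training loops: alternation, determinism, layer-wise decay, AUC, warm start."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from toobert.cohorts import CohortExample
from toobert.corruption import SwapMethod
from toobert.ehr_data import filter_rare_codes, tokenize
from toobert.model import ModelConfig, TooBert
from toobert.swap_stats import compute_ccs, count_pairs
from toobert.synthetic_data import generate_corpus, short_regime
from toobert.training import (
    FinetuneConfig,
    PretrainConfig,
    evaluate_auc,
    evaluate_too,
    finetune,
    layerwise_groups,
    prepare_pretraining_sequences,
    pretrain,
    quantile_max_length,
    rank_auc,
    warm_start,
)


@pytest.fixture(scope="module")
def small_setup():
    corpus = generate_corpus(short_regime(120, seed=21))
    corpus, vocab = filter_rare_codes(corpus, 3)
    seqs, max_len = prepare_pretraining_sequences(corpus, vocab)
    max_visits = max(max(s.visit_numbers) for s in seqs)
    cfg = ModelConfig(vocab_size=len(vocab), max_len=64, max_visits=max(max_visits, 12))
    return corpus, vocab, seqs, cfg


def small_pretrain_cfg(**kw):
    base = dict(
        lr=2e-3,
        weight_decay=1e-4,
        batch_size=16,
        max_epochs=2,
        too_method=SwapMethod.RVS,
        too_fraction=1.0,
        seed=5,
        plateau_patience=10,
    )
    base.update(kw)
    return PretrainConfig(**base)


class TestPretrain:
    def test_objectives_strictly_alternate(self, small_setup):
        _, vocab, seqs, cfg = small_setup
        model = TooBert(cfg, seed=0)
        log = pretrain(model, seqs, vocab, small_pretrain_cfg())
        steps = [e for e in log if e.get("objective") in ("mlm", "too")]
        for prev, cur in zip(steps, steps[1:]):
            assert prev["objective"] != cur["objective"]

    def test_zero_too_weight_runs_mlm_only(self, small_setup):
        _, vocab, seqs, cfg = small_setup
        model = TooBert(cfg, seed=0)
        log = pretrain(model, seqs, vocab, small_pretrain_cfg(w_too=0.0))
        assert all(e["objective"] != "too" for e in log if "objective" in e)

    def test_identical_seed_reproduces_metrics_log(self, small_setup):
        _, vocab, seqs, cfg = small_setup
        logs = []
        for _ in range(2):
            model = TooBert(cfg, seed=1)
            logs.append(pretrain(model, seqs, vocab, small_pretrain_cfg()))
        assert logs[0] == logs[1]

    def test_monitor_mlm_loss_improves(self, small_setup):
        _, vocab, seqs, cfg = small_setup
        model = TooBert(cfg, seed=2)
        log = pretrain(model, seqs, vocab, small_pretrain_cfg(max_epochs=5))
        mons = [e for e in log if e.get("objective") == "monitor"]
        assert mons[-1]["mlm_loss"] < mons[0]["mlm_loss"]

    def test_conditional_method_without_weights_errors(self, small_setup):
        _, vocab, seqs, cfg = small_setup
        model = TooBert(cfg, seed=0)
        with pytest.raises(ValueError, match="ccs"):
            pretrain(model, seqs, vocab, small_pretrain_cfg(too_method=SwapMethod.CCS))


class TestEvaluateToo:
    def test_untrained_model_near_chance(self, small_setup):
        _, vocab, seqs, cfg = small_setup
        model = TooBert(cfg, seed=4)
        res = evaluate_too(model, seqs[:80], SwapMethod.RVS, [1.0], seed=0)
        acc, n = res[1.0]
        assert n > 50
        assert 0.35 <= acc <= 0.65

    def test_balanced_support(self, small_setup):
        _, vocab, seqs, cfg = small_setup
        model = TooBert(cfg, seed=4)
        res = evaluate_too(model, seqs[:60], SwapMethod.RVS, [0.5], seed=0)
        _, n = res[0.5]
        assert n % 2 == 0  # one ordered + one permuted per eligible sequence


class TestQuantileLength:
    def test_quantile_rule(self, small_setup):
        _, _, seqs, _ = small_setup
        q = quantile_max_length(seqs, 0.7)
        lengths = sorted(len(s) for s in seqs)
        assert q >= lengths[int(0.5 * len(lengths))]
        assert q <= lengths[-1]


class TestLayerwiseDecay:
    def test_geometric_schedule(self, small_setup):
        *_, cfg = small_setup
        model = TooBert(cfg, seed=0)
        groups = layerwise_groups(model, lr=1e-3, factor=0.5)
        lrs = {}
        for g in groups:
            for name, _ in g["params"]:
                lrs[name.split(".")[0]] = g["lr"]
        assert lrs["code_emb"] == pytest.approx(1e-3 * 0.5**2)
        assert lrs["layers"] == pytest.approx(1e-3 * 0.5)
        assert lrs["gru"] == pytest.approx(1e-3)

    def test_factor_one_uniform(self, small_setup):
        *_, cfg = small_setup
        model = TooBert(cfg, seed=0)
        groups = layerwise_groups(model, lr=1e-3, factor=1.0)
        assert {g["lr"] for g in groups} == {1e-3}


class TestFinetune:
    @staticmethod
    def cohort_from(corpus, n=40):
        rng = np.random.default_rng(3)
        out = []
        for traj in corpus[:n]:
            if traj.n_visits < 2:
                continue
            out.append(
                CohortExample(traj.patient_id, traj, int(rng.random() < 0.5), "HF")
            )
        return out

    def test_returns_one_model_per_fold_and_metrics(self, small_setup):
        corpus, vocab, _, cfg = small_setup
        model = TooBert(cfg, seed=0)
        cohort = self.cohort_from(corpus)
        fcfg = FinetuneConfig(n_splits=3, lr=1e-3, max_epochs=2, patience=2, seed=0)
        models, log = finetune(model, cohort, vocab, fcfg)
        assert len(models) == 3
        assert sum(1 for e in log if "best_val_auc" in e) == 3
        # the input model is untouched
        assert np.array_equal(
            model.state_dict()["clf.weight"], TooBert(cfg, seed=0).state_dict()["clf.weight"]
        )

    def test_single_class_split_errors(self, small_setup):
        corpus, vocab, _, cfg = small_setup
        model = TooBert(cfg, seed=0)
        cohort = [
            CohortExample(t.patient_id, t, 1, "HF") for t in corpus[:12]
        ]
        fcfg = FinetuneConfig(n_splits=3, max_epochs=1, seed=0)
        with pytest.raises(ValueError, match="single class"):
            finetune(model, cohort, vocab, fcfg)


class TestEvaluateAuc:
    def test_rank_auc_closed_forms(self):
        assert rank_auc([1, 1, 0], [0.9, 0.8, 0.1]) == 1.0
        assert rank_auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == 0.5
        assert rank_auc([1, 0], [0.2, 0.8]) == 0.0

    def test_rank_auc_matches_sklearn(self, rng):
        y = rng.integers(0, 2, size=200)
        y[0], y[1] = 0, 1
        s = np.round(rng.random(200), 2)  # ties included
        assert rank_auc(y, s) == pytest.approx(roc_auc_score(y, s))

    def test_single_class_test_set_errors(self, small_setup):
        corpus, vocab, _, cfg = small_setup
        model = TooBert(cfg, seed=0)
        cohort = [CohortExample(t.patient_id, t, 1, "HF") for t in corpus[:6]]
        with pytest.raises(ValueError, match="single class"):
            evaluate_auc([model], cohort, vocab)


class TestWarmStart:
    def test_self_transfer_identity(self, small_setup):
        *_, cfg = small_setup
        src = TooBert(cfg, seed=7).eval()
        dst = TooBert(cfg, seed=8).eval()
        transferred = warm_start(src.state_dict(), dst)
        assert "layers.0.attn.wq.weight" in transferred
        a = src.encode(np.array([[1, 6, 2]]), np.array([[0, 1, 1]])).x1.data
        b = dst.encode(np.array([[1, 6, 2]]), np.array([[0, 1, 1]])).x1.data
        assert np.array_equal(a, b)

    def test_vocab_mismatch_errors(self, small_setup):
        *_, cfg = small_setup
        from dataclasses import replace

        src = TooBert(replace(cfg, vocab_size=cfg.vocab_size + 5), seed=0)
        dst = TooBert(cfg, seed=0)
        with pytest.raises(ValueError, match="[Vv]ocabulary"):
            warm_start(src.state_dict(), dst)

    def test_head_mismatch_keeps_fresh_heads(self, small_setup):
        *_, cfg = small_setup
        from dataclasses import replace

        src = TooBert(replace(cfg, gru_hidden=8), seed=0)
        dst = TooBert(cfg, seed=9)
        fresh_clf = dst.state_dict()["clf.weight"].copy()
        transferred = warm_start(src.state_dict(), dst)
        assert "code_emb.weight" in transferred
        assert "gru.fwd.wx" not in transferred
        assert np.array_equal(dst.state_dict()["clf.weight"], fresh_clf)
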