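"""The trajectory encoder: embeddings, transformer, and task heads.

Architecture (BERT-family, deliberately small):

* token embedding + trainable visit-number embedding + fixed sinusoidal
  embedding *indexed by visit number* (temporal position is the visit, not
  the token offset), summed into X0;
* a multihead self-attention encoder (default: 1 layer, 5 heads, each head
  using the full d_k = d_v = 36 with a 5*36 -> 36 output projection);
* an MLM head (softmax over the vocabulary at every position);
* a trajectory-order head (binary classifier on the [CLS] representation);
* a bidirectional-GRU fine-tuning head (64 hidden units per direction)
  over the encoder output for downstream risk prediction.

With the default configuration and a realistic vocabulary (~2300 codes)
the model has roughly 2.5e5 learnable parameters; `parameter_report`
prints the per-component breakdown at build time.
"""

from __future__ import annotations

import io
import json
import logging
import zipfile
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .ehr_data import CLS_ID, PAD_ID, TokenizedSequence
from .nn import Tensor

IGNORE_ID = -100


@dataclass
class ModelConfig:
    vocab_size: int
    max_len: int = 128
    max_visits: int = 64
    d_model: int = 36
    n_heads: int = 5
    d_head: int = 36
    n_layers: int = 1
    d_ff: int = 144
    dropout: float = 0.1
    gru_hidden: int = 64

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if min(self.vocab_size, self.max_len, self.d_model, self.n_heads) < 1:
            raise ValueError("invalid model configuration")


@dataclass
class EncoderOutput:
    x1: Tensor  # (B, L, d) per-token representations
    attention: list[np.ndarray]  # per layer: (B, heads, L, L), rows sum to 1
    pad_mask: np.ndarray  # (B, L) True at padding


def pad_batch(
    seqs: Sequence[TokenizedSequence] | Sequence[tuple[np.ndarray, np.ndarray]],
    max_len: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad token-id and visit-number tracks into dense (B, L) arrays.

    Sequences longer than `max_len` keep their *most recent* tokens (the
    [CLS] is re-attached at the front).
    """
    pairs = []
    for s in seqs:
        if isinstance(s, TokenizedSequence):
            ids, nums = np.asarray(s.token_ids), np.asarray(s.visit_numbers)
        else:
            ids, nums = np.asarray(s[0]), np.asarray(s[1])
        if max_len is not None and len(ids) > max_len:
            ids = np.concatenate([[CLS_ID], ids[-(max_len - 1) :]])
            nums = np.concatenate([[0], nums[-(max_len - 1) :]])
        pairs.append((ids, nums))
    L = max(len(ids) for ids, _ in pairs)
    B = len(pairs)
    tok = np.full((B, L), PAD_ID, dtype=np.int64)
    vis = np.zeros((B, L), dtype=np.int64)
    for b, (ids, nums) in enumerate(pairs):
        tok[b, : len(ids)] = ids
        vis[b, : len(ids)] = nums
    return tok, vis


class TooBert(nn.Module):
    def __init__(self, cfg: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.code_emb = nn.Embedding(cfg.vocab_size, cfg.d_model, rng)
        self.visit_emb = nn.Embedding(cfg.max_visits + 1, cfg.d_model, rng)
        self._sin_table = nn.sinusoidal_table(cfg.max_visits + 1, cfg.d_model)
        self.emb_ln = nn.LayerNorm(cfg.d_model)
        self.emb_drop = nn.Dropout(cfg.dropout, rng)
        self.layers = [
            nn.TransformerEncoderLayer(
                cfg.d_model, cfg.n_heads, cfg.d_head, cfg.d_ff, cfg.dropout, rng
            )
            for _ in range(cfg.n_layers)
        ]
        self.mlm_out = nn.Linear(cfg.d_model, cfg.vocab_size, rng)
        self.too_out = nn.Linear(cfg.d_model, 1, rng)
        self.gru = nn.BiGRU(cfg.d_model, cfg.gru_hidden, rng)
        self.clf = nn.Linear(2 * cfg.gru_hidden, 1, rng)

    # -- forward pieces --------------------------------------------------
    def embed(self, token_ids: np.ndarray, visit_numbers: np.ndarray) -> Tensor:
        """X0[t] = E_code(token_t) + E_visit(vnum_t) + PE_sin(vnum_t)."""
        if visit_numbers.max(initial=0) > self.cfg.max_visits:
            raise ValueError(
                f"visit number {visit_numbers.max()} exceeds "
                f"max_visits={self.cfg.max_visits}"
            )
        x = (
            self.code_emb(token_ids)
            + self.visit_emb(visit_numbers)
            + Tensor(self._sin_table[visit_numbers])
        )
        return self.emb_drop(self.emb_ln(x))

    def encode(
        self, token_ids: np.ndarray, visit_numbers: np.ndarray
    ) -> EncoderOutput:
        if token_ids.shape[1] > self.cfg.max_len:
            raise ValueError(
                f"sequence length {token_ids.shape[1]} > max_len={self.cfg.max_len}"
            )
        pad_mask = token_ids == PAD_ID
        x = self.embed(token_ids, visit_numbers)
        attn = []
        for layer in self.layers:
            x = layer(x, pad_mask)
            attn.append(layer.attn.last_attention)
        return EncoderOutput(x, attn, pad_mask)

    # -- heads ------------------------------------------------------------
    def mlm_logits(self, out: EncoderOutput) -> Tensor:
        return self.mlm_out(out.x1)

    def mlm_loss(self, out: EncoderOutput, targets: np.ndarray) -> Tensor:
        """Mean NLL of the original token at supervised positions only."""
        logits = self.mlm_logits(out)
        lp = logits.log_softmax(axis=-1)
        b, t = np.nonzero(targets != IGNORE_ID)
        if b.size == 0:
            logging.getLogger(__name__).warning("MLM batch with no targets")
            return Tensor(0.0)
        picked = lp[b, t, targets[b, t]]
        return -picked.mean()

    def too_logit(self, out: EncoderOutput) -> Tensor:
        return self.too_out(out.x1[:, 0, :])  # [CLS] position

    def too_probability(self, out: EncoderOutput) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.too_logit(out).data[:, 0]))

    def bigru_logit(self, out: EncoderOutput) -> Tensor:
        mask = (~out.pad_mask).astype(float)
        h = self.gru(out.x1, mask)
        return self.clf(h)

    def downstream_probability(self, out: EncoderOutput) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.bigru_logit(out).data[:, 0]))

    # -- reporting / persistence ------------------------------------------
    def parameter_report(self) -> str:
        groups: dict[str, int] = {}
        for name, p in self.named_parameters():
            head = name.split(".")[0]
            groups[head] = groups.get(head, 0) + p.data.size
        lines = [f"{k:12s} {v:>9,d}" for k, v in sorted(groups.items())]
        lines.append(f"{'total':12s} {self.n_parameters():>9,d}")
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        """Single-file archive: JSON config header + named float64 tensors."""
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.json", json.dumps(asdict(self.cfg)))
            for name, p in self.named_parameters():
                buf = io.BytesIO()
                np.save(buf, p.data)
                zf.writestr(f"tensors/{name}.npy", buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "TooBert":
        with zipfile.ZipFile(path) as zf:
            cfg = ModelConfig(**json.loads(zf.read("config.json")))
            model = cls(cfg)
            state = {}
            for info in zf.namelist():
                if info.startswith("tensors/"):
                    name = info[len("tensors/") : -len(".npy")]
                    state[name] = np.load(io.BytesIO(zf.read(info)))
        model.load_state_dict(state)
        return model


def binary_cross_entropy_with_logits(logit: Tensor, labels: np.ndarray) -> Tensor:
    """Numerically stable BCE via a two-class log-softmax."""
    z = nn.concat([Tensor(np.zeros_like(logit.data)), logit], axis=-1)
    lp = z.log_softmax(axis=-1)
    y = np.asarray(labels).reshape(-1)
    rows = np.arange(y.size)
    return -lp[rows, y.astype(np.int64)].mean()


def extract_attention(
    model: TooBert, seq: TokenizedSequence, per_head: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Raw and display-normalized attention maps for one sequence.

    Returns (raw, normalized), each (n_layers, n_heads, L, L).  The display
    copy is min-max scaled to [0, 1] per head by default (per matrix when
    ``per_head`` is False); a constant map normalizes to all zeros.
    """
    was_training = model.training
    model.eval()
    tok, vis = pad_batch([seq])
    out = model.encode(tok, vis)
    model.train(was_training)
    raw = np.stack([a[0] for a in out.attention])  # (layers, heads, L, L)
    norm = raw.copy()
    if per_head:
        for l in range(norm.shape[0]):
            for h in range(norm.shape[1]):
                norm[l, h] = _minmax(norm[l, h])
    else:
        for l in range(norm.shape[0]):
            norm[l] = _minmax(norm[l])
    return raw, norm


def _minmax(a: np.ndarray) -> np.ndarray:
    lo, hi = a.min(), a.max()
    if hi - lo < 1e-12:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)
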