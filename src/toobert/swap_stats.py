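"""Temporal co-occurrence counts and conditional swap weights.

The trajectory-order objective needs to know which code transitions carry
directional information.  ``CCnt(c_i, c_j)`` counts, over all trajectories
in a pretraining corpus, occurrences of code ``c_i`` in a strictly later
visit than code ``c_j``.  The conditional code-swap weight

    CCS(c_i, c_j) = S(kind_i, kind_j) * max(CCnt(i,j) - CCnt(j,i), 0)
                    / (CCnt(i,j) + CCnt(j,i) + 1) + eps

turns the bidirectional transition graph into a unidirectional one (the max
keeps only the dominant direction) and normalizes by the total pair traffic
so the weight is a scale-free asymmetry score in [eps, 1+eps).  ``S``
rebalances diagnosis/medication pair types; ``eps`` keeps every pair
selectable.  The visit-level weight CVS(v_x, v_y) sums CCS(b, a) over codes
a in the earlier visit x and b in the later visit y.

The traffic-normalizing denominator and the exact form of the kind-pair
scaling are this package's own design choices (the qualitative
ingredients -- max-of-differences numerator, kind rebalancing, additive
floor -- are fixed); both are configurable and documented in
docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .ehr_data import CodeKind, Trajectory, Visit, Vocabulary

__all__ = [
    "PairCounts",
    "SwapWeights",
    "count_pairs",
    "compute_type_scaling",
    "compute_ccs",
    "compute_cvs",
    "export_ccs_heatmap",
]


@dataclass
class PairCounts:
    """Sparse ordered-pair counts keyed by (later_code_id, earlier_code_id)."""

    counts: dict[tuple[int, int], int]
    vocab: Vocabulary

    def __getitem__(self, pair: tuple[int, int]) -> int:
        return self.counts.get(pair, 0)


@dataclass
class SwapWeights:
    """CCS weights over ordered code-id pairs, with the epsilon floor.

    Pairs absent from ``ccs`` have weight exactly ``epsilon``.
    """

    ccs: dict[tuple[int, int], float]
    epsilon: float
    scaling: dict[tuple[CodeKind, CodeKind], float]
    vocab: Vocabulary
    symmetric_cvs: bool = False

    def weight(self, later_id: int, earlier_id: int) -> float:
        if later_id == earlier_id:
            return self.epsilon
        return self.ccs.get((later_id, earlier_id), self.epsilon)

    # -- persistence: sorted 3-column text table -------------------------
    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# epsilon\t{self.epsilon}\n")
            scale = ";".join(
                f"{a.value},{b.value}:{s}" for (a, b), s in sorted(self.scaling.items())
            )
            fh.write(f"# scaling\t{scale}\n")
            rows = sorted(
                self.ccs.items(), key=lambda kv: (-kv[1], kv[0])
            )
            for (i, j), w in rows:
                ci = self.vocab.id_to_code[i]
                cj = self.vocab.id_to_code[j]
                fh.write(f"{ci}\t{cj}\t{w:.8g}\n")

    @classmethod
    def load(cls, path: str | Path, vocab: Vocabulary) -> "SwapWeights":
        ccs: dict[tuple[int, int], float] = {}
        epsilon = 0.01
        scaling: dict[tuple[CodeKind, CodeKind], float] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("# epsilon"):
                    epsilon = float(line.split("\t")[1])
                elif line.startswith("# scaling"):
                    for item in line.split("\t")[1].strip().split(";"):
                        kinds, s = item.split(":")
                        a, b = kinds.split(",")
                        scaling[(CodeKind(a), CodeKind(b))] = float(s)
                elif line.strip():
                    ci, cj, w = line.split("\t")
                    ccs[(vocab.id_of(ci), vocab.id_of(cj))] = float(w)
        return cls(ccs, epsilon, scaling, vocab)


def count_pairs(corpus: Sequence[Trajectory], vocab: Vocabulary) -> PairCounts:
    """Count cross-visit ordered code-occurrence pairs over a corpus.

    For every trajectory and every pair of code occurrences in distinct
    visits with the first strictly earlier, increments
    ``CCnt(later_code, earlier_code)``.  Each occurrence pair counts once
    (multiplicity per occurrence, not per patient); same-code pairs are
    excluded.  Vectorized per trajectory.
    """
    if not corpus:
        raise ValueError("empty corpus")
    V = len(vocab)
    total = np.zeros(V * V, dtype=np.int64)
    for traj in corpus:
        ids: list[int] = []
        vnums: list[int] = []
        for visit in traj.visits:
            for tok in visit.codes:
                cid = vocab.id_of(tok.code)
                ids.append(cid)
                vnums.append(visit.index)
        if len(ids) < 2:
            continue
        c = np.asarray(ids)
        v = np.asarray(vnums)
        later = v[:, None] > v[None, :]  # occurrence row strictly later
        diff = c[:, None] != c[None, :]
        sel = later & diff
        if not sel.any():
            continue
        li, ei = np.nonzero(sel)
        keys = c[li] * V + c[ei]
        total += np.bincount(keys, minlength=V * V)
    nz = np.nonzero(total)[0]
    counts = {(int(k // V), int(k % V)): int(total[k]) for k in nz}
    return PairCounts(counts, vocab)


def compute_type_scaling(
    vocab: Vocabulary,
) -> dict[tuple[CodeKind, CodeKind], float]:
    """Kind-pair scaling factors S from corpus token shares.

    S(kind_i, kind_j) is the inverse of the relative token share of that
    kind pair, normalized so S(dx, dx) = 1; it compensates for the typical
    imbalance between diagnosis and medication code volumes.
    """
    kind_tokens = {CodeKind.DIAGNOSIS: 0, CodeKind.MEDICATION: 0}
    for code, n in vocab.counts.items():
        kind = vocab.kinds.get(code)
        if kind in kind_tokens:
            kind_tokens[kind] += n
    total = sum(kind_tokens.values())
    if total == 0:
        raise ValueError("vocabulary has no code counts")
    share = {k: n / total for k, n in kind_tokens.items()}
    dx = CodeKind.DIAGNOSIS
    base = share[dx] ** 2 if share[dx] > 0 else 1.0
    scaling = {}
    for a in (CodeKind.DIAGNOSIS, CodeKind.MEDICATION):
        for b in (CodeKind.DIAGNOSIS, CodeKind.MEDICATION):
            pair_share = share[a] * share[b]
            scaling[(a, b)] = base / pair_share if pair_share > 0 else 1.0
    return scaling


def compute_ccs(
    pc: PairCounts,
    epsilon: float = 0.01,
    scaling: dict[tuple[CodeKind, CodeKind], float] | None = None,
) -> SwapWeights:
    """Conditional code-swap weights from the pair-count table.

    Only pairs with a strictly positive asymmetry term are stored; all other
    pairs implicitly sit at the epsilon floor.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if scaling is None:
        scaling = compute_type_scaling(pc.vocab)
    ccs: dict[tuple[int, int], float] = {}
    for (i, j), nij in pc.counts.items():
        nji = pc[(j, i)]
        num = max(nij - nji, 0)
        if num == 0:
            continue
        ki = pc.vocab.kind_of_id(i)
        kj = pc.vocab.kind_of_id(j)
        s = scaling.get((ki, kj), 1.0)
        ccs[(i, j)] = s * num / (nij + nji + 1) + epsilon
    return SwapWeights(ccs, epsilon, scaling, pc.vocab)


def compute_cvs(weights: SwapWeights, v_x: Visit, v_y: Visit) -> float:
    """Visit-pair swap weight: summed CCS evidence that y's codes follow x's.

    ``v_x`` must precede ``v_y``.  One-way by default (CCS(later, earlier)
    only); set ``weights.symmetric_cvs`` to also add the reverse direction.
    """
    if v_x.index >= v_y.index:
        raise ValueError("v_x must precede v_y")
    vocab = weights.vocab
    xs = [vocab.id_of(t.code) for t in v_x.codes if t.code in vocab]
    ys = [vocab.id_of(t.code) for t in v_y.codes if t.code in vocab]
    total = 0.0
    for a in xs:
        for b in ys:
            total += weights.weight(b, a)
            if weights.symmetric_cvs:
                total += weights.weight(a, b)
    return total


def cvs_from_id_blocks(
    weights: SwapWeights, earlier_ids: Sequence[int], later_ids: Sequence[int]
) -> float:
    """CVS on raw token-id blocks (used by the corruption sampler)."""
    total = 0.0
    for a in earlier_ids:
        for b in later_ids:
            total += weights.weight(b, a)
            if weights.symmetric_cvs:
                total += weights.weight(a, b)
    return total


def export_ccs_heatmap(
    weights: SwapWeights, top_k: int = 20
) -> tuple[np.ndarray, list[str], list[tuple[str, str, float]]]:
    """Dense CCS matrix over the top-k most frequent codes.

    Returns (matrix, labels, top_pairs) with row = later code c_i and
    column = earlier code c_j; the diagonal (self pairs, undefined) is 0.
    Labels are ordered by descending corpus frequency.
    """
    if top_k < 2:
        raise ValueError("top_k must be >= 2")
    labels = weights.vocab.top_codes(top_k)
    idx = [weights.vocab.id_of(c) for c in labels]
    mat = np.zeros((len(idx), len(idx)))
    for r, i in enumerate(idx):
        for col, j in enumerate(idx):
            if i != j:
                mat[r, col] = weights.weight(i, j)
    pairs = sorted(
        (
            (weights.vocab.id_to_code[i], weights.vocab.id_to_code[j], w)
            for (i, j), w in weights.ccs.items()
        ),
        key=lambda t: -t[2],
    )
    return mat, labels, pairs[: top_k * 2]
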