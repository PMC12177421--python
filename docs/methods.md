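# Methods

This note documents the models, statistics, and synthetic-data design the
package implements, the tunable parameters that matter, and the numerical
choices made where the design was genuinely open.

## Data model

A trajectory is one patient's ordered sequence of visits; each visit is a
multiset of diagnosis and medication codes with optional length-of-stay
and date.  Codes are normalized by removing the dot separator and keeping
the first 4 characters (the clinically meaningful prefix of ICD/ATC
codes).  Codes seen fewer than `min_count` times in a corpus (default 50
at realistic scale; the synthetic experiments use 5–10 at their smaller
vocabularies) are dropped, and visits emptied by the filter are removed.
For event-stream inputs (flat CSV), visits are formed greedily: a visit
opens at its first event and absorbs every event up to `window_days`
(default 183, boundary inclusive) after that opening event.  Boundary
convention: an event exactly 183 days after the opener still joins the
visit; the first later event opens the next one.

Sequences are flattened as `[CLS] v₁ [SEP] v₂ [SEP] …` with a parallel
visit-number track: `[CLS]` carries visit number 0; each code and its
trailing `[SEP]` carry their visit's 1-based number.  Long sequences are
cut into visit-aligned sliding windows (never splitting a visit) with
stride equal to half the window in visits; windows keep their original
visit numbers, so a mid-history window remains recognizable as
mid-history.  The pretraining maximum length is the 0.7 quantile of the
tokenized lengths of the corpus.

## Conditional swap weights

`CCnt(c_i, c_j)` counts, over all trajectories, occurrence pairs where
`c_i` appears in a strictly later visit than `c_j`; every occurrence pair
counts once and same-code pairs are excluded.  The conditional code-swap
weight is

    CCS(i, j) = S(kind_i, kind_j) · max(CCnt(i,j) − CCnt(j,i), 0)
                / (CCnt(i,j) + CCnt(j,i) + 1) + ε .

Two elements of this closed form are this package's own reconstruction
(the published description fixes the max-of-differences numerator, a
kind-pair scaling factor, and the additive ε, but not the denominator or
the exact form of S):

* the denominator `CCnt(i,j) + CCnt(j,i) + 1` normalizes by total pair
  traffic, making the weight a scale-free asymmetry score in `[ε, 1+ε)`
  that is comparable across pairs and corpus sizes (the `+1` keeps it
  finite for unseen pairs);
* `S` is the inverse relative token share of the (kind_i, kind_j) pair,
  normalized so `S(dx, dx) = 1`, compensating the typical volume imbalance
  between diagnosis and medication codes.

ε defaults to 0.01.  The visit-level weight `CVS(v_x, v_y)` for
`x < y` sums `CCS(b, a)` over `a ∈ v_x`, `b ∈ v_y` — one-way by default
(the evidence that later-visit codes conditionally follow earlier-visit
codes); a `symmetric_cvs` switch adds the reverse direction for users who
prefer the symmetric reading.

## Corruption

MLM: each non-special token is selected independently with probability
0.15; a selected token becomes `[MASK]` with probability 0.8, a random
non-special code with 0.1, and stays unchanged (still supervised) with
0.1.  `[CLS]`/`[SEP]`/`[PAD]` are never corrupted.

Order permutation: a swap fraction `f` maps to `k = max(1, round(f·n/2))`
disjoint pairs over `n` code positions (code level) or `n` visits (visit
level) — i.e. `f` is the fraction of positions touched, and the minimum
of one pair guarantees every "permutated" sample differs from its source.
Code swaps exchange token values only; `[SEP]` positions and the
visit-number track are untouched.  Visit swaps exchange whole code blocks
between slots; contents move, slots do not, so the visit-number track is
re-derived with each slot keeping its number.  Conditional variants
sample pairs sequentially, proportional to `CCS(later, earlier)` (or
`CVS`) over pairs whose endpoints are still free; eligibility at code
level is restricted to occurrence pairs ordered later-after-earlier so a
swap destroys the observed direction.

## Model

* Embedding: code embedding + trainable visit-number embedding + fixed
  sinusoidal table, both temporal terms indexed by visit number (not token
  offset), then LayerNorm and dropout.
* Encoder: one post-norm transformer layer, 5 heads, each head using the
  full `d_k = d_v = 36` with a `5·36 → 36` output projection (the only
  reading on which all three published head dimensions are equal),
  feed-forward width 144, dropout 0.1, padding masked out of attention.
* Heads: MLM softmax over the vocabulary at every position; order head =
  binary classifier on the `[CLS]` representation; fine-tuning head =
  bidirectional GRU (64 hidden units per direction) over the encoder
  output, final states → sigmoid.
* Initialization: truncated normal, σ = 0.02 (BERT-family convention).
* With a realistic vocabulary (≈2,300 codes) the model has ≈2.5·10⁵
  parameters; `parameter_report()` prints the breakdown.

The network runs on `toobert.nn`, a small reverse-mode automatic
differentiation engine over NumPy arrays written for this package (tensor
ops, fused softmax/log-softmax, embedding gather, layer norm, multi-head
attention, GRU, Adam with coupled L2 weight decay).  Gradient correctness
is established by finite-difference checks in the test suite.  All
randomness flows through seeded `numpy` generators, so training runs are
bit-reproducible; checkpoints are zip archives of named float64 tensors
plus a JSON config and round-trip exactly.

## Training

Pretraining alternates strictly between MLM and order-objective batches;
each step optimizes `W_obj · L_obj` for its batch's objective (defaults
`W_MLM = W_TOO = 1`, configurable).  A 10% monitor split tracks both
losses and order-detection accuracy; training stops when the weighted
monitor loss improves by less than 0.1% for 3 consecutive epochs
(operationalizing "train until the loss curve stabilizes") or at the
epoch cap.  Published optimizer settings (Adam, lr 7·10⁻⁵, weight decay
0.015, dropout 0.1) are the defaults; the desk-scale synthetic
experiments use lr 5·10⁻³ and weight decay 10⁻⁴ because at a few hundred
training steps the published settings leave the order head pinned at its
weight-decay equilibrium before it can learn (documented sizing choice,
set in the experiment configs, not in the library defaults).

Fine-tuning splits the labeled cohort into 5 label-stratified folds:
train on 4, early-stop on the held-out fold's AUC (patience in
evaluations), restore the best state, and report mean ± SD of per-fold
test AUC.  Layer-wise learning-rate decay assigns level 0 to embeddings,
levels 1..L to encoder layers, and the top level to heads; level `l`
trains at `lr · f^(T−l)` (default factor 0.9; the synthetic benchmark
uses 0.5 to preserve pretrained features harder).  AUC uses the rank
statistic with tie correction (scikit-learn), cross-checked against an
independent Mann-Whitney implementation in the tests.

## Cohorts

Code-onset cohorts (heart failure, Alzheimer): a patient with any target
code is a positive whose history is truncated strictly before the first
visit containing a target code (a target in visit 1 leaves no history and
drops the patient); patients without the code are negatives with full
history; treatment medication prefixes can be stripped from histories to
block leakage through prescriptions; a minimum-visit filter applies to
the final history, and per-class mean visit counts are reported so
length bias between classes is visible (an optional greedy trimming
routine can equalize them).  Default target prefixes (HF: `I50`/`428`;
AD: `G30`/`3310`; HF-treatment ATC: `C03`/`C07`/`C09`) are standard
reconstructions and fully configurable.  Prolonged length of stay: index
visit = last visit; label = stay strictly longer than 5 days; histories
are the preceding visits; trajectories with fewer than 3 visits are
excluded.

## Synthetic generator

The generator emulates the statistical structure that matters to
order-aware pretraining; codes are included per visit by independent
Bernoulli draws whose log-odds add up:

* Zipf(1.1) base rates over 60 diagnosis + 20 medication codes, scaled to
  an expected `5 + 0.5·(j−1)` codes at visit `j` (progression);
* 20 planted directed transitions (a → b) among diagnosis codes: once `a`
  has occurred, `b`'s odds in later visits are multiplied by the lift
  (default 8);
* persistence: a code already in the history has its re-inclusion odds
  multiplied by 6 (chronic conditions recur);
* indication structure: each medication maps to a diagnosis of similar
  frequency and is rare (odds × 0.04) until its indication has appeared,
  common afterwards (odds × 12) — prescriptions follow diagnoses;
* care-phase typing: code `i` prefers phase `φ_i ∈ [0,1]` and its
  log-odds at relative position `pos = (j−1)/(O−1)` gain
  `−κ(pos − φ_i)²` with κ = 12, normalized per visit so typing
  redistributes which codes occur without thinning visits.  Intake-type
  codes cluster early and follow-up codes late, which is what makes true
  visit order recognizable; because the position is relative, adjacent
  visits in long trajectories differ little in phase, so local order cues
  weaken as trajectories grow — the long-regime preset is intrinsically
  harder for code-level order detection than the short regime.

Planted pairs are vertex-disjoint (each code joins exactly one pair, so
pairwise asymmetry is identifiable without chain confounding) and pair
codes a moderate phase apart oriented along the gradient: close enough
that onset order given both codes remains genuinely variable, far enough
that the planted direction agrees with the natural phase direction.
Working in odds space makes the planted lift exactly recoverable as a
Mantel-Haenszel odds ratio stratified by (visit index, trajectory length,
prior occurrence of the target code); `estimate_lift` implements that
estimator.

Two presets mirror the acute-inpatient vs long-cohort contrast: "short"
(mean 2.5 visits) and "long" (mean 18 visits, gentler progression).

Labeled cohorts: onset risk is logistic in the number of trigger pairs
with both codes present and the number whose *onset order* (first
occurrence of `a` before first occurrence of `b`) is canonical
(defaults: 8 trigger pairs drawn from the most frequent planted pairs,
β₀ = −2, β_presence = 0, β_order = 3).  Positives receive a terminal
visit containing the synthetic target code, so truncation at first target
occurrence recovers exactly the risk-bearing history, and positives and
negatives have identical visit-count distributions by construction (no
length bias).  The generating logit doubles as a Bayes-ceiling oracle
classifier.

What the generator does **not** emulate: clinical semantics of codes,
calendar seasonality, inter-visit time irregularity (order only), coding
noise/miscoding, demographic covariates, and site effects.  Passing tests
therefore demonstrate correctness and qualitative behaviour of the
machinery, not clinical performance.

## Canonical experiments and problem sizes

`toobert.experiments` freezes three desk-scale recipes (all deterministic
per seed, one CPU core):

* **Sign recovery** — 2,000 long-regime patients, lift 8; fraction of the
  20 planted directions with `CCS(b,a) > CCS(a,b)`.
* **Learnability curve** — 2,000 short-regime patients; alternating
  MLM+TOO(RVS) pretraining (≤40 epochs with plateau stop); detection
  accuracy on 500 held-out full trajectories over swap fractions
  0.2–1.0, plus the untrained-model baseline (chance).
* **Headroom benchmark** — 1,200 labeled short-regime patients split
  50/20/30 (pretrain/fine-tune/test); MLM-only vs alternating
  MLM+TOO(CCS) at loss weights 1 : 0.5 and swap fraction 0.4; both
  encoders fine-tuned (5 stratified folds, lr 1.5·10⁻³, layer decay 0.5,
  ≤18 epochs, patience 5) on the full fine-tuning cohort and on 50%/20%
  stratified subsets; mean test AUC per variant.

The headroom benchmark is the package's hardest property.  At this
problem size the AUC contrast between the two pretraining variants is of
the same order as the fold-to-fold noise, so single-seed comparisons are
not meaningful and the benchmark reports multi-seed summaries.  Detecting
the contrast reliably needs corpora and fine-tuning budgets several times
larger per seed; the shipped sizes favour a complete, reproducible
multi-seed battery over a larger but partial one, and the benchmark
reports whatever sign and magnitude the data deliver.

## Known limitations

* The CCS denominator and the kind-pair scaling are reconstructions (see
  above); both are configurable, and the persisted weight tables record
  ε and S so any alternative can be swapped in.
* The NumPy engine is single-threaded and unsuitable for corpora beyond
  tens of thousands of visits; it exists to make the method fully
  testable without a deep-learning runtime.
* Visit-level swap sampling enumerates visit pairs, which is quadratic in
  trajectory length; acceptable at ≤ ~40 visits.
* The order-benefit of conditional-swap pretraining on downstream AUC is
  a small effect at desk scale (see above) — the benchmark measures it
  honestly rather than guaranteeing it.
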