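# Methods

## Problem setting

The package predicts a binary patient outcome from a longitudinal sequence
of medical events (OMOP-style concept occurrences with calendar dates, as
found in administrative claims).  Each patient has an *index day* (time 0):
events strictly before it form the observation window from which features
are drawn, and the outcome refers to the period after it.  Accuracy is
measured by AUC — the probability that a random case outscores a random
non-case — computed as the rank-based Mann–Whitney statistic with midrank
tie handling.

## Data preparation

Events are tokenized against a dictionary of the K most frequent concepts
in the build corpus (K = 10,000 by default), with two reserved tokens:
PAD = 0 and EOS = 1.  Per patient, the most recent `max_len − 1` in-dictionary
events before time 0 are kept (default `max_len` = 768 including EOS),
EOS is appended and the sequence is front-padded with PAD.  The EOS token
guarantees a non-empty input for patients with no prior observations.
Times are carried as `days_before_index` (t in the decay model); PAD and
EOS positions hold the sentinel 0, EOS is treated as a real pooling
candidate with t = 0, and PAD is masked out of every computation.

Three additional mechanisms follow standard practice for this class of
models:

* **Whitelist** (evaluation-time): test-sample tokens whose *training*-corpus
  frequency is below a threshold (default 50) are removed — their
  embeddings are essentially untrained and would corrupt predictions.  The
  dictionary carries training counts so no test information is used.
* **Event dropout** (training-time): each real token is independently
  dropped with probability 0.5.  Claims-based outcomes hinge on a few
  crucial events, so this aggressive augmentation regularizes without
  destroying signal.
* **Deterministic tie-breaks**: events sort by (day, concept_id); dictionary
  rank ties break lexically by concept id.  Every ordering in the package
  is reproducible across runs and platforms.

Calendar dates are converted to Julian day numbers with the
Fliegel–Van Flandern integer algorithm.  Only day *differences* enter any
model, so the epoch convention is immaterial; the conversion is tested
against an independent proleptic-Gregorian day count.

## Partitioned preprocessing

Records are hashed by person id (MD5 prefix, or FNV-1a; never a
per-process randomized hash) into N partitions (default 1000), so all data
of one patient lands in exactly one partition and each partition fits in
memory.  Partitions are reduced independently — grouped by patient, sorted
by time — and persisted in a length-prefixed little-endian binary layout
with optional whole-file deflate and a plain-text JSON manifest.
Operations are pure per partition; parallelism is a caller's choice, not a
primitive.

## Models

All architectures share an embedding table e(·) mapping tokens to dense
vectors (width `d_hidden`, 1024 at production scale), followed by an
encoder and a readout that produces one history vector f(S), and a linear
head yielding the outcome logit.

* **Max-pool baseline**: identity encoder; f(S) is the coordinate-wise
  maximum of the event embeddings (PAD masked).  Order-free by
  construction.
* **Recurrent**: stacked LSTM over the embedded sequence (forget-gate bias
  1, PAD positions skipped by carrying state through), read out by masked
  pooling or the EOS-position state.
* **Attention**: post-norm transformer blocks (multi-head scaled
  dot-product attention with PAD key masking, 2× feed-forward, residual +
  layer norm).  Depth 0 reduces exactly to the baseline.

Mean- and sum-pool readouts are retained as configurable alternatives for
pooling comparisons; max is the default.  The EOS readout is forbidden for
the baseline, whose identity encoder leaves the EOS position without any
history.

### Time decay

Each event's feature vector is down-weighted as f′(event) = f(event)·e^(−a·t),
where t is the event's age in days at time 0 and a = ln2 / half-life.  One
max-pooled channel per half-life — default (∞, 50, 100) days, i.e. rates
(0, ln2/50, ln2/100) — is concatenated, giving a 3·`d_hidden` history
vector (3072 at width 1024).  The ∞ channel makes the decay model a strict
superset of the baseline.  EOS carries t = 0 so empty histories stay
well-defined.

### Time encoding

Alternatively, the absolute Julian day is passed through a sinusoidal
positional-style encoding (`enc_width` geometrically spaced sin/cos pairs,
default width `d_hidden`), reduced by a learned linear map to `d_time`
(default 64) and concatenated to the concept embedding before pooling.
The widths are exposed as configuration because only the mechanism, not
the sizes, is canonical.

## Contrastive pre-training

The pre-training assumption: given an observed history, some future events
are more likely than others.  For a timeline of n events, each prefix
S_i (i = 1..n−1) yields one task — the whole sequence yields none, since
no event remains to hold out.  The positive P_i is drawn uniformly from
the held-out suffix; the negative N_i is a dictionary concept sampled
uniformly among concepts *absent from the suffix* (the suffix is the
outcome window; the prefix is not excluded).  Compatibility is scored by
dot products with the history encoding:

    logit₊ = e(P_i)·f(S_i),   logit₋ = e(N_i)·f(S_i)
    (Pr₊, Pr₋) = softmax(logit₊, logit₋)
    L_i = −[log Pr₊ + log(1 − Pr₋)] = −2·log Pr₊

The algebraic identity (Pr₋ = 1 − Pr₊) means the loss depends on the
logits only through their difference; it is computed as
2·softplus(logit₋ − logit₊) via log-sum-exp, stable for logits up to ~1e3.
A sequence contributes the *sum* of its per-prefix losses (dense
prediction — every prefix generates gradients); batches average the
per-sequence sums so long records do not dominate.

A cosine-similarity alternative, −cos(e(P_i), f(S_i)) + cos(e(N_i), f(S_i)),
is provided for comparison (bounded in [−2, 2]; zero-norm vectors are
assigned cosine 0 for continuity at initialization).  The second term uses
the *negative* event — the only reading under which the expression defines
a contrast.

This pairwise formulation avoids the `d_hidden × d_dict` weight matrix of
a 1-out-of-N prediction head (10⁷ weights at 1000 × 10,000), which would
dwarf the rest of the network and invite overfitting.  Pre-training
requires f(·) and e(·) to share a dimension, so it runs with the
single-channel (time-free) encoder; the max-pool encoder admits an exact
vectorization of all prefix encodings via a running maximum, and the LSTM's
hidden states are already per-prefix.

Progress is tracked by **pair-ranking accuracy** — the fraction of held-out
tasks with logit₊ > logit₋ — which is 0.5 for an untrained model.

## Two-stage fine-tuning

Initializing the downstream embedding from a pre-trained checkpoint and
training naively converges to slightly worse AUC than scratch training
(though much faster), so fine-tuning is two-staged: phase 1 freezes the
embedding (bit-exactly — the optimizer skips both the update and the
moment bookkeeping) and trains the rest at the regular learning rate for 5
epochs; phase 2 trains everything at 1/10 of that rate.  Checkpoints carry
a fingerprint of the concept dictionary and are refused when it does not
match.  The downstream loss is binary cross-entropy on the single logit,
in the stable softplus(z) − y·z form; the head bias is initialized at the
empirical log-odds of the training prevalence, so early epochs learn
discrimination instead of spending steps fitting the intercept (without
this, the first epochs can transiently anti-correlate the scores).

Cohorts are split 75/25 (the referenced evaluation framework's convention;
configurable), stratified, after subsampling to at most 100,000 patients,
all deterministically per seed.

## Numerical implementation

No deep-learning framework is used: the models run on a small reverse-mode
automatic-differentiation engine over numpy arrays written for this
package (`claimseq.autodiff`), providing broadcast arithmetic, matmul,
pointwise nonlinearities, masked max / running-max reductions (gradients
routed to the earliest argmax — a valid subgradient choice), gather with
scatter-add backward, and an Adam optimizer (β = 0.9/0.999, ε = 1e-8) with
per-step parameter freezing.  Every operator is verified against central
finite differences.  Masked pooling uses −1e30 as the neutral element;
parameters initialize symmetric-uniform scaled by 1/√fan-in from a fixed
seed.  Layer norm uses ε = 1e-6; cosine norms are floored at 1e-12 in the
vectorized loss.

## Synthetic data generator

No public claims corpus exists at this scale, so all benchmarks run on a
built-in simulator with planted, analytically known structure:

* each patient independently activates each of 20 latent disease
  processes (probability 0.3); a process emits its 10 private concepts as
  a homogeneous point process (3 events/year while active) over a 5-year
  span, on top of patient-wide background noise (6 events/year over 300
  background concepts); 500 concepts and 2,000 patients by default;
* the first 3 processes are *risk* processes and activate with probability
  0.9 — they are common, so their mere presence is weakly informative and
  the outcome signal is genuinely temporal;
* the outcome is Bernoulli with logit β·Σ e^(−a·t) over risk-concept
  occurrences at lags t (β = 2, half-life 50 days), with the intercept
  calibrated by root-finding so the population prevalence hits the target
  (0.3);
* a Monte-Carlo Bayes oracle scores patients by their true outcome
  probability; its AUC (≈0.86 at the defaults) is the ceiling used to
  calibrate benchmark margins, and no fitted model may exceed it beyond
  noise.

The latent-process co-occurrence makes future events predictable from
history (what pre-training must learn), and the 50-day half-life makes
recency the dominant outcome signal (what the decay channels must find).

What the simulator does **not** emulate: bursty or clinically structured
visit patterns, concept hierarchies, coding-practice drift, censoring or
death, and realistic marginal frequency distributions.  Passing benchmarks
therefore demonstrate that the implementation learns the structures it
targets, not that the paper-scale accuracy ranking transfers to any real
claims database.

## Benchmark problem sizes

The standing benchmarks (also recomputed by `scripts/acceptance.py`) use
desk-scale sizes chosen for minutes-scale single-CPU runs while keeping
all comparisons statistically comfortable: hidden width 32, observation
windows truncated to 256 tokens (128 for pre-training), 2,000 patients for
the decay benchmark (1,500/500 split), a 600-patient generic corpus for
pre-training and a disjoint 500-patient downstream cohort, learning rate
3e-3, 12 downstream epochs (5+5 for the two-stage schedule), 4
pre-training epochs.  Margins in the acceptance checks (e.g. decay beats
no-time by ≥0.05 AUC; pair-ranking accuracy >0.65) were calibrated once
against the Bayes oracle and multi-seed runs, then frozen.

## Known limitations

* The engine is CPU-only and unbatched across partitions; production-scale
  runs (10⁴ concepts, width 1024, millions of patients) are out of reach —
  the defaults express the intended scale, not a tested one.
* LSTM and transformer variants are implemented and verified at small
  scale but are not tuned; as comparators they use modest depths.
* Negative sampling excludes only suffix concepts; with very short
  dictionaries the rejection loop assumes the suffix never covers the
  whole vocabulary.
* The bucketed baseline features use cumulative lookback windows (an event
  within 30 days also sets the 180/365/∞ slots), the standard construction
  in patient-level-prediction pipelines; disjoint windows would be an
  equally defensible reading.
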