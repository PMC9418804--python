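# claimseq

Patient-level outcome prediction from longitudinal medical-event sequences
(claims / EHR extracts in OMOP-style form): a max-pool concept-embedding
classifier with exponential **time-decay channels**, **contrastive
future-event pre-training** with two-stage fine-tuning, PLP-style tree
baselines, a patient-hashed map-reduce preprocessor, and a synthetic
claims simulator with planted temporal structure so the whole stack is
testable without access to proprietary data.

Intended users: researchers in observational health / biostatistics who
want a transparent, dependency-light reference implementation of
time-aware sequence models for binary patient outcomes.

## The models

Each patient contributes a time-ordered sequence of concept tokens cut at
an index day (time 0).  Tokens are embedded (e(·), width D), and a history
vector f(S) is read out by coordinate-wise max pooling — optionally through
exponential decay channels: every event embedding is down-weighted by

    f′(event) = f(event) · e^(−a·t),     a = ln 2 / half-life,

with t the event's age in days at time 0, one channel per half-life
(∞, 50, 100 days by default, so D = 1024 gives a 3072-dim history vector).
LSTM and transformer encoders, an absolute-date sinusoidal time encoding,
and mean/sum pooling are available as comparators.  A linear head maps
f(S) to the outcome logit; accuracy is Mann–Whitney AUC.

Pre-training pairs each timeline prefix S_i with a true future event P_i
and a random negative N_i and minimizes the softmax-pair cross-entropy

    L_i = −[log Pr₊ + log(1−Pr₋)],   (Pr₊,Pr₋) = softmax(e(P_i)·f(S_i), e(N_i)·f(S_i)),

summed over all n−1 prefixes (a cosine-similarity variant is included).
Fine-tuning is two-staged: 5 epochs with the embedding frozen at the
regular learning rate, then everything at 1/10 of it.

See `docs/methods.md` for assumptions, parameters and numerical details.
The neural stack runs on a small built-in numpy autodiff engine — no
deep-learning framework required.

## Worked example

```bash
python examples/04_decay_model.py
```

simulates a 1,000-patient cohort whose outcome depends on risk-concept
exposure decaying with a 50-day half-life, then trains the time-blind
baseline and the decay-channel model:

```
time_mode=none   history dim   32  test AUC 0.548
time_mode=decay  history dim   96  test AUC 0.798
```

The time-blind model is near chance — risk concepts are present in almost
every history, so *whether* they occur says little — while the decay
channels recover most of the Bayes-oracle ceiling (≈0.86) from *when* they
occurred.  The other examples cover simulation (`01`), partitioned
preprocessing (`02`), tree baselines on presence vs time-bucket features
(`03`), and pre-training + two-stage fine-tuning vs scratch training
(`05`), each printing the quantities it computes.  A thin CLI mirrors the
pipeline stages (`claimseq simulate | partition | build-dict | pretrain |
finetune | baseline | evaluate`).

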