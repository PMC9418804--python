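"""Contrastive history-vs-future-event pre-training.

The pre-training assumption: given any observed history, some future events
are more likely than others.  For a timeline of n events, every prefix
S_i (i = 1..n−1) produces one task: a positive event P_i drawn from the
held-out suffix, and a negative event N_i whose concept is sampled from the
dictionary among concepts absent from the suffix.  Compatibility is the
dot product between the history encoding f(S_i) and the concept embedding
e(·); the two logits go through a two-way softmax and the per-task loss is

    L_i = −[log Pr₊ + log(1 − Pr₋)]  =  −2·log Pr₊ ,

summed over all prefixes of a sequence (dense prediction: every prefix
contributes gradients).  A cosine-similarity alternative,
−cos(e(P_i), f(S_i)) + cos(e(N_i), f(S_i)), is provided for comparison.
This pairwise formulation avoids the d_hidden × d_dict weight matrix a
1-out-of-N prediction head would need.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .events import N_RESERVED, ConceptDictionary, PatientTimeline
from .models import EncoderConfig, SequenceModel, save_checkpoint

__all__ = [
    "PretrainTask",
    "PairLoss",
    "PretrainConfig",
    "sample_tasks",
    "pair_logits",
    "pair_loss_ce",
    "pair_loss_cos",
    "sequence_loss",
    "pair_ranking_accuracy",
    "run_pretraining",
]


@dataclass(frozen=True)
class PretrainTask:
    """One (history prefix, positive future event, negative event) triple.

    ``prefix_tokens`` are the first i concept tokens of the timeline;
    ``positive`` is a token occurring in the held-out suffix; ``negative``
    is a dictionary token absent from the suffix.
    """

    prefix_tokens: np.ndarray
    positive: int
    negative: int

    @property
    def i(self) -> int:
        return len(self.prefix_tokens)


@dataclass(frozen=True)
class PairLoss:
    logit_pos: float
    logit_neg: float
    pr_pos: float
    pr_neg: float
    loss: float


def tokenize_timeline(
    timeline: PatientTimeline, dictionary: ConceptDictionary
) -> np.ndarray:
    """In-dictionary concept tokens of a timeline, in time order."""
    toks = [dictionary.tokenize(ev.concept_id) for ev in timeline.events]
    return np.array([t for t in toks if t is not None], dtype=np.int64)


def sample_tasks(
    timeline: PatientTimeline | np.ndarray,
    rng: np.random.Generator,
    dictionary: ConceptDictionary,
) -> list[PretrainTask]:
    """One task per prefix i = 1..n−1 of a timeline.

    The whole sequence itself yields no task (no event left to hold out);
    a timeline with fewer than two in-dictionary events yields none.
    Positives are uniform over suffix events; negatives are uniform over
    dictionary concept tokens not occurring in the suffix (rejection
    sampling against the suffix concept set).  Deterministic given the rng
    state.
    """
    if isinstance(timeline, PatientTimeline):
        tokens = tokenize_timeline(timeline, dictionary)
    else:
        tokens = np.asarray(timeline, dtype=np.int64)
    n = len(tokens)
    tasks: list[PretrainTask] = []
    n_concepts = dictionary.size
    for i in range(1, n):
        suffix = tokens[i:]
        present = set(int(t) for t in suffix)
        positive = int(suffix[rng.integers(len(suffix))])
        if len(present) >= n_concepts:
            raise ValueError("suffix covers the whole dictionary; no negative exists")
        while True:
            negative = int(rng.integers(n_concepts)) + N_RESERVED
            if negative not in present:
                break
        tasks.append(
            PretrainTask(prefix_tokens=tokens[:i], positive=positive, negative=negative)
        )
    return tasks


def pair_logits(
    embedding_table: np.ndarray, history_vector: np.ndarray, task: PretrainTask
) -> tuple[float, float]:
    """(dot(e(P), f(S)), dot(e(N), f(S))) for one task."""
    emb = np.asarray(embedding_table, dtype=np.float64)
    f = np.asarray(history_vector, dtype=np.float64)
    if emb.shape[1] != f.shape[-1]:
        raise ValueError(
            f"embedding dim {emb.shape[1]} != history dim {f.shape[-1]}: "
            "pre-training requires f(.) to match e(.)"
        )
    return float(emb[task.positive] @ f), float(emb[task.negative] @ f)


def pair_loss_ce(logit_pos: float, logit_neg: float) -> PairLoss:
    """Two-way-softmax cross-entropy of a positive/negative logit pair.

    Pr₊ and Pr₋ sum to 1, so the loss −[log Pr₊ + log(1 − Pr₋)] reduces to
    −2·log Pr₊ and depends on the logits only through their difference.
    Computed with log-sum-exp so logits of magnitude ~1e3 stay finite.
    """
    if not (np.isfinite(logit_pos) and np.isfinite(logit_neg)):
        raise ValueError("logits must be finite")
    d = logit_pos - logit_neg
    pr_pos = float(1.0 / (1.0 + np.exp(-np.clip(d, -700, 700))))
    loss = float(2.0 * np.logaddexp(0.0, -d))
    return PairLoss(
        logit_pos=float(logit_pos),
        logit_neg=float(logit_neg),
        pr_pos=pr_pos,
        pr_neg=1.0 - pr_pos,
        loss=loss,
    )


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0  # continuity convention for zero-norm vectors
    return float(a @ b / (na * nb))


def pair_loss_cos(
    embedding_table: np.ndarray, history_vector: np.ndarray, task: PretrainTask
) -> float:
    """Cosine-similarity pair loss −cos(e(P), f(S)) + cos(e(N), f(S)).

    Bounded in [−2, 2]; zero-norm vectors contribute cosine 0.
    """
    emb = np.asarray(embedding_table, dtype=np.float64)
    f = np.asarray(history_vector, dtype=np.float64)
    return -_cosine(emb[task.positive], f) + _cosine(emb[task.negative], f)


def sequence_loss(
    timeline: PatientTimeline | np.ndarray,
    model: SequenceModel,
    rng: np.random.Generator,
    dictionary: ConceptDictionary,
    loss: str = "ce",
) -> float:
    """Sum of per-prefix pair losses over all n−1 prefixes of one timeline.

    Reference (non-differentiable) path used for evaluation and testing;
    training uses the vectorized batch loss inside :func:`run_pretraining`.
    """
    if loss not in ("ce", "cosine"):
        raise ValueError(f"unknown loss {loss!r}")
    tasks = sample_tasks(timeline, rng, dictionary)
    emb = model.params["emb"].data
    total = 0.0
    for task in tasks:
        f = model.encode_history(
            task.prefix_tokens[None, :], np.zeros((1, task.i))
        ).data[0]
        if loss == "ce":
            lp, ln = pair_logits(emb, f, task)
            total += pair_loss_ce(lp, ln).loss
        else:
            total += pair_loss_cos(emb, f, task)
    return total


@dataclass(frozen=True)
class PretrainConfig:
    encoder: EncoderConfig = field(
        default_factory=lambda: EncoderConfig(architecture="maxpool_baseline")
    )
    loss: str = "ce"  # or "cosine"
    epochs: int = 5
    batch_size: int = 32
    lr: float = 1e-3
    max_len: int = 768
    seed: int = 0
    heldout_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.loss not in ("ce", "cosine"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.encoder.time_mode != "none":
            raise ValueError(
                "pre-training requires f(.) with the embedding's dimension; "
                "use time_mode='none'"
            )


def _pack_token_batch(seqs: list[np.ndarray], max_len: int) -> np.ndarray:
    """Back-pad variable-length token sequences into a (B, L) PAD matrix."""
    seqs = [s[-max_len:] for s in seqs]
    length = max(len(s) for s in seqs)
    out = np.zeros((len(seqs), length), dtype=np.int64)  # PAD = 0
    for r, s in enumerate(seqs):
        out[r, : len(s)] = s
    return out


def _dense_pair_arrays(
    tokens: np.ndarray, rng: np.random.Generator, n_concepts: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-position positive/negative tokens and the valid-prefix mask.

    Position j (0-based) carries the task for prefix i = j+1; valid while
    j+1 < n.  Negatives are rejection-sampled outside the suffix concepts.
    """
    b_sz, length = tokens.shape
    lengths = (tokens != 0).sum(axis=1)
    pos = np.full((b_sz, length), 2, dtype=np.int64)
    neg = np.full((b_sz, length), 2, dtype=np.int64)
    valid = np.zeros((b_sz, length), dtype=bool)
    for r in range(b_sz):
        n = int(lengths[r])
        suffix_sets: dict[int, set[int]] = {}
        present: set[int] = set()
        for j in range(n - 1, 0, -1):  # suffix after prefix length j
            present.add(int(tokens[r, j]))
            suffix_sets[j] = set(present)
        for j in range(n - 1):
            i = j + 1
            suffix = tokens[r, i:n]
            pos[r, j] = suffix[rng.integers(len(suffix))]
            sset = suffix_sets[i]
            while True:
                cand = int(rng.integers(n_concepts)) + N_RESERVED
                if cand not in sset:
                    break
            neg[r, j] = cand
            valid[r, j] = True
    return pos, neg, valid


def _batch_loss(
    model: SequenceModel,
    tokens: np.ndarray,
    pos: np.ndarray,
    neg: np.ndarray,
    valid: np.ndarray,
    loss: str,
) -> Tensor:
    """Mean over sequences of the within-sequence sum of pair losses."""
    prefix_enc = model.encode_prefixes(tokens, np.zeros_like(tokens))  # [B,L,D]
    e_pos = model.embed(pos)
    e_neg = model.embed(neg)
    if loss == "ce":
        lp = (prefix_enc * e_pos).sum(axis=-1)
        ln = (prefix_enc * e_neg).sum(axis=-1)
        per = (ln - lp).softplus() * 2.0
    else:
        fnorm = ((prefix_enc * prefix_enc).sum(axis=-1) + 1e-12).sqrt()
        pnorm = ((e_pos * e_pos).sum(axis=-1) + 1e-12).sqrt()
        nnorm = ((e_neg * e_neg).sum(axis=-1) + 1e-12).sqrt()
        cos_p = (prefix_enc * e_pos).sum(axis=-1) / (fnorm * pnorm)
        cos_n = (prefix_enc * e_neg).sum(axis=-1) / (fnorm * nnorm)
        per = cos_n - cos_p
    masked = ad.where(valid, per, Tensor(0.0))
    return masked.sum(axis=1).mean()


def pair_ranking_accuracy(
    model: SequenceModel,
    timelines: Sequence[PatientTimeline | np.ndarray],
    dictionary: ConceptDictionary,
    seed: int = 0,
) -> float:
    """Fraction of sampled tasks with logit₊ > logit₋ (0.5 = chance)."""
    rng = np.random.default_rng(seed)
    emb = model.params["emb"].data
    wins = 0
    total = 0
    for tl in timelines:
        tokens = (
            tokenize_timeline(tl, dictionary)
            if isinstance(tl, PatientTimeline)
            else np.asarray(tl, dtype=np.int64)
        )
        if len(tokens) < 2:
            continue
        batch = tokens[None, :]
        prefix_enc = model.encode_prefixes(batch, np.zeros_like(batch)).data[0]
        for task in sample_tasks(tokens, rng, dictionary):
            f = prefix_enc[task.i - 1]
            lp, ln = pair_logits(emb, f, task)
            wins += int(lp > ln)
            total += 1
    return wins / total if total else float("nan")


def run_pretraining(
    timelines: Sequence[PatientTimeline | np.ndarray],
    dictionary: ConceptDictionary,
    config: PretrainConfig = PretrainConfig(),
    checkpoint_path=None,
):
    """Optimize embedding + encoder on dense per-prefix contrastive tasks.

    A held-out fraction of timelines is set aside for pair-ranking
    evaluation; positives/negatives are re-sampled every epoch.  Returns
    ``(model, log)`` where the log holds one record per epoch (loss and
    held-out pair-ranking accuracy); optionally writes a reloadable
    checkpoint.  Deterministic given the config seed.
    """
    token_seqs = [
        tokenize_timeline(tl, dictionary) if isinstance(tl, PatientTimeline) else
        np.asarray(tl, dtype=np.int64)
        for tl in timelines
    ]
    token_seqs = [s for s in token_seqs if len(s) >= 2]
    if not token_seqs:
        raise ValueError("corpus has no timeline with >= 2 in-dictionary events")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(token_seqs))
    n_held = max(1, int(round(config.heldout_fraction * len(token_seqs))))
    held = [token_seqs[i] for i in order[:n_held]]
    train = [token_seqs[i] for i in order[n_held:]] or held

    model = SequenceModel(config.encoder, dictionary.n_tokens, seed=config.seed)
    opt = Adam(model.params, lr=config.lr)
    log: list[dict] = []
    for epoch in range(config.epochs):
        epoch_rng = np.random.default_rng((config.seed, epoch, 7919))
        perm = epoch_rng.permutation(len(train))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(train), config.batch_size):
            batch_seqs = [train[i] for i in perm[start : start + config.batch_size]]
            tokens = _pack_token_batch(batch_seqs, config.max_len)
            pos, neg, valid = _dense_pair_arrays(tokens, epoch_rng, dictionary.size)
            loss = _batch_loss(model, tokens, pos, neg, valid, config.loss)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            n_batches += 1
        acc = pair_ranking_accuracy(model, held, dictionary, seed=config.seed + 1)
        log.append(
            {
                "epoch": epoch,
                "loss": epoch_loss / max(n_batches, 1),
                "pair_ranking_accuracy": acc,
            }
        )
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, model, dictionary.fingerprint())
    return model, log


def write_pretrain_log(log: Sequence[dict], path) -> None:
    """Write the per-epoch pre-training log as delimited text."""
    with open(path, "w") as fh:
        fh.write("epoch\tloss\tpair_ranking_accuracy\n")
        for rec in log:
            fh.write(
                f"{rec['epoch']}\t{rec['loss']:.6f}\t"
                f"{rec['pair_ranking_accuracy']:.6f}\n"
            )
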