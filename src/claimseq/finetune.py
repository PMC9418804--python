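"""Downstream binary-outcome training and evaluation.

Supports training from scratch or from a pre-trained checkpoint via a
two-stage schedule: phase 1 freezes the embedding table and trains the rest
of the network at the regular learning rate for a fixed number of epochs;
phase 2 unfreezes everything and trains at 1/10 of the regular rate.  The
downstream loss is binary cross-entropy on the single outcome logit;
accuracy is measured as rank-based (Mann–Whitney, midrank ties) AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .autodiff import Adam, Tensor
from .events import ConceptDictionary, LabeledSample
from .models import EncoderConfig, SequenceModel, batch_samples, load_checkpoint

__all__ = [
    "SplitSpec",
    "FinetuneSchedule",
    "split_cohort",
    "train_downstream",
    "evaluate_auc",
    "roc_auc",
    "write_predictions",
    "write_metrics",
]


@dataclass(frozen=True)
class SplitSpec:
    """Cohort train/test split parameters.

    Cohorts larger than ``max_cohort_size`` are subsampled first (very
    common outcomes would otherwise dominate compute without adding much
    signal); the split is stratified by default so prevalence is preserved
    on both sides.
    """

    train_fraction: float = 0.75
    stratified: bool = True
    seed: int = 0
    max_cohort_size: int = 100_000

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.max_cohort_size < 2:
            raise ValueError("max_cohort_size must be >= 2")


def split_cohort(
    samples: Sequence[LabeledSample], spec: SplitSpec
) -> tuple[list[LabeledSample], list[LabeledSample]]:
    """Deterministic, optionally stratified train/test split of a cohort."""
    samples = list(samples)
    labels = np.array([s.label for s in samples])
    if any(lbl is None for lbl in labels):
        raise ValueError("all samples must be labeled before splitting")
    if len(np.unique(labels)) < 2:
        raise ValueError("cohort contains a single outcome class")
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise ValueError("need at least 2 samples per class to split")
    rng = np.random.default_rng(spec.seed)
    if len(samples) > spec.max_cohort_size:
        keep = rng.choice(len(samples), size=spec.max_cohort_size, replace=False)
        keep.sort()
        samples = [samples[i] for i in keep]
        labels = labels[keep]
    idx = np.arange(len(samples))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=spec.train_fraction,
        random_state=spec.seed % (2**32),
        stratify=labels if spec.stratified else None,
        shuffle=True,
    )
    return [samples[i] for i in train_idx], [samples[i] for i in test_idx]


@dataclass(frozen=True)
class FinetuneSchedule:
    """Two-stage fine-tuning schedule for pre-trained initializations.

    Phase 1: embedding frozen, remaining parameters trained at ``base_lr``
    for ``phase1_epochs``.  Phase 2: all parameters trained at
    ``base_lr × phase2_lr_factor`` for ``phase2_epochs``.
    """

    phase1_epochs: int = 5
    phase1_freeze_embedding: bool = True
    phase2_lr_factor: float = 0.1
    phase2_epochs: int = 5
    base_lr: float = 1e-3

    def __post_init__(self) -> None:
        if self.phase1_epochs < 1:
            raise ValueError("phase1_epochs must be >= 1")
        if not (0.0 < self.phase2_lr_factor <= 1.0):
            raise ValueError("phase2_lr_factor must be in (0, 1]")


class NeuralScorer:
    """Trained model plus its epoch-by-epoch training log."""

    def __init__(self, model: SequenceModel, log: list[dict]):
        self.model = model
        self.log = log

    def scores(self, samples: Sequence[LabeledSample]) -> np.ndarray:
        return self.model.scores(samples)


def _bce_loss(
    model: SequenceModel,
    batch: Sequence[LabeledSample],
    dropout_rate: float,
    rng: np.random.Generator,
) -> Tensor:
    tokens, days, index_days, labels = batch_samples(batch)
    if dropout_rate > 0.0:
        # event-dropout augmentation: dropped positions become PAD, which is
        # masked out everywhere, so this equals removing the events
        real = tokens >= 2
        drop = real & (rng.random(tokens.shape) < dropout_rate)
        tokens = np.where(drop, 0, tokens)
    z = model.forward_logits(tokens, days, index_days)
    # softplus(z) - y*z is the stable form of -[y log σ(z) + (1-y) log(1-σ(z))]
    return (z.softplus() - z * Tensor(labels)).mean()


def train_downstream(
    train_set: Sequence[LabeledSample],
    config: EncoderConfig,
    schedule: FinetuneSchedule | None = None,
    checkpoint=None,
    dictionary: ConceptDictionary | None = None,
    epochs: int = 10,
    batch_size: int = 32,
    seed: int = 0,
    dropout_rate: float = 0.0,
    eval_set: Sequence[LabeledSample] | None = None,
    n_tokens: int | None = None,
) -> NeuralScorer:
    """Train the outcome classifier, from scratch or from a checkpoint.

    Without a checkpoint: end-to-end training for ``epochs`` at the
    schedule's base learning rate.  With a checkpoint: the embedding table
    is initialized from it (after verifying the dictionary fingerprint)
    and the two-stage schedule applies.  The per-epoch log records phase,
    learning rate, training loss and — when ``eval_set`` is given — the
    held-out AUC, so convergence speed can be compared across
    initializations.  Deterministic given ``seed``.
    """
    schedule = schedule or FinetuneSchedule()
    if n_tokens is None:
        if dictionary is None:
            raise ValueError("provide a dictionary or an explicit n_tokens")
        n_tokens = dictionary.n_tokens
    model = SequenceModel(config, n_tokens=n_tokens, seed=seed)
    pretrained = checkpoint is not None
    if pretrained:
        ck_model, fingerprint = load_checkpoint(checkpoint)
        if dictionary is not None and fingerprint != dictionary.fingerprint():
            raise ValueError(
                "checkpoint was pre-trained against a different concept "
                "dictionary (fingerprint mismatch)"
            )
        if ck_model.params["emb"].data.shape != model.params["emb"].data.shape:
            raise ValueError("checkpoint embedding shape does not match config")
        model.params["emb"].data = ck_model.params["emb"].data.copy()

    # start the head at the empirical class prior so early epochs learn
    # discrimination rather than spending steps fitting the intercept
    prevalence = float(np.mean([s.label for s in train_set]))
    prevalence = min(max(prevalence, 1e-6), 1 - 1e-6)
    model.params["head_b"].data[:] = np.log(prevalence / (1 - prevalence))

    opt = Adam(model.params, lr=schedule.base_lr)
    rng = np.random.default_rng(seed)
    log: list[dict] = []
    if pretrained:
        phases = [
            ("phase1", schedule.phase1_epochs, schedule.base_lr,
             frozenset({"emb"}) if schedule.phase1_freeze_embedding else frozenset()),
            ("phase2", schedule.phase2_epochs,
             schedule.base_lr * schedule.phase2_lr_factor, frozenset()),
        ]
    else:
        phases = [("scratch", epochs, schedule.base_lr, frozenset())]

    train_set = list(train_set)
    epoch_counter = 0
    for phase_name, n_epochs, lr, frozen in phases:
        opt.lr = lr
        for _ in range(n_epochs):
            perm = rng.permutation(len(train_set))
            total = 0.0
            n_batches = 0
            for start in range(0, len(train_set), batch_size):
                batch = [train_set[i] for i in perm[start : start + batch_size]]
                loss = _bce_loss(model, batch, dropout_rate, rng)
                opt.zero_grad()
                loss.backward()
                opt.step(freeze=frozen)
                total += loss.item()
                n_batches += 1
            record = {
                "epoch": epoch_counter,
                "phase": phase_name,
                "lr": lr,
                "loss": total / max(n_batches, 1),
            }
            if eval_set is not None:
                record["eval_auc"] = evaluate_auc(NeuralScorer(model, []), eval_set)
            log.append(record)
            epoch_counter += 1
    return NeuralScorer(model, log)


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based (Mann–Whitney) AUC with midrank tie handling."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both outcome classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def evaluate_auc(scorer, test_set: Sequence[LabeledSample]) -> float:
    """AUC of a scorer on a labeled test set.

    ``scorer`` needs a ``scores(samples) -> array`` method (neural and tree
    scorers both provide one); invariant under any strictly increasing
    transform of the scores.
    """
    labels = np.array([s.label for s in test_set])
    return roc_auc(labels, scorer.scores(list(test_set)))


def write_predictions(test_set: Sequence[LabeledSample], scores, path) -> None:
    with open(path, "w") as fh:
        fh.write("person_id\tscore\n")
        for s, sc in zip(test_set, scores):
            fh.write(f"{s.person_id}\t{sc:.6f}\n")


def write_metrics(path, task: str, n_train: int, n_test: int, auc: float,
                  seed: int, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write("task\tn_train\tn_test\tauc\tseed\tconfig_hash\n")
        fh.write(f"{task}\t{n_train}\t{n_test}\t{auc:.6f}\t{seed}\t{config_hash}\n")
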