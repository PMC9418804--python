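"""End-to-end synthetic benchmarks exercising the whole method stack.

Two drivers, both fully determined by a single seed:

* :func:`run_decay_benchmark` — trains the no-time max-pool baseline, the
  decay-channel model, and the two tree comparators (random forest on
  presence features, gradient-boosted trees on four-bucket time features)
  on one simulated cohort with a 50-day planted half-life, and reports all
  test AUCs next to the simulator's Bayes-oracle AUC.

* :func:`run_pretrain_benchmark` — pre-trains on a generic simulated
  corpus (cross-entropy and cosine variants), then fine-tunes on a small
  disjoint downstream cohort with the two-stage schedule, against training
  from scratch; reports pair-ranking accuracies, downstream AUCs and
  epochs-to-convergence.

Problem sizes default to minutes-scale single-CPU runs: 2,000 patients for
the decay benchmark, 600 pre-training + 500 downstream patients for the
transfer benchmark, hidden width 32.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .events import WindowSpec, build_dictionary
from .features import feature_matrix, fit_tree_baseline
from .finetune import (
    FinetuneSchedule,
    SplitSpec,
    evaluate_auc,
    roc_auc,
    split_cohort,
    train_downstream,
)
from .models import EncoderConfig, SequenceModel
from .pretrain import PretrainConfig, pair_ranking_accuracy, run_pretraining
from .simulate import SimConfig, oracle_auc, prepare_cohort_samples, simulate_cohort

__all__ = ["run_decay_benchmark", "run_pretrain_benchmark", "epochs_to_reach"]

_WINDOW = WindowSpec(max_len=256)
_D_HIDDEN = 32
_BASE_LR = 3e-3
_DROPOUT = 0.5


def run_decay_benchmark(
    seed: int,
    n_patients: int = 2000,
    epochs: int = 12,
    with_oracle: bool = True,
) -> dict[str, float]:
    """Time-decay vs no-time neural models vs tree baselines, one cohort."""
    sim_cfg = SimConfig(seed=seed * 1000 + 1, n_patients=n_patients)
    sim = simulate_cohort(sim_cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        samples, dic = prepare_cohort_samples(sim, window=_WINDOW)
    train, test = split_cohort(samples, SplitSpec(seed=seed))
    y_train = np.array([s.label for s in train])
    y_test = np.array([s.label for s in test])

    out: dict[str, float] = {"n_train": len(train), "n_test": len(test)}
    for kind, learner, name in (
        ("presence", "random_forest", "auc_rf_presence"),
        ("time_buckets", "gradient_boosted_trees", "auc_gbt_time_buckets"),
    ):
        x_tr = feature_matrix(train, dic, kind)
        x_te = feature_matrix(test, dic, kind)
        scorer = fit_tree_baseline(x_tr, y_train, learner, seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[name] = roc_auc(y_test, scorer.scores(x_te))

    for time_mode, name in (("none", "auc_neural_no_time"), ("decay", "auc_neural_decay")):
        config = EncoderConfig(d_hidden=_D_HIDDEN, time_mode=time_mode)
        scorer = train_downstream(
            train,
            config,
            schedule=FinetuneSchedule(base_lr=_BASE_LR),
            dictionary=dic,
            epochs=epochs,
            seed=seed,
            dropout_rate=_DROPOUT,
        )
        out[name] = evaluate_auc(scorer, test)
    if with_oracle:
        out["auc_oracle"] = oracle_auc(sim_cfg, n_mc=4000)
    return out


def epochs_to_reach(trajectory: list[float], level: float) -> int:
    """First epoch (0-based) at which the AUC trajectory reaches ``level``;
    one past the end if it never does."""
    for i, v in enumerate(trajectory):
        if v >= level:
            return i
    return len(trajectory)


def run_pretrain_benchmark(
    seed: int,
    n_pretrain_patients: int = 600,
    n_downstream_patients: int = 500,
    pretrain_epochs: int = 4,
    downstream_epochs: int = 10,
) -> dict[str, float]:
    """Contrastive pre-training + two-stage fine-tuning vs scratch training.

    The pre-training corpus and the downstream cohort come from disjoint
    simulator seeds (generic background data vs a specific task, as in
    transfer learning).  Both pre-training losses are run; every downstream
    model uses the decay-channel encoder.
    """
    pre_sim = simulate_cohort(
        SimConfig(seed=seed * 1000 + 11, n_patients=n_pretrain_patients)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dictionary = build_dictionary(pre_sim.timelines, 500)

    encoder = EncoderConfig(d_hidden=_D_HIDDEN)
    out: dict[str, float] = {}
    models = {}
    for loss in ("ce", "cosine"):
        config = PretrainConfig(
            encoder=encoder,
            loss=loss,
            epochs=pretrain_epochs,
            batch_size=32,
            lr=_BASE_LR,
            max_len=128,
            seed=seed,
        )
        model, log = run_pretraining(pre_sim.timelines, dictionary, config)
        models[loss] = model
        out[f"pair_ranking_accuracy_{loss}"] = log[-1]["pair_ranking_accuracy"]

    untrained = SequenceModel(encoder, dictionary.n_tokens, seed=seed + 1)
    heldout = pre_sim.timelines[: max(40, n_pretrain_patients // 10)]
    out["pair_ranking_accuracy_untrained"] = pair_ranking_accuracy(
        untrained, heldout, dictionary, seed=seed + 2
    )

    down_sim = simulate_cohort(
        SimConfig(seed=seed * 1000 + 21, n_patients=n_downstream_patients)
    )
    samples, _ = prepare_cohort_samples(down_sim, dictionary=dictionary, window=_WINDOW)
    train, test = split_cohort(samples, SplitSpec(seed=seed))
    down_config = EncoderConfig(d_hidden=_D_HIDDEN, time_mode="decay")
    schedule = FinetuneSchedule(
        base_lr=_BASE_LR, phase1_epochs=5, phase2_epochs=downstream_epochs - 5
    )

    import tempfile
    from pathlib import Path

    from .models import save_checkpoint

    trajectories: dict[str, list[float]] = {}
    with tempfile.TemporaryDirectory() as tmp:
        runs = {"scratch": None}
        for loss, model in models.items():
            path = Path(tmp) / f"ck_{loss}.npz"
            save_checkpoint(path, model, dictionary.fingerprint())
            runs[f"pretrained_{loss}"] = path
        for name, ckpt in runs.items():
            scorer = train_downstream(
                train,
                down_config,
                schedule=schedule,
                checkpoint=ckpt,
                dictionary=dictionary,
                epochs=downstream_epochs,
                seed=seed,
                dropout_rate=_DROPOUT,
                eval_set=test,
            )
            trajectories[name] = [r["eval_auc"] for r in scorer.log]
            out[f"auc_downstream_{name}"] = trajectories[name][-1]

    # convergence speed: epochs needed to reach the scratch model's final AUC
    level = out["auc_downstream_scratch"] - 0.01
    out["epochs_to_scratch_level_scratch"] = epochs_to_reach(
        trajectories["scratch"], level
    )
    out["epochs_to_scratch_level_pretrained"] = epochs_to_reach(
        trajectories["pretrained_ce"], level
    )
    return out
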