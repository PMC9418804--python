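"""Exponential time-decay channels vs the no-time max-pool baseline.

Both models embed concept tokens and max-pool over the sequence; the decay
model additionally weights each event embedding by exp(-a t) for three
half-lives (inf, 50, 100 days) and concatenates the pooled channels, so
its history vector sees how recently each concept pattern occurred.
"""

from claimseq import (
    EncoderConfig,
    FinetuneSchedule,
    SimConfig,
    SplitSpec,
    WindowSpec,
    evaluate_auc,
    simulate_cohort,
    split_cohort,
    train_downstream,
)
from claimseq.simulate import prepare_cohort_samples

sim = simulate_cohort(SimConfig(seed=7, n_patients=1000))
samples, dictionary = prepare_cohort_samples(sim, window=WindowSpec(max_len=256))
train, test = split_cohort(samples, SplitSpec(seed=7))

for time_mode in ("none", "decay"):
    config = EncoderConfig(d_hidden=32, time_mode=time_mode)
    scorer = train_downstream(
        train,
        config,
        schedule=FinetuneSchedule(base_lr=3e-3),
        dictionary=dictionary,
        epochs=12,
        seed=7,
        dropout_rate=0.5,  # 50% event dropout augmentation
    )
    print(f"time_mode={time_mode:5s}  history dim {config.history_dim:4d}  "
          f"test AUC {evaluate_auc(scorer, test):.3f}")
# The planted 50-day half-life makes recency the dominant signal: the decay
# channels should add roughly +0.2 AUC over the time-blind baseline here.
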