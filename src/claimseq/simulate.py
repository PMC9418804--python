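"""Synthetic longitudinal-claims generator with planted structure.

Emulates OMOP-style per-patient timestamped concept sequences: each patient
activates a random subset of latent disease processes; an active process
emits its own small pool of concepts as a time-homogeneous point process
over the observation span, on top of patient-wide background noise
concepts.  The binary outcome is drawn from a logistic model whose linear
predictor is the decayed exposure to designated *risk* concepts — each
occurrence at lag t days before the index date contributes
exp(−(ln2 / planted_half_life)·t) — so recency genuinely carries signal
and time-decay models have something real to find.  The latent-process
co-occurrence structure makes future events predictable from history,
which is what contrastive pre-training must learn.

A Monte-Carlo Bayes oracle (:func:`oracle_auc`) scores patients by their
true outcome probability; no fitted model can beat it beyond noise, so it
is the reference for calibrating benchmark margins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .events import (
    LabeledSample,
    PatientTimeline,
    WindowSpec,
    build_dictionary,
    from_julian_day,
    prepare_sample,
    timelines_from_table,
    to_julian_day,
)
from .finetune import roc_auc

__all__ = ["SimConfig", "SimulatedCohort", "simulate_population", "simulate_cohort",
           "oracle_auc", "prepare_cohort_samples"]

_EPOCH_DAY = to_julian_day(2015, 1, 1)  # arbitrary calendar anchor


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; the seed is mandatory for reproducibility.

    Rates are events/year.  The first ``n_risk_processes`` latent processes
    are the risk processes; their concepts carry the outcome coefficient.
    ``planted_half_life`` may be ``inf``, in which case labels depend on
    risk-concept counts only and time decay loses its advantage.
    """

    seed: int
    n_patients: int = 2000
    n_concepts: int = 500
    n_latent_processes: int = 20
    concepts_per_process: int = 10
    process_activation_prob: float = 0.3
    risk_activation_prob: float = 0.9
    process_rate: float = 3.0
    background_rate: float = 6.0
    span_days: int = 1825  # 5 years of observation
    planted_half_life: float = 50.0
    n_risk_processes: int = 3
    risk_coefficient: float = 2.0
    prevalence_target: float = 0.3

    def __post_init__(self) -> None:
        if self.process_rate <= 0 or self.background_rate < 0:
            raise ValueError("emission rates must be positive")
        if not (0.0 < self.prevalence_target < 1.0):
            raise ValueError("prevalence target must be in (0, 1)")
        if self.planted_half_life <= 0:
            raise ValueError("planted_half_life must be positive (or inf)")
        if self.n_risk_processes > self.n_latent_processes:
            raise ValueError("more risk processes than latent processes")
        if self.concepts_per_process * self.n_latent_processes > self.n_concepts:
            raise ValueError("not enough concepts for the latent processes")

    @property
    def decay_rate(self) -> float:
        return 0.0 if math.isinf(self.planted_half_life) else (
            math.log(2.0) / self.planted_half_life
        )

    @property
    def index_day(self) -> int:
        return _EPOCH_DAY + self.span_days

    def process_concepts(self, p: int) -> np.ndarray:
        lo = p * self.concepts_per_process
        return np.arange(lo, lo + self.concepts_per_process)

    @property
    def risk_concepts(self) -> np.ndarray:
        return np.concatenate(
            [self.process_concepts(p) for p in range(self.n_risk_processes)]
        )

    @property
    def background_concepts(self) -> np.ndarray:
        return np.arange(
            self.concepts_per_process * self.n_latent_processes, self.n_concepts
        )


def _concept_id(c: int) -> str:
    return f"C{c:04d}"


def _date_str(jdn: int) -> str:
    y, m, d = from_julian_day(jdn)
    return f"{y:04d}-{m:02d}-{d:02d}"


def simulate_population(config: SimConfig) -> pd.DataFrame:
    """Draw the event table for a synthetic population.

    Per patient: latent processes activate independently with the
    configured probability; each active process emits Poisson(rate·span)
    events at uniform days over the span, choosing uniformly among its
    concepts; background concepts are emitted likewise.  Returns the
    standard event table (person_id, concept_id, event_date, day),
    byte-identical for a given seed.
    """
    rng = np.random.default_rng(config.seed)
    persons: list[str] = []
    concepts: list[int] = []
    days: list[int] = []
    years = config.span_days / 365.0
    bg_pool = config.background_concepts
    act_prob = np.full(config.n_latent_processes, config.process_activation_prob)
    # risk processes are common: the outcome signal is when they flare, not whether
    act_prob[: config.n_risk_processes] = config.risk_activation_prob
    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        active = rng.random(config.n_latent_processes) < act_prob
        for p in np.flatnonzero(active):
            n = rng.poisson(config.process_rate * years)
            if n == 0:
                continue
            ev_days = rng.integers(0, config.span_days, size=n)
            ev_concepts = rng.choice(config.process_concepts(p), size=n)
            persons.extend([pid] * n)
            concepts.extend(ev_concepts.tolist())
            days.extend(ev_days.tolist())
        n_bg = rng.poisson(config.background_rate * years)
        if n_bg and len(bg_pool):
            ev_days = rng.integers(0, config.span_days, size=n_bg)
            ev_concepts = rng.choice(bg_pool, size=n_bg)
            persons.extend([pid] * n_bg)
            concepts.extend(ev_concepts.tolist())
            days.extend(ev_days.tolist())
    day_arr = np.array(days, dtype=np.int64) + _EPOCH_DAY
    df = pd.DataFrame(
        {
            "person_id": persons,
            "concept_id": [_concept_id(c) for c in concepts],
            "event_date": [_date_str(d) for d in day_arr],
            "day": day_arr,
        }
    )
    return df.sort_values(
        ["person_id", "day", "concept_id"], kind="stable"
    ).reset_index(drop=True)


@dataclass(frozen=True)
class SimulatedCohort:
    """Population events plus labels and generator-side ground truth."""

    config: SimConfig
    events: pd.DataFrame
    cohort: pd.DataFrame  # person_id, index_date, label
    true_prob: np.ndarray  # per person, in cohort row order

    @property
    def timelines(self) -> list[PatientTimeline]:
        return timelines_from_table(self.events)


def _decayed_exposures(config: SimConfig, events: pd.DataFrame) -> pd.Series:
    """Per-patient sum over risk-concept occurrences of exp(−a·lag)."""
    risk_ids = {_concept_id(c) for c in config.risk_concepts}
    mask = events["concept_id"].isin(risk_ids)
    lag = config.index_day - events.loc[mask, "day"]
    weight = np.exp(-config.decay_rate * lag.to_numpy(dtype=np.float64))
    contrib = pd.Series(weight, index=events.loc[mask, "person_id"])
    totals = contrib.groupby(level=0).sum()
    all_persons = pd.Index(sorted(events["person_id"].unique()))
    return totals.reindex(all_persons, fill_value=0.0)


def simulate_cohort(
    config: SimConfig, events: pd.DataFrame | None = None
) -> SimulatedCohort:
    """Label a simulated population with the planted logistic outcome.

    The logistic intercept is calibrated so the population-mean outcome
    probability equals the prevalence target; labels are then Bernoulli
    draws from each patient's true probability.  A degenerate realized
    cohort (all labels equal) is rejected.
    """
    if events is None:
        events = simulate_population(config)
    exposures = _decayed_exposures(config, events)
    lin = config.risk_coefficient * exposures.to_numpy(dtype=np.float64)

    def mean_prev(b0: float) -> float:
        return float(expit(b0 + lin).mean()) - config.prevalence_target

    b0 = brentq(mean_prev, -60.0, 60.0)
    prob = expit(b0 + lin)
    rng = np.random.default_rng((config.seed, 104729))
    labels = (rng.random(len(prob)) < prob).astype(int)
    if labels.min() == labels.max():
        raise ValueError(
            "degenerate cohort: all labels identical; adjust coefficients"
        )
    cohort = pd.DataFrame(
        {
            "person_id": exposures.index,
            "index_date": _date_str(config.index_day),
            "index_day": config.index_day,
            "label": labels,
        }
    )
    return SimulatedCohort(
        config=config, events=events, cohort=cohort, true_prob=prob
    )


def oracle_auc(config: SimConfig, n_mc: int = 5000) -> float:
    """Monte-Carlo estimate of the Bayes-optimal AUC for a configuration.

    Scores each simulated patient by the true outcome probability; no
    scorer fit to the observable data can exceed this beyond Monte-Carlo
    noise.  Used once to calibrate benchmark margins.
    """
    if n_mc < 1000:
        warnings.warn("n_mc < 1000 gives a noisy oracle AUC", stacklevel=2)
    sim = simulate_cohort(replace(config, n_patients=n_mc))
    return roc_auc(sim.cohort["label"].to_numpy(), sim.true_prob)


def prepare_cohort_samples(
    sim: SimulatedCohort,
    dictionary=None,
    window: WindowSpec = WindowSpec(),
    k: int | None = None,
) -> tuple[list[LabeledSample], "object"]:
    """Tokenize a simulated cohort into labeled samples.

    Builds the concept dictionary from the cohort's own timelines when one
    is not supplied (``k`` defaults to all concepts).  Returns (samples,
    dictionary).
    """
    timelines = sim.timelines
    if dictionary is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dictionary = build_dictionary(timelines, k or sim.config.n_concepts)
    label_of = dict(zip(sim.cohort["person_id"], sim.cohort["label"]))
    samples = [
        prepare_sample(
            tl, dictionary, sim.config.index_day, window, label=int(label_of[tl.person_id])
        )
        for tl in timelines
    ]
    return samples, dictionary
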