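"""Core domain types and sequence preparation for longitudinal claims data.

The unit of data is a timestamped medical concept occurrence (an *event*).
Per patient, events form a time-ordered timeline; for supervised learning a
timeline is cut at a per-patient *index day* (time 0): events strictly before
the index day form the observation window, and the binary outcome is sought
after it.  Sequences are tokenized against a frequency-ranked concept
dictionary with reserved PAD=0 and EOS=1 tokens, truncated to a maximum
length keeping the most recent events, EOS-terminated and front-padded.
"""

from __future__ import annotations

import hashlib
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

PAD = 0
EOS = 1
N_RESERVED = 2

__all__ = [
    "PAD",
    "EOS",
    "N_RESERVED",
    "Event",
    "PatientTimeline",
    "ConceptDictionary",
    "LabeledSample",
    "WindowSpec",
    "to_julian_day",
    "from_julian_day",
    "build_dictionary",
    "prepare_sample",
    "apply_whitelist",
    "event_dropout",
    "read_event_table",
    "write_event_table",
    "read_cohort_table",
    "write_cohort_table",
    "timelines_from_table",
]


def _is_gregorian_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


_DAYS_IN_MONTH = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)


def to_julian_day(year: int, month: int, day_of_month: int) -> int:
    """Julian day number of a proleptic Gregorian calendar date.

    Uses the Fliegel–Van Flandern integer algorithm.  The absolute epoch is
    irrelevant for relative-time features (differences of two Julian days
    equal elapsed calendar days); only differences ever enter the models.

    Raises
    ------
    ValueError
        If the (year, month, day) triple is not a valid calendar date.
    """
    if not (1 <= month <= 12):
        raise ValueError(f"invalid month {month!r}: must be in 1..12")
    n_days = _DAYS_IN_MONTH[month - 1]
    if month == 2 and _is_gregorian_leap(year):
        n_days = 29
    if not (1 <= day_of_month <= n_days):
        raise ValueError(
            f"invalid day {day_of_month!r} for {year:04d}-{month:02d}: "
            f"must be in 1..{n_days}"
        )
    a = (14 - month) // 12
    y = year + 4800 - a
    m = month + 12 * a - 3
    return (
        day_of_month
        + (153 * m + 2) // 5
        + 365 * y
        + y // 4
        - y // 100
        + y // 400
        - 32045
    )


def from_julian_day(jdn: int) -> tuple[int, int, int]:
    """Inverse of :func:`to_julian_day` (proleptic Gregorian)."""
    a = jdn + 32044
    b = (4 * a + 3) // 146097
    c = a - 146097 * b // 4
    d = (4 * c + 3) // 1461
    e = c - 1461 * d // 4
    m = (5 * e + 2) // 153
    day = e - (153 * m + 2) // 5 + 1
    month = m + 3 - 12 * (m // 10)
    year = 100 * b + d - 4800 + m // 10
    return year, month, day


@dataclass(frozen=True, slots=True)
class Event:
    """One timestamped medical concept occurrence.

    ``concept_id`` is an opaque source-vocabulary code (kept as text) and
    ``day`` is an integer Julian day number.
    """

    concept_id: str
    day: int

    def __post_init__(self) -> None:
        if not self.concept_id:
            raise ValueError("concept_id must be non-empty")
        if not np.isfinite(self.day):
            raise ValueError("event day must be finite")


@dataclass(frozen=True)
class PatientTimeline:
    """Time-ordered event sequence for one patient.

    Events are sorted ascending by ``(day, concept_id)``; the secondary
    lexical key makes same-day ties deterministic across runs.
    """

    person_id: str
    events: tuple[Event, ...]

    @classmethod
    def from_events(cls, person_id: str, events: Iterable[Event]) -> "PatientTimeline":
        ordered = tuple(sorted(events, key=lambda ev: (ev.day, ev.concept_id)))
        return cls(person_id=person_id, events=ordered)

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class ConceptDictionary:
    """Frequency-ranked concept→token mapping with reserved PAD/EOS tokens.

    The K most frequent concepts of the build corpus receive tokens
    ``2 .. K+1`` in rank order; training-corpus frequencies are retained for
    the evaluation-time whitelist.
    """

    token_of: Mapping[str, int]
    counts: Mapping[str, int]

    @property
    def size(self) -> int:
        """Number of concept tokens K (reserved tokens excluded)."""
        return len(self.token_of)

    @property
    def n_tokens(self) -> int:
        """Total token-table size including PAD and EOS."""
        return self.size + N_RESERVED

    def tokenize(self, concept_id: str) -> int | None:
        return self.token_of.get(concept_id)

    def detokenize(self, token: int) -> str:
        if token in (PAD, EOS):
            raise KeyError(f"token {token} is reserved")
        return self._concept_of[token]

    @property
    def _concept_of(self) -> dict[int, str]:
        inv = getattr(self, "_inv_cache", None)
        if inv is None:
            inv = {tok: cid for cid, tok in self.token_of.items()}
            object.__setattr__(self, "_inv_cache", inv)
        return inv

    def count_of_token(self, token: int) -> int:
        if token in (PAD, EOS):
            return 0
        return self.counts[self._concept_of[token]]

    def fingerprint(self) -> str:
        """Stable hash of the concept→token mapping, for checkpoint checks."""
        h = hashlib.md5()
        for cid, tok in sorted(self.token_of.items()):
            h.update(f"{cid}\t{tok}\n".encode())
        return h.hexdigest()


@dataclass(frozen=True)
class WindowSpec:
    """Observation-window preparation parameters.

    ``max_len`` bounds the token sequence including the terminal EOS;
    ``whitelist_threshold`` is the minimum training-corpus frequency a
    concept needs to survive evaluation-time filtering; ``dropout_rate`` is
    the training-time event-dropout probability.
    """

    max_len: int = 768
    whitelist_threshold: int = 50
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.max_len < 2:
            raise ValueError("max_len must be >= 2 (EOS plus at least one event)")
        if self.whitelist_threshold < 0:
            raise ValueError("whitelist_threshold must be non-negative")
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ValueError("dropout_rate must be in [0, 1]")


@dataclass(frozen=True)
class LabeledSample:
    """Tokenized observation window for one patient.

    ``tokens`` is PAD-front-padded and EOS-terminated; ``days_before_index``
    holds, per position, the elapsed days between the event and the index day
    (the decay time t).  PAD and EOS positions carry the sentinel 0 and are
    masked out of all time computations.  ``label`` is the binary outcome, or
    None before labeling.
    """

    person_id: str
    tokens: np.ndarray
    days_before_index: np.ndarray
    index_day: int
    label: int | None = None

    def __post_init__(self) -> None:
        tokens = np.asarray(self.tokens, dtype=np.int64)
        days = np.asarray(self.days_before_index, dtype=np.int64)
        object.__setattr__(self, "tokens", tokens)
        object.__setattr__(self, "days_before_index", days)
        if tokens.shape != days.shape:
            raise ValueError("tokens and days_before_index must have equal length")
        if int((tokens == EOS).sum()) != 1:
            raise ValueError("sample must contain exactly one EOS token")
        pad_positions = np.flatnonzero(tokens == PAD)
        real_positions = np.flatnonzero(tokens != PAD)
        if pad_positions.size and pad_positions.max() > real_positions.min():
            raise ValueError("all PAD tokens must precede all real tokens")
        if (days[tokens >= N_RESERVED] < 0).any():
            raise ValueError("days_before_index must be non-negative for real tokens")

    @property
    def real_mask(self) -> np.ndarray:
        """Positions holding actual concept tokens (PAD and EOS excluded)."""
        return self.tokens >= N_RESERVED

    def with_label(self, label: int) -> "LabeledSample":
        return replace(self, label=int(label))


def build_dictionary(
    timelines: Iterable[PatientTimeline], k: int = 10_000
) -> ConceptDictionary:
    """Build the K-most-frequent concept dictionary over a corpus.

    Ties at rank K are broken by concept_id lexical order so the mapping is
    deterministic across runs.  If the corpus holds fewer than K distinct
    concepts, all of them are mapped (with a warning).
    """
    if k <= 0:
        raise ValueError("dictionary size K must be >= 1")
    counts: Counter[str] = Counter()
    for tl in timelines:
        counts.update(ev.concept_id for ev in tl.events)
    if not counts:
        raise ValueError("cannot build a dictionary from a corpus with no events")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) < k:
        warnings.warn(
            f"corpus has only {len(ranked)} distinct concepts (< K={k}); "
            "mapping all of them",
            stacklevel=2,
        )
    chosen = ranked[:k]
    token_of = {cid: N_RESERVED + rank for rank, (cid, _) in enumerate(chosen)}
    return ConceptDictionary(token_of=token_of, counts=dict(counts))


def prepare_sample(
    timeline: PatientTimeline,
    dictionary: ConceptDictionary,
    index_day: int,
    window: WindowSpec = WindowSpec(),
    label: int | None = None,
) -> LabeledSample:
    """Tokenize the observation window of a timeline against a dictionary.

    Keeps events strictly before the index day (time 0) whose concepts are
    in the dictionary, keeps the most recent ``max_len - 1`` of them,
    appends EOS, and front-pads with PAD to ``max_len``.  A patient with no
    prior observations yields a PAD…PAD,EOS sequence — the EOS token keeps
    empty histories well-defined downstream.
    """
    kept: list[tuple[int, int]] = []
    for ev in timeline.events:
        if ev.day >= index_day:
            continue
        tok = dictionary.tokenize(ev.concept_id)
        if tok is not None:
            kept.append((tok, index_day - ev.day))
    kept = kept[-(window.max_len - 1):]
    n_real = len(kept)
    n_pad = window.max_len - n_real - 1
    tokens = np.concatenate(
        [
            np.full(n_pad, PAD, dtype=np.int64),
            np.fromiter((t for t, _ in kept), dtype=np.int64, count=n_real),
            np.array([EOS], dtype=np.int64),
        ]
    )
    days = np.concatenate(
        [
            np.zeros(n_pad, dtype=np.int64),
            np.fromiter((d for _, d in kept), dtype=np.int64, count=n_real),
            np.array([0], dtype=np.int64),  # EOS carries t=0
        ]
    )
    return LabeledSample(
        person_id=timeline.person_id,
        tokens=tokens,
        days_before_index=days,
        index_day=index_day,
        label=label,
    )


def _repack(sample: LabeledSample, keep: np.ndarray) -> LabeledSample:
    """Drop real positions where ``keep`` is False, preserving length."""
    real = sample.real_mask
    drop = real & ~keep
    retained = ~drop & (sample.tokens != PAD)
    tokens = sample.tokens[retained]
    days = sample.days_before_index[retained]
    n_pad = len(sample.tokens) - len(tokens)
    return replace(
        sample,
        tokens=np.concatenate([np.full(n_pad, PAD, dtype=np.int64), tokens]),
        days_before_index=np.concatenate([np.zeros(n_pad, dtype=np.int64), days]),
    )


def apply_whitelist(
    sample: LabeledSample, dictionary: ConceptDictionary, threshold: int
) -> LabeledSample:
    """Drop tokens whose training-corpus frequency is below ``threshold``.

    Applied to evaluation-time samples only: rare concepts have essentially
    untrained embeddings and would otherwise corrupt predictions.  The
    dictionary must carry frequencies from the *training* corpus so no
    information leaks from the test set.
    """
    if threshold < 0:
        raise ValueError("whitelist threshold must be non-negative")
    keep = np.ones(len(sample.tokens), dtype=bool)
    for pos in np.flatnonzero(sample.real_mask):
        keep[pos] = dictionary.count_of_token(int(sample.tokens[pos])) >= threshold
    return _repack(sample, keep)


def event_dropout(
    sample: LabeledSample, rate: float, rng: np.random.Generator
) -> LabeledSample:
    """Training-time augmentation: drop each real token independently.

    PAD and EOS are untouched.  A high default rate (0.5) reflects that
    claims-based predictions hinge on a few crucial events rather than the
    joint structure of all of them.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("dropout rate must be in [0, 1]")
    keep = np.ones(len(sample.tokens), dtype=bool)
    real = sample.real_mask
    keep[real] = rng.random(int(real.sum())) >= rate
    return _repack(sample, keep)


# ---------------------------------------------------------------------------
# External interfaces: delimited event and cohort tables


def _read_delimited(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str)


def read_event_table(path) -> pd.DataFrame:
    """Read a delimited event table (person_id, concept_id, event_date).

    Dates are ISO-8601 and converted to integer Julian days in a new
    ``day`` column.  Comma and tab delimiters are both accepted.
    """
    df = _read_delimited(path)
    required = {"person_id", "concept_id", "event_date"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    dates = pd.to_datetime(df["event_date"], format="%Y-%m-%d")
    df["day"] = [to_julian_day(d.year, d.month, d.day) for d in dates]
    return df


def write_event_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=["person_id", "concept_id", "event_date"])


def read_cohort_table(path) -> pd.DataFrame:
    """Read a delimited cohort table (person_id, index_date, label)."""
    df = _read_delimited(path)
    required = {"person_id", "index_date", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    dates = pd.to_datetime(df["index_date"], format="%Y-%m-%d")
    df["index_day"] = [to_julian_day(d.year, d.month, d.day) for d in dates]
    df["label"] = df["label"].astype(int)
    if not df["label"].isin([0, 1]).all():
        raise ValueError("cohort labels must be 0/1")
    return df


def write_cohort_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=["person_id", "index_date", "label"])


def timelines_from_table(df: pd.DataFrame) -> list[PatientTimeline]:
    """Group an event table (with ``day`` column) into per-patient timelines."""
    out = []
    for person_id, grp in df.groupby("person_id", sort=True):
        events = (
            Event(concept_id=str(c), day=int(d))
            for c, d in zip(grp["concept_id"], grp["day"])
        )
        out.append(PatientTimeline.from_events(str(person_id), events))
    return out
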