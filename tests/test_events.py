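"""Core data layer: calendar arithmetic, dictionary, sequence preparation."""

import datetime

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from claimseq.events import (
    EOS,
    PAD,
    Event,
    PatientTimeline,
    WindowSpec,
    apply_whitelist,
    build_dictionary,
    event_dropout,
    from_julian_day,
    prepare_sample,
    read_cohort_table,
    read_event_table,
    timelines_from_table,
    to_julian_day,
)

# datetime.date.toordinal is an independent proleptic-Gregorian day count;
# the offset to the Julian day number is a fixed constant.
_ORDINAL_TO_JDN = 1_721_425


class TestJulianDay:
    def test_reference_date(self):
        assert to_julian_day(2000, 1, 1) == 2_451_545

    def test_consecutive_days_differ_by_one(self):
        assert to_julian_day(2020, 2, 28) + 1 == to_julian_day(2020, 2, 29)
        assert to_julian_day(2020, 2, 29) + 1 == to_julian_day(2020, 3, 1)
        assert to_julian_day(1999, 12, 31) + 1 == to_julian_day(2000, 1, 1)

    def test_agrees_with_independent_day_count_oracle(self, rng):
        for _ in range(1000):
            ordinal = int(rng.integers(1, 3_650_000))
            d = datetime.date.fromordinal(ordinal)
            assert to_julian_day(d.year, d.month, d.day) == ordinal + _ORDINAL_TO_JDN

    def test_roundtrip_inverse(self, rng):
        for _ in range(200):
            jdn = int(rng.integers(1_000_000, 3_000_000))
            assert to_julian_day(*from_julian_day(jdn)) == jdn

    @pytest.mark.parametrize(
        "ymd", [(2021, 2, 29), (2000, 13, 1), (2000, 0, 5), (1999, 4, 31)]
    )
    def test_invalid_dates_rejected(self, ymd):
        with pytest.raises(ValueError):
            to_julian_day(*ymd)

    def test_epoch_shift_leaves_relative_times_unchanged(self):
        # only day differences enter the models, and differences equal
        # elapsed calendar days regardless of the epoch convention
        a = to_julian_day(2014, 3, 1)
        b = to_julian_day(2014, 6, 1)
        assert b - a == (datetime.date(2014, 6, 1) - datetime.date(2014, 3, 1)).days


class TestTimeline:
    def test_events_sorted_stably_by_day_then_concept(self):
        tl = PatientTimeline.from_events(
            "p",
            [Event("B", 10), Event("A", 10), Event("C", 5)],
        )
        assert [(e.concept_id, e.day) for e in tl.events] == [
            ("C", 5),
            ("A", 10),
            ("B", 10),
        ]

    def test_event_validation(self):
        with pytest.raises(ValueError):
            Event("", 5)


class TestDictionary:
    def test_top_k_by_frequency_with_rank_order_tokens(self, toy_timelines):
        d = build_dictionary(toy_timelines, 2)
        assert set(d.token_of) == {"A", "B"}
        assert d.token_of["A"] == 2 and d.token_of["B"] == 3
        assert d.counts == {"A": 5, "B": 3, "C": 2, "D": 1}

    def test_k_larger_than_corpus_maps_all_with_warning(self, toy_timelines):
        with pytest.warns(UserWarning):
            d = build_dictionary(toy_timelines, 100)
        assert d.size == 4

    def test_rank_tie_broken_lexically_and_stable(self):
        tls = [
            PatientTimeline.from_events(
                "p", [Event("Z", 1), Event("Y", 2), Event("A", 3)]
            )
        ]
        for _ in range(3):
            d = build_dictionary(tls, 2)
            assert set(d.token_of) == {"A", "Y"}

    def test_tokenize_detokenize_roundtrip(self, toy_dictionary):
        for cid in toy_dictionary.token_of:
            assert toy_dictionary.detokenize(toy_dictionary.tokenize(cid)) == cid

    def test_rejects_bad_k(self, toy_timelines):
        with pytest.raises(ValueError):
            build_dictionary(toy_timelines, 0)


class TestPrepareSample:
    def test_layout_pad_tokens_eos(self, toy_timelines, toy_dictionary):
        s = prepare_sample(
            toy_timelines[0], toy_dictionary, 2_450_100, WindowSpec(max_len=6)
        )
        toks = list(s.tokens)
        # 4 events, all in dictionary: A A B C -> tokens 2 2 3 4
        assert toks == [PAD, 2, 2, 3, 4, EOS]
        assert list(s.days_before_index) == [0, 99, 90, 80, 70, 0]

    def test_truncation_keeps_most_recent(self, toy_dictionary):
        events = [Event("A", 2_450_000 + i) for i in range(10)]
        tl = PatientTimeline.from_events("p", events)
        s = prepare_sample(tl, toy_dictionary, 2_450_100, WindowSpec(max_len=4))
        assert list(s.tokens) == [2, 2, 2, EOS]
        # earliest 7 discarded: remaining days are the 3 most recent
        assert list(s.days_before_index) == [93, 92, 91, 0]

    def test_empty_history_is_pad_then_eos(self, toy_dictionary):
        tl = PatientTimeline.from_events("p", [])
        s = prepare_sample(tl, toy_dictionary, 2_450_100, WindowSpec(max_len=4))
        assert list(s.tokens) == [PAD, PAD, PAD, EOS]

    def test_index_day_events_excluded(self, toy_dictionary):
        tl = PatientTimeline.from_events("p", [Event("A", 100), Event("B", 99)])
        s = prepare_sample(tl, toy_dictionary, 100, WindowSpec(max_len=4))
        assert list(s.tokens) == [PAD, PAD, 3, EOS]  # only B, strictly before

    def test_out_of_dictionary_concepts_dropped(self, toy_timelines):
        d = build_dictionary(toy_timelines, 1)  # only A
        s = prepare_sample(toy_timelines[1], d, 2_450_100, WindowSpec(max_len=4))
        assert list(s.tokens) == [PAD, PAD, 2, EOS]

    def test_idempotent_on_own_output(self, toy_timelines, toy_dictionary):
        w = WindowSpec(max_len=6)
        index_day = 2_450_100
        s1 = prepare_sample(toy_timelines[0], toy_dictionary, index_day, w)
        # reconstruct a timeline from the prepared sample and re-prepare
        events = [
            Event(toy_dictionary.detokenize(int(t)), index_day - int(d))
            for t, d in zip(s1.tokens, s1.days_before_index)
            if t >= 2
        ]
        s2 = prepare_sample(
            PatientTimeline.from_events("p1", events), toy_dictionary, index_day, w
        )
        assert np.array_equal(s1.tokens, s2.tokens)
        assert np.array_equal(s1.days_before_index, s2.days_before_index)


class TestWhitelist:
    def test_threshold_zero_is_identity(self, toy_sample, toy_dictionary):
        out = apply_whitelist(toy_sample, toy_dictionary, 0)
        assert np.array_equal(out.tokens, toy_sample.tokens)

    def test_rare_tokens_removed(self, toy_sample, toy_dictionary):
        # counts: A=5, B=3, C=2; threshold 3 removes C
        out = apply_whitelist(toy_sample, toy_dictionary, 3)
        kept = [int(t) for t in out.tokens if t >= 2]
        assert toy_dictionary.token_of["C"] not in kept
        assert toy_dictionary.token_of["A"] in kept

    def test_all_rare_leaves_eos_only(self, toy_sample, toy_dictionary):
        out = apply_whitelist(toy_sample, toy_dictionary, 10_000)
        assert list(out.tokens[out.tokens != PAD]) == [EOS]

    def test_no_surviving_token_below_threshold_exhaustive(
        self, toy_timelines, toy_dictionary
    ):
        for tl in toy_timelines:
            s = prepare_sample(tl, toy_dictionary, 2_450_100, WindowSpec(max_len=8))
            for thr in range(0, 7):
                out = apply_whitelist(s, toy_dictionary, thr)
                for tok in out.tokens[out.real_mask]:
                    assert toy_dictionary.count_of_token(int(tok)) >= thr

    def test_negative_threshold_rejected(self, toy_sample, toy_dictionary):
        with pytest.raises(ValueError):
            apply_whitelist(toy_sample, toy_dictionary, -1)


class TestEventDropout:
    def test_rate_zero_identity_rate_one_eos_only(self, toy_sample, rng):
        out0 = event_dropout(toy_sample, 0.0, rng)
        assert np.array_equal(out0.tokens, toy_sample.tokens)
        out1 = event_dropout(toy_sample, 1.0, rng)
        assert list(out1.tokens[out1.tokens != PAD]) == [EOS]

    def test_kept_count_binomial(self, toy_dictionary):
        n = 1000
        tl = PatientTimeline.from_events(
            "p", [Event("A", 2_450_000 + i) for i in range(n)]
        )
        s = prepare_sample(tl, toy_dictionary, 2_460_000, WindowSpec(max_len=n + 1))
        kept = []
        for seed in range(30):
            out = event_dropout(s, 0.5, np.random.default_rng(seed))
            kept.append(int(out.real_mask.sum()))
        # per-draw 99.99% binomial(1000, 0.5) interval (z=3.9, sd=15.8),
        # wide enough that 30 independent draws jointly stay inside
        assert all(438 <= k <= 562 for k in kept)
        assert 480 <= np.mean(kept) <= 520

    def test_deterministic_given_seed(self, toy_sample):
        a = event_dropout(toy_sample, 0.5, np.random.default_rng(7))
        b = event_dropout(toy_sample, 0.5, np.random.default_rng(7))
        assert np.array_equal(a.tokens, b.tokens)

    def test_bad_rate_rejected(self, toy_sample, rng):
        with pytest.raises(ValueError):
            event_dropout(toy_sample, 1.5, rng)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    n_events=st.integers(0, 30),
    max_len=st.integers(2, 12),
    seed=st.integers(0, 10_000),
)
def test_prepare_sample_invariants(n_events, max_len, seed):
    """Any prepared sample has one EOS, PADs in front, non-negative times."""
    r = np.random.default_rng(seed)
    concepts = ["A", "B", "C"]
    events = [
        Event(concepts[int(r.integers(3))], 2_450_000 + int(r.integers(100)))
        for _ in range(n_events)
    ]
    tl = PatientTimeline.from_events("p", events)
    d = build_dictionary(
        [PatientTimeline.from_events("q", [Event(c, 1) for c in concepts])], 3
    )
    s = prepare_sample(tl, d, 2_450_100, WindowSpec(max_len=max_len))
    assert len(s.tokens) == max_len
    assert int((s.tokens == EOS).sum()) == 1
    real_days = s.days_before_index[s.real_mask]
    assert (real_days > 0).all()


def test_table_roundtrip(tmp_path, toy_timelines):
    import pandas as pd

    from claimseq.events import write_event_table

    rows = []
    for tl in toy_timelines:
        for ev in tl.events:
            y, m, d = from_julian_day(ev.day)
            rows.append(
                {
                    "person_id": tl.person_id,
                    "concept_id": ev.concept_id,
                    "event_date": f"{y:04d}-{m:02d}-{d:02d}",
                }
            )
    df = pd.DataFrame(rows)
    path = tmp_path / "events.csv"
    write_event_table(df, path)
    back = read_event_table(path)
    tls = timelines_from_table(back)
    assert [tl.person_id for tl in tls] == ["p1", "p2", "p3"]
    orig = {(t.person_id, e.concept_id, e.day) for t in toy_timelines for e in t.events}
    got = {(t.person_id, e.concept_id, e.day) for t in tls for e in t.events}
    assert got == orig


def test_cohort_table_validation(tmp_path):
    path = tmp_path / "cohort.csv"
    path.write_text("person_id,index_date,label\np1,2014-01-01,1\np2,2014-01-01,0\n")
    df = read_cohort_table(path)
    assert list(df["label"]) == [1, 0]
    assert df["index_day"].nunique() == 1
    bad = tmp_path / "bad.csv"
    bad.write_text("person_id,index_date,label\np1,2014-01-01,2\n")
    with pytest.raises(ValueError):
        read_cohort_table(bad)
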