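"""Exposure-window expansion and day classification."""

import datetime as dt
from collections import Counter

import pytest

from adstar.windows import (
    AdsEvent,
    EventList,
    WindowLabel,
    WINDOW_DAYS,
    classify_days,
    dsi_dummies,
    expand_events,
)

D = dt.date
ONE = dt.timedelta(days=1)


def calendar(start, end):
    out = []
    d = start
    while d <= end:
        out.append(d)
        d += ONE
    return out


def oracle_classify(events, cal):
    """Per-day, rule-by-rule reference classification (independent of the
    window-expansion implementation)."""
    evs = sorted(events, key=lambda e: e.start)
    event_days = set()
    for e in evs:
        d = e.start
        while d <= e.end:
            event_days.add(d)
            d += ONE
    labels = {}
    for day in cal:
        in_event = day in event_days
        in_gap = any(
            prev.end < day <= prev.end + WINDOW_DAYS * ONE
            and nxt.start - WINDOW_DAYS * ONE <= day < nxt.start
            for prev, nxt in zip(evs, evs[1:])
        )
        in_post = any(e.end < day <= e.end + WINDOW_DAYS * ONE for e in evs)
        in_pre = any(e.start - WINDOW_DAYS * ONE <= day < e.start for e in evs)
        if in_event or in_gap:
            labels[day] = WindowLabel.EVENT
        elif in_post:
            labels[day] = WindowLabel.POST
        elif in_pre:
            labels[day] = WindowLabel.PRE
        else:
            labels[day] = WindowLabel.OTHER
    return labels


@pytest.mark.parametrize(
    "start,end,n",
    [
        (D(1998, 4, 17), D(1998, 4, 19), 3),
        (D(1997, 1, 1), D(1997, 1, 1), 1),
        (D(2000, 5, 13), D(2000, 5, 18), 6),
    ],
)
def test_expand_events_inclusive(start, end, n):
    dates = expand_events(EventList([AdsEvent(start, end)]))
    assert len(dates) == n
    assert min(dates) == start and max(dates) == end


def test_reversed_interval_rejected():
    with pytest.raises(ValueError, match="1998-04-19"):
        AdsEvent(D(1998, 4, 19), D(1998, 4, 17))


def test_isolated_event_windows():
    """An isolated 1997 episode: a full pre-week before and post-week after."""
    cal = calendar(D(1997, 2, 1), D(1997, 4, 30))
    got = {c.date: c.label for c in
           classify_days([AdsEvent(D(1997, 3, 7), D(1997, 3, 8))], cal)}
    for day in calendar(D(1997, 2, 28), D(1997, 3, 6)):
        assert got[day] is WindowLabel.PRE
    for day in calendar(D(1997, 3, 9), D(1997, 3, 15)):
        assert got[day] is WindowLabel.POST
    assert got[D(1997, 3, 7)] is WindowLabel.EVENT
    assert got[D(1997, 2, 27)] is WindowLabel.OTHER
    assert got[D(1997, 3, 16)] is WindowLabel.OTHER


def test_overlapping_windows_become_event_days():
    """Post-week of one episode meeting the pre-week of the next makes the
    whole squeezed stretch event days (the 1998 double episode)."""
    cal = calendar(D(1998, 4, 1), D(1998, 5, 15))
    events = [AdsEvent(D(1998, 4, 17), D(1998, 4, 19)),
              AdsEvent(D(1998, 4, 24), D(1998, 4, 26))]
    got = {c.date: c.label for c in classify_days(events, cal)}
    for day in calendar(D(1998, 4, 17), D(1998, 4, 26)):
        assert got[day] is WindowLabel.EVENT, day
    for day in calendar(D(1998, 4, 10), D(1998, 4, 16)):
        assert got[day] is WindowLabel.PRE
    for day in calendar(D(1998, 4, 27), D(1998, 5, 3)):
        assert got[day] is WindowLabel.POST


def test_no_events_all_other():
    cal = calendar(D(2001, 1, 1), D(2001, 2, 1))
    assert all(c.label is WindowLabel.OTHER
               for c in classify_days(EventList([]), cal))


def test_empty_calendar_rejected():
    with pytest.raises(ValueError):
        classify_days(EventList([]), [])


def test_partition_and_precedence(taipei_events):
    cal = calendar(D(1997, 1, 1), D(2007, 12, 31))
    out = classify_days(taipei_events, cal)
    assert len(out) == len(cal)  # exactly one label per day
    counts = Counter(c.label for c in out)
    assert sum(counts.values()) == 4017
    event_dates = expand_events(taipei_events)
    by_date = {c.date: c.label for c in out}
    assert all(by_date[d] is WindowLabel.EVENT for d in event_dates)


def test_idempotent(taipei_events):
    cal = calendar(D(1999, 1, 1), D(1999, 12, 31))
    a = classify_days(taipei_events, cal)
    b = classify_days(taipei_events, cal)
    assert a == b


def test_full_1999_matches_oracle(taipei_events):
    cal = calendar(D(1999, 1, 1), D(1999, 12, 31))
    ev_1999 = [e for e in taipei_events if e.start.year == 1999]
    got = {c.date: c.label for c in classify_days(ev_1999, cal)}
    assert got == oracle_classify(ev_1999, cal)


def test_random_event_lists_match_oracle():
    """100 random event lists (<= 10 events, gaps 1-20 days) agree with the
    per-day rule-application oracle."""
    import numpy as np

    rng = np.random.default_rng(2024)
    for _ in range(100):
        cal = calendar(D(2003, 1, 1), D(2003, 12, 31))
        events, cursor = [], D(2003, 2, 1)
        for _ in range(int(rng.integers(1, 11))):
            cursor += int(rng.integers(1, 21)) * ONE
            dur = int(rng.integers(1, 7))
            end = cursor + (dur - 1) * ONE
            if end > D(2003, 11, 30):
                break
            events.append(AdsEvent(cursor, end))
            cursor = end + ONE
        got = {c.date: c.label for c in classify_days(events, cal)}
        assert got == oracle_classify(events, cal)


def test_event_list_merges_and_sorts():
    ev = EventList([
        AdsEvent(D(2002, 4, 8), D(2002, 4, 12)),
        AdsEvent(D(2002, 3, 1), D(2002, 3, 2)),
        AdsEvent(D(2002, 4, 11), D(2002, 4, 15)),
    ])
    assert [(e.start, e.end) for e in ev] == [
        (D(2002, 3, 1), D(2002, 3, 2)),
        (D(2002, 4, 8), D(2002, 4, 15)),
    ]


@pytest.mark.parametrize(
    "label,expected",
    [
        (WindowLabel.PRE, (0, 0, 0)),
        (WindowLabel.EVENT, (1, 0, 0)),
        (WindowLabel.POST, (0, 1, 0)),
        (WindowLabel.OTHER, (0, 0, 1)),
        ("EVENT", (1, 0, 0)),
    ],
)
def test_dsi_dummies(label, expected):
    assert dsi_dummies(label) == expected


def test_dsi_dummies_unknown_label():
    with pytest.raises(ValueError):
        dsi_dummies("DURING")


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 300), st.integers(1, 6)),
                    max_size=8))
    def test_labels_partition_calendar(raw):
        """Property: labels always partition the calendar, events keep
        precedence, and no event day is ever PRE/POST/OTHER."""
        cal = calendar(D(2003, 1, 1), D(2003, 12, 31))
        events = EventList([
            AdsEvent(D(2003, 1, 1) + off * ONE,
                     D(2003, 1, 1) + (off + dur - 1) * ONE)
            for off, dur in raw
        ])
        out = classify_days(events, cal)
        assert len(out) == len(cal)
        by_date = {c.date: c.label for c in out}
        for d in expand_events(events):
            if D(2003, 1, 1) <= d <= D(2003, 12, 31):
                assert by_date[d] is WindowLabel.EVENT
except ImportError:  # pragma: no cover - hypothesis is an extra
    pass
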