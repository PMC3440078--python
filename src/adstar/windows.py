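"""Exposure-window classification for Asian dust storm (ADS) episodes.

Every day of the study calendar is assigned exactly one label:

* ``EVENT`` -- a day inside an ADS episode, or a day where the post-window of
  one episode overlaps the pre-window of the next (such squeezed gaps are
  counted as event days);
* ``PRE``   -- one of the 7 calendar days before an episode's first day;
* ``POST``  -- one of the 7 calendar days after an episode's last day;
* ``OTHER`` -- everything else.

Pre-ADS days act as the reference level of the dust storm index (DSI), so
:func:`dsi_dummies` emits three indicators (event, post, other) and all-zeros
for PRE.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "WindowLabel",
    "AdsEvent",
    "EventList",
    "DayClassification",
    "WINDOW_DAYS",
    "expand_events",
    "classify_days",
    "dsi_dummies",
]

logger = logging.getLogger(__name__)

#: length, in calendar days, of the pre- and post-episode windows
WINDOW_DAYS = 7

_ONE_DAY = dt.timedelta(days=1)


class WindowLabel(str, Enum):
    """Day label with respect to the surrounding ADS episodes."""

    PRE = "PRE"
    EVENT = "EVENT"
    POST = "POST"
    OTHER = "OTHER"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True, order=True)
class AdsEvent:
    """One ADS episode as an inclusive date interval."""

    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"ADS event has end before start: {self.start} .. {self.end}"
            )

    def dates(self) -> list[dt.date]:
        """All dates of the episode, start through end inclusive."""
        n = (self.end - self.start).days + 1
        return [self.start + dt.timedelta(days=i) for i in range(n)]


class EventList:
    """Ordered, non-overlapping list of :class:`AdsEvent`.

    Episodes are sorted by start date on construction; overlapping or
    immediately adjacent intervals are merged into one episode.
    """

    def __init__(self, events: Iterable[AdsEvent | tuple[dt.date, dt.date]]):
        evs = [
            e if isinstance(e, AdsEvent) else AdsEvent(e[0], e[1]) for e in events
        ]
        evs.sort(key=lambda e: (e.start, e.end))
        merged: list[AdsEvent] = []
        for e in evs:
            if merged and e.start <= merged[-1].end + _ONE_DAY:
                last = merged[-1]
                if e.start <= last.end:
                    logger.warning(
                        "merging overlapping ADS events %s..%s and %s..%s",
                        last.start, last.end, e.start, e.end,
                    )
                merged[-1] = AdsEvent(last.start, max(last.end, e.end))
            else:
                merged.append(e)
        self._events = merged

    def __iter__(self):
        return iter(self._events)

    def __len__(self) -> int:
        return len(self._events)

    def __getitem__(self, i):
        return self._events[i]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"EventList({len(self)} events)"


@dataclass(frozen=True)
class DayClassification:
    """A single day's window label."""

    date: dt.date
    label: WindowLabel


def expand_events(events: EventList | Iterable[AdsEvent]) -> set[dt.date]:
    """Union of all episode dates, each interval taken inclusively."""
    out: set[dt.date] = set()
    for e in events:
        out.update(e.dates())
    return out


def _window(first: dt.date, last: dt.date) -> list[dt.date]:
    return [first + dt.timedelta(days=i) for i in range((last - first).days + 1)]


def classify_days(
    events: EventList | Iterable[AdsEvent],
    calendar: Sequence[dt.date],
) -> list[DayClassification]:
    """Classify every calendar day as PRE, EVENT, POST or OTHER.

    Precedence is EVENT > POST > PRE > OTHER.  When the post-window of one
    episode intersects the pre-window of the next (episodes fewer than 15 days
    apart), the intersecting days are promoted to EVENT.  Windows reaching
    beyond the calendar are truncated with a logged warning.

    Parameters
    ----------
    events
        ADS episodes (merged and sorted if an :class:`EventList`).
    calendar
        The study days, in order, without gaps.

    Returns
    -------
    list of :class:`DayClassification`, one per calendar day, in calendar
    order.
    """
    if len(calendar) == 0:
        raise ValueError("calendar is empty")
    if not isinstance(events, EventList):
        events = EventList(events)
    cal_set = set(calendar)
    first_day, last_day = min(cal_set), max(cal_set)

    labels: dict[dt.date, WindowLabel] = {d: WindowLabel.OTHER for d in cal_set}

    evs = list(events)
    event_days: set[dt.date] = set()
    for e in evs:
        for d in e.dates():
            event_days.add(d)
            if d not in cal_set:
                logger.warning("ADS event day %s lies outside the calendar", d)
    # squeezed gaps: post-window of episode i meets pre-window of episode i+1
    for prev, nxt in zip(evs, evs[1:]):
        post = set(_window(prev.end + _ONE_DAY, prev.end + WINDOW_DAYS * _ONE_DAY))
        pre = set(_window(nxt.start - WINDOW_DAYS * _ONE_DAY, nxt.start - _ONE_DAY))
        event_days.update(post & pre)

    def assign(days: Iterable[dt.date], label: WindowLabel) -> None:
        for d in days:
            if d not in cal_set:
                logger.warning(
                    "%s window day %s truncated at calendar bounds [%s, %s]",
                    label.value, d, first_day, last_day,
                )
                continue
            if labels[d] is WindowLabel.OTHER:
                labels[d] = label

    # precedence realized by assignment order: EVENT first, then POST, then PRE
    for d in event_days:
        if d in cal_set:
            labels[d] = WindowLabel.EVENT
        else:
            logger.warning(
                "EVENT day %s truncated at calendar bounds [%s, %s]",
                d, first_day, last_day,
            )
    for e in evs:
        assign(_window(e.end + _ONE_DAY, e.end + WINDOW_DAYS * _ONE_DAY),
               WindowLabel.POST)
    for e in evs:
        assign(_window(e.start - WINDOW_DAYS * _ONE_DAY, e.start - _ONE_DAY),
               WindowLabel.PRE)
    return [DayClassification(d, labels[d]) for d in calendar]


def dsi_dummies(label: WindowLabel | str) -> tuple[int, int, int]:
    """Dust storm index indicators ``(event, post, other)``.

    PRE is the reference level and maps to ``(0, 0, 0)``.
    """
    label = WindowLabel(label)
    if label is WindowLabel.PRE:
        return (0, 0, 0)
    if label is WindowLabel.EVENT:
        return (1, 0, 0)
    if label is WindowLabel.POST:
        return (0, 1, 0)
    if label is WindowLabel.OTHER:
        return (0, 0, 1)
    raise ValueError(f"unknown window label: {label!r}")  # pragma: no cover
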