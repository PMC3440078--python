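"""Readers and writers for the delimited-text interchange formats.

All tables are comma-delimited with a header row and ISO-8601 dates:

* counts:       ``date,district,count``
* environment:  ``date,pm10,temperature``
* events:       ``event_id,start_date,end_date``
* population:   ``district,population``
* adjacency:    tab-delimited edge list ``district_a<TAB>district_b`` (a
  ``node,comma-separated-neighbours`` dialect is also accepted)

Bundled fixtures: the 1997-2007 Taipei dust-storm event list, a 12-district
Taipei adjacency graph (read off the district map; approximate), an
approximate district population table (synthetic stand-in for the 2000
census figures, which the package does not redistribute), and the published
spatial variance components used in worked examples.
"""

from __future__ import annotations

import datetime as dt
import logging
from importlib import resources

import networkx as nx
import pandas as pd

from .windows import AdsEvent, EventList

__all__ = [
    "read_counts",
    "read_environment",
    "read_events",
    "read_population",
    "read_adjacency",
    "write_classification",
    "load_taipei_events",
    "load_taipei_adjacency",
    "load_taipei_population",
    "load_reported_variance_components",
]

logger = logging.getLogger(__name__)


def _read_table(path, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}; found "
                         f"{list(df.columns)}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    return df


def read_counts(path) -> pd.DataFrame:
    """Long count table ``date,district,count``; duplicates are rejected."""
    df = _read_table(path, ["date", "district", "count"])
    df["date"] = pd.to_datetime(df["date"]).dt.date
    dup = df.duplicated(["date", "district"])
    if dup.any():
        lines = (df.index[dup] + 2).tolist()[:10]
        raise ValueError(f"{path}: duplicate (date, district) rows at lines "
                         f"{lines}")
    if (df["count"] < 0).any():
        bad = (df.index[df["count"] < 0] + 2).tolist()[:10]
        raise ValueError(f"{path}: negative counts at lines {bad}")
    return df


def read_environment(path) -> pd.DataFrame:
    """Daily ``date,pm10,temperature`` series from the monitoring station."""
    df = _read_table(path, ["date", "pm10", "temperature"])
    df["date"] = pd.to_datetime(df["date"]).dt.date
    if df["date"].duplicated().any():
        raise ValueError(f"{path}: duplicate dates")
    return df


def read_events(path) -> EventList:
    """ADS event list ``event_id,start_date,end_date`` (inclusive dates)."""
    df = _read_table(path, ["event_id", "start_date", "end_date"])
    events = []
    for row in df.itertuples():
        start = pd.Timestamp(row.start_date).date()
        end = pd.Timestamp(row.end_date).date()
        if end < start:
            raise ValueError(
                f"{path}: event {row.event_id} has end before start "
                f"({start} .. {end})"
            )
        events.append(AdsEvent(start, end))
    return EventList(events)


def read_population(path) -> pd.Series:
    """District population table ``district,population``."""
    df = _read_table(path, ["district", "population"])
    pop = df.set_index("district")["population"].astype(float)
    if (pop <= 0).any():
        raise ValueError(f"{path}: nonpositive populations")
    return pop


def read_adjacency(path) -> nx.Graph:
    """District adjacency graph from an edge list (or neighbour-list) file.

    One-sided edge listings are symmetrized with a warning; self-loops are
    dropped.
    """
    graph = nx.Graph()
    seen_directed: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                parts = [p.strip() for p in line.split("\t") if p.strip()]
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected two "
                                     f"tab-separated districts, got {line!r}")
                pairs = [(parts[0], parts[1])]
            else:
                parts = [p.strip() for p in line.split(",") if p.strip()]
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected "
                                     f"node,neighbour[,neighbour...], got {line!r}")
                pairs = [(parts[0], nb) for nb in parts[1:]]
            for a, b in pairs:
                if a == b:
                    logger.warning("%s:%d: dropping self-loop on %s",
                                   path, lineno, a)
                    continue
                seen_directed.add((a, b))
                graph.add_edge(a, b)
    if len(graph) == 0:
        raise ValueError(f"{path}: no edges found")
    asymmetric = [e for e in seen_directed if (e[1], e[0]) not in seen_directed]
    if asymmetric and len(asymmetric) < len(seen_directed):
        logger.warning("%s: %d one-sided edge listings symmetrized",
                       path, len(asymmetric))
    return graph


def write_classification(classification, path) -> None:
    """Write ``date,label`` rows for a day classification sequence."""
    with open(path, "w") as fh:
        fh.write("date,label\n")
        for c in classification:
            fh.write(f"{c.date.isoformat()},{c.label.value}\n")


# --- bundled fixtures ------------------------------------------------------


def _data(name: str):
    return resources.files("adstar.data").joinpath(name)


def load_taipei_events() -> EventList:
    """The 76 Taipei ADS episodes announced during 1997-2007."""
    with resources.as_file(_data("taipei_ads_events_1997_2007.csv")) as p:
        return read_events(p)


def load_taipei_adjacency() -> nx.Graph:
    """Approximate adjacency of the 12 Taipei City districts."""
    with resources.as_file(_data("taipei_adjacency.tsv")) as p:
        return read_adjacency(p)


def load_taipei_population() -> pd.Series:
    """Approximate (synthetic) district populations around the 2000 census."""
    with resources.as_file(_data("taipei_population_synthetic.csv")) as p:
        return read_population(p)


def load_reported_variance_components() -> pd.DataFrame:
    """Published spatial variance components by age group."""
    with resources.as_file(_data("reported_variance_components.csv")) as p:
        return pd.read_csv(p)


def study_calendar(
    start: dt.date = dt.date(1997, 1, 1), end: dt.date = dt.date(2007, 12, 31)
) -> list[dt.date]:
    """The study calendar, daily and inclusive (4,017 days by default)."""
    if end < start:
        raise ValueError(f"reversed calendar range {start} .. {end}")
    return [d.date() for d in pd.date_range(start, end, freq="D")]
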