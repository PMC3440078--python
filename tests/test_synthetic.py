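"""Ground-truth data generator: calendars, episodes, environment, counts."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from adstar.synthetic import (
    TrueParameters,
    simulate_calendar,
    simulate_counts,
    simulate_dataset,
    simulate_environment,
    simulate_events,
)
from adstar.windows import WindowLabel, classify_days, expand_events

D = dt.date


def test_calendar_lengths():
    assert len(simulate_calendar(D(1997, 1, 1), D(2007, 12, 31))) == 4017
    assert len(simulate_calendar(D(2001, 5, 5), D(2001, 5, 5))) == 1
    # leap February 2000
    assert len(simulate_calendar(D(2000, 2, 1), D(2000, 3, 1))) == 30
    with pytest.raises(ValueError):
        simulate_calendar(D(2001, 1, 2), D(2001, 1, 1))


def test_event_counts_in_plausible_envelope():
    """Over an 11-year calendar the generator should place episode counts
    consistent with 4-5 per year, for every seed."""
    cal = simulate_calendar(D(1997, 1, 1), D(2007, 12, 31))
    for seed in range(20):
        events = simulate_events(cal, seed=seed)
        assert 33 <= len(events) <= 66
        dates = sorted(expand_events(events))
        assert len(dates) == len(set(dates))  # non-overlapping
        durations = [(e.end - e.start).days + 1 for e in events]
        assert all(1 <= d <= 6 for d in durations)


def test_events_seasonal_and_deterministic():
    cal = simulate_calendar(D(1997, 1, 1), D(2006, 12, 31))
    a = simulate_events(cal, seed=5)
    b = simulate_events(cal, seed=5)
    assert [(e.start, e.end) for e in a] == [(e.start, e.end) for e in b]
    months = [e.start.month for e in a]
    winter_spring = sum(m in (1, 2, 3, 4, 5, 12) for m in months)
    assert winter_spring / len(months) > 0.7


def test_near_zero_rate_gives_empty_list():
    cal = simulate_calendar(D(2001, 1, 1), D(2001, 12, 31))
    assert len(simulate_events(cal, events_per_year=1e-9, seed=0)) == 0


def test_environment_event_elevation():
    cal = simulate_calendar(D(2000, 1, 1), D(2003, 12, 31))
    events = simulate_events(cal, seed=1)
    env = simulate_environment(cal, events, seed=1)
    assert (env["pm10"] > 0).all()
    on = env["date"].isin(expand_events(events))
    assert env.loc[on, "pm10"].mean() > 100.0
    assert env.loc[on, "pm10"].mean() > env.loc[~on, "pm10"].mean()
    # ablation: no elevation, means agree within noise
    flat = simulate_environment(cal, events, seed=1, event_elevation=0.0)
    ratio = flat.loc[on, "pm10"].mean() / flat.loc[~on, "pm10"].mean()
    assert 0.9 < ratio < 1.1


def test_environment_zero_noise_is_exact_sinusoid():
    cal = simulate_calendar(D(2001, 1, 1), D(2001, 12, 31))
    env = simulate_environment(cal, [], seed=0, temp_noise_sd=0.0)
    doy = np.array([d.timetuple().tm_yday for d in cal], float)
    expected = 23.0 - 7.0 * np.cos(2 * np.pi * (doy - 25.0) / 365.25)
    np.testing.assert_allclose(env["temperature"], expected, atol=1e-12)


def _flat_truth(**kw):
    pop = pd.Series(1000.0,
                    index=[f"d{i}" for i in range(12)])
    base = dict(
        alpha=np.log(0.5), dow=(0.0,) * 6,
        beta_event=0.0, beta_post=0.0, beta_other=0.0, gamma=0.0,
        temperature_response=lambda tp: np.zeros_like(np.asarray(tp, float)),
        trend=lambda t: np.zeros_like(np.asarray(t, float)),
        sigma2_u=0.0, sigma2_s=0.0, populations=pop,
    )
    base.update(kw)
    return TrueParameters(**base)


def test_counts_poisson_mean():
    """All effects zero, offset log(1000), alpha = log(0.5): the mean count
    must be ~500 over the full study length."""
    cal = simulate_calendar(D(1997, 1, 1), D(2007, 12, 31))
    env = simulate_environment(cal, [], seed=0)
    truth = _flat_truth()
    counts, u, eta = simulate_counts(cal, [], env, truth, seed=0,
                                     eta=np.zeros(12))
    assert abs(counts["count"].mean() / 500.0 - 1.0) < 0.01
    assert np.all(u == 0)


def test_counts_post_event_rate_ratio():
    """With only a post-window effect log(1.05), the empirical POST/PRE rate
    ratio is ~1.05."""
    cal = simulate_calendar(D(1997, 1, 1), D(2007, 12, 31))
    events = simulate_events(cal, seed=3)
    env = simulate_environment(cal, events, seed=3)
    truth = _flat_truth(beta_post=np.log(1.05))
    counts, _, _ = simulate_counts(cal, events, env, truth, seed=3,
                                   eta=np.zeros(12))
    labels = {c.date: c.label for c in classify_days(events, cal)}
    counts["label"] = counts["date"].map(labels)
    post = counts.loc[counts["label"] == WindowLabel.POST, "count"].mean()
    pre = counts.loc[counts["label"] == WindowLabel.PRE, "count"].mean()
    assert abs(post / pre - 1.05) < 0.01


def test_counts_dispersion():
    cal = simulate_calendar(D(2000, 1, 1), D(2003, 12, 31))
    env = simulate_environment(cal, [], seed=5)
    poisson, _, _ = simulate_counts(cal, [], env, _flat_truth(), seed=5,
                                    eta=np.zeros(12))
    over, _, _ = simulate_counts(cal, [], env, _flat_truth(dispersion=3.0),
                                 seed=5, eta=np.zeros(12))
    # constant mean 500 by construction: variance/mean ratio is the
    # dispersion parameter
    for frame, phi in ((poisson, 1.0), (over, 3.0)):
        ratio = frame["count"].var() / frame["count"].mean()
        assert abs(ratio / phi - 1.0) < 0.15


def test_dataset_determinism_and_roundtrip():
    a = simulate_dataset(seed=9, n_years=1)
    b = simulate_dataset(seed=9, n_years=1)
    pd.testing.assert_frame_equal(a.counts, b.counts)
    pd.testing.assert_frame_equal(a.environment, b.environment)
    np.testing.assert_array_equal(a.eta, b.eta)
    bundle = a.design()
    assert bundle.n_districts == 12
    assert bundle.n_days == len(a.calendar)
    assert np.isclose(a.eta.sum(), 0.0, atol=1e-10)
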