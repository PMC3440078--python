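"""Sampler building blocks: schedule arithmetic, variance updates, block
updates, determinism."""

import numpy as np
import pytest
from scipy import special, stats

from adstar.mcmc import (
    _DenseBlock,
    retained_count,
    run_chain,
    update_gaussian_block,
    update_variance,
)


@pytest.mark.parametrize(
    "total,burnin,thin,expected",
    [(22000, 2000, 20, 1000), (100, 0, 1, 100), (21, 1, 2, 10),
     (2200, 200, 20, 100)],
)
def test_retained_count(total, burnin, thin, expected):
    assert retained_count(total, burnin, thin) == expected


@pytest.mark.parametrize("total,burnin,thin", [(10, 10, 1), (5, 6, 1),
                                               (10, 0, 0), (10, -1, 1)])
def test_retained_count_invalid(total, burnin, thin):
    with pytest.raises(ValueError):
        retained_count(total, burnin, thin)


def test_variance_update_zero_coefficients_mean():
    """With zero coefficients the full conditional is IG(a + S/2, b), whose
    mean is b / (a + S/2 - 1)."""
    rng = np.random.default_rng(1)
    S, a, b = 8, 0.001, 0.001
    draws = np.array([
        update_variance(np.zeros(S), np.eye(S), a, b, rng, rank=S)
        for _ in range(100_000)
    ])
    expected = b / (a + S / 2 - 1)
    assert abs(draws.mean() / expected - 1) < 0.03


def test_variance_update_matches_direct_ig_sampler():
    """Kolmogorov-Smirnov agreement with scipy's inverse-gamma sampler for a
    fixed coefficient vector."""
    rng = np.random.default_rng(2)
    theta = np.array([0.3, -0.5, 0.8, 0.1])
    K = np.eye(4)
    a, b = 0.001, 0.001
    ours = np.array([update_variance(theta, K, a, b, rng)
                     for _ in range(100_000)])
    shape = a + 4 / 2
    scale = b + 0.5 * float(theta @ theta)
    direct = stats.invgamma.rvs(shape, scale=scale, size=100_000,
                                random_state=3)
    _, p = stats.ks_2samp(ours, direct)
    assert p > 0.01


def test_variance_update_monotone_in_b():
    rng = np.random.default_rng(4)
    small = np.median([update_variance(np.zeros(3), np.eye(3), 1.0, 0.1, rng)
                       for _ in range(2000)])
    large = np.median([update_variance(np.zeros(3), np.eye(3), 1.0, 100.0, rng)
                       for _ in range(2000)])
    assert large > small * 100


def test_variance_update_invalid():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        update_variance(np.zeros(3), np.zeros((3, 3)), 0.001, 0.001, rng)
    with pytest.raises(ValueError):
        update_variance(np.zeros(3), np.eye(3), -1.0, 0.001, rng)


def test_block_update_matches_analytic_posterior():
    """Intercept-only Poisson model: under a flat prior on the rate the
    posterior of the log-rate is a log-gamma with known mean (digamma) and
    variance (trigamma); the block sampler must reproduce both."""
    rng = np.random.default_rng(8)
    n = 200
    y = rng.poisson(20.0, size=n)
    block = _DenseBlock(np.ones((n, 1)))
    eta_rest = np.zeros(n)
    prior = np.array([[1e-10]])
    theta = np.array([np.log(y.mean())])  # start inside the typical set
    draws = []
    for i in range(3000):
        theta, _ = update_gaussian_block(block, theta, eta_rest, y, prior, rng)
        if i >= 500:
            draws.append(theta[0])
    draws = np.asarray(draws)
    a_post = y.sum()  # lambda | y ~ Gamma(sum y, n), theta = log lambda
    exact_mean = special.digamma(a_post) - np.log(n)
    exact_var = special.polygamma(1, a_post)
    mc_se = draws.std() / np.sqrt(len(draws))
    assert abs(draws.mean() - exact_mean) < 3 * mc_se + 1e-4
    assert 0.5 < draws.var() / exact_var < 2.0


def test_block_update_pinned_by_infinite_prior_precision():
    rng = np.random.default_rng(9)
    y = rng.poisson(5.0, size=50)
    block = _DenseBlock(np.ones((50, 1)))
    theta = np.array([0.0])
    prior = np.array([[1e14]])  # essentially a point mass at the prior mean
    for _ in range(50):
        theta, _ = update_gaussian_block(block, theta, np.zeros(50), y,
                                         prior, rng)
    assert abs(theta[0]) < 1e-4


def test_chain_seed_determinism(small_dataset):
    bundle = small_dataset.design()
    kw = dict(iterations=60, burnin=20, thin=4, seed=99,
              adjacency=small_dataset.adjacency)
    a = run_chain(bundle, **kw)
    b = run_chain(bundle, **kw)
    assert a.n_draws == 10
    for key in a.params:
        np.testing.assert_array_equal(a[key], b[key])


def test_chain_log_posterior_finite_and_acceptance_sane(fitted_small):
    draws = fitted_small.draws_
    assert np.isfinite(draws["log_post"]).all()
    for name, rate in draws.acceptance.items():
        assert 0.1 < rate <= 1.0, (name, rate)


def test_chain_requires_adjacency(small_dataset):
    with pytest.raises(ValueError, match="adjacency"):
        run_chain(small_dataset.design(), iterations=10, burnin=1, thin=1)


def test_draws_archive_roundtrip(tmp_path, fitted_small):
    from adstar.mcmc import PosteriorDraws

    d = fitted_small.draws_
    path = tmp_path / "draws.npz"
    d.save(path)
    back = PosteriorDraws.load(path)
    assert back.total == d.total and back.thin == d.thin
    assert back.districts == d.districts
    np.testing.assert_array_equal(back["dsi"], d["dsi"])
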