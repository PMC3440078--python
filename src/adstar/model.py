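"""Scikit-learn style front end for the structured additive Poisson model.

:class:`StarPoissonRegression` is a Bayesian estimator in the scikit-learn
idiom: hyperparameters in ``__init__``, data in ``fit``, fitted state in
trailing-underscore attributes.  ``X`` is the long district-day covariate
frame and ``y`` the visit counts; the district adjacency graph is a model
hyperparameter (as connectivity structure, much like the ``connectivity``
of agglomerative clustering).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .design import build_design, LINEAR_COLUMNS
from .mcmc import run_chain
from .smoothers import bspline_basis
from .summaries import (
    district_table,
    percent_change,
    pm10_percent_change,
    variance_ratio,
)
from .windows import DayClassification, WindowLabel

__all__ = ["StarPoissonRegression"]

_X_COLUMNS = ["date", "district", "pm10", "temperature", "population", "window"]


class StarPoissonRegression(BaseEstimator):
    """Bayesian structured additive Poisson regression for district-day counts.

    The log rate is modelled as intercept + day-of-week effects (Sunday
    reference) + dust-storm-index effects (pre-event week reference) + a
    linear PM10 term + P-spline smooths of temperature and calendar time +
    unstructured and intrinsic-CAR district effects + a log-population
    offset.  Posterior sampling is Metropolis-within-Gibbs with IWLS
    proposals for the Gaussian blocks and conjugate inverse-gamma variance
    updates.

    Parameters
    ----------
    adjacency : networkx.Graph
        Undirected district adjacency graph (nodes must cover the districts
        appearing in ``X``).
    iterations, burnin, thin : int
        MCMC schedule; the default (22000, 2000, 20) retains 1000 draws.
    m_temperature, m_time : int
        B-spline basis sizes of the temperature and calendar-time smooths.
    ig_a, ig_b : float
        IG(a, b) hyperprior on every variance parameter.
    dispersion_nu : float or None
        Fixed gamma shape of Poisson-gamma observation-level overdispersion;
        ``None`` fits a plain Poisson likelihood.
    random_state : int
        Seed of the sampler's random stream.

    Attributes
    ----------
    draws_ : PosteriorDraws
        Retained posterior samples of every parameter block.
    effects_ : pandas.DataFrame
        Percent-change summaries for the dust-storm-index effects and PM10
        (per 10 ug/m3), with 95% credible intervals and significance flags.
    district_rr_ : pandas.DataFrame
        District relative rates exp(eta_s) with the 80% posterior
        classification.
    rho_ : float
        Structured share of spatial variance, in percent, at the posterior
        means of the variance components.
    phi_ : pandas.Series
        Per-district Pearson overdispersion estimates at the posterior mean
        fit.
    acceptance_rates_ : dict
        Metropolis acceptance rate per coefficient block.

    Examples
    --------
    >>> from adstar import StarPoissonRegression, simulate_dataset
    >>> from adstar.model import dataset_to_Xy
    >>> ds = simulate_dataset(seed=1)
    >>> X, y = dataset_to_Xy(ds)
    >>> model = StarPoissonRegression(adjacency=ds.adjacency,
    ...                               iterations=2200, burnin=200)
    >>> model.fit(X, y)                                    # doctest: +SKIP
    """

    def __init__(
        self,
        adjacency=None,
        iterations: int = 22000,
        burnin: int = 2000,
        thin: int = 20,
        m_temperature: int = 10,
        m_time: int = 20,
        ig_a: float = 0.001,
        ig_b: float = 0.001,
        dispersion_nu: float | None = None,
        fixed_prior_var: float = 1e6,
        random_state: int = 20120315,
    ):
        self.adjacency = adjacency
        self.iterations = iterations
        self.burnin = burnin
        self.thin = thin
        self.m_temperature = m_temperature
        self.m_time = m_time
        self.ig_a = ig_a
        self.ig_b = ig_b
        self.dispersion_nu = dispersion_nu
        self.fixed_prior_var = fixed_prior_var
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------

    @staticmethod
    def _bundle_from_Xy(X: pd.DataFrame, y) -> "DesignBundle":  # noqa: F821
        missing = [c for c in _X_COLUMNS if c not in X.columns]
        if missing:
            raise ValueError(f"X is missing columns {missing}")
        X = X.copy()
        X["date"] = pd.to_datetime(X["date"]).dt.date
        counts = X[["date", "district"]].copy()
        counts["count"] = np.asarray(y)
        env = (X[["date", "pm10", "temperature"]]
               .drop_duplicates("date").sort_values("date"))
        pop = (X[["district", "population"]]
               .drop_duplicates("district").set_index("district")["population"])
        labels = [
            DayClassification(d, WindowLabel(l))
            for d, l in X[["date", "window"]].drop_duplicates("date").itertuples(
                index=False)
        ]
        return build_design(counts, env, pop, labels)

    # -- estimator API ---------------------------------------------------

    def fit(self, X: pd.DataFrame, y):
        """Sample the posterior given the district-day frame and counts.

        Parameters
        ----------
        X : pandas.DataFrame
            Columns ``date, district, pm10, temperature, population,
            window`` — one row per district-day; ``window`` is the
            PRE/EVENT/POST/OTHER label from
            :func:`adstar.windows.classify_days`.
        y : array-like
            Visit counts aligned with the rows of ``X``.
        """
        bundle = self._bundle_from_Xy(X, y)
        self.bundle_ = bundle
        self.draws_ = run_chain(
            bundle,
            iterations=self.iterations,
            burnin=self.burnin,
            thin=self.thin,
            seed=self.random_state,
            m_temperature=self.m_temperature,
            m_time=self.m_time,
            ig_a=self.ig_a,
            ig_b=self.ig_b,
            adjacency=self.adjacency,
            dispersion_nu=self.dispersion_nu,
            fixed_prior_var=self.fixed_prior_var,
        )
        d = self.draws_
        rows = []
        for j, name in enumerate(["ADS event days", "Post-ADS days",
                                  "Other days"]):
            s = percent_change(d["dsi"][:, j])
            rows.append((name, s.point, s.lower, s.upper, s.significant))
        s = pm10_percent_change(d["gamma"])
        rows.append(("PM10 per 10 ug/m3", s.point, s.lower, s.upper,
                     s.significant))
        self.effects_ = pd.DataFrame(
            rows, columns=["effect", "percent", "lower", "upper",
                           "significant"])
        self.district_rr_ = district_table(d["eta"], d.districts)
        self.rho_ = variance_ratio(float(d["sigma2_u"].mean()),
                                   float(d["sigma2_s"].mean()))
        self.acceptance_rates_ = dict(d.acceptance)
        self.n_iter_ = self.iterations
        mu = self._posterior_mean_mu(bundle)
        pearson = (bundle.y - mu) ** 2 / mu
        self.phi_ = pd.Series(
            np.bincount(bundle.district_index, weights=pearson)
            / np.bincount(bundle.district_index),
            index=bundle.districts, name="phi",
        )
        return self

    def _posterior_mean_mu(self, bundle) -> np.ndarray:
        d = self.draws_
        basis_tp = bspline_basis(bundle.temperature, self.m_temperature)
        basis_t = bspline_basis(np.arange(bundle.n_days, dtype=float),
                                self.m_time)
        fixed = np.concatenate([
            [d["alpha"].mean()], d["dow"].mean(axis=0),
            d["dsi"].mean(axis=0), [d["gamma"].mean()],
        ])
        day_part = (
            basis_tp.basis @ d["spline_tp"].mean(axis=0)
            + basis_t.basis @ d["spline_t"].mean(axis=0)
        )
        eta = (
            bundle.X @ fixed
            + day_part[bundle.day_index]
            + (d["u"].mean(axis=0) + d["eta"].mean(axis=0))[bundle.district_index]
            + bundle.offset
        )
        return np.exp(eta)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Posterior-mean expected counts for new district-day rows.

        Districts must be among those seen in ``fit``; smooths are evaluated
        on the fitted bases (covariates outside the fitted range are clipped
        to it).
        """
        check_is_fitted(self, "draws_")
        fitted = self.bundle_
        missing = [c for c in _X_COLUMNS if c not in X.columns]
        if missing:
            raise ValueError(f"X is missing columns {missing}")
        X = X.copy()
        X["date"] = pd.to_datetime(X["date"]).dt.date
        unknown = set(X["district"]) - set(fitted.districts)
        if unknown:
            raise ValueError(f"unknown districts: {sorted(unknown)}")

        d = self.draws_
        basis_tp = bspline_basis(fitted.temperature, self.m_temperature)
        basis_t = bspline_basis(np.arange(fitted.n_days, dtype=float),
                                self.m_time)
        date_pos = {dd: i for i, dd in enumerate(fitted.dates)}
        t_idx = np.array([date_pos.get(dd, -1) for dd in X["date"]], float)
        if (t_idx < 0).any():
            # dates outside the fitted calendar: extend the time axis, the
            # spline basis clips to its range (trend held at the boundary)
            base = fitted.dates[0]
            t_idx = np.array([(dd - base).days for dd in X["date"]], float)

        lin = np.empty((len(X), len(LINEAR_COLUMNS)))
        from .design import dow_dummies
        from .windows import dsi_dummies

        for i, row in enumerate(X.itertuples(index=False)):
            lin[i] = (1.0, *dow_dummies(row.date),
                      *dsi_dummies(WindowLabel(row.window)), row.pm10)
        fixed = np.concatenate([
            [d["alpha"].mean()], d["dow"].mean(axis=0),
            d["dsi"].mean(axis=0), [d["gamma"].mean()],
        ])
        spat = d["u"].mean(axis=0) + d["eta"].mean(axis=0)
        dist_pos = {s: j for j, s in enumerate(fitted.districts)}
        j_idx = np.array([dist_pos[s] for s in X["district"]])
        eta = (
            lin @ fixed
            + basis_tp.evaluate(X["temperature"].to_numpy(float))
            @ d["spline_tp"].mean(axis=0)
            + basis_t.evaluate(t_idx) @ d["spline_t"].mean(axis=0)
            + spat[j_idx]
            + np.log(X["population"].to_numpy(float))
        )
        return np.exp(eta)

    def score(self, X: pd.DataFrame, y) -> float:
        """Mean Poisson log-likelihood per observation at the posterior mean."""
        from scipy.stats import poisson

        mu = self.predict(X)
        return float(np.mean(poisson.logpmf(np.asarray(y), mu)))


def dataset_to_Xy(dataset) -> tuple[pd.DataFrame, np.ndarray]:
    """Flatten a :class:`~adstar.synthetic.SyntheticDataset` into (X, y)."""
    from .windows import classify_days

    labels = {c.date: c.label.value
              for c in classify_days(dataset.events, dataset.calendar)}
    df = dataset.counts.merge(dataset.environment, on="date")
    df["population"] = df["district"].map(dataset.population)
    df["window"] = df["date"].map(labels)
    X = df[_X_COLUMNS]
    y = df["count"].to_numpy()
    return X, y
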