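"""Posterior summaries on the reporting scale.

Log-rate coefficients are reported as percent changes,
``100 (exp(b) - 1)``, with 95% credible intervals from posterior quantiles;
an effect is flagged significant when its 95% interval excludes zero on the
coefficient scale.  District effects are reported as relative rates
``RR_s = exp(eta_s)`` against the city-wide mean level and classified
LOW / HIGH / NEUTRAL by whether at least 80% of the posterior mass of RR_s
lies below / above one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EffectSummary",
    "percent_change",
    "pm10_percent_change",
    "variance_ratio",
    "classify_spatial",
    "district_table",
]


@dataclass(frozen=True)
class EffectSummary:
    """Percent-change point estimate with a 95% credible interval."""

    point: float
    lower: float
    upper: float
    significant: bool

    def __str__(self) -> str:
        star = "*" if self.significant else ""
        return f"{self.point:.2f}% (95% CI {self.lower:.2f}, {self.upper:.2f}){star}"


def _summary(draws: np.ndarray, scale: float = 1.0) -> EffectSummary:
    draws = np.asarray(draws, dtype=float)
    if draws.size < 2:
        raise ValueError("need at least two posterior draws")
    lo, hi = np.quantile(scale * draws, [0.025, 0.975])
    point = 100.0 * np.expm1(scale * draws.mean())
    return EffectSummary(
        point=float(point),
        lower=float(100.0 * np.expm1(lo)),
        upper=float(100.0 * np.expm1(hi)),
        significant=bool(lo > 0 or hi < 0),
    )


def percent_change(coefficient_draws: np.ndarray) -> EffectSummary:
    """Percent change for a log-rate coefficient.

    Point estimate is the posterior mean of the coefficient, transformed;
    bounds are the transformed 2.5th/97.5th posterior quantiles.
    """
    return _summary(coefficient_draws)


def pm10_percent_change(
    gamma_draws: np.ndarray, increment: float = 10.0
) -> EffectSummary:
    """Percent change per ``increment`` ug/m3 of PM10 (default 10)."""
    return _summary(gamma_draws, scale=increment)


def variance_ratio(sigma2_u: float, sigma2_s: float) -> float:
    """Structured share of the spatial variance, rho (%) = 100 s2_s/(s2_u+s2_s)."""
    if sigma2_u < 0 or sigma2_s < 0:
        raise ValueError("variances must be nonnegative")
    total = sigma2_u + sigma2_s
    if total == 0:
        raise ValueError("both spatial variances are zero")
    return 100.0 * sigma2_s / total


def classify_spatial(rr_draws: np.ndarray, threshold: float = 0.8) -> str:
    """LOW / HIGH / NEUTRAL from the posterior mass of RR below/above one.

    Draws exactly equal to one count toward neither tail (the rule uses
    strict inequalities).
    """
    rr = np.asarray(rr_draws, dtype=float)
    if rr.size < 2:
        raise ValueError("need at least two posterior draws")
    if np.mean(rr < 1.0) >= threshold:
        return "LOW"
    if np.mean(rr > 1.0) >= threshold:
        return "HIGH"
    return "NEUTRAL"


def district_table(
    eta_draws: np.ndarray, districts: list, threshold: float = 0.8
) -> pd.DataFrame:
    """Per-district relative rates and their 80%-posterior classification.

    Parameters
    ----------
    eta_draws : ndarray of shape (n_draws, S)
        Posterior draws of the structured spatial effects.
    districts
        District identifiers in column order.
    """
    eta_draws = np.asarray(eta_draws, dtype=float)
    rr = np.exp(eta_draws)
    rows = []
    for j, name in enumerate(districts):
        rows.append({
            "district": name,
            "RR": float(np.exp(eta_draws[:, j].mean())),
            "RR_lower": float(np.exp(np.quantile(eta_draws[:, j], 0.025))),
            "RR_upper": float(np.exp(np.quantile(eta_draws[:, j], 0.975))),
            "P_RR_gt_1": float(np.mean(rr[:, j] > 1.0)),
            "classification": classify_spatial(rr[:, j], threshold),
        })
    return pd.DataFrame(rows)
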