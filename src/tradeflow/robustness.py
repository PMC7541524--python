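"""Replacement-based robustness of inference for a fitted coefficient.

Quantifies how much of the data would have to be replaced with
null-hypothesis cases (zero effect) before a significant estimate drops
below its significance threshold: with threshold = SE * t_crit(df, alpha)
the invalidating fraction is 1 - threshold/|estimate|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from tradeflow.errors import ValidationError
from tradeflow.netmodel import time_series_se


@dataclass
class RobustnessResult:
    """Threshold, fraction and case count needed to invalidate an inference."""

    estimate: float
    se: float
    df: int
    alpha: float
    threshold: float
    fraction_to_invalidate: float
    cases_to_invalidate: int
    n_cases: int
    inference_made: bool

    @property
    def percent_to_invalidate(self) -> float:
        return 100.0 * self.fraction_to_invalidate


def rir(
    estimate: float,
    se: float,
    df: int,
    alpha: float = 0.05,
    n_cases: int = 1,
) -> RobustnessResult:
    """Robustness of inference to replacement, closed form.

    When |estimate| does not exceed the two-sided significance threshold no
    inference is made and the fraction is zero (flagged via
    ``inference_made``).
    """
    if se <= 0 or not np.isfinite(se):
        raise ValidationError("se must be positive and finite")
    if df < 1:
        raise ValidationError("df must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must be in (0, 1)")
    if n_cases < 1:
        raise ValidationError("n_cases must be >= 1")
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    threshold = se * t_crit
    made = abs(estimate) > threshold
    fraction = max(0.0, 1.0 - threshold / abs(estimate)) if estimate != 0 else 0.0
    if not made:
        fraction = 0.0
    cases = int(round(fraction * n_cases))
    return RobustnessResult(
        estimate=float(estimate),
        se=float(se),
        df=int(df),
        alpha=float(alpha),
        threshold=float(threshold),
        fraction_to_invalidate=float(fraction),
        cases_to_invalidate=cases,
        n_cases=int(n_cases),
        inference_made=bool(made),
    )


def rir_from_posterior(
    draws,
    df: int,
    alpha: float = 0.05,
    n_cases: int = 1,
) -> RobustnessResult:
    """Robustness from an MCMC chain of a coefficient.

    The point estimate is the posterior mean and the standard error is the
    autocorrelation-adjusted (time-series) standard error of the chain.
    """
    x = np.asarray(draws, dtype=float).ravel()
    if x.size < 50:
        raise ValidationError("need at least 50 draws")
    se = time_series_se(x)
    return rir(float(np.mean(x)), se, df=df, alpha=alpha, n_cases=n_cases)
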