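"""Scikit-learn style estimator façades over the demography pipeline.

Both estimators accept a cohort in any of three forms: a
:class:`~killrate.cohort.CohortTable`, a pandas DataFrame in the cohort CSV
dialect, or (for :class:`KillRateEstimator`) a pre-built
:class:`~killrate.schedule.LifeSchedule`.  They follow the fit /
fitted-attribute convention and compose with sklearn tooling via
``get_params`` / ``set_params``.
"""

from __future__ import annotations

import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import CohortTable
from .demography import DemographicRates, demographic_rates
from .schedule import LifeSchedule, build_life_schedule
from .uncertainty import JackknifeResult, jackknife_rate

__all__ = ["KillRateEstimator", "JackknifeEstimator"]


def _as_cohort(X, treatment: str | None) -> CohortTable:
    if isinstance(X, CohortTable):
        return X
    if isinstance(X, pd.DataFrame):
        return CohortTable(X, treatment or "cohort")
    raise TypeError(
        f"expected a CohortTable or a cohort DataFrame, got {type(X).__name__}"
    )


class KillRateEstimator(BaseEstimator):
    """Estimate the demographic rate bundle of a predator cohort.

    Parameters
    ----------
    female_fraction : float, default 1.0
        Proportion of eggs counted toward the reproductive schedule
        (1.0 reports raw eggs per female).
    tolerance : float, default 1e-10
        Accepted residual of the Euler–Lotka equation at the solved root.

    Attributes (after ``fit``)
    --------------------------
    schedule_ : LifeSchedule
    K0_, Tk_, km_, km_approx_, Tk_lotka_ : float
    R0_, T_, rm_ : float or None (None when the cohort laid no eggs)
    doubling_km_, doubling_rm_ : float or None
    rates_ : DemographicRates
    """

    def __init__(self, female_fraction: float = 1.0, tolerance: float = 1e-10):
        self.female_fraction = female_fraction
        self.tolerance = tolerance

    def fit(self, X, y=None, treatment: str | None = None) -> "KillRateEstimator":
        if isinstance(X, LifeSchedule):
            schedule = X
        else:
            schedule = build_life_schedule(_as_cohort(X, treatment))
        rates: DemographicRates = demographic_rates(
            schedule, self.female_fraction, self.tolerance
        )
        self.schedule_ = schedule
        self.rates_ = rates
        self.K0_ = rates.K0
        self.Tk_ = rates.Tk
        self.km_ = rates.km
        self.km_approx_ = rates.km_approx
        self.Tk_lotka_ = rates.Tk_lotka
        self.R0_ = rates.R0
        self.T_ = rates.T
        self.rm_ = rates.rm
        self.doubling_km_ = rates.doubling_km
        self.doubling_rm_ = rates.doubling_rm
        self.n_features_in_ = 0
        return self


class JackknifeEstimator(BaseEstimator):
    """Leave-one-out jackknife of a Lotka-type rate over individuals.

    Parameters
    ----------
    rate : {"km", "rm"}, default "km"
        Which Euler–Lotka rate to resample.
    alpha : float, default 0.05
        Two-sided significance level of the t interval.
    female_fraction, tolerance :
        Forwarded to the rate solver.

    Attributes (after ``fit``)
    --------------------------
    full_estimate_ : float      rate from all n individuals
    pseudovalues_ : ndarray
    estimate_, se_ : float      jackknife point estimate and standard error
    interval_ : (float, float)  t-based confidence interval
    result_ : JackknifeResult
    """

    def __init__(
        self,
        rate: str = "km",
        alpha: float = 0.05,
        female_fraction: float = 1.0,
        tolerance: float = 1e-10,
    ):
        self.rate = rate
        self.alpha = alpha
        self.female_fraction = female_fraction
        self.tolerance = tolerance

    def fit(self, X, y=None, treatment: str | None = None) -> "JackknifeEstimator":
        cohort = _as_cohort(X, treatment)
        result: JackknifeResult = jackknife_rate(
            cohort,
            rate=self.rate,
            alpha=self.alpha,
            female_fraction=self.female_fraction,
            tolerance=self.tolerance,
        )
        self.result_ = result
        self.full_estimate_ = result.full_estimate
        self.pseudovalues_ = result.pseudovalues
        self.estimate_ = result.estimate
        self.se_ = result.se
        self.interval_ = result.interval
        self.n_ = result.n
        self.n_features_in_ = 0
        return self
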