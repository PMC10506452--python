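"""Demographic rates from a life schedule.

The central quantity is the pest kill rate k_m: the unique root of the
Euler–Lotka equation with the daily predation schedule k_x substituted for
the fertility schedule m_x,

    sum_x exp(-k_m * x) * l_x * k_x = 1.

Alongside it this module computes the net consumption rate
K0 = sum_x l_x k_x (prey killed per predator per generation, corrected by
age-specific mortality), the mean predation time
T_k = sum_x x l_x k_x / sum_x l_x k_x, the fertility-based analogues
(R0, T, r_m), and doubling times ln(2)/rate.

Two generation-time conventions coexist in the kill-rate literature: the
cohort formula above and the Lotka form T = ln(K0)/k_m derived from the
solved rate.  Both are reported (``Tk`` / ``Tk_lotka``); ln(K0)/Tk is also
reported as ``km_approx`` and is an approximation to k_m only when net
predation is concentrated near a single age.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .schedule import LifeSchedule

__all__ = [
    "DemographyError",
    "DemographicRates",
    "NonPositiveRateWarning",
    "net_rates",
    "solve_kill_rate",
    "solve_intrinsic_rate",
    "doubling_time",
    "kill_rate_approx",
    "demographic_rates",
]


class DemographyError(ValueError):
    """A rate is undefined for the given schedule."""


class NonPositiveRateWarning(UserWarning):
    """The Euler–Lotka root is not positive (lifetime total <= 1)."""


@dataclass
class DemographicRates:
    """Bundle of cohort demographic parameters for one treatment."""

    K0: float
    Tk: float
    km: float
    km_approx: float
    Tk_lotka: float
    R0: float | None = None
    T: float | None = None
    rm: float | None = None
    doubling_km: float | None = None
    doubling_rm: float | None = None
    treatment: str | None = None


def _lotka_root(ages: np.ndarray, net: np.ndarray, tolerance: float) -> float:
    """Root of f(k) = sum(net * exp(-k*ages)) - 1.

    f is strictly decreasing in k whenever net has mass at a positive age,
    so the root is unique; a bracketing Brent solve is guaranteed to
    converge.  The returned root satisfies |f(root)| <= tolerance.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    ages = np.asarray(ages, dtype=float)
    net = np.asarray(net, dtype=float)
    total = net.sum()
    if total <= 0:
        raise DemographyError("net schedule is identically zero; no rate exists")
    if net[ages > 0].sum() == 0:
        raise DemographyError(
            "all net mass at age 0: Euler-Lotka equation is degenerate"
        )

    def f(k: float) -> float:
        return float(np.sum(net * np.exp(-k * ages)) - 1.0)

    lo, hi = -1.0, 10.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - unreachable for finite schedules
            raise DemographyError("failed to bracket the Euler-Lotka root")
    while f(lo) < 0:
        lo *= 2.0
        if not math.isfinite(f(lo)) or lo < -700:
            raise DemographyError("failed to bracket the Euler-Lotka root")
    root = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    if abs(f(root)) > tolerance:
        raise DemographyError(
            f"solver residual {abs(f(root)):.3e} exceeds tolerance {tolerance:.3e}"
        )
    return float(root)


def net_rates(schedule: LifeSchedule) -> tuple[float, float]:
    """Net consumption rate K0 and mean predation time Tk.

    ``K0 = sum_x lx*kx`` exactly; ``Tk = sum_x x*lx*kx / K0``.  With an
    all-zero predation schedule K0 is 0 and Tk is undefined: NaN is returned
    with a warning rather than propagating silently.
    """
    net = schedule.net_predation
    K0 = float(net.sum())
    if K0 <= 0:
        warnings.warn(
            "predation schedule is all zero: K0 = 0 and Tk is undefined",
            UserWarning,
            stacklevel=2,
        )
        return 0.0, float("nan")
    Tk = float((schedule.ages * net).sum() / K0)
    return K0, Tk


def solve_kill_rate(schedule: LifeSchedule, tolerance: float = 1e-10) -> float:
    """Pest kill rate k_m: the Euler–Lotka root on the predation schedule.

    Requires K0 > 0; when K0 <= 1 the root is non-positive and a
    :class:`NonPositiveRateWarning` is emitted (the value is still returned).
    """
    K0 = float(schedule.net_predation.sum())
    if K0 <= 0:
        raise DemographyError("K0 = 0: kill rate undefined")
    km = _lotka_root(schedule.ages, schedule.net_predation, tolerance)
    if K0 <= 1:
        warnings.warn(
            f"K0 = {K0:.4g} <= 1: kill rate is non-positive ({km:.4g})",
            NonPositiveRateWarning,
            stacklevel=2,
        )
    return km


def solve_intrinsic_rate(
    schedule: LifeSchedule,
    female_fraction: float = 1.0,
    tolerance: float = 1e-10,
) -> tuple[float, float, float]:
    """Net reproductive rate R0, generation time T, intrinsic rate r_m.

    ``R0 = sum_x lx*mx*female_fraction``; ``T = sum_x x*lx*mx / sum_x lx*mx``
    (the female fraction cancels); ``r_m`` solves the Euler–Lotka equation on
    the scaled fertility schedule.  ``female_fraction`` defaults to 1 (raw
    eggs per female); pass the daughters-per-egg proportion for a
    daughters-only R0.
    """
    if not (0 < female_fraction <= 1):
        raise ValueError("female_fraction must be in (0, 1]")
    net = schedule.net_fertility * female_fraction
    total = float(net.sum())
    if total <= 0:
        raise DemographyError("fertility schedule is all zero: rm undefined")
    R0 = total
    T = float((schedule.ages * schedule.net_fertility).sum()
              / schedule.net_fertility.sum())
    rm = _lotka_root(schedule.ages, net, tolerance)
    if R0 <= 1:
        warnings.warn(
            f"R0 = {R0:.4g} <= 1: intrinsic rate is non-positive ({rm:.4g})",
            NonPositiveRateWarning,
            stacklevel=2,
        )
    return R0, T, rm


def doubling_time(rate: float) -> float:
    """Days for the quantity growing at ``rate`` per day to double: ln(2)/rate."""
    if rate <= 0:
        raise DemographyError(f"doubling time requires a positive rate, got {rate}")
    return math.log(2.0) / rate


def kill_rate_approx(K0: float, Tk: float) -> float:
    """The approximation ln(K0)/Tk for the kill rate.

    Exact only when all net predation falls at the single age Tk; reported
    alongside the solved root for comparison with published tables.
    """
    if K0 <= 0 or Tk <= 0:
        raise DemographyError("kill_rate_approx requires K0 > 0 and Tk > 0")
    return math.log(K0) / Tk


def demographic_rates(
    schedule: LifeSchedule,
    female_fraction: float = 1.0,
    tolerance: float = 1e-10,
) -> DemographicRates:
    """All demographic parameters of a schedule in one bundle.

    Fertility-based parameters are ``None`` when the cohort laid no eggs.
    """
    K0, Tk = net_rates(schedule)
    if K0 <= 0:
        raise DemographyError("K0 = 0: no demographic rates exist")
    km = solve_kill_rate(schedule, tolerance)
    rates = DemographicRates(
        K0=K0,
        Tk=Tk,
        km=km,
        km_approx=kill_rate_approx(K0, Tk),
        Tk_lotka=math.log(K0) / km if km > 0 else float("nan"),
        doubling_km=doubling_time(km) if km > 0 else None,
        treatment=schedule.treatment,
    )
    if schedule.net_fertility.sum() > 0:
        R0, T, rm = solve_intrinsic_rate(schedule, female_fraction, tolerance)
        rates.R0, rates.T, rates.rm = R0, T, rm
        rates.doubling_rm = doubling_time(rm) if rm > 0 else None
    return rates
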