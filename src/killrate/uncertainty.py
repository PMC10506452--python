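"""Jackknife uncertainty for Lotka-type rates and Newman–Keuls comparison.

Leave-one-out resampling over individuals turns the nonlinear Euler–Lotka
rate into pseudovalues

    v_i = n * theta_all - (n - 1) * theta_(-i)

whose mean and standard error give a point estimate and a t-based interval.
Groups of jackknifed rates are compared by the Student–Newman–Keuls
sequential studentized-range procedure with a compact letter display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import studentized_range, t as t_dist

from .cohort import CohortTable
from .demography import DemographyError, solve_intrinsic_rate, solve_kill_rate
from .schedule import build_life_schedule

__all__ = [
    "JackknifeError",
    "JackknifeResult",
    "ComparisonResult",
    "jackknife_rate",
    "jackknife_statistic",
    "newman_keuls",
    "t_interval",
]

RateKind = Literal["km", "rm"]


class JackknifeError(ValueError):
    """A leave-one-out sub-cohort made the rate unsolvable."""


def t_interval(estimate: float, se: float, n: int, alpha: float) -> tuple[float, float]:
    """Two-sided ``estimate +/- t(1-alpha/2, n-1) * se`` interval."""
    half = t_dist.ppf(1 - alpha / 2, n - 1) * se
    return (estimate - half, estimate + half)


@dataclass
class JackknifeResult:
    """Jackknife estimate of a rate for one treatment group."""

    treatment: str
    rate: str
    full_estimate: float
    pseudovalues: np.ndarray
    alpha: float = 0.05
    estimate: float = field(init=False)
    se: float = field(init=False)
    interval: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        self.pseudovalues = np.asarray(self.pseudovalues, dtype=float)
        if self.n < 2:
            raise JackknifeError("jackknife needs at least 2 individuals")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        self.estimate = float(self.pseudovalues.mean())
        self.se = float(self.pseudovalues.std(ddof=1) / np.sqrt(self.n))
        self.interval = t_interval(self.estimate, self.se, self.n, self.alpha)

    @property
    def n(self) -> int:
        return len(self.pseudovalues)

    @property
    def df(self) -> int:
        return self.n - 1

    @classmethod
    def from_summary(
        cls,
        treatment: str,
        estimate: float,
        se: float,
        n: int,
        rate: str = "km",
        alpha: float = 0.05,
    ) -> "JackknifeResult":
        """Construct a result whose pseudovalues exactly match a printed
        mean +/- SE (symmetric two-point-per-pair spread; useful for
        re-analysing published tables)."""
        base = np.resize([-1.0, 1.0], n).astype(float)
        base -= base.mean()
        sd = se * np.sqrt(n)
        base *= sd / base.std(ddof=1)
        return cls(treatment, rate, estimate, base + estimate, alpha)


def _rate_of(cohort: CohortTable, rate: RateKind, female_fraction: float,
             tolerance: float) -> float:
    schedule = build_life_schedule(cohort)
    if rate == "km":
        return solve_kill_rate(schedule, tolerance)
    if rate == "rm":
        return solve_intrinsic_rate(schedule, female_fraction, tolerance)[2]
    raise ValueError(f"unknown rate kind {rate!r}; expected 'km' or 'rm'")


def jackknife_rate(
    cohort: CohortTable,
    rate: RateKind = "km",
    alpha: float = 0.05,
    female_fraction: float = 1.0,
    tolerance: float = 1e-10,
) -> JackknifeResult:
    """Leave-one-out jackknife of the kill rate (or intrinsic rate).

    Each sub-cohort's schedule is rebuilt from scratch and the rate
    re-solved.  A sub-cohort on which the rate is unsolvable (e.g. zero net
    predation after removing the only killer) aborts with a diagnostic —
    pseudovalues are never silently dropped.
    """
    ids = cohort.individuals
    if len(ids) < 2:
        raise JackknifeError("jackknife needs at least 2 individuals")
    theta_all = _rate_of(cohort, rate, female_fraction, tolerance)
    n = len(ids)
    loo = np.empty(n)
    for i, iid in enumerate(ids):
        try:
            loo[i] = _rate_of(cohort.drop_individual(iid), rate,
                              female_fraction, tolerance)
        except DemographyError as exc:
            raise JackknifeError(
                f"treatment {cohort.treatment!r}: rate unsolvable after "
                f"removing individual {iid!r}: {exc}"
            ) from exc
    pseudo = n * theta_all - (n - 1) * loo
    return JackknifeResult(cohort.treatment, rate, theta_all, pseudo, alpha)


def jackknife_statistic(
    values: Sequence[float],
    statistic: Callable[[np.ndarray], float],
    alpha: float = 0.05,
    label: str = "",
) -> JackknifeResult:
    """Generic leave-one-out jackknife of ``statistic`` over a 1-D sample.

    For ``statistic = mean`` the pseudovalues reduce to the data themselves,
    so the jackknife SE coincides exactly with the classical standard error
    of the mean.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise JackknifeError("jackknife needs at least 2 values")
    theta_all = float(statistic(values))
    loo = np.array(
        [statistic(np.delete(values, i)) for i in range(n)], dtype=float
    )
    pseudo = n * theta_all - (n - 1) * loo
    return JackknifeResult(label, "statistic", theta_all, pseudo, alpha)


@dataclass
class ComparisonResult:
    """Outcome of a sequential multiple comparison across treatments.

    ``treatments`` are ordered by decreasing estimate; ``different`` maps
    unordered label pairs to the procedure's decision, and ``letters`` is the
    compact letter display (two groups share a letter iff they were not
    declared different).
    """

    treatments: list[str]
    estimates: dict[str, float]
    se: dict[str, float]
    different: dict[frozenset, bool]
    letters: dict[str, str]
    alpha: float
    method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "treatment": self.treatments,
                "estimate": [self.estimates[t] for t in self.treatments],
                "se": [self.se[t] for t in self.treatments],
                "letters": [self.letters[t] for t in self.treatments],
            }
        )


def _compact_letters(order: list[str], ns_runs: list[tuple[int, int]]) -> dict[str, str]:
    """Letter display from maximal non-significant runs of ordered groups.

    ``order`` is sorted by decreasing mean; runs are (start, stop) inclusive
    indices into that order.  Groups covered by no run get a private letter.
    """
    runs = sorted(set(ns_runs))
    # drop runs contained in another
    maximal = [
        r for r in runs
        if not any(o != r and o[0] <= r[0] and r[1] <= o[1] for o in runs)
    ]
    covered = {i for a, b in maximal for i in range(a, b + 1)}
    for i in range(len(order)):
        if i not in covered:
            maximal.append((i, i))
    maximal.sort()
    letters: dict[str, str] = {t: "" for t in order}
    for j, (a, b) in enumerate(maximal):
        letter = chr(ord("a") + j)
        for i in range(a, b + 1):
            letters[order[i]] += letter
    return letters


def newman_keuls(
    groups: Sequence[JackknifeResult],
    alpha: float = 0.05,
    error: Literal["pairwise", "pooled"] = "pairwise",
) -> ComparisonResult:
    """Student–Newman–Keuls sequential studentized-range comparison.

    Groups are ranked by jackknife estimate; each stretch of r adjacent
    ordered means is tested via ``q_obs`` against the critical value
    ``q(1-alpha; r, df)`` with pooled ``df = sum(n_i - 1)``.  A stretch that
    fails to reach significance is not subdivided, and a pair is declared
    different only when its own stretch and every containing stretch are
    significant (the standard sequential rule).  Ties in ranked means are
    broken by treatment label.

    The error term for a stretch uses its two extreme groups:

    * ``"pairwise"`` (default): ``q_obs = diff / sqrt(se_lo^2 + se_hi^2)``,
      the standard error of the difference of the two jackknife estimates —
      appropriate when group variances are unequal, as jackknife SEs of a
      nonlinear rate typically are;
    * ``"pooled"``: classical SNK with the pooled pseudovalue variance,
      ``q_obs = diff / sqrt(s2_pooled / n_h)`` (harmonic mean n of the two
      extreme groups).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    labels = [g.treatment for g in groups]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate treatment labels")
    for g in groups:
        if g.n < 2:
            raise JackknifeError(f"group {g.treatment!r} has n < 2")

    # ascending by estimate, ties broken by label (deterministic)
    asc = sorted(groups, key=lambda g: (g.estimate, g.treatment))
    k = len(asc)
    df = sum(g.n - 1 for g in asc)
    s2_pooled = (
        sum((g.n - 1) * g.pseudovalues.var(ddof=1) for g in asc) / df
    )

    def stretch_significant(i: int, j: int) -> bool:
        r = j - i + 1
        diff = asc[j].estimate - asc[i].estimate
        if error == "pairwise":
            denom = np.sqrt(asc[i].se ** 2 + asc[j].se ** 2)
        elif error == "pooled":
            n_h = 2.0 / (1.0 / asc[i].n + 1.0 / asc[j].n)
            denom = np.sqrt(s2_pooled / n_h)
        else:
            raise ValueError(f"unknown error convention {error!r}")
        if denom == 0:
            return diff > 0
        q_crit = studentized_range.ppf(1 - alpha, r, df)
        return diff / denom > q_crit

    sig_pairs: set[tuple[int, int]] = set()
    ns_runs: list[tuple[int, int]] = []
    candidates: set[tuple[int, int]] = {(0, k - 1)}
    for r in range(k, 1, -1):
        for (i, j) in sorted(c for c in candidates if c[1] - c[0] + 1 == r):
            candidates.discard((i, j))
            if any(a <= i and j <= b for a, b in ns_runs):
                continue  # contained in an accepted stretch: not subdivided
            if stretch_significant(i, j):
                sig_pairs.add((i, j))
                if j - i > 1:
                    candidates.add((i, j - 1))
                    candidates.add((i + 1, j))
            else:
                ns_runs.append((i, j))

    different: dict[frozenset, bool] = {}
    for i in range(k):
        for j in range(i + 1, k):
            different[frozenset((asc[i].treatment, asc[j].treatment))] = (
                (i, j) in sig_pairs
            )

    desc = [g.treatment for g in reversed(asc)]
    desc_runs = [(k - 1 - b, k - 1 - a) for a, b in ns_runs]
    letters = _compact_letters(desc, desc_runs)
    return ComparisonResult(
        treatments=desc,
        estimates={g.treatment: g.estimate for g in asc},
        se={g.treatment: g.se for g in asc},
        different=different,
        letters=letters,
        alpha=alpha,
        method=f"newman-keuls/{error}",
    )
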