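"""Age-specific schedules (l_x, m_x, k_x) and descriptive period summaries.

The life schedule is the bridge between raw daily records and the
demographic rates: ``lx`` is the fraction of the starting cohort alive at
age x, while ``mx`` (eggs/female/day) and ``kx`` (prey killed/female/day)
are means over the individuals *alive* at age x — mortality enters the
downstream rates only through ``lx``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import KILL_COLUMNS, CohortTable, PeriodPartition

__all__ = ["LifeSchedule", "build_life_schedule", "period_summary"]

_LIFETABLE_COLUMNS = ["x", "lx", "mx", "kx", "kx_egg", "kx_immature", "kx_adult"]


@dataclass
class LifeSchedule:
    """Age-indexed survival, fecundity and predation schedules.

    All vectors share the age grid ``ages = 0..x_max`` (integer days).
    ``kx`` is the total daily kill schedule and must equal the sum of the
    three prey-stage components elementwise.
    """

    ages: np.ndarray
    lx: np.ndarray
    mx: np.ndarray
    kx: np.ndarray
    kx_egg: np.ndarray
    kx_immature: np.ndarray
    kx_adult: np.ndarray
    treatment: str | None = None

    def __post_init__(self) -> None:
        arrays = [self.ages, self.lx, self.mx, self.kx,
                  self.kx_egg, self.kx_immature, self.kx_adult]
        for i, a in enumerate(arrays):
            arrays[i] = np.asarray(a, dtype=float)
        (self.ages, self.lx, self.mx, self.kx,
         self.kx_egg, self.kx_immature, self.kx_adult) = arrays
        n = len(self.ages)
        if any(len(a) != n for a in arrays[1:]):
            raise ValueError("all schedule vectors must be length-aligned")
        if n == 0:
            raise ValueError("empty schedule")
        if abs(self.lx[0] - 1.0) > 1e-12:
            raise ValueError("lx[0] must be 1 (whole cohort alive at age 0)")
        if (np.diff(self.lx) > 1e-12).any():
            raise ValueError("lx must be non-increasing")
        if ((self.lx < -1e-12) | (self.lx > 1 + 1e-12)).any():
            raise ValueError("lx must lie in [0, 1]")
        stage_sum = self.kx_egg + self.kx_immature + self.kx_adult
        # tolerance admits round-tripping through decimal CSV text
        if not np.allclose(stage_sum, self.kx, rtol=1e-7, atol=1e-7):
            raise ValueError("kx must equal kx_egg + kx_immature + kx_adult")

    @property
    def net_predation(self) -> np.ndarray:
        """lx * kx — the net kill schedule whose sum is K0."""
        return self.lx * self.kx

    @property
    def net_fertility(self) -> np.ndarray:
        return self.lx * self.mx

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.ages.astype(int),
                "lx": self.lx,
                "mx": self.mx,
                "kx": self.kx,
                "kx_egg": self.kx_egg,
                "kx_immature": self.kx_immature,
                "kx_adult": self.kx_adult,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, treatment: str | None = None) -> "LifeSchedule":
        missing = [c for c in _LIFETABLE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"life-table frame missing column(s): {missing}")
        return cls(
            ages=frame["x"].to_numpy(),
            lx=frame["lx"].to_numpy(),
            mx=frame["mx"].to_numpy(),
            kx=frame["kx"].to_numpy(),
            kx_egg=frame["kx_egg"].to_numpy(),
            kx_immature=frame["kx_immature"].to_numpy(),
            kx_adult=frame["kx_adult"].to_numpy(),
            treatment=treatment,
        )


def build_life_schedule(cohort: CohortTable) -> LifeSchedule:
    """Construct the age-specific schedules of a cohort.

    ``lx[x]`` is the number of individuals alive at age x over the cohort
    size; ``mx``/``kx`` are means over individuals alive at age x (zero when
    none are).  Vectors extend to the last age at which any individual was
    alive.
    """
    df = cohort.data
    n = cohort.n_individuals
    alive = df[df["alive"] == 1]
    if alive.empty:
        raise ValueError("cohort has no alive records")
    x_max = int(alive["age"].max())
    ages = np.arange(x_max + 1)

    counts = alive.groupby("age").size().reindex(ages, fill_value=0).to_numpy()
    lx = counts / n

    def _mean(col: pd.Series) -> np.ndarray:
        sums = col.groupby(alive["age"]).sum().reindex(ages, fill_value=0).to_numpy()
        return np.divide(sums, counts, out=np.zeros_like(sums, dtype=float),
                         where=counts > 0)

    mx = _mean(alive["eggs_laid"])
    kx_egg = _mean(alive["kills_egg"])
    kx_imm = _mean(alive["kills_immature"])
    kx_ad = _mean(alive["kills_adult"])
    return LifeSchedule(
        ages=ages,
        lx=lx,
        mx=mx,
        kx=kx_egg + kx_imm + kx_ad,
        kx_egg=kx_egg,
        kx_immature=kx_imm,
        kx_adult=kx_ad,
        treatment=cohort.treatment,
    )


def period_summary(
    cohort: CohortTable, partition: PeriodPartition | None = None
) -> pd.DataFrame:
    """Descriptive per-period statistics of daily kills and fecundity.

    For each life-cycle period the per-individual daily mean (over that
    individual's alive days within the period) and the per-individual period
    total are formed first; the reported ``mean``, ``sd`` and ``se`` are then
    taken across individuals.  ``sd`` uses n-1 degrees of freedom and is 0
    for a single individual.  Periods in which no individual was alive are
    reported with ``n = 0`` and NaN statistics (undefined, not zero).

    Returns a tidy frame with columns
    ``treatment, period, variable, basis, mean, sd, se, n``
    where ``variable`` is one of ``kills_total``, ``kills_egg``,
    ``kills_immature``, ``kills_adult``, ``eggs_laid`` and ``basis`` is
    ``daily`` (per-individual daily mean) or ``total`` (per-individual
    period total).
    """
    partition = partition or PeriodPartition()
    df = cohort.data[cohort.data["alive"] == 1].copy()
    df["kills_total"] = df[KILL_COLUMNS].sum(axis=1)
    df["period"] = df["age"].map(partition.period_of)

    variables = ["kills_total", *KILL_COLUMNS, "eggs_laid"]
    rows = []
    for p, label in enumerate(partition.labels):
        in_period = df[df["period"] == p]
        per_ind_mean = in_period.groupby("individual_id")[variables].mean()
        per_ind_total = in_period.groupby("individual_id")[variables].sum()
        for basis, per_ind in (("daily", per_ind_mean), ("total", per_ind_total)):
            n = len(per_ind)
            for var in variables:
                if n == 0:
                    mean = sd = se = np.nan
                else:
                    vals = per_ind[var].to_numpy(dtype=float)
                    mean = float(vals.mean())
                    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
                    se = sd / np.sqrt(n)
                rows.append(
                    (cohort.treatment, label, var, basis, mean, sd, se, n)
                )
    return pd.DataFrame(
        rows,
        columns=["treatment", "period", "variable", "basis", "mean", "sd", "se", "n"],
    )
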