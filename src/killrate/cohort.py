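"""Cohort data model: per-individual daily observation records and CSV I/O.

A cohort is a group of predator females followed daily from egg deposition
(age 0) to death.  Each predator-day row records survival, developmental
stage, eggs laid, and the number of prey killed split by prey stage
(egg / immature / adult).  The CSV dialect is one row per predator-day::

    individual_id,age,alive,stage,eggs_laid,kills_egg,kills_immature,kills_adult

with ``alive`` coded 0/1 and a single terminal ``alive=0`` row (all counts
zero) marking death.  Individuals still alive on their last observed day are
treated as dying the following day, with a :class:`CensoredCohortWarning`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STAGES",
    "COLUMNS",
    "KILL_COLUMNS",
    "DailyRecord",
    "PeriodPartition",
    "CohortTable",
    "CohortError",
    "CohortParseError",
    "CohortValidationError",
    "CensoredCohortWarning",
    "read_cohort",
    "write_cohort",
]

#: Developmental stages in chronological order (rank is used to check that a
#: stage never regresses within an individual).
STAGES: tuple[str, ...] = ("egg", "larva", "protonymph", "deutonymph", "adult")
_STAGE_RANK = {s: i for i, s in enumerate(STAGES)}

COLUMNS = [
    "individual_id",
    "age",
    "alive",
    "stage",
    "eggs_laid",
    "kills_egg",
    "kills_immature",
    "kills_adult",
]
KILL_COLUMNS = ["kills_egg", "kills_immature", "kills_adult"]
_COUNT_COLUMNS = ["eggs_laid", *KILL_COLUMNS]


class CohortError(ValueError):
    """Base class for cohort input problems."""


class CohortParseError(CohortError):
    """A CSV row could not be parsed into a daily record."""


class CohortValidationError(CohortError):
    """A structurally valid table violates a cohort invariant."""


class CensoredCohortWarning(UserWarning):
    """An individual was last seen alive; it is treated as dying the next day."""


@dataclass(frozen=True)
class DailyRecord:
    """One predator-day observation.

    Ages count days since egg deposition.  A dead record (``alive=False``)
    must carry all-zero counts and terminates the individual's series.
    """

    individual_id: str
    age: int
    alive: bool
    stage: str
    eggs_laid: int = 0
    kills_egg: int = 0
    kills_immature: int = 0
    kills_adult: int = 0

    def __post_init__(self) -> None:
        if self.age < 0:
            raise CohortValidationError(f"age must be >= 0, got {self.age}")
        if self.stage not in _STAGE_RANK:
            raise CohortValidationError(
                f"unknown stage {self.stage!r}; expected one of {STAGES}"
            )
        for name in _COUNT_COLUMNS:
            if getattr(self, name) < 0:
                raise CohortValidationError(f"{name} must be >= 0")
        if not self.alive and (
            self.eggs_laid or self.kills_egg or self.kills_immature or self.kills_adult
        ):
            raise CohortValidationError(
                f"individual {self.individual_id!r}: dead record at age "
                f"{self.age} has non-zero counts"
            )

    @property
    def kills_total(self) -> int:
        return self.kills_egg + self.kills_immature + self.kills_adult


@dataclass(frozen=True)
class PeriodPartition:
    """Split of the life cycle into three age periods.

    Ages ``0..b1`` form the developmental/preoviposition period, ages
    ``b1+1..b2`` the generation-time period, and ages ``> b2`` the residual
    lifetime.  Defaults (9, 29) give the periods 0-9 / 10-29 / 30+ days.
    """

    b1: int = 9
    b2: int = 29

    def __post_init__(self) -> None:
        if not (0 < self.b1 < self.b2):
            raise ValueError(f"need 0 < b1 < b2, got ({self.b1}, {self.b2})")

    @property
    def labels(self) -> tuple[str, str, str]:
        return (f"0-{self.b1}", f"{self.b1 + 1}-{self.b2}", f"{self.b2 + 1}+")

    def period_of(self, age: int) -> int:
        """Return the 0-based period index of an age."""
        if age <= self.b1:
            return 0
        if age <= self.b2:
            return 1
        return 2


def _normalise(df: pd.DataFrame) -> pd.DataFrame:
    df = df.loc[:, COLUMNS].copy()
    df["individual_id"] = df["individual_id"].astype(str)
    for col in ("age", "alive", *_COUNT_COLUMNS):
        df[col] = df[col].astype(np.int64)
    df["stage"] = df["stage"].astype(str)
    df = df.sort_values(["individual_id", "age"], kind="stable").reset_index(drop=True)
    return df


def _validate(df: pd.DataFrame) -> None:
    """Enforce cohort invariants; raise CohortValidationError naming the culprit."""
    bad_stage = set(df["stage"]) - set(STAGES)
    if bad_stage:
        raise CohortValidationError(f"unknown stage value(s): {sorted(bad_stage)}")
    if (df["age"] < 0).any():
        iid = df.loc[df["age"] < 0, "individual_id"].iloc[0]
        raise CohortValidationError(f"individual {iid!r}: negative age")
    if not df["alive"].isin((0, 1)).all():
        iid = df.loc[~df["alive"].isin((0, 1)), "individual_id"].iloc[0]
        raise CohortValidationError(f"individual {iid!r}: alive must be 0 or 1")
    neg = (df[_COUNT_COLUMNS] < 0).any(axis=1)
    if neg.any():
        iid = df.loc[neg, "individual_id"].iloc[0]
        raise CohortValidationError(f"individual {iid!r}: negative count")

    censored: list[str] = []
    for iid, grp in df.groupby("individual_id", sort=False):
        ages = grp["age"].to_numpy()
        if len(np.unique(ages)) != len(ages):
            raise CohortValidationError(f"individual {iid!r}: duplicate age")
        if ages[0] != 0:
            raise CohortValidationError(
                f"individual {iid!r}: series must start at age 0 (egg deposition), "
                f"starts at {ages[0]}"
            )
        if not np.all(np.diff(ages) == 1):
            raise CohortValidationError(f"individual {iid!r}: gap in age series")
        alive = grp["alive"].to_numpy()
        if (alive[:-1] == 0).any():
            raise CohortValidationError(
                f"individual {iid!r}: record after death row"
            )
        if alive[-1] == 0:
            dead = grp.iloc[-1]
            if dead[_COUNT_COLUMNS].to_numpy().any():
                raise CohortValidationError(
                    f"individual {iid!r}: dead record at age {dead['age']} has "
                    "non-zero counts"
                )
        else:
            censored.append(str(iid))
        ranks = grp["stage"].map(_STAGE_RANK).to_numpy()
        if (np.diff(ranks) < 0).any():
            raise CohortValidationError(f"individual {iid!r}: stage regression")
    if censored:
        warnings.warn(
            f"{len(censored)} individual(s) last seen alive (no death record); "
            f"treated as dying the following day: {censored[:5]}"
            + ("..." if len(censored) > 5 else ""),
            CensoredCohortWarning,
            stacklevel=3,
        )


class CohortTable:
    """Validated collection of daily records for one treatment.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per predator-day in the documented column dialect.
    treatment : str
        Cohort label (e.g. the rearing origin ``"Ld"``, ``"Gd"``, ``"Po"``).
    validate : bool
        Skip invariant checks when the frame is known-valid (internal use).
    """

    def __init__(self, data: pd.DataFrame, treatment: str, *, validate: bool = True):
        missing = [c for c in COLUMNS if c not in data.columns]
        if missing:
            raise CohortParseError(f"missing column(s): {missing}")
        df = _normalise(data)
        if df.empty:
            raise CohortValidationError("cohort has no records")
        if validate:
            _validate(df)
        self.data = df
        self.treatment = str(treatment)

    @classmethod
    def from_records(
        cls, records: Iterable[DailyRecord], treatment: str
    ) -> "CohortTable":
        rows = [
            (r.individual_id, r.age, int(r.alive), r.stage, r.eggs_laid,
             r.kills_egg, r.kills_immature, r.kills_adult)
            for r in records
        ]
        return cls(pd.DataFrame(rows, columns=COLUMNS), treatment)

    @property
    def individuals(self) -> list[str]:
        return list(dict.fromkeys(self.data["individual_id"]))

    @property
    def n_individuals(self) -> int:
        return self.data["individual_id"].nunique()

    def drop_individual(self, individual_id: str) -> "CohortTable":
        """Leave-one-out sub-cohort (records already validated)."""
        sub = self.data[self.data["individual_id"] != individual_id]
        if sub.empty:
            raise CohortValidationError("dropping the last individual")
        return CohortTable(sub, self.treatment, validate=False)

    def kills_total(self) -> pd.Series:
        """Per-row total prey killed (all prey stages)."""
        return self.data[KILL_COLUMNS].sum(axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return self.treatment == other.treatment and self.data.equals(other.data)

    def __repr__(self) -> str:
        return (
            f"CohortTable(treatment={self.treatment!r}, "
            f"n_individuals={self.n_individuals}, rows={len(self.data)})"
        )


def read_cohort(path: str | Path, treatment: str) -> CohortTable:
    """Read and validate a cohort CSV.

    Malformed rows raise :class:`CohortParseError` naming the 1-based file
    line; invariant violations raise :class:`CohortValidationError` naming
    the individual.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # malformed CSV structure
        raise CohortParseError(f"{path}: {exc}") from exc
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise CohortParseError(f"{path}: missing column(s) {missing}")
    for col in ("age", "alive", *_COUNT_COLUMNS):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() | (converted != converted.round())
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 zero-based
            raise CohortParseError(
                f"{path}:{line}: cannot parse {col}={raw.loc[bad.idxmax(), col]!r} "
                "as a non-negative integer"
            )
        raw[col] = converted.astype(np.int64)
    return CohortTable(raw, treatment)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort to CSV in the canonical dialect (round-trip safe)."""
    cohort.data.to_csv(path, index=False)


def records_of(cohort: CohortTable) -> list[DailyRecord]:
    """Materialise the table as a list of :class:`DailyRecord`."""
    return [
        DailyRecord(
            individual_id=row.individual_id,
            age=int(row.age),
            alive=bool(row.alive),
            stage=row.stage,
            eggs_laid=int(row.eggs_laid),
            kills_egg=int(row.kills_egg),
            kills_immature=int(row.kills_immature),
            kills_adult=int(row.kills_adult),
        )
        for row in cohort.data.itertuples(index=False)
    ]
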