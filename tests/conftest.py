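import numpy as np
import pandas as pd
import pytest

from killrate import (
    CohortTable,
    LifeSchedule,
    preset_configs,
    simulate_cohort,
)


def bisect_root(ages, net, lo=-1.0, hi=20.0, iters=200):
    """Independent plain-bisection oracle for the Euler-Lotka root."""
    ages = np.asarray(ages, dtype=float)
    net = np.asarray(net, dtype=float)

    def f(k):
        return np.sum(net * np.exp(-k * ages)) - 1.0

    assert f(lo) > 0 > f(hi), "oracle bracket must straddle the root"
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def make_schedule(lx, kx, mx=None, **kw):
    """LifeSchedule from bare survival/kill vectors (kills booked as prey eggs)."""
    lx = np.asarray(lx, dtype=float)
    kx = np.asarray(kx, dtype=float)
    mx = np.zeros_like(lx) if mx is None else np.asarray(mx, dtype=float)
    z = np.zeros_like(lx)
    return LifeSchedule(
        ages=np.arange(len(lx)), lx=lx, mx=mx, kx=kx,
        kx_egg=kx, kx_immature=z, kx_adult=z, **kw,
    )


def cohort_from_rows(rows, treatment="T"):
    """Cohort from (id, age, alive, stage, eggs, ke, ki, ka) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["individual_id", "age", "alive", "stage", "eggs_laid",
                 "kills_egg", "kills_immature", "kills_adult"],
    )
    return CohortTable(df, treatment)


def random_valid_schedule(rng, min_k0=1.5):
    """Random non-degenerate schedule whose Euler-Lotka root is positive."""
    while True:
        n_ages = int(rng.integers(4, 40))
        lx = np.cumprod(np.r_[1.0, rng.uniform(0.7, 1.0, n_ages - 1)])
        kx = rng.uniform(0, 6, n_ages) * (rng.random(n_ages) < 0.8)
        kx[0] = 0.0  # an egg cannot kill
        if (lx * kx).sum() > min_k0 and kx[1:].sum() > 0:
            return make_schedule(lx, kx)


@pytest.fixture(scope="session")
def ld_config():
    return preset_configs()["Ld"]


@pytest.fixture(scope="session")
def ld_cohort15(ld_config):
    """One 15-female cohort simulated under the Ld preset."""
    return simulate_cohort(ld_config, seed=2024)


@pytest.fixture(scope="session")
def ld_cohort200(ld_config):
    """A large Ld cohort for law-of-large-numbers checks."""
    from dataclasses import replace

    return simulate_cohort(replace(ld_config, n_females=200), seed=2024)


@pytest.fixture
def toy_schedule():
    """lx=(1,1,.5), kx=(0,2,4): K0=4, Tk=1.5, root of 2e^-k+2e^-2k=1."""
    return make_schedule([1.0, 1.0, 0.5], [0.0, 2.0, 4.0])
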