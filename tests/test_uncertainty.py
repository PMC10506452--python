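"""Jackknife resampling and Newman-Keuls sequential comparison."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import sem, studentized_range, t as t_dist

from killrate import (
    JackknifeError,
    JackknifeEstimator,
    JackknifeResult,
    build_life_schedule,
    expected_schedule,
    jackknife_rate,
    jackknife_statistic,
    newman_keuls,
    preset_configs,
    simulate_cohort,
    solve_kill_rate,
)
from conftest import bisect_root, cohort_from_rows


def _clone_cohort(n, kills=(0, 2, 4)):
    rows = []
    for i in range(n):
        iid = f"C{i}"
        for x, k in enumerate(kills):
            rows.append((iid, x, 1, "adult" if x else "egg", 0, k, 0, 0))
        rows.append((iid, len(kills), 0, "adult", 0, 0, 0, 0))
    return cohort_from_rows(rows)


class TestJackknifeRate:
    def test_identical_clones_have_zero_se(self):
        res = jackknife_rate(_clone_cohort(6))
        assert res.se == pytest.approx(0.0, abs=1e-12)
        assert res.estimate == pytest.approx(res.full_estimate, abs=1e-10)
        lo, hi = res.interval
        assert lo == pytest.approx(hi, abs=1e-10)  # degenerate point interval

    def test_three_individual_enumeration(self):
        """Pseudovalues match a by-hand leave-one-out enumeration."""
        series = {"A": (0, 2, 4), "B": (0, 3, 3), "C": (0, 1, 1)}
        rows = []
        for iid, kills in series.items():
            for x, k in enumerate(kills):
                rows.append((iid, x, 1, "adult" if x else "egg", 0, k, 0, 0))
            rows.append((iid, 3, 0, "adult", 0, 0, 0, 0))
        cohort = cohort_from_rows(rows)

        ages = np.arange(3)

        def rate_of(ids):
            kx = np.mean([series[i] for i in ids], axis=0)  # all alive ages 0-2
            return bisect_root(ages, kx)

        theta_all = rate_of(list(series))
        expected_pseudo = [
            3 * theta_all - 2 * rate_of([j for j in series if j != i])
            for i in series
        ]
        res = jackknife_rate(cohort)
        assert res.full_estimate == pytest.approx(theta_all, abs=1e-8)
        assert np.allclose(res.pseudovalues, expected_pseudo, atol=1e-7)

    def test_interval_is_t_based(self):
        rng = np.random.default_rng(0)
        pseudo = rng.normal(0.5, 0.05, 15)
        res = JackknifeResult("T", "km", 0.5, pseudo)
        half = t_dist.ppf(0.975, 14) * res.se
        assert res.interval[1] - res.interval[0] == pytest.approx(2 * half, abs=1e-12)
        assert res.interval[0] <= res.estimate <= res.interval[1]

    def test_unsolvable_leave_one_out_aborts_with_diagnostic(self):
        # only one of two females ever kills: dropping her leaves no predation
        rows = []
        for iid, k in (("killer", 3), ("pacifist", 0)):
            for x in range(3):
                rows.append((iid, x, 1, "adult" if x else "egg", 0,
                             k if x else 0, 0, 0))
            rows.append((iid, 3, 0, "adult", 0, 0, 0, 0))
        with pytest.raises(JackknifeError, match="killer"):
            jackknife_rate(cohort_from_rows(rows))

    def test_needs_two_individuals(self):
        with pytest.raises(JackknifeError):
            jackknife_rate(_clone_cohort(1))

    def test_rm_rate_kind(self, ld_cohort15):
        res = jackknife_rate(ld_cohort15, rate="rm")
        assert res.rate == "rm"
        assert 0 < res.estimate < 1

    def test_estimator_facade(self, ld_cohort15):
        est = JackknifeEstimator(rate="km", alpha=0.05).fit(ld_cohort15)
        res = jackknife_rate(ld_cohort15)
        assert est.estimate_ == pytest.approx(res.estimate, abs=1e-12)
        assert est.se_ == pytest.approx(res.se, abs=1e-12)
        assert est.interval_ == pytest.approx(res.interval, abs=1e-12)


def test_jackknife_of_mean_equals_classical_se():
    """For the sample mean, pseudovalues are the data: SE matches sem exactly."""
    rng = np.random.default_rng(42)
    values = rng.gamma(2.0, 3.0, 25)
    res = jackknife_statistic(values, np.mean)
    assert np.allclose(np.sort(res.pseudovalues), np.sort(values), atol=1e-9)
    assert res.estimate == pytest.approx(values.mean(), abs=1e-12)
    assert res.se == pytest.approx(sem(values), abs=1e-12)


def test_from_summary_reproduces_mean_and_se():
    res = JackknifeResult.from_summary("Ld", 0.515, 0.015, 15)
    assert res.estimate == pytest.approx(0.515, abs=1e-12)
    assert res.se == pytest.approx(0.015, abs=1e-12)
    assert res.n == 15


class TestNewmanKeuls:
    @staticmethod
    def summaries(spec, alpha=0.05):
        return [
            JackknifeResult.from_summary(label, est, se, n, alpha=alpha)
            for label, est, se, n in spec
        ]

    def test_identical_groups_not_different(self):
        groups = self.summaries([("A", 0.5, 0.01, 15), ("B", 0.5, 0.01, 15)])
        comp = newman_keuls(groups)
        assert comp.different[frozenset(("A", "B"))] is False
        assert comp.letters["A"] == comp.letters["B"]

    def test_widely_separated_groups_differ(self):
        """Means 10 SE apart: q_obs clears the critical value by direct check."""
        groups = self.summaries([("A", 0.5, 0.01, 15), ("B", 0.6, 0.01, 15)])
        q_obs = 0.1 / np.sqrt(2 * 0.01**2)
        assert q_obs > studentized_range.ppf(0.95, 2, 28)
        comp = newman_keuls(groups)
        assert comp.different[frozenset(("A", "B"))] is True
        assert comp.letters["A"] != comp.letters["B"]

    def test_pooled_error_convention_is_more_liberal_here(self):
        """With unequal SEs the pooled convention can split what the
        pairwise convention keeps together (documented difference)."""
        spec = [("Ld", 0.515, 0.015, 15), ("Gd", 0.517, 0.007, 15),
                ("Po", 0.475, 0.006, 15)]
        pairwise = newman_keuls(self.summaries(spec), error="pairwise")
        pooled = newman_keuls(self.summaries(spec), error="pooled")
        assert pairwise.different[frozenset(("Ld", "Po"))] is False
        assert pooled.different[frozenset(("Ld", "Po"))] is True

    @pytest.mark.parametrize("seed", range(8))
    def test_letters_consistent_with_decisions(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        spec = [
            (f"G{i}", float(rng.normal(0.5, 0.05)),
             float(rng.uniform(0.002, 0.03)), int(rng.integers(5, 20)))
            for i in range(k)
        ]
        comp = newman_keuls(self.summaries(spec))
        for pair, diff in comp.different.items():
            a, b = sorted(pair)
            shared = set(comp.letters[a]) & set(comp.letters[b])
            assert bool(shared) == (not diff), (
                f"letters {comp.letters} inconsistent with {pair}: {diff}"
            )

    @pytest.mark.parametrize("seed", range(12))
    def test_never_splits_when_full_range_test_accepts(self, seed):
        """Sequential dominance: if the widest stretch fails the studentized
        range test (the Tukey full-range check), nothing may be declared."""
        rng = np.random.default_rng(100 + seed)
        k = int(rng.integers(3, 6))
        spec = [
            (f"G{i}", float(rng.normal(0.5, 0.01)),
             float(rng.uniform(0.005, 0.03)), 15)
            for i in range(k)
        ]
        groups = self.summaries(spec)
        ordered = sorted(groups, key=lambda g: g.estimate)
        lo, hi = ordered[0], ordered[-1]
        q_full = (hi.estimate - lo.estimate) / np.sqrt(lo.se**2 + hi.se**2)
        df = sum(g.n - 1 for g in groups)
        full_range_ns = q_full <= studentized_range.ppf(0.95, k, df)
        comp = newman_keuls(groups)
        if full_range_ns:
            assert not any(comp.different.values())

    def test_needs_two_groups_and_valid_sizes(self):
        (only,) = self.summaries([("A", 0.5, 0.01, 15)])
        with pytest.raises(ValueError):
            newman_keuls([only])
        with pytest.raises(ValueError, match="duplicate"):
            newman_keuls(self.summaries([("A", 0.5, 0.01, 5),
                                         ("A", 0.6, 0.01, 5)]))

    def test_result_frame_layout(self):
        comp = newman_keuls(self.summaries(
            [("A", 0.4, 0.01, 10), ("B", 0.6, 0.01, 10)]))
        frame = comp.to_frame()
        assert list(frame.columns) == ["treatment", "estimate", "se", "letters"]
        assert list(frame["treatment"]) == ["B", "A"]  # descending estimate


def test_jackknife_interval_coverage_of_limiting_rate():
    """Loose stochastic check: the (1-alpha) interval for km covers the
    large-cohort limiting km in at least 1-alpha-0.05 of replicates."""
    config = preset_configs()["Ld"]
    limit = solve_kill_rate(expected_schedule(config))
    reps = 200
    hits = 0
    base = np.random.SeedSequence(31415).generate_state(reps) % (2**31)
    for seed in base:
        res = jackknife_rate(simulate_cohort(config, seed=int(seed)))
        hits += res.interval[0] <= limit <= res.interval[1]
    assert hits / reps >= 0.90
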