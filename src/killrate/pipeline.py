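"""End-to-end pipeline: cohorts -> schedules -> rates -> jackknife -> comparison.

``run_pipeline`` drives the whole analysis for a set of treatments, each
sourced either from a cohort CSV or from a named simulator preset, and
writes a flat-file report bundle:

* ``cohort_<t>.csv``       simulated cohorts (only for preset sources)
* ``lifetable_<t>.csv``    age-specific lx, mx, kx schedules
* ``period_summary.csv``   descriptive period means ± SD/SE
* ``rates.csv``            K0, Tk, km, km_approx, R0, T, rm, doubling times
* ``comparison.csv``       jackknife estimates, intervals, letters
* ``summary.txt``          human-readable layout of the main table
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable, PeriodPartition, read_cohort, write_cohort
from .demography import DemographicRates, demographic_rates
from .schedule import build_life_schedule, period_summary
from .simulate import SimulationConfig, preset_configs, simulate_cohort
from .uncertainty import ComparisonResult, JackknifeResult, jackknife_rate, newman_keuls

__all__ = ["RunManifest", "PipelineError", "run_pipeline"]

logger = logging.getLogger("killrate")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and treatment."""


@dataclass
class RunManifest:
    """Inputs and options of one pipeline run.

    ``inputs`` maps treatment labels to cohort CSV paths; ``presets`` lists
    simulator preset names (Ld, Gd, Po).  A label may appear in only one of
    the two.
    """

    inputs: dict[str, Path] = field(default_factory=dict)
    presets: list[str] = field(default_factory=list)
    n_females: int | None = None
    partition: PeriodPartition = field(default_factory=PeriodPartition)
    alpha: float = 0.05
    tolerance: float = 1e-10
    female_fraction: float = 1.0
    seed: int = 0
    outdir: Path = Path("killrate-out")
    nk_error: str = "pairwise"

    def __post_init__(self) -> None:
        self.inputs = {str(k): Path(v) for k, v in self.inputs.items()}
        self.outdir = Path(self.outdir)
        overlap = set(self.inputs) & set(self.presets)
        if overlap:
            raise ValueError(
                f"treatment(s) {sorted(overlap)} given both as input file and preset"
            )
        if not self.inputs and not self.presets:
            raise ValueError("manifest names no treatments")


def _load_cohorts(manifest: RunManifest) -> dict[str, tuple[CohortTable, bool]]:
    """Return {label: (cohort, simulated?)} in manifest order."""
    cohorts: dict[str, tuple[CohortTable, bool]] = {}
    available = preset_configs()
    seeds = np.random.SeedSequence(manifest.seed).generate_state(
        max(1, len(manifest.presets))
    ) % (2**31)
    for i, name in enumerate(manifest.presets):
        if name not in available:
            raise PipelineError(
                f"stage simulate, treatment {name!r}: unknown preset "
                f"(have {sorted(available)})"
            )
        config = available[name]
        if manifest.n_females is not None:
            config = replace(config, n_females=manifest.n_females)
        seed = int(seeds[i])
        logger.info("simulate %s: n_females=%d seed=%d", name, config.n_females, seed)
        cohorts[name] = (simulate_cohort(config, seed=seed), True)
    for label, path in manifest.inputs.items():
        if not path.exists():
            raise PipelineError(
                f"stage read, treatment {label!r}: no such file {path}"
            )
        try:
            cohorts[label] = (read_cohort(path, label), False)
        except Exception as exc:
            raise PipelineError(
                f"stage read, treatment {label!r}: {exc}"
            ) from exc
    return cohorts


def _format_summary(
    rates: dict[str, DemographicRates],
    jack: dict[str, JackknifeResult],
    comparison: ComparisonResult | None,
    period_tables: pd.DataFrame,
    manifest: RunManifest,
) -> str:
    labels = list(rates)
    letters = comparison.letters if comparison else {t: "" for t in labels}
    width = max(12, *(len(t) + 2 for t in labels))
    lines = [
        "Pest kill rate report",
        f"alpha={manifest.alpha}  solver tolerance={manifest.tolerance}  "
        f"seed={manifest.seed}",
        "",
        "Parameter".ljust(28) + "".join(t.rjust(width) for t in labels),
    ]

    def row(name: str, fmt: str, values: list) -> str:
        cells = ["-" if v is None else format(v, fmt) for v in values]
        return name.ljust(28) + "".join(c.rjust(width) for c in cells)

    lines.append(row("km (Euler-Lotka root)", ".3f", [rates[t].km for t in labels]))
    lines.append(
        "km jackknife +/- SE".ljust(28)
        + "".join(
            f"{jack[t].estimate:.3f}±{jack[t].se:.3f} {letters.get(t, ''):2s}".rjust(width)
            for t in labels
        )
    )
    lines.append(
        "km interval".ljust(28)
        + "".join(
            f"[{jack[t].interval[0]:.3f}, {jack[t].interval[1]:.3f}]".rjust(width)
            for t in labels
        )
    )
    lines.append(row("K0 (net consumption)", ".2f", [rates[t].K0 for t in labels]))
    lines.append(row("Tk (mean predation age)", ".2f", [rates[t].Tk for t in labels]))
    lines.append(row("Tk = ln(K0)/km", ".2f", [rates[t].Tk_lotka for t in labels]))
    lines.append(row("ln(K0)/Tk (approx km)", ".3f", [rates[t].km_approx for t in labels]))
    lines.append(row("R0 (eggs/female)", ".2f", [rates[t].R0 for t in labels]))
    lines.append(row("rm (intrinsic rate)", ".3f", [rates[t].rm for t in labels]))
    lines.append(row("doubling time km (d)", ".2f", [rates[t].doubling_km for t in labels]))
    if comparison is None:
        lines.append("")
        lines.append("Single treatment: multiple comparison omitted.")
    else:
        lines.append("")
        lines.append(
            f"Newman-Keuls sequential test ({comparison.method}, "
            f"P<{manifest.alpha:g}): treatments sharing a letter do not differ."
        )
    lines.append("")
    lines.append("Period summaries (daily kills and eggs, mean ± SD over females):")
    daily = period_tables[
        (period_tables["basis"] == "daily")
        & (period_tables["variable"].isin(["kills_total", "eggs_laid"]))
    ]
    for (variable), grp in daily.groupby("variable"):
        lines.append(f"  {variable}:")
        for _, r in grp.iterrows():
            mean = "undefined" if r["n"] == 0 else f"{r['mean']:6.2f} ± {r['sd']:.2f}"
            lines.append(
                f"    {r['treatment']:<6s} {r['period']:>7s}: {mean} (n={int(r['n'])})"
            )
    return "\n".join(lines) + "\n"


def run_pipeline(manifest: RunManifest) -> dict:
    """Run every stage for every treatment and write the report bundle.

    Returns a dict with the in-memory objects (cohorts, schedules, rates,
    jackknife results, comparison) and the output directory path.
    """
    outdir = manifest.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    cohorts = _load_cohorts(manifest)

    schedules, rates, jack = {}, {}, {}
    summaries = []
    for label, (cohort, simulated) in cohorts.items():
        try:
            if simulated:
                write_cohort(cohort, outdir / f"cohort_{label}.csv")
            schedule = build_life_schedule(cohort)
            schedule.to_csv(outdir / f"lifetable_{label}.csv")
            schedules[label] = schedule
            rates[label] = demographic_rates(
                schedule, manifest.female_fraction, manifest.tolerance
            )
            jack[label] = jackknife_rate(
                cohort,
                rate="km",
                alpha=manifest.alpha,
                female_fraction=manifest.female_fraction,
                tolerance=manifest.tolerance,
            )
            summaries.append(period_summary(cohort, manifest.partition))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage rates, treatment {label!r}: {exc}") from exc

    period_tables = pd.concat(summaries, ignore_index=True)
    period_tables.to_csv(outdir / "period_summary.csv", index=False,
                         float_format="%.10g")

    rates_frame = pd.DataFrame(
        [
            {
                "treatment": t,
                "K0": r.K0,
                "Tk": r.Tk,
                "km": r.km,
                "km_approx": r.km_approx,
                "Tk_lotka": r.Tk_lotka,
                "R0": r.R0,
                "T": r.T,
                "rm": r.rm,
                "doubling_km": r.doubling_km,
                "doubling_rm": r.doubling_rm,
            }
            for t, r in rates.items()
        ]
    )
    rates_frame.to_csv(outdir / "rates.csv", index=False, float_format="%.10g")

    comparison = None
    if len(jack) >= 2:
        try:
            comparison = newman_keuls(
                list(jack.values()), alpha=manifest.alpha, error=manifest.nk_error
            )
        except Exception as exc:
            raise PipelineError(f"stage compare: {exc}") from exc
        letters = comparison.letters
    else:
        logger.info("single treatment: comparison stage omitted")
        letters = {t: "" for t in jack}
    comp_frame = pd.DataFrame(
        [
            {
                "treatment": t,
                "estimate": j.estimate,
                "se": j.se,
                "interval_low": j.interval[0],
                "interval_high": j.interval[1],
                "letters": letters.get(t, ""),
            }
            for t, j in jack.items()
        ]
    )
    comp_frame.to_csv(outdir / "comparison.csv", index=False, float_format="%.10g")

    text = _format_summary(rates, jack, comparison, period_tables, manifest)
    (outdir / "summary.txt").write_text(text)
    logger.info("report bundle written to %s", outdir)
    return {
        "cohorts": {t: c for t, (c, _) in cohorts.items()},
        "schedules": schedules,
        "rates": rates,
        "jackknife": jack,
        "comparison": comparison,
        "period_summary": period_tables,
        "outdir": outdir,
        "summary_text": text,
    }
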