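"""Monte-Carlo power and type-I-error estimation across scenario grids.

The driver simulates replicate trials under a scenario, fits the requested
models per replicate, applies the interaction (heterogeneity) and/or
treatment (main-effect) Wald tests at the scenario's alpha, and tallies
rejections. A replicate on which a model fails to converge is dropped from
that model's denominator only; failures are counted, never raised.

Replicate seeds are spawned from a master seed with ``numpy.random
.SeedSequence(master_seed).spawn``, so runs are reproducible and replicates
are independent. With ``crn=True`` the simulator inverts a common uniform
stream per replicate index, so the same draws are reused across scenarios
(common random numbers) and power comparisons between scenarios are
monotonically coupled.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ScenarioSpec
from .models import (
    composite_main_effect_test,
    fit_gee,
    fit_logistic,
    fit_re_logistic,
    fit_weighted_dd,
    fit_weighted_rs,
    wald_test,
)
from .simulate import generate_trial

__all__ = [
    "PowerResult",
    "MODEL_TAGS",
    "run_scenario",
    "table1_grid",
    "table2_grid",
    "table3_grid",
    "render_table",
]

logger = logging.getLogger(__name__)

MODEL_TAGS = ("independent", "weighted_dd", "weighted_rs", "gee", "random_effects")

_FITTERS = {
    "independent": lambda d: fit_logistic(d),
    "weighted_dd": fit_weighted_dd,
    "weighted_rs": fit_weighted_rs,
    "gee": lambda d: fit_gee(d, working="unstructured"),
    "random_effects": fit_re_logistic,
}


@dataclass(frozen=True)
class PowerResult:
    """Rejection tally for one scenario x model x test combination."""

    scenario: ScenarioSpec
    model_tag: str
    test: str  # "interaction" or "treatment"
    n_reps: int
    n_converged: int
    n_reject: int

    @property
    def power(self) -> float:
        return self.n_reject / self.n_converged if self.n_converged else float("nan")

    @property
    def mc_se(self) -> float:
        if not self.n_converged:
            return float("nan")
        p = self.power
        return float(np.sqrt(p * (1.0 - p) / self.n_converged))


def run_scenario(
    spec: ScenarioSpec,
    models: tuple[str, ...] = ("gee",),
    tests: tuple[str, ...] = ("interaction",),
    n_reps: int = 2000,
    master_seed: int | np.random.SeedSequence = 0,
    crn: bool = False,
    log_every: int = 0,
) -> list[PowerResult]:
    """Estimate power for each requested model/test by Monte-Carlo replication.

    ``tests`` may contain "interaction" (Wald test of beta3 from the full
    model) and "treatment" (the composite main-effect test: each participant
    collapsed to the composite indicator, continuity-corrected chi-square;
    supported alongside the "gee" model only, the pairing used in the
    main-effect-vs-heterogeneity comparison).
    """
    for tag in models:
        if tag not in _FITTERS:
            raise ValueError(f"unknown model tag {tag!r}")
    for t in tests:
        if t not in ("interaction", "treatment"):
            raise ValueError(f"unknown test {t!r}")
    if "treatment" in tests and any(tag != "gee" for tag in models):
        raise ValueError("the treatment (main-effect) test is run on the GEE only")
    if isinstance(master_seed, np.random.SeedSequence):
        seeds = master_seed.spawn(n_reps)
    else:
        seeds = np.random.SeedSequence(int(master_seed)).spawn(n_reps)
    method = "inverse" if crn else "direct"

    tally = {
        (tag, t): [0, 0]  # [n_converged, n_reject]
        for tag in models
        for t in tests
    }
    for rep, seed in enumerate(seeds):
        data = generate_trial(spec, seed, method=method)
        for tag in models:
            if "interaction" in tests:
                fit = _FITTERS[tag](data)
                if fit.converged:
                    res = wald_test(fit, "interaction", spec.alpha)
                    tally[(tag, "interaction")][0] += 1
                    tally[(tag, "interaction")][1] += int(res.reject)
            if "treatment" in tests:
                try:
                    res = composite_main_effect_test(
                        data, "collapsed_chisq", spec.alpha
                    )
                    tally[(tag, "treatment")][0] += 1
                    tally[(tag, "treatment")][1] += int(res.reject)
                except Exception:  # non-convergence is data, not an error
                    pass
        if log_every and (rep + 1) % log_every == 0:
            counts = {f"{tag}/{t}": f"{v[1]}/{v[0]}" for (tag, t), v in tally.items()}
            logger.info("replicate %d/%d rejections %s", rep + 1, n_reps, counts)

    return [
        PowerResult(spec, tag, t, n_reps, conv, rej)
        for (tag, t), (conv, rej) in tally.items()
    ]


def _grid_or2(start: float) -> list[float]:
    return [round(start + 0.05 * i, 2) for i in range(int(round((1.20 - start) / 0.05)) + 1)]


def table1_grid(**overrides) -> list[ScenarioSpec]:
    """Heterogeneity sweep: or1 = 0.65, or2 in 0.65 .. 1.20, balanced."""
    return [ScenarioSpec(or1=0.65, or2=o2, **overrides) for o2 in _grid_or2(0.65)]


def table2_grid(**overrides) -> list[ScenarioSpec]:
    """Balance sweep at (or1, or2) = (0.65, 1.00): p1:p2 in 1:1,1:3,1:5,3:1,5:1."""
    ratios = [1.0, 1.0 / 3.0, 0.2, 3.0, 5.0]
    return [
        ScenarioSpec(or1=0.65, or2=1.00, balance_ratio=r, **overrides) for r in ratios
    ]


def table3_grid(**overrides) -> list[ScenarioSpec]:
    """Main-effect vs heterogeneity sweep: or1 in {0.65, 0.70, 0.75},
    or2 from or1 to 1.20 (rows with or2 < or1 are not run), balanced."""
    specs = []
    for o1 in (0.65, 0.70, 0.75):
        specs.extend(ScenarioSpec(or1=o1, or2=o2, **overrides) for o2 in _grid_or2(o1))
    return specs


def results_frame(results: list[PowerResult]) -> pd.DataFrame:
    """Flat per-result table with the CSV column contract of the CLI."""
    rows = []
    for r in results:
        s = r.scenario
        rows.append(
            {
                "or1": s.or1,
                "or2": s.or2,
                "ratio": s.balance_ratio,
                "model": r.model_tag,
                "test": r.test,
                "n_reps": r.n_reps,
                "n_converged": r.n_converged,
                "n_reject": r.n_reject,
                "power_pct": round(100.0 * r.power, 4),
                "mc_se_pct": round(100.0 * r.mc_se, 4),
            }
        )
    return pd.DataFrame(rows)


def render_table(results: list[PowerResult], layout: int) -> pd.DataFrame:
    """Pivot results into the row/column structure of the published tables.

    Layout 1: rows or2, columns models (interaction test, balanced).
    Layout 2: rows balance ratio, columns models (interaction test).
    Layout 3: rows or2, columns (or1, test) for the GEE model.
    Powers are percentages to one decimal; a companion ``mc_se`` column per
    cell column reports the Monte-Carlo standard error. Missing cells are NA.
    """
    df = results_frame(results)
    if df.empty:
        logger.warning("no results to render: emitting header-only table")
        return df
    if layout == 1:
        sub = df[(df.test == "interaction")]
        out = sub.pivot_table(index="or2", columns="model", values="power_pct")
        se = sub.pivot_table(index="or2", columns="model", values="mc_se_pct")
    elif layout == 2:
        sub = df[(df.test == "interaction")]
        out = sub.pivot_table(index="ratio", columns="model", values="power_pct")
        se = sub.pivot_table(index="ratio", columns="model", values="mc_se_pct")
    elif layout == 3:
        sub = df[df.model == "gee"]
        out = sub.pivot_table(index="or2", columns=["or1", "test"], values="power_pct")
        se = sub.pivot_table(index="or2", columns=["or1", "test"], values="mc_se_pct")
    else:
        raise ValueError("layout must be 1, 2 or 3")
    out = out.round(1)
    se.columns = [
        ("mc_se_" + "_".join(str(c) for c in col)) if isinstance(col, tuple)
        else f"mc_se_{col}"
        for col in se.columns
    ]
    table = pd.concat([out, se.round(2)], axis=1)
    if table.isna().any().any():
        logger.warning("missing cells rendered as NA")
    return table


def print_table(table: pd.DataFrame, file=sys.stdout) -> None:
    file.write(table.to_string() + "\n")
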