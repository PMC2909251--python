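"""Deterministic design mathematics for a two-component binary composite outcome.

A scenario fixes the control-arm composite event rate R, the ratio r = p1:p2 of
the two component marginal probabilities, their Pearson correlation rho, and a
per-component treatment odds ratio. From these the module recovers the
component-level probabilities in each arm, the joint probability that both
components occur, the composite (union) rate, and the analytic power of the
continuity-corrected chi-square test used to size the trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.stats import norm

__all__ = [
    "ScenarioSpec",
    "ArmDesign",
    "UnattainableCorrelationError",
    "InfeasibleDesignError",
    "joint_prob",
    "solve_component_probs",
    "or_to_prob",
    "build_arm_designs",
    "cc_chisq_power",
]

_BISECT_TOL = 1e-10
_BISECT_MAX_ITER = 200


class UnattainableCorrelationError(ValueError):
    """The requested correlation is outside the Frechet-attainable range."""


class InfeasibleDesignError(ValueError):
    """No component probabilities satisfy the composite-rate constraint."""


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete parameterization of one simulated two-arm trial design.

    Parameters
    ----------
    or1, or2
        Treatment odds ratios acting on the marginal odds of components 1 and 2.
        Equal ORs mean no heterogeneity; the gap ``ln(or2/or1)`` is the
        interaction effect the heterogeneity test targets.
    n_participants
        Total sample size across both arms.
    allocation
        ``(treatment, control)`` allocation ratio.
    control_composite_rate
        Probability R that a control participant experiences at least one
        component.
    icc
        Pearson correlation rho between the two binary components within a
        participant; applied identically in both arms.
    balance_ratio
        r = p1 / p2, the ratio of the control-arm component marginal
        probabilities.
    alpha
        Two-sided level of all Wald tests.
    """

    or1: float = 1.0
    or2: float = 1.0
    n_participants: int = 2000
    allocation: tuple[float, float] = (1.0, 1.0)
    control_composite_rate: float = 0.50
    icc: float = 0.10
    balance_ratio: float = 1.0
    alpha: float = 0.05
    n_components: int = field(default=2)

    def __post_init__(self) -> None:
        if not 0.0 < self.control_composite_rate < 1.0:
            raise ValueError("control_composite_rate must lie in (0, 1)")
        if self.or1 <= 0 or self.or2 <= 0:
            raise ValueError("odds ratios must be positive")
        if self.balance_ratio <= 0:
            raise ValueError("balance_ratio must be positive")
        if not 0.0 <= self.icc < 1.0:
            raise ValueError("icc must lie in [0, 1); the shared-component "
                             "generator cannot induce negative correlation")
        if self.n_participants < 2:
            raise ValueError("n_participants must be at least 2")
        if any(a <= 0 for a in self.allocation):
            raise ValueError("allocation entries must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_components != 2:
            raise ValueError("scenario grids support exactly 2 components")

    @property
    def arm_sizes(self) -> tuple[int, int]:
        """(n_control, n_treatment) implied by the allocation ratio."""
        a_t, a_c = self.allocation
        n_t = round(self.n_participants * a_t / (a_t + a_c))
        return self.n_participants - n_t, n_t


@dataclass(frozen=True)
class ArmDesign:
    """Per-arm event structure: component marginals, joint, and union rate."""

    p1: float
    p2: float
    p11: float

    def __post_init__(self) -> None:
        lo = max(0.0, self.p1 + self.p2 - 1.0)
        hi = min(self.p1, self.p2)
        if not lo - 1e-12 <= self.p11 <= hi + 1e-12:
            raise UnattainableCorrelationError(
                f"joint probability {self.p11:.6g} outside Frechet bounds "
                f"[{lo:.6g}, {hi:.6g}]"
            )

    @property
    def composite_rate(self) -> float:
        """P(component 1 or component 2) = p1 + p2 - p11."""
        return self.p1 + self.p2 - self.p11


def joint_prob(p1: float, p2: float, rho: float) -> float:
    """Joint probability that two correlated Bernoulli events both occur.

    Inverts the Pearson correlation of two Bernoulli(p1), Bernoulli(p2)
    variables: p11 = p1*p2 + rho*sqrt(p1 q1 p2 q2).

    Raises
    ------
    UnattainableCorrelationError
        If the implied p11 falls outside the Frechet bounds
        [max(0, p1+p2-1), min(p1, p2)].
    """
    if not (0.0 < p1 < 1.0 and 0.0 < p2 < 1.0):
        raise ValueError("marginal probabilities must lie in (0, 1)")
    p11 = p1 * p2 + rho * math.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    lo = max(0.0, p1 + p2 - 1.0)
    hi = min(p1, p2)
    if p11 < lo - 1e-12:
        raise UnattainableCorrelationError(
            f"correlation {rho} gives joint {p11:.6g} below the lower "
            f"Frechet bound max(0, p1+p2-1) = {lo:.6g}"
        )
    if p11 > hi + 1e-12:
        raise UnattainableCorrelationError(
            f"correlation {rho} gives joint {p11:.6g} above the upper "
            f"Frechet bound min(p1, p2) = {hi:.6g}"
        )
    return min(max(p11, lo), hi)


def or_to_prob(p: float, odds_ratio: float) -> float:
    """Apply an odds ratio to a baseline probability on the odds scale."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    odds = odds_ratio * p / (1.0 - p)
    return odds / (1.0 + odds)


def solve_component_probs(R: float, r: float, rho: float) -> tuple[float, float]:
    """Recover component marginals (p1, p2) with p1 = r*p2 and union rate R.

    Solves p1 + p2 - joint_prob(p1, p2, rho) = R by bisection on p2. The union
    rate is strictly increasing in p2 so the root is unique when it exists.
    """
    if not 0.0 < R < 1.0:
        raise ValueError("composite rate must lie in (0, 1)")
    if r <= 0:
        raise ValueError("balance ratio must be positive")

    def union(p2: float) -> float:
        """Union rate, or nan where the correlation is Frechet-infeasible."""
        p1 = r * p2
        try:
            return p1 + p2 - joint_prob(p1, p2, rho)
        except UnattainableCorrelationError:
            return math.nan

    p2_cap = min(1.0, 1.0 / r) * (1.0 - 1e-12)
    # the feasible p2 form an interior interval: locate one point of it
    hi = p2_cap
    for _ in range(4000):
        if not math.isnan(union(hi)):
            break
        hi *= 0.995
    else:
        raise InfeasibleDesignError(
            f"correlation {rho} unattainable at ratio {r} for any marginal level"
        )
    lo = 1e-12
    while math.isnan(union(lo)) and lo < hi:
        lo *= 2.0
    lo = min(lo, hi)
    # push hi back up toward the cap while it stays feasible
    step = (p2_cap - hi) / 64.0
    if step > 0:
        while hi + step <= p2_cap and not math.isnan(union(hi + step)):
            hi += step
    f_lo, f_hi = union(lo) - R, union(hi) - R
    if f_hi < 0:
        raise InfeasibleDesignError(
            f"composite rate {R} exceeds the maximum attainable union rate "
            f"{f_hi + R:.6g} at ratio {r}, correlation {rho}"
        )
    if f_lo > 0:
        raise InfeasibleDesignError(
            f"composite rate {R} below the minimum attainable union rate "
            f"{f_lo + R:.6g} at ratio {r}, correlation {rho}"
        )
    for _ in range(_BISECT_MAX_ITER):
        mid = 0.5 * (lo + hi)
        if union(mid) - R <= 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < _BISECT_TOL:
            break
    p2 = 0.5 * (lo + hi)
    return r * p2, p2


def build_arm_designs(spec: ScenarioSpec) -> tuple[ArmDesign, ArmDesign]:
    """Solve the control arm and derive the treatment arm for a scenario.

    The control arm comes from the composite-rate constraint; the treatment
    arm applies or1 and or2 to the control component marginal odds and re-uses
    the same within-participant correlation rho.
    """
    p1c, p2c = solve_component_probs(
        spec.control_composite_rate, spec.balance_ratio, spec.icc
    )
    control = ArmDesign(p1c, p2c, joint_prob(p1c, p2c, spec.icc))
    p1t = or_to_prob(p1c, spec.or1)
    p2t = or_to_prob(p2c, spec.or2)
    treatment = ArmDesign(p1t, p2t, joint_prob(p1t, p2t, spec.icc))
    return control, treatment


def cc_chisq_power(
    p_control: float,
    p_treatment: float,
    n_per_arm: int,
    alpha: float = 0.05,
    n_control: int | None = None,
) -> float:
    """Power of the continuity-corrected chi-square test of two proportions.

    Normal approximation with Yates-type continuity correction and the pooled
    variance of the chi-square statistic:

        z = (|p_c - p_t| - (1/n_c + 1/n_t)/2) / sqrt(pbar qbar (1/n_c + 1/n_t))
        power = Phi(z - z_{1-alpha/2})

    clamped to [0, 1]. ``n_per_arm`` is the treatment-arm size; pass
    ``n_control`` for unequal allocation.
    """
    for p in (p_control, p_treatment):
        if not 0.0 < p < 1.0:
            raise ValueError("proportions must lie in (0, 1)")
    n_t = int(n_per_arm)
    n_c = int(n_control) if n_control is not None else n_t
    if min(n_c, n_t) < 2:
        raise ValueError("need at least 2 participants per arm")
    diff = abs(p_control - p_treatment)
    cc = 0.5 * (1.0 / n_c + 1.0 / n_t)
    pbar = (n_c * p_control + n_t * p_treatment) / (n_c + n_t)
    se = math.sqrt(pbar * (1.0 - pbar) * (1.0 / n_c + 1.0 / n_t))
    z_eff = (diff - cc) / se
    power = norm.cdf(z_eff - norm.ppf(1.0 - alpha / 2.0))
    return float(min(max(power, 0.0), 1.0))
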