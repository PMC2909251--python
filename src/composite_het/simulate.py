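"""Correlated binary composite-outcome data via shared Poisson components.

Each participant contributes two binary component outcomes with prescribed
marginals (p1, p2) and Pearson correlation rho. Three independent Poisson
counts A1, A2, A12 are drawn; the sums Z1 = A1 + A12 and Z2 = A2 + A12 are
correlated Poisson variables, and the event indicators are Y_k = 1{Z_k = 0},
so P(Y_k = 1) = exp(-total rate of Z_k). Choosing the total rates as -ln(p_k)
and the shared rate as

    alpha12 = ln(1 + rho * sqrt(p1 q1 p2 q2) / (p1 p2))

reproduces the target marginals and correlation exactly. Only nonnegative rho
is attainable this way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .design import ScenarioSpec, UnattainableCorrelationError, build_arm_designs

__all__ = ["PoissonParams", "TrialData", "park_params", "generate_pairs", "generate_trial"]


@dataclass(frozen=True)
class PoissonParams:
    """Rates of the three independent Poisson components behind one pair."""

    lambda1: float  # specific to component 1
    lambda2: float  # specific to component 2
    alpha12: float  # shared between the two

    @property
    def total1(self) -> float:
        return self.lambda1 + self.alpha12

    @property
    def total2(self) -> float:
        return self.lambda2 + self.alpha12


@dataclass
class TrialData:
    """Long-format trial outcomes: two rows (components) per participant.

    Covariates follow the interaction-model coding: x1 = arm (0 control,
    1 treatment), x2 = component index (0 or 1), x3 = x1 * x2. ``event`` is
    the 0/1 component outcome y.
    """

    participant_id: np.ndarray
    arm: np.ndarray
    component: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        n_rows = len(self.participant_id)
        for name in ("arm", "component", "event"):
            if len(getattr(self, name)) != n_rows:
                raise ValueError(f"column {name} has mismatched length")
        if n_rows % 2:
            raise ValueError("expected exactly 2 rows per participant")
        for name in ("arm", "component", "event"):
            col = np.asarray(getattr(self, name))
            if not np.isin(col, (0, 1)).all():
                raise ValueError(f"column {name} must be 0/1")

    @property
    def n_participants(self) -> int:
        return len(self.participant_id) // 2

    @property
    def n_control(self) -> int:
        return int((self.arm[self.component == 0] == 0).sum())

    @property
    def n_treatment(self) -> int:
        return self.n_participants - self.n_control

    @property
    def interaction(self) -> np.ndarray:
        """x3 = x1 * x2, the treatment-by-component interaction covariate."""
        return self.arm * self.component

    def design_matrix(self, include_interaction: bool = True) -> np.ndarray:
        cols = [np.ones(len(self.arm)), self.arm, self.component]
        if include_interaction:
            cols.append(self.interaction)
        return np.column_stack(cols).astype(float)

    def pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """(arm, y) with y of shape (n_participants, 2) ordered by component.

        Requires every participant to have exactly one row per component.
        """
        order = np.lexsort((self.component, self.participant_id))
        pid = self.participant_id[order]
        comp = self.component[order]
        if not (pid[0::2] == pid[1::2]).all() or not (
            (comp[0::2] == 0).all() and (comp[1::2] == 1).all()
        ):
            raise ValueError("each participant needs one row per component")
        arm = self.arm[order][0::2]
        y = np.column_stack((self.event[order][0::2], self.event[order][1::2]))
        return arm.astype(np.int64), y.astype(np.int64)

    def to_dataframe(self, wide: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "arm": self.arm,
                "component": self.component,
                "event": self.event,
            }
        )
        if wide:
            df["interaction"] = self.interaction
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TrialData":
        return cls(
            participant_id=df["participant_id"].to_numpy(np.int64),
            arm=df["arm"].to_numpy(np.int64),
            component=df["component"].to_numpy(np.int64),
            event=df["event"].to_numpy(np.int64),
        )


def park_params(p1: float, p2: float, rho: float) -> PoissonParams:
    """Poisson rates whose zero-count indicators have the target moments.

    Raises :class:`UnattainableCorrelationError` when the shared rate would
    exceed either total rate (i.e. alpha12 > -ln p_k for some component).
    """
    if not (0.0 < p1 <= 1.0 and 0.0 < p2 <= 1.0):
        raise ValueError("marginals must lie in (0, 1]")
    if rho < 0:
        raise ValueError("shared-component construction needs rho >= 0")
    t1, t2 = -math.log(p1), -math.log(p2)
    if rho == 0 or p1 == 1.0 or p2 == 1.0:
        alpha12 = 0.0
    else:
        q1, q2 = 1.0 - p1, 1.0 - p2
        alpha12 = math.log1p(rho * math.sqrt(p1 * q1 * p2 * q2) / (p1 * p2))
    if alpha12 > min(t1, t2) + 1e-12:
        raise UnattainableCorrelationError(
            f"correlation {rho} needs shared rate {alpha12:.6g} exceeding the "
            f"total rate {min(t1, t2):.6g} = -ln(max(p1, p2))"
        )
    return PoissonParams(lambda1=t1 - alpha12, lambda2=t2 - alpha12, alpha12=alpha12)


def generate_pairs(
    n: int,
    p1: float,
    p2: float,
    rho: float,
    rng: np.random.Generator,
    method: str = "direct",
) -> np.ndarray:
    """Draw n correlated Bernoulli pairs; returns an (n, 2) 0/1 array.

    ``method="direct"`` draws the three Poisson components natively;
    ``method="inverse"`` inverts three uniforms through the Poisson CDF, so
    that the same generator state yields monotonically coupled outcomes across
    scenarios (common random numbers).
    """
    params = park_params(p1, p2, rho)
    rates = (params.lambda1, params.lambda2, params.alpha12)
    if method == "direct":
        draws = [rng.poisson(lam, size=n) for lam in rates]
    elif method == "inverse":
        u = rng.random((n, 3))
        draws = [
            poisson.ppf(u[:, j], lam).astype(np.int64) if lam > 0 else np.zeros(n, np.int64)
            for j, lam in enumerate(rates)
        ]
    else:
        raise ValueError(f"unknown method {method!r}")
    z1 = draws[0] + draws[2]
    z2 = draws[1] + draws[2]
    return np.column_stack((z1 == 0, z2 == 0)).astype(np.int64)


def generate_trial(
    spec: ScenarioSpec,
    rng_seed: int | np.random.SeedSequence | np.random.Generator,
    method: str = "direct",
) -> TrialData:
    """Simulate one long-format trial under a scenario, 2 rows per participant.

    Control participants come first (ids 0 .. n_control-1). Deterministic for
    a given seed.
    """
    if isinstance(rng_seed, np.random.Generator):
        rng = rng_seed
    else:
        rng = np.random.default_rng(rng_seed)
    control, treatment = build_arm_designs(spec)
    n_c, n_t = spec.arm_sizes
    y_c = generate_pairs(n_c, control.p1, control.p2, spec.icc, rng, method)
    y_t = generate_pairs(n_t, treatment.p1, treatment.p2, spec.icc, rng, method)
    y = np.vstack((y_c, y_t))
    n = n_c + n_t
    arm_per_participant = np.repeat((np.arange(n) >= n_c).astype(np.int64), 2)
    return TrialData(
        participant_id=np.repeat(np.arange(n, dtype=np.int64), 2),
        arm=arm_per_participant,
        component=np.tile(np.array([0, 1], dtype=np.int64), n),
        event=y.reshape(-1),
    )
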