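"""Dataset and configuration serialization shared by the CLI and library."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import ScenarioSpec
from .simulate import TrialData

__all__ = ["RunConfig", "SchemaError", "read_trial_csv", "write_trial_csv",
           "load_config", "parse_ratio"]

_CSV_COLUMNS = ["participant_id", "arm", "component", "event"]


class SchemaError(ValueError):
    """Input file violates the trial-data or config schema."""


def parse_ratio(value: str | float | int) -> float:
    """Parse a balance ratio: "a:b" means p1:p2 and maps to r = a/b."""
    if isinstance(value, (int, float)):
        r = float(value)
    else:
        parts = str(value).split(":")
        if len(parts) == 1:
            r = float(parts[0])
        elif len(parts) == 2:
            a, b = (float(p) for p in parts)
            if b == 0:
                raise SchemaError(f"invalid ratio {value!r}: zero denominator")
            r = a / b
        else:
            raise SchemaError(f"invalid ratio {value!r}")
    if r <= 0:
        raise SchemaError(f"ratio must be positive, got {value!r}")
    return r


def read_trial_csv(path: str | Path) -> TrialData:
    """Read and validate a long-format trial CSV.

    Expects the header ``participant_id,arm,component,event``; every
    participant must have exactly one row per component and all of arm /
    component / event must be 0 or 1.
    """
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for col in ("arm", "component", "event"):
        bad = ~df[col].isin((0, 1))
        if bad.any():
            row = int(df.index[bad][0])
            raise SchemaError(
                f"{path}: row {row}: column {col!r} must be 0/1, "
                f"got {df.loc[row, col]!r}"
            )
    dup = df.duplicated(subset=["participant_id", "component"])
    if dup.any():
        row = int(df.index[dup][0])
        raise SchemaError(f"{path}: row {row}: duplicated (participant, component) pair")
    sizes = df.groupby("participant_id").size()
    incomplete = sizes[sizes != 2]
    if not incomplete.empty:
        raise SchemaError(
            f"{path}: incomplete cluster: participant {incomplete.index[0]} "
            f"has {incomplete.iloc[0]} component row(s), expected 2"
        )
    arms = df.groupby("participant_id")["arm"].nunique()
    if (arms != 1).any():
        pid = arms.index[arms != 1][0]
        raise SchemaError(f"{path}: participant {pid} appears in both arms")
    # re-densify participant ids to 0..n-1 preserving order of appearance
    codes, _ = pd.factorize(df["participant_id"])
    df = df.assign(participant_id=codes)
    return TrialData.from_dataframe(df)


def write_trial_csv(data: TrialData, path: str | Path, wide: bool = False) -> None:
    data.to_dataframe(wide=wide).to_csv(path, index=False, lineterminator="\n")


_CONFIG_DEFAULTS = {
    "n": 2000,
    "control_rate": 0.50,
    "icc": 0.10,
    "or1": 1.0,
    "or2": 1.0,
    "ratio": 1.0,
    "alpha": 0.05,
    "reps": 2000,
    "seed": 0,
    "models": ["gee"],
    "tests": ["interaction"],
    "quadrature": 15,
}


@dataclass
class RunConfig:
    """Validated execution parameters for a simulation/power run."""

    spec: ScenarioSpec
    reps: int = 2000
    seed: int = 0
    models: tuple[str, ...] = ("gee",)
    tests: tuple[str, ...] = ("interaction",)
    quadrature: int = 15
    raw: dict = field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run config, apply defaults, reject unknown keys."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise SchemaError(f"{path}: cannot parse config: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    unknown = set(raw) - set(_CONFIG_DEFAULTS)
    if unknown:
        raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg = {**_CONFIG_DEFAULTS, **raw}
    try:
        spec = ScenarioSpec(
            or1=float(cfg["or1"]),
            or2=float(cfg["or2"]),
            n_participants=int(cfg["n"]),
            control_composite_rate=float(cfg["control_rate"]),
            icc=float(cfg["icc"]),
            balance_ratio=parse_ratio(cfg["ratio"]),
            alpha=float(cfg["alpha"]),
        )
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc
    reps = int(cfg["reps"])
    if reps < 1:
        raise SchemaError(f"{path}: reps must be >= 1")
    quad = int(cfg["quadrature"])
    if quad < 2:
        raise SchemaError(f"{path}: quadrature must be >= 2")
    return RunConfig(
        spec=spec,
        reps=reps,
        seed=int(cfg["seed"]),
        models=tuple(cfg["models"]),
        tests=tuple(cfg["tests"]),
        quadrature=quad,
        raw=raw,
    )


def fit_report(fit, tests) -> dict:
    """JSON-serializable report of a model fit plus its Wald tests."""
    return {
        "model": fit.model_tag,
        "converged": fit.converged,
        "n_iterations": fit.n_iterations,
        "coefficients": {
            name: float(b)
            for name, b in zip(
                ("intercept", "treatment", "component", "interaction"),
                fit.coefficients,
            )
        },
        "se": {
            name: float(s)
            for name, s in zip(
                ("intercept", "treatment", "component", "interaction"), fit.se
            )
        },
        "vcov": np.asarray(fit.vcov).tolist(),
        "extras": {k: v for k, v in fit.extras.items()},
        "tests": [
            {
                "term": t.term,
                "estimate": t.estimate,
                "se": t.se,
                "z": t.z,
                "p": t.p,
                "alpha": t.alpha,
                "reject": t.reject,
            }
            for t in tests
        ],
    }


def dump_json(obj, path: str | Path | None) -> str:
    text = json.dumps(obj, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
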