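import numpy as np
import pytest

from composite_het import ScenarioSpec, TrialData, generate_trial


@pytest.fixture(scope="session")
def base_spec() -> ScenarioSpec:
    """The balanced moderate-heterogeneity scenario used throughout."""
    return ScenarioSpec(or1=0.65, or2=1.00)


@pytest.fixture(scope="session")
def medium_trial(base_spec) -> TrialData:
    """One simulated 2000-participant trial under the base scenario."""
    return generate_trial(base_spec, 42)


@pytest.fixture()
def cell_count_trial() -> TrialData:
    """Deterministic dataset with known per-cell event proportions.

    100 participants per arm; events per (arm, component) cell:
    (0,0) 30, (0,1) 20, (1,0) 15, (1,1) 25 out of 100 each.
    """
    rows = {"participant_id": [], "arm": [], "component": [], "event": []}
    counts = {(0, 0): 30, (0, 1): 20, (1, 0): 15, (1, 1): 25}
    pid = 0
    for arm in (0, 1):
        for i in range(100):
            for comp in (0, 1):
                rows["participant_id"].append(pid)
                rows["arm"].append(arm)
                rows["component"].append(comp)
                rows["event"].append(1 if i < counts[(arm, comp)] else 0)
            pid += 1
    return TrialData(**{k: np.array(v, dtype=np.int64) for k, v in rows.items()})


@pytest.fixture()
def random_small_trial() -> TrialData:
    """30 participants (60 rows) with arbitrary outcomes for oracle checks."""
    rng = np.random.default_rng(7)
    n = 30
    arm = np.repeat(rng.integers(0, 2, n), 2)
    event = rng.integers(0, 2, 2 * n)
    # ensure variation in every (arm, component) cell to avoid separation
    event[:8] = [0, 1, 1, 0, 1, 0, 0, 1]
    arm[:8] = [0, 0, 0, 0, 1, 1, 1, 1]
    return TrialData(
        participant_id=np.repeat(np.arange(n, dtype=np.int64), 2),
        arm=arm.astype(np.int64),
        component=np.tile(np.array([0, 1], dtype=np.int64), n),
        event=event.astype(np.int64),
    )
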