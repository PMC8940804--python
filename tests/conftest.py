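import numpy as np
import pandas as pd
import pytest

from cowjbt.simulator import simulate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 12-cow simulated cohort (4 per punisher arm), reused across tests."""
    return simulate_cohort(4, rng_seed=3)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_trained_cow_log(
    cow_id: str,
    group_id: str,
    punisher: str,
    batch: int = 1,
    trained: bool = True,
    testing_latencies: dict | None = None,
    period2_latencies: dict | None = None,
) -> list[dict]:
    """Hand-built deterministic trial log for one cow.

    A trained cow responds perfectly during training and wash-out (Go at
    5 s to P, NoGo to N); an untrained cow approaches N at 30 s in every
    session (so each session scores 4 correct and the 13/14 criterion is
    never met).  ``testing_latencies`` maps cue -> latency for the testing
    trials of period 1 (NoGo encoded as 90), default a clean monotone
    profile; ``period2_latencies`` likewise for period 2 (defaults to the
    period-1 values).
    """
    from cowjbt.schedule import generate_experiment_plan

    lat1 = {"P": 10.0, "N": 90.0, "Ap": 30.0, "A": 50.0, "An": 70.0}
    lat1.update(testing_latencies or {})
    lat2 = dict(lat1)
    lat2.update(period2_latencies or {})
    plan = generate_experiment_plan(cow_id, rng_seed=0)
    rows = []
    for session in plan.sessions:
        for spec in session:
            if spec.phase == "testing":
                lat = (lat1 if spec.period == 1 else lat2)[spec.cue]
                response = "nogo" if lat >= 90 else "go"
            elif spec.cue == "P":
                response, lat = "go", 5.0
            else:  # N during training/wash-out
                if trained:
                    response, lat = "nogo", 90.0
                else:
                    response, lat = "go", 30.0
            rows.append(
                {
                    "cow_id": cow_id,
                    "group_id": group_id,
                    "punisher": punisher,
                    "batch": batch,
                    "phase": spec.phase,
                    "period": spec.period,
                    "session": spec.session_index,
                    "trial": spec.trial_index,
                    "cue": spec.cue,
                    "response": response,
                    "latency_s": float(lat),
                }
            )
    return rows
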