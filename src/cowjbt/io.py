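"""Trial-log serialisation and validation.

The on-disk interchange format is a UTF-8 CSV with one row per trial and
header ``cow_id,group_id,punisher,batch,phase,period,session,trial,cue,
response,latency_s``.  Latencies are seconds in (0, 90], censored at the
90 s trial ceiling; a NoGo is recorded at exactly 90 s.  Validation
reports every offending row with its line number rather than failing on
the first.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from cowjbt.schedule import AMBIGUOUS_CUES, CUES, PHASES, TRIALS_PER_SESSION
from cowjbt.scoring import TRIAL_CEILING_S
from cowjbt.simulator import PUNISHERS, TRIAL_COLUMNS


@dataclass(frozen=True)
class TrialRecord:
    """One behavioural trial, typed."""

    cow_id: str
    group_id: str
    punisher: str
    batch: int
    phase: str
    period: int
    session: int
    trial: int
    cue: str
    response: str
    latency_s: float


class TrialValidationError(ValueError):
    """Raised when a trial log violates the schema; lists offending lines."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        shown = problems[:20]
        more = f"\n... and {len(problems) - 20} more" if len(problems) > 20 else ""
        super().__init__("invalid trial log:\n" + "\n".join(shown) + more)


def validate_trials(df: pd.DataFrame, first_data_line: int = 2) -> pd.DataFrame:
    """Validate a trial-log DataFrame against every record invariant.

    Returns a typed copy on success; raises :class:`TrialValidationError`
    naming each offending line (``first_data_line`` is the file line of
    the first data row, 2 for a CSV with header).
    """
    problems: list[str] = []
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError([f"missing column(s): {missing}"])
    out = df.copy().reset_index(drop=True)
    out["latency_s"] = pd.to_numeric(out["latency_s"], errors="coerce")
    out["batch"] = pd.to_numeric(out["batch"], errors="coerce")
    for col in ("period", "session", "trial"):
        out[col] = pd.to_numeric(out[col], errors="coerce")

    def complain(mask, message):
        for i in np.flatnonzero(np.asarray(mask)):
            problems.append(f"line {i + first_data_line}: {message}")

    complain(~out["punisher"].isin(PUNISHERS), "unknown punisher label")
    complain(~out["phase"].isin(PHASES), "unknown phase label")
    complain(~out["cue"].isin(CUES), "unknown cue label")
    complain(~out["response"].isin(["go", "nogo"]), "unknown response label")
    bad_lat = out["latency_s"].isna() | (out["latency_s"] <= 0) | (out["latency_s"] > TRIAL_CEILING_S)
    complain(bad_lat, "latency outside (0, 90] seconds")
    nogo = out["response"] == "nogo"
    complain(nogo & ~bad_lat & (out["latency_s"] != TRIAL_CEILING_S), "nogo must be recorded at latency 90")
    complain((out["response"] == "go") & (out["latency_s"] == TRIAL_CEILING_S), "go with latency 90 violates the censoring convention")
    complain(~out["trial"].isin(range(1, TRIALS_PER_SESSION + 1)), "trial index outside 1..7")
    testing = out["phase"] == "testing"
    complain(testing & ~out["period"].isin([1, 2]), "testing rows need period 1 or 2")
    complain(~testing & (out["period"] != 0), "non-testing rows must have period 0")
    complain(out["cue"].isin(AMBIGUOUS_CUES) & ~testing, "ambiguous cue outside the testing phase")
    if problems:
        raise TrialValidationError(problems)
    out["batch"] = out["batch"].astype(int)
    for col in ("period", "session", "trial"):
        out[col] = out[col].astype(int)
    for col in ("cow_id", "group_id", "punisher", "phase", "cue", "response"):
        out[col] = out[col].astype(str)
    return out


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-log CSV."""
    df = pd.read_csv(path, dtype={"cow_id": str, "group_id": str})
    return validate_trials(df)


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a trial log as CSV (latencies with 2 decimals)."""
    out = df.loc[:, list(TRIAL_COLUMNS)].copy()
    out["latency_s"] = out["latency_s"].map(lambda v: f"{float(v):.2f}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


def to_records(df: pd.DataFrame) -> list[TrialRecord]:
    """Typed view of a validated trial log."""
    return [TrialRecord(**{k: row[k] for k in TRIAL_COLUMNS}) for row in df.to_dict("records")]
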