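"""Experiment plans for the spatial Go/NoGo judgement bias task.

The design is fixed for every cow: 8 training sessions of 7 trials, a first
testing period of 2 sessions, a wash-out of 3 regular training sessions, and
a second testing period of 2 sessions (15 sessions, 105 trials).

Training sessions use only the conditioned cues P and N under three ordering
constraints: trial 1 is P, trial 2 is N, trial 7 is P, and no cue occurs
three times in a row.  With the composition fixed at 4 P / 3 N per session,
exactly five cue orders are admissible; a session is a seeded uniform draw
from that set.

Testing sessions are [P, N, a1, a2, a3, N, P] where the middle block holds
the three ambiguous cues, in the order Ap/An/A during the first testing
period and A/Ap/An during the second.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Cue labels on the spatial axis from positive to negative.
CUES = ("P", "Ap", "A", "An", "N")
CONDITIONED_CUES = ("P", "N")
AMBIGUOUS_CUES = ("Ap", "A", "An")

PHASES = ("training", "testing", "washout")

TRIALS_PER_SESSION = 7
N_TRAINING_SESSIONS = 8
N_WASHOUT_SESSIONS = 3
N_TESTING_SESSIONS_PER_PERIOD = 2

#: Per-session composition of a training session (4 positive, 3 negative).
TRAINING_COMPOSITION = {"P": 4, "N": 3}

#: Positions (1-based) of the ambiguous trials within a testing session.
AMBIGUOUS_POSITIONS = (3, 4, 5)

#: Middle-block cue order per testing period.
AMBIGUOUS_ORDER = {1: ("Ap", "An", "A"), 2: ("A", "Ap", "An")}


def _enumerate_admissible_training_sequences() -> tuple[tuple[str, ...], ...]:
    """All 7-trial cue orders satisfying the training constraints.

    Constraints: positions 1, 2, 7 fixed at P, N, P; composition 4 P / 3 N;
    no run of three identical cues.
    """
    out = []
    for middle in itertools.product("PN", repeat=TRIALS_PER_SESSION - 3):
        seq = ("P", "N", *middle, "P")
        if sum(c == "P" for c in seq) != TRAINING_COMPOSITION["P"]:
            continue
        if any(seq[i] == seq[i + 1] == seq[i + 2] for i in range(len(seq) - 2)):
            continue
        out.append(seq)
    return tuple(sorted(out))


#: The five admissible training-session cue orders.
ADMISSIBLE_TRAINING_SEQUENCES = _enumerate_admissible_training_sequences()


@dataclass(frozen=True)
class TrialSpec:
    """One planned trial (cue only; response/latency filled by simulation or data).

    ``period`` is 1 or 2 for testing trials and 0 otherwise.  ``session_index``
    counts sessions within the phase block (within-period for testing).
    """

    phase: str
    period: int
    session_index: int
    trial_index: int
    cue: str

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.cue not in CUES:
            raise ValueError(f"unknown cue {self.cue!r}")
        if not 1 <= self.trial_index <= TRIALS_PER_SESSION:
            raise ValueError(f"trial_index {self.trial_index} outside 1..{TRIALS_PER_SESSION}")
        if self.cue in AMBIGUOUS_CUES and self.phase != "testing":
            raise ValueError("ambiguous cues occur only in the testing phase")
        if self.phase == "testing":
            if self.period not in (1, 2):
                raise ValueError("testing trials need period 1 or 2")
        elif self.period != 0:
            raise ValueError("period must be 0 outside testing")


@dataclass
class ExperimentPlan:
    """The ordered per-cow schedule: 15 sessions of 7 planned trials."""

    cow_id: str
    sessions: list[list[TrialSpec]] = field(default_factory=list)

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)

    @property
    def trials(self) -> list[TrialSpec]:
        return [t for session in self.sessions for t in session]

    def count_trials(self, phase: str) -> int:
        return sum(t.phase == phase for t in self.trials)

    def validate(self) -> None:
        """Check every design-level invariant; raise ``ValueError`` on violation."""
        if self.n_sessions != 15:
            raise ValueError(f"expected 15 sessions, got {self.n_sessions}")
        phases = [s[0].phase for s in self.sessions]
        expected = (
            ["training"] * N_TRAINING_SESSIONS
            + ["testing"] * N_TESTING_SESSIONS_PER_PERIOD
            + ["washout"] * N_WASHOUT_SESSIONS
            + ["testing"] * N_TESTING_SESSIONS_PER_PERIOD
        )
        if phases != expected:
            raise ValueError("phase layout does not match the design timeline")
        if self.count_trials("training") != N_TRAINING_SESSIONS * TRIALS_PER_SESSION:
            raise ValueError("training phase must hold exactly 56 trials")
        for session in self.sessions:
            if len(session) != TRIALS_PER_SESSION:
                raise ValueError("every session holds exactly 7 trials")
            if session[0].phase == "testing":
                amb = [t.trial_index for t in session if t.cue in AMBIGUOUS_CUES]
                if tuple(amb) != AMBIGUOUS_POSITIONS:
                    raise ValueError("ambiguous trials must sit at positions 3, 4, 5")


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def generate_training_session(rng_seed) -> tuple[str, ...]:
    """Draw one training-session cue order.

    Uniform seeded choice among the five admissible sequences (fixed P, N
    start, fixed P end, 4 P / 3 N, no triple run).  ``rng_seed`` may be an
    integer seed or a ``numpy.random.Generator``.
    """
    rng = _as_rng(rng_seed)
    idx = rng.integers(len(ADMISSIBLE_TRAINING_SEQUENCES))
    return ADMISSIBLE_TRAINING_SEQUENCES[idx]


def generate_testing_session(period: int, session_in_period: int) -> tuple[str, ...]:
    """Cue order of one testing session.

    ``[P, N, a1, a2, a3, N, P]`` with the ambiguous block Ap/An/A in period 1
    and A/Ap/An in period 2.
    """
    if period not in (1, 2):
        raise ValueError(f"period must be 1 or 2, got {period!r}")
    if session_in_period not in (1, 2):
        raise ValueError(f"session_in_period must be 1 or 2, got {session_in_period!r}")
    a1, a2, a3 = AMBIGUOUS_ORDER[period]
    return ("P", "N", a1, a2, a3, "N", "P")


def generate_experiment_plan(cow_id: str, rng_seed) -> ExperimentPlan:
    """Build the full 15-session plan for one cow.

    8 training sessions, testing period 1 (2 sessions), 3 wash-out sessions
    (regular training draws), testing period 2 (2 sessions).  Training and
    wash-out cue orders are seeded draws; testing orders are fixed.
    """
    rng = _as_rng(rng_seed)
    plan = ExperimentPlan(cow_id=str(cow_id))

    def training_block(phase: str, n_sessions: int) -> None:
        for s in range(1, n_sessions + 1):
            cues = generate_training_session(rng)
            plan.sessions.append(
                [
                    TrialSpec(phase=phase, period=0, session_index=s, trial_index=i + 1, cue=c)
                    for i, c in enumerate(cues)
                ]
            )

    def testing_block(period: int) -> None:
        for s in (1, 2):
            cues = generate_testing_session(period, s)
            plan.sessions.append(
                [
                    TrialSpec(
                        phase="testing", period=period, session_index=s, trial_index=i + 1, cue=c
                    )
                    for i, c in enumerate(cues)
                ]
            )

    training_block("training", N_TRAINING_SESSIONS)
    testing_block(1)
    training_block("washout", N_WASHOUT_SESSIONS)
    testing_block(2)
    plan.validate()
    return plan
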