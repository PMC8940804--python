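"""Deterministic scores and transforms for JBT trial logs.

Covers the quantities every downstream analysis consumes:

* remaining latency ``1 - latency/90`` (NoGo -> 0);
* correct/incorrect scoring of responses to the conditioned cues
  (Go within 20 s at P; NoGo at N);
* the training criterion (>= 13 correct out of 14 trials over two
  consecutive sessions) and learning speed (session index of attainment,
  coded 9 when never reached);
* per-cow adjusted latencies rescaling mean P to 0 and mean N to 1
  (removes between-cow walking-speed differences);
* the signed-area statistic SA: the dominant area between the observed
  adjusted-latency curve over (P, Ap, A, An, N) and the linear unbiased
  baseline, signed positive when the observed curve sits above the baseline
  (pessimistic) and negative when below (optimistic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from cowjbt.schedule import AMBIGUOUS_CUES, CUES, TRIALS_PER_SESSION

#: Trial ceiling in seconds; a NoGo is recorded at this value.
TRIAL_CEILING_S = 90.0
#: Go responses to P count as correct only when at most this fast (s).
GO_CORRECT_THRESHOLD_S = 20.0
#: Training criterion: >= 13 correct of 14 over two consecutive sessions.
CRITERION_CORRECT = 13
CRITERION_TRIALS = 2 * TRIALS_PER_SESSION
#: Learning-speed code for cows that never reach the criterion.
UNTRAINED_CODE = 9

#: Normalised cue positions on the P -> N axis (equal 1.6 m spacing).
CUE_POSITIONS = {"P": 0.0, "Ap": 0.25, "A": 0.5, "An": 0.75, "N": 1.0}


class NonDiscriminatingCowError(ValueError):
    """Mean latency to N does not exceed mean latency to P; adjusted
    latencies are undefined for this cow-period."""


@dataclass
class TrainingOutcome:
    """Per-cow training summary over the 8 sessions."""

    cow_id: str
    correct_counts: tuple[int, ...]
    trained: bool
    learning_speed: int


@dataclass
class CueProfile:
    """Per cow and testing period: mean and adjusted latency at each cue."""

    cow_id: str
    period: int
    mean_latency: dict[str, float]
    adjusted_latency: dict[str, float]


@dataclass
class SensitivityResult:
    """Signed-area decomposition for one cow in one testing period."""

    cow_id: str
    a_plus: float
    a_minus: float
    sa: float


def remaining_latency(latency_s):
    """Map a censored approach latency in (0, 90] to ``1 - latency/90``.

    A NoGo (latency 90) maps to exactly 0; fast approaches map near 1.
    Accepts scalars or arrays.
    """
    lat = np.asarray(latency_s, dtype=float)
    if np.any(lat <= 0) or np.any(lat > TRIAL_CEILING_S):
        raise ValueError("latency must lie in (0, 90] seconds")
    out = 1.0 - lat / TRIAL_CEILING_S
    return float(out) if np.isscalar(latency_s) or out.ndim == 0 else out


def score_correct(cue: str, response: str, latency_s: float) -> int:
    """Score one conditioned-cue trial as correct (1) or incorrect (0).

    P: correct iff a Go within 20 s.  N: correct iff a NoGo.  Ambiguous
    cues are never scored and raise ``ValueError``.
    """
    if cue in AMBIGUOUS_CUES:
        raise ValueError("ambiguous trials are not scored correct/incorrect")
    if cue not in ("P", "N"):
        raise ValueError(f"unknown cue {cue!r}")
    if response not in ("go", "nogo"):
        raise ValueError(f"unknown response {response!r}")
    if cue == "P":
        return int(response == "go" and latency_s <= GO_CORRECT_THRESHOLD_S)
    return int(response == "nogo")


def learning_speed(correct_counts: Sequence[int]) -> int:
    """Sessions needed to reach the training criterion; 9 when never reached.

    ``correct_counts`` holds the per-session number of correct responses
    (0-7) over the 8 training sessions.  The criterion is at least 13
    correct over two consecutive sessions; the returned speed is the
    1-based index of the second session of the earliest qualifying pair.
    """
    counts = list(correct_counts)
    if len(counts) != 8:
        raise ValueError("expected correct counts for exactly 8 training sessions")
    for c in counts:
        if not 0 <= int(c) <= TRIALS_PER_SESSION or int(c) != c:
            raise ValueError(f"per-session correct count must be an integer 0..7, got {c!r}")
    for i in range(len(counts) - 1):
        if counts[i] + counts[i + 1] >= CRITERION_CORRECT:
            return i + 2
    return UNTRAINED_CODE


def adjusted_latencies(mean_latency: Mapping[str, float]) -> dict[str, float]:
    """Rescale one cow-period's mean latencies so P -> 0 and N -> 1.

    ``adjusted(cue) = (lat(cue) - lat(P)) / (lat(N) - lat(P))``.  Values for
    ambiguous cues may fall below 0 or above 1.  Raises
    :class:`NonDiscriminatingCowError` when mean N latency does not exceed
    mean P latency (the rescaling is then undefined).
    """
    if "P" not in mean_latency or "N" not in mean_latency:
        raise ValueError("mean latencies must include the conditioned cues P and N")
    lat_p = float(mean_latency["P"])
    lat_n = float(mean_latency["N"])
    if not lat_n > lat_p:
        raise NonDiscriminatingCowError(
            f"mean latency to N ({lat_n:.3g}) must exceed mean latency to P ({lat_p:.3g})"
        )
    return {
        cue: (float(v) - lat_p) / (lat_n - lat_p) for cue, v in mean_latency.items()
    }


def area_decomposition(adjusted_ambiguous: Sequence[float]) -> tuple[float, float]:
    """Positive and negative area between the observed curve and the baseline.

    The observed curve is piecewise linear through (0, 0), (0.25, v_Ap),
    (0.5, v_A), (0.75, v_An), (1, 1); the unbiased baseline is the identity
    line.  Segments are split at sign crossings and each part integrated by
    the trapezoid rule, so both returned areas are nonnegative.
    """
    v = [float(x) for x in adjusted_ambiguous]
    if len(v) != 3:
        raise ValueError("expected adjusted values at (Ap, A, An)")
    if not all(np.isfinite(v)):
        raise ValueError("adjusted values must be finite")
    xs = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    diff = np.array([0.0, *v, 1.0]) - xs  # observed minus baseline at the knots
    a_plus = 0.0
    a_minus = 0.0
    for i in range(len(xs) - 1):
        d0, d1 = diff[i], diff[i + 1]
        w = xs[i + 1] - xs[i]
        if d0 * d1 >= 0:  # no crossing inside the segment
            area = 0.5 * (abs(d0) + abs(d1)) * w
            if d0 + d1 > 0:
                a_plus += area
            elif d0 + d1 < 0:
                a_minus += area
        else:  # split at the root of the linear difference
            t = d0 / (d0 - d1)
            first = 0.5 * abs(d0) * t * w
            second = 0.5 * abs(d1) * (1.0 - t) * w
            if d0 > 0:
                a_plus += first
                a_minus += second
            else:
                a_minus += first
                a_plus += second
    return a_plus, a_minus


def signed_area(a_plus: float, a_minus: float) -> float:
    """Signed magnitude of the dominant area.

    ``+a_plus`` when the pessimistic (above-baseline) area dominates,
    ``-a_minus`` when the optimistic area dominates; ties take the positive
    branch.  Positive SA thus indicates a punisher-driven negative
    judgement bias.
    """
    if a_plus < 0 or a_minus < 0:
        raise ValueError("areas must be nonnegative")
    return float(a_plus) if a_plus >= a_minus else -float(a_minus)


def sensitivity_result(cow_id: str, adjusted: Mapping[str, float]) -> SensitivityResult:
    """Convenience wrapper: areas and SA from a cow's adjusted profile."""
    a_plus, a_minus = area_decomposition([adjusted[c] for c in AMBIGUOUS_CUES])
    return SensitivityResult(cow_id=cow_id, a_plus=a_plus, a_minus=a_minus, sa=signed_area(a_plus, a_minus))


def cue_profile(cow_id: str, period: int, trials) -> CueProfile:
    """Build a :class:`CueProfile` from one cow-period's testing trials.

    ``trials`` is a DataFrame (or mapping of columns) with ``cue`` and
    ``latency_s`` for the period's two testing sessions.  NoGo trials enter
    the means at the 90 s ceiling, which is how they are recorded.
    """
    import pandas as pd

    df = pd.DataFrame(trials)
    means = df.groupby("cue")["latency_s"].mean()
    missing = [c for c in CUES if c not in means.index]
    if missing:
        raise ValueError(f"cow {cow_id} period {period}: no trials at cue(s) {missing}")
    mean_latency = {c: float(means[c]) for c in CUES}
    adjusted = adjusted_latencies(mean_latency)
    return CueProfile(cow_id=str(cow_id), period=int(period), mean_latency=mean_latency, adjusted_latency=adjusted)
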