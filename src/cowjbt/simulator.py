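"""Generalisation-gradient cow agent and cohort simulator.

Each synthetic cow carries two Gaussian generalisation gradients on the
normalised spatial axis (P at x=0, N at x=1, ambiguous cues at 0.25, 0.5,
0.75, i.e. 1.6 m apart in the arena): an appetitive gradient of width
``sigma_P`` and salience ``V_P`` anchored at P, and an aversive gradient of
width ``sigma_N`` and salience ``V_N`` anchored at N.  The net approach
tendency at a cue is the difference of the two gradients; a logistic rule
on that tendency yields the Go/NoGo decision, and an affine map with
Gaussian noise yields the approach latency, censored at the 90 s trial
ceiling (a cow that does not reach the feeder within 90 s is a NoGo by
definition, recorded at 90 s).

Simple session-level conditioning makes the training criterion reachable:
every punished approach to N multiplies the aversive salience by
``1 + eta_V``, and each completed training session sharpens both gradients
by the factor ``1 - eta_sigma`` down to a floor.  Ambiguous cues are never
reinforced and trigger no update; testing sessions leave the agent
unchanged.

The three punisher presets differ in the strength and persistence of the
aversive gradient: NOTH (no reward + time-out) leaves ``V_N`` low, so the
approach response stays invigorated everywhere; AIR (air puff) balances
the two gradients; ELEC (electric shock) drives ``V_N`` high with a wide,
floor-limited ``sigma_N``, reproducing the peak-shift-like suppression of
approaches that spreads toward P.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from cowjbt.schedule import (
    AMBIGUOUS_CUES,
    ExperimentPlan,
    generate_experiment_plan,
)
from cowjbt.scoring import CUE_POSITIONS, TRIAL_CEILING_S

PUNISHERS = ("NOTH", "AIR", "ELEC")

#: Physical layout metadata (m): adjacent cues and ambiguous-cue distance.
ADJACENT_CUE_SPACING_M = 1.6
AMBIGUOUS_DISTANCE_FROM_START_M = 6.40

#: Columns of the trial-log table, in serialisation order.
TRIAL_COLUMNS = (
    "cow_id",
    "group_id",
    "punisher",
    "batch",
    "phase",
    "period",
    "session",
    "trial",
    "cue",
    "response",
    "latency_s",
)


@dataclass
class CowAgentParams:
    """State of one synthetic cow.

    Gradient widths are on the normalised cue axis; saliences are in
    tendency units; ``theta`` is the Go threshold and ``beta_dec`` the
    decision steepness; latency is ``L0 - k_lat * tendency`` seconds plus
    Gaussian noise of sd ``sd_lat``, clipped to [1, 90].
    """

    sigma_P: float
    sigma_N: float
    V_P: float
    V_N: float
    beta_dec: float
    theta: float
    L0: float
    k_lat: float
    sd_lat: float
    eta_V: float = 0.0
    eta_sigma: float = 0.0
    sigma_floor: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma_P <= 0 or self.sigma_N <= 0 or self.sigma_floor <= 0:
            raise ValueError("gradient widths and floor must be positive")
        if self.V_P < 0 or self.V_N < 0:
            raise ValueError("saliences must be nonnegative")
        if self.beta_dec <= 0:
            raise ValueError("decision steepness must be positive")
        if self.sd_lat < 0:
            raise ValueError("latency noise sd must be nonnegative")
        for name in ("eta_V", "eta_sigma"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")


def approach_tendency(params: CowAgentParams, x: float) -> float:
    """Net approach tendency T(x) at normalised cue position x.

    ``T(x) = V_P exp(-x^2 / 2 sigma_P^2) - V_N exp(-(x-1)^2 / 2 sigma_N^2)``.
    """
    x = float(x)
    if not 0.0 <= x <= 1.0:
        raise ValueError("cue position must lie in [0, 1]")
    pull = params.V_P * np.exp(-(x**2) / (2.0 * params.sigma_P**2))
    push = params.V_N * np.exp(-((x - 1.0) ** 2) / (2.0 * params.sigma_N**2))
    return float(pull - push)


def simulate_trial(
    params: CowAgentParams, cue: str, rng: np.random.Generator
) -> tuple[str, float]:
    """One trial: Go/NoGo decision and censored latency.

    Go occurs with probability ``logistic(beta_dec (T - theta))``; the Go
    latency is ``L0 - k_lat T`` plus noise, clipped below at 1 s.  A draw
    reaching the 90 s ceiling means the cow did not arrive in time and is
    recorded as a NoGo at exactly 90 s.
    """
    t = approach_tendency(params, CUE_POSITIONS[cue])
    p_go = expit(params.beta_dec * (t - params.theta))
    if rng.random() < p_go:
        lat = params.L0 - params.k_lat * t + rng.normal(0.0, params.sd_lat)
        lat = float(np.clip(lat, 1.0, TRIAL_CEILING_S))
        if lat < TRIAL_CEILING_S:
            return "go", lat
    return "nogo", TRIAL_CEILING_S


def apply_session_learning(
    params: CowAgentParams, session_outcomes: Sequence[tuple[str, str]]
) -> CowAgentParams:
    """Update the agent after one completed training (or wash-out) session.

    ``session_outcomes`` holds ``(cue, response)`` pairs.  Each punished
    approach to N inflates the aversive salience multiplicatively; both
    gradients then sharpen by ``1 - eta_sigma`` down to ``sigma_floor``.
    Ambiguous trials never contribute (they are unreinforced).
    """
    v_n = params.V_N
    for cue, response in session_outcomes:
        if cue == "N" and response == "go":
            v_n *= 1.0 + params.eta_V
    shrink = 1.0 - params.eta_sigma
    return replace(
        params,
        V_N=v_n,
        sigma_P=max(params.sigma_floor, params.sigma_P * shrink),
        sigma_N=max(params.sigma_floor, params.sigma_N * shrink),
    )


@dataclass
class PunisherPreset:
    """Population distribution of agent parameters for one punisher arm.

    ``means`` holds the population means of the :class:`CowAgentParams`
    fields; ``cv`` the between-cow coefficient of variation applied to the
    gradient and salience parameters (truncated lognormal-free: Gaussian
    multiplicative jitter, floored at 10% of the mean).
    """

    means: dict
    cv: float = 0.15

    def draw(self, rng: np.random.Generator) -> CowAgentParams:
        jittered = dict(self.means)
        for key in ("sigma_P", "sigma_N", "V_P", "V_N", "eta_V"):
            m = jittered[key]
            if m > 0:
                jittered[key] = max(0.1 * m, rng.normal(m, self.cv * m))
        jittered["eta_V"] = min(jittered["eta_V"], 0.95)  # learning rate stays in [0, 1)
        return CowAgentParams(**jittered)


def default_presets() -> dict[str, PunisherPreset]:
    """Committed punisher presets.

    Calibrated once by coarse search so that the simulated cohorts show the
    qualitative contrasts of the real arms -- NoGo rates ordered
    NOTH < AIR < ELEC, per-arm trained fractions between roughly 50% and
    90%, near-linear AIR profiles and N-shifted ELEC profiles -- with all
    knobs surfaced here.
    """
    base = dict(
        sigma_P=0.45,
        V_P=1.0,
        beta_dec=5.0,
        theta=0.05,
        L0=21.0,
        k_lat=14.0,
        sd_lat=5.0,
        eta_sigma=0.04,
        sigma_floor=0.35,
    )
    return {
        # weak punisher: aversion stays low, approaches invigorated
        "NOTH": PunisherPreset(
            means=dict(base, sigma_N=0.45, V_N=0.06, eta_V=0.10), cv=0.25
        ),
        # balanced punisher: gradients roughly symmetric once trained
        "AIR": PunisherPreset(
            means=dict(base, sigma_N=0.45, V_N=0.10, eta_V=0.18), cv=0.25
        ),
        # strong punisher: high initial salience, wide aversive gradient that
        # never sharpens (coarse discrimination under severe threat)
        "ELEC": PunisherPreset(
            means=dict(base, sigma_N=0.60, V_N=0.30, eta_V=0.70, eta_sigma=0.0, sd_lat=6.0),
            cv=0.30,
        ),
    }


def simulate_cow(
    cow_id: str,
    group_id: str,
    punisher: str,
    batch: int,
    params: CowAgentParams,
    rng: np.random.Generator,
    plan: Optional[ExperimentPlan] = None,
) -> list[dict]:
    """Run one cow through a full experiment plan; returns trial-log rows."""
    if plan is None:
        plan = generate_experiment_plan(cow_id, rng)
    rows = []
    state = params
    for session in plan.sessions:
        outcomes = []
        for spec in session:
            response, latency = simulate_trial(state, spec.cue, rng)
            outcomes.append((spec.cue, response))
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
                    "latency_s": round(latency, 2),
                }
            )
        if session[0].phase in ("training", "washout"):
            state = apply_session_learning(state, outcomes)
    return rows


def simulate_cohort(
    n_per_arm: int,
    presets: Optional[Mapping[str, PunisherPreset]] = None,
    rng_seed=0,
    n_batches: int = 2,
) -> pd.DataFrame:
    """Simulate a full cohort trial log.

    ``n_per_arm`` cows per punisher arm, organised in groups of three (one
    cow per punisher, mirroring the barn's test groups, so the Friedman
    analysis can block on group), groups split across ``n_batches``
    experimental batches.  Returns a tidy DataFrame with one row per trial
    (``n_per_arm * 3 * 105`` rows).
    """
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be >= 1")
    if presets is None:
        presets = default_presets()
    missing = [p for p in PUNISHERS if p not in presets]
    if missing:
        raise ValueError(f"presets missing punisher arm(s): {missing}")
    root = np.random.SeedSequence(rng_seed)
    cow_seeds = root.spawn(n_per_arm * len(PUNISHERS))
    rows: list[dict] = []
    idx = 0
    for g in range(1, n_per_arm + 1):
        group_id = f"G{g:02d}"
        batch = 1 + (g - 1) % n_batches
        for punisher in PUNISHERS:
            rng = np.random.default_rng(cow_seeds[idx])
            idx += 1
            cow_id = f"{punisher[0]}{g:02d}"
            params = presets[punisher].draw(rng)
            rows.extend(
                simulate_cow(cow_id, group_id, punisher, batch, params, rng)
            )
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
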