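"""The four JBT evaluation analyses over a trial log.

:class:`JudgementBiasAnalysis` is the front door: build it from a
validated trial log (simulated or observed) and call

* :meth:`~JudgementBiasAnalysis.feasibility` -- learning success
  (trained proportions with a Freeman-Halton exact test, learning speeds
  with a group-blocked Friedman test) and contingency learning (binary
  correct-response GLMM and hurdle beta GLMM on remaining latencies, with
  Wald tests and Bonferroni-corrected pairwise contrasts of marginal
  means);
* :meth:`~JudgementBiasAnalysis.validity_sensitivity` -- adjusted-latency
  profiles of trained cows in one testing period, signed-rank tests
  between adjacent cues (overall) and A-vs-P / A-vs-N per punisher, the
  per-cow signed area SA, and rank-sum comparisons of SA and of
  per-ambiguous-cue adjusted latencies between punisher arms;
* :meth:`~JudgementBiasAnalysis.repeatability` -- paired signed-rank
  tests and Spearman correlations of adjusted latencies between the two
  testing periods, per punisher and ambiguous cue, with null-variance
  cells reported as unavailable;
* :meth:`~JudgementBiasAnalysis.run_all` -- all sections plus a
  provenance block, as one JSON-serialisable report.

Every section accounts for its exclusions explicitly:
``cows_in == cows_analysed + cows_excluded`` with reasons.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from cowjbt import io as jio
from cowjbt.glmm import HurdleBetaModel, MixedLogit
from cowjbt.nonparam import (
    TestResult,
    fisher_freeman_halton,
    friedman_block,
    spearman_safe,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)
from cowjbt.schedule import AMBIGUOUS_CUES, CUES
from cowjbt.scoring import (
    CUE_POSITIONS,
    NonDiscriminatingCowError,
    TrainingOutcome,
    cue_profile,
    learning_speed,
    remaining_latency,
    score_correct,
    sensitivity_result,
)
from cowjbt.simulator import PUNISHERS

logger = logging.getLogger("cowjbt")

ADJACENT_PAIRS = tuple(zip(CUES[:-1], CUES[1:]))  # (P,Ap), (Ap,A), (A,An), (An,N)


@dataclass
class AnalysisConfig:
    """Thresholds and labels of the analysis pipeline."""

    alpha_sig: float = 0.05
    alpha_tend: float = 0.10
    go_correct_threshold_s: float = 20.0
    trial_ceiling_s: float = 90.0
    criterion_correct: int = 13
    criterion_trials: int = 14
    criterion_consecutive_sessions: int = 2
    cue_positions: dict = field(default_factory=lambda: dict(CUE_POSITIONS))
    punishers: tuple = PUNISHERS
    rng_seed: int = 0
    nogo_interaction: bool = False

    def __post_init__(self):
        if self.go_correct_threshold_s <= 0 or self.trial_ceiling_s <= 0:
            raise ValueError("thresholds must be positive")
        if self.criterion_correct > self.criterion_trials:
            raise ValueError("criterion numerator cannot exceed its denominator")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "punishers" in raw:
            raw["punishers"] = tuple(raw["punishers"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["punishers"] = list(d["punishers"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _num(x):
    """Cast numpy scalars for JSON."""
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    return x


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, TestResult):
        return _jsonable(obj.as_dict())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict("records"))
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return _num(obj)


class JudgementBiasAnalysis:
    """All four evaluation analyses over one validated trial log."""

    def __init__(self, trials: pd.DataFrame, config: Optional[AnalysisConfig] = None):
        self.config = config or AnalysisConfig()
        self.trials = jio.validate_trials(trials)
        self.trials["cow_session"] = (
            self.trials["cow_id"]
            + "/"
            + self.trials["phase"].str[0]
            + self.trials["period"].astype(str)
            + "s"
            + self.trials["session"].astype(str)
        )
        self._training_outcomes: Optional[dict[str, TrainingOutcome]] = None

    @classmethod
    def from_csv(cls, path, config: Optional[AnalysisConfig] = None) -> "JudgementBiasAnalysis":
        return cls(jio.read_trials(path), config)

    @classmethod
    def from_dataframe(cls, trials, config=None) -> "JudgementBiasAnalysis":
        return cls(pd.DataFrame(trials), config)

    # -- helpers -------------------------------------------------------------

    @property
    def cow_table(self) -> pd.DataFrame:
        return (
            self.trials.groupby("cow_id")
            .agg(punisher=("punisher", "first"), group_id=("group_id", "first"), batch=("batch", "first"))
            .reset_index()
        )

    def training_outcomes(self) -> dict[str, TrainingOutcome]:
        """Per-cow correct counts, trained flag and learning speed.

        Cows without the full 8 x 7 training trials are skipped with a
        warning (they cannot be scored against the criterion).
        """
        if self._training_outcomes is not None:
            return self._training_outcomes
        out: dict[str, TrainingOutcome] = {}
        tr = self.trials[self.trials["phase"] == "training"]
        for cow, sub in tr.groupby("cow_id"):
            if len(sub) != 56:
                warnings.warn(f"cow {cow}: incomplete training ({len(sub)} trials), excluded")
                continue
            counts = (
                sub.assign(
                    correct=[
                        score_correct(r.cue, r.response, r.latency_s) for r in sub.itertuples()
                    ]
                )
                .groupby("session")["correct"]
                .sum()
                .reindex(range(1, 9), fill_value=0)
                .astype(int)
                .tolist()
            )
            speed = learning_speed(counts)
            out[cow] = TrainingOutcome(
                cow_id=cow, correct_counts=tuple(counts), trained=speed < 9, learning_speed=speed
            )
        self._training_outcomes = out
        return out

    def trained_cows(self) -> list[str]:
        return [c for c, o in self.training_outcomes().items() if o.trained]

    def _profiles(self, period: int, cows: list[str]):
        """Cue profiles for a testing period; returns (profiles, excluded)."""
        te = self.trials[(self.trials["phase"] == "testing") & (self.trials["period"] == period)]
        profiles = {}
        excluded = []
        for cow in cows:
            sub = te[te["cow_id"] == cow]
            if sub.empty or set(CUES) - set(sub["cue"]):
                excluded.append({"cow_id": cow, "reason": f"missing testing trials in period {period}"})
                continue
            try:
                profiles[cow] = cue_profile(cow, period, sub[["cue", "latency_s"]])
            except NonDiscriminatingCowError:
                excluded.append(
                    {"cow_id": cow, "reason": "non-discriminating (mean N latency <= mean P latency)"}
                )
                logger.warning("cow %s period %d: non-discriminating, excluded", cow, period)
        return profiles, excluded

    def _model_frame(self) -> pd.DataFrame:
        """Training-phase conditioned trials with model covariates."""
        tr = self.trials[self.trials["phase"] == "training"].copy()
        tr["correct"] = [score_correct(r.cue, r.response, r.latency_s) for r in tr.itertuples()]
        tr["remaining"] = remaining_latency(tr["latency_s"].to_numpy())
        tr["batch"] = tr["batch"].astype(str)
        return tr

    # -- sections ------------------------------------------------------------

    def feasibility(self, fit_models: bool = True) -> dict:
        """Learning success and contingency learning during training."""
        outcomes = self.training_outcomes()
        cows = self.cow_table
        all_cows = cows["cow_id"].tolist()
        excluded = [
            {"cow_id": c, "reason": "incomplete training data"}
            for c in all_cows
            if c not in outcomes
        ]
        analysed = [c for c in all_cows if c in outcomes]
        pun = cows.set_index("cow_id")["punisher"]
        grp = cows.set_index("cow_id")["group_id"]

        trained_table = []
        for p in self.config.punishers:
            arm = [c for c in analysed if pun[c] == p]
            n_trained = sum(outcomes[c].trained for c in arm)
            trained_table.append(
                {"punisher": p, "trained": n_trained, "untrained": len(arm) - n_trained}
            )
        counts = [[row["trained"], row["untrained"]] for row in trained_table]
        fisher = fisher_freeman_halton(counts)

        speeds = pd.DataFrame(
            {
                "cow_id": analysed,
                "punisher": [pun[c] for c in analysed],
                "group_id": [grp[c] for c in analysed],
                "learning_speed": [outcomes[c].learning_speed for c in analysed],
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            friedman = friedman_block(
                speeds["learning_speed"], speeds["punisher"], speeds["group_id"]
            )

        section = {
            "cows_in": len(all_cows),
            "cows_analysed": len(analysed),
            "excluded": excluded,
            "trained_by_punisher": trained_table,
            "fisher_freeman_halton": fisher,
            "learning_speed_by_punisher": {
                p: {
                    "mean": float(speeds.loc[speeds.punisher == p, "learning_speed"].mean()),
                    "iqr": float(
                        speeds.loc[speeds.punisher == p, "learning_speed"].quantile(0.75)
                        - speeds.loc[speeds.punisher == p, "learning_speed"].quantile(0.25)
                    ),
                }
                for p in self.config.punishers
            },
            "friedman_learning_speed": friedman,
            "learning_speeds": speeds.to_dict("records"),
        }

        if fit_models:
            frame = self._model_frame()
            frame = frame[frame["cow_id"].isin(analysed)]
            binary = MixedLogit.from_dataframe(
                frame,
                "correct",
                ["batch", "punisher", "cue"],
                ["group_id", "cow_id", "cow_session"],
                interactions=[("punisher", "cue")],
            ).fit()
            hurdle = HurdleBetaModel(
                frame, response="remaining", zero_interaction=self.config.nogo_interaction
            ).fit()
            section["binary_correct_glmm"] = self._glmm_section(binary, interaction=True)
            section["hurdle_glmm"] = {
                "nogo_part": self._glmm_section(
                    hurdle.nogo, interaction=self.config.nogo_interaction
                ),
                "positive_part": self._glmm_section(hurdle.positive, interaction=True),
                "loglik": hurdle.llf,
            }
        return section

    def _glmm_section(self, res, interaction: bool) -> dict:
        sec = {
            "coefficients": [
                {"name": n, "estimate": float(b), "se": float(s)}
                for n, b, s in zip(res.exog_names, res.params, res.bse)
            ],
            "variance_components_sd": res.vc,
            "loglik": res.llf,
            "converged": res.converged,
        }
        if res.phi is not None:
            sec["phi"] = res.phi
        for term in ("punisher", "cue") + (("punisher:cue",) if interaction else ()):
            try:
                w = res.wald_test(term)
                sec[f"wald_{term.replace(':', '_x_')}"] = {
                    "chi2": w.chi2,
                    "df": w.df,
                    "p_value": w.p_value,
                }
            except KeyError:
                pass
        if interaction:
            # punisher contrasts within each cue type, as in the cue-level
            # pairwise comparisons of the training analyses
            sec["emm_punisher_within_cue"] = {
                cue: res.emm_pairwise("punisher", within=("cue", cue)) for cue in ("P", "N")
            }
        else:
            sec["emm_punisher"] = res.emm_pairwise("punisher")
        return sec

    def validity_sensitivity(self, period: int = 1) -> dict:
        """Internal validity and sensitivity over one testing period.

        Analyses are restricted to cows that met the training criterion.
        """
        trained = self.trained_cows()
        profiles, excluded = self._profiles(period, trained)
        pun = self.cow_table.set_index("cow_id")["punisher"]

        adj = pd.DataFrame({c: p.adjusted_latency for c, p in profiles.items()}).T
        # overall adjacent-cue discrimination, all punishers combined
        adjacent = {}
        for a, b in ADJACENT_PAIRS:
            adjacent[f"{a}_vs_{b}"] = wilcoxon_signed_rank((adj[a] - adj[b]).to_numpy())
        # per punisher: truly ambiguous cue against the conditioned anchors
        per_punisher = {}
        for p in self.config.punishers:
            cows_p = [c for c in profiles if pun[c] == p]
            sub = adj.loc[cows_p]
            per_punisher[p] = {
                "n": len(cows_p),
                "mean_adjusted": {c: float(sub[c].mean()) if len(sub) else None for c in CUES},
                "A_vs_P": wilcoxon_signed_rank((sub["A"] - sub["P"]).to_numpy())
                if len(sub)
                else None,
                "A_vs_N": wilcoxon_signed_rank((sub["A"] - sub["N"]).to_numpy())
                if len(sub)
                else None,
            }

        sens = {c: sensitivity_result(c, p.adjusted_latency) for c, p in profiles.items()}
        sa = pd.Series({c: s.sa for c, s in sens.items()}, dtype=float)
        sa_by_arm = {p: sa[[c for c in sa.index if pun[c] == p]] for p in self.config.punishers}
        sa_tests = {}
        cue_tests = {c: {} for c in AMBIGUOUS_CUES}
        for pa, pb in combinations(self.config.punishers, 2):
            key = f"{pa}_vs_{pb}"
            if len(sa_by_arm[pa]) and len(sa_by_arm[pb]):
                sa_tests[key] = wilcoxon_rank_sum(
                    sa_by_arm[pa].to_numpy(), sa_by_arm[pb].to_numpy()
                )
                for cue in AMBIGUOUS_CUES:
                    cue_tests[cue][key] = wilcoxon_rank_sum(
                        adj.loc[sa_by_arm[pa].index, cue].to_numpy(),
                        adj.loc[sa_by_arm[pb].index, cue].to_numpy(),
                    )

        return {
            "period": period,
            "cows_in": len(trained),
            "cows_analysed": len(profiles),
            "excluded": excluded,
            "adjusted_latency_by_cow": {
                c: {cue: float(v) for cue, v in p.adjusted_latency.items()}
                for c, p in profiles.items()
            },
            "adjacent_cue_tests": adjacent,
            "per_punisher": per_punisher,
            "sensitivity_by_cow": {
                c: {"a_plus": s.a_plus, "a_minus": s.a_minus, "sa": s.sa}
                for c, s in sens.items()
            },
            "sa_by_punisher": {
                p: {"mean": float(v.mean()) if len(v) else None, "n": len(v)}
                for p, v in sa_by_arm.items()
            },
            "sa_rank_sum_tests": sa_tests,
            "adjusted_latency_rank_sum_tests": cue_tests,
        }

    def repeatability(self) -> dict:
        """Between-period stability of responses to the ambiguous cues."""
        trained = self.trained_cows()
        prof1, exc1 = self._profiles(1, trained)
        prof2, exc2 = self._profiles(2, trained)
        paired = sorted(set(prof1) & set(prof2))
        excluded = [e for e in exc1 + exc2 if e["cow_id"] not in paired]
        pun = self.cow_table.set_index("cow_id")["punisher"]

        by_punisher = {}
        for p in self.config.punishers:
            cows_p = [c for c in paired if pun[c] == p]
            cues = {}
            for cue in AMBIGUOUS_CUES:
                v1 = np.array([prof1[c].adjusted_latency[cue] for c in cows_p])
                v2 = np.array([prof2[c].adjusted_latency[cue] for c in cows_p])
                cues[cue] = {
                    "n": len(cows_p),
                    "period_means": [
                        float(v1.mean()) if len(v1) else None,
                        float(v2.mean()) if len(v2) else None,
                    ],
                    "signed_rank": wilcoxon_signed_rank(v2 - v1) if len(cows_p) else None,
                    "spearman": spearman_safe(v1, v2) if len(cows_p) >= 3 else None,
                }
            by_punisher[p] = cues
        return {
            "cows_in": len(trained),
            "cows_analysed": len(paired),
            "excluded": excluded,
            "by_punisher": by_punisher,
        }

    # -- full report ---------------------------------------------------------

    def run_all(self, fit_models: bool = True) -> dict:
        from cowjbt import __version__

        cfg = asdict(self.config)
        cfg["punishers"] = list(cfg["punishers"])
        cfg_hash = hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]
        report = {
            "provenance": {
                "package": "cowjbt",
                "version": __version__,
                "config": cfg,
                "config_sha256": cfg_hash,
                "n_trials": int(len(self.trials)),
                "n_cows": int(self.trials["cow_id"].nunique()),
            },
            "feasibility": self.feasibility(fit_models=fit_models),
            "validity_sensitivity": self.validity_sensitivity(period=1),
            "repeatability": self.repeatability(),
        }
        return _jsonable(report)

    def save_report(self, path, fit_models: bool = True) -> dict:
        report = self.run_all(fit_models=fit_models)
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(report, indent=2))
        return report
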