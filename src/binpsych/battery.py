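"""The two-session test protocol for one simulated participant.

Session 1 runs IPD FL, ILD JND (three interleaved rove conditions),
IPD JND, IPD FL; session 2 runs IPD FL, INT JND, IPD JND, IPD FL.  The
IPD FL is therefore measured four times and the IPD JND twice.  Every
measurement is preceded by its training runs (an adaptive 15-trial ILD
run at 500 Hz plus a 10-trial task run before each FL measurement; a
10-trial run before each IPD JND / INT measurement; a 6-trial No Rove
run plus three interleaved 10-trial runs before the ILD battery).
Training runs are recorded but never contribute to the fitted data.

Practice effects are modelled as multiplicative shifts of the
participant's true threshold per measurement index, normalised to mean
1 so that the participant's trait value equals the across-measurement
mean.  Default trajectories are calibrated to the least-squares means
745/756/812/833 Hz (FL; performance improves, the limit rises) and
35/22 deg (IPD JND; the JND falls).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adaptive import ILD_CONDITIONS, make_grid, run_interleaved_ild, run_procedure
from .observers import ObserverModel
from .psychometrics import pf_from_threshold

__all__ = [
    "SessionPlan",
    "ParticipantSpec",
    "MeasurementRecord",
    "BatteryResult",
    "run_battery",
    "DEFAULT_PRACTICE",
]

SESSION_PLAN = (
    ("ipd_fl", "ild_jnd", "ipd_jnd", "ipd_fl"),   # session 1
    ("ipd_fl", "int_jnd", "ipd_jnd", "ipd_fl"),   # session 2
)

# least-squares-mean trajectories, normalised to mean 1.0
_FL_LSMEANS = np.array([745.0, 756.0, 812.0, 833.0])
_JND_LSMEANS = np.array([35.0, 22.0])
DEFAULT_PRACTICE = {
    "ipd_fl": tuple(_FL_LSMEANS / _FL_LSMEANS.mean()),
    "ipd_jnd": tuple(_JND_LSMEANS / _JND_LSMEANS.mean()),
}

_TASK_PF = {
    # kind -> (family, axis, slope_sign)
    "ipd_fl": ("logistic", "log2_frequency", -1),
    "ipd_jnd": ("logistic", "log_ipd", 1),
    "ild_jnd": ("weibull", "log_ild", 1),
    "int_jnd": ("weibull", "log_increment", 1),
}


@dataclass(frozen=True)
class SessionPlan:
    sessions: tuple = SESSION_PLAN
    fl_ild_training_trials: int = 15
    fl_task_training_trials: int = 10
    jnd_training_trials: int = 10
    ild_norove_training_trials: int = 6
    ild_interleaved_training_trials: int = 10


@dataclass(frozen=True)
class ParticipantSpec:
    """True thresholds (natural units) plus observer and practice shape.

    ``ild_thresholds`` maps the three rove conditions to thresholds;
    ``practice`` maps a task kind to per-measurement multiplicative
    factors; ``skips`` lists (kind, measurement_number) pairs that were
    not performed.
    """

    ipd_fl: float
    ipd_jnd: float
    ild_thresholds: dict
    int_jnd: float
    width_oct: float = 2.0
    lapse: float = 0.02
    practice: dict = field(default_factory=lambda: dict(DEFAULT_PRACTICE))
    skips: tuple = ()


@dataclass(frozen=True)
class MeasurementRecord:
    test: str
    condition: str           # rove condition, or "none"
    measurement: int         # 1-based measurement number
    estimate: float          # finalized value (NaN when skipped)
    flagged: bool
    skipped: bool = False
    raw_fit: float = float("nan")


@dataclass
class BatteryResult:
    records: list            # MeasurementRecord, measurement runs only
    training: list           # (test, condition, n_trials, reported value)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    def estimates(self, test: str) -> list:
        return [r for r in self.records if r.test == test and not r.skipped]


def _observer(spec: ParticipantSpec, kind: str, threshold: float) -> ObserverModel:
    family, axis, slope = _TASK_PF[kind]
    pf = pf_from_threshold(family, axis, threshold, spec.width_oct,
                           lapse=spec.lapse, slope_sign=slope)
    return ObserverModel("pf", pf=pf)


def _practice_factor(spec: ParticipantSpec, kind: str, measurement: int) -> float:
    factors = spec.practice.get(kind)
    if not factors:
        return 1.0
    return float(factors[min(measurement - 1, len(factors) - 1)])


def run_battery(participant: ParticipantSpec, seed,
                plan: SessionPlan = SessionPlan()) -> BatteryResult:
    """Execute the full protocol; a pure function of (participant, seed)."""
    for cond in ILD_CONDITIONS:
        if cond not in participant.ild_thresholds:
            raise ValueError(f"missing ILD threshold for condition {cond!r}")
    seedseq = np.random.SeedSequence(seed)
    next_seed = iter(s % (2**31) for s in seedseq.generate_state(64))

    counters = {k: 0 for k in _TASK_PF}
    records, training = [], []

    for session in plan.sessions:
        for kind in session:
            counters[kind] += 1
            meas = counters[kind]
            if (kind, meas) in set(participant.skips):
                records.append(MeasurementRecord(kind, "none", meas,
                                                 float("nan"), False, True))
                continue

            if kind == "ipd_fl":
                thr = participant.ipd_fl * _practice_factor(participant, kind, meas)
                obs = _observer(participant, kind, thr)
                # ILD-cue familiarisation at 500 Hz, then a short task run
                ild_obs = _observer(participant, "ild_jnd",
                                    participant.ild_thresholds["no_rove"])
                tr = run_procedure(
                    ild_obs,
                    make_grid("ild_jnd", n_trials=plan.fl_ild_training_trials),
                    int(next(next_seed)))
                training.append(("ipd_fl", "ild_training",
                                 plan.fl_ild_training_trials, tr.reported.value))
                tr = run_procedure(
                    obs, make_grid("ipd_fl", n_trials=plan.fl_task_training_trials),
                    int(next(next_seed)))
                training.append(("ipd_fl", "task_training",
                                 plan.fl_task_training_trials, tr.reported.value))
                run = run_procedure(obs, make_grid("ipd_fl"), int(next(next_seed)))
                records.append(MeasurementRecord(
                    kind, "none", meas, run.reported.value,
                    run.reported.flagged, raw_fit=run.fit.threshold75))

            elif kind == "ipd_jnd":
                thr = participant.ipd_jnd * _practice_factor(participant, kind, meas)
                obs = _observer(participant, kind, thr)
                tr = run_procedure(
                    obs, make_grid("ipd_jnd", n_trials=plan.jnd_training_trials),
                    int(next(next_seed)))
                training.append(("ipd_jnd", "task_training",
                                 plan.jnd_training_trials, tr.reported.value))
                run = run_procedure(obs, make_grid("ipd_jnd"), int(next(next_seed)))
                records.append(MeasurementRecord(
                    kind, "none", meas, run.reported.value,
                    run.reported.flagged, raw_fit=run.fit.threshold75))

            elif kind == "ild_jnd":
                observers = {
                    cond: _observer(participant, "ild_jnd",
                                    participant.ild_thresholds[cond])
                    for cond in ILD_CONDITIONS
                }
                tr = run_procedure(
                    observers["no_rove"],
                    make_grid("ild_jnd", n_trials=plan.ild_norove_training_trials),
                    int(next(next_seed)))
                training.append(("ild_jnd", "no_rove_training",
                                 plan.ild_norove_training_trials, tr.reported.value))
                tr_runs = run_interleaved_ild(
                    observers, int(next(next_seed)),
                    n_trials=plan.ild_interleaved_training_trials)
                for cond, res in tr_runs.items():
                    training.append(("ild_jnd", f"{cond}_training",
                                     plan.ild_interleaved_training_trials,
                                     res.reported.value))
                runs = run_interleaved_ild(observers, int(next(next_seed)))
                for cond in ILD_CONDITIONS:
                    res = runs[cond]
                    records.append(MeasurementRecord(
                        "ild_jnd", cond, meas, res.reported.value,
                        res.reported.flagged, raw_fit=res.fit.threshold75))

            elif kind == "int_jnd":
                obs = _observer(participant, kind, participant.int_jnd)
                tr = run_procedure(
                    obs, make_grid("int_jnd", n_trials=plan.jnd_training_trials),
                    int(next(next_seed)))
                training.append(("int_jnd", "task_training",
                                 plan.jnd_training_trials, tr.reported.value))
                run = run_procedure(obs, make_grid("int_jnd"), int(next(next_seed)))
                records.append(MeasurementRecord(
                    kind, "none", meas, run.reported.value,
                    run.reported.flagged, raw_fit=run.fit.threshold75))

    return BatteryResult(records, training)
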